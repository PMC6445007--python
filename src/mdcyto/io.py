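"""On-disk formats: TIFF stacks / PNG frame directories, feature CSVs
with JSON sidecars, ground-truth tables, YAML configs.

Frame sequences are written as multi-page 16-bit grayscale TIFF (one
page per frame) with the frame interval stored in the image-description
tag, or as a directory of zero-padded PNG frames with a small JSON
metadata file.  Feature tables are plain CSV (diff-able) plus a JSON
sidecar recording the registry version, window sizes and unit
conventions; missing values are empty fields, never zero.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import FrameSequence
from .errors import ConfigError, DataError
from .features import ROUGHNESS_WINDOW_DEG, SHAPE_WINDOW_DEG
from .registry import FEATURE_NAMES, registry_metadata

_U16 = 65535


def write_tiff(sequence: FrameSequence, path) -> Path:
    """One 16-bit page per frame; frame interval in the description tag."""
    path = Path(path)
    stack = np.clip(np.round(sequence.frames * _U16), 0, _U16).astype(
        np.uint16)
    desc = json.dumps({"frame_interval_us": sequence.frame_interval_us,
                       "cell_id": sequence.cell_id})
    tifffile.imwrite(path, stack, description=desc)
    return path


def read_tiff(path, frame_interval_us: float = None) -> FrameSequence:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    interval = frame_interval_us or meta.get("frame_interval_us")
    if interval is None:
        raise DataError(
            f"{path}: no frame_interval_us in metadata; pass it explicitly")
    if stack.ndim == 2:
        stack = stack[None]
    return FrameSequence(stack.astype(float) / _U16, float(interval),
                         cell_id=meta.get("cell_id") or path.stem)


def write_png_dir(sequence: FrameSequence, directory) -> Path:
    """Zero-padded PNG frames plus a meta.json with the frame interval."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.clip(np.round(sequence.frames * _U16), 0, _U16).astype(
        np.uint16)
    for i, frame in enumerate(stack):
        iio.imwrite(directory / f"frame_{i:05d}.png", frame)
    (directory / "meta.json").write_text(json.dumps(
        {"frame_interval_us": sequence.frame_interval_us,
         "cell_id": sequence.cell_id}))
    return directory


def read_png_dir(directory, frame_interval_us: float = None) -> FrameSequence:
    directory = Path(directory)
    files = sorted(directory.glob("frame_*.png"))
    if not files:
        raise DataError(f"{directory}: no frame_*.png files")
    meta = {}
    meta_path = directory / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    interval = frame_interval_us or meta.get("frame_interval_us")
    if interval is None:
        raise DataError(
            f"{directory}: no frame_interval_us metadata; pass it "
            "explicitly")
    frames = np.stack([iio.imread(f) for f in files]).astype(float)
    peak = frames.max()
    scale = _U16 if peak > 255 else (255 if peak > 1 else 1)
    return FrameSequence(frames / scale, float(interval),
                         cell_id=meta.get("cell_id") or directory.name)


def read_sequence(path, frame_interval_us: float = None) -> FrameSequence:
    """Dispatch on path type: .tif/.tiff file or a PNG frame directory."""
    path = Path(path)
    if path.is_dir():
        return read_png_dir(path, frame_interval_us)
    if path.suffix.lower() in (".tif", ".tiff"):
        return read_tiff(path, frame_interval_us)
    raise ConfigError(f"unsupported input {path}: expected a TIFF stack or "
                      "a PNG frame directory")


def find_sequences(root) -> list[Path]:
    """All TIFF stacks / PNG frame directories under a directory."""
    root = Path(root)
    if not root.exists():
        raise ConfigError(f"input path does not exist: {root}")
    if root.is_file():
        return [root]
    seqs = sorted(root.glob("*.tif")) + sorted(root.glob("*.tiff"))
    seqs += sorted(d for d in root.iterdir()
                   if d.is_dir() and any(d.glob("frame_*.png")))
    if not seqs:
        raise ConfigError(f"no frame sequences found under {root}")
    return seqs


# ---------------------------------------------------------------------------
# feature tables

def feature_sidecar(extra: dict = None) -> dict:
    meta = registry_metadata()
    meta.update({
        "angular_bin_deg": 1,
        "roughness_window_deg": ROUGHNESS_WINDOW_DEG,
        "shape_window_deg": SHAPE_WINDOW_DEG,
        "units": {"length": "px", "time": "us"},
        "missing_value": "empty field",
    })
    if extra:
        meta.update(extra)
    return meta


def write_feature_table(table: pd.DataFrame, path, extra_meta: dict = None):
    """CSV + JSON sidecar; column order is validated against the registry."""
    path = Path(path)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise DataError(f"feature table lacks registry columns: {missing}")
    table.to_csv(path, index=False, na_rep="")
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(feature_sidecar(extra_meta), indent=2,
                                  sort_keys=True))
    return path


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"feature table not found: {path}")
    return pd.read_csv(path)


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: YAML root must be a mapping")
    return data


def dump_yaml(data: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
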