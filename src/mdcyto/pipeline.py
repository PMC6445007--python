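"""End-to-end pipeline: simulate/ingest -> extract -> featurize ->
classify -> embed, driven by one YAML config.

Every run echoes its resolved config (with a content hash) next to the
artifacts; rerunning the same config reproduces all CSV/JSON artifacts
byte-identically because every stage is seeded from the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .classify import compare_baseline_vs_full, forward_select
from .contour import build_trace
from .embedding import embed, recolor
from .errors import ConfigError, DataError
from .features import phenotype_table
from .registry import FEATURE_NAMES, validate_feature_names
from .synthetic import RenderConfig, generate_population

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "seed": 0,
    "out_dir": "mdc_out",
    "simulate": None,      # {n_cells_per_class, classes: {label: spec},
                           #  render: {...}, format: tiff|png}
    "input_frames": None,  # {label: path} of recorded sequences
    "features_csv": None,  # pre-extracted feature table
    "extract": {"entry_threshold": 0.05, "swap_axes": False},
    "classify": {"mode": "compare", "train_per_class": 5000,
                 "subset_per_class": 500, "folds": 5, "n_add": 5,
                 "label_col": "label"},
    "embed": {"perplexity": 30, "n_iter": 1000,
              "color_by": ["mean_diameter", "max_deformation",
                           "surface_roughness_5deg",
                           "mean_relaxation_rate"]},
}


def resolve_config(config: dict) -> dict:
    """Merge a user config over the defaults and validate its shape."""
    unknown = set(config) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {}
    for key, default in _DEFAULTS.items():
        value = config.get(key, default)
        if isinstance(default, dict) and value is not default:
            if not isinstance(value, dict):
                raise ConfigError(f"config section {key!r} must be a "
                                  "mapping")
            bad = set(value) - set(default)
            if bad:
                raise ConfigError(
                    f"unknown keys in config section {key!r}: {sorted(bad)}")
            merged[key] = {**default, **value}
        else:
            merged[key] = value
    sources = [k for k in ("simulate", "input_frames", "features_csv")
               if merged[k]]
    if not sources:
        raise ConfigError(
            "config needs one of: simulate, input_frames, features_csv")
    if merged["features_csv"] and not Path(merged["features_csv"]).exists():
        raise ConfigError(
            f"features_csv not found: {merged['features_csv']}")
    if merged["input_frames"]:
        for label, path in merged["input_frames"].items():
            if not Path(path).exists():
                raise ConfigError(
                    f"input_frames[{label!r}] not found: {path}")
    return merged


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _simulate_stage(cfg: dict, out_dir: Path, seed: int) -> pd.DataFrame:
    sim = cfg["simulate"]
    classes = sim.get("classes")
    if not classes or len(classes) < 1:
        raise ConfigError("simulate.classes must map label -> class spec")
    render_cfg = RenderConfig(**{**sim.get("render", {}), "seed": seed})
    n = int(sim.get("n_cells_per_class", 100))
    fmt = sim.get("format", "tiff")
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    gt_tables, feat_tables = [], []
    for j, (label, spec) in enumerate(sorted(classes.items())):
        seqs, gt = generate_population(
            n, spec or {}, render_cfg, seed=seed + 1000 * (j + 1),
            label=str(label))
        gt_tables.append(gt)
        for seq in seqs:
            if fmt == "png":
                mio.write_png_dir(seq, frames_dir / seq.cell_id)
            else:
                mio.write_tiff(seq, frames_dir / f"{seq.cell_id}.tif")
        feat = phenotype_table(seqs, label=str(label),
                               swap_axes=cfg["extract"]["swap_axes"])
        feat_tables.append(feat)
    pd.concat(gt_tables, ignore_index=True).to_csv(
        out_dir / "ground_truth.csv", index=False)
    return pd.concat(feat_tables, ignore_index=True)


def _ingest_stage(cfg: dict, out_dir: Path) -> pd.DataFrame:
    tables = []
    for label, path in sorted(cfg["input_frames"].items()):
        seq_paths = mio.find_sequences(path)
        seqs = [mio.read_sequence(p) for p in seq_paths]
        tables.append(phenotype_table(seqs, label=str(label),
                                      swap_axes=cfg["extract"]["swap_axes"]))
    return pd.concat(tables, ignore_index=True)


def _classify_stage(cfg: dict, features: pd.DataFrame, seed: int) -> dict:
    c = cfg["classify"]
    mode = c["mode"]
    if mode not in ("baseline", "full", "compare", "forward"):
        raise ConfigError(f"classify.mode {mode!r} not one of "
                          "baseline/full/compare/forward")
    report = {"mode": mode, "seed": seed}
    comparison = compare_baseline_vs_full(
        features, seed=seed, train_per_class=c["train_per_class"],
        subset_per_class=c["subset_per_class"], folds=c["folds"],
        label_col=c["label_col"])
    report["baseline_accuracy_pct"] = comparison.baseline_accuracy
    report["full_accuracy_pct"] = comparison.full_accuracy
    report["improvement_points"] = comparison.improvement_points
    report["baseline_params"] = list(comparison.baseline_params)
    report["full_params"] = list(comparison.full_params)
    if mode == "forward":
        sel = forward_select(
            features, n_add=c["n_add"], seed=seed,
            train_per_class=c["train_per_class"],
            subset_per_class=c["subset_per_class"], folds=c["folds"],
            label_col=c["label_col"])
        report["selected_features"] = sel.ordered_added_features
        report["accuracy_trajectory_pct"] = sel.accuracy_trajectory
    return report


def _embed_stage(cfg: dict, features: pd.DataFrame, out_dir: Path,
                 seed: int) -> dict:
    e = cfg["embed"]
    usable = features.dropna(subset=[c for c in FEATURE_NAMES
                                     if c in features.columns])
    perplexity = int(e["perplexity"])
    cap = max(len(usable) // 3 - 1, 2)
    if perplexity > cap:
        logger.warning("perplexity %d too large for %d rows; using %d",
                       perplexity, len(usable), cap)
        perplexity = cap
    emb = embed(usable, perplexity=perplexity, seed=seed,
                n_iter=int(e["n_iter"]))
    coords = emb.to_frame()
    if "label" in usable.columns:
        coords["label"] = usable["label"].to_numpy()
    coords_path = out_dir / "embedding_coords.csv"
    coords.to_csv(coords_path, index=False)
    plots = []
    for param in validate_feature_names(e["color_by"]):
        plot_path = out_dir / f"embedding_{param}.png"
        fig = recolor(emb, usable, param, out_path=plot_path)
        import matplotlib.pyplot as plt
        plt.close(fig)
        plots.append(str(plot_path))
    return {"coords": str(coords_path), "plots": plots,
            "perplexity": perplexity}


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute all configured stages; returns a manifest of artifacts."""
    cfg = resolve_config(config)
    out_dir = Path(out_dir or cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = config_hash(cfg)
    seed = int(cfg["seed"])
    mio.dump_yaml({**cfg, "config_hash": digest}, out_dir / "config.yaml")

    if cfg["features_csv"]:
        features = mio.read_feature_table(cfg["features_csv"])
    elif cfg["input_frames"]:
        features = _ingest_stage(cfg, out_dir)
    else:
        features = _simulate_stage(cfg, out_dir, seed)
    feat_path = out_dir / "features.csv"
    mio.write_feature_table(features, feat_path,
                            extra_meta={"config_hash": digest})
    if "qc_flags" in features.columns:
        qc = features[["cell_id", "qc_flags"]][
            features["qc_flags"].fillna("") != ""]
        qc.to_csv(out_dir / "qc_log.csv", index=False)

    report = _classify_stage(cfg, features, seed)
    report["config_hash"] = digest
    report_path = out_dir / "classification.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))

    emb_info = _embed_stage(cfg, features, out_dir, seed)

    manifest = {"config_hash": digest,
                "features": str(feat_path),
                "classification": str(report_path),
                "embedding": emb_info}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def extract_traces(input_path, out_dir, frame_interval_us=None,
                   swap_axes=False, entry_threshold=0.05) -> Path:
    """Extraction-only stage: per-cell trace CSVs plus a QC log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qc_rows = []
    for seq_path in mio.find_sequences(input_path):
        seq = mio.read_sequence(seq_path, frame_interval_us)
        cid = seq.cell_id
        try:
            res = build_trace(seq, swap_axes=swap_axes,
                              entry_threshold=entry_threshold)
        except DataError as exc:
            qc_rows.append({"cell_id": cid, "status": "failed",
                            "detail": str(exc)})
            continue
        tr = res.trace
        pd.DataFrame({
            "frame_index": res.frame_indices, "t_us": tr.t_us,
            "l_vertical": tr.l_vertical, "l_horizontal": tr.l_horizontal,
            "D": tr.D,
        }).to_csv(out_dir / f"{cid}_trace.csv", index=False)
        qc_rows.append({
            "cell_id": cid, "status": "ok",
            "detail": "|".join(res.flags) or "",
            "n_frames_used": len(tr.t_us),
            "n_frames_dropped": len(res.dropped),
            "reference_frame": int(res.frame_indices[res.reference_index]),
        })
        for idx, reason in res.dropped:
            qc_rows.append({"cell_id": cid, "status": "frame_dropped",
                            "detail": f"frame {idx}: {reason}"})
    qc_path = out_dir / "qc_log.csv"
    pd.DataFrame(qc_rows).to_csv(qc_path, index=False)
    return qc_path
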