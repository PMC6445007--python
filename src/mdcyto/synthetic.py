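"""Synthetic deforming-cell video generator with known ground truth.

The latent cell model is an area-preserving ellipse stretch decorated with
multiplicative cosine boundary modes:

    r(theta, t) = r_ell(theta; a(t), b(t)) * (1 + sum_k eps_k cos(k theta + phi_k))

with vertical semi-axis a(t) = r0 * sqrt(D(t)) and horizontal semi-axis
b(t) = r0 / sqrt(D(t)), so the unperturbed contour conserves area
(pi r0^2) and its vertical/horizontal extent ratio equals the aspect
ratio D(t) exactly.  Low harmonics (k = 2..4) model gross cell shape,
high harmonics (k = 8..24) model surface roughness; the split straddles
the 5-degree / 30-degree moving-average cutoffs of the morphology scores
so each score responds to its own ground-truth knob.

The deformation trace D(t) rises from a resting aspect ratio D0 to a peak
Dmax by a smoothstep, then decays monotonically toward
Dmax - relax_fraction * (Dmax - D0), emulating a cell entering the
extensional-flow junction, deforming, and partially relaxing.

Rendering emulates high-speed bright-field photography: the cell appears
as a dark-rimmed convex blob on a mid-gray background, with Gaussian
imaging blur and additive sensor noise.  All generation is a pure
function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .core import N_THETA_BINS, FrameSequence, RadialProfile
from .errors import ConfigError, GeometryError
from .registry import FEATURE_NAMES

#: harmonic bands for the two morphology knobs
SHAPE_HARMONICS = (2, 4)
ROUGHNESS_HARMONICS = (8, 24)


@dataclass
class GroundTruthCell:
    """Parametric description of one synthetic cell.

    shape_modes / roughness_modes are lists of (harmonic k, amplitude,
    phase_rad) tuples.  The contour stays star-shaped around the centroid
    as long as the total mode amplitude is < 0.5.
    """

    base_radius_px: float
    shape_modes: list = field(default_factory=list)
    roughness_modes: list = field(default_factory=list)
    d_initial: float = 1.0
    d_max: float = 1.0
    t_peak_frame: int = 0
    relax_fraction: float = 0.0
    centroid_path: Optional[np.ndarray] = None   # (n_frames, 2) (row, col)
    seed: int = 0

    def __post_init__(self):
        if self.base_radius_px <= 0:
            raise ConfigError("base_radius_px must be > 0")
        if not (self.d_max >= self.d_initial >= 1.0):
            raise ConfigError(
                f"need d_max >= d_initial >= 1; got d_initial="
                f"{self.d_initial}, d_max={self.d_max}")
        if not (0.0 <= self.relax_fraction <= 1.0):
            raise ConfigError("relax_fraction must lie in [0, 1]")
        for k, eps, _ in self.all_modes():
            if eps < 0:
                raise ConfigError("mode amplitudes must be >= 0")
            if k < 1:
                raise ConfigError("mode harmonics must be >= 1")
        total = sum(eps for _, eps, _ in self.all_modes())
        if total >= 0.5:
            raise ConfigError(
                f"total mode amplitude {total:.3f} >= 0.5: contour would "
                "not be star-shaped around the centroid")

    def all_modes(self):
        return list(self.shape_modes) + list(self.roughness_modes)

    def validate_frames(self, n_frames: int):
        if not (0 <= self.t_peak_frame < n_frames):
            raise ConfigError(
                f"t_peak_frame {self.t_peak_frame} outside 0..{n_frames - 1}")
        if self.centroid_path is not None:
            path = np.asarray(self.centroid_path, dtype=float)
            if path.shape != (n_frames, 2):
                raise ConfigError(
                    f"centroid_path must have shape ({n_frames}, 2)")


@dataclass
class RenderConfig:
    """Imaging model for bright-field emulation.

    The default 2 us frame interval corresponds to a ~500 000 frames per
    second high-speed camera.  Intensities are gray levels in [0, 1]; the
    cell is drawn as interior_intensity with a rim band of width
    rim_width_px at rim_intensity just inside the latent contour (the
    contour itself is the outer rim edge), over background_intensity.
    """

    frame_shape_px: tuple[int, int] = (128, 128)
    n_frames: int = 30
    frame_interval_us: float = 2.0
    rim_intensity: float = 0.15
    interior_intensity: float = 0.70
    background_intensity: float = 0.55
    rim_width_px: float = 2.5
    blur_sigma_px: float = 1.0
    noise_sd: float = 0.01
    supersample: int = 4
    um_per_px: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval_us <= 0:
            raise ConfigError("frame_interval_us must be > 0")
        if self.n_frames < 3:
            raise ConfigError("n_frames must be >= 3")
        for name in ("rim_intensity", "interior_intensity",
                     "background_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]; got {v}")
        if self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise ConfigError("blur_sigma_px and noise_sd must be >= 0")
        if int(self.supersample) < 1:
            raise ConfigError("supersample must be >= 1")


def deformation_trace(cell: GroundTruthCell, n_frames: int) -> np.ndarray:
    """Piecewise-smoothstep aspect-ratio trace D(t) of length n_frames.

    D(0) = d_initial; D rises monotonically to d_max at t_peak_frame and
    then decays monotonically toward
    d_max - relax_fraction * (d_max - d_initial).
    """
    if n_frames < 3:
        raise ConfigError("n_frames must be >= 3")
    cell.validate_frames(n_frames)

    def smoothstep(x):
        x = np.clip(x, 0.0, 1.0)
        return x * x * (3.0 - 2.0 * x)

    t = np.arange(n_frames, dtype=float)
    d0, dmax = float(cell.d_initial), float(cell.d_max)
    peak = float(cell.t_peak_frame)
    D = np.empty(n_frames)
    if peak > 0:
        rise = smoothstep(t / peak)
    else:
        rise = np.ones(n_frames)
    D = d0 + (dmax - d0) * rise
    last = float(n_frames - 1)
    if last > peak:
        decay = smoothstep((t - peak) / (last - peak))
        after = t > peak
        D[after] = dmax - cell.relax_fraction * (dmax - d0) * decay[after]
    return D


def _ellipse_radius(theta_rad: np.ndarray, a: float, b: float) -> np.ndarray:
    # polar radius of an origin-centered ellipse, vertical semi-axis a,
    # horizontal semi-axis b, theta from the +col axis
    return (a * b) / np.sqrt((a * np.cos(theta_rad)) ** 2
                             + (b * np.sin(theta_rad)) ** 2)


def contour_radii(cell: GroundTruthCell, D: float,
                  theta_deg: Optional[np.ndarray] = None) -> np.ndarray:
    """Analytic r(theta) for one aspect ratio D, on a 1-degree grid by
    default."""
    if theta_deg is None:
        theta_deg = np.arange(N_THETA_BINS, dtype=float)
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    a = cell.base_radius_px * np.sqrt(D)
    b = cell.base_radius_px / np.sqrt(D)
    r = _ellipse_radius(th, a, b)
    pert = np.zeros_like(th)
    for k, eps, phi in cell.all_modes():
        pert += eps * np.cos(k * th + phi)
    return r * (1.0 + pert)


def analytic_contour(cell: GroundTruthCell, frame_index: int,
                     n_frames: int = None,
                     theta_deg: Optional[np.ndarray] = None) -> RadialProfile:
    """Ground-truth radial profile of the cell at one frame.

    n_frames defaults to t_peak_frame + 1 when not given, which is only
    sensible for frame_index <= t_peak_frame; callers rendering sequences
    pass the true length.
    """
    if n_frames is None:
        n_frames = max(cell.t_peak_frame + 1, 3)
    if not (0 <= frame_index < n_frames):
        raise ConfigError(
            f"frame_index {frame_index} outside 0..{n_frames - 1}")
    D = deformation_trace(cell, n_frames)[frame_index]
    radii = contour_radii(cell, D, theta_deg)
    return RadialProfile(radii, centroid=(0.0, 0.0), frame_index=frame_index)


def _polygon_rowcol(radii: np.ndarray, center: tuple[float, float]):
    th = np.deg2rad(np.arange(len(radii), dtype=float))
    rows = center[0] - radii * np.sin(th)   # +theta goes "up" (smaller row)
    cols = center[1] + radii * np.cos(th)
    return rows, cols


def render_sequence(cell: GroundTruthCell,
                    config: RenderConfig) -> FrameSequence:
    """Rasterise the cell into a bright-field-like frame sequence.

    Bit-identical output for identical (cell, config), including seeds.
    Raises GeometryError when the contour (plus a 3-sigma blur margin)
    does not fit inside the frame.

    Each frame is rasterised on a supersampled grid and box-averaged to
    the sensor resolution, emulating pixel-area integration of the
    irradiance (sub-pixel edge positions survive into the gray levels
    instead of being quantised to whole pixels).
    """
    n = config.n_frames
    cell.validate_frames(n)
    D = deformation_trace(cell, n)
    shape = tuple(config.frame_shape_px)
    if cell.centroid_path is not None:
        path = np.asarray(cell.centroid_path, dtype=float)
    else:
        path = np.tile([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0], (n, 1))

    rng = np.random.default_rng([int(cell.seed) & 0x7FFFFFFF,
                                 int(config.seed) & 0x7FFFFFFF])
    margin = 3.0 * config.blur_sigma_px
    frames = np.empty((n,) + shape, dtype=float)
    for i in range(n):
        radii = contour_radii(cell, D[i])
        rows, cols = _polygon_rowcol(radii, tuple(path[i]))
        if (rows.min() < margin or cols.min() < margin
                or rows.max() > shape[0] - 1 - margin
                or cols.max() > shape[1] - 1 - margin):
            raise GeometryError(
                f"frame {i}: contour exceeds frame bounds (need "
                f"{margin:.1f} px margin)")
        S = int(config.supersample)
        fine_shape = (shape[0] * S, shape[1] * S)
        img = np.full(fine_shape, config.background_intensity)
        rr, cc = skdraw.polygon((rows + 0.5) * S - 0.5,
                                (cols + 0.5) * S - 0.5, shape=fine_shape)
        img[rr, cc] = config.rim_intensity
        inner = np.clip(radii - config.rim_width_px, 1e-3, None)
        ir, ic = _polygon_rowcol(inner, tuple(path[i]))
        rr, cc = skdraw.polygon((ir + 0.5) * S - 0.5, (ic + 0.5) * S - 0.5,
                                shape=fine_shape)
        img[rr, cc] = config.interior_intensity
        if S > 1:   # pixel-area integration
            img = img.reshape(shape[0], S, shape[1], S).mean(axis=(1, 3))
        if config.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, config.blur_sigma_px)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=shape)
        frames[i] = np.clip(img, 0.0, 1.0)
    return FrameSequence(frames, config.frame_interval_us, ground_truth=cell)


# ---------------------------------------------------------------------------
# population sampling

#: class_spec keys understood by sample_cell; values are either a scalar
#: (held fixed) or a [low, high] pair (sampled uniformly).
_SPEC_KEYS = ("base_radius_px", "d_initial", "d_max", "t_peak_frac",
              "relax_fraction", "n_shape_modes", "shape_amplitude",
              "n_roughness_modes", "roughness_amplitude",
              "roughness_harmonic")

DEFAULT_CLASS_SPEC: dict = {
    "base_radius_px": [10.0, 20.0],
    "d_initial": [1.0, 1.1],
    "d_max": [1.5, 2.5],
    "t_peak_frac": 0.6,
    "relax_fraction": [0.3, 0.7],
    "n_shape_modes": 1,
    "shape_amplitude": [0.0, 0.05],
    "n_roughness_modes": 1,
    "roughness_amplitude": [0.0, 0.05],
    "roughness_harmonic": 12,
}


def _draw(rng: np.random.Generator, value):
    if np.isscalar(value):
        return float(value)
    lo, hi = value
    if hi < lo:
        raise ConfigError(f"invalid range [{lo}, {hi}]")
    if hi == lo:
        return float(lo)
    return float(rng.uniform(lo, hi))


def sample_cell(class_spec: dict, n_frames: int,
                rng: np.random.Generator) -> GroundTruthCell:
    """Draw one GroundTruthCell from a class spec (see DEFAULT_CLASS_SPEC)."""
    spec = dict(DEFAULT_CLASS_SPEC)
    unknown = set(class_spec) - set(_SPEC_KEYS)
    if unknown:
        raise ConfigError(f"unknown class_spec keys: {sorted(unknown)}")
    spec.update(class_spec)

    r0 = _draw(rng, spec["base_radius_px"])
    d0 = _draw(rng, spec["d_initial"])
    dmax = max(_draw(rng, spec["d_max"]), d0)
    t_peak = int(round(_draw(rng, spec["t_peak_frac"]) * (n_frames - 1)))
    t_peak = min(max(t_peak, 0), n_frames - 1)
    relax = _draw(rng, spec["relax_fraction"])

    shape_modes = []
    for _ in range(int(_draw(rng, spec["n_shape_modes"]))):
        k = int(rng.integers(SHAPE_HARMONICS[0], SHAPE_HARMONICS[1] + 1))
        shape_modes.append((k, _draw(rng, spec["shape_amplitude"]),
                            float(rng.uniform(0, 2 * np.pi))))
    rough_modes = []
    for _ in range(int(_draw(rng, spec["n_roughness_modes"]))):
        k = int(round(_draw(rng, spec["roughness_harmonic"])))
        if not (ROUGHNESS_HARMONICS[0] <= k <= ROUGHNESS_HARMONICS[1]):
            raise ConfigError(
                f"roughness_harmonic {k} outside "
                f"{ROUGHNESS_HARMONICS[0]}..{ROUGHNESS_HARMONICS[1]}")
        rough_modes.append((k, _draw(rng, spec["roughness_amplitude"]),
                            float(rng.uniform(0, 2 * np.pi))))

    return GroundTruthCell(
        base_radius_px=r0, shape_modes=shape_modes,
        roughness_modes=rough_modes, d_initial=d0, d_max=dmax,
        t_peak_frame=t_peak, relax_fraction=relax,
        seed=int(rng.integers(0, 2**31 - 1)))


def ground_truth_row(cell: GroundTruthCell) -> dict:
    """Flatten one GroundTruthCell into a CSV-ready record."""
    def fmt(modes):
        return ";".join(f"{k}:{eps:.6g}:{phi:.6g}" for k, eps, phi in modes)
    return {
        "base_radius_px": cell.base_radius_px,
        "shape_modes": fmt(cell.shape_modes),
        "roughness_modes": fmt(cell.roughness_modes),
        "shape_amplitude_total": sum(e for _, e, _ in cell.shape_modes),
        "roughness_amplitude_total": sum(
            e for _, e, _ in cell.roughness_modes),
        "d_initial": cell.d_initial,
        "d_max": cell.d_max,
        "t_peak_frame": cell.t_peak_frame,
        "relax_fraction": cell.relax_fraction,
        "seed": cell.seed,
    }


def generate_population(n_cells: int, class_spec: dict, config: RenderConfig,
                        seed: int, render: bool = True,
                        label: str = "synthetic"):
    """Sample n_cells from class_spec and (optionally) render each one.

    Returns (sequences, ground_truth_table).  sequences is a list of
    FrameSequence when render=True, else a list of GroundTruthCell.
    Reproducible under seed.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    cells = [sample_cell(class_spec, config.n_frames, rng)
             for _ in range(n_cells)]
    rows = []
    for i, c in enumerate(cells):
        row = {"cell_id": f"{label}_{i:04d}", "label": label}
        row.update(ground_truth_row(c))
        rows.append(row)
    table = pd.DataFrame(rows)
    if not render:
        return cells, table
    seqs = []
    for i, c in enumerate(cells):
        seq = render_sequence(c, config)
        seq.cell_id = f"{label}_{i:04d}"
        seqs.append(seq)
    return seqs, table


def generate_feature_table(n_per_class: int,
                           class_means: dict[str, Sequence[float]],
                           class_sds: dict[str, Sequence[float]],
                           seed: int) -> pd.DataFrame:
    """Gaussian feature-space fixture bypassing imaging entirely.

    class_means / class_sds map class label -> 21-vector aligned with the
    phenotype registry.  Returns a DataFrame with the 21 registry columns
    plus a 'label' column; deterministic under seed.
    """
    if len(class_means) < 2:
        raise ConfigError("need two or more classes")
    if set(class_means) != set(class_sds):
        raise ConfigError("class_means and class_sds must share labels")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    blocks = []
    for label in class_means:
        mu = np.asarray(class_means[label], dtype=float)
        sd = np.asarray(class_sds[label], dtype=float)
        if mu.shape != (len(FEATURE_NAMES),) or sd.shape != mu.shape:
            raise ConfigError(
                f"class {label!r}: means/sds must be length "
                f"{len(FEATURE_NAMES)} vectors matching the registry")
        if np.any(sd <= 0):
            raise ConfigError(f"class {label!r}: sds must be > 0")
        X = rng.normal(mu, sd, size=(int(n_per_class), len(FEATURE_NAMES)))
        df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        df["label"] = label
        blocks.append(df)
    return pd.concat(blocks, ignore_index=True)


def two_class_table(n_per_class: int, seed: int,
                    shift_features: dict[str, float] | None = None,
                    labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Convenience fixture: standard-normal features for both classes,
    with class B's mean shifted by shift_features (in sd units)."""
    mu = {labels[0]: np.zeros(len(FEATURE_NAMES)),
          labels[1]: np.zeros(len(FEATURE_NAMES))}
    sds = {lab: np.ones(len(FEATURE_NAMES)) for lab in labels}
    if shift_features:
        names = list(FEATURE_NAMES)
        for feat, shift in shift_features.items():
            mu[labels[1]][names.index(feat)] = float(shift)
    return generate_feature_table(n_per_class, mu, sds, seed)
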