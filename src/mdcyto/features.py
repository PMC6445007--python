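"""Computation of the 21-parameter physical phenotype of one cell.

Size and morphology are measured on the pre-deformation reference
profile r_membrane(theta); deformability and kinetics on the aspect-ratio
trace D(t) = l_vertical(t) / l_horizontal(t).

The morphology scores accumulate the absolute deviation of
r_membrane(theta) from a trailing circular moving average over
[theta - n, theta] (n + 1 one-degree bins, wrapping around the closed
contour): a short 5-degree window isolates high-frequency surface
roughness, a long 30-degree window low-frequency cell shape.  Absolute
rather than signed deviations are accumulated because signed deviations
from a moving average integrate to approximately zero around any closed
contour, which would make the score degenerate.

Kinetics are per-step differences of D(t) divided by the frame interval:
positive increments are deformation, negative increments relaxation.
Their undirected sum telescopes to D_end - D_0 (net_deformation_change).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .contour import build_trace, extents
from .core import DeformationTrace, FrameSequence, RadialProfile
from .errors import DataError
from .registry import FEATURE_NAMES

ROUGHNESS_WINDOW_DEG = 5
SHAPE_WINDOW_DEG = 30


class SizeMetrics(NamedTuple):
    mean_diameter: float
    area: float
    perimeter: float
    equivalent_diameter: float


class MorphologyMetrics(NamedTuple):
    surface_roughness_5deg: float
    cell_shape_30deg: float
    initial_aspect_ratio: float
    circularity: float
    normalized_roughness: float
    normalized_shape: float


class DeformabilityMetrics(NamedTuple):
    max_deformation: float
    relative_deformability: float
    deformation_gain: float
    size_normalized_deformation: float
    final_deformation: float


class KineticsMetrics(NamedTuple):
    mean_deformation_rate: float
    mean_relaxation_rate: float
    max_deformation_rate: float
    min_deformation_rate: float
    time_to_max_deformation: float
    net_deformation_change: float


def size_metrics(profile: RadialProfile) -> SizeMetrics:
    """Size of the resting cell from its 360-bin radial profile.

    mean_diameter is twice the mean radius (the angular sum of
    r_membrane normalised to a diameter); area and perimeter come from
    the 360-gon with the profile's vertices (shoelace / closed polyline).
    """
    r = profile.r_membrane
    mean_diameter = 2.0 * float(r.mean())
    v = profile.vertices()
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(float(np.sum(x * y1 - x1 * y)))
    perimeter = float(np.sum(np.hypot(x1 - x, y1 - y)))
    return SizeMetrics(mean_diameter, area, perimeter,
                       float(np.sqrt(4.0 * area / np.pi)))


def circular_moving_average(values: np.ndarray, window_deg: int) -> np.ndarray:
    """Trailing circular moving average over [theta - window, theta].

    The window includes both endpoints (window_deg + 1 one-degree bins)
    and wraps around the closed contour.  values may be a RadialProfile
    or a length-360 array.
    """
    if isinstance(values, RadialProfile):
        values = values.r_membrane
    values = np.asarray(values, dtype=float)
    n = int(window_deg)
    if not (2 <= n <= 180):
        raise DataError(f"window_deg must be in 2..180; got {window_deg}")
    padded = np.concatenate([values[-n:], values])
    kernel = np.full(n + 1, 1.0 / (n + 1))
    return np.convolve(padded, kernel, mode="valid")


def morphology_metrics(profile: RadialProfile,
                       roughness_window: int = ROUGHNESS_WINDOW_DEG,
                       shape_window: int = SHAPE_WINDOW_DEG,
                       swap_axes: bool = False) -> MorphologyMetrics:
    """Morphology scores of the pre-deformation profile.

    surface_roughness / cell_shape sum |r - MA| over the 360 bins (each
    bin counted once around the closed circle); the normalised variants
    divide by the mean radius so they are scale-free.
    """
    r = profile.r_membrane
    rough = float(np.sum(np.abs(r - circular_moving_average(
        r, roughness_window))))
    shape = float(np.sum(np.abs(r - circular_moving_average(
        r, shape_window))))
    lv, lh = extents(profile, swap_axes=swap_axes)
    d0 = lv / lh
    size = size_metrics(profile)
    circ = 4.0 * np.pi * size.area / size.perimeter ** 2
    mean_radius = float(r.mean())
    return MorphologyMetrics(rough, shape, d0, float(circ),
                             rough / mean_radius, shape / mean_radius)


def deformability_metrics(trace: DeformationTrace,
                          initial_aspect_ratio: float,
                          equivalent_diameter: float) -> DeformabilityMetrics:
    """Peak and baseline-corrected deformation measures from D(t)."""
    if len(trace) < 3:
        raise DataError("trace must have at least 3 frames")
    d0 = float(initial_aspect_ratio)
    if d0 <= 0:
        raise DataError("initial aspect ratio must be > 0")
    dmax = float(trace.D.max())
    return DeformabilityMetrics(
        max_deformation=dmax,
        relative_deformability=dmax / d0,
        deformation_gain=dmax - d0,
        size_normalized_deformation=dmax / float(equivalent_diameter),
        final_deformation=float(trace.D[-1]))


def kinetics_metrics(trace: DeformationTrace) -> tuple[KineticsMetrics, list]:
    """Frame-to-frame kinetics of D(t) in physical time.

    Rates are (D(t) - D(t-1)) / dt in 1/us.  Positive increments count
    as deformation, negative as relaxation; when a direction never
    occurs its mean rate is 0 and a flag is returned.
    net_deformation_change is the telescoped sum D_end - D_0.
    """
    if len(trace) < 3:
        raise DataError("trace must have at least 3 frames")
    dt = np.diff(trace.t_us)
    if np.any(dt <= 0):
        raise DataError("frame times must be strictly increasing")
    dD = np.diff(trace.D)
    rates = dD / dt
    flags = []
    pos, neg = rates[rates > 0], rates[rates < 0]
    if len(pos):
        mean_def = float(pos.mean())
    else:
        mean_def, flags = 0.0, flags + ["no deformation observed"]
    if len(neg):
        mean_rel = float(neg.mean())
    else:
        mean_rel, flags = 0.0, flags + ["no relaxation observed"]
    t_max = float(trace.t_us[int(np.argmax(trace.D))] - trace.t_us[0])
    net = float(np.sum(dD))   # telescopes to D_end - D_0
    return KineticsMetrics(mean_def, mean_rel, float(rates.max()),
                           float(rates.min()), t_max, net), flags


def assemble_phenotype(size: SizeMetrics, deform: DeformabilityMetrics,
                       morph: MorphologyMetrics,
                       kinetics: KineticsMetrics) -> pd.Series:
    """Assemble category metrics into the 21-entry registry-ordered
    vector.  Missing (NaN) entries are allowed and flag the cell."""
    values = {}
    for group in (size, morph, deform, kinetics):
        values.update(group._asdict())
    vec = pd.Series({name: values[name] for name in FEATURE_NAMES},
                    index=list(FEATURE_NAMES), dtype=float)
    assert len(vec) == len(FEATURE_NAMES), "registry mismatch"
    return vec


def compute_phenotype(profile: RadialProfile, trace: DeformationTrace,
                      swap_axes: bool = False) -> tuple[pd.Series, list]:
    """Full 21-parameter phenotype from a reference profile and a trace.

    Returns (vector, qc_flags).
    """
    size = size_metrics(profile)
    morph = morphology_metrics(profile, swap_axes=swap_axes)
    deform = deformability_metrics(trace, morph.initial_aspect_ratio,
                                   size.equivalent_diameter)
    kin, flags = kinetics_metrics(trace)
    return assemble_phenotype(size, deform, morph, kin), flags


def phenotype_from_sequence(sequence: FrameSequence,
                            swap_axes: bool = False,
                            **trace_kwargs) -> tuple[pd.Series, list]:
    """Segment a frame sequence and compute its phenotype vector."""
    result = build_trace(sequence, swap_axes=swap_axes, **trace_kwargs)
    vec, flags = compute_phenotype(result.reference_profile, result.trace,
                                   swap_axes=swap_axes)
    flags = result.flags + flags
    if result.dropped:
        flags.append(f"{len(result.dropped)} frames dropped")
    return vec, flags


def phenotype_table(sequences, label: str = None,
                    swap_axes: bool = False) -> pd.DataFrame:
    """Feature table (one row per cell) for a list of FrameSequences.

    Cells whose trace cannot be built get a row of NaNs and a QC flag
    rather than silently disappearing.
    """
    rows = []
    for i, seq in enumerate(sequences):
        cell_id = seq.cell_id or f"cell_{i:04d}"
        try:
            vec, flags = phenotype_from_sequence(seq, swap_axes=swap_axes)
        except DataError as exc:
            vec = pd.Series(np.nan, index=list(FEATURE_NAMES))
            flags = [f"failed: {exc}"]
        row = vec.to_dict()
        row["cell_id"] = cell_id
        row["qc_flags"] = "|".join(flags)
        if label is not None:
            row["label"] = label
        rows.append(row)
    lead = ["cell_id"] + (["label"] if label is not None else [])
    cols = lead + list(FEATURE_NAMES) + ["qc_flags"]
    return pd.DataFrame(rows)[cols]
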