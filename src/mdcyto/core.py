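"""Shared data containers: frame sequences, contours, radial profiles,
deformation traces.

Image convention throughout the package: origin at the top-left corner,
(row, col) indexing, pixel centers at integer coordinates.  Angles theta
are measured counterclockwise from the +col axis as seen on screen, i.e.
theta = 90 deg points toward decreasing row ("up").  The flow axis is
horizontal (cols) and the extension axis vertical (rows), so the aspect
ratio D = l_vertical / l_horizontal is >= 1 for a cell stretched by the
extensional flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DataError

N_THETA_BINS = 360


@dataclass
class FrameSequence:
    """Ordered grayscale frames on a uniform timebase.

    frames: float array of shape (n_frames, rows, cols), values in [0, 1].
    frame_interval_us: time between consecutive frames in microseconds.
    ground_truth: optional latent cell description (synthetic data only).
    """

    frames: np.ndarray
    frame_interval_us: float
    ground_truth: Optional[object] = None
    cell_id: Optional[str] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise DataError(
                f"frames must be (n_frames, rows, cols); got shape "
                f"{self.frames.shape}")
        if self.frame_interval_us <= 0:
            raise DataError("frame_interval_us must be > 0")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise DataError(
                f"pixel values must lie in [0, 1]; got [{lo:.3g}, {hi:.3g}]")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def times_us(self) -> np.ndarray:
        """Frame timestamps in microseconds, starting at 0."""
        return np.arange(len(self)) * float(self.frame_interval_us)


@dataclass
class Contour:
    """Closed sub-pixel boundary of a segmented cell in one frame."""

    points: np.ndarray          # (n, 2) sub-pixel (row, col), ordered
    centroid: tuple[float, float]
    frame_index: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise DataError("contour points must have shape (n, 2)")
        if self.points.shape[0] < 8:
            raise DataError("contour needs at least 8 boundary points")


@dataclass
class RadialProfile:
    """Membrane-to-centroid distance r_membrane(theta) on a 1-degree grid.

    r_membrane holds exactly 360 positive radii (pixels), one per integer
    degree bin 0..359.  The profile is centroid-relative, hence invariant
    to translation of the cell within the frame.
    """

    r_membrane: np.ndarray
    centroid: tuple[float, float] = (0.0, 0.0)
    frame_index: int = 0
    is_reference: bool = False
    theta_deg: np.ndarray = field(
        default_factory=lambda: np.arange(N_THETA_BINS, dtype=float))

    def __post_init__(self):
        self.r_membrane = np.asarray(self.r_membrane, dtype=float)
        if self.r_membrane.shape != (N_THETA_BINS,):
            raise DataError(
                f"radial profile must have exactly {N_THETA_BINS} bins; got "
                f"{self.r_membrane.shape}")
        if not np.all(np.isfinite(self.r_membrane)):
            raise DataError("radial profile contains non-finite radii")
        if np.any(self.r_membrane <= 0):
            raise DataError("all r_membrane values must be > 0")

    def scaled(self, s: float) -> "RadialProfile":
        """New profile with every radius multiplied by s (s > 0)."""
        return RadialProfile(self.r_membrane * float(s), self.centroid,
                             self.frame_index, self.is_reference)

    def vertices(self) -> np.ndarray:
        """Contour vertices (x, y) in centroid-relative math coordinates
        (x along +col, y up)."""
        th = np.deg2rad(self.theta_deg)
        return np.column_stack(
            [self.r_membrane * np.cos(th), self.r_membrane * np.sin(th)])


@dataclass
class DeformationTrace:
    """Per-frame vertical/horizontal extents and aspect ratio D(t)."""

    t_us: np.ndarray            # timestamps, microseconds
    l_vertical: np.ndarray      # px
    l_horizontal: np.ndarray    # px
    D: np.ndarray = None        # l_vertical / l_horizontal

    def __post_init__(self):
        self.t_us = np.asarray(self.t_us, dtype=float)
        self.l_vertical = np.asarray(self.l_vertical, dtype=float)
        self.l_horizontal = np.asarray(self.l_horizontal, dtype=float)
        n = len(self.t_us)
        if not (len(self.l_vertical) == len(self.l_horizontal) == n):
            raise DataError("trace arrays must have equal length")
        if np.any(self.l_vertical <= 0) or np.any(self.l_horizontal <= 0):
            raise DataError("extents must be strictly positive")
        computed = self.l_vertical / self.l_horizontal
        if self.D is None:
            self.D = computed
        else:
            self.D = np.asarray(self.D, dtype=float)
            if self.D.shape != computed.shape or not np.allclose(
                    self.D, computed, rtol=1e-9, atol=1e-12):
                raise DataError("D must equal l_vertical/l_horizontal")

    def __len__(self) -> int:
        return len(self.t_us)
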