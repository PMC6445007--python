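import numpy as np
import pytest

from mdcyto import GroundTruthCell, RadialProfile, RenderConfig, \
    render_sequence


def disk_mask(radius, center=(64.0, 64.0), shape=(128, 128)):
    """Exact rasterised disk: pixel centers within `radius` of `center`."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def ellipse_mask(a, b, center=(64.0, 64.0), shape=(128, 128)):
    """Exact rasterised ellipse, vertical semi-axis a, horizontal b."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / a) ** 2 + ((xx - center[1]) / b) ** 2 <= 1.0


def cosine_profile(r0=20.0, k=12, eps=0.05, phase=0.0):
    """Analytic radial profile r0 * (1 + eps cos(k theta + phase))."""
    th = np.deg2rad(np.arange(360))
    return RadialProfile(r0 * (1.0 + eps * np.cos(k * th + phase)))


@pytest.fixture(scope="session")
def rendered_circle():
    """Noiseless, blur-free rendering of a resting circular cell r0=20."""
    cell = GroundTruthCell(base_radius_px=20.0, seed=1)
    config = RenderConfig(n_frames=3, blur_sigma_px=0.0, noise_sd=0.0,
                          seed=2)
    return render_sequence(cell, config)


@pytest.fixture(scope="session")
def deforming_sequence():
    """Default-imaging sequence of a cell deforming 1 -> 2 and relaxing."""
    cell = GroundTruthCell(base_radius_px=15.0, d_initial=1.0, d_max=2.0,
                           t_peak_frame=20, relax_fraction=0.5, seed=3)
    config = RenderConfig(n_frames=30, seed=4)
    return render_sequence(cell, config)
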