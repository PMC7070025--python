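import numpy as np
import pytest

from seepflux import bubble_plume as bp
from seepflux import synthetic_data as sd


def dist_from_radii(radii, duration=10.0, bin_width=100.0):
    """Binned emission size distribution directly from per-bubble radii,
    bypassing video simulation: Phi = counts / (duration * bin_width)."""
    lo = np.floor(radii.min() / bin_width) * bin_width
    hi = np.ceil(radii.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(radii, bins=edges)
    return bp.EmissionSizeDistribution(
        bin_edges=edges, phi=counts / (duration * bin_width), duration=duration)


@pytest.fixture(scope="session")
def clean_stream():
    """A steady near-monodisperse clean stream analysed once per session."""
    spec = sd.StreamSpec(modes=[(1530.0, 150.0, 1.0)], emission_rate=200.0,
                         duration=10.0, fov_height=5.0, fps=60.0,
                         cleanliness="clean", v_up=1.0, seed=7)
    obs = sd.simulate_bubble_stream(spec)
    return spec, obs


@pytest.fixture(scope="session")
def clean_stream_analysis(clean_stream):
    spec, obs = clean_stream
    return bp.analyze_vent(obs, fov_height=spec.fov_height, fps=spec.fps,
                           duration=spec.duration)
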