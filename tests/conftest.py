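"""Shared fixtures: straight-trace geometry and packaged simulation sets."""

import numpy as np
import pytest

from punctapipe import ProcessTraces, SimulationConfig
from punctapipe.detection import DetectionParams


def straight_trace(length_um=20.0, y_um=12.0, x0_um=2.0, pixel_size=0.1,
                   image_shape=(256, 256), n_vertices=None):
    """A horizontal polyline of the given arc length."""
    if n_vertices is None:
        n_vertices = int(round(length_um / pixel_size)) + 1
    xs = np.linspace(x0_um, x0_um + length_um, n_vertices)
    poly = np.column_stack([xs, np.full(n_vertices, y_um)])
    return ProcessTraces([poly], pixel_size, image_shape)


# The packaged seed set: the conditions under which detection fidelity is
# scored (small confocal-like fields, two processes, resolvable puncta).
FIDELITY_SEEDS = list(range(20))


def fidelity_config(seed, background_sigma):
    return SimulationConfig(
        image_shape=(256, 256), n_processes=2, process_length_um=28.0,
        puncta_per_micron=0.3, min_separation_um=2.0,
        background_sigma=background_sigma, seed=seed)


FIDELITY_PARAMS = DetectionParams(threshold_mode="fixed", fixed_threshold=25.0)


@pytest.fixture(scope="session")
def rendered_image():
    """One default-condition rendered image pair with traces and truth."""
    from punctapipe import make_process_traces, render_image_pair

    cfg = SimulationConfig(image_shape=(256, 256), n_processes=2,
                           process_length_um=25.0, seed=11)
    traces = make_process_traces(cfg)
    marker, signal, truth = render_image_pair(traces, cfg)
    return cfg, traces, marker, signal, truth
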