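import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import valveflow as vf


@pytest.fixture(scope="session")
def texture_256():
    """Smooth random texture used as a registration target."""
    rng = np.random.default_rng(11)
    tex = gaussian_filter(rng.normal(0.0, 1.0, (256, 256)), 3.0)
    return 100.0 * (tex - tex.min()) / np.ptp(tex)


@pytest.fixture(scope="session")
def poiseuille_movie():
    """Seeded oscillatory tube scenario with analytic ground truth
    (geometry/tracks only; no rendering)."""
    sc = vf.synthetic.TubeFlowScenario(
        radius_fn=25.0, centerline=((0.0, 0.0), (400.0, 0.0)),
        peak_flow=1.0, period=0.5, frame_interval=0.005, n_frames=200,
        viscosity=1.5, tracer_count=150, tracer_radius=1.0, seed=1)
    return sc, vf.synthetic.generate_tube_movie(sc, render=False)


@pytest.fixture(scope="session")
def demo_report():
    return vf.pipeline.run_demo(vf.pipeline.PipelineConfig(seed=0))
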