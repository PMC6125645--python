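import numpy as np
import pytest

from skifuse import fusion, synthetic


def small_course_spec(n_gates: int = 12) -> synthetic.CourseSpec:
    """A shortened giant-slalom course for fast pipeline tests."""
    mean_spacing = 24.8
    length = mean_spacing * (n_gates - 1)
    return synthetic.CourseSpec(n_gates=n_gates, total_length=length,
                                vertical_drop=length * 150.0 / 700.0)


@pytest.fixture(scope="session")
def small_run():
    """A 12-gate synthetic run with default sensor noise."""
    return synthetic.simulate_run(small_course_spec(), seed=7)


@pytest.fixture(scope="session")
def noiseless_run():
    """The same 12-gate run with noise-free sensors."""
    spec = small_course_spec()
    noise = synthetic.SensorNoiseModel.noiseless(seed=9)
    return synthetic.simulate_run(spec, noise, seed=7)


@pytest.fixture(scope="session")
def pipeline_result(small_run):
    gt, sensors = small_run
    return fusion.run_fusion_pipeline(sensors, gt.gates)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
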