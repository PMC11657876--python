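import numpy as np
import pytest

from redoximg.image_io import AcquisitionMeta, ChannelStack, channel_stack_from_frames
from redoximg.segmentation import LabelMask
from redoximg.simulate import SimulationConfig, meta_from_config, simulate_timelapse


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def meta():
    return AcquisitionMeta(
        illumination_mw=4.14, exposure_ms=10.0, frame_rate_hz=99.4
    )


def small_noiseless_config(**overrides) -> SimulationConfig:
    base = dict(
        n_cells=3,
        fov_shape=(64, 128),
        n_frames=40,
        frame_rate_hz=20.0,
        cell_radius_px=(7.0, 10.0),
        min_area_hint=None,
        shot_noise=False,
        read_noise_sd=0.0,
        quantize=False,
        seed=7,
    )
    base.pop("min_area_hint")
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def noiseless_config():
    return small_noiseless_config()


@pytest.fixture
def noiseless_run(noiseless_config):
    stack, truth = simulate_timelapse(noiseless_config)
    cs = channel_stack_from_frames(stack, meta_from_config(noiseless_config))
    return noiseless_config, stack, truth, cs


def truth_label_mask(truth) -> LabelMask:
    return LabelMask(labels=truth.label_mask, provenance={"source": "ground_truth"})


@pytest.fixture
def constant_channel_stack(meta):
    """Tiny stack with constant, distinct channel values."""
    t, h, w = 5, 8, 10
    data_451 = np.full((t, h, w), 30.0)
    data_560 = np.full((t, h, w), 10.0)
    time_s = np.arange(t) / meta.frame_rate_hz
    return ChannelStack(data_451=data_451, data_560=data_560, time_s=time_s, meta=meta)
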