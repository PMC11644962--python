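import numpy as np
import pytest

from thermoknee import SyntheticConfig, generate_kinematics, render_thermal


def make_cfg(**overrides) -> SyntheticConfig:
    """A fast small-frame configuration with the layout scaled to fit.

    The geometry (zone spacing / blob footprint ratio) matches the
    default full-frame layout, so zero-noise behaviour is identical.
    """
    base = dict(duration_s=60.0, width_px=128, height_px=96,
                layout_scale=0.33, excursion_amplitude_px=13.0, seed=0)
    base.update(overrides)
    return SyntheticConfig(**base)


def make_noiseless_cfg(**overrides) -> SyntheticConfig:
    base = dict(thermal_noise_c=0.0, tracker_rms_px=0.0, dropout_prob=0.0,
                loadcell_noise_kg=0.0)
    base.update(overrides)
    return make_cfg(**base)


@pytest.fixture(scope="session")
def small_run():
    """One rendered small noiseless participant shared across tests."""
    from thermoknee import (generate_participant, sample_indices)

    cfg = make_noiseless_cfg(seed=5)
    gt, track, cells = generate_participant(cfg)
    idx = sample_indices(gt.times, 1.0)
    seq = render_thermal(cfg, gt, indices=idx)
    return cfg, gt, track, cells, idx, seq


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
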