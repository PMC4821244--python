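import numpy as np
import pytest

import frapkit as fk

# desk-scale acquisition used by most unit tests: 9.6 um field, 1 um bleach
# disc, 24 s of recovery
SMALL_KW = dict(
    grid_shape=(96, 96),
    pixel_size=0.1,
    frame_interval=0.15,
    n_prebleach=3,
    n_recovery=160,
    bleach_radius=1.0,
    bleach_edge_sigma=0.05,
    cell_free_size=1.5,
    bit_depth="float",
)


def small_config(**overrides) -> fk.SimulationConfig:
    kw = dict(SMALL_KW, diffusion_coeff=0.05, mobile_fraction=0.7,
              noise_model="none", monitor_bleach_rate=0.0)
    kw.update(overrides)
    return fk.SimulationConfig(**kw)


def small_noisy_config(**overrides) -> fk.SimulationConfig:
    kw = dict(SMALL_KW, diffusion_coeff=0.05, mobile_fraction=0.7)
    kw.update(overrides)
    return fk.SimulationConfig(**kw)


@pytest.fixture
def noiseless_cfg() -> fk.SimulationConfig:
    return small_config()


@pytest.fixture
def noisy_cfg() -> fk.SimulationConfig:
    return small_noisy_config()


def run_pipeline(cfg: fk.SimulationConfig, **analyze_kw) -> fk.FrapResult:
    series, _ = fk.simulate_frap(cfg)
    return fk.analyze_frap(series, fk.default_roiset(cfg), **analyze_kw)


def random_traces(rng: np.random.Generator, n: int, n_pre: int):
    """Random raw traces satisfying the chain preconditions."""
    i_b = rng.uniform(0.0, 5.0, n)
    i_r = i_b + rng.uniform(5.0, 50.0, n)
    i = i_b + rng.uniform(20.0, 100.0, n)
    # force a detectable bleach at the first post-bleach frame (deep enough
    # that the corrected, normalized value stays below 1)
    i[n_pre] = i_b[n_pre] + rng.uniform(0.01, 0.1) * (i_r[n_pre] - i_b[n_pre])
    return i, i_b, i_r


def make_curve(rng: np.random.Generator, n: int = 40,
               n_pre: int = 5) -> fk.RecoveryCurve:
    i, i_b, i_r = random_traces(rng, n, n_pre)
    t = (np.arange(n) - n_pre) * 0.2
    return fk.RecoveryCurve(t=t, I=i, I_b=i_b, I_r=i_r,
                            n_prebleach=n_pre, bleach_index=n_pre)
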