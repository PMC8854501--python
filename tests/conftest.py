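import numpy as np
import pytest

from tofcast.preprocessing import make_windows, scale_series, split_half
from tofcast.sequence_models import ModelSpec, train_predictor
from tofcast.synthetic_cohort import (
    GeneratorConfig,
    LatentCurveParams,
    TOFRSeries,
    generate_cohort,
    solve_t50,
    tofr_curve,
)


def sigmoid_series(n=160, slope=9.0, end=93.0, noise=0.0, seed=0, t_max=100.0) -> TOFRSeries:
    """A single synthetic recovery series with known latent curve."""
    t50 = solve_t50(n / 4.0, end, slope, t_max)
    t = np.arange(n) / 4.0
    clean = tofr_curve(t, LatentCurveParams(t50=t50, slope=slope, t_max=t_max))
    rng = np.random.default_rng(seed)
    values = np.maximum(clean + rng.normal(0.0, noise, n), 0.0)
    return TOFRSeries(values=values, observed=np.ones(n, dtype=bool))


@pytest.fixture(scope="session")
def noiseless_series():
    return sigmoid_series()


@pytest.fixture(scope="session")
def small_cohort():
    """Six noisy patients with gaps, for functional (non-quality) checks."""
    cfg = GeneratorConfig(n_patients=6, seed=42)
    return generate_cohort(cfg)


#: Cheap hyperparameters for tests that exercise plumbing, not fit quality.
FAST_SPEC = dict(hidden_units=8, epochs=25, batch_size=16, learning_rate=1e-3)


@pytest.fixture(scope="session")
def fast_gru_predictor(noiseless_series):
    split = split_half(noiseless_series)
    windows = make_windows(scale_series(split.train))
    return train_predictor(windows, ModelSpec(kind="GRU", seed=7, **FAST_SPEC), donor_id="p001"), split
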