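import numpy as np
import pandas as pd
import pytest

import irgpsig as ir


def random_expression(rng: np.random.Generator, n_genes: int = 12,
                      n_samples: int = 8) -> pd.DataFrame:
    """Small random positive expression matrix with unique ids."""
    values = np.exp(rng.normal(2.0, 1.0, size=(n_genes, n_samples)))
    return pd.DataFrame(values,
                        index=[f"G{i}" for i in range(n_genes)],
                        columns=[f"S{i}" for i in range(n_samples)])


def random_survival(rng: np.random.Generator, n: int, censor_frac: float = 0.3,
                    sample_ids=None) -> pd.DataFrame:
    """Random exponential survival with independent censoring."""
    t_event = rng.exponential(2.0, n)
    t_cens = rng.exponential(2.0 * (1 - censor_frac) / max(censor_frac, 1e-9), n) \
        if censor_frac > 0 else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    ids = sample_ids if sample_ids is not None else [f"S{i}" for i in range(n)]
    return pd.DataFrame({"time": np.maximum(time, 1e-9), "event": event},
                        index=pd.Index(ids, name="sample_id"))


def monotone_warp(rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
    """A random strictly increasing transform of a positive vector."""
    a = rng.normal(0, 2)
    b = rng.uniform(0.2, 5.0)
    g = rng.uniform(0.3, 3.0)
    return a + b * np.log1p(x) ** g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Deterministic 60-gene / 200-sample cohort with 3 strong planted pairs."""
    cfg = ir.SimulationConfig(n_samples=200, n_genes=60, n_signal_pairs=3,
                              pair_effects=(1.5, 1.5, -1.5),
                              covariate_effects=(), seed=11)
    return ir.simulate_cohort(cfg)
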