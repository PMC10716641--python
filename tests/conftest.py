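import numpy as np
import pandas as pd
import pytest

from fincee import synthetic
from fincee.pipeline import default_generator_params


@pytest.fixture(scope="session")
def gen_params():
    """Three-state, two-context generator with no exposure effect."""
    return default_generator_params(3, k_contexts=2)


@pytest.fixture(scope="session")
def small_dataset(gen_params):
    """Six whales x 60 dives, no covariate; shared across cheap tests."""
    data, truth = synthetic.simulate_dives(gen_params, None, n_whales=6,
                                           dives_per_whale=60, seed=71)
    return data, truth


@pytest.fixture(scope="session")
def fixture_tables():
    return synthetic.load_study_tables()


def toy_hmm_params(n_states=2, n_contexts=1, beta=0.0, seed=0):
    """Small, well-separated HMM parameters for oracle comparisons."""
    rng = np.random.default_rng(seed)
    N, K = n_states, n_contexts
    eta = rng.normal(-1.0, 0.5, (K, N, N))
    b = np.zeros((1, K, N, N))
    b[0, :, :, :] = beta
    from fincee.hmm import HMMParams
    delta = rng.dirichlet(np.ones(N) * 5, K)
    pi = rng.dirichlet(np.ones(K) * 5)
    base = np.linspace(1.0, 2.5, N)
    return HMMParams(
        time_shape=3.0 * base, time_rate=0.02 * np.ones(N),
        depth_shape=4.0 * base, depth_rate=0.1 * np.ones(N),
        lunge_rate=np.linspace(0.5, 4.0, N),
        speed_shape=5.0 * np.ones(N), speed_rate=2.0 * base,
        mu=np.linspace(-1.0, 1.0, N), kappa=np.linspace(0.3, 2.0, N),
        eta=eta, beta=b, delta=delta, pi=pi)


def toy_sequence(T, seed=0, with_cov=False):
    """A tiny observation frame with all five streams (positive values)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "whale_id": "w0",
        "dive_time_s": rng.gamma(5, 40, T),
        "max_depth_m": rng.gamma(4, 20, T),
        "lunges": rng.poisson(2, T),
        "speed_ms": rng.gamma(5, 0.4, T),
        "turn_angle_rad": rng.vonmises(0, 1, T),
    })
    if with_cov:
        df["covariate"] = rng.normal(0, 1, T)
    return df


def enumerate_loglik(seq, params, k):
    """Brute-force HMM log likelihood: explicit sum over all state paths.

    Independent of the forward recursion: transition rows are rebuilt with
    a local softmax and emission densities with scipy.stats.
    """
    import itertools

    from scipy import stats as st
    N = params.delta.shape[1]
    T = len(seq)
    x = seq["covariate"].to_numpy() if "covariate" in seq else np.zeros(T)

    def emis(t, i):
        r = seq.iloc[t]
        return (st.gamma.logpdf(r["dive_time_s"], params.time_shape[i],
                                scale=1 / params.time_rate[i])
                + st.gamma.logpdf(r["max_depth_m"], params.depth_shape[i],
                                  scale=1 / params.depth_rate[i])
                + st.poisson.logpmf(r["lunges"], params.lunge_rate[i])
                + st.gamma.logpdf(r["speed_ms"], params.speed_shape[i],
                                  scale=1 / params.speed_rate[i])
                + st.vonmises.logpdf(r["turn_angle_rad"], params.kappa[i],
                                     loc=params.mu[i]))

    def trow(t, i):
        logits = params.eta[k, i].copy() + params.beta[0, k, i] * x[t]
        logits[i] = 0.0
        e = np.exp(logits - logits.max())
        return e / e.sum()

    total = -np.inf
    for path in itertools.product(range(N), repeat=T):
        lp = np.log(params.delta[k, path[0]]) + emis(0, path[0])
        for t in range(1, T):
            lp += np.log(trow(t, path[t - 1])[path[t]]) + emis(t, path[t])
        total = np.logaddexp(total, lp)
    return total
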