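"""Multivariate hidden Markov model with discrete random-effect contexts.

The behavioural model at the centre of the package.  Each dive yields a
five-variable observation vector — dive time (s), maximum depth (m),
lunge count, speed over ground (m/s) and turning angle (rad) — modelled
conditionally on an N-state hidden chain with gamma, gamma, Poisson,
gamma and von Mises emission families respectively.  Two extensions on
top of the basic HMM:

* **Contexts** (discrete random effects): each whale belongs to one of K
  latent state-switching regimes, drawn with mixing probabilities pi_k.
  Contexts have their own transition intercepts and initial state
  distributions; emission parameters are shared across contexts.
* **Exposure covariates on transitions**: a per-dive covariate x_t (binary
  exposure flag, categorical CEE phase, or a received-level measure)
  shifts the off-diagonal transition logits, gamma_ij proportional to
  exp(eta0_ij + beta_ij * x), with the diagonal as the multinomial-logit
  reference.  The covariate at dive t acts on the transition into dive t.
  Coefficients may be shared across contexts or context-specific.

The whole-dataset log likelihood sums per-whale mixture log likelihoods,
log sum_k pi_k L_wk, with each L_wk an exact forward-recursion HMM
likelihood under regime k.  Fitting maximizes this over unconstrained
working parameters (logs for positive parameters, multinomial logits for
probability vectors) by quasi-Newton iteration with the exact analytic
score, obtained from the forward-backward posteriors via the Fisher
identity.  Model selection (number of contexts, covariate choice and
sharing) uses AIC; inference on coefficients uses Wald intervals from the
numerically differentiated observed information.

Continuous received-level covariates are standardized using the mean and
standard deviation over exposed dives before entering the logits (raw dB
values near 150 would overflow the link); fitted coefficients are
reported on both scales.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import circmean

__all__ = [
    "HMMSpec",
    "HMMParams",
    "HMMFit",
    "DecodeResult",
    "FitFailureError",
    "tpm_from_logits",
    "emission_logdensity",
    "forward_loglik",
    "mixture_loglik",
    "n_parameters",
    "n_parameters_breakdown",
    "fit_hmm",
    "jitter_refit",
    "select_model",
    "wald_ci",
    "local_decode",
    "fit_to_json",
]

#: observation column names in stream order
STREAMS = ("dive_time_s", "max_depth_m", "lunges", "speed_ms", "turn_angle_rad")
_GAMMA_FLOOR = 1e-6  # tiny positive floor for gamma streams (zero depth etc.)
_COVARIATES = ("none", "exposure_binary", "phase_categorical", "avg_rl", "max_rl", "custom")


class FitFailureError(RuntimeError):
    """No optimization start converged; carries per-start diagnostics."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class HMMSpec:
    """Model structure: states, contexts, covariate choice and sharing."""

    n_states: int = 3
    n_contexts: int = 1
    covariate: str = "none"
    covariate_sharing: str = "shared"

    def __post_init__(self):
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if not 1 <= self.n_contexts:
            raise ValueError("n_contexts must be >= 1")
        if self.covariate not in _COVARIATES:
            raise ValueError(f"covariate must be one of {_COVARIATES}")
        if self.covariate_sharing not in ("shared", "per_context"):
            raise ValueError("covariate_sharing must be 'shared' or 'per_context'")
        if self.covariate != "none" and self.n_states < 2:
            raise ValueError("a covariate effect needs n_states >= 2")

    @property
    def covariate_dim(self) -> int:
        """Number of covariate columns (phase enters as two dummies)."""
        return {"none": 0, "phase_categorical": 2}.get(self.covariate, 1)


@dataclass
class HMMParams:
    """Natural-scale parameters.

    Emission parameters are arrays of length N (shared across contexts);
    ``eta`` (K, N, N) holds off-diagonal transition intercepts (diagonal
    entries are ignored), ``beta`` (d, K, N, N) covariate coefficients
    (replicated across contexts when shared), ``delta`` (K, N) initial
    state distributions and ``pi`` (K,) context mixing probabilities.
    """

    time_shape: np.ndarray
    time_rate: np.ndarray
    depth_shape: np.ndarray
    depth_rate: np.ndarray
    lunge_rate: np.ndarray
    speed_shape: np.ndarray
    speed_rate: np.ndarray
    mu: np.ndarray
    kappa: np.ndarray
    eta: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    pi: np.ndarray

    def validate(self):
        for name in ("time_shape", "time_rate", "depth_shape", "depth_rate",
                     "lunge_rate", "speed_shape", "speed_rate"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(self.kappa < 0):
            raise ValueError("kappa must be non-negative")
        if not np.allclose(self.delta.sum(axis=1), 1.0):
            raise ValueError("each initial distribution must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("mixing probabilities must sum to 1")


# ---------------------------------------------------------------------------
# Working-parameter packing
# ---------------------------------------------------------------------------

def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _layout(spec: HMMSpec) -> dict[str, slice]:
    N, K, d = spec.n_states, spec.n_contexts, spec.covariate_dim
    M = N * (N - 1)
    nbeta = d * M * (K if spec.covariate_sharing == "per_context" else 1)
    sizes = [("emis", 9 * N), ("eta", K * M), ("beta", nbeta),
             ("delta", K * (N - 1)), ("pi", K - 1)]
    out, pos = {}, 0
    for name, sz in sizes:
        out[name] = slice(pos, pos + sz)
        pos += sz
    out["total"] = pos
    return out


def n_parameters(spec: HMMSpec) -> int:
    """Free-parameter count of a model structure."""
    return _layout(spec)["total"]


def n_parameters_breakdown(spec: HMMSpec) -> dict[str, int]:
    lay = _layout(spec)
    return {"emissions": lay["emis"].stop - lay["emis"].start,
            "transition_intercepts": lay["eta"].stop - lay["eta"].start,
            "covariate": lay["beta"].stop - lay["beta"].start,
            "initial_distributions": lay["delta"].stop - lay["delta"].start,
            "mixing": lay["pi"].stop - lay["pi"].start}


def _softmax_ref(z: np.ndarray) -> np.ndarray:
    """Softmax of [z, 0] (last category is the reference)."""
    full = np.concatenate([z, [0.0]])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def _unpack(theta: np.ndarray, spec: HMMSpec) -> HMMParams:
    N, K, d = spec.n_states, spec.n_contexts, spec.covariate_dim
    lay = _layout(spec)
    off = _offdiag_mask(N)
    e = theta[lay["emis"]].reshape(N, 9)
    eta = np.zeros((K, N, N))
    eta[:, off] = theta[lay["eta"]].reshape(K, N * (N - 1))
    beta = np.zeros((d, K, N, N))
    if d:
        if spec.covariate_sharing == "per_context":
            beta[:, :, off] = theta[lay["beta"]].reshape(d, K, N * (N - 1))
        else:
            beta[:, :, off] = theta[lay["beta"]].reshape(d, 1, N * (N - 1))
    delta = np.stack([_softmax_ref(z) for z in theta[lay["delta"]].reshape(K, N - 1)]) \
        if N > 1 else np.ones((K, 1))
    pi = _softmax_ref(theta[lay["pi"]])
    return HMMParams(
        time_shape=np.exp(e[:, 0]), time_rate=np.exp(e[:, 1]),
        depth_shape=np.exp(e[:, 2]), depth_rate=np.exp(e[:, 3]),
        lunge_rate=np.exp(e[:, 4]),
        speed_shape=np.exp(e[:, 5]), speed_rate=np.exp(e[:, 6]),
        mu=e[:, 7], kappa=np.exp(e[:, 8]),
        eta=eta, beta=beta, delta=delta, pi=pi)


def _pack(p: HMMParams, spec: HMMSpec) -> np.ndarray:
    N, K, d = spec.n_states, spec.n_contexts, spec.covariate_dim
    lay = _layout(spec)
    off = _offdiag_mask(N)
    theta = np.empty(lay["total"])
    e = np.column_stack([
        np.log(p.time_shape), np.log(p.time_rate),
        np.log(p.depth_shape), np.log(p.depth_rate),
        np.log(p.lunge_rate),
        np.log(p.speed_shape), np.log(p.speed_rate),
        p.mu, np.log(np.maximum(p.kappa, 1e-8))])
    theta[lay["emis"]] = e.ravel()
    theta[lay["eta"]] = p.eta[:, off].ravel()
    if d:
        if spec.covariate_sharing == "per_context":
            theta[lay["beta"]] = p.beta[:, :, off].ravel()
        else:
            theta[lay["beta"]] = p.beta[:, :1, off].ravel()
    if N > 1:
        zd = np.log(np.maximum(p.delta, 1e-300))
        theta[lay["delta"]] = (zd[:, :N - 1] - zd[:, [N - 1]]).ravel()
    zp = np.log(np.maximum(p.pi, 1e-300))
    theta[lay["pi"]] = zp[:K - 1] - zp[K - 1]
    return theta


def param_names(spec: HMMSpec) -> list[str]:
    """Working-parameter names in packing order."""
    N, K, d = spec.n_states, spec.n_contexts, spec.covariate_dim
    names = []
    lab = ["log_time_shape", "log_time_rate", "log_depth_shape", "log_depth_rate",
           "log_lunge_rate", "log_speed_shape", "log_speed_rate", "mu", "log_kappa"]
    for n in range(N):
        names += [f"{l}[{n + 1}]" for l in lab]
    for k in range(K):
        names += [f"eta[{k + 1},{i + 1}->{j + 1}]"
                  for i in range(N) for j in range(N) if j != i]
    kk = range(K) if spec.covariate_sharing == "per_context" else [None]
    for c in range(d):
        for k in kk:
            tag = f",{c + 1}" if d > 1 else ""
            ctag = f"{k + 1}," if k is not None else ""
            names += [f"beta[{ctag}{i + 1}->{j + 1}{tag}]"
                      for i in range(N) for j in range(N) if j != i]
    for k in range(K):
        names += [f"delta_logit[{k + 1},{i + 1}]" for i in range(N - 1)]
    names += [f"pi_logit[{k + 1}]" for k in range(K - 1)]
    return names


# ---------------------------------------------------------------------------
# Densities and single-row TPMs (public primitives)
# ---------------------------------------------------------------------------

def tpm_from_logits(intercepts_row: np.ndarray, beta_row: np.ndarray,
                    covariate_value: float, diag_index: int = 0) -> np.ndarray:
    """One transition-matrix row from off-diagonal logits.

    ``intercepts_row`` and ``beta_row`` hold the N-1 off-diagonal entries in
    destination order; the diagonal (position ``diag_index``) is the
    multinomial-logit reference with logit 0.
    """
    eta = np.asarray(intercepts_row, dtype=float)
    b = np.asarray(beta_row, dtype=float)
    logits = eta + b * covariate_value
    if not np.all(np.isfinite(logits)) or np.max(np.abs(logits)) > 700:
        raise FloatingPointError("transition logits overflow exp; "
                                 "standardize the covariate")
    full = np.insert(logits, diag_index, 0.0)
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def emission_logdensity(record, state_params) -> float:
    """Joint log density of one dive's five streams given a state.

    ``record`` maps the observation columns to values and ``state_params``
    maps the nine per-state parameters.  Streams are conditionally
    independent given the state, so the result is the sum of the gamma,
    gamma, Poisson, gamma and von Mises log densities.  Non-positive values
    in a gamma stream yield ``-inf`` with a warning.
    """
    sp = state_params
    total = 0.0
    for val, a, b in ((record["dive_time_s"], sp["time_shape"], sp["time_rate"]),
                      (record["max_depth_m"], sp["depth_shape"], sp["depth_rate"]),
                      (record["speed_ms"], sp["speed_shape"], sp["speed_rate"])):
        if val <= 0:
            warnings.warn("non-positive value in a gamma stream; density is -inf")
            return -np.inf
        total += a * np.log(b) - special.gammaln(a) + (a - 1) * np.log(val) - b * val
    lam = sp["lunge_rate"]
    y = record["lunges"]
    total += y * np.log(lam) - lam - special.gammaln(y + 1)
    kap, mu = sp["kappa"], sp["mu"]
    ang = record["turn_angle_rad"]
    total += kap * np.cos(ang - mu) - np.log(2 * np.pi) - (np.log(special.ive(0, kap)) + kap)
    return float(total)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def _build_X(df: pd.DataFrame, spec: HMMSpec,
             cov_scale: tuple[float, float] | None) -> tuple[np.ndarray, tuple[float, float]]:
    n = len(df)
    c = spec.covariate
    if c == "none":
        return np.zeros((n, 0)), (0.0, 1.0)
    if c == "exposure_binary":
        return df["exposure"].to_numpy(dtype=float)[:, None], (0.0, 1.0)
    if c == "phase_categorical":
        ph = df["phase"].astype(str)
        return np.column_stack([(ph == "during").to_numpy(dtype=float),
                                (ph == "after").to_numpy(dtype=float)]), (0.0, 1.0)
    if c == "custom":
        return df["covariate"].to_numpy(dtype=float)[:, None], (0.0, 1.0)
    x = df[c].to_numpy(dtype=float)
    if cov_scale is None:
        exposed = df["exposure"].to_numpy(dtype=bool) if "exposure" in df else x > 0
        if exposed.any() and np.std(x[exposed]) > 0:
            cov_scale = (float(np.mean(x[exposed])), float(np.std(x[exposed])))
        else:
            cov_scale = (0.0, 1.0)
    m, s = cov_scale
    return ((x - m) / s)[:, None], cov_scale


def _prepare(dataset: pd.DataFrame, spec: HMMSpec,
             cov_scale: tuple[float, float] | None = None):
    """Group whale sequences by length into batched arrays."""
    X_all, cov_scale = _build_X(dataset, spec, cov_scale)
    seqs = []
    for wid, g in dataset.groupby("whale_id", sort=True):
        y = {s: g[s].to_numpy(dtype=float) for s in STREAMS}
        for s in ("dive_time_s", "max_depth_m", "speed_ms"):
            bad = y[s] <= 0
            if bad.any():
                warnings.warn(f"{bad.sum()} non-positive values in {s} floored to {_GAMMA_FLOOR}")
                y[s] = np.maximum(y[s], _GAMMA_FLOOR)
        seqs.append((wid, y, X_all[g.index.to_numpy()]))
    batches = []
    for T in sorted({v[1]["dive_time_s"].size for v in seqs}):
        grp = [v for v in seqs if v[1]["dive_time_s"].size == T]
        batch = {
            "whale_ids": [v[0] for v in grp],
            "X": np.stack([v[2] for v in grp]),
        }
        for s in STREAMS:
            batch[s] = np.stack([v[1][s] for v in grp])
        batch["log_time"] = np.log(batch["dive_time_s"])
        batch["log_depth"] = np.log(batch["max_depth_m"])
        batch["log_speed"] = np.log(batch["speed_ms"])
        batch["lgam_lunges"] = special.gammaln(batch["lunges"] + 1)
        batches.append(batch)
    return batches, cov_scale


def _emission_logB(batch, p: HMMParams) -> np.ndarray:
    """Per-dive per-state log emission density, shape (W, T, N)."""
    y_t = batch["dive_time_s"][..., None]
    y_d = batch["max_depth_m"][..., None]
    y_l = batch["lunges"][..., None]
    y_s = batch["speed_ms"][..., None]
    y_a = batch["turn_angle_rad"][..., None]
    logB = (p.time_shape * np.log(p.time_rate) - special.gammaln(p.time_shape)
            + (p.time_shape - 1) * batch["log_time"][..., None] - p.time_rate * y_t)
    logB += (p.depth_shape * np.log(p.depth_rate) - special.gammaln(p.depth_shape)
             + (p.depth_shape - 1) * batch["log_depth"][..., None] - p.depth_rate * y_d)
    logB += y_l * np.log(p.lunge_rate) - p.lunge_rate - batch["lgam_lunges"][..., None]
    logB += (p.speed_shape * np.log(p.speed_rate) - special.gammaln(p.speed_shape)
             + (p.speed_shape - 1) * batch["log_speed"][..., None] - p.speed_rate * y_s)
    logI0 = np.log(special.ive(0, p.kappa)) + p.kappa
    logB += p.kappa * np.cos(y_a - p.mu) - np.log(2 * np.pi) - logI0
    return logB


def _tpm_seq(batch, p: HMMParams, k: int) -> np.ndarray:
    """Per-dive transition matrices under context k, shape (W, T, N, N).

    Entry [:, t] is the TPM governing the transition into dive t (built
    from the covariate at dive t); [:, 0] is unused by the recursions.
    """
    N = p.eta.shape[1]
    logits = np.broadcast_to(p.eta[k], batch["X"].shape[:2] + (N, N)).copy()
    if p.beta.shape[0] and batch["X"].shape[2]:
        logits += np.einsum("wtc,cij->wtij", batch["X"], p.beta[:, k])
    idx = np.arange(N)
    logits[:, :, idx, idx] = 0.0
    logits -= logits.max(axis=3, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=3, keepdims=True)


def _forward_backward(batch, p: HMMParams, k: int, want_posteriors: bool):
    """Scaled forward (and optionally backward) pass for one batch/context.

    Returns (loglik (W,), gamma (W,T,N), xi (W,T-1,N,N)); the latter two are
    ``None`` unless requested.
    """
    logB = _emission_logB(batch, p)
    W, T, N = logB.shape
    m = logB.max(axis=2)
    Bt = np.exp(logB - m[..., None])
    Gam = _tpm_seq(batch, p, k)
    ahat = np.empty((W, T, N))
    c = np.empty((W, T))
    a = p.delta[k][None, :] * Bt[:, 0]
    c[:, 0] = a.sum(axis=1)
    ahat[:, 0] = a / c[:, [0]]
    for t in range(1, T):
        a = np.einsum("wi,wij->wj", ahat[:, t - 1], Gam[:, t]) * Bt[:, t]
        c[:, t] = a.sum(axis=1)
        ahat[:, t] = a / c[:, [t]]
    ll = np.log(c).sum(axis=1) + m.sum(axis=1)
    if not want_posteriors:
        return ll, None, None
    bhat = np.empty((W, T, N))
    bhat[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        tmp = Bt[:, t + 1] * bhat[:, t + 1]
        bhat[:, t] = np.einsum("wij,wj->wi", Gam[:, t + 1], tmp) / c[:, [t + 1]]
    gamma = ahat * bhat
    xi = (ahat[:, :-1, :, None] * Gam[:, 1:]
          * (Bt[:, 1:] * bhat[:, 1:])[:, :, None, :] / c[:, 1:, None, None])
    return ll, gamma, (xi, Gam)


# ---------------------------------------------------------------------------
# Likelihood and analytic score
# ---------------------------------------------------------------------------

def _loglik_and_grad(theta: np.ndarray, spec: HMMSpec, batches, want_grad: bool):
    p = _unpack(theta, spec)
    N, K, d = spec.n_states, spec.n_contexts, spec.covariate_dim
    lay = _layout(spec)
    off = _offdiag_mask(N)
    total = 0.0
    grad = np.zeros(lay["total"]) if want_grad else None
    log_pi = np.log(np.maximum(p.pi, 1e-300))

    for batch in batches:
        W = batch["dive_time_s"].shape[0]
        lls = np.empty((W, K))
        posts = []
        for k in range(K):
            ll_k, gamma_k, trans_k = _forward_backward(batch, p, k, want_grad)
            lls[:, k] = ll_k
            posts.append((gamma_k, trans_k))
        lw = special.logsumexp(lls + log_pi[None, :], axis=1)
        total += lw.sum()
        if not want_grad:
            continue
        pwk = np.exp(lls + log_pi[None, :] - lw[:, None])  # (W, K)

        # --- emissions via mixed posteriors and sufficient statistics
        gmix = np.einsum("wk,kwtn->wtn", pwk,
                         np.stack([posts[k][0] for k in range(K)]))
        def ssum(stat):
            return np.einsum("wtn,wt->n", gmix, stat)
        S0 = gmix.sum(axis=(0, 1))
        ge = np.empty((N, 9))
        for j, (yk, lyk, sh, rt) in enumerate((
                ("dive_time_s", "log_time", p.time_shape, p.time_rate),
                ("max_depth_m", "log_depth", p.depth_shape, p.depth_rate),
                ("speed_ms", "log_speed", p.speed_shape, p.speed_rate))):
            Sy = ssum(batch[yk])
            Sly = ssum(batch[lyk])
            col = (0, 2, 5)[j]
            ge[:, col] = sh * ((np.log(rt) - special.digamma(sh)) * S0 + Sly)
            ge[:, col + 1] = sh * S0 - rt * Sy
        ge[:, 4] = ssum(batch["lunges"]) - p.lunge_rate * S0
        Ssin = ssum(np.sin(batch["turn_angle_rad"]))
        Scos = ssum(np.cos(batch["turn_angle_rad"]))
        ge[:, 7] = p.kappa * (Ssin * np.cos(p.mu) - Scos * np.sin(p.mu))
        A1 = special.ive(1, p.kappa) / special.ive(0, p.kappa)
        ge[:, 8] = p.kappa * (Scos * np.cos(p.mu) + Ssin * np.sin(p.mu) - S0 * A1)
        grad[lay["emis"]] += ge.ravel()

        # --- transitions, initials, mixing
        g_eta = np.zeros((K, N, N))
        g_beta = np.zeros((d, K, N, N))
        g_delta = np.zeros((K, N - 1)) if N > 1 else None
        for k in range(K):
            gamma_k, (xi, Gam) = posts[k]
            R = xi - xi.sum(axis=3, keepdims=True) * Gam[:, 1:]
            g_eta[k] = np.einsum("w,wtij->ij", pwk[:, k], R)
            if d:
                g_beta[:, k] = np.einsum("w,wtc,wtij->cij",
                                         pwk[:, k], batch["X"][:, 1:], R)
            if N > 1:
                g_delta[k] = (pwk[:, [k]] * (gamma_k[:, 0, :N - 1]
                                             - p.delta[k, :N - 1])).sum(axis=0)
        grad[lay["eta"]] += g_eta[:, off].ravel()
        if d:
            if spec.covariate_sharing == "per_context":
                grad[lay["beta"]] += g_beta[:, :, off].ravel()
            else:
                grad[lay["beta"]] += g_beta.sum(axis=1)[:, off].ravel()
        if N > 1:
            grad[lay["delta"]] += g_delta.ravel()
        if K > 1:
            grad[lay["pi"]] += (pwk[:, :K - 1] - p.pi[None, :K - 1]).sum(axis=0)

    return total, grad


def _neg_loglik_grad(theta, spec, batches):
    ll, g = _loglik_and_grad(theta, spec, batches, True)
    return -ll, -g


def forward_loglik(sequence: pd.DataFrame, params: HMMParams, context_k: int,
                   spec: HMMSpec | None = None) -> float:
    """Exact log likelihood of one whale's sequence under one context.

    ``context_k`` is 1-based.  ``sequence`` uses the observation column
    names in :data:`STREAMS`; the transition covariate, if the model has
    one, is read from the ``covariate`` column (model/link scale) unless a
    spec naming another covariate source is given.
    """
    d = params.beta.shape[0]
    N = params.delta.shape[1]
    if spec is None:
        cov = "custom" if (d and N > 1 and "covariate" in sequence) else "none"
        spec = HMMSpec(n_states=N, n_contexts=params.pi.size, covariate=cov)
    df = sequence.copy()
    if "whale_id" not in df:
        df["whale_id"] = "w0"
    batches, _ = _prepare(df, spec)
    ll, _, _ = _forward_backward(batches[0], params, context_k - 1, False)
    return float(ll[0])


def mixture_loglik(dataset: pd.DataFrame, params: HMMParams,
                   spec: HMMSpec | None = None) -> float:
    """Whole-dataset log likelihood: whales independent, contexts mixed.

    ``sum_w log sum_k pi_k exp(forward_loglik(w, k))`` evaluated with
    log-sum-exp.
    """
    d = params.beta.shape[0]
    if spec is None:
        cov = "custom" if (d and "covariate" in dataset) else "none"
        spec = HMMSpec(n_states=params.delta.shape[1], n_contexts=params.pi.size,
                       covariate=cov)
    batches, _ = _prepare(dataset, spec)
    K = params.pi.size
    log_pi = np.log(np.maximum(params.pi, 1e-300))
    total = 0.0
    for batch in batches:
        lls = np.stack([_forward_backward(batch, params, k, False)[0]
                        for k in range(K)], axis=1)
        total += special.logsumexp(lls + log_pi[None, :], axis=1).sum()
    return float(total)


# ---------------------------------------------------------------------------
# Initialization, canonicalization, fitting
# ---------------------------------------------------------------------------

def _moment_emissions(dataset: pd.DataFrame, N: int, rng, jitter: float) -> np.ndarray:
    """Moment-based per-state emission start values from a depth-quantile split."""
    depth = dataset["max_depth_m"].to_numpy(dtype=float)
    qs = np.quantile(depth, np.linspace(0, 1, N + 1))
    qs[0] -= 1.0
    groups = np.clip(np.searchsorted(qs, depth, side="left") - 1, 0, N - 1)
    e = np.empty((N, 9))
    for n in range(N):
        g = dataset[groups == n]
        if len(g) < 3:
            g = dataset
        for j, col in enumerate(("dive_time_s", "max_depth_m", "speed_ms")):
            y = np.maximum(g[col].to_numpy(dtype=float), _GAMMA_FLOOR)
            m, v = y.mean(), max(y.var(), 1e-6)
            c = (0, 2, 5)[j]
            e[n, c] = np.log(max(m * m / v, 1e-3))
            e[n, c + 1] = np.log(max(m / v, 1e-6))
        e[n, 4] = np.log(max(g["lunges"].mean(), 0.05))
        ang = g["turn_angle_rad"].to_numpy(dtype=float)
        e[n, 7] = circmean(ang, high=np.pi, low=-np.pi)
        Rbar = min(np.hypot(np.sin(ang).mean(), np.cos(ang).mean()), 0.99)
        kap = Rbar * (2 - Rbar ** 2) / max(1 - Rbar ** 2, 1e-3)
        e[n, 8] = np.log(max(kap, 1e-3))
    if jitter:
        e += rng.normal(0, jitter, e.shape)
    # keep states ordered deep-first at the start
    order = np.argsort(-(np.exp(e[:, 2]) / np.exp(e[:, 3])))
    return e[order].ravel()


def _random_start(dataset, spec, rng, init_emissions, start_idx) -> np.ndarray:
    lay = _layout(spec)
    theta = np.zeros(lay["total"])
    if init_emissions is not None:
        theta[lay["emis"]] = init_emissions
        if start_idx > 0:
            theta[lay["emis"]] += rng.normal(0, 0.02, lay["emis"].stop - lay["emis"].start)
    else:
        theta[lay["emis"]] = _moment_emissions(dataset, spec.n_states, rng,
                                               jitter=0.0 if start_idx == 0 else 0.15)
    theta[lay["eta"]] = rng.normal(-1.5, 0.7, lay["eta"].stop - lay["eta"].start)
    theta[lay["beta"]] = rng.normal(0, 0.1, lay["beta"].stop - lay["beta"].start)
    theta[lay["delta"]] = rng.normal(0, 0.5, lay["delta"].stop - lay["delta"].start)
    theta[lay["pi"]] = rng.normal(0, 0.3, lay["pi"].stop - lay["pi"].start)
    return theta


def _canonicalize(theta: np.ndarray, spec: HMMSpec) -> np.ndarray:
    """Relabel states by descending mean max depth and contexts by descending pi."""
    p = _unpack(theta, spec)
    order = np.argsort(-(p.depth_shape / p.depth_rate), kind="stable")
    korder = np.argsort(-p.pi, kind="stable")
    q = replace(
        p,
        time_shape=p.time_shape[order], time_rate=p.time_rate[order],
        depth_shape=p.depth_shape[order], depth_rate=p.depth_rate[order],
        lunge_rate=p.lunge_rate[order],
        speed_shape=p.speed_shape[order], speed_rate=p.speed_rate[order],
        mu=p.mu[order], kappa=p.kappa[order],
        eta=p.eta[np.ix_(korder, order, order)],
        beta=p.beta[np.ix_(range(p.beta.shape[0]), korder, order, order)],
        delta=p.delta[np.ix_(korder, order)],
        pi=p.pi[korder])
    return _pack(q, spec)


@dataclass
class HMMFit:
    """A fitted context HMM with selection and inference bookkeeping."""

    spec: HMMSpec
    params: HMMParams
    theta: np.ndarray
    param_names: list[str]
    loglik: float
    n_parameters: int
    aic: float
    cov_scale: tuple[float, float]
    starts: pd.DataFrame
    best_start: int
    converged: bool
    _batches: list = field(default_factory=list, repr=False)

    def se(self) -> np.ndarray:
        ci = wald_ci(self)
        return ci["se"].to_numpy()


def fit_hmm(
    dataset: pd.DataFrame,
    spec: HMMSpec,
    n_starts: int = 50,
    seed: int = 0,
    init_emissions: np.ndarray | None = None,
    maxiter: int = 500,
) -> HMMFit:
    """Maximum-likelihood fit by multi-start quasi-Newton iteration.

    Each start draws working-scale initial values (emissions from a
    depth-quantile moment split, or warm-started from ``init_emissions``,
    typically a baseline fit's emission block; transition logits at random)
    and runs L-BFGS-B with the exact analytic score.  The best converged
    start wins; states are then relabelled deepest-first and contexts by
    descending mixing probability.  The same seed and start count reproduce
    the fit exactly.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    for col in STREAMS:
        if dataset[col].nunique() <= 1:
            raise ValueError(f"stream {col} is degenerate (no variation)")
    batches, cov_scale = _prepare(dataset, spec)
    rng = np.random.default_rng(seed)

    rows, best = [], None
    for s in range(n_starts):
        theta0 = _random_start(dataset, spec, rng, init_emissions, s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                _neg_loglik_grad, theta0, args=(spec, batches),
                method="L-BFGS-B", jac=True,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6})
        ok = bool(res.success) or res.status == 1  # status 1 = hit maxiter
        converged = bool(res.success)
        rows.append({"start": s, "loglik": -res.fun, "converged": converged,
                     "n_iter": res.nit})
        if np.isfinite(res.fun) and (best is None or -res.fun > best[0]) and ok:
            best = (-res.fun, res.x, s, converged)
    starts = pd.DataFrame(rows)
    if best is None:
        raise FitFailureError("no optimization start produced a finite likelihood",
                              diagnostics=starts)
    ll, theta, best_idx, conv = best
    theta = _canonicalize(theta, spec)
    npar = n_parameters(spec)
    return HMMFit(spec=spec, params=_unpack(theta, spec), theta=theta,
                  param_names=param_names(spec), loglik=float(ll),
                  n_parameters=npar, aic=float(-2 * ll + 2 * npar),
                  cov_scale=cov_scale, starts=starts, best_start=int(best_idx),
                  converged=conv, _batches=batches)


def jitter_refit(fit: HMMFit, dataset: pd.DataFrame, n_trials: int = 10,
                 seed: int = 0, scale: float = 0.3) -> HMMFit:
    """Re-optimize from jittered copies of a fit's non-emission parameters.

    Emulates the published safeguard against nearby local maxima: emission
    parameters are held at the fitted start values while transition,
    initial-distribution and mixing parameters are perturbed.
    """
    rng = np.random.default_rng(seed)
    lay = _layout(fit.spec)
    best_ll, best_theta = fit.loglik, fit.theta
    for _ in range(n_trials):
        theta0 = fit.theta.copy()
        theta0[lay["eta"].start:] += rng.normal(0, scale,
                                                lay["total"] - lay["eta"].start)
        res = optimize.minimize(_neg_loglik_grad, theta0, args=(fit.spec, fit._batches),
                                method="L-BFGS-B", jac=True,
                                options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6})
        if res.success and -res.fun > best_ll + 1e-9:
            best_ll, best_theta = -res.fun, res.x
    if best_ll > fit.loglik + 1e-9:
        theta = _canonicalize(best_theta, fit.spec)
        return replace(fit, theta=theta, params=_unpack(theta, fit.spec),
                       loglik=float(best_ll),
                       aic=float(-2 * best_ll + 2 * fit.n_parameters))
    return fit


def select_model(dataset: pd.DataFrame, candidate_specs, n_starts: int = 50,
                 seed: int = 0, warm_start: bool = True) -> list[HMMFit]:
    """Fit candidate structures and rank them by AIC.

    A baseline (K=1, no covariate) fit provides warm-start emission values
    for the richer candidates, mirroring the two-stage published procedure.
    Ties in AIC break toward fewer parameters.  Candidates whose fits fail
    are recorded and skipped, not fatal.
    """
    candidate_specs = list(candidate_specs)
    if len(candidate_specs) < 2:
        raise ValueError("need at least two candidate specs")
    init = None
    if warm_start:
        base = HMMSpec(n_states=candidate_specs[0].n_states, n_contexts=1,
                       covariate="none")
        try:
            base_fit = fit_hmm(dataset, base, n_starts=n_starts, seed=seed)
            init = base_fit.theta[_layout(base)["emis"]]
        except FitFailureError:
            init = None
    fits = []
    for i, sp in enumerate(candidate_specs):
        try:
            fits.append(fit_hmm(dataset, sp, n_starts=n_starts, seed=seed + 1 + i,
                                init_emissions=init))
        except (FitFailureError, ValueError) as exc:
            warnings.warn(f"candidate {sp} failed to fit: {exc}")
    fits.sort(key=lambda f: (round(f.aic, 10), f.n_parameters))
    return fits


# ---------------------------------------------------------------------------
# Inference and decoding
# ---------------------------------------------------------------------------

def _observed_information(fit: HMMFit, step: float = 1e-5) -> np.ndarray:
    """Hessian of the negative log likelihood by central differences of the score."""
    theta = fit.theta
    n = theta.size
    H = np.empty((n, n))
    for j in range(n):
        h = step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _loglik_and_grad(tp, fit.spec, fit._batches, True)
        _, gm = _loglik_and_grad(tm, fit.spec, fit._batches, True)
        H[:, j] = -(gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def wald_ci(fit: HMMFit, level: float = 0.95) -> pd.DataFrame:
    """Working-scale Wald intervals from the inverse observed information.

    Returns one row per parameter with the estimate, standard error, the
    interval bounds and an ``excludes_zero`` flag (the quantity of interest
    for exposure-covariate coefficients).  A singular information matrix
    triggers a pseudo-inverse fallback, flagged in the ``pinv`` attribute.
    """
    from scipy.stats import norm
    H = _observed_information(fit)
    pinv_used = False
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information; using pseudo-inverse "
                      "(possible non-identifiability)")
        cov = np.linalg.pinv(H)
        pinv_used = True
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = norm.ppf(0.5 + level / 2)
    out = pd.DataFrame({
        "parameter": fit.param_names,
        "estimate": fit.theta,
        "se": se,
        "lower": fit.theta - z * se,
        "upper": fit.theta + z * se,
    })
    out["excludes_zero"] = (out["lower"] > 0) | (out["upper"] < 0)
    out.attrs["pinv"] = pinv_used
    out.attrs["level"] = level
    return out


@dataclass
class DecodeResult:
    """Mixture-weighted local decoding output."""

    context_posterior: pd.DataFrame   # whales x K
    state_posterior: pd.DataFrame     # one row per dive, columns state_1..N
    states: pd.Series                 # most probable state per dive (1-based)


def local_decode(fit: HMMFit, dataset: pd.DataFrame) -> DecodeResult:
    """Per-whale context posteriors and per-dive state posteriors.

    The context posterior is proportional to ``pi_k * L_wk``; the state
    posterior mixes the per-context forward-backward posteriors with those
    context weights.  The most probable state takes the argmax (ties to the
    lower state index).
    """
    batches, _ = _prepare(dataset, fit.spec, cov_scale=fit.cov_scale)
    p = fit.params
    K = fit.spec.n_contexts
    log_pi = np.log(np.maximum(p.pi, 1e-300))
    ctx_rows, post_rows = {}, {}
    for batch in batches:
        lls, gammas = [], []
        for k in range(K):
            ll_k, gamma_k, _ = _forward_backward(batch, p, k, True)
            lls.append(ll_k)
            gammas.append(gamma_k)
        lls = np.stack(lls, axis=1)
        lw = special.logsumexp(lls + log_pi[None, :], axis=1)
        pwk = np.exp(lls + log_pi[None, :] - lw[:, None])
        gmix = np.einsum("wk,kwtn->wtn", pwk, np.stack(gammas))
        for i, wid in enumerate(batch["whale_ids"]):
            ctx_rows[wid] = pwk[i]
            post_rows[wid] = gmix[i]
    whale_order = list(dict.fromkeys(dataset["whale_id"]))
    ctx = pd.DataFrame([ctx_rows[w] for w in whale_order],
                       index=whale_order,
                       columns=[f"context_{k + 1}" for k in range(K)])
    chunks = [pd.DataFrame(post_rows[w],
                           columns=[f"state_{n + 1}" for n in range(fit.spec.n_states)])
              for w in whale_order]
    state_post = pd.concat(chunks, ignore_index=True)
    # rows are grouped per whale in first-appearance order (dataset order
    # when the input frame is already contiguous by whale)
    states = pd.Series(np.argmax(state_post.to_numpy(), axis=1) + 1, name="state")
    return DecodeResult(context_posterior=ctx, state_posterior=state_post,
                        states=states)


def fit_to_json(fit: HMMFit) -> str:
    """Serialize a fit (spec, parameters, selection quantities) to JSON."""
    p = fit.params
    return json.dumps({
        "spec": {"n_states": fit.spec.n_states, "n_contexts": fit.spec.n_contexts,
                 "covariate": fit.spec.covariate,
                 "covariate_sharing": fit.spec.covariate_sharing},
        "loglik": fit.loglik, "n_parameters": fit.n_parameters, "aic": fit.aic,
        "cov_scale": list(fit.cov_scale),
        "params": {k: np.asarray(getattr(p, k)).tolist() for k in (
            "time_shape", "time_rate", "depth_shape", "depth_rate", "lunge_rate",
            "speed_shape", "speed_rate", "mu", "kappa", "eta", "beta", "delta", "pi")},
        "best_start": fit.best_start, "n_starts": int(len(fit.starts)),
        "converged": fit.converged,
    }, indent=1)
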