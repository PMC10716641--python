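"""Within-individual change metrics and dose-as-time exposure-response.

Two individual-level analyses.  First, a Mahalanobis-distance series:
multivariate behaviour summarized in sliding windows is compared with a
pre-exposure baseline via ``sqrt((x - mu)' S^-1 (x - mu))``, with mean and
covariance estimated from baseline windows (ridge-regularized when the
baseline is too short to support a full covariance).

Second, exposure-response functions over expert severity scores.  Each
exposure CEE contributes one observation per severity band (low = scores
1-3, moderate = 4-6; no high-band responses were observed): an *event* at
the cumulative sound exposure level (cSEL) printed at the change point
when the band was reached, otherwise right-censoring at the maximum cSEL
of the exposure sequence.  Accumulated dose thus plays the role of time
in marginal stratified Cox proportional-hazards models (Breslow ties,
coefficients shared across strata unless an interaction is requested),
with standard errors corrected for within-whale correlation by a grouped
(leave-one-whale-out) jackknife.  Proportional hazards are checked with
the scaled-Schoenfeld (Grambsch-Therneau) test against dose rank, and
dose-response curves come from the Breslow baseline cumulative hazard,
with pointwise intervals from the jackknife on the log-cumulative-hazard
scale.

A moderate-severity response implies that a change of at least low
severity occurred, so by default it also contributes a low-stratum event
at the same dose (switchable).  Controls carry no signal type and are
excluded from hazard fitting by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "MahalanobisSeries",
    "HazardsFit",
    "PHTestResult",
    "mahalanobis_series",
    "build_event_table",
    "breslow_partial_loglik",
    "fit_hazards",
    "ph_test",
    "response_function",
    "SEVERITY_BANDS",
]

SEVERITY_BANDS = {"low": (1, 3), "moderate": (4, 6), "high": (7, 9)}


# ---------------------------------------------------------------------------
# Mahalanobis change metric
# ---------------------------------------------------------------------------

@dataclass
class MahalanobisSeries:
    """Windowed multivariate distance from a baseline behaviour cloud."""

    times: np.ndarray
    distances: np.ndarray
    baseline_interval: tuple[float, float]
    metrics: list[str]
    regularized: bool = False


def mahalanobis_series(
    metric_series: pd.DataFrame,
    baseline_interval: tuple[float, float],
    window_s: float = 300.0,
    regularization: float = 1e-6,
) -> MahalanobisSeries:
    """Windowed Mahalanobis distance of behaviour from its baseline.

    ``metric_series`` needs a ``time_s`` column plus one column per metric.
    Rows are averaged into consecutive windows of ``window_s``; windows
    whose centres fall inside ``baseline_interval`` define the baseline
    mean and covariance.  A ridge of ``regularization * trace(S)/p`` is
    added when the covariance is near-singular, and is forced (with a
    warning) when there are fewer baseline windows than metrics.
    """
    cols = [c for c in metric_series.columns if c != "time_s"]
    if not cols:
        raise ValueError("metric_series has no metric columns")
    t = metric_series["time_s"].to_numpy(dtype=float)
    n_win = int(np.floor((t.max() - t.min()) / window_s)) + 1
    edges = t.min() + np.arange(n_win + 1) * window_s
    centres, rows = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (t >= lo) & (t < hi)
        sub = metric_series.loc[m, cols]
        if m.any() and not sub.isna().any().any():
            centres.append((lo + hi) / 2)
            rows.append(sub.mean().to_numpy())
    centres = np.asarray(centres)
    Xw = np.asarray(rows)
    base = (centres >= baseline_interval[0]) & (centres < baseline_interval[1])
    nb = int(base.sum())
    if nb < 2:
        raise ValueError("baseline interval must contain at least 2 windows")
    mu = Xw[base].mean(axis=0)
    S = np.cov(Xw[base], rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    p = len(cols)
    regularized = False
    if nb <= p:
        warnings.warn("fewer baseline windows than metrics; forcing ridge regularization")
        regularized = True
    cond = np.linalg.cond(S)
    if regularized or not np.isfinite(cond) or cond > 1e10:
        S = S + np.eye(p) * max(regularization * np.trace(S) / p, 1e-12)
        regularized = True
    Sinv = np.linalg.inv(S)
    dev = Xw - mu
    d2 = np.einsum("wi,ij,wj->w", dev, Sinv, dev)
    return MahalanobisSeries(times=centres, distances=np.sqrt(np.maximum(d2, 0.0)),
                             baseline_interval=tuple(baseline_interval),
                             metrics=cols, regularized=regularized)


# ---------------------------------------------------------------------------
# Severity event table
# ---------------------------------------------------------------------------

def build_event_table(
    severity_table: pd.DataFrame,
    dose_field: str = "csel_db",
    strata: tuple[str, ...] = ("low", "moderate"),
    moderate_implies_low: bool = True,
    include_unscored_moderate: bool = True,
) -> pd.DataFrame:
    """Expand the expert-severity table into per-stratum survival rows.

    Exposure CEEs only (controls have no signal type).  For each CEE and
    severity band the row is an event at the change-point dose when the
    band's score range was reached and a right-censored row at the CEE's
    printed (maximum) dose otherwise.  An unscored change described as
    moderate is coded as a moderate-band event when
    ``include_unscored_moderate`` (switchable); a moderate response also
    fires the low stratum at the same dose when ``moderate_implies_low``.
    """
    df = severity_table[severity_table["cee_type"].isin(["MFAS", "PRN"])].copy()
    rows = []
    for _, r in df.iterrows():
        dose = r[dose_field]
        if pd.isna(dose):
            warnings.warn(f"{r['subject_id']}: exposure CEE without a usable dose; excluded")
            continue
        score = r.get("severity_score")
        changed = str(r.get("change", "no")).lower() == "yes"
        if changed and pd.isna(score) and include_unscored_moderate \
                and "moderate" in str(r.get("description", "")):
            score = 5.0  # coded into the moderate band; dose is as printed
        for stratum in strata:
            lo, hi = SEVERITY_BANDS[stratum]
            event = 0
            if changed and not pd.isna(score):
                in_band = lo <= float(score) <= hi
                implied = (moderate_implies_low and stratum == "low"
                           and float(score) > hi)
                event = int(in_band or implied)
            rows.append({
                "whale_id": r["subject_id"], "stratum": stratum,
                "dose": float(dose), "event": event,
                "signal_type": r["cee_type"],
                "behavioural_state": r["behavioural_state"],
            })
    out = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# Stratified Cox model (Breslow ties) and inference
# ---------------------------------------------------------------------------

def _design(event_table: pd.DataFrame, covariates: list[str],
            interaction: bool = False) -> pd.DataFrame:
    """Dummy-coded covariate design appended to the survival columns."""
    df = event_table[["whale_id", "stratum", "dose", "event"]].copy()
    names = []
    for cov in covariates:
        col = event_table[cov]
        if pd.api.types.is_numeric_dtype(col):
            df[cov] = col.to_numpy(dtype=float)
            names.append(cov)
        else:
            d = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True, dtype=float)
            for c in d.columns:
                df[c] = d[c].to_numpy()
            names.extend(d.columns)
    if interaction:
        sd = pd.get_dummies(df["stratum"], prefix="stratum", drop_first=True, dtype=float)
        for base in list(names):
            for sc in sd.columns:
                df[f"{base}:{sc}"] = df[base] * sd[sc].to_numpy()
                names.append(f"{base}:{sc}")
    df.attrs["covariate_columns"] = names
    return df


def breslow_partial_loglik(df: pd.DataFrame, covariate_columns: list[str],
                           beta: np.ndarray) -> float:
    """Stratified Cox partial log likelihood with Breslow tie handling.

    Each tied event group of size ``d`` at dose ``t`` contributes
    ``sum of x_i'beta - d * log(sum over the risk set of exp(x'beta))``.
    The null model is this quantity at ``beta = 0``.
    """
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for _, g in df.groupby("stratum"):
        X = g[covariate_columns].to_numpy(dtype=float) if covariate_columns else \
            np.zeros((len(g), 0))
        eta = X @ beta if beta.size else np.zeros(len(g))
        dose = g["dose"].to_numpy(dtype=float)
        ev = g["event"].to_numpy(dtype=bool)
        for t in np.unique(dose[ev]):
            died = ev & (dose == t)
            at_risk = dose >= t
            total += eta[died].sum() - died.sum() * np.log(np.exp(eta[at_risk]).sum())
    return float(total)


def _score_info(df: pd.DataFrame, cols: list[str], beta: np.ndarray):
    """Breslow partial-likelihood score vector and information matrix."""
    p = len(cols)
    U = np.zeros(p)
    I = np.zeros((p, p))
    for _, g in df.groupby("stratum"):
        X = g[cols].to_numpy(dtype=float)
        dose = g["dose"].to_numpy(dtype=float)
        ev = g["event"].to_numpy(dtype=bool)
        eta = X @ beta
        w = np.exp(eta)
        for t in np.unique(dose[ev]):
            died = ev & (dose == t)
            at_risk = dose >= t
            ww = w[at_risk] / w[at_risk].sum()
            xbar = ww @ X[at_risk]
            V = (ww[:, None] * X[at_risk]).T @ X[at_risk] - np.outer(xbar, xbar)
            d = int(died.sum())
            U += X[died].sum(axis=0) - d * xbar
            I += d * V
    return U, I


def _newton_breslow(df: pd.DataFrame, cols: list[str],
                    tol: float = 1e-10, maxiter: int = 50):
    """Newton-Raphson maximization of the Breslow partial likelihood."""
    beta = np.zeros(len(cols))
    ll = breslow_partial_loglik(df, cols, beta)
    for _ in range(maxiter):
        U, I = _score_info(df, cols, beta)
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(I) @ U
        # step-halving for robustness
        for _ in range(30):
            cand = beta + step
            ll_new = breslow_partial_loglik(df, cols, cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2
        if np.any(np.abs(cand) > 50):
            warnings.warn("possible monotone likelihood (perfect separation); "
                          "coefficient diverging")
            beta, ll = cand, ll_new
            break
        delta_ll = ll_new - ll
        beta, ll = cand, ll_new
        if abs(delta_ll) < tol:
            break
    _, I = _score_info(df, cols, beta)
    try:
        cov = np.linalg.inv(I)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(I)
    return beta, ll, np.sqrt(np.maximum(np.diag(cov), 0.0))


@dataclass
class HazardsFit:
    """Fitted stratified proportional-hazards model with jackknife SEs."""

    coefficients: pd.DataFrame      # coef, se_model, se_jackknife, z, p
    loglik: float
    aic: float
    n_events: int
    strata: list[str]
    covariate_columns: list[str]
    interaction: bool
    ties: str = "breslow"
    design: pd.DataFrame = field(repr=False, default=None)


def _fit_beta(frame: pd.DataFrame, cols: list[str], ties: str) -> np.ndarray:
    if ties == "breslow":
        return _newton_breslow(frame, cols)[0]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(frame[["dose", "event", "stratum"] + cols],
                duration_col="dose", event_col="event", strata="stratum")
    return cph.params_.reindex(cols).to_numpy()


def fit_hazards(
    event_table: pd.DataFrame,
    covariates: list[str] | None,
    strata: str = "stratum",
    interaction: bool = False,
    ties: str = "breslow",
) -> HazardsFit:
    """Fit a marginal stratified Cox model with dose as the event axis.

    ``covariates`` of ``None`` or ``[]`` fits the null model (AIC =
    ``-2 * partial loglik at beta 0``).  Coefficients are shared across
    strata unless ``interaction`` adds stratum-specific terms.  Ties are
    handled with Breslow's method (Newton iteration on the stratified
    partial likelihood); ``ties="efron"`` delegates coefficient estimation
    to lifelines.  Model-based SEs come from the partial-likelihood
    information; grouped-jackknife SEs re-fit the model leaving out one
    whale's rows at a time.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    covariates = list(covariates or [])
    df = _design(event_table, covariates, interaction)
    cols = df.attrs["covariate_columns"]
    n_events = int(df["event"].sum())

    if not cols:
        ll0 = breslow_partial_loglik(df, [], np.empty(0))
        coefs = pd.DataFrame(columns=["coef", "se_model", "se_jackknife", "z", "p"])
        return HazardsFit(coefficients=coefs, loglik=ll0, aic=-2 * ll0,
                          n_events=n_events, strata=sorted(df["stratum"].unique()),
                          covariate_columns=[], interaction=interaction,
                          ties=ties, design=df)

    if ties == "breslow":
        beta, ll, se_model = _newton_breslow(df, cols)
    else:
        beta = _fit_beta(df, cols, ties)
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[["dose", "event", "stratum"] + cols],
                    duration_col="dose", event_col="event", strata="stratum")
        ll = float(cph.log_likelihood_)
        se_model = cph.standard_errors_.reindex(cols).to_numpy()

    # grouped jackknife over whales
    whales = df["whale_id"].unique()
    jack = []
    for w in whales:
        sub = df[df["whale_id"] != w]
        if sub["event"].sum() == 0:
            continue
        try:
            jack.append(_fit_beta(sub, cols, ties))
        except Exception:
            continue
    if len(jack) >= 2:
        J = np.asarray(jack)
        se_jack = np.sqrt((len(J) - 1) / len(J) * ((J - J.mean(0)) ** 2).sum(0))
    else:
        se_jack = np.full(len(cols), np.nan)

    z = beta / np.where(se_jack > 0, se_jack, np.nan)
    coefs = pd.DataFrame({
        "coef": beta, "se_model": se_model, "se_jackknife": se_jack,
        "z": z, "p": 2 * stats.norm.sf(np.abs(z)),
    }, index=cols)
    return HazardsFit(coefficients=coefs, loglik=float(ll),
                      aic=float(-2 * ll + 2 * len(cols)), n_events=n_events,
                      strata=sorted(df["stratum"].unique()),
                      covariate_columns=cols, interaction=interaction,
                      ties=ties, design=df)


def _schoenfeld(fit: HazardsFit):
    """Unscaled Schoenfeld residuals and per-event risk-set covariances."""
    df = fit.design
    cols = fit.covariate_columns
    beta = fit.coefficients["coef"].to_numpy()
    res_rows, V_list, doses = [], [], []
    for _, g in df.groupby("stratum"):
        X = g[cols].to_numpy(dtype=float)
        eta = X @ beta
        w = np.exp(eta)
        dose = g["dose"].to_numpy(dtype=float)
        ev = g["event"].to_numpy(dtype=bool)
        for t in np.unique(dose[ev]):
            at_risk = dose >= t
            ww = w[at_risk] / w[at_risk].sum()
            xbar = ww @ X[at_risk]
            V = (ww[:, None] * X[at_risk]).T @ X[at_risk] - np.outer(xbar, xbar)
            for xi in X[ev & (dose == t)]:
                res_rows.append(xi - xbar)
                V_list.append(V)
                doses.append(t)
    return (np.asarray(res_rows), np.asarray(V_list), np.asarray(doses))


@dataclass
class PHTestResult:
    """Scaled-Schoenfeld proportional-hazards test (dose-rank transform)."""

    per_term: pd.DataFrame          # chi2, df, p per covariate
    global_chi2: float
    global_df: int
    global_p: float
    residual_score_sum: np.ndarray  # ~0 at the MLE


def ph_test(fit: HazardsFit, event_table: pd.DataFrame | None = None) -> PHTestResult:
    """Test proportional hazards via Schoenfeld-residual association with dose rank.

    Grambsch-Therneau form: with residuals ``s_t``, centred transform
    ``g_t`` (rank of the event dose) and average information ``Vbar``, the
    global statistic is ``u' [Vbar * sum((g-gbar)^2)]^{-1} u`` with
    ``u = sum((g_t - gbar) s_t)``, chi-square on one df per coefficient.
    """
    if not fit.covariate_columns:
        raise ValueError("PH test undefined for the null model")
    S, Vs, doses = _schoenfeld(fit)
    if S.shape[0] == 0:
        raise ValueError("PH test undefined without events")
    g = stats.rankdata(doses)
    gc = g - g.mean()
    u = gc @ S
    # Grambsch-Therneau variance of u, including the cross-term that
    # accounts for estimating beta
    sumV = Vs.sum(axis=0)
    sumgV = (gc[:, None, None] * Vs).sum(axis=0)
    sumg2V = ((gc ** 2)[:, None, None] * Vs).sum(axis=0)
    try:
        cov_u = sumg2V - sumgV @ np.linalg.solve(sumV, sumgV)
        chi2 = float(u @ np.linalg.solve(cov_u, u))
    except np.linalg.LinAlgError:
        cov_u = sumg2V - sumgV @ np.linalg.pinv(sumV) @ sumgV
        chi2 = float(u @ np.linalg.pinv(cov_u) @ u)
    p_global = float(stats.chi2.sf(chi2, df=len(u)))
    per = []
    for j, name in enumerate(fit.covariate_columns):
        c = u[j] ** 2 / cov_u[j, j] if cov_u[j, j] > 0 else np.nan
        per.append({"term": name, "chi2": c, "df": 1,
                    "p": float(stats.chi2.sf(c, df=1)) if np.isfinite(c) else np.nan})
    return PHTestResult(per_term=pd.DataFrame(per).set_index("term"),
                        global_chi2=chi2, global_df=len(u), global_p=p_global,
                        residual_score_sum=S.sum(axis=0))


def _baseline_cumhaz(df: pd.DataFrame, cols: list[str], beta: np.ndarray,
                     stratum: str, doses_out: np.ndarray) -> np.ndarray:
    """Breslow baseline cumulative hazard of one stratum on a dose grid."""
    g = df[df["stratum"] == stratum]
    X = g[cols].to_numpy(dtype=float) if cols else np.zeros((len(g), 0))
    eta = X @ beta if beta.size else np.zeros(len(g))
    w = np.exp(eta)
    dose = g["dose"].to_numpy(dtype=float)
    ev = g["event"].to_numpy(dtype=bool)
    times = np.unique(dose[ev])
    increments = np.array([np.sum(ev & (dose == t)) / w[dose >= t].sum() for t in times])
    H = np.array([increments[times <= d].sum() for d in doses_out])
    return H


def response_function(
    fit: HazardsFit,
    event_table: pd.DataFrame,
    newdata: pd.DataFrame,
    doses: np.ndarray | None = None,
    level: float = 0.95,
) -> dict[tuple, pd.DataFrame]:
    """Dose-response curves ``1 - S(dose)`` per stratum and covariate profile.

    ``newdata`` holds one row per profile with the model's covariate
    columns (raw categories are dummy-coded the same way as in fitting).
    Pointwise intervals use the grouped-jackknife variance of the log
    cumulative hazard.  Doses outside the observed range are clamped to
    the range boundary (the curve is flat there) and flagged via the
    frame's ``clamped`` column.
    """
    df = fit.design
    cols = fit.covariate_columns
    beta = fit.coefficients["coef"].to_numpy() if cols else np.empty(0)
    if doses is None:
        doses = np.linspace(df["dose"].min(), df["dose"].max(), 101)
    doses = np.asarray(doses, dtype=float)
    lo_d, hi_d = df["dose"].min(), df["dose"].max()
    # below the observed range the cumulative hazard is exactly 0; above it
    # the baseline is flat, so evaluation clamps to the largest dose
    clamped = (doses < lo_d) | (doses > hi_d)
    d_eval = np.minimum(doses, hi_d)

    # dummy-code the profiles against the fitted column names (robust to
    # profiles containing a single category level)
    prof_X = np.zeros((len(newdata), len(cols)))
    for j, col in enumerate(cols):
        if col in newdata.columns:
            prof_X[:, j] = newdata[col].to_numpy(dtype=float)
            continue
        for c in newdata.columns:
            if col.startswith(f"{c}_"):
                lev = col[len(c) + 1:]
                prof_X[:, j] = (newdata[c].astype(str) == lev).to_numpy(float)
                break

    whales = df["whale_id"].unique()
    out = {}
    z = stats.norm.ppf(0.5 + level / 2)
    for stratum in fit.strata:
        H0 = _baseline_cumhaz(df, cols, beta, stratum, d_eval)
        for i in range(len(newdata)):
            risk = float(np.exp(prof_X[i] @ beta)) if cols else 1.0
            H = H0 * risk
            # jackknife on log H
            logs = []
            for w in whales:
                sub = df[df["whale_id"] != w]
                if sub.loc[sub["stratum"] == stratum, "event"].sum() == 0:
                    continue
                if cols:
                    try:
                        b_i = _fit_beta(sub, cols, fit.ties)
                    except Exception:
                        continue
                else:
                    b_i = np.empty(0)
                H_i = _baseline_cumhaz(sub, cols, b_i, stratum, d_eval)
                if cols:
                    H_i = H_i * float(np.exp(prof_X[i] @ b_i))
                logs.append(np.log(np.maximum(H_i, 1e-300)))
            prob = 1.0 - np.exp(-H)
            if len(logs) >= 2:
                L = np.asarray(logs)
                var = (len(L) - 1) / len(L) * ((L - L.mean(0)) ** 2).sum(0)
                sd = np.sqrt(var)
                logH = np.log(np.maximum(H, 1e-300))
                lo = 1.0 - np.exp(-np.exp(np.minimum(logH - z * sd, 700.0)))
                hi = 1.0 - np.exp(-np.exp(np.minimum(logH + z * sd, 700.0)))
                lo[H <= 0] = 0.0
                hi[H <= 0] = 0.0
            else:
                lo = np.full_like(prob, np.nan)
                hi = np.full_like(prob, np.nan)
            key = (stratum,) + tuple(newdata.iloc[i])
            out[key] = pd.DataFrame({
                "dose": doses, "response_prob": prob,
                "lower": lo, "upper": hi, "clamped": clamped})
    return out
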