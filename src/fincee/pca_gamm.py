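"""Group-level response analysis: PCA of dive metrics + additive models.

Per metric category, the dive-by-dive metrics are reduced by principal
component analysis of their correlation matrix (the metrics carry
incommensurate units, so each is standardized first).  Components
explaining more than 10% of the variance become response variables in
penalized-spline additive models with parametric treatment terms:

* phase model (all dives):
  ``axis ~ treatment_status * treatment_type + behavioural_state
  + s(max RL) + s(cumulative SEL) + s(average RL)``
* exposure-only model (exposure-phase dives):
  ``axis ~ treatment_type * behavioural_state
  + s(max RL) + s(min RL) + s(cumulative SEL)``

Whale identity enters as a grouping intercept (per-whale dummy terms
approximating the mixed structure).  Spline penalties are chosen by
generalized cross-validation unless fixed; term-level approximate tests
and effective degrees of freedom are reported per smooth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "PCAResult",
    "ResponseModelFit",
    "run_pca",
    "select_components",
    "fit_response_model",
    "VARIANCE_THRESHOLD",
]

VARIANCE_THRESHOLD = 0.10
_SMOOTHS = {
    "phase_model": ["max_rl", "cumulative_sel", "avg_rl"],
    "exposure_only_model": ["max_rl", "min_rl", "cumulative_sel"],
}


@dataclass
class PCAResult:
    """Correlation-matrix PCA of one metric category."""

    loadings: pd.DataFrame          # metrics x components, orthonormal columns
    variance_fraction: np.ndarray   # sums to 1
    scores: pd.DataFrame            # dives x components, zero-mean
    category: str
    dropped: list[str] = field(default_factory=list)


def run_pca(metric_table: pd.DataFrame, category: str | None = None) -> PCAResult:
    """PCA on the correlation matrix of a category's metrics.

    ``category`` of ``"dive"``/``"angular"``/``"horizontal"`` selects the
    ``c1_``/``c2_``/``c3_`` column prefix; ``None`` uses every numeric
    column.  Rows with missing values are dropped listwise and constant
    columns removed with a warning.  Components are ordered by decreasing
    variance and each loading column's sign is fixed so its
    largest-magnitude entry is positive.
    """
    prefix = {"dive": "c1_", "angular": "c2_", "horizontal": "c3_"}.get(category)
    if prefix is not None:
        cols = [c for c in metric_table.columns if c.startswith(prefix)]
    else:
        cols = [c for c in metric_table.columns
                if pd.api.types.is_numeric_dtype(metric_table[c])]
    if len(cols) < 2:
        raise ValueError("need at least two metrics for a PCA")
    X = metric_table[cols].dropna()
    if len(X) < 2:
        raise ValueError("need at least two complete dives for a PCA")
    dropped = [c for c in cols if X[c].std() == 0]
    if dropped:
        warnings.warn(f"dropping constant metric columns: {dropped}")
        X = X.drop(columns=dropped)
    Z = (X - X.mean()) / X.std(ddof=1)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    # sign convention: largest-magnitude loading of each component positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=list(X.columns), columns=comp_names)
    scores = pd.DataFrame(Z.to_numpy() @ evecs, index=X.index, columns=comp_names)
    return PCAResult(loadings=loadings,
                     variance_fraction=evals / evals.sum(),
                     scores=scores, category=category or "all", dropped=dropped)


def select_components(pca: PCAResult, threshold: float = VARIANCE_THRESHOLD) -> list[str]:
    """Components whose variance fraction strictly exceeds ``threshold``.

    Component 1 is always retained (with a warning if it falls at or below
    the threshold) so every category yields at least one response axis.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    keep = [name for name, v in zip(pca.loadings.columns, pca.variance_fraction)
            if v > threshold]
    if not keep:
        warnings.warn("no component exceeds the variance threshold; keeping PC1")
        keep = [pca.loadings.columns[0]]
    return keep


@dataclass
class ResponseModelFit:
    """One additive response model for one PCA axis."""

    axis: str
    formula_variant: str
    parametric_pvalues: dict[str, float]
    smooth_pvalues: dict[str, float]
    smooth_edf: dict[str, float]
    alpha: np.ndarray
    r2_adj: float
    n_obs: int
    fitted: np.ndarray
    partial_effects: dict[str, pd.DataFrame]
    results: object = field(repr=False, default=None)


_ALPHA_GRID = 10.0 ** np.arange(-1, 9)


def _select_alpha_gcv(y: np.ndarray, Xlin: np.ndarray, smoother,
                      n_sweeps: int = 2) -> list[float]:
    """Per-block penalty weights by coordinate descent on a GCV grid.

    Deterministic and cheap: each block's weight is optimized over a log
    grid while the others are held fixed, for a couple of sweeps.
    """
    k = len(smoother.smoothers)
    alpha = [1.0] * k

    def gcv(al):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return GLMGam(y, exog=Xlin, smoother=smoother, alpha=al).fit().gcv
        except Exception:
            return np.inf

    for _ in range(n_sweeps):
        for j in range(k):
            scores = []
            for a in _ALPHA_GRID:
                trial = list(alpha)
                trial[j] = float(a)
                scores.append(gcv(trial))
            alpha[j] = float(_ALPHA_GRID[int(np.nanargmin(scores))])
    return alpha


def _dummies(s: pd.Series, name: str) -> pd.DataFrame:
    return pd.get_dummies(s.astype(str), prefix=name, drop_first=True, dtype=float)


def _whale_smoother(whale_ids: pd.Series):
    """Ridge-penalized whale-intercept block (a random intercept in
    penalized form): all-level dummy basis with an identity penalty, so the
    per-whale offsets are shrunk toward zero with a GCV-chosen variance."""
    from statsmodels.gam.smooth_basis import UnivariateGenericSmoother
    codes = pd.Categorical(whale_ids.astype(str)).codes.astype(float)
    D = np.eye(int(codes.max()) + 1)[codes.astype(int)]
    return UnivariateGenericSmoother(codes, D, np.zeros_like(D), np.zeros_like(D),
                                     np.eye(D.shape[1]), variable_name="whale"), codes


def fit_response_model(
    scores: pd.Series | np.ndarray,
    design_table: pd.DataFrame,
    formula_variant: str = "phase_model",
    axis: str = "PC1",
    spline_df: int = 8,
    alpha: list[float] | np.ndarray | None = None,
    whale_intercepts: bool = True,
) -> ResponseModelFit:
    """Fit one PCA axis against treatment terms and received-level smooths.

    ``design_table`` must carry ``phase`` (before/during/after),
    ``cee_type``, ``behavioural_state``, ``whale_id`` and the smooth
    covariates named in the chosen variant.  The exposure-only variant is
    fitted on exposure-phase dives only.

    Splines are built on the empirical-rank (quantile) scale of each
    covariate: received-level doses carry a point mass at 0 (unexposed
    dives) and a gap up to the lowest exposed level, which would leave
    equally-spaced-knot basis functions without support; the monotone rank
    transform is the usual quantile-style knot placement and leaves term
    tests and monotonicity statements unchanged.  Whale identity enters as
    a ridge-penalized intercept block.  When ``alpha`` is ``None`` all
    penalty weights (smooths and whale block) are chosen by generalized
    cross-validation on a log grid.  Term-level inference uses drop-one-term
    approximate F tests, which stay defined under the strong concurvity
    among the received-level covariates.  Basis dimension falls back
    automatically when a covariate has too few unique values.
    """
    if formula_variant not in _SMOOTHS:
        raise ValueError("formula_variant must be 'phase_model' or 'exposure_only_model'")
    df = design_table.copy()
    df = df.assign(_y=np.asarray(scores, dtype=float))
    if formula_variant == "exposure_only_model":
        df = df[df["phase"] == "during"]
    df = df.dropna(subset=_SMOOTHS[formula_variant]).reset_index(drop=True)
    y = df["_y"].to_numpy()

    # parametric design
    parts = {"intercept": pd.DataFrame({"const": np.ones(len(df))})}
    if formula_variant == "phase_model":
        parts["treatment_status"] = _dummies(df["phase"], "phase")
        parts["treatment_type"] = _dummies(df["cee_type"], "type")
        inter = {}
        for pc in parts["treatment_status"].columns:
            for tc in parts["treatment_type"].columns:
                inter[f"{pc}:{tc}"] = parts["treatment_status"][pc] * parts["treatment_type"][tc]
        parts["status_x_type"] = pd.DataFrame(inter)
        parts["behavioural_state"] = _dummies(df["behavioural_state"], "state")
    else:
        parts["treatment_type"] = _dummies(df["cee_type"], "type")
        parts["behavioural_state"] = _dummies(df["behavioural_state"], "state")
        inter = {}
        for pc in parts["treatment_type"].columns:
            for tc in parts["behavioural_state"].columns:
                inter[f"{pc}:{tc}"] = parts["treatment_type"][pc] * parts["behavioural_state"][tc]
        parts["type_x_state"] = pd.DataFrame(inter)
    # drop empty / constant dummy blocks (e.g. single-level factors)
    parts = {k: v for k, v in parts.items()
             if v.shape[1] and not (k != "intercept" and (v.std() == 0).all())}
    Xlin = pd.concat(parts.values(), axis=1)
    term_cols = {k: list(v.columns) for k, v in parts.items() if k != "intercept"}

    smooth_names = _SMOOTHS[formula_variant]
    xs, dfs, transforms = [], [], {}
    for name in smooth_names:
        x = df[name].to_numpy(dtype=float)
        ranks = rankdata(x, method="average") / len(x)
        transforms[name] = (np.sort(x), np.sort(ranks))
        uq = np.unique(x).size
        k = min(spline_df, max(uq - 1, 4))
        if k < spline_df:
            warnings.warn(f"smooth '{name}': basis reduced to df={k} "
                          f"({uq} unique values)")
        xs.append(ranks)
        dfs.append(k)
    bs = BSplines(np.column_stack(xs), df=dfs, degree=[3] * len(xs),
                  variable_names=smooth_names)

    from statsmodels.gam.smooth_basis import GenericSmoothers
    smooths = list(bs.smoothers)
    x_cols = list(xs)
    use_whale = whale_intercepts and df["whale_id"].nunique() > 1
    if use_whale:
        ws, codes = _whale_smoother(df["whale_id"])
        smooths.append(ws)
        x_cols.append(codes)

    def _make_smoother(keep_spline_idx):
        kept = [smooths[j] for j in keep_spline_idx]
        kx = [x_cols[j] for j in keep_spline_idx]
        if use_whale:
            kept.append(smooths[-1])
            kx.append(x_cols[-1])
        if not kept:
            return None
        return GenericSmoothers(np.column_stack(kx), smoothers=kept)

    gs = _make_smoother(list(range(len(smooth_names))))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if alpha is None:
            alpha = _select_alpha_gcv(y, Xlin.to_numpy(), gs)
        res = GLMGam(y, exog=Xlin.to_numpy(), smoother=gs, alpha=list(alpha)).fit()

    nlin = Xlin.shape[1]
    n = len(y)
    rss_full = float(((y - res.fittedvalues) ** 2).sum())
    edf_total = float(np.sum(res.edf))
    df_resid = max(n - edf_total, 1.0)

    smooth_edf = {}
    pos = nlin
    for i, name in enumerate(smooth_names):
        dbi = bs.smoothers[i].dim_basis
        smooth_edf[name] = float(res.edf[pos:pos + dbi].sum())
        pos += dbi

    # drop-one-term approximate F tests
    def _rss_without(drop_cols, drop_smooth):
        cols_keep = [c for c in Xlin.columns if drop_cols is None or c not in drop_cols]
        Xl = Xlin[cols_keep].to_numpy()
        keep_idx = [j for j in range(len(smooth_names)) if j != drop_smooth]
        sm_r = _make_smoother(keep_idx)
        al = [alpha[j] for j in keep_idx] + ([alpha[-1]] if use_whale else [])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = GLMGam(y, exog=Xl, smoother=sm_r, alpha=al).fit()
        return float(((y - r.fittedvalues) ** 2).sum())

    def _fp(rss_red, df1):
        if rss_red <= rss_full or df1 <= 0:
            return 1.0
        from scipy.stats import f as fdist
        F = ((rss_red - rss_full) / df1) / (rss_full / df_resid)
        return float(fdist.sf(F, df1, df_resid))

    smooth_p = {name: _fp(_rss_without(None, i), max(smooth_edf[name], 1.0))
                for i, name in enumerate(smooth_names)}
    param_p = {term: _fp(_rss_without(cols, None), float(len(cols)))
               for term, cols in term_cols.items()}
    # joint test of the whole received-level block: under the strong
    # concurvity among the RL covariates, single-term deletions understate
    # a shared RL effect, so the block-level question ("does received level
    # influence the response at all?") gets its own F test
    def _rss_without_all_smooths():
        sm_r = _make_smoother([])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sm_r is None:
                import statsmodels.api as sm_api
                r = sm_api.OLS(y, Xlin.to_numpy()).fit()
            else:
                r = GLMGam(y, exog=Xlin.to_numpy(), smoother=sm_r,
                           alpha=[alpha[-1]] if use_whale else []).fit()
        return float(((y - r.fittedvalues) ** 2).sum())

    smooth_p["rl_joint"] = _fp(_rss_without_all_smooths(),
                               max(sum(smooth_edf.values()), 1.0))

    r2 = 1.0 - rss_full / (y.var() * n) if y.var() > 0 else np.nan
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - edf_total - 1, 1)

    partials = {}
    for i, name in enumerate(smooth_names):
        grid = np.linspace(df[name].min(), df[name].max(), 100)
        xv, rv = transforms[name]
        grid_r = np.interp(grid, xv, rv)
        sm = bs.smoothers[i]
        basis = sm.transform(grid_r)
        start = nlin + sum(bs.smoothers[j].dim_basis for j in range(i))
        coefs = res.params[start:start + sm.dim_basis]
        partials[name] = pd.DataFrame({name: grid, "effect": basis @ coefs})

    return ResponseModelFit(
        axis=axis, formula_variant=formula_variant,
        parametric_pvalues=param_p, smooth_pvalues=smooth_p,
        smooth_edf=smooth_edf, alpha=np.asarray(alpha, dtype=float),
        r2_adj=float(r2_adj), n_obs=n, fitted=np.asarray(res.fittedvalues),
        partial_effects=partials, results=res)
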