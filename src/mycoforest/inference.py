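"""Statistical core: boundary transform, mixed-effects models, moderation
slopes, collinearity diagnostics, random-forest screening, and the
ecoregion-stratified 50% subsampling check.

The carbon-stock models are linear mixed models on the natural-log scale
with an ecoregion random intercept. The transformed EcM dominance enters on
its natural (0, 1) scale so its coefficient is directly interpretable;
continuous covariates and interaction moderators are z-scored within the
sample, and standardized coefficients are reported alongside as
b * sd(x) / sd(y).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (DegenerateInputError, DomainError, SpecificationError,
                     StagingError)

log = logging.getLogger("mycoforest")

RESPONSES = ("tree_c", "soil_c", "forest_c")
MODERATORS = ("richness", "stage", "climate")

#: the random intercept is kept only when the likelihood-ratio statistic for
#: its variance exceeds this (chi-square(1) 5% point); below it the variance
#: is indistinguishable from zero (singular) and the flagged OLS fallback is
#: used, which also makes zero-heterogeneity fits agree with OLS exactly
_VARIANCE_LRT = 3.841


def boundary_transform(y, n: int):
    """Squeeze proportions off the boundary: y' = (y*(N-1) + 0.5) / N.

    Keeps pure-AM (0) and pure-EcM (1) plots inside (0, 1) for models that
    cannot tolerate boundary values; 0.5 is a fixed point.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise DomainError("proportions must lie in [0, 1]")
    if n < 1:
        raise DomainError("sample size N must be >= 1")
    out = (y * (n - 1) + 0.5) / n
    return float(out) if out.ndim == 0 else out


def inverse_boundary_transform(y_t, n: int):
    """Inverse of :func:`boundary_transform` (exact for n > 1)."""
    y_t = np.asarray(y_t, dtype=float)
    if n <= 1:
        raise DomainError("inverse requires N > 1")
    out = (y_t * n - 0.5) / (n - 1)
    return float(out) if out.ndim == 0 else out


@dataclass
class SimpleFit:
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    conf_band: pd.DataFrame  # x, fit, ci_low, ci_high


def fit_simple_regression(x, y) -> SimpleFit:
    """OLS of y on x with the slope test and a pointwise 95% CI band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DegenerateInputError("need >= 3 finite (x, y) pairs")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in x")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), 100)
    pred = res.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    band = pd.DataFrame({"x": grid, "fit": pred["mean"],
                         "ci_low": pred["mean_ci_lower"],
                         "ci_high": pred["mean_ci_upper"]})
    return SimpleFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                     p_value=float(res.pvalues[1]), r_squared=float(res.rsquared),
                     conf_band=band)


@dataclass
class ModelSpec:
    """Fixed/random/interaction structure of a carbon-stock model.

    ``response`` is one of tree_c / soil_c / forest_c (ln-transformed before
    fitting); interactions are EcM dominance x moderator and require the
    moderator's main effect, which is always included here.
    """

    response: str = "tree_c"
    interactions: tuple[str, ...] = MODERATORS
    covariates: tuple[str, ...] = ("richness", "stage", "climate", "slope", "altitude")

    def validate(self) -> "ModelSpec":
        if self.response not in RESPONSES:
            raise SpecificationError(f"unknown response {self.response!r}")
        bad = set(self.interactions) - set(MODERATORS)
        if bad:
            raise SpecificationError(f"unknown interaction moderator(s): {sorted(bad)}")
        missing = set(self.interactions) - set(self.covariates)
        if missing:
            raise SpecificationError(
                f"interaction moderator(s) lack main effects: {sorted(missing)}"
            )
        return self


@dataclass
class FitResult:
    params: pd.DataFrame          # est, se, z, p, std_est, ci_low, ci_high per term
    cov_params: pd.DataFrame
    aic: float
    r2_marginal: float
    r2_conditional: float
    vif: pd.Series
    group_var: float
    resid_var: float
    method: str                   # "mixed" or "ols_fallback"
    n: int
    spec: ModelSpec | None = None
    meta: dict = field(default_factory=dict)

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "est"])


def build_model_frame(metrics: pd.DataFrame, response: str,
                      n_transform: int | None = None) -> pd.DataFrame:
    """Model-ready frame: ln response, transformed EcMD, z-scored covariates.

    ``n_transform`` is the N of the boundary transform; it defaults to the
    number of plots entering the model for this response.
    """
    df = metrics.copy()
    df = df[np.isfinite(df[response]) & (df[response] > 0) & df["ecmd"].notna()]
    n_dropped = len(metrics) - len(df)
    if n_dropped:
        log.info("model frame (%s): dropped %d plot(s) with missing/non-positive data",
                 response, n_dropped)
    n = n_transform if n_transform is not None else len(df)
    out = pd.DataFrame(index=df.index)
    out["y"] = np.log(df[response])
    out["ecmd_t"] = boundary_transform(df["ecmd"].to_numpy(), n)
    for name, col in [("richness", "richness"), ("climate", "climate_score"),
                      ("slope", "slope"), ("altitude", "altitude")]:
        x = df[col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise DegenerateInputError(f"zero variance in covariate {name}")
        out[f"{name}_z"] = (x - x.mean()) / sd
    out["stage"] = pd.Categorical(df["stage"], categories=["early", "middle", "late"])
    out["ecoregion_id"] = df["ecoregion_id"].to_numpy()
    return out


def _design(frame: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, pd.DataFrame]:
    X = pd.DataFrame(index=frame.index)
    X["const"] = 1.0
    X["ecmd_t"] = frame["ecmd_t"]
    cont = {"richness": "richness_z", "climate": "climate_z",
            "slope": "slope_z", "altitude": "altitude_z"}
    for cov in spec.covariates:
        if cov == "stage":
            X["stage_middle"] = (frame["stage"] == "middle").astype(float)
            X["stage_late"] = (frame["stage"] == "late").astype(float)
        else:
            X[cont[cov]] = frame[cont[cov]]
    for mod in spec.interactions:
        if mod == "stage":
            X["ecmd_t:stage_middle"] = X["ecmd_t"] * X["stage_middle"]
            X["ecmd_t:stage_late"] = X["ecmd_t"] * X["stage_late"]
        else:
            col = cont[mod]
            X[f"ecmd_t:{col}"] = X["ecmd_t"] * X[col]
    return frame["y"].to_numpy(), X


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    The constant column is skipped; perfectly collinear (aliased) columns
    are reported as infinite.
    """
    cols = [c for c in X.columns if c != "const"]
    out = {}
    for col in cols:
        others = [c for c in cols if c != col]
        if not others:
            out[col] = 1.0
            continue
        Z = sm.add_constant(X[others].to_numpy())
        res = sm.OLS(X[col].to_numpy(), Z).fit()
        r2 = min(res.rsquared, 1.0)
        if 1.0 - r2 < 1e-12:
            log.warning("vif: term %s is aliased (perfect collinearity)", col)
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def _mixed_or_ols(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray):
    """Fit MixedLM (ML); fall back to OLS when the random intercept is singular.

    Returns (params, bse, cov_params, aic, group_var, resid_var, method).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X.to_numpy(), groups=groups)
            res = model.fit(reml=False, maxiter=200)
            group_var = float(np.asarray(res.cov_re)[0, 0])
            converged = bool(getattr(res, "converged", True))
        except Exception:
            res, group_var, converged = None, 0.0, False
    ols = sm.OLS(y, X.to_numpy()).fit()
    lrt = (2.0 * (float(res.llf) - float(ols.llf))
           if res is not None and np.isfinite(res.llf) else -np.inf)
    if res is not None and converged and lrt > _VARIANCE_LRT:
        k = X.shape[1]
        params = pd.Series(np.asarray(res.params)[:k], index=X.columns)
        bse = pd.Series(np.asarray(res.bse)[:k], index=X.columns)
        cov = pd.DataFrame(np.asarray(res.cov_params())[:k, :k],
                           index=X.columns, columns=X.columns)
        return params, bse, cov, float(res.aic), group_var, float(res.scale), "mixed"
    if res is None or not converged:
        log.warning("mixed model did not converge; falling back to OLS (flagged)")
    else:
        log.info("random-intercept variance not supported by the data "
                 "(LRT %.2f); OLS fallback (flagged)", max(lrt, 0.0))
    params = pd.Series(ols.params, index=X.columns)
    bse = pd.Series(ols.bse, index=X.columns)
    cov = pd.DataFrame(ols.cov_params(), index=X.columns, columns=X.columns)
    return params, bse, cov, float(ols.aic), 0.0, float(ols.scale), "ols_fallback"


def fit_mixed_model(frame: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Fit the carbon-stock linear mixed model on a prepared model frame.

    ``frame`` comes from :func:`build_model_frame`. Returns estimates,
    Wald-based inference, post-hoc standardized coefficients, Nakagawa-style
    marginal/conditional variance explained, and per-term VIFs.
    """
    spec = (spec or ModelSpec()).validate()
    if frame["ecoregion_id"].nunique() < 2:
        raise SpecificationError("need >= 2 ecoregions for a random intercept")
    y, X = _design(frame, spec)
    params, bse, cov, aic, group_var, resid_var, method = _mixed_or_ols(
        y, X, frame["ecoregion_id"].to_numpy())
    z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    sd_y = float(np.std(y, ddof=0))
    std_est = {}
    for c in X.columns:
        if c == "const":
            std_est[c] = np.nan
        elif c.startswith("stage") or ":stage" in c:
            std_est[c] = params[c]  # dummy contrasts left unstandardized
        else:
            std_est[c] = params[c] * float(np.std(X[c], ddof=0)) / sd_y
    tab = pd.DataFrame({
        "est": params, "se": bse, "z": z, "p": p,
        "std_est": pd.Series(std_est),
        "ci_low": params - 1.959963984540054 * bse,
        "ci_high": params + 1.959963984540054 * bse,
    })
    fitted_fixed = X.to_numpy() @ params.to_numpy()
    var_f = float(np.var(fitted_fixed, ddof=0))
    denom = var_f + group_var + resid_var
    moderator_values = {
        m: frame[{"richness": "richness_z", "climate": "climate_z"}[m]].to_numpy()
        for m in spec.interactions if m != "stage"
    }
    return FitResult(
        params=tab, cov_params=cov, aic=aic,
        r2_marginal=var_f / denom, r2_conditional=(var_f + group_var) / denom,
        vif=vif(X), group_var=group_var, resid_var=resid_var, method=method,
        n=len(frame), spec=spec,
        meta={"sd_y": sd_y, "moderator_values": moderator_values},
    )


def _tertile_midpoints(x: np.ndarray) -> dict[str, float]:
    lo, hi = np.quantile(x, [1 / 3, 2 / 3])
    return {
        "low": float(np.median(x[x <= lo])),
        "middle": float(np.median(x[(x > lo) & (x <= hi)])),
        "high": float(np.median(x[x > hi])),
    }


def interaction_slopes(fit: FitResult, moderator: str,
                       levels: dict[str, float] | None = None) -> pd.DataFrame:
    """Simple slopes of EcM dominance at levels of one moderator.

    Continuous moderators default to tertile midpoints (on the z-scored
    scale used in the fit); the succession moderator uses its three stages.
    Standard errors come from the coefficient covariance.
    """
    if fit.spec is None or moderator not in fit.spec.interactions:
        raise SpecificationError(f"fit has no EcMD x {moderator} interaction")
    cov = fit.cov_params
    b = fit.params["est"]
    rows = []
    if moderator == "stage":
        for stage in ["early", "middle", "late"]:
            terms = {"ecmd_t": 1.0}
            if stage != "early":
                terms[f"ecmd_t:stage_{stage}"] = 1.0
            est = sum(v * b[t] for t, v in terms.items())
            var = sum(vi * vj * cov.loc[ti, tj]
                      for ti, vi in terms.items() for tj, vj in terms.items())
            rows.append((stage, np.nan, est, np.sqrt(var)))
    else:
        col = {"richness": "richness_z", "climate": "climate_z"}[moderator]
        term = f"ecmd_t:{col}"
        if levels is None:
            levels = _tertile_midpoints(fit.meta["moderator_values"][moderator])
        for label, m in levels.items():
            est = b["ecmd_t"] + m * b[term]
            var = (cov.loc["ecmd_t", "ecmd_t"] + m ** 2 * cov.loc[term, term]
                   + 2 * m * cov.loc["ecmd_t", term])
            rows.append((label, m, est, np.sqrt(var)))
    return pd.DataFrame(rows, columns=["level", "moderator_value", "slope", "se"])


def driver_importance(metrics: pd.DataFrame, response: str, *, seed: int = 0,
                      n_repeats: int = 10, n_estimators: int = 200) -> pd.DataFrame:
    """Random-forest permutation-importance screening of the plot drivers.

    Predictors: EcM dominance, richness, stage (ordinal-coded), climate
    score, slope, altitude; response is the ln carbon stock. Importances are
    averaged over permutation repeats under a fixed seed.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance

    df = metrics[np.isfinite(metrics[response]) & (metrics[response] > 0)].copy()
    if len(df) < 50:
        log.warning("driver_importance: n=%d < 50, importances may be unstable", len(df))
    stage_code = pd.Categorical(df["stage"], categories=["early", "middle", "late"]).codes
    X = pd.DataFrame({
        "ecmd": df["ecmd"], "richness": df["richness"], "stage": stage_code,
        "climate": df["climate_score"], "slope": df["slope"], "altitude": df["altitude"],
    })
    y = np.log(df[response].to_numpy())
    rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    imp = permutation_importance(rf, X, y, n_repeats=n_repeats, random_state=seed, n_jobs=1)
    out = pd.DataFrame({
        "importance": imp.importances_mean,
        "importance_sd": imp.importances_std,
    }, index=X.columns).sort_values("importance", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class BootstrapSummary:
    n_replicates: int
    sign_consistency: pd.Series       # share of replicates matching full-data sign
    quantiles: pd.DataFrame           # 2.5 / 50 / 97.5 percentiles per term
    full_estimates: pd.Series
    replicate_estimates: pd.DataFrame


def ecoregion_subsample(frame: pd.DataFrame, spec: ModelSpec | None = None, *,
                        fraction: float = 0.5, n_replicates: int = 200,
                        seed: int = 0) -> BootstrapSummary:
    """Ecoregion-stratified subsampling check of model stability.

    Each replicate keeps floor(fraction * n_e) plots per ecoregion, sampled
    without replacement, and refits the mixed model; the summary reports how
    consistently each term keeps the sign of the full-data estimate, plus
    replicate quantiles.
    """
    spec = (spec or ModelSpec()).validate()
    counts = frame.groupby("ecoregion_id").size()
    if (counts < 2).any():
        raise StagingError("every ecoregion needs >= 2 plots for stratified subsampling")
    full = fit_mixed_model(frame, spec)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        idx = []
        for _, grp in frame.groupby("ecoregion_id"):
            k = int(np.floor(fraction * len(grp)))
            idx.extend(rng.choice(grp.index.to_numpy(), size=k, replace=False))
        sub = frame.loc[idx]
        try:
            reps.append(fit_mixed_model(sub, spec).params["est"])
        except Exception as exc:  # a degenerate replicate is recorded, not fatal
            log.warning("subsample replicate failed: %s", exc)
    est = pd.DataFrame(reps).reset_index(drop=True)
    full_est = full.params["est"]
    sign = (np.sign(est) == np.sign(full_est)).mean()
    q = est.quantile([0.025, 0.5, 0.975]).T
    q.columns = ["q2.5", "q50", "q97.5"]
    return BootstrapSummary(n_replicates=len(est), sign_consistency=sign,
                            quantiles=q, full_estimates=full_est,
                            replicate_estimates=est)
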