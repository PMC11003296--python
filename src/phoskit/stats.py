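"""Regression, partial correlation, and model-comparison layer.

Participant-level analyses use ordinary least squares on standardized
predictors (β: standardized regression coefficient) together with partial
correlation coefficients (r); across-participant analyses use a linear
mixed-effects model with a random intercept per participant. Model families
are compared by AIC/BIC with the conventional evidence bands (ΔAIC < 2: no
preference; 2 ≤ ΔAIC < 7 / 2 ≤ ΔBIC < 6: some evidence; ΔAIC ≥ 7 /
ΔBIC ≥ 6: strong evidence against the higher-scoring model).

Ordinary fits are delegated to statsmodels; partial correlations, Welch's
t-test, variance inflation factors, and the Bonferroni correction are small
closed forms computed directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from phoskit.errors import CollinearityError, DomainError


@dataclass
class PredictorStats:
    name: str
    beta: float
    partial_r: float
    p: float
    se: float = float("nan")
    p_adj: float | None = None
    stars: str = ""


@dataclass
class FitResult:
    """Coefficients and diagnostics for one fitted model."""

    model: str
    response: str
    predictors: list[PredictorStats]
    n: int
    aic: float
    bic: float
    vif: dict[str, float] = field(default_factory=dict)
    intercept: bool = True
    random_effect: str = "none"

    def predictor(self, name: str) -> PredictorStats:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def beta(self) -> dict[str, float]:
        return {p.name: p.beta for p in self.predictors}


@dataclass
class ModelComparison:
    model_a: FitResult
    model_b: FitResult
    delta_aic: float
    delta_bic: float
    verdict_aic: str
    verdict_bic: str


def _design(X: pd.DataFrame | np.ndarray, names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    if arr.shape[0] == 1 and arr.shape[1] > 1:
        arr = arr.T
    names = names or [f"x{i}" for i in range(arr.shape[1])]
    return arr, names


def _check_rank(arr: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        corr = np.corrcoef(arr, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise CollinearityError(f"rank-deficient design; collinear columns: {pairs or names}")


def partial_correlation(y, x, Z=None) -> tuple[float, float]:
    """Correlation between y and x after removing the linear effect of Z.

    Residualizes both y and x on Z (with intercept) and correlates the
    residuals; the p-value comes from the t transform with n − |Z| − 2
    degrees of freedom. With empty Z this is the Pearson correlation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if Z is None or (hasattr(Z, "shape") and np.size(Z) == 0) or (isinstance(Z, (list, tuple)) and not Z):
        Zarr = np.empty((n, 0))
    else:
        Zarr, _ = _design(Z)
    k = Zarr.shape[1]
    if n <= k + 2:
        raise DomainError("too few observations for partial correlation")
    design = np.column_stack([np.ones(n), Zarr])
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    if np.allclose(rx, 0, atol=1e-10 * max(1.0, np.abs(x).max())):
        raise DomainError("x lies in the span of Z; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_clamped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clamped * np.sqrt(df / (1 - r_clamped**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def vif(X) -> dict[str, float]:
    """Variance inflation factor 1/(1−R²_j) for each predictor column."""
    arr, names = _design(X)
    if arr.shape[1] < 2:
        raise DomainError("VIF requires at least two predictors")
    out = {}
    for j, name in enumerate(names):
        others = np.column_stack([np.ones(len(arr)), np.delete(arr, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
        resid = arr[:, j] - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((arr[:, j] - arr[:, j].mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1 - ss_res / ss_tot
        out[name] = float(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
    return out


def ols_standardized(y, X, *, intercept: bool = True, response: str = "y", model: str = "ols") -> FitResult:
    """Least-squares fit reporting β, partial r, and two-sided p per predictor.

    Predictors are used as given (the pipeline supplies them z-scored); the
    response stays on its transformed scale, matching the convention of
    standardized-predictor regression tables.
    """
    y = np.asarray(y, dtype=float)
    arr, names = _design(X)
    n, k = arr.shape
    if n <= k + 1:
        raise DomainError(f"need n > k + 1 observations (n={n}, k={k})")
    _check_rank(np.column_stack([np.ones(n), arr]) if intercept else arr, names)
    exog = sm.add_constant(arr, has_constant="add") if intercept else arr
    fit = sm.OLS(y, exog).fit()
    offset = 1 if intercept else 0
    preds = []
    for j, name in enumerate(names):
        if k >= 2:
            r, _ = partial_correlation(y, arr[:, j], np.delete(arr, j, axis=1))
        elif np.ptp(y) == 0 or np.ptp(arr[:, j]) == 0:
            r = float("nan")  # degenerate: correlation undefined
        else:
            # single predictor: the (centered) Pearson correlation, also for
            # intercept-free fits where the slope is constrained through zero
            r, _ = partial_correlation(y, arr[:, j])
        preds.append(
            PredictorStats(name=name, beta=float(fit.params[offset + j]),
                           partial_r=r, p=float(fit.pvalues[offset + j]),
                           se=float(fit.bse[offset + j]))
        )
    return FitResult(
        model=model,
        response=response,
        predictors=preds,
        n=n,
        aic=float(fit.aic),
        bic=float(fit.bic),
        vif=vif(pd.DataFrame(arr, columns=names)) if k >= 2 else {},
        intercept=intercept,
    )


def mixed_effects(y, X, groups, *, response: str = "y", model: str = "mixed", reml: bool = True) -> FitResult:
    """Random-intercept-per-group linear mixed model (REML by default).

    Partial correlations are computed after subtracting each group's
    estimated random intercept from the response. On a singular or
    non-converging fit the model falls back to pooled OLS and flags it.
    """
    y = np.asarray(y, dtype=float)
    arr, names = _design(X)
    groups = np.asarray(groups)
    n, k = arr.shape
    if n <= k + 2:
        raise DomainError("too few observations for a mixed model")
    exog = sm.add_constant(arr, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, exog, groups=groups).fit(reml=reml, method="lbfgs")
        if not np.isfinite(np.asarray(fit.cov_re)).all() or not np.isfinite(fit.params).all():
            fit = None
    except (np.linalg.LinAlgError, ValueError):
        fit = None
    if fit is None:
        pooled = ols_standardized(y, pd.DataFrame(arr, columns=names),
                                  response=response, model=model)
        pooled.random_effect = "none (singular fit fallback)"
        return pooled
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranef = {g: float(np.asarray(re).ravel()[0])
                     for g, re in fit.random_effects.items()}
    except (np.linalg.LinAlgError, ValueError):
        # between-group variance estimated at (numerically) zero:
        # random intercepts vanish and the fixed effects stand alone
        ranef = {g: 0.0 for g in np.unique(groups)}
    y_adj = y - np.array([ranef[g] for g in groups])
    preds = []
    for j, name in enumerate(names):
        Zother = np.delete(arr, j, axis=1)
        r, _ = partial_correlation(y_adj, arr[:, j], Zother if k >= 2 else None)
        preds.append(
            PredictorStats(name=name, beta=float(fit.params[1 + j]),
                           partial_r=r, p=float(fit.pvalues[1 + j]),
                           se=float(fit.bse[1 + j]))
        )
    # ML log-likelihood based information criteria (k = fixed effects +
    # random-intercept variance + residual variance)
    if reml:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            llf = float(sm.MixedLM(y, exog, groups=groups).fit(reml=False, method="lbfgs").llf)
    else:
        llf = float(fit.llf)
    if not np.isfinite(llf):
        # random-intercept variance at the zero boundary: the ML likelihood
        # coincides with the fixed-effects-only Gaussian likelihood
        llf = float(sm.OLS(y, exog).fit().llf)
    n_par = (k + 1) + 2
    return FitResult(
        model=model,
        response=response,
        predictors=preds,
        n=n,
        aic=2 * n_par - 2 * llf,
        bic=n_par * np.log(n) - 2 * llf,
        vif=vif(pd.DataFrame(arr, columns=names)) if k >= 2 else {},
        random_effect="participant intercept",
    )


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, Welch–Satterthwaite df, and p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    return float(t), float(df), p


def bonferroni(pvals, m: int | None = None, alpha: float = 0.05):
    """Bonferroni adjustment p_adj = min(1, p·m) plus significance stars.

    Stars follow the conventional bands on the adjusted p-values:
    ``*`` < .05, ``**`` < .01, ``***`` < .001.
    """
    pvals = np.asarray(pvals, dtype=float)
    m = len(pvals) if m is None else int(m)
    if m < len(pvals):
        raise DomainError("family size m must be at least the number of p-values")
    adj = np.minimum(1.0, pvals * m)
    stars = ["***" if p < 0.001 else "**" if p < 0.01 else "*" if p < alpha else "" for p in adj]
    return adj, stars


def _verdict(delta: float, some: float, strong: float) -> str:
    mag = abs(delta)
    if mag < some:
        return "no preference"
    loser = "A" if delta > 0 else "B"
    strength = "strong evidence" if mag >= strong else "some evidence"
    return f"{strength} against model {loser}"


def compare_models(
    data: pd.DataFrame,
    response: str,
    predictors_a: list[str],
    predictors_b: list[str],
    *,
    groups: str | None = None,
) -> ModelComparison:
    """Fit two model families on the same rows and compare AIC/BIC.

    Rows with missing values in the response or in either predictor set are
    dropped before fitting so both models see an identical sample. With
    ``groups`` set, both models are random-intercept mixed models whose
    information criteria use the ML (not REML) log-likelihood.
    """
    cols = {response, *predictors_a, *predictors_b} | ({groups} if groups else set())
    sub = data.dropna(subset=list(cols))
    y = sub[response]
    if groups:
        fit_a = mixed_effects(y, sub[predictors_a], sub[groups], response=response,
                              model="A", reml=False)
        fit_b = mixed_effects(y, sub[predictors_b], sub[groups], response=response,
                              model="B", reml=False)
    else:
        fit_a = ols_standardized(y, sub[predictors_a], response=response, model="A")
        fit_b = ols_standardized(y, sub[predictors_b], response=response, model="B")
    if fit_a.n != fit_b.n:
        raise DomainError("models must be fit on the same sample")
    d_aic = fit_a.aic - fit_b.aic
    d_bic = fit_a.bic - fit_b.bic
    return ModelComparison(
        model_a=fit_a,
        model_b=fit_b,
        delta_aic=d_aic,
        delta_bic=d_bic,
        verdict_aic=_verdict(d_aic, 2.0, 7.0),
        verdict_bic=_verdict(d_bic, 2.0, 6.0),
    )


def summation_regression(
    paired_points: pd.DataFrame,
    single_points: pd.DataFrame,
    descriptors: list[str] | None = None,
) -> tuple[dict[str, FitResult], pd.DataFrame, list[dict]]:
    """Regress paired descriptors on the sum of their single-electrode counterparts.

    Every paired data point (participant, electrode pair, amplitude) is
    matched to the two constituent single-electrode data points at the same
    frequency and the nearest available amplitude (in multiples of
    threshold). The regression is intercept-free: a zero predictor must map
    to a zero response. Returns per-descriptor fits, the matched table, and
    an exclusion log for unmatched pairs.
    """
    descriptors = descriptors or ["area", "perimeter", "major", "minor"]
    rows, excluded = [], []
    for _, prow in paired_points.iterrows():
        singles = []
        for electrode in prow.electrode_key.split("+"):
            cand = single_points[
                (single_points.participant == prow.participant)
                & (single_points.electrode_key == electrode)
                & np.isclose(single_points.frequency, prow.frequency)
            ]
            if cand.empty:
                break
            singles.append(cand.loc[(cand.amplitude - prow.amplitude).abs().idxmin()])
        if len(singles) != 2:
            excluded.append(
                {"participant": prow.participant, "electrode_key": prow.electrode_key,
                 "amplitude": prow.amplitude, "reason": "missing single-electrode match"}
            )
            continue
        row = {"participant": prow.participant, "electrode_key": prow.electrode_key,
               "amplitude": prow.amplitude}
        for d in descriptors:
            row[f"paired_{d}"] = prow[d]
            row[f"single_sum_{d}"] = singles[0][d] + singles[1][d]
        rows.append(row)
    matched = pd.DataFrame(rows)
    fits: dict[str, FitResult] = {}
    for d in descriptors:
        if matched.empty:
            continue
        fits[d] = ols_standardized(
            matched[f"paired_{d}"], matched[[f"single_sum_{d}"]],
            intercept=False, response=d, model="summation",
        )
    return fits, matched, excluded
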