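"""Disability/fatigue outcome models and supporting statistics.

Covers the statistical toolkit around the eating-hub analysis:

* dichotomisation of clinical outcomes (EDSS <= 1.5 vs >= 2; FSS split at the
  cohort median),
* a Spearman collinearity screen among hub items,
* bivariate logistic regression of outcome classes on single hubs, fitted by
  iteratively reweighted least squares with explicit separation diagnostics,
* hierarchical (blockwise) OLS with standardized coefficients and per-block
  R-squared,
* a sensitivity analysis giving the minimum detectable logistic slope for a
  given sample size, alpha and power,
* descriptive two-group comparisons (pooled-variance t-test, Pearson
  chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng

EDSS_GRID = np.arange(0.0, 5.51, 0.5)


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: the MLE does not exist."""


# ---------------------------------------------------------------------------
# outcome classes
# ---------------------------------------------------------------------------

@dataclass
class OutcomeClasses:
    disability_class: np.ndarray  # 0: EDSS <= 1.5, 1: EDSS >= 2
    fatigue_class: np.ndarray     # 0: FSS <= cohort median, 1: above
    fss_median: float


def classify_outcomes(edss, fss) -> OutcomeClasses:
    """Dichotomise EDSS and FSS for the analysed (MS) cohort.

    EDSS must sit on the clinical 0.5 grid and not exceed 5.5; values
    strictly between 1.5 and 2 are impossible on the grid and rejected.
    FSS ties at the median go to class 0.
    """
    edss = np.asarray(edss, dtype=float)
    fss = np.asarray(fss, dtype=float)
    if edss.shape != fss.shape:
        raise ValueError("edss and fss must have equal length")
    if np.any(np.isnan(edss)) or np.any(np.isnan(fss)):
        raise ValueError("missing EDSS/FSS in the analysed cohort")
    if np.any(edss > 5.5) or np.any(edss < 0):
        raise ValueError("EDSS outside [0, 5.5]")
    on_grid = np.isclose(edss[:, None], EDSS_GRID[None, :]).any(axis=1)
    if not on_grid.all():
        bad = edss[~on_grid][0]
        raise ValueError(f"EDSS {bad} not on the 0.5 grid")
    disability = (edss >= 2.0).astype(int)
    median = float(np.median(fss))
    fatigue = (fss > median).astype(int)
    return OutcomeClasses(disability_class=disability, fatigue_class=fatigue,
                          fss_median=median)


# ---------------------------------------------------------------------------
# collinearity screen
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> tuple[float, float]:
    """Midrank Spearman correlation with large-sample p-value.

    Constant input yields (nan, nan): the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CollinearityReport:
    pairs: pd.DataFrame           # columns: a, b, rho, p, significant
    joint_model_allowed: bool
    alpha: float

    @property
    def bivariate_mandated(self) -> bool:
        return not self.joint_model_allowed


def collinearity_screen(hub_scores: pd.DataFrame, alpha: float = 0.05) -> CollinearityReport:
    """Pairwise Spearman screen among hub items.

    Any significant pair (p < alpha, uncorrected - deliberately conservative)
    disallows a joint multiple model and mandates per-hub bivariate models.
    A single hub trivially permits the joint model.
    """
    cols = list(hub_scores.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rho, p = spearman_rho(hub_scores[cols[i]], hub_scores[cols[j]])
            rows.append({
                "a": cols[i], "b": cols[j], "rho": rho, "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            })
    pairs = pd.DataFrame(rows, columns=["a", "b", "rho", "p", "significant"])
    allowed = not bool(pairs["significant"].any()) if len(pairs) else True
    return CollinearityReport(pairs=pairs, joint_model_allowed=allowed, alpha=alpha)


# ---------------------------------------------------------------------------
# model-fit container
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    model_kind: str
    n_used: int
    coefficients: dict[str, float] = field(default_factory=dict)
    std_betas: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    r_squared: float | None = None
    r_squared_by_block: dict[str, float] = field(default_factory=dict)
    statistic: float | None = None
    converged: bool = True
    notes: str = ""


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

def _check_separation(y: np.ndarray, x: np.ndarray) -> None:
    x1, x0 = x[y == 1], x[y == 0]
    if x1.min() >= x0.max() or x0.min() >= x1.max():
        raise SeparationError(
            "perfect separation: predictor ranges of the two outcome classes "
            "do not overlap; the logistic MLE does not exist"
        )


def bivariate_logistic(outcome_class, predictor, tol: float = 1e-8,
                       max_iter: int = 100) -> ModelFit:
    """Logistic regression of a binary outcome on one predictor, via IRLS.

    Reports the maximum-likelihood intercept and slope (log-odds per score
    unit) with Wald p-values.  A constant outcome or perfect separation
    raises an explicit error instead of returning a silent estimate.
    """
    y = np.asarray(outcome_class, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and predictor must have equal length")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("outcome must be coded 0/1")
    if classes.size < 2:
        raise ValueError("outcome is constant; both classes must be present")
    if np.all(x == x[0]):
        raise ValueError("predictor is constant")
    _check_separation(y, x)

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.min() < 1e-12 and np.abs(beta).max() > 30:
            raise SeparationError("diverging coefficients: quasi-separation")
        XtWX = X.T @ (X * w[:, None])
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    else:
        converged = False

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
    se = np.sqrt(np.diag(cov))
    zvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    return ModelFit(
        model_kind="bivariate_logistic",
        n_used=int(y.size),
        coefficients={"intercept": float(beta[0]), "slope": float(beta[1])},
        p_values={"intercept": float(pvals[0]), "slope": float(pvals[1])},
        converged=converged,
        notes="" if converged else f"IRLS did not converge in {max_iter} iterations",
    )


def fit_logistic_batch(y: np.ndarray, x: np.ndarray, tol: float = 1e-8,
                       max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised 2-parameter logistic fits across replicates.

    ``y`` and ``x`` are (R, n) arrays; returns (beta, se) each of shape
    (R, 2).  Used by the sensitivity-analysis power simulation, where R is
    large and per-replicate model objects would dominate runtime.
    Non-converging or separated replicates get NaN estimates.
    """
    R, n = y.shape
    b0 = np.zeros(R)
    b1 = np.zeros(R)
    active = np.ones(R, dtype=bool)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        s0 = (y - mu).sum(axis=1)
        s1 = ((y - mu) * x).sum(axis=1)
        a = w.sum(axis=1)
        b = (w * x).sum(axis=1)
        c = (w * x * x).sum(axis=1)
        det = a * c - b * b
        bad = det < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            d0 = (c * s0 - b * s1) / det
            d1 = (a * s1 - b * s0) / det
        d0[bad] = np.nan
        d1[bad] = np.nan
        b0 = b0 + np.where(active, d0, 0.0)
        b1 = b1 + np.where(active, d1, 0.0)
        step = np.maximum(np.abs(d0), np.abs(d1))
        active = active & ~(step < tol)
        diverged = np.abs(b1) > 30
        b0[diverged] = np.nan
        b1[diverged] = np.nan
        active &= ~diverged
        if not active.any():
            break
    eta = b0[:, None] + b1[:, None] * x
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    a = w.sum(axis=1)
    b = (w * x).sum(axis=1)
    c = (w * x * x).sum(axis=1)
    det = a * c - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        se0 = np.sqrt(c / det)
        se1 = np.sqrt(a / det)
    beta = np.column_stack([b0, b1])
    se = np.column_stack([se0, se1])
    return beta, se


# ---------------------------------------------------------------------------
# hierarchical OLS
# ---------------------------------------------------------------------------

def hierarchical_ols(outcome, predictor_blocks: Sequence[tuple[str, pd.DataFrame]]) -> ModelFit:
    """Blockwise (hierarchical) least squares with standardized coefficients.

    Blocks are entered cumulatively; R-squared is reported after each block
    and for the final model, whose coefficients are standardized betas
    (outcome and predictors z-scored).  Rank deficiency raises with the name
    of the offending predictor.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    blocks = [(name, pd.DataFrame(df)) for name, df in predictor_blocks]
    all_cols: list[str] = []
    for _, df in blocks:
        all_cols.extend(df.columns)
    if len(set(all_cols)) != len(all_cols):
        raise ValueError("duplicate predictor names across blocks")
    X_full = pd.concat([df for _, df in blocks], axis=1)
    if y.size <= X_full.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")

    # incremental rank check names the first predictor that adds no rank
    cols_so_far: list[np.ndarray] = [np.ones(y.size)]
    for name in X_full.columns:
        col = X_full[name].to_numpy(dtype=float)
        trial = np.column_stack(cols_so_far + [col])
        if np.linalg.matrix_rank(trial) <= len(cols_so_far):
            raise ValueError(f"rank deficiency: predictor {name!r} is collinear "
                             "with the preceding design")
        cols_so_far.append(col)

    r2_by_block: dict[str, float] = {}
    cum_cols: list[str] = []
    for name, df in blocks:
        cum_cols.extend(df.columns)
        X = sm.add_constant(X_full[cum_cols].to_numpy(dtype=float))
        r2_by_block[name] = float(sm.OLS(y, X).fit().rsquared)

    Xz = (X_full - X_full.mean()) / X_full.std(ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    fit_z = sm.OLS(yz, sm.add_constant(Xz.to_numpy(dtype=float))).fit()
    fit_raw = sm.OLS(y, sm.add_constant(X_full.to_numpy(dtype=float))).fit()

    names = ["intercept", *X_full.columns]
    return ModelFit(
        model_kind="ols_hierarchical",
        n_used=int(y.size),
        coefficients=dict(zip(names, map(float, fit_raw.params))),
        std_betas=dict(zip(X_full.columns, map(float, fit_z.params[1:]))),
        p_values=dict(zip(names, map(float, fit_raw.pvalues))),
        r_squared=float(fit_raw.rsquared),
        r_squared_by_block=r2_by_block,
    )


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    n: int
    alpha: float
    power: float
    min_beta: float
    outcome_prevalence: float
    predictor_sd: float
    achieved_power: float | None = None
    assumptions: str = (
        "standardized normal predictor, fixed marginal outcome prevalence, "
        "two-sided Wald test, information evaluated under the alternative"
    )


def _logistic_information(beta: float, prevalence: float, predictor_sd: float,
                          n_gh: int = 64) -> float:
    """E[x^2 p(x)(1-p(x))] for x ~ N(0, sd^2) under the slope-beta model,
    with the intercept solved so that E[p(x)] equals the prevalence."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_gh)
    w = weights / weights.sum()
    x = nodes * predictor_sd

    def mean_p(b0: float) -> float:
        return float(w @ (1.0 / (1.0 + np.exp(-(b0 + beta * x)))))

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    p = 1.0 / (1.0 + np.exp(-(b0 + beta * x)))
    return float(w @ (x * x * p * (1.0 - p)))


def min_detectable_beta(n: int, alpha: float = 0.05, power: float = 0.90,
                        outcome_prevalence: float = 0.5, predictor_sd: float = 1.0,
                        information: str = "alternative",
                        simulate: bool = False, n_sims: int = 10_000,
                        seed: int = 0) -> SensitivityResult:
    """Minimum detectable absolute logistic slope at given n, alpha, power.

    Default (``information="alternative"``) solves the two-variance Wald
    power equation

        beta * sqrt(n) = z_{1-alpha/2} / sqrt(I0) + z_power / sqrt(I1(beta)),

    where I0 = sd^2 p(1-p) is the per-observation slope information under
    independence and I1(beta) = E[x^2 p(x)(1-p(x))] the information under
    the alternative (Gauss-Hermite quadrature; fixed-point iteration in
    beta).  ``information="null"`` collapses both terms onto I0, the
    textbook single-variance approximation.  ``simulate=True`` additionally
    runs a Monte-Carlo power check at the returned beta.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if not 0 < outcome_prevalence < 1:
        raise ValueError("outcome prevalence must lie strictly in (0, 1)")
    if predictor_sd <= 0:
        raise ValueError("predictor SD must be positive")

    z_alpha = stats.norm.ppf(1 - alpha / 2)
    z_power = stats.norm.ppf(power)
    p = outcome_prevalence
    i0 = predictor_sd**2 * p * (1 - p)
    beta = (z_alpha + z_power) / np.sqrt(n * i0)
    if information == "alternative":
        for _ in range(100):
            i1 = _logistic_information(beta, p, predictor_sd)
            new = (z_alpha / np.sqrt(i0) + z_power / np.sqrt(i1)) / np.sqrt(n)
            if abs(new - beta) < 1e-10:
                beta = new
                break
            beta = new
    elif information != "null":
        raise ValueError("information must be 'alternative' or 'null'")

    result = SensitivityResult(
        n=int(n), alpha=float(alpha), power=float(power), min_beta=float(beta),
        outcome_prevalence=float(p), predictor_sd=float(predictor_sd),
    )
    if simulate:
        result.achieved_power = simulated_power(
            beta, n, alpha=alpha, outcome_prevalence=p,
            predictor_sd=predictor_sd, n_sims=n_sims, seed=seed,
        )
    return result


def simulated_power(beta: float, n: int, alpha: float = 0.05,
                    outcome_prevalence: float = 0.5, predictor_sd: float = 1.0,
                    n_sims: int = 10_000, seed: int = 0,
                    batch: int = 2000) -> float:
    """Monte-Carlo power of the Wald test for a logistic slope ``beta``.

    Simulates x ~ N(0, sd^2), y ~ Bernoulli(logistic(b0 + beta x)) with the
    intercept solving the target prevalence, fits each replicate by batched
    IRLS and counts Wald rejections at ``alpha`` (two-sided).
    """
    rng = stage_rng(seed, "power_sim")
    # intercept for the target prevalence under the alternative
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    w = weights / weights.sum()
    xg = nodes * predictor_sd
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(w @ (1.0 / (1.0 + np.exp(-(mid + beta * xg))))) < outcome_prevalence:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)

    zc = stats.norm.ppf(1 - alpha / 2)
    rejections = 0
    used = 0
    done = 0
    while done < n_sims:
        r = min(batch, n_sims - done)
        x = rng.standard_normal((r, n)) * predictor_sd
        pr = 1.0 / (1.0 + np.exp(-(b0 + beta * x)))
        y = (rng.random((r, n)) < pr).astype(float)
        est, se = fit_logistic_batch(y, x)
        wald = np.abs(est[:, 1] / se[:, 1])
        ok = np.isfinite(wald)
        rejections += int(np.count_nonzero(wald[ok] > zc))
        used += int(np.count_nonzero(ok))
        done += r
    return rejections / used if used else float("nan")


# ---------------------------------------------------------------------------
# descriptive group comparisons
# ---------------------------------------------------------------------------

def group_compare(values_a, values_b=None, kind: str = "t_test",
                  welch: bool = False) -> ModelFit:
    """Two-group descriptive comparison.

    ``kind="t_test"``: unpaired two-sample t-test on ``values_a`` vs
    ``values_b`` (pooled variance by default; ``welch=True`` for unequal
    variances).  ``kind="chi_square"``: Pearson chi-square (no continuity
    correction) where ``values_a`` is a contingency table.
    """
    if kind == "t_test":
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least 2 observations per group")
        res = stats.ttest_ind(a, b, equal_var=not welch)
        return ModelFit(
            model_kind="t_test", n_used=int(a.size + b.size),
            statistic=float(res.statistic),
            p_values={"t": float(res.pvalue)},
        )
    if kind == "chi_square":
        table = np.asarray(values_a, dtype=float)
        if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("degenerate contingency table: empty row or column")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return ModelFit(
            model_kind="chi_square", n_used=int(table.sum()),
            statistic=float(chi2), p_values={"chi2": float(p)},
        )
    raise ValueError(f"unknown comparison kind {kind!r}")
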