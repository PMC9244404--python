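"""Synthetic Mediterranean-diet questionnaire cohorts.

Generates participant tables with the statistical structure the downstream
analysis assumes, so every stage is testable without clinical data:

* nine ordinal 0-2 intake items per subject, sampled through a Gaussian
  copula: a latent multivariate normal vector is discretised per item into
  the configured 3-level marginals, with the latent correlation of each pair
  solved numerically (monotone bisection) so the induced *Spearman*
  correlation matches its target;
* group-specific marginals - the MS group consumes fish more and alcohol
  less frequently than controls;
* demographics, anthropometrics and lifestyle (smoking, IPAQ MET-min/week)
  from truncated normal / lognormal / mixture distributions;
* clinical outcomes for the MS group only: a disability class drawn from a
  logistic model on vegetables and fish intake, a continuous EDSS on the
  clinical 0.5 grid consistent with that class and carrying a calibrated
  lifestyle signal, and a fatigue score (FSS) from a linear lifestyle model.

All randomness flows from a single master seed through documented per-stage
substreams (:mod:`medinet._rng`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng
from .scoring import ITEMS, NEGATIVE_ITEMS

GROUPS = ("MS", "HC")

CSV_COLUMNS = (
    "participant_id", "group", "age", "sex",
    *ITEMS,
    "weight_kg", "height_m", "waist_cm", "hip_cm",
    "cigs_per_day", "years_smoked", "ipaq_met", "edss", "fss",
)

# Packaged default marginals (p0, p1, p2) per item and group.  Chosen as a
# plausible Italian adult intake profile; the MS group differs from controls
# in fish (more frequent) and alcohol (less frequent) only.
_BASE_MARGINALS = {
    "fruit": (0.15, 0.40, 0.45),
    "vegetables": (0.12, 0.40, 0.48),
    "legumes": (0.25, 0.50, 0.25),
    "cereals": (0.08, 0.32, 0.60),
    "fish": (0.25, 0.50, 0.25),
    "meat": (0.10, 0.40, 0.50),
    "dairy": (0.12, 0.38, 0.50),
    "olive_oil": (0.05, 0.15, 0.80),
    "alcohol": (0.35, 0.35, 0.30),
}
_MS_OVERRIDES = {
    "fish": (0.15, 0.45, 0.40),     # more mass on score 2 than HC
    "alcohol": (0.50, 0.32, 0.18),  # less mass on score 2 than HC
}


def default_item_marginals() -> dict[str, dict[str, tuple[float, float, float]]]:
    ms = {**_BASE_MARGINALS, **_MS_OVERRIDES}
    return {"MS": dict(ms), "HC": dict(_BASE_MARGINALS)}


def default_rank_corr_targets() -> np.ndarray:
    """Target Spearman correlations among the nine items.

    Non-zero entries are the reported hub inter-correlations
    (fruit-vegetables 0.33, fruit-cereal 0.13, fruit-fish 0.22,
    vegetables-cereal 0.19, vegetables-fish 0.21, cereal-fish 0.12);
    all other pairs are independent.
    """
    r = np.eye(len(ITEMS))
    idx = {name: i for i, name in enumerate(ITEMS)}
    for a, b, rho in [
        ("fruit", "vegetables", 0.33),
        ("fruit", "cereals", 0.13),
        ("fruit", "fish", 0.22),
        ("vegetables", "cereals", 0.19),
        ("vegetables", "fish", 0.21),
        ("cereals", "fish", 0.12),
    ]:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
    return r


@dataclass
class CohortConfig:
    """Full specification of a simulated two-group cohort.

    ``outcome_coefs`` are the logit coefficients (intercept, vegetables,
    fish) of the disability-class model; ``lifestyle_coefs`` are standardized
    linear coefficients of EDSS on (pack-years, IPAQ, negative-foods score)
    and of FSS on (pack-years, IPAQ); ``noise_sd`` holds the residual SD of
    the standardized latent outcome per continuous outcome.
    """

    n_ms: int = 424
    n_hc: int = 165
    item_marginals: dict = field(default_factory=default_item_marginals)
    rank_corr_targets: np.ndarray = field(default_factory=default_rank_corr_targets)
    age_dist: dict = field(default_factory=lambda: {
        "MS": (42.6, 11.0), "HC": (40.9, 14.5)})
    sex_ratio: dict = field(default_factory=lambda: {"MS": 0.67, "HC": 0.68})
    outcome_coefs: dict = field(default_factory=lambda: {
        "intercept": 0.91, "vegetables": -0.36, "fish": -0.34})
    lifestyle_coefs: dict = field(default_factory=lambda: {
        "edss": {"pack_years": 0.190, "ipaq_met": -0.138, "negative_score": 0.098},
        "fss": {"pack_years": 0.135, "ipaq_met": -0.169},
    })
    noise_sd: dict = field(default_factory=lambda: {"edss": 0.967, "fss": 0.976})
    seed: int = 0

    def validate(self) -> None:
        if self.n_ms < 2 or self.n_hc < 2:
            raise ValueError(f"n_ms and n_hc must be >= 2, got {self.n_ms}/{self.n_hc}")
        for group in GROUPS:
            if group not in self.item_marginals:
                raise ValueError(f"item_marginals missing group {group!r}")
            for item in ITEMS:
                triple = np.asarray(self.item_marginals[group].get(item), dtype=float)
                if triple.shape != (3,):
                    raise ValueError(f"item_marginals[{group!r}][{item!r}] must be a triple")
                if (triple < 0).any():
                    raise ValueError(f"item_marginals[{group!r}][{item!r}] has a negative entry")
                if abs(triple.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"item_marginals[{group!r}][{item!r}] sums to {triple.sum()!r}, not 1")
        r = np.asarray(self.rank_corr_targets, dtype=float)
        if r.shape != (len(ITEMS), len(ITEMS)):
            raise ValueError(f"rank_corr_targets must be {len(ITEMS)}x{len(ITEMS)}")
        if not np.allclose(r, r.T):
            raise ValueError("rank_corr_targets must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("rank_corr_targets must have unit diagonal")
        if (np.abs(r) > 1).any():
            raise ValueError("rank_corr_targets entries must lie in [-1, 1]")
        for key in ("intercept", "vegetables", "fish"):
            if key not in self.outcome_coefs:
                raise ValueError(f"outcome_coefs missing {key!r}")


# ---------------------------------------------------------------------------
# Gaussian-copula ordinal sampling
# ---------------------------------------------------------------------------

def _thresholds(triple: np.ndarray) -> np.ndarray:
    """Latent-normal cut points producing the 3-level marginal."""
    c = np.cumsum(triple)[:2]
    return stats.norm.ppf(np.clip(c, 1e-12, 1 - 1e-12))


def _bvn_cdf(x: float, y: float, r: float) -> float:
    if np.isinf(x) and x > 0:
        return float(stats.norm.cdf(y)) if np.isfinite(y) else (1.0 if y > 0 else 0.0)
    if np.isinf(y) and y > 0:
        return float(stats.norm.cdf(x))
    if np.isinf(x) or np.isinf(y):  # -inf
        return 0.0
    return float(stats.multivariate_normal(cov=[[1.0, r], [r, 1.0]]).cdf([x, y]))


def _joint_probs(r: float, tx: np.ndarray, ty: np.ndarray) -> np.ndarray:
    """3x3 cell probabilities of the discretised bivariate normal."""
    gx = np.concatenate([[-np.inf], tx, [np.inf]])
    gy = np.concatenate([[-np.inf], ty, [np.inf]])
    cdf = np.array([[_bvn_cdf(a, b, r) for b in gy] for a in gx])
    return np.diff(np.diff(cdf, axis=0), axis=1)


def _pop_spearman(P: np.ndarray) -> float:
    """Population Spearman (midrank/grade correlation) of a discrete joint."""
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    u = np.cumsum(px) - px / 2
    v = np.cumsum(py) - py / 2
    mu_u = px @ u
    mu_v = py @ v
    var_u = px @ u**2 - mu_u**2
    var_v = py @ v**2 - mu_v**2
    if var_u <= 0 or var_v <= 0:
        return 0.0
    cov = u @ P @ v - mu_u * mu_v
    return float(cov / math.sqrt(var_u * var_v))


def latent_correlation(target_spearman: float, marg_x, marg_y,
                       tol: float = 1e-4) -> float:
    """Latent-normal correlation inducing ``target_spearman`` after
    discretisation into the two 3-level marginals.

    Solved by monotone bisection.  If the target exceeds the bound attainable
    at |r| -> 1 (Frechet-type limit of the copula family), raises and reports
    the attainable range.
    """
    if target_spearman == 0.0:
        return 0.0
    tx = _thresholds(np.asarray(marg_x, dtype=float))
    ty = _thresholds(np.asarray(marg_y, dtype=float))
    r_lim = 0.9999
    lo_val = _pop_spearman(_joint_probs(-r_lim, tx, ty))
    hi_val = _pop_spearman(_joint_probs(r_lim, tx, ty))
    if not lo_val <= target_spearman <= hi_val:
        raise ValueError(
            f"target Spearman {target_spearman} unattainable for these marginals; "
            f"attainable range is [{lo_val:.4f}, {hi_val:.4f}]"
        )
    lo, hi = -r_lim, r_lim
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = _pop_spearman(_joint_probs(mid, tx, ty))
        if abs(val - target_spearman) < tol:
            return mid
        if val < target_spearman:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _nearest_pd(matrix: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest positive-definite
    correlation matrix (unit diagonal restored after clipping)."""
    vals, vecs = np.linalg.eigh(matrix)
    if vals.min() > eps:
        return matrix
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


_LATENT_CACHE: dict[bytes, np.ndarray] = {}


def _latent_matrix(config: CohortConfig, group: str) -> np.ndarray:
    marg = config.item_marginals[group]
    targets = np.asarray(config.rank_corr_targets, dtype=float)
    key = (
        np.asarray([marg[i] for i in ITEMS], dtype=float).tobytes()
        + np.round(targets, 10).tobytes()
    )
    if key in _LATENT_CACHE:
        return _LATENT_CACHE[key]
    k = len(ITEMS)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            latent[i, j] = latent[j, i] = latent_correlation(
                targets[i, j], marg[ITEMS[i]], marg[ITEMS[j]]
            )
    latent = _nearest_pd(latent)
    _LATENT_CACHE[key] = latent
    return latent


def sample_ordinal_items(config: CohortConfig, group: str, n: int,
                         seed: int | None = None) -> np.ndarray:
    """Sample an n x 9 matrix of 0-2 intake scores for ``group``.

    Marginals and pairwise Spearman correlations converge to the configured
    targets as n grows.
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if seed is None:
        seed = config.seed
    latent = _latent_matrix(config, group)
    chol = np.linalg.cholesky(latent)
    rng = stage_rng(seed, "items_ms" if group == "MS" else "items_hc")
    z = rng.standard_normal((n, len(ITEMS))) @ chol.T
    scores = np.zeros((n, len(ITEMS)), dtype=int)
    for k, item in enumerate(ITEMS):
        t = _thresholds(np.asarray(config.item_marginals[group][item], dtype=float))
        scores[:, k] = (z[:, k] > t[0]).astype(int) + (z[:, k] > t[1]).astype(int)
    return scores


# ---------------------------------------------------------------------------
# demographics / lifestyle
# ---------------------------------------------------------------------------

# (mean, sd, lower, upper) truncated normals, keyed by sex where relevant
_HEIGHT = {"F": (1.63, 0.06, 1.45, 1.90), "M": (1.76, 0.07, 1.55, 2.05)}
_BMI = {"F": (23.3, 4.0, 16.0, 45.0), "M": (24.8, 3.0, 16.0, 45.0)}
_WAIST = {"F": (80.0, 12.0, 55.0, 130.0), "M": (89.6, 9.5, 60.0, 140.0)}
_HIP = {"F": (100.4, 9.9, 70.0, 150.0), "M": (101.3, 5.6, 70.0, 150.0)}
# smoking mixture: (smoker probability, cigs/day mean, sd; years mean, sd)
_SMOKING = {"MS": (0.35, 12.0, 6.0, 15.0, 9.0), "HC": (0.20, 10.0, 5.0, 10.0, 8.0)}
# lognormal IPAQ parameters (mu, sigma) of log MET-min/week
_IPAQ = {"MS": (7.07, 1.13), "HC": (7.32, 1.34)}

AGE_BOUNDS = (18.0, 80.0)


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_demographics(config: CohortConfig, group: str, n: int) -> pd.DataFrame:
    rng = stage_rng(config.seed, f"demographics_{group.lower()}")
    mean, sd = config.age_dist[group]
    age = _trunc_normal(rng, mean, sd, *AGE_BOUNDS, n)
    sex = np.where(rng.random(n) < config.sex_ratio[group], "F", "M")
    height = np.empty(n)
    bmi = np.empty(n)
    waist = np.empty(n)
    hip = np.empty(n)
    for s in ("F", "M"):
        mask = sex == s
        k = int(mask.sum())
        height[mask] = _trunc_normal(rng, *_HEIGHT[s], k)
        bmi[mask] = _trunc_normal(rng, *_BMI[s], k)
        waist[mask] = _trunc_normal(rng, *_WAIST[s], k)
        hip[mask] = _trunc_normal(rng, *_HIP[s], k)
    return pd.DataFrame({
        "age": age,
        "sex": sex,
        "height_m": height,
        "weight_kg": bmi * height**2,
        "waist_cm": waist,
        "hip_cm": hip,
    })


def _sample_lifestyle(config: CohortConfig, group: str, n: int) -> pd.DataFrame:
    rng = stage_rng(config.seed, f"lifestyle_{group.lower()}")
    p_smoke, c_mean, c_sd, y_mean, y_sd = _SMOKING[group]
    smoker = rng.random(n) < p_smoke
    cigs = np.where(
        smoker, np.round(_trunc_normal(rng, c_mean, c_sd, 1.0, 60.0, n)), 0.0)
    years = np.where(smoker, np.round(_trunc_normal(rng, y_mean, y_sd, 1.0, 50.0, n)), 0.0)
    mu, sigma = _IPAQ[group]
    ipaq = np.round(rng.lognormal(mu, sigma, n), 1)
    return pd.DataFrame({
        "cigs_per_day": cigs,
        "years_smoked": years,
        "ipaq_met": ipaq,
    })


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

# Band geometry of the continuous EDSS: class 0 lives on [0, 1.5] around
# 0.75, class 1 on [2, 5.5] around 3.75.
_EDSS_BANDS = {0: (0.75, 0.55, 0.0, 1.5), 1: (3.75, 1.15, 2.0, 5.5)}
# Within-band gain applied to the standardized lifestyle signal so that the
# lifestyle model explains ~6% of the EDSS variance after banding, clipping
# and grid-snapping attenuate it; fixed by a one-off calibration simulation
# (see docs/methods.md).
_EDSS_LIFESTYLE_GAIN = 2.7
_FSS_MEAN, _FSS_SD, _FSS_LO, _FSS_HI = 3.8, 1.7, 1.0, 7.0


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def simulate_outcomes(items: np.ndarray, lifestyle: pd.DataFrame,
                      config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw disability class, EDSS and FSS for an MS cohort.

    The disability class follows a logistic model on vegetables and fish
    intake.  Continuous EDSS is placed in the band implied by the class
    ([0, 1.5] vs [2, 5.5]), snapped to the clinical 0.5 grid, and carries a
    standardized lifestyle signal (pack-years +, IPAQ -, negative foods +).
    FSS is linear in pack-years (+) and IPAQ (-) plus noise, clipped to
    [1, 7].
    """
    items = np.asarray(items)
    if items.shape[0] != len(lifestyle):
        raise ValueError(
            f"items has {items.shape[0]} rows but lifestyle has {len(lifestyle)}")
    if seed is None:
        seed = config.seed
    rng = stage_rng(seed, "outcomes")
    idx = {name: i for i, name in enumerate(ITEMS)}
    veg = items[:, idx["vegetables"]].astype(float)
    fish = items[:, idx["fish"]].astype(float)
    coefs = config.outcome_coefs
    lin = coefs["intercept"] + coefs["vegetables"] * veg + coefs["fish"] * fish
    p_disability = 1.0 / (1.0 + np.exp(-lin))
    disability = (rng.random(items.shape[0]) < p_disability).astype(int)

    if "pack_years" in lifestyle.columns:
        pack_years = lifestyle["pack_years"].to_numpy(dtype=float)
    else:
        pack_years = (lifestyle["cigs_per_day"].to_numpy() / 20.0
                      * lifestyle["years_smoked"].to_numpy())
    ipaq = lifestyle["ipaq_met"].to_numpy(dtype=float)
    neg = items[:, [idx[i] for i in NEGATIVE_ITEMS]].sum(axis=1).astype(float)
    z_py, z_ipaq, z_neg = _zscore(pack_years), _zscore(ipaq), _zscore(neg)

    le = config.lifestyle_coefs["edss"]
    eta_e = (le["pack_years"] * z_py + le["ipaq_met"] * z_ipaq
             + le["negative_score"] * z_neg)
    w = _EDSS_LIFESTYLE_GAIN * eta_e + config.noise_sd["edss"] * rng.standard_normal(eta_e.size)
    edss = np.empty(eta_e.size)
    for cls, (mu, scale, lo, hi) in _EDSS_BANDS.items():
        mask = disability == cls
        edss[mask] = np.clip(mu + scale * w[mask], lo, hi)
    edss = np.clip(np.round(edss * 2.0) / 2.0, 0.0, 5.5)

    lf = config.lifestyle_coefs["fss"]
    eta_f = lf["pack_years"] * z_py + lf["ipaq_met"] * z_ipaq
    fss = _FSS_MEAN + _FSS_SD * (eta_f + config.noise_sd["fss"] * rng.standard_normal(eta_f.size))
    fss = np.clip(fss, _FSS_LO, _FSS_HI)

    return pd.DataFrame({
        "disability_class": disability,
        "edss": edss,
        "fss": fss,
    })


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate the full two-group participant table.

    Returns n_ms + n_hc rows with the canonical CSV columns; control rows
    have missing (NaN) EDSS/FSS.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    frames = []
    for group, n in (("MS", config.n_ms), ("HC", config.n_hc)):
        demo = _sample_demographics(config, group, n)
        life = _sample_lifestyle(config, group, n)
        items = sample_ordinal_items(config, group, n)
        df = pd.concat([demo, life], axis=1)
        for k, item in enumerate(ITEMS):
            df[item] = items[:, k]
        df["group"] = group
        df["participant_id"] = [f"{group}{i + 1:04d}" for i in range(n)]
        if group == "MS":
            outcomes = simulate_outcomes(items, life, config)
            df["edss"] = outcomes["edss"].to_numpy()
            df["fss"] = outcomes["fss"].to_numpy()
        else:
            df["edss"] = np.nan
            df["fss"] = np.nan
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)[list(CSV_COLUMNS)]
    validate_cohort(table)
    return table


def validate_cohort(table: pd.DataFrame) -> None:
    """Check every participant-record invariant; raise naming row and field."""
    missing = sorted(set(CSV_COLUMNS) - set(table.columns))
    if missing:
        raise ValueError(f"participant table missing columns: {missing}")
    for row, group in table["group"].items():
        if group not in GROUPS:
            raise ValueError(f"row {row}: group {group!r} not in {GROUPS}")
    for item in ITEMS:
        bad = ~table[item].isin([0, 1, 2])
        if bad.any():
            row = table.index[bad][0]
            raise ValueError(
                f"row {row}: item {item!r} has score {table.loc[row, item]!r}; "
                "must be 0, 1 or 2")
    for col in ("weight_kg", "height_m", "waist_cm", "hip_cm"):
        bad = ~(table[col] > 0)
        if bad.any():
            row = table.index[bad][0]
            raise ValueError(f"row {row}: {col} must be strictly positive")
    for col in ("cigs_per_day", "years_smoked", "ipaq_met"):
        bad = table[col] < 0
        if bad.any():
            row = table.index[bad][0]
            raise ValueError(f"row {row}: {col} must be >= 0")
    ms = table["group"] == "MS"
    if table.loc[ms, "edss"].isna().any():
        row = table.index[ms & table["edss"].isna()][0]
        raise ValueError(f"row {row}: MS record missing EDSS")
    if (table.loc[ms, "edss"] > 5.5).any():
        row = table.index[ms & (table["edss"] > 5.5)][0]
        raise ValueError(f"row {row}: EDSS above 5.5 (exclusion criterion)")
    hc = table["group"] == "HC"
    if table.loc[hc, ["edss", "fss"]].notna().any().any():
        raise ValueError("HC records must have absent EDSS/FSS")


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write the participant table with the canonical header; NaN -> empty."""
    table[list(CSV_COLUMNS)].to_csv(path, index=False, float_format="%.6g")


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_cohort(table)
    return table


def enrollment_rate(n_screened: int, n_enrolled: int) -> int:
    """Enrollment percentage of a screening stage, rounded to whole percent."""
    if n_screened <= 0 or n_enrolled < 0 or n_enrolled > n_screened:
        raise ValueError(f"invalid screening counts {n_enrolled}/{n_screened}")
    return round(100.0 * n_enrolled / n_screened)
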