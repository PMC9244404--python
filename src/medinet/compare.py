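"""Two-group comparison of mutual-information matrices via a reshuffle null.

The 55 off-diagonal (upper-triangle) entries of both groups' MI matrices are
pooled (110 values).  Each of ``n_reshuffles`` replicates randomly partitions
the pool, without replacement, into two 55-entry matrices and takes their
difference.  The observed difference matrix is then converted to per-cell
Z-scores against this null and flagged significant where |z| > 1.96
(two-sided normal critical value at alpha = 0.05).

The null is orientation-symmetrized: every random partition contributes both
(P1 - P2) and (P2 - P1), so the null mean vanishes identically and swapping
the two groups negates every Z-score exactly.  The pooled entries are sorted
before partitioning, making the null invariant to argument order.

Matrix entries - not subjects - are the exchangeable units, which ignores
within-matrix dependence; the resulting test is conservative (see the
package methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng
from .network import MutualInfoMatrix


def z_critical(alpha: float = 0.05) -> float:
    """Two-sided normal critical value; 1.96 at alpha = 0.05."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.norm.ppf(1 - alpha / 2))


def _check_pair(mat_a: MutualInfoMatrix, mat_b: MutualInfoMatrix) -> None:
    if mat_a.variable_names != mat_b.variable_names:
        raise ValueError(
            f"variable labels differ: {mat_a.variable_names} vs {mat_b.variable_names}"
        )


def reshuffle_null(mat_a: MutualInfoMatrix, mat_b: MutualInfoMatrix,
                   n_reshuffles: int = 1000, seed: int = 0,
                   replace: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell null mean and SD of the reshuffled difference matrices.

    Returns (null_mean, null_sd) as full symmetric matrices with NaN on the
    diagonal.  ``replace=True`` resamples pooled entries with replacement
    instead of partitioning them.
    """
    _check_pair(mat_a, mat_b)
    if n_reshuffles < 100:
        raise ValueError("n_reshuffles must be >= 100")
    p = len(mat_a.variable_names)
    iu = np.triu_indices(p, k=1)
    m = iu[0].size
    pool = np.sort(np.concatenate([mat_a.values[iu], mat_b.values[iu]]))
    rng = stage_rng(seed, "reshuffle")

    if replace:
        first = rng.choice(pool, size=(n_reshuffles, m), replace=True)
        second = rng.choice(pool, size=(n_reshuffles, m), replace=True)
        diffs = first - second
    else:
        idx = np.argsort(rng.random((n_reshuffles, pool.size)), axis=1)
        shuffled = pool[idx]
        diffs = shuffled[:, :m] - shuffled[:, m:]

    # orientation symmetrization: mean is exactly 0, SD over {+-diff}
    sq = np.square(diffs)
    null_var = sq.sum(axis=0) * 2.0 / (2 * n_reshuffles - 1)
    null_sd_cells = np.sqrt(null_var)

    null_mean = np.full((p, p), np.nan)
    null_sd = np.full((p, p), np.nan)
    null_mean[iu] = 0.0
    null_sd[iu] = null_sd_cells
    null_mean.T[iu] = 0.0
    null_sd.T[iu] = null_sd_cells
    return null_mean, null_sd


@dataclass
class GroupDifferenceResult:
    """Per-cell Z-scores for the difference of two groups' MI matrices.

    All matrices are symmetric with NaN diagonals.  ``significant`` uses the
    raw per-cell rule |z| > z_crit; ``bonferroni_significant`` additionally
    divides alpha by the number of off-diagonal cells (reported for
    transparency only - the default verdict follows the raw rule).
    """

    variable_names: tuple[str, ...]
    observed_diff: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    significant: np.ndarray
    bonferroni_significant: np.ndarray
    alpha: float
    z_crit: float
    n_reshuffles: int

    @property
    def no_difference(self) -> bool:
        """True when no cell is significant (the null verdict)."""
        return not bool(self.significant.any())

    def to_frame(self) -> pd.DataFrame:
        p = len(self.variable_names)
        iu = np.triu_indices(p, k=1)
        rows = []
        for i, j in zip(*iu):
            rows.append({
                "pair": f"{self.variable_names[i]}-{self.variable_names[j]}",
                "observed_diff": self.observed_diff[i, j],
                "null_mean": self.null_mean[i, j],
                "null_sd": self.null_sd[i, j],
                "z": self.z[i, j],
                "significant": bool(self.significant[i, j]),
                "bonferroni_significant": bool(self.bonferroni_significant[i, j]),
            })
        return pd.DataFrame(rows)


def compare_groups(mat_a: MutualInfoMatrix, mat_b: MutualInfoMatrix,
                   n_reshuffles: int = 1000, seed: int = 0,
                   alpha: float = 0.05, replace: bool = False) -> GroupDifferenceResult:
    """Z-score the observed MI difference (A - B) against the reshuffle null.

    Cells with zero null SD get an undefined (NaN) Z and are never flagged
    significant.
    """
    _check_pair(mat_a, mat_b)
    p = len(mat_a.variable_names)
    observed = mat_a.values - mat_b.values
    np.fill_diagonal(observed, np.nan)
    null_mean, null_sd = reshuffle_null(mat_a, mat_b, n_reshuffles=n_reshuffles,
                                        seed=seed, replace=replace)
    zc = z_critical(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - null_mean) / null_sd
    z[~(null_sd > 0)] = np.nan
    significant = np.abs(z) > zc
    significant &= ~np.isnan(z)
    n_cells = p * (p - 1) // 2
    zc_bonf = z_critical(alpha / n_cells)
    bonf = (np.abs(z) > zc_bonf) & ~np.isnan(z)
    return GroupDifferenceResult(
        variable_names=mat_a.variable_names,
        observed_diff=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        significant=significant,
        bonferroni_significant=bonf,
        alpha=alpha,
        z_crit=zc,
        n_reshuffles=n_reshuffles,
    )
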