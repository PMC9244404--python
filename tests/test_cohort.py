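"""Synthetic-cohort generator: copula items, outcomes, full tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medinet.cohort import (
    CohortConfig,
    default_item_marginals,
    default_rank_corr_targets,
    enrollment_rate,
    generate_cohort,
    latent_correlation,
    sample_ordinal_items,
    simulate_outcomes,
    validate_cohort,
    write_cohort_csv,
)
from medinet.network import mutual_information
from medinet.scoring import ITEMS


def uniform_marginals():
    m = {item: (1 / 3, 1 / 3, 1 / 3) for item in ITEMS}
    return {"MS": dict(m), "HC": dict(m)}


class TestConfigValidation:
    def test_default_config_is_valid(self):
        CohortConfig().validate()

    def test_marginal_sum_checked(self):
        m = default_item_marginals()
        m["MS"]["fish"] = (0.5, 0.5, 0.5)
        with pytest.raises(ValueError, match="fish"):
            CohortConfig(item_marginals=m).validate()

    def test_negative_marginal_checked(self):
        m = default_item_marginals()
        m["HC"]["alcohol"] = (1.2, -0.1, -0.1)
        with pytest.raises(ValueError, match="alcohol"):
            CohortConfig(item_marginals=m).validate()

    def test_asymmetric_targets_rejected(self):
        r = default_rank_corr_targets()
        r[0, 1] = 0.5  # leave r[1,0] at 0.33
        with pytest.raises(ValueError, match="symmetric"):
            CohortConfig(rank_corr_targets=r).validate()

    def test_minimum_group_size(self):
        with pytest.raises(ValueError, match="n_ms"):
            CohortConfig(n_ms=1).validate()


class TestOrdinalSampling:
    def test_determinism_same_seed(self):
        cfg = CohortConfig(seed=5)
        a = sample_ordinal_items(cfg, "MS", 500, seed=5)
        b = sample_ordinal_items(cfg, "MS", 500, seed=5)
        assert np.array_equal(a, b)
        c = sample_ordinal_items(cfg, "MS", 500, seed=6)
        assert not np.array_equal(a, c)

    def test_independence_case(self):
        """Identity targets: all off-diagonal empirical Spearman near zero."""
        cfg = CohortConfig(rank_corr_targets=np.eye(9))
        items = sample_ordinal_items(cfg, "MS", 10_000, seed=3)
        rho = stats.spearmanr(items).statistic
        off = rho[~np.eye(9, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_marginal_consistency(self):
        """Empirical per-item frequencies within 3 SE of the configured ones."""
        cfg = CohortConfig(seed=2)
        n = 5000
        items = sample_ordinal_items(cfg, "HC", n, seed=2)
        for k, item in enumerate(ITEMS):
            target = np.asarray(cfg.item_marginals["HC"][item])
            emp = np.bincount(items[:, k], minlength=3) / n
            se = np.sqrt(target * (1 - target) / n)
            assert np.all(np.abs(emp - target) <= 3 * se + 1e-12), item

    def test_planted_spearman_monte_carlo(self):
        """Fruit-vegetables target 0.33 under uniform marginals: Monte-Carlo
        mean of the empirical Spearman within +-0.03 of the target."""
        cfg = CohortConfig(item_marginals=uniform_marginals())
        rhos = []
        for rep in range(200):
            items = sample_ordinal_items(cfg, "MS", 5000, seed=1000 + rep)
            rhos.append(stats.spearmanr(items[:, 0], items[:, 1]).statistic)
        assert np.mean(rhos) == pytest.approx(0.33, abs=0.03)

    def test_unattainable_target_reports_bound(self):
        m = uniform_marginals()
        m["MS"]["fruit"] = (0.98, 0.01, 0.01)
        m["MS"]["vegetables"] = (0.01, 0.01, 0.98)
        r = np.eye(9)
        r[0, 1] = r[1, 0] = 0.95
        cfg = CohortConfig(item_marginals=m, rank_corr_targets=r)
        with pytest.raises(ValueError, match="attainable"):
            sample_ordinal_items(cfg, "MS", 100, seed=0)

    def test_latent_correlation_monotone_and_signed(self):
        marg = (1 / 3, 1 / 3, 1 / 3)
        r_small = latent_correlation(0.1, marg, marg)
        r_big = latent_correlation(0.4, marg, marg)
        assert 0 < r_small < r_big < 1
        assert latent_correlation(-0.2, marg, marg) < 0
        assert latent_correlation(0.0, marg, marg) == 0.0


class TestOutcomes:
    def _lifestyle(self, rng, n):
        return pd.DataFrame({
            "cigs_per_day": rng.integers(0, 20, n).astype(float),
            "years_smoked": rng.integers(0, 30, n).astype(float),
            "ipaq_met": rng.lognormal(7, 1, n),
        })

    def test_null_model_prevalence(self, rng):
        """With zero coefficients the class rate is logistic(intercept),
        independent of diet."""
        cfg = CohortConfig(outcome_coefs={"intercept": 0.0, "vegetables": 0.0,
                                          "fish": 0.0})
        n = 5000
        items = sample_ordinal_items(cfg, "MS", n, seed=9)
        out = simulate_outcomes(items, self._lifestyle(rng, n), cfg, seed=9)
        rate = out["disability_class"].mean()
        assert rate == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))
        # independence from vegetable intake
        by_veg = out.groupby(items[:, 1])["disability_class"].mean()
        assert by_veg.max() - by_veg.min() < 0.08

    def test_noiseless_fss_linear_in_lifestyle(self, rng):
        """noise_sd -> 0: FSS is an exact linear function of pack-years and
        IPAQ wherever the [1, 7] clipping is inactive."""
        cfg = CohortConfig(noise_sd={"edss": 0.967, "fss": 0.0})
        n = 400
        items = sample_ordinal_items(cfg, "MS", n, seed=4)
        life = self._lifestyle(rng, n)
        out = simulate_outcomes(items, life, cfg, seed=4)
        inside = (out["fss"] > 1.0 + 1e-9) & (out["fss"] < 7.0 - 1e-9)
        assert inside.sum() > 100
        X = np.column_stack([
            np.ones(inside.sum()),
            (life["cigs_per_day"] / 20 * life["years_smoked"])[inside],
            life["ipaq_met"][inside],
        ])
        resid = out["fss"][inside] - X @ np.linalg.lstsq(X, out["fss"][inside], rcond=None)[0]
        assert np.abs(resid).max() < 1e-9

    def test_edss_respects_class_bands(self, default_cohort):
        ms = default_cohort[default_cohort.group == "MS"]
        edss = ms["edss"].to_numpy()
        assert np.all(np.isin(edss * 2, np.arange(0, 12))), "EDSS on 0.5 grid"
        assert edss.max() <= 5.5
        assert not np.any((edss > 1.5) & (edss < 2.0))

    def test_shape_mismatch_rejected(self, rng):
        cfg = CohortConfig()
        items = sample_ordinal_items(cfg, "MS", 10, seed=0)
        with pytest.raises(ValueError, match="rows"):
            simulate_outcomes(items, self._lifestyle(rng, 9), cfg)


class TestGenerateCohort:
    def test_default_sizes(self, default_cohort):
        assert len(default_cohort) == 589
        assert (default_cohort["group"] == "MS").sum() == 424
        assert (default_cohort["group"] == "HC").sum() == 165

    def test_minimum_size(self):
        table = generate_cohort(CohortConfig(n_ms=2, n_hc=2, seed=1))
        assert len(table) == 4
        validate_cohort(table)

    def test_hc_outcomes_absent(self, default_cohort):
        hc = default_cohort[default_cohort.group == "HC"]
        assert hc["edss"].isna().all()
        assert hc["fss"].isna().all()

    def test_group_marginal_contrast_fish_alcohol(self, default_cohort):
        """The MS group eats fish more frequently and drinks less than
        controls: mass on score 2 differs in the planted directions."""
        ms = default_cohort[default_cohort.group == "MS"]
        hc = default_cohort[default_cohort.group == "HC"]
        assert (ms["fish"] == 2).mean() > (hc["fish"] == 2).mean()
        assert (ms["alcohol"] == 2).mean() < (hc["alcohol"] == 2).mean()

    def test_byte_identical_output_under_fixed_seed(self, tmp_path):
        cfg = CohortConfig(n_ms=50, n_hc=30, seed=11)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort_csv(generate_cohort(cfg), p1)
        write_cohort_csv(generate_cohort(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_validate_names_offending_row_and_field(self, small_cohort):
        bad = small_cohort.copy()
        bad.loc[5, "vegetables"] = 9
        with pytest.raises(ValueError, match=r"row 5.*vegetables"):
            validate_cohort(bad)
        bad2 = small_cohort.copy()
        bad2.loc[7, "height_m"] = -1.0
        with pytest.raises(ValueError, match=r"row 7.*height_m"):
            validate_cohort(bad2)

    def test_dependence_planting(self):
        """With the default targets the four clique items (fruit, vegetables,
        cereals, fish) share more mutual information among themselves than
        the remaining item pairs do, in nearly every seed at n = 424."""
        clique = ["fruit", "vegetables", "cereals", "fish"]
        idx = {name: i for i, name in enumerate(ITEMS)}
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            items = sample_ordinal_items(CohortConfig(), "MS", 424, seed=seed)
            within, other = [], []
            for i in range(9):
                for j in range(i + 1, 9):
                    mi = mutual_information(items[:, i], items[:, j])
                    if ITEMS[i] in clique and ITEMS[j] in clique:
                        within.append(mi)
                    else:
                        other.append(mi)
            wins += np.mean(within) > np.mean(other)
        assert wins >= int(0.95 * n_seeds)


class TestEnrollment:
    @pytest.mark.parametrize("screened, enrolled, pct",
                             [(571, 424, 74), (284, 165, 58)])
    def test_reported_rates(self, screened, enrolled, pct):
        assert enrollment_rate(screened, enrolled) == pct

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            enrollment_rate(100, 101)
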