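"""Censoring rules, truncated-normal imputation and the percentile bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidfc.inference import (
    CensoringFit,
    bootstrap_log_fc,
    censor_discard_rule,
    fit_censoring_model,
    impute_censored,
    run_comparisons,
)


class TestDiscardRule:
    @pytest.mark.parametrize("counts,keep", [
        ((0, 0), True),
        ((1, 0), True),
        ((0, 2), False),
        ((1, 1), True),   # exactly one per group is tolerated
        ((2, 0), False),
        ((3, 3), False),
    ])
    def test_more_than_one_censored_in_any_group_discards(self, counts, keep):
        assert censor_discard_rule(counts) is keep

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            censor_discard_rule([-1, 0])


class TestCensoringFit:
    def test_sample_moments_and_lod(self):
        fit = fit_censoring_model([10.0, 12.0, 14.0])
        assert fit.mean == 12.0
        assert fit.sd == 2.0
        assert fit.lod == 10.0
        assert fit.n_detected == 3

    def test_nan_treated_as_censored(self):
        fit = fit_censoring_model([10.0, np.nan, 14.0])
        assert fit.n_detected == 2

    def test_single_detected_rejected(self):
        with pytest.raises(ValueError):
            fit_censoring_model([10.0, np.nan, np.nan])


class TestImputation:
    def test_draws_below_lod_and_positive(self):
        rng = np.random.default_rng(0)
        fit = CensoringFit(mean=12.0, sd=5.0, lod=10.0, n_detected=5)
        draws = impute_censored(fit, 1000, rng)
        assert (draws < 10.0).all() and (draws > 0.0).all()

    def test_degenerate_sd_collapses_to_mean(self):
        fit = CensoringFit(mean=8.0, sd=0.0, lod=10.0, n_detected=3)
        draws = impute_censored(fit, 5, np.random.default_rng(0))
        assert np.allclose(draws, 8.0)

    def test_non_positive_lod_rejected(self):
        with pytest.raises(ValueError):
            impute_censored(CensoringFit(1.0, 1.0, 0.0, 3), 1,
                            np.random.default_rng(0))

    def test_matches_truncated_normal_distribution(self):
        """1e5 draws from N(12,2) truncated to (0,10) pass a KS test at α=0.01
        against the inverse-CDF truncated-normal oracle."""
        rng = np.random.default_rng(42)
        fit = CensoringFit(mean=12.0, sd=2.0, lod=10.0, n_detected=5)
        draws = impute_censored(fit, 100_000, rng)
        a, b = (0 - 12.0) / 2.0, (10.0 - 12.0) / 2.0
        stat, p = stats.kstest(draws, stats.truncnorm(a, b, loc=12, scale=2).cdf)
        assert p > 0.01

    def test_seeded_and_reproducible(self):
        fit = CensoringFit(mean=12.0, sd=2.0, lod=10.0, n_detected=5)
        d1 = impute_censored(fit, 10, np.random.default_rng(3))
        d2 = impute_censored(fit, 10, np.random.default_rng(3))
        assert np.array_equal(d1, d2)


class TestBootstrapLogFC:
    def test_identical_groups_center_zero(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = bootstrap_log_fc(x, x, B=4000, rng=np.random.default_rng(0))
        assert abs(res.central) < 0.05
        assert res.ci_low < 0 < res.ci_high

    def test_doubled_group_centers_ln2(self):
        rng = np.random.default_rng(1)
        c = np.exp(rng.normal(0, 0.2, 10))
        res = bootstrap_log_fc(2 * c, c, B=5000, rng=np.random.default_rng(2))
        assert res.central == pytest.approx(np.log(2), abs=0.02)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        t = np.exp(rng.normal(0.5, 0.2, 8))
        c = np.exp(rng.normal(0.0, 0.2, 8))
        a = bootstrap_log_fc(t, c, B=20_000, rng=np.random.default_rng(4))
        b = bootstrap_log_fc(c, t, B=20_000, rng=np.random.default_rng(5))
        se = 3 * 0.2 / np.sqrt(20_000)
        assert a.central == pytest.approx(-b.central, abs=3 * se + 0.01)

    def test_scale_invariance(self):
        t, c = np.array([3.0, 4.0, 5.0]), np.array([2.0, 2.5, 3.0])
        a = bootstrap_log_fc(t, c, B=1000, rng=np.random.default_rng(6))
        b = bootstrap_log_fc(17.3 * t, 17.3 * c, B=1000,
                             rng=np.random.default_rng(6))
        assert a.central == pytest.approx(b.central, rel=1e-12)
        assert a.ci_low == pytest.approx(b.ci_low, rel=1e-12)

    def test_same_seed_identical_to_full_precision(self):
        t, c = [1.0, 2.0, 3.0], [1.5, 2.5, 3.5]
        a = bootstrap_log_fc(t, c, B=2000, rng=np.random.default_rng(7))
        b = bootstrap_log_fc(t, c, B=2000, rng=np.random.default_rng(7))
        assert (a.central, a.ci_low, a.ci_high) == (b.central, b.ci_low, b.ci_high)

    def test_mean_matches_exhaustive_enumeration_at_n3(self):
        """The sampled bootstrap mean agrees with the exact mean over all
        3³ × 3³ = 729 resample pairs within 3 Monte-Carlo SE."""
        t = np.array([2.0, 3.0, 5.0])
        c = np.array([1.0, 1.5, 2.5])
        means_t = [np.mean([t[i] for i in idx])
                   for idx in itertools.product(range(3), repeat=3)]
        means_c = [np.mean([c[i] for i in idx])
                   for idx in itertools.product(range(3), repeat=3)]
        exact = np.mean([np.log(mt / mc) for mt in means_t for mc in means_c])

        B = 20_000
        res = bootstrap_log_fc(t, c, B=B, rng=np.random.default_rng(8))
        sd = np.std([np.log(mt / mc) for mt in means_t for mc in means_c])
        assert res.central == pytest.approx(exact, abs=3 * sd / np.sqrt(B))

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_log_fc([1.0, 0.0, 2.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            bootstrap_log_fc([1.0, np.nan, 2.0], [1.0, 1.0, 1.0])


def _toy_matrix_and_meta():
    """10 species × (3 treated + 3 vehicle); 4 species censored enough to discard."""
    rng = np.random.default_rng(0)
    samples = [f"t{i}" for i in range(3)] + [f"v{i}" for i in range(3)]
    meta = pd.DataFrame(
        dict(cell_line="HepG2",
             treatment=["DOX"] * 3 + ["vehicle-DOX"] * 3),
        index=pd.Index(samples, name="sample_id"),
    )
    mat = pd.DataFrame(np.exp(rng.normal(0, 0.2, (10, 6))) * 10,
                       index=[f"sp{i}" for i in range(10)], columns=samples)
    # censoring pattern: sp0, sp1 → 2 missing in treated; sp2 → 2 in vehicle;
    # sp3 → 3 in treated; sp4, sp5 → 1 per group (kept, imputed)
    mat.loc["sp0", ["t0", "t1"]] = np.nan
    mat.loc["sp1", ["t1", "t2"]] = np.nan
    mat.loc["sp2", ["v0", "v2"]] = np.nan
    mat.loc["sp3", ["t0", "t1", "t2"]] = np.nan
    mat.loc["sp4", ["t0", "v1"]] = np.nan
    mat.loc["sp5", ["v0"]] = np.nan
    return mat, meta


class TestRunComparisons:
    def test_discard_rule_fixture_yields_six_estimated_rows(self):
        mat, meta = _toy_matrix_and_meta()
        res = run_comparisons(mat, meta, B=200, seed=0, levels=("species",))
        assert (res["status"] == "estimated").sum() == 6
        assert (res["status"] == "discarded").sum() == 4
        assert set(res.loc[res["status"] == "discarded", "name"]) == \
            {"sp0", "sp1", "sp2", "sp3"}

    def test_kept_singly_censored_species_report_counts(self):
        mat, meta = _toy_matrix_and_meta()
        res = run_comparisons(mat, meta, B=200, seed=0,
                              levels=("species",)).set_index("name")
        assert res.loc["sp4", "censored_treated"] == 1
        assert res.loc["sp4", "censored_control"] == 1
        assert res.loc["sp4", "status"] == "estimated"

    def test_unmatched_treatment_group_rejected(self):
        mat, meta = _toy_matrix_and_meta()
        meta = meta[meta["treatment"] != "vehicle-DOX"]
        with pytest.raises(ValueError, match="DOX"):
            run_comparisons(mat[meta.index], meta, B=50, seed=0)

    def test_same_seed_identical_results(self, mini_study):
        from lipidfc.quantification import normalize_by_cells
        areas = mini_study.features.set_index("feature_id")[
            mini_study.sample_columns()]
        norm = normalize_by_cells(areas, mini_study.metadata["cell_count"])
        fmap = mini_study.truth.set_index("feature_id")["family"]
        a = run_comparisons(norm, mini_study.metadata, family_map=fmap,
                            B=300, seed=11)
        b = run_comparisons(norm, mini_study.metadata, family_map=fmap,
                            B=300, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_one_row_per_species_per_comparison(self, mini_study):
        from lipidfc.quantification import normalize_by_cells
        areas = mini_study.features.set_index("feature_id")[
            mini_study.sample_columns()]
        norm = normalize_by_cells(areas, mini_study.metadata["cell_count"])
        res = run_comparisons(norm, mini_study.metadata, B=100, seed=0,
                              levels=("species",))
        d = mini_study.design
        n_comp = len(d.cell_lines) * len(d.drugs)
        assert len(res) == len(norm) * n_comp
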