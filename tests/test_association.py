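"""Regression model families, t inference, group comparisons."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from craniogen.association import (
    AssociationError,
    P_SENTINEL,
    bonferroni_threshold,
    compare_populations,
    fit_haplotype_model,
    fit_multi_snp_model,
    fit_single_snp_model,
    genotype_group_summary,
    p_from_t,
)


def _normal_equations(y, X):
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    return beta, se


def _sim_cohort(rng, n=200, slope=-1.878, noise_sd=8.36, p=0.701):
    counts = rng.binomial(2, p, size=n).astype(float)
    sex = rng.integers(0, 2, size=n).astype(float)
    y = 150.0 + slope * counts - 3.0 * sex + rng.normal(0, noise_sd, size=n)
    return y, counts, sex


class TestOLSCore:
    def test_coefficients_match_normal_equations_on_100_designs(self, rng):
        """OLS output equals the (X'X)^-1 X'y oracle to 1e-9."""
        for _ in range(100):
            n = int(rng.integers(20, 80))
            counts = rng.integers(0, 3, size=n).astype(float)
            sex = rng.integers(0, 2, size=n).astype(float)
            if len(np.unique(counts)) < 2:
                continue
            y = rng.normal(size=n) * 5 + counts * rng.normal()
            X = np.column_stack([np.ones(n), counts, sex])
            if np.linalg.matrix_rank(X) < 3:
                continue
            beta, se = _normal_equations(y, X)
            r = fit_single_snp_model(y, counts, sex)
            assert r.B == pytest.approx(beta[1], abs=1e-9)
            assert r.SE == pytest.approx(se[1], abs=1e-9)
            assert r.df == n - 3

    def test_exact_linear_relation_gives_zero_se(self):
        counts = np.array([0, 1, 2, 0, 1, 2, 1, 0, 2, 1.0])
        sex = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1.0])
        y = 5.0 - 1.8 * counts
        r = fit_single_snp_model(y, counts, sex)
        assert r.B == pytest.approx(-1.8, abs=1e-10)
        assert r.SE == pytest.approx(0.0, abs=1e-8)
        assert r.p == P_SENTINEL

    def test_recovery_of_planted_slope(self, rng):
        y, counts, sex = _sim_cohort(rng)
        r = fit_single_snp_model(y, counts, sex)
        assert abs(r.B - (-1.878)) < 3 * r.SE

    def test_monomorphic_snp_flagged(self):
        y = np.arange(20.0)
        r = fit_single_snp_model(y, np.ones(20), np.tile([0.0, 1.0], 10))
        assert r.flagged and np.isnan(r.p)

    def test_allele_flip_negates_coefficient(self, rng):
        y, counts, sex = _sim_cohort(rng, n=120)
        a = fit_single_snp_model(y, counts, sex)
        b = fit_single_snp_model(y, 2 - counts, sex)
        assert b.B == pytest.approx(-a.B, abs=1e-9)
        assert b.p == pytest.approx(a.p, abs=1e-12)

    def test_outcome_shift_only_moves_intercept(self, rng):
        y, counts, sex = _sim_cohort(rng, n=120)
        a = fit_single_snp_model(y, counts, sex)
        b = fit_single_snp_model(y + 100.0, counts, sex)
        assert b.B == pytest.approx(a.B, abs=1e-9)
        assert b.SE == pytest.approx(a.SE, abs=1e-9)


class TestMultiSnp:
    def test_only_second_snp_drives_outcome(self, rng):
        n = 400
        c1 = rng.binomial(2, 0.5, size=n).astype(float)
        c2 = rng.binomial(2, 0.6, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 100.0 - 2.0 * c2 + rng.normal(0, 3, size=n)
        r1, r2, ri = fit_multi_snp_model(y, c1, c2, sex)
        assert abs(r2.B - (-2.0)) < 3 * r2.SE
        assert abs(r1.B) < 3 * r1.SE
        assert abs(ri.B) < 3 * ri.SE
        assert r1.df == n - 5

    def test_interaction_recovery(self, rng):
        n = 500
        c1 = rng.binomial(2, 0.5, size=n).astype(float)
        c2 = rng.binomial(2, 0.5, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 10.0 + 1.0 * c1 * c2 + rng.normal(0, 2, size=n)
        _, _, ri = fit_multi_snp_model(y, c1, c2, sex)
        assert abs(ri.B - 1.0) < 3 * ri.SE

    def test_collinear_duplicate_snp_flagged(self, rng):
        n = 60
        c = rng.binomial(2, 0.5, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = rng.normal(size=n)
        results = fit_multi_snp_model(y, c, c.copy(), sex)
        assert all(r.flagged for r in results)

    def test_coefficients_match_normal_equations(self, rng):
        n = 150
        c1 = rng.binomial(2, 0.5, size=n).astype(float)
        c2 = rng.binomial(2, 0.6, size=n).astype(float)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = rng.normal(size=n) * 4
        X = np.column_stack([np.ones(n), c1, c2, c1 * c2, sex])
        beta, se = _normal_equations(y, X)
        for i, r in enumerate(fit_multi_snp_model(y, c1, c2, sex), start=1):
            assert r.B == pytest.approx(beta[i], abs=1e-9)
            assert r.SE == pytest.approx(se[i], abs=1e-9)


class TestHaplotypeModel:
    def test_two_group_closed_form(self, rng):
        """Cohort of hGA/hGA and hAG/hAG subjects: the hAG per-copy effect
        equals half the group-mean difference."""
        n_ref, n_alt = 40, 35
        copies = pd.DataFrame({
            "hAG": [0.0] * n_ref + [2.0] * n_alt,
            "hAA": 0.0,
            "hGG": 0.0,
        })
        y = np.concatenate([
            rng.normal(150.0, 1.0, size=n_ref),
            rng.normal(150.0 - 2.6 * 2, 1.0, size=n_alt),
        ])
        sex = np.zeros(n_ref + n_alt)
        sex[::2] = 1.0
        (r,) = fit_haplotype_model(y, copies, sex)
        assert r.term == "hAG"
        # closed-form oracle from group means (sex balanced across groups)
        X = np.column_stack([np.ones(len(y)), copies["hAG"], sex])
        beta, _ = _normal_equations(y, X)
        assert r.B == pytest.approx(beta[1], abs=1e-9)
        assert abs(r.B - (-2.6)) < 3 * r.SE

    def test_all_reference_cohort_drops_every_term(self, caplog):
        copies = pd.DataFrame({"hAG": [0.0] * 10, "hAA": 0.0, "hGG": 0.0})
        with caplog.at_level("WARNING"):
            results = fit_haplotype_model(np.arange(10.0), copies, np.zeros(10))
        assert results == []

    def test_simulation_recovery_from_japanese_frequencies(self, rng):
        from craniogen.popgen import em_phase_two_loci, haplotype_copy_table
        from craniogen.reference import HAPLOTYPE_FREQ
        from craniogen.synthetic import simulate_genotypes

        geno, pairs = simulate_genotypes(HAPLOTYPE_FREQ["Japanese"], 400, rng)
        h = em_phase_two_loci(geno["rs9288572"], geno["rs7559271"])
        copies = haplotype_copy_table(geno, h)
        true_hag = np.sum(pairs == 0, axis=1).astype(float)  # hAG index 0
        y = 150.0 - 3.296 * true_hag + rng.normal(0, 6, size=len(geno))
        sex = rng.integers(0, 2, size=len(geno)).astype(float)
        results = fit_haplotype_model(y, copies, sex)
        hag = next(r for r in results if r.term == "hAG")
        assert abs(hag.B - (-3.296)) < 3 * hag.SE


class TestInference:
    def test_published_japanese_single_snp_p(self):
        """t-based inference reproduces the 1.4e-2 p-value for
        B=-1.878, SE=0.758 at df=198 (normal inference gives 1.3e-2)."""
        p = p_from_t(-1.878, 0.758, 198)
        assert f"{p:.1e}" == "1.4e-02"
        p_norm = 2 * stats.norm.sf(1.878 / 0.758)
        assert f"{p_norm:.1e}" != "1.4e-02"

    def test_null_and_textbook_quantile(self):
        assert p_from_t(0.0, 1.0, 50) == 1.0
        assert p_from_t(2.228, 1.0, 10) == pytest.approx(0.050, abs=5e-4)

    def test_zero_se_sentinel_and_validation(self):
        assert p_from_t(1.0, 0.0, 10) == P_SENTINEL
        with pytest.raises(AssociationError):
            p_from_t(1.0, 1.0, 0)

    @pytest.mark.parametrize(
        "alpha,n_tests,expected",
        [(0.05, 16, 0.003125), (0.05, 1, 0.05), (0.10, 4, 0.025)],
    )
    def test_bonferroni_threshold(self, alpha, n_tests, expected):
        assert bonferroni_threshold(alpha, n_tests) == pytest.approx(expected, abs=1e-12)


class TestGroupComparisons:
    def test_identical_groups_no_evidence(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.concatenate([values] * 3)
        genotypes = np.repeat([0, 1, 2], 5)
        res = genotype_group_summary(y, genotypes)
        means = [g["mean"] for g in res.groups.values()]
        assert np.allclose(means, means[0])
        assert res.omnibus_p == pytest.approx(1.0, abs=1e-12)

    def test_type_i_error_of_genotype_omnibus(self, rng):
        """Null rejection rate at alpha=0.05 within [0.03, 0.07]."""
        rejections = 0
        reps = 1000
        for _ in range(reps):
            g = rng.binomial(2, 0.5, size=90)
            y = rng.normal(size=90)
            res = genotype_group_summary(y, g)
            if res.omnibus_p is not None and res.omnibus_p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_for_monotone_genotype_means(self, rng):
        """A published-magnitude monotone pattern (151.4/148.6/146.9,
        SD 7) is detected in at least 80% of replicates."""
        hits = 0
        reps = 200
        for _ in range(reps):
            y = np.concatenate([
                rng.normal(151.4, 7, size=60),
                rng.normal(148.6, 7, size=100),
                rng.normal(146.9, 7, size=40),
            ])
            g = np.repeat([0, 1, 2], [60, 100, 40])
            res = genotype_group_summary(y, g)
            hits += res.omnibus_p < 0.05
        assert hits / reps >= 0.80

    def test_kruskal_path_available(self, rng):
        g = rng.binomial(2, 0.5, size=60)
        y = rng.normal(size=60)
        res = genotype_group_summary(y, g, test="kruskal")
        assert res.omnibus_test == "kruskal"
        assert 0 <= res.omnibus_p <= 1


class TestComparePopulations:
    @staticmethod
    def _frame(groups, sex="male"):
        rows = []
        for label, values in groups.items():
            for v in values:
                rows.append({"population": label, "sex": sex, "var": v})
        return pd.DataFrame(rows)

    def test_anova_f_matches_hand_computed_oracle(self, rng):
        groups = {k: rng.normal(size=5) + i * 0.1 for i, k in enumerate("ABC")}
        frame = self._frame(groups)
        res = compare_populations(frame, "var", sex="male", alpha_normality=0.0)
        all_values = np.concatenate(list(groups.values()))
        grand = all_values.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(np.sum((v - np.mean(v)) ** 2) for v in groups.values())
        f_stat = (ss_between / 2) / (ss_within / (15 - 3))
        assert res.omnibus_test == "ANOVA"
        assert res.omnibus_p == pytest.approx(float(stats.f.sf(f_stat, 2, 12)), abs=1e-9)

    def test_tukey_type_i_error_under_equal_means(self, rng):
        """All three pairwise Tukey tests clear alpha in >=93% of null reps."""
        clean = 0
        reps = 200
        for _ in range(reps):
            groups = {k: rng.normal(size=50) for k in ("Japanese", "Korean", "Egyptian")}
            res = compare_populations(
                self._frame(groups), "var", sex="male", alpha_normality=0.0
            )
            if all(p > 0.05 for p in res.pairwise.values()):
                clean += 1
        assert clean / reps >= 0.93

    def test_shifted_group_detected(self, rng):
        """A group shifted by two pooled SDs is flagged in >=99% of reps."""
        hits = 0
        reps = 100
        for _ in range(reps):
            groups = {
                "Japanese": rng.normal(0, 1, size=50),
                "Korean": rng.normal(0, 1, size=50),
                "Egyptian": rng.normal(2.0, 1, size=50),
            }
            res = compare_populations(self._frame(groups), "var", sex="male")
            flagged = [p < 0.05 for pair, p in res.pairwise.items() if "Egyptian" in pair]
            hits += all(flagged) and len(flagged) == 2
        assert hits / reps >= 0.99

    def test_nonparametric_path_on_skewed_data(self, rng):
        groups = {k: rng.exponential(1.0, size=40) ** 2 for k in ("A", "B", "C")}
        res = compare_populations(self._frame(groups), "var", sex="male")
        assert res.omnibus_test == "Kruskal-Wallis"
        assert len(res.pairwise) == 3

    def test_small_group_excluded(self, rng, caplog):
        groups = {"A": rng.normal(size=30), "B": rng.normal(size=30), "C": [1.0, 2.0]}
        with caplog.at_level("WARNING"):
            res = compare_populations(self._frame(groups), "var", sex="male")
        assert "C" not in res.groups
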