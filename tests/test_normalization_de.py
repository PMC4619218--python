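import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from afmaturity.io_formats import SampleMetadata, ValidationError
from afmaturity.normalization_de import (
    anova_stage_test,
    benjamini_hochberg,
    classify_temporal_patterns,
    estimate_variance_prior,
    filter_expressed,
    moderated_t_test,
    tmm_normalize,
)
from afmaturity.synthetic import SimulationConfig, simulate_study

from conftest import make_matrix


def bh_brute_force(p):
    """Independent step-up oracle: adj_(i) = min over j >= i of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        candidate = p[order[rank - 1]] * m / rank
        running_min = min(running_min, candidate)
        adj_sorted[rank - 1] = min(running_min, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


class TestTmm:
    def test_identical_samples_factors_one(self):
        m = make_matrix(np.tile(np.arange(1.0, 21.0)[:, None], (1, 2)),
                        scale="counts")
        _, factors = tmm_normalize(m)
        np.testing.assert_allclose(factors.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_doubled_sample_gives_sqrt2_pair(self):
        """B = 2 x A elementwise: every log ratio is 1, so the trimmed
        weighted mean is 1 and geometric-mean rescaling forces factors
        (1/sqrt(2), sqrt(2))."""
        a = np.arange(1.0, 21.0)
        m = make_matrix(np.column_stack([a, 2 * a]), scale="counts")
        normalized, factors = tmm_normalize(m)
        np.testing.assert_allclose(
            factors.to_numpy(), [2 ** -0.5, 2 ** 0.5], atol=1e-9
        )
        # normalization divides the doubling back out entirely
        np.testing.assert_allclose(normalized.data["S1"].to_numpy(),
                                   normalized.data["S2"].to_numpy(), rtol=1e-9)

    def test_two_sample_factors_multiply_to_one(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.poisson(50.0, size=(100, 2)) + 1.0, scale="counts")
        _, factors = tmm_normalize(m)
        assert factors.prod() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        m = make_matrix([[1.0, 0.0], [2.0, 0.0]], scale="counts")
        with pytest.raises(ValidationError, match="S2"):
            tmm_normalize(m)

    def test_single_sample_rejected(self):
        m = make_matrix([[1.0], [2.0]], scale="counts")
        with pytest.raises(ValidationError):
            tmm_normalize(m)


class TestFilterExpressed:
    def test_threshold_rule(self):
        m = make_matrix([[0.5, 0.9, 0.99], [0.0, 1.01, 0.0], [1.0, 1.0, 1.0]])
        kept = filter_expressed(m, rpkm_min=1.0)
        # max must strictly exceed the threshold: (0.5,0.9,0.99) and the
        # all-exactly-1 gene drop, (0,1.01,0) survives
        assert kept.gene_ids == ["g2"]

    def test_zero_threshold_keeps_positive_matrix(self):
        m = make_matrix([[0.1, 2.0], [5.0, 0.2]])
        assert filter_expressed(m, rpkm_min=0.0).gene_ids == m.gene_ids


class TestBenjaminiHochberg:
    def test_known_step_up_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0] * 5), 1.0)

    def test_tied_p_values_scale_cancel(self):
        np.testing.assert_allclose(benjamini_hochberg([0.02] * 7), 0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_is_monotone(self, p):
        adj = benjamini_hochberg(p)
        np.testing.assert_allclose(adj, bh_brute_force(p), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestAnovaStageTest:
    def test_constant_gene_not_differential(self, three_stage_metadata):
        m = make_matrix(np.full((1, 6), 7.0))
        (res,) = anova_stage_test(m, three_stage_metadata)
        assert res.anova_p == 1.0 and res.anova_p_adjusted == 1.0
        assert not res.is_differential

    def test_strong_separation_matches_f_oracle(self):
        """Groups (log2) PN=0x4, PT=FT=3x6 with tiny jitter: the F statistic
        computed from the definitional sums of squares puts p far below
        1e-6, and the PN/FT fold of pseudocounted linear means is ~8."""
        rng = np.random.default_rng(0)
        metadata = [SampleMetadata(f"S{i + 1}", st)
                    for i, st in enumerate(["PN"] * 4 + ["PT"] * 6 + ["FT"] * 6)]
        jitter = rng.normal(0, 1e-3, 16)
        log2_vals = np.array([0.0] * 4 + [3.0] * 12) + jitter
        m = make_matrix((np.exp2(log2_vals) - 1.0).clip(min=0)[None, :])
        (res,) = anova_stage_test(m, metadata)

        # independent oracle: definitional one-way ANOVA on the log2 values
        logv = np.log2(m.data.to_numpy()[0] + 1.0)
        groups = [logv[:4], logv[4:10], logv[10:]]
        grand = logv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ssb / 2) / (ssw / 13)
        p_oracle = stats.f.sf(f, 2, 13)
        assert res.anova_p == pytest.approx(p_oracle, rel=1e-9)
        assert res.anova_p < 1e-6
        assert res.pairwise[("PN", "FT")].fold_change == pytest.approx(8.0, rel=5e-3)
        assert res.pairwise[("PN", "FT")].direction == "up"
        assert res.is_differential

    def test_requires_two_samples_per_stage(self):
        metadata = [SampleMetadata(f"S{i + 1}", st)
                    for i, st in enumerate(["PN", "PT", "PT", "FT", "FT"])]
        m = make_matrix(np.ones((2, 5)))
        with pytest.raises(ValidationError, match="PN"):
            anova_stage_test(m, metadata)

    def test_invariant_to_column_order_and_global_rescale(self, default_bundle):
        b = default_bundle
        m = filter_expressed(b.expression)
        sub = make_matrix(m.data.iloc[:80].to_numpy(), gene_ids=m.gene_ids[:80],
                          sample_ids=m.sample_ids)
        res = anova_stage_test(sub, b.metadata)
        shuffled_cols = list(reversed(sub.sample_ids))
        scaled = make_matrix(sub.data[shuffled_cols].to_numpy() * 3.7,
                             gene_ids=sub.gene_ids, sample_ids=shuffled_cols)
        res2 = anova_stage_test(scaled, b.metadata)
        # the log2(x+1) pseudocount makes rescaling invariance approximate:
        # the pseudocount's relative weight changes with the scale
        for r1, r2 in zip(res, res2):
            assert r1.gene_id == r2.gene_id
            assert r1.anova_p == pytest.approx(r2.anova_p, abs=0.02)

    def test_invariant_to_column_order_exact(self, default_bundle):
        b = default_bundle
        m = filter_expressed(b.expression)
        sub = make_matrix(m.data.iloc[:50].to_numpy(), gene_ids=m.gene_ids[:50],
                          sample_ids=m.sample_ids)
        res = anova_stage_test(sub, b.metadata)
        cols = list(reversed(sub.sample_ids))
        perm = make_matrix(sub.data[cols].to_numpy(), gene_ids=sub.gene_ids,
                           sample_ids=cols)
        res2 = anova_stage_test(perm, b.metadata)
        for r1, r2 in zip(res, res2):
            assert r1.anova_p == pytest.approx(r2.anova_p, rel=1e-12)
            assert r1.is_differential == r2.is_differential


class TestModeratedT:
    def _two_group_meta(self, na=3, nb=3):
        return [SampleMetadata(f"S{i + 1}", "PT") for i in range(na)] + \
               [SampleMetadata(f"T{i + 1}", "FT") for i in range(nb)]

    def test_zero_prior_df_equals_ordinary_t(self):
        rng = np.random.default_rng(4)
        metadata = self._two_group_meta()
        m = make_matrix(rng.lognormal(2.0, 1.0, size=(40, 6)),
                        sample_ids=[s.sample_id for s in metadata])
        mod = moderated_t_test(m, metadata, "PT", "FT", prior_df=0.0)
        logm = np.log2(m.data.to_numpy() + 1.0)
        t_ref, p_ref = stats.ttest_ind(logm[:, 3:], logm[:, :3], axis=1)
        for r, t_o, p_o in zip(mod, t_ref, p_ref):
            assert r.t_moderated == pytest.approx(t_o, rel=1e-9)
            assert r.p == pytest.approx(p_o, rel=1e-9)

    def test_identical_group_means_give_null_result(self):
        metadata = self._two_group_meta(2, 2)
        m = make_matrix([[5.0, 7.0, 5.0, 7.0]],
                        sample_ids=[s.sample_id for s in metadata])
        (r,) = moderated_t_test(m, metadata, "PT", "FT")
        assert r.t_moderated == 0.0 and r.p == 1.0 and not r.is_regulated

    def test_shrinkage_pulls_variances_toward_prior(self):
        # heteroskedastic genes: per-gene sd spread forces a finite d0
        rng = np.random.default_rng(5)
        metadata = self._two_group_meta()
        sd = rng.uniform(0.2, 1.5, size=300)
        log2_expr = rng.normal(5.0, 1.0, size=(300, 6)) * sd[:, None]
        m = make_matrix(np.exp2(log2_expr),
                        sample_ids=[s.sample_id for s in metadata])
        mod = moderated_t_test(m, metadata, "PT", "FT")
        assert 0 < mod[0].prior_df < np.inf
        assert mod[0].prior_variance > 0
        # posterior variances sit between raw and prior: the moderated |t|
        # never exceeds the larger of ordinary |t| and the prior-only |t|
        logm = np.log2(m.data.to_numpy() + 1.0)
        t_ord = np.abs(stats.ttest_ind(logm[:, 3:], logm[:, :3], axis=1).statistic)
        lfc = logm[:, 3:].mean(axis=1) - logm[:, :3].mean(axis=1)
        t_prior = np.abs(lfc / np.sqrt(mod[0].prior_variance * (2 / 3)))
        t_mod = np.abs(np.array([r.t_moderated for r in mod]))
        assert np.all(t_mod <= np.maximum(t_ord, t_prior) + 1e-9)

    def test_moderated_beats_ordinary_t_power(self):
        """Monte-Carlo power comparison: 1000 null genes + 100 genes with a
        true log2 shift of 2 at n=3 vs 3; across replicates the moderated
        test flags more of the shifted genes at alpha=0.05 on average than
        the ordinary t-test."""
        rng = np.random.default_rng(6)
        n_rep, n_null, n_shift = 200, 1000, 100
        metadata = self._two_group_meta()
        power_mod, power_ord = [], []
        for _ in range(n_rep):
            log2_expr = rng.normal(5.0, 1.0, size=(n_null + n_shift, 6))
            log2_expr[n_null:, 3:] += 2.0
            values = np.exp2(log2_expr) - 1.0
            m = make_matrix(values.clip(min=0),
                            sample_ids=[s.sample_id for s in metadata])
            mod = moderated_t_test(m, metadata, "PT", "FT", fold_min=1.0)
            p_mod = np.array([r.p for r in mod])
            logm = np.log2(m.data.to_numpy() + 1.0)
            p_ord = stats.ttest_ind(logm[:, 3:], logm[:, :3], axis=1).pvalue
            power_mod.append(np.mean(p_mod[n_null:] <= 0.05))
            power_ord.append(np.mean(p_ord[n_null:] <= 0.05))
        assert np.mean(power_mod) > np.mean(power_ord)

    def test_morbidity_groups_resolve_from_flags(self, default_bundle):
        b = default_bundle
        m = filter_expressed(b.expression)
        res = moderated_t_test(m, b.metadata, "gavage_feeding", "FT")
        assert len(res) == m.shape[0]

    def test_unknown_group_rejected(self, default_bundle):
        m = filter_expressed(default_bundle.expression)
        with pytest.raises(ValidationError):
            moderated_t_test(m, default_bundle.metadata, "nonexistent", "FT")


class TestVariancePrior:
    def test_recovers_known_prior_approximately(self):
        """Variances drawn from s0^2 * chi2_d0 / d0-scaled F structure:
        s^2 ~ s0^2 * (chi2_d/d) / (chi2_d0/d0) with d0=8, s0=1."""
        rng = np.random.default_rng(7)
        d, d0_true, s0_true = 4, 8.0, 1.0
        s2 = (s0_true * (rng.chisquare(d, 20_000) / d)
              / (rng.chisquare(d0_true, 20_000) / d0_true))
        d0, s0_sq = estimate_variance_prior(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0_sq == pytest.approx(s0_true, rel=0.1)

    def test_constant_variances_give_infinite_prior_df(self):
        from scipy import special

        d0, s0_sq = estimate_variance_prior(np.full(100, 2.0), 4)
        assert np.isinf(d0)
        # with zero spread the prior scale is the common value corrected for
        # the chi-square bias of E[log s^2]: exp(log 2 - psi(d/2) + log(d/2))
        expected = 2.0 * np.exp(np.log(2.0) - special.digamma(2.0))
        assert s0_sq == pytest.approx(expected, rel=1e-9)


class TestTemporalPatterns:
    def _results_for(self, m, metadata, **kwargs):
        res = anova_stage_test(m, metadata)
        return classify_temporal_patterns(res, m, metadata, **kwargs)

    def test_monotone_means_classified_by_sign(self, three_stage_metadata):
        # stage means (1, 2, 4) -> induced; (4, 2, 1) -> suppressed
        up = np.exp2([1, 1, 2, 2, 4, 4]) - 1
        down = np.exp2([4, 4, 2, 2, 1, 1]) - 1
        m = make_matrix(np.vstack([up, down]))
        res = self._results_for(m, three_stage_metadata)
        trends = {r.gene_id: r.trend for r in res if r.is_differential}
        assert trends == {"g1": "induced", "g2": "suppressed"}

    def test_unknown_method_rejected(self, three_stage_metadata):
        m = make_matrix(np.ones((1, 6)))
        res = anova_stage_test(m, three_stage_metadata)
        with pytest.raises(ValidationError):
            classify_temporal_patterns(res, m, three_stage_metadata,
                                       method="kmeans")

    def test_som_agrees_with_sign_on_noiseless_data(self, noiseless_bundle):
        b = noiseless_bundle
        m = filter_expressed(b.expression)
        res = anova_stage_test(m, b.metadata)
        by_sign = classify_temporal_patterns(res, m, b.metadata, method="sign")
        by_som = classify_temporal_patterns(res, m, b.metadata, method="som",
                                            seed=0)
        planted = set(b.truth.induced_gene_ids) | set(b.truth.suppressed_gene_ids)
        sign_map = {r.gene_id: r.trend for r in by_sign}
        som_map = {r.gene_id: r.trend for r in by_som}
        for gene in planted:
            assert som_map[gene] == sign_map[gene]

    def test_recovers_planted_trends(self, noiseless_bundle):
        b = noiseless_bundle
        m = filter_expressed(b.expression)
        res = self._results_for(m, b.metadata)
        trends = {r.gene_id: r.trend for r in res}
        assert all(trends[g] == "induced" for g in b.truth.induced_gene_ids)
        assert all(trends[g] == "suppressed" for g in b.truth.suppressed_gene_ids)
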