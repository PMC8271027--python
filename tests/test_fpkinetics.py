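"""FP association fitting, ratio statistics and replicate summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pepxkit.fpkinetics import (AssociationKinetics, FlatTraceError, FPTrace,
                                fit_association, fold_change,
                                relative_activity, subtract_baseline,
                                summarize_conditions, welch_t_test)
from pepxkit.synthgen import FPPreset, fp_preset, gen_fp_trace


def _trace(t, y, **kw):
    return FPTrace(time=np.asarray(t, float), fp=np.asarray(y, float), **kw)


class TestSubtractBaseline:
    def test_zero_baseline_is_identity(self):
        t = np.linspace(0, 100, 10)
        tr = _trace(t, np.arange(10.0))
        base = _trace(t, np.zeros(10), role="baseline")
        out = subtract_baseline(tr, base, mode="pointwise")
        assert np.array_equal(out.fp, tr.fp)
        assert out.baseline_subtracted

    def test_constant_baseline_shifts_every_point(self):
        t = np.linspace(0, 100, 10)
        out = subtract_baseline(_trace(t, np.full(10, 50.0)),
                                _trace(t, np.full(10, 35.0)))
        assert np.allclose(out.fp, 15.0)

    def test_mismatched_grid_uses_hand_computed_mean_in_constant_mode(self):
        # 8-point baseline (minimum trace length) with mean (1+2+...+8)/8 = 4.5
        tr = _trace(np.linspace(0, 90, 10), np.full(10, 100.0))
        base = _trace(np.linspace(0, 40, 8), np.arange(1.0, 9.0),
                      role="baseline")
        out = subtract_baseline(tr, base, mode="constant")
        assert np.allclose(out.fp, 100.0 - 4.5)

    def test_mismatched_grid_rejected_in_pointwise_mode(self):
        tr = _trace(np.linspace(0, 90, 10), np.full(10, 100.0))
        base = _trace(np.linspace(0, 40, 8), np.zeros(8))
        with pytest.raises(ValueError, match="grid"):
            subtract_baseline(tr, base, mode="pointwise")


class TestAssociationFit:
    def test_noiseless_roundtrip_recovers_parameters(self):
        t = np.linspace(0, 6000, 40)
        y = 150.0 - 150.0 * np.exp(-1e-3 * t)
        est = AssociationKinetics().fit(t, y)
        assert est.k_on_ == pytest.approx(1e-3, rel=1e-6)
        assert est.y0_ == pytest.approx(150.0, rel=1e-6)
        assert est.a_ == pytest.approx(150.0, rel=1e-6)
        assert est.converged_

    def test_three_noisy_replicates_recover_rate_within_five_percent(self):
        p = FPPreset("A*03:01", "Tsn-WT", k_true=1.089e-3, noise_sd=2.0)
        ks = []
        for rep in range(3):
            trace, base = gen_fp_trace(p, seed=101, replicate=rep)
            fit = fit_association(subtract_baseline(trace, base))
            ks.append(fit.k_on)
        assert np.mean(ks) == pytest.approx(p.k_true, rel=0.05)

    def test_flat_trace_refused(self):
        t = np.linspace(0, 1000, 20)
        with pytest.raises(FlatTraceError, match="no association"):
            AssociationKinetics().fit(t, np.full(20, 50.0))

    def test_optimizer_matches_profiled_grid_search(self):
        """RSS within 0.1% of a dense k-grid with profiled linear params."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            k = 10 ** rng.uniform(-4, -2.5)
            t = np.linspace(0, 6.0 / k, 30)
            y = (rng.uniform(80, 200) - rng.uniform(50, 150)
                 * np.exp(-k * t) + rng.normal(0, 2.0, t.size))
            est = AssociationKinetics().fit(t, y)
            best = np.inf
            for kg in np.geomspace(k / 20, k * 20, 400):
                X = np.column_stack([np.ones_like(t), -np.exp(-kg * t)])
                coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
                if rss.size and rss[0] < best:
                    best = rss[0]
            assert est.rss_ <= best * 1.001

    def test_estimator_sklearn_interface(self):
        est = AssociationKinetics(multi_start=(1.0,))
        assert est.get_params()["multi_start"] == (1.0,)
        t = np.linspace(0, 5000, 20)
        y = 100 - 100 * np.exp(-1e-3 * t)
        pred = est.fit(t, y).predict(t)
        assert np.allclose(pred, y, atol=1e-6)

    def test_replicate_mean_scatter_shrinks_with_replicate_count(self):
        """SD of the replicate-mean rate scales roughly as 1/sqrt(n)."""
        p = FPPreset("B*27:05", "Tsn-WT", k_true=5.83e-4, noise_sd=2.0,
                     t_end=9000.0)
        ks = []
        for rep in range(240):
            trace, base = gen_fp_trace(p, seed=300, replicate=rep)
            ks.append(fit_association(subtract_baseline(trace, base)).k_on)
        ks = np.random.default_rng(1).permutation(ks)
        sd1 = ks.std()
        for n, groups in ((3, 80), (12, 20), (48, 5)):
            sd_n = ks.reshape(groups, n).mean(axis=1).std()
            # empirical SD of n-replicate means tracks sigma/sqrt(n)
            assert 0.4 < sd_n / (sd1 / np.sqrt(n)) < 2.3, n


class TestRatioStatistics:
    def test_fold_change_identity_and_doubling(self):
        assert fold_change(2e-4, 2e-4) == 1.0
        assert fold_change(4e-4, 2e-4) == pytest.approx(2.0)

    def test_fold_change_requires_positive_rates(self):
        with pytest.raises(ValueError):
            fold_change(1e-4, 0.0)

    def test_noiseless_preset_pair_reproduces_published_fold(self):
        pc = fp_preset("A*03:01", "Tsn-WT")
        pu = fp_preset("A*03:01", "none")
        ks = {}
        for p in (pc, pu):
            trace, base = gen_fp_trace(
                FPPreset(p.allotype, p.catalyst, p.k_true, noise_sd=0.0),
                seed=0)
            ks[p.catalyst] = fit_association(
                subtract_baseline(trace, base)).k_on
        assert fold_change(ks["Tsn-WT"], ks["none"]) == pytest.approx(
            10.89, rel=1e-4)

    def test_relative_activity_endpoints(self):
        assert relative_activity(5e-4, 5e-4, 1e-4) == 1.0
        assert relative_activity(1e-4, 5e-4, 1e-4) == 0.0

    def test_relative_activity_undefined_when_wt_equals_none(self):
        with pytest.raises(ValueError):
            relative_activity(2e-4, 1e-4, 1e-4)

    def test_noiseless_mutant_triple_reproduces_published_activity(self):
        ks = {}
        for cat in ("none", "Tsn-WT", "K16L"):
            p = fp_preset("B*27:09", cat)
            trace, base = gen_fp_trace(
                FPPreset(p.allotype, cat, p.k_true, noise_sd=0.0), seed=0)
            ks[cat] = fit_association(subtract_baseline(trace, base)).k_on
        assert relative_activity(ks["K16L"], ks["Tsn-WT"], ks["none"]) == \
            pytest.approx(1.26, abs=1e-3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_ratios_invariant_under_common_rescaling(self, scale):
        k_mut, k_wt, k_none = 3e-4, 5e-4, 1e-4
        assert fold_change(k_wt * scale, k_none * scale) == \
            pytest.approx(fold_change(k_wt, k_none), rel=1e-9)
        assert relative_activity(k_mut * scale, k_wt * scale,
                                 k_none * scale) == \
            pytest.approx(relative_activity(k_mut, k_wt, k_none), rel=1e-9)

    def test_relative_activity_monotone_in_mutant_rate(self):
        vals = [relative_activity(k, 5e-4, 1e-4)
                for k in np.linspace(1e-4, 8e-4, 15)]
        assert np.all(np.diff(vals) > 0)


class TestWelch:
    def test_identical_groups(self):
        t, dof, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_independent_implementation(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        t, dof, p = welch_t_test(a, b)
        # hand formula: means 2 and 3, each variance 1 -> se = sqrt(2/3)
        assert t == pytest.approx(-1.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert dof == pytest.approx(4.0, rel=1e-12)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestSummarize:
    def _fits(self, spec):
        """spec: {(allotype, catalyst): [k values]} -> KineticsFit list."""
        from pepxkit.fpkinetics import KineticsFit
        fits = []
        for (allo, cat), ks in spec.items():
            for i, k in enumerate(ks):
                fits.append(KineticsFit(
                    y0=150, a=150, k_on=k, y0_stderr=1, a_stderr=1,
                    k_on_stderr=1e-6, rss=0.0, converged=True, n_points=40,
                    condition=(allo, cat, i)))
        return fits

    def test_single_replicate_reports_mean_without_sd(self):
        s = summarize_conditions(self._fits({("A", "none"): [1e-4],
                                             ("A", "Tsn-WT"): [5e-4]}))
        wt = s[s["catalyst"] == "Tsn-WT"].iloc[0]
        assert wt["k_on_mean"] == pytest.approx(5e-4)
        assert np.isnan(wt["k_on_sd"])
        assert wt["fold_change"] == pytest.approx(5.0)

    def test_identical_replicates_have_zero_sd(self):
        s = summarize_conditions(self._fits({("A", "none"): [1e-4] * 3}))
        assert s.iloc[0]["k_on_sd"] == 0.0

    def test_missing_uncatalyzed_condition_rejected(self):
        with pytest.raises(ValueError, match="none"):
            summarize_conditions(self._fits({("A", "Tsn-WT"): [5e-4] * 3}))

    def test_mutant_gets_relative_activity_and_welch_columns(self):
        s = summarize_conditions(self._fits({
            ("A", "none"): [1e-4, 1.1e-4, 0.9e-4],
            ("A", "Tsn-WT"): [5e-4, 5.2e-4, 4.8e-4],
            ("A", "L18G"): [2e-4, 2.1e-4, 1.9e-4]}))
        mut = s[s["catalyst"] == "L18G"].iloc[0]
        expected = (2e-4 - 1e-4) / (5e-4 - 1e-4)
        assert mut["relative_activity"] == pytest.approx(expected, rel=1e-9)
        assert np.isfinite(mut["p_value"])
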