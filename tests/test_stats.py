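"""Time-resolved factorial ANOVA, Holm corrections, gradients, RT bins."""

import numpy as np
import pytest
from scipy import stats as sps

from neurocue import stats, synth
from neurocue.stats import (DegenerateDesignError, factorial_anova,
                            factorial_anova_timecourse, holm_bonferroni,
                            holm_sidak, interaction_effectsize_gradient,
                            rt_bin_analysis, rt_quantile_bins)


class TestFactorialAnova:
    def test_single_factor_F_equals_t_squared(self, rng):
        """Two-group one-factor reduction: F = t^2 from an independent
        t-test implementation."""
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.6, 1, 30)
        data = np.stack([a, b], axis=1)          # (30, 2)
        table = factorial_anova(data, ("group",))
        t, p = sps.ttest_ind(b, a)
        assert table.F.iloc[0] == pytest.approx(t ** 2, rel=1e-10)
        assert table.p.iloc[0] == pytest.approx(p, rel=1e-10)

    def test_matches_statsmodels_two_way(self, rng):
        """Balanced 2x3 ANOVA agrees with the statsmodels OLS route."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        data = rng.normal(size=(12, 2, 3))
        data[:, 1, :] += 0.5
        rows = []
        for i in range(12):
            for a in range(2):
                for b in range(3):
                    rows.append({"y": data[i, a, b], "A": a, "B": b})
        frame = pd.DataFrame(rows)
        fit = ols("y ~ C(A) * C(B)", frame).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        table = factorial_anova(data, ("A", "B")).set_index("term")
        assert table.loc["A", "F"] == pytest.approx(ref.loc["C(A)", "F"])
        assert table.loc["B", "F"] == pytest.approx(ref.loc["C(B)", "F"])
        assert table.loc["A:B", "F"] == pytest.approx(ref.loc["C(A):C(B)", "F"])

    def test_sums_of_squares_partition_exactly(self, rng):
        """SS_total = sum of effect SS + SS_error on a 3-way design."""
        from neurocue.stats import _anova_decompose
        data = rng.normal(size=(9, 2, 2, 2))
        terms, SS, df, SS_err, df_err = _anova_decompose(data, 3)
        total = ((data - data.mean()) ** 2).sum()
        assert sum(SS) + SS_err == pytest.approx(total, rel=1e-12)
        assert sum(df) + df_err == data.size - 1

    def test_null_type_I_error_calibrated(self, rng):
        """Per-timepoint uncorrected type-I rate ~ alpha over replicates."""
        n_rej, n_tot = 0, 0
        for rep in range(200):
            data = rng.normal(size=(10, 2, 2, 5))
            res = factorial_anova_timecourse(data, np.arange(5.0), ("v", "r"))
            n_rej += int((res.p["v:r"] < 0.05).sum())
            n_tot += 5
        lo, hi = sps.binom.interval(0.999, n_tot, 0.05)
        assert lo <= n_rej <= hi

    def test_planted_effect_recovered_in_window(self):
        """A sustained seen>unseen effect is flagged over >=80% of its
        planted window at default SNR."""
        ds = synth.generate_contacts(
            n_per_cluster={"sustained": 20}, n_trials=160, noise_sd=1.0, seed=0)
        vr = ds.validity_report_means()
        res = factorial_anova_timecourse(vr, ds.times_ms,
                                         ("validity", "report"))
        mask = res.significant["report"]
        window = ((ds.times_ms >= 170) & (ds.times_ms <= 200)) | \
                 ((ds.times_ms >= 250) & (ds.times_ms <= 300))
        assert mask[window].mean() >= 0.8

    def test_degenerate_design_rejected(self, rng):
        with pytest.raises(DegenerateDesignError):
            factorial_anova(rng.normal(size=(5, 1, 2)), ("a", "b"))
        bad = rng.normal(size=(5, 2, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(DegenerateDesignError):
            factorial_anova(bad, ("a", "b"))


class TestHolm:
    def test_hand_stepdown_example(self):
        """p = {0.001, 0.02, 0.03} at alpha 0.05, m=3: all rejected."""
        reject, _ = holm_bonferroni([0.001, 0.02, 0.03], alpha=0.05)
        assert reject.all()
        # but 0.03 alone against m=3 Bonferroni (0.0167) would fail:
        reject2, _ = holm_bonferroni([0.03, 0.04, 0.045], alpha=0.05)
        assert not reject2.any()

    def test_all_ones_no_rejections_and_m1_reduces_to_alpha(self):
        reject, _ = holm_bonferroni([1.0, 1.0, 1.0])
        assert not reject.any()
        assert holm_bonferroni([0.049])[0].all()
        assert not holm_bonferroni([0.051])[0].any()

    def test_empty_input(self):
        reject, p = holm_bonferroni([])
        assert reject.size == 0 and p.size == 0

    def test_holm_mask_subset_of_uncorrected(self, rng):
        p = rng.uniform(0, 0.2, 40)
        reject, _ = holm_bonferroni(p)
        assert np.all(~reject | (p < 0.05))

    def test_sidak_at_least_as_powerful_as_holm(self, rng):
        p = rng.uniform(0, 0.1, 20)
        rj_h, _ = holm_bonferroni(p)
        rj_s, _ = holm_sidak(p)
        assert np.all(rj_h <= rj_s)

    def test_matches_statsmodels_reference(self, rng):
        """Both step-down procedures agree with the statsmodels route on
        random p-vectors (independent implementation cross-check)."""
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            for ours, method in ((holm_bonferroni, "holm"),
                                 (holm_sidak, "holm-sidak")):
                rej, pc = ours(p)
                ref_rej, ref_pc, _, _ = multipletests(p, 0.05, method=method)
                assert np.array_equal(rej, ref_rej)
                assert np.allclose(pc, ref_pc)


class TestEffectGradient:
    def _clusters(self, amplitudes, seed, n=15):
        out = {}
        for i, amp in enumerate(amplitudes):
            bank = synth.make_profile_templates(interaction_amplitude=amp)
            ds = synth.generate_contacts(bank, {"sustained": n}, n_trials=128,
                                         noise_sd=1.0, seed=seed + i)
            out[f"c{i}"] = ds.validity_report_means()
        return out, ds.times_ms

    def test_null_gradient_t_small(self):
        clusters, times = self._clusters((0.5, 0.5, 0.5), seed=10)
        windows = {name: (270.0, 330.0) for name in clusters}
        grad = interaction_effectsize_gradient(clusters, windows, times)
        assert abs(grad.linear_t) < 3.0

    def test_planted_gradient_detected(self):
        """Interaction amplitudes 0.2/0.5/0.8 z give a positive significant
        linear contrast."""
        hits = 0
        for rep in range(5):
            clusters, times = self._clusters((0.2, 0.5, 0.8), seed=100 + 10 * rep)
            windows = {name: (270.0, 330.0) for name in clusters}
            grad = interaction_effectsize_gradient(clusters, windows, times)
            if grad.linear_t > 0 and grad.linear_p < 0.05:
                hits += 1
        assert hits >= 4

    def test_equal_n_linear_contrast_hand_computed(self):
        """With 3 equal-n clusters the contrast t equals the hand formula on
        toy means."""
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1.0, size=(3, 20, 1, 1, 4))
        shift = np.array([0.0, 0.5, 1.0])
        clusters, d = {}, []
        for i in range(3):
            data = np.zeros((20, 2, 2, 4))
            data[:, 1, 1] = base[i, :, 0, 0] + shift[i]   # seen-valid cell
            data += rng.normal(0, 0.01, size=data.shape)
            clusters[f"c{i}"] = data
        windows = {f"c{i}": (0.0, 3.0) for i in range(3)}
        grad = interaction_effectsize_gradient(clusters, windows,
                                               np.arange(4.0))
        groups = [grad.per_contact_window_contrast[f"c{i}"] for i in range(3)]
        means = np.array([g.mean() for g in groups])
        mse = np.mean([g.var(ddof=1) for g in groups])
        w = np.array([-1.0, 0.0, 1.0])
        t_hand = (w @ means) / np.sqrt(mse * (w ** 2 / 20).sum())
        assert grad.linear_t == pytest.approx(t_hand, rel=1e-10)

    def test_needs_three_clusters(self):
        with pytest.raises(ValueError):
            interaction_effectsize_gradient({"a": np.zeros((5, 2, 2, 3)),
                                             "b": np.zeros((5, 2, 2, 3))},
                                            {}, np.arange(3.0))


class TestRTBins:
    def test_forty_trials_give_twenty_bins_of_two(self):
        rts = np.linspace(300, 900, 40)
        bins = rt_quantile_bins(rts, 20)
        counts = np.bincount(bins, minlength=20)
        assert np.all(counts == 2)

    def test_tie_handling_stable(self):
        rts = np.full(40, 500.0)
        bins = rt_quantile_bins(rts, 20)
        # stable sort by trial index: first two trials in bin 0, etc.
        assert np.array_equal(bins, np.repeat(np.arange(20), 2))

    def test_rt_independent_activity_rarely_significant(self):
        """Null calibration: no Holm-significant bins in >= 95% of reps."""
        n_sig = 0
        for rep in range(60):
            act, rts, times = synth.rt_coupled_activity(
                n_trials=120, coupling=0.0, seed=rep)
            res = rt_bin_analysis(act, rts, times)
            if res.fastslow_significant.any() or res.anova_significant.any():
                n_sig += 1
        assert n_sig / 60 <= 0.05 + 0.05   # binomial slack at n=60

    def test_planted_rt_coupling_detected_late(self):
        """Activity duration proportional to RT: slow > fast in the late
        window after correction."""
        act, rts, times = synth.rt_coupled_activity(
            n_trials=400, coupling=1.5, noise_sd=1.0, seed=5)
        res = rt_bin_analysis(act, rts, times)
        late = res.times_ms >= 500
        assert (res.fastslow_significant & late
                & (res.fastslow_t > 0)).any()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            rt_quantile_bins(np.arange(10.0), 20)
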