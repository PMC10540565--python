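"""Stability-MPRA statistics: spike normalization, decay ratios and tests,
curve fitting, half-life identity, and the A/B/C filter logic."""

import numpy as np
import pandas as pd
import pytest

from utrmpra.stability import (LN2, StabilityThresholds, call_stability,
                               decay_ratios, decay_test, fit_all_decays,
                               fit_decay, first_timepoint_sums, spike_normalize)
from utrmpra.synthetic import gen_stability_counts


@pytest.fixture()
def small_matrix():
    counts, samples = gen_stability_counts(
        ["a", "b"], [0.1, 0.4], n_reps=3, depth=200, seed=1)
    return counts, samples


class TestSpikeNormalize:
    def test_scale_invariance(self, small_matrix):
        counts, samples = small_matrix
        norm = spike_normalize(counts, samples)
        scaled = counts.copy()
        scaled_samples = samples.copy()
        sid = samples["sample_id"].iloc[0]
        scaled[sid] = scaled[sid] * 7
        scaled_samples.loc[scaled_samples["sample_id"] == sid, "spike_count"] *= 7
        norm2 = spike_normalize(scaled, scaled_samples)
        pd.testing.assert_frame_equal(norm, norm2)

    def test_unit_spikes_identity(self, small_matrix):
        counts, samples = small_matrix
        s = samples.copy()
        s["spike_count"] = 1.0
        pd.testing.assert_frame_equal(spike_normalize(counts, s),
                                      counts.astype(float))

    def test_elementwise_recount(self, small_matrix):
        counts, samples = small_matrix
        norm = spike_normalize(counts, samples)
        spikes = samples.set_index("sample_id")["spike_count"]
        for c in counts.columns:
            for i in counts.index:
                assert norm.loc[i, c] == counts.loc[i, c] / spikes[c]

    def test_zero_spike_excluded(self, small_matrix):
        counts, samples = small_matrix
        s = samples.copy()
        sid = s["sample_id"].iloc[0]
        s.loc[s["sample_id"] == sid, "spike_count"] = 0
        with pytest.warns(UserWarning, match="spike"):
            norm = spike_normalize(counts, s)
        assert sid not in norm.columns


class TestDecayRatios:
    def test_flat_counts_ratio_one(self):
        counts, samples = gen_stability_counts(["x"], [1e-9], noise="none", seed=2)
        norm = spike_normalize(counts, samples)
        r = decay_ratios(norm, samples, 6.0)
        assert np.allclose(r.loc["x"], 1.0, atol=1e-6)

    def test_noiseless_closed_form(self):
        counts, samples = gen_stability_counts(["x"], [0.2], noise="none", seed=3)
        norm = spike_normalize(counts, samples)
        r6 = decay_ratios(norm, samples, 6.0)
        assert np.allclose(r6.loc["x"], np.exp(-1.0), rtol=1e-12)
        r3 = decay_ratios(norm, samples, 3.0)
        assert np.allclose(r3.loc["x"], np.exp(-0.4), rtol=1e-12)

    def test_matches_bruteforce(self, small_matrix):
        counts, samples = small_matrix
        norm = spike_normalize(counts, samples)
        r = decay_ratios(norm, samples, 3.0)
        for rep in (1, 2, 3):
            num = norm[f"t3h_r{rep}"]
            den = norm[f"t1h_r{rep}"]
            expected = num / den
            assert np.allclose(r[rep].to_numpy(), expected.to_numpy())


class TestDecayTest:
    def test_identical_vectors(self):
        p, lfc = decay_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert p == 1.0 and lfc == 0.0

    def test_exact_halving(self):
        p, lfc = decay_test([0.5, 0.5, 0.5], [0.25, 0.25, 0.25])
        assert lfc == pytest.approx(-1.0)
        assert p == 0.0  # degenerate zero-variance, unequal means

    def test_matches_welch_closed_form(self):
        rng = np.random.default_rng(4)
        wt, mut = rng.uniform(0.2, 0.8, 6), rng.uniform(0.2, 0.8, 6)
        p, lfc = decay_test(wt, mut)
        se = np.sqrt(wt.var(ddof=1) / 6 + mut.var(ddof=1) / 6)
        t = (mut.mean() - wt.mean()) / se
        df = se ** 4 / ((wt.var(ddof=1) / 6) ** 2 / 5 + (mut.var(ddof=1) / 6) ** 2 / 5)
        from scipy import stats
        p_hand = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(p_hand, rel=1e-10)
        assert lfc == pytest.approx(np.log2(mut.mean() / wt.mean()), rel=1e-12)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            decay_test([0.5], [0.4, 0.3])


class TestFitDecay:
    def test_half_life_identity(self):
        t = np.array([1, 3, 6, 12, 24], dtype=float)
        y = 0.5 * np.exp(-LN2 * t)
        fit = fit_decay(t, y)
        assert fit.converged
        assert fit.alpha == pytest.approx(LN2, rel=1e-8)
        assert fit.half_life == LN2 / fit.alpha  # exact identity by construction
        assert fit.half_life == pytest.approx(1.0, rel=1e-8)

    def test_noiseless_recovery(self):
        t = np.tile([1.0, 3, 6, 12, 24], 6)
        y = 0.0 + (0.5 - 0.0) * np.exp(-0.2 * t)
        fit = fit_decay(t, y)
        assert abs(fit.alpha - 0.2) < 1e-6

    def test_all_zero_curve_not_exception(self):
        fit = fit_decay([1, 3, 6, 12, 24], [0, 0, 0, 0, 0])
        assert not fit.converged and np.isnan(fit.half_life)

    def test_poisson_noise_recovery_within_10pct(self):
        rng = np.random.default_rng(5)
        alphas = np.exp(rng.uniform(np.log(0.05), np.log(0.5), 60))
        ids = [f"i{k}" for k in range(60)]
        counts, samples = gen_stability_counts(ids, alphas, depth=400, seed=6)
        norm = spike_normalize(counts, samples)
        fits = fit_all_decays(norm, samples)
        rel = np.abs(fits["alpha"].to_numpy() / alphas - 1)
        assert np.median(rel) < 0.10

    def test_fitted_half_life_decreasing_in_alpha(self):
        grid = [0.05, 0.1, 0.2, 0.3, 0.5]
        counts, samples = gen_stability_counts(
            [f"g{k}" for k in range(5)], grid, noise="none", seed=7)
        norm = spike_normalize(counts, samples)
        fits = fit_all_decays(norm, samples)
        hl = fits["half_life"].to_numpy()
        assert (np.diff(hl) < 0).all()


class TestCallStability:
    def _make(self, alphas, depth=400, seed=8, n_pairs=None):
        n_pairs = n_pairs or len(alphas) // 2
        ids = []
        pairs = []
        for k in range(n_pairs):
            ids += [f"p{k}_WT", f"p{k}_MUT"]
            pairs.append({"pair_id": f"p{k}", "mutation_key": f"m{k}",
                          "wt_id": f"p{k}_WT", "mut_id": f"p{k}_MUT"})
        counts, samples = gen_stability_counts(ids, alphas, depth=depth, seed=seed)
        return counts, samples, pd.DataFrame(pairs)

    def test_filter_a_boundary(self):
        counts, samples, pairs = self._make([0.2, 0.2])
        sums = first_timepoint_sums(counts, samples)
        # force exact boundary sums by rescaling raw counts
        first_cols = samples.loc[samples["fraction_or_timepoint"] == 1.0,
                                 "sample_id"]
        calls, _ = call_stability(counts, samples, pairs)
        th = StabilityThresholds(min_first_timepoint_sum=float(sums.min()))
        calls_eq, _ = call_stability(counts, samples, pairs, th)
        assert calls_eq["passes_A"].all()  # >= is inclusive at the boundary
        th2 = StabilityThresholds(min_first_timepoint_sum=float(sums.min()) + 0.5)
        calls_gt, _ = call_stability(counts, samples, pairs, th2)
        assert not calls_gt["passes_A"].all()

    def test_filter_c_strict_inequality(self):
        counts, samples, pairs = self._make([0.2, 0.2 * 2 ** 0.6], seed=9)
        calls, _ = call_stability(counts, samples, pairs)
        hl_lfc = calls["log2fc_half_life"].iloc[0]
        th = StabilityThresholds(half_life_lfc_threshold=abs(hl_lfc))
        calls_eq, _ = call_stability(counts, samples, pairs, th)
        assert not calls_eq["passes_C"].iloc[0]  # |lfc| == threshold fails

    def test_filter_logic_truth_table(self):
        """significant == A & B & C, with B and C recomputable from the outputs."""
        rng = np.random.default_rng(10)
        alphas = np.exp(rng.uniform(np.log(0.05), np.log(0.5), 40))
        counts, samples, pairs = self._make(alphas, seed=11)
        th = StabilityThresholds()
        calls, fits = call_stability(counts, samples, pairs, th)
        for rec in calls.itertuples(index=False):
            b = ((rec.p_3h < th.p_threshold and abs(rec.log2fc_decay_3h) > th.lfc_threshold)
                 or (rec.p_6h < th.p_threshold and abs(rec.log2fc_decay_6h) > th.lfc_threshold))
            c = (np.isfinite(rec.log2fc_half_life)
                 and abs(rec.log2fc_half_life) > th.half_life_lfc_threshold)
            assert rec.passes_B == b
            assert rec.passes_C == c
            assert rec.significant == (rec.passes_A and b and c)

    def test_sample_scale_invariance_downstream(self):
        counts, samples, pairs = self._make([0.1, 0.3], seed=12)
        calls1, fits1 = call_stability(counts, samples, pairs)
        sid = samples["sample_id"].iloc[3]
        counts2, samples2 = counts.copy(), samples.copy()
        counts2[sid] *= 5
        samples2.loc[samples2["sample_id"] == sid, "spike_count"] *= 5
        calls2, fits2 = call_stability(counts2, samples2, pairs)
        for col in ("log2fc_decay_3h", "log2fc_decay_6h", "log2fc_half_life"):
            assert calls1[col].iloc[0] == pytest.approx(calls2[col].iloc[0],
                                                        rel=1e-9)
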