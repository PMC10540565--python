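"""Generators: determinism, composition targets, ground-truth conservation,
and the closed-form behavior of the noiseless decay model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utrmpra import stability, synthetic
from utrmpra.motifs import classify_context, enumerate_context_classes
from utrmpra.synthetic import (GenerationError, gen_caller_tables, gen_mutations,
                               gen_polysome_counts, gen_stability_counts,
                               gen_utrome, plant_motifs)


class TestUtrome:
    def test_empty(self):
        assert gen_utrome(0) == []

    def test_gc_target(self):
        utrs = gen_utrome(100, (300, 600), gc=0.4, seed=1)
        seq = "".join(u.sequence for u in utrs)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.4) < 0.02

    def test_deterministic(self):
        a = gen_utrome(10, (200, 400), seed=7)
        b = gen_utrome(10, (200, 400), seed=7)
        assert a == b

    def test_coordinates_consistent(self, small_utrome):
        for u in small_utrome:
            assert u.end - u.start == len(u.sequence)
        assert len({u.chrom for u in small_utrome}) == len(small_utrome)

    @pytest.mark.parametrize("bad", [{"gc": 0.0}, {"gc": 1.2},
                                     {"length_range": (100, 50)}])
    def test_invalid_config(self, bad):
        with pytest.raises(GenerationError):
            gen_utrome(5, **bad)


class TestMutations:
    def test_empty(self, small_utrome):
        muts, truth = gen_mutations(small_utrome, 0, seed=1)
        assert len(muts) == 0 and truth.planted_mutations == []

    def test_refs_match_sequence(self, mutation_set, small_utrome):
        muts, _ = mutation_set
        by_id = {u.utr_id: u for u in small_utrome}
        for rec in muts.itertuples(index=False):
            assert by_id[rec.utr_id].sequence[rec.offset] == rec.ref
            assert rec.pos == by_id[rec.utr_id].start + rec.offset + 1

    def test_ground_truth_matches_table(self, mutation_set):
        muts, truth = mutation_set
        emitted = list(zip(muts["utr_id"], muts["offset"], muts["ref"], muts["alt"]))
        assert emitted == truth.planted_mutations

    def test_class_frequencies_multinomial(self):
        """Counts under explicit uniform full-trinucleotide frequencies pass a GOF test."""
        utrome = gen_utrome(20, (700, 900), seed=3)
        full = [c for c in enumerate_context_classes() if "." not in c.context]
        freqs = {c.key: 1.0 / len(full) for c in full}
        muts, _ = gen_mutations(utrome, 10000, context_freqs=freqs, seed=3)
        by_id = {u.utr_id: u for u in utrome}
        keys = [classify_context(by_id[r.utr_id], r.offset, r.ref, r.alt).key
                for r in muts.itertuples(index=False)]
        counts = pd.Series(keys).value_counts().reindex(
            [c.key for c in full], fill_value=0)
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_planted_motif_hits_exact(self, small_utrome):
        planted, sites = plant_motifs(small_utrome,
                                      [("PAS", "AATAAA", 8)], seed=4)
        muts, truth = gen_mutations(planted, 30, planted_motif_hits=5,
                                    motif_sites=sites, seed=5)
        assert muts["in_motif_site"].sum() == 5
        assert len(truth.motif_overlap_keys) == 5
        span = {(r.utr_id, off) for r in sites.itertuples(index=False)
                for off in range(r.start, r.end)}
        for rec in muts.itertuples(index=False):
            assert ((rec.utr_id, rec.offset) in span) == rec.in_motif_site

    def test_planted_hits_exceed_sites(self, small_utrome):
        planted, sites = plant_motifs(small_utrome, [("PAS", "AATAAA", 1)], seed=4)
        with pytest.raises(GenerationError):
            gen_mutations(planted, 30, planted_motif_hits=20,
                          motif_sites=sites, seed=5)


class TestCallerTables:
    def test_perfect_sensitivity(self, small_utrome, mutation_set):
        muts, _ = mutation_set
        tables, presence = gen_caller_tables(muts, [1.0] * 4, seed=6)
        for df in tables.values():
            assert set(zip(df.chrom, df.pos, df.ref, df.alt)) == \
                set(zip(muts.chrom, muts.pos, muts.ref, muts.alt))
        assert presence.to_numpy().all()

    def test_zero_sensitivity_only_fps(self, small_utrome, mutation_set):
        muts, _ = mutation_set
        tables, presence = gen_caller_tables(muts, [0.0] * 4, fp_per_caller=7,
                                             utrome=small_utrome, seed=6)
        true_keys = set(zip(muts.chrom, muts.pos, muts.ref, muts.alt))
        for df in tables.values():
            assert len(df) == 7
            assert not (set(zip(df.chrom, df.pos, df.ref, df.alt)) & true_keys)
        assert not presence.to_numpy().any()

    def test_two_caller_counts_match_presence(self, small_utrome):
        muts, _ = gen_mutations(small_utrome, 120, seed=8)
        tables, presence = gen_caller_tables(muts, (0.9, 0.9, 0.9, 0.9), seed=5)
        # brute-force recount over the emitted tables
        support = {}
        for caller, df in tables.items():
            for key in zip(df.chrom, df.pos, df.ref, df.alt):
                support.setdefault(key, set()).add(caller)
        n_ge2 = sum(1 for s in support.values() if len(s) >= 2)
        assert n_ge2 == int((presence.sum(axis=1) >= 2).sum())


class TestStabilityCounts:
    def test_noiseless_closed_form_ratio(self):
        counts, samples = gen_stability_counts(["x"], [0.2], noise="none", seed=1)
        norm = stability.spike_normalize(counts, samples)
        r = norm["t6h_r1"]["x"] / norm["t1h_r1"]["x"]
        assert r == pytest.approx(np.exp(-0.2 * 5), rel=1e-12)

    def test_near_zero_alpha_flat(self):
        counts, samples = gen_stability_counts(["x"], [1e-9], noise="none", seed=1)
        norm = stability.spike_normalize(counts, samples)
        assert norm.loc["x"].max() / norm.loc["x"].min() == pytest.approx(1.0, abs=1e-6)

    def test_depth_anchors_first_timepoint(self):
        """Spike-normalized 1h abundance (x spike scale) averages to the depth.

        Raw 1h counts also center on the depth but carry the per-sample
        efficiency factor the spike-in exists to remove, so the normalized
        scale is the stable one.
        """
        counts, samples = gen_stability_counts(
            [f"i{k}" for k in range(500)], np.full(500, 0.2), depth=400,
            spike_scale=5000.0, seed=11)
        norm = stability.spike_normalize(counts, samples)
        first_cols = samples.loc[samples["fraction_or_timepoint"] == 1.0,
                                 "sample_id"]
        mean_1h = (norm[list(first_cols)] * 5000.0).mean(axis=1).mean()
        assert abs(mean_1h / 400 - 1) < 0.05

    def test_noiseless_regression_r2(self):
        rng = np.random.default_rng(2)
        alphas = rng.uniform(0.05, 0.5, 20)
        counts, samples = gen_stability_counts(
            [f"i{k}" for k in range(20)], alphas, noise="none", seed=2)
        norm = stability.spike_normalize(counts, samples)
        t = pd.to_numeric(samples.set_index("sample_id")["fraction_or_timepoint"])
        for k, alpha in enumerate(alphas):
            y = np.log(norm.iloc[k].to_numpy(dtype=float))
            x = t[norm.columns].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            assert r ** 2 > 0.99

    def test_deterministic(self):
        a = gen_stability_counts(["x", "y"], [0.1, 0.3], seed=9)
        b = gen_stability_counts(["x", "y"], [0.1, 0.3], seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    @pytest.mark.parametrize("kwargs", [{"depth": 0}, {"depth": -5}])
    def test_bad_depth(self, kwargs):
        with pytest.raises(GenerationError):
            gen_stability_counts(["x"], [0.1], **kwargs)

    def test_alpha_must_be_positive(self):
        with pytest.raises(GenerationError):
            gen_stability_counts(["x"], [0.0])


class TestPolysomeCounts:
    def test_planted_multiplier_realized(self):
        ids = ["a_WT", "a_MUT"]
        counts, samples = gen_polysome_counts(ids, {"a_MUT": 16.0}, noise="none",
                                              seed=3)
        def te(insert):
            tot = counts.loc[insert, [c for c in counts if c.startswith("total")]].mean()
            poly = counts.loc[insert, [c for c in counts
                                       if c.startswith(("low_poly", "high_poly"))]].sum() / 6
            return poly / tot
        assert te("a_MUT") / te("a_WT") == pytest.approx(16.0, rel=1e-9)

    def test_bad_depth(self):
        with pytest.raises(GenerationError):
            gen_polysome_counts(["x"], depth=0)

    def test_deterministic(self):
        a = gen_polysome_counts(["x"], seed=4)
        b = gen_polysome_counts(["x"], seed=4)
        pd.testing.assert_frame_equal(a[0], b[0])
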