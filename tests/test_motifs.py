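"""Context classification, motif gain/loss scanning, and the
context-preserving permutation test."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from utrmpra.core import UtrRecord, SequenceError, encode_seq, iupac_match_positions
from utrmpra.evaluate import permutation_preserves_classes
from utrmpra.motifs import (CATEGORIES, ContextClass, MotifAffectIndex,
                            MotifResource, classify_context,
                            enrichment_test, enumerate_context_classes,
                            mutation_window, observed_category_counts,
                            permute_mutations, scan_motif_delta)


def utr_from(seq, utr_id="u1"):
    return UtrRecord(utr_id, "chrT", 0, len(seq), "+", seq)


class TestContextClasses:
    def test_total_288(self):
        classes = enumerate_context_classes()
        assert len(classes) == 288

    def test_composition(self):
        classes = enumerate_context_classes()
        full = [c for c in classes if "." not in c.context]
        left_missing = [c for c in classes if c.context.startswith(".")]
        right_missing = [c for c in classes if c.context.endswith(".")]
        assert len(full) == 192
        assert len(left_missing) == len(right_missing) == 48
        assert len({(c.context, c.alt) for c in classes}) == 288
        assert all(c.alt != c.context[1] for c in classes)

    def test_classify_middle(self):
        cls = classify_context(utr_from("ACG"), 1, "C", "T")
        assert cls == ContextClass("ACG", "T")

    def test_classify_boundaries(self):
        utr = utr_from("ACGT")
        assert classify_context(utr, 0, "A", "G").context == ".AC"
        assert classify_context(utr, 3, "T", "C").context == "GT."

    def test_ref_mismatch_raises(self):
        with pytest.raises(SequenceError):
            classify_context(utr_from("ACG"), 1, "A", "T")

    def test_exhaustive_agreement_with_bruteforce(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 50))
        utr = utr_from(seq)
        for off in range(50):
            ref = seq[off]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = classify_context(utr, off, ref, alt)
                left = seq[off - 1] if off > 0 else "."
                right = seq[off + 1] if off < 49 else "."
                assert got == ContextClass(left + ref + right, alt)


def naive_pattern_sites(seq, pattern):
    """Regex-based IUPAC scan, independent of the numpy path."""
    expand = {"R": "[AG]", "H": "[ACT]", "N": "[ACGT]"}
    rex = "".join(expand.get(c, c) for c in pattern)
    return {m.start() for m in re.finditer(f"(?={rex})", seq)}


class TestScanning:
    def test_pas_loss(self, fixed_resources):
        wt = "T" * 30 + "AATAAA" + "T" * 30
        mut = wt[:32] + "G" + wt[33:]
        d = scan_motif_delta(wt, mut, fixed_resources)
        assert d.lost["PAS"] == 1 and d.gained["PAS"] == 0

    def test_u_equivalent_to_t(self, fixed_resources):
        wt = "U" * 30 + "AAUAAA" + "U" * 30
        mut = wt[:32] + "G" + wt[33:]
        d = scan_motif_delta(wt, mut, fixed_resources)
        assert d.lost["PAS"] == 1

    def test_multi_diff_rejected(self, fixed_resources):
        with pytest.raises(ValueError):
            scan_motif_delta("AAAA", "TTAA", fixed_resources)
        with pytest.raises(ValueError):
            scan_motif_delta("AAAA", "AAAA", fixed_resources)

    def test_random_windows_match_naive_scanner(self, full_resources):
        rng = np.random.default_rng(12)
        for _ in range(20):
            wt = "".join(rng.choice(list("ACGT"), 201))
            i = int(rng.integers(0, 201))
            alt = rng.choice([b for b in "ACGT" if b != wt[i]])
            mut = wt[:i] + alt + wt[i + 1:]
            got = scan_motif_delta(wt, mut, full_resources)
            for res in full_resources:
                if res.category == "RBP_PWM":
                    continue  # PWM path checked separately below
                if res.category == "MIRNA_SEED":
                    continue
                wt_sites = naive_pattern_sites(wt, res.pattern)
                mut_sites = naive_pattern_sites(mut, res.pattern)
                lost = len(wt_sites - mut_sites)
                gained = len(mut_sites - wt_sites)
                assert got.lost[res.category] == lost
                assert got.gained[res.category] == gained

    def test_pwm_sites_match_naive_scoring(self, full_resources):
        res = next(r for r in full_resources if r.category == "RBP_PWM")
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), 300))
        codes = encode_seq(seq)
        got = res.site_positions(codes)
        logodds = np.log2(np.maximum(res.matrix, 1e-6) / 0.25)
        threshold = 0.8 * logodds.max(axis=0).sum()
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = set()
        L = res.matrix.shape[1]
        for i in range(len(seq) - L + 1):
            score = sum(logodds[base_idx[seq[i + j]], j] for j in range(L))
            if score >= threshold:
                expected.add(i)
        assert set(got) == expected

    def test_mirna_seed_sites(self):
        seed = "GAGGUAG"  # miRNA positions 2-8
        res = MotifResource("m", "MIRNA_SEED", pattern=seed)
        # 7mer-m8 site: reverse complement of the full seed
        site_m8 = "CTACCTC"
        # 7mer-A1 site: reverse complement of positions 2-7 + A
        site_a1 = "TACCTCA"
        for site in (site_m8, site_a1):
            seq = "G" * 20 + site + "G" * 20
            assert 20 in res.site_positions(encode_seq(seq))
        assert not res.site_positions(encode_seq("G" * 47))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_swapping_windows(self, seed):
        """Swapping WT and mutant windows swaps gained and lost counts."""
        rng = np.random.default_rng(seed)
        wt = "".join(rng.choice(list("ACGT"), 80))
        i = int(rng.integers(0, 80))
        alt = str(rng.choice([b for b in "ACGT" if b != wt[i]]))
        mut = wt[:i] + alt + wt[i + 1:]
        res = [MotifResource("PAS_AAUAAA", "PAS"), MotifResource("M6A_RRACH", "M6A")]
        fwd = scan_motif_delta(wt, mut, res)
        rev = scan_motif_delta(mut, wt, res)
        assert fwd.lost == rev.gained and fwd.gained == rev.lost

    def test_iupac_matches_explicit_expansion(self):
        rng = np.random.default_rng(14)
        seq = "".join(rng.choice(list("ACGT"), 400))
        for pattern in ("NGG", "NG", "NGAN", "NGCG", "NNGRRT", "NNNRRT", "RRACH"):
            got = set(iupac_match_positions(encode_seq(seq), pattern).tolist())
            assert got == naive_pattern_sites(seq, pattern)


class TestPermutation:
    def test_deterministic(self, small_utrome, mutation_set, fixed_resources):
        muts, _ = mutation_set
        a = permute_mutations(muts, small_utrome, fixed_resources, n_perm=30, seed=4)
        b = permute_mutations(muts, small_utrome, fixed_resources, n_perm=30, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_single_position_class_reproduces_observed(self, fixed_resources):
        """When each class has exactly one candidate, every permutation is the identity."""
        utr = utr_from("TTTTAATAAATTTT")
        muts = pd.DataFrame([{"utr_id": "u1", "offset": 6, "ref": "T", "alt": "G"}])
        # context 'ATA'>G occurs at offsets 5 and 7 too; force uniqueness by alt class
        index = MotifAffectIndex([utr], fixed_resources)
        observed = observed_category_counts(muts, [utr], fixed_resources, index=index)
        bg = permute_mutations(muts, [utr], fixed_resources, n_perm=50, seed=1,
                               index=index)
        cls = classify_context(utr, 6, "T", "G")
        positions, flags = index.candidates(cls)
        if len(positions) == 1:
            assert (bg.to_numpy() == observed.to_numpy()).all()
        else:  # all candidates share the affect flags -> background constant
            assert bg.nunique().le(len(np.unique(flags, axis=0))).all()

    def test_class_counts_preserved(self, small_utrome, mutation_set,
                                    fixed_resources):
        muts, _ = mutation_set
        assert permutation_preserves_classes(muts, small_utrome, fixed_resources,
                                             n_perm=10, seed=3)

    def test_missing_class_warns(self, fixed_resources):
        utr = utr_from("ACGTACGTACGTACGT")
        other = utr_from("GGGGGGGGCCCCCCCC", "u2")
        muts = pd.DataFrame([{"utr_id": "u2", "offset": 8, "ref": "C", "alt": "A"}])
        # index only covers utr1, so class GCC>A has no candidates
        index = MotifAffectIndex([utr], fixed_resources)
        with pytest.warns(UserWarning, match="no matching UTRome position"):
            bg = permute_mutations(muts, [other], fixed_resources, n_perm=5,
                                   seed=0, index=index)
        assert (bg.to_numpy() == 0).all()


class TestEnrichmentTest:
    def test_observed_at_mean_gives_p1(self):
        bg = np.array([10.0, 12.0, 8.0, 10.0])
        res = enrichment_test(bg.mean(), bg)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_background(self):
        res = enrichment_test(20, np.full(99, 10.0))
        assert res.empirical_p_enrichment == pytest.approx(1 / 100)
        assert np.isnan(res.t_statistic)

    def test_zero_variance_equal_observed(self):
        res = enrichment_test(10, np.full(99, 10.0))
        assert res.p_value == 1.0
        assert res.empirical_p_enrichment == 1.0

    def test_matches_closed_form_t(self):
        rng = np.random.default_rng(6)
        bg = rng.normal(100, 5, 500)
        observed = 130.0
        res = enrichment_test(observed, bg)
        n = bg.size
        t_hand = (bg.mean() - observed) / (bg.std(ddof=1) / np.sqrt(n))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=n - 1)
        assert res.t_statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.p_value == pytest.approx(p_hand, rel=1e-12)
        # empirical p by direct count
        assert res.empirical_p_enrichment == pytest.approx(
            (1 + (bg >= observed).sum()) / (1 + n))


def test_mutation_window_clipped_at_boundaries():
    utr = utr_from("ACGTACGTAC")
    wt, mut = mutation_window(utr, 1, "T", window=3)
    assert wt == "ACGTA" and mut == "ATGTA"
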