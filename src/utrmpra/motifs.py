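"""Mutation context classification, motif gain/loss scanning, and the
context-preserving permutation enrichment test.

The substitution scheme stratifies single-nucleotide changes by their
trinucleotide context: 64 full trinucleotide contexts, plus 16 dinucleotide
contexts missing the left flank and 16 missing the right flank (mutations at
the first or last base of a UTR), each with 3 possible alternate middle
bases — 288 classes in all. Permutations redraw each observed mutation
uniformly among UTRome positions of the same class, so base change and
context frequencies are preserved exactly, and enrichment of motif-altering
mutations is judged against that background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DNA_BASES,
    SequenceError,
    encode_seq,
    iupac_match_positions,
    normalize_seq,
    revcomp,
)

MISSING_FLANK = "."

#: categories of regulatory elements scanned for gain/loss
CATEGORIES = ("RBP_PWM", "MIRNA_SEED", "PAS", "M6A")

PAS_PATTERN = "AATAAA"   # polyadenylation signal AAUAAA, DNA alphabet
M6A_PATTERN = "RRACH"    # m6A consensus; R=A/G, H=A/C/T

DEFAULT_SCAN_WINDOW = 100  # nt of flank either side of the mutation


class ContextClass(NamedTuple):
    """A (trinucleotide-or-boundary context, alternate middle base) pair."""

    context: str  # e.g. "ACG", ".CG" (no left flank), "AC." (no right flank)
    alt: str

    @property
    def key(self) -> str:
        return f"{self.context}>{self.alt}"


def enumerate_context_classes() -> list:
    """All 288 substitution classes: (64 + 16 + 16 contexts) x 3 alts."""
    classes = []
    contexts = []
    for mid in DNA_BASES:
        for left in DNA_BASES:
            for right in DNA_BASES:
                contexts.append(left + mid + right)
        for right in DNA_BASES:
            contexts.append(MISSING_FLANK + mid + right)
        for left in DNA_BASES:
            contexts.append(left + mid + MISSING_FLANK)
    for ctx in contexts:
        for alt in DNA_BASES:
            if alt != ctx[1]:
                classes.append(ContextClass(ctx, alt))
    return classes


def classify_context(utr, offset: int, ref: str, alt: str) -> ContextClass:
    """Class of a mutation at ``offset`` (0-based) of a UTR's sense sequence.

    UTR-terminal positions fall in boundary classes with the absent flank
    marked ``.``.
    """
    seq = utr.sequence
    if not 0 <= offset < len(seq):
        raise IndexError(f"offset {offset} outside {utr.utr_id} (length {len(seq)})")
    ref = normalize_seq(ref)
    alt = normalize_seq(alt)
    if seq[offset] != ref:
        raise SequenceError(
            f"{utr.utr_id}:{offset}: reference mismatch (sequence has "
            f"{seq[offset]}, mutation says {ref})"
        )
    if ref == alt:
        raise ValueError("ref and alt are identical")
    left = seq[offset - 1] if offset > 0 else MISSING_FLANK
    right = seq[offset + 1] if offset + 1 < len(seq) else MISSING_FLANK
    return ContextClass(left + ref + right, alt)


# ---------------------------------------------------------------------------
# Motif resources and site scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifResource:
    """One scannable regulatory element.

    For PWMs, ``matrix`` is a 4xL probability matrix (rows A,C,G,T) and
    ``score_threshold`` the fraction of the maximum achievable log-odds score
    above which a position counts as a site (default 0.8). For miRNA seeds,
    ``pattern`` is the seed (miRNA positions 2-8, 5'->3'); sites are the
    reverse-complement 7mer-m8 and 7mer-A1 matches. PAS and M6A use fixed
    IUPAC patterns.
    """

    motif_id: str
    category: str
    source_db: str = ""
    pattern: str | None = None
    matrix: np.ndarray | None = None
    score_threshold: float = 0.8

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "RBP_PWM":
            if self.matrix is None:
                raise ValueError(f"{self.motif_id}: PWM category requires a matrix")
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.shape[0] != 4:
                raise ValueError(f"{self.motif_id}: PWM must have 4 rows (A,C,G,T)")
            colsums = self.matrix.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-6):
                raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")
        elif self.category == "MIRNA_SEED":
            if self.pattern is None or not 6 <= len(self.pattern) <= 8:
                raise ValueError(f"{self.motif_id}: seed must be 6-8 nt")
            self.pattern = normalize_seq(self.pattern)
        elif self.category == "PAS":
            self.pattern = PAS_PATTERN
        elif self.category == "M6A":
            self.pattern = M6A_PATTERN

    def site_positions(self, seq_codes: np.ndarray, background: np.ndarray | None = None) -> frozenset:
        """0-based start positions of sites in an encoded sequence."""
        if self.category == "RBP_PWM":
            return frozenset(_pwm_match_positions(
                seq_codes, self.matrix, self.score_threshold, background))
        if self.category == "MIRNA_SEED":
            hits = set()
            seed = self.pattern
            # 7mer-m8: perfect complement of miRNA positions 2-8
            hits.update(iupac_match_positions(seq_codes, revcomp(seed[:7])).tolist())
            # 7mer-A1: complement of positions 2-7 followed by A in the target
            hits.update(iupac_match_positions(seq_codes, revcomp(seed[:6]) + "A").tolist())
            return frozenset(hits)
        return frozenset(iupac_match_positions(seq_codes, self.pattern).tolist())


def _pwm_match_positions(seq_codes, matrix, threshold_frac, background=None):
    L = matrix.shape[1]
    if L > seq_codes.size:
        return np.empty(0, dtype=np.int64)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    logodds = np.log2(np.maximum(matrix, 1e-6) / bg[:, None])  # 4 x L
    threshold = threshold_frac * logodds.max(axis=0).sum()
    windows = np.lib.stride_tricks.sliding_window_view(seq_codes, L)
    scores = logodds.T[np.arange(L)[None, :], windows].sum(axis=1)
    return np.flatnonzero(scores >= threshold)


def default_resources(seeds: pd.DataFrame | None = None,
                      pwms: dict | None = None) -> list:
    """Assemble a resource list from the fixed motifs plus optional PWMs/seeds."""
    res = [
        MotifResource("PAS_AAUAAA", "PAS"),
        MotifResource("M6A_RRACH", "M6A"),
    ]
    if pwms:
        for motif_id, (category, source, matrix) in pwms.items():
            res.append(MotifResource(motif_id, category, source, matrix=matrix))
    if seeds is not None:
        for _, row in seeds.iterrows():
            res.append(MotifResource(row["mirna_id"], "MIRNA_SEED",
                                     pattern=row["seed_sequence"]))
    return res


@dataclass
class MotifDelta:
    """Sites lost/gained by one mutation, per category and per motif."""

    mutation_key: str | None
    lost: dict
    gained: dict
    details: list = field(default_factory=list)  # (motif_id, category, 'lost'|'gained', position)

    def affects(self, category: str) -> bool:
        return self.lost.get(category, 0) + self.gained.get(category, 0) > 0


def scan_motif_delta(wt_window: str, mut_window: str, resources,
                     background: np.ndarray | None = None,
                     mutation_key: str | None = None) -> MotifDelta:
    """Compare motif-site sets between a WT window and its 1-edit mutant.

    Lost = sites present in WT only; gained = present in the mutant only.
    Windows must be equal length and differ at exactly one position.
    """
    wt = normalize_seq(wt_window)
    mut = normalize_seq(mut_window)
    if len(wt) != len(mut):
        raise ValueError("WT and mutant windows differ in length")
    ndiff = sum(a != b for a, b in zip(wt, mut))
    if ndiff != 1:
        raise ValueError(f"windows must differ at exactly one position, found {ndiff}")
    wt_codes = encode_seq(wt)
    mut_codes = encode_seq(mut)
    lost = {c: 0 for c in CATEGORIES}
    gained = {c: 0 for c in CATEGORIES}
    details = []
    for res in resources:
        wt_sites = res.site_positions(wt_codes, background)
        mut_sites = res.site_positions(mut_codes, background)
        for pos in sorted(wt_sites - mut_sites):
            lost[res.category] += 1
            details.append((res.motif_id, res.category, "lost", pos))
        for pos in sorted(mut_sites - wt_sites):
            gained[res.category] += 1
            details.append((res.motif_id, res.category, "gained", pos))
    return MotifDelta(mutation_key, lost, gained, details)


def mutation_window(utr, offset: int, alt: str, window: int = DEFAULT_SCAN_WINDOW):
    """(wt_window, mut_window) of up to ``window`` nt flank either side, clipped at UTR ends."""
    seq = utr.sequence
    a = max(0, offset - window)
    b = min(len(seq), offset + window + 1)
    wt = seq[a:b]
    i = offset - a
    mut = wt[:i] + normalize_seq(alt) + wt[i + 1:]
    return wt, mut


def scan_mutation_table(mutations: pd.DataFrame, utrome, resources,
                        window: int = DEFAULT_SCAN_WINDOW,
                        background: np.ndarray | None = None) -> pd.DataFrame:
    """Per-mutation lost/gained counts per category over the scan window."""
    by_id = {u.utr_id: u for u in utrome}
    rows = []
    for rec in mutations.itertuples(index=False):
        utr = by_id[rec.utr_id]
        wt, mut = mutation_window(utr, int(rec.offset), rec.alt, window)
        key = f"{rec.utr_id}:{rec.offset}:{rec.ref}>{rec.alt}"
        delta = scan_motif_delta(wt, mut, resources, background, mutation_key=key)
        row = {"mutation_key": key, "utr_id": rec.utr_id, "offset": rec.offset,
               "ref": rec.ref, "alt": rec.alt}
        for c in CATEGORIES:
            row[f"lost_{c}"] = delta.lost[c]
            row[f"gained_{c}"] = delta.gained[c]
            row[f"affects_{c}"] = delta.affects(c)
        rows.append(row)
    return pd.DataFrame(rows)


def utrome_background(utrome) -> np.ndarray:
    """Base composition (A,C,G,T) of a UTRome, for PWM log-odds."""
    counts = np.zeros(4)
    for u in utrome:
        codes = encode_seq(u.sequence)
        counts += np.bincount(codes, minlength=4)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Context-preserving permutation
# ---------------------------------------------------------------------------

class MotifAffectIndex:
    """Candidate positions per context class, with cached affect flags.

    For each class the index holds every UTRome position whose context matches,
    and a boolean matrix saying whether placing that class's mutation there
    alters each motif category. Built lazily per class; shared across
    permutations (and across simulated datasets on the same UTRome).
    """

    def __init__(self, utrome, resources, window: int = DEFAULT_SCAN_WINDOW,
                 background: np.ndarray | None = None):
        self.utrome = list(utrome)
        self.resources = list(resources)
        self.window = window
        self.background = background
        self._positions_by_context = {}
        for ui, utr in enumerate(self.utrome):
            seq = utr.sequence
            n = len(seq)
            for off in range(n):
                left = seq[off - 1] if off > 0 else MISSING_FLANK
                right = seq[off + 1] if off + 1 < n else MISSING_FLANK
                ctx = left + seq[off] + right
                self._positions_by_context.setdefault(ctx, []).append((ui, off))
        self._class_cache = {}

    def candidates(self, cls: ContextClass):
        """(positions array of (utr_idx, offset), affect flags [n_cand x n_categories])."""
        key = cls.key
        if key in self._class_cache:
            return self._class_cache[key]
        positions = self._positions_by_context.get(cls.context, [])
        flags = np.zeros((len(positions), len(CATEGORIES)), dtype=bool)
        for i, (ui, off) in enumerate(positions):
            wt, mut = mutation_window(self.utrome[ui], off, cls.alt, self.window)
            delta = scan_motif_delta(wt, mut, self.resources, self.background)
            flags[i] = [delta.affects(c) for c in CATEGORIES]
        entry = (np.array(positions, dtype=np.int64).reshape(len(positions), 2), flags)
        self._class_cache[key] = entry
        return entry

    def affect_flags(self, utr_idx: int, offset: int, cls: ContextClass) -> np.ndarray:
        positions, flags = self.candidates(cls)
        hit = np.flatnonzero((positions[:, 0] == utr_idx) & (positions[:, 1] == offset))
        if hit.size == 0:
            raise KeyError(f"position ({utr_idx}, {offset}) not a candidate for {cls.key}")
        return flags[hit[0]]


def observed_category_counts(mutations: pd.DataFrame, utrome, resources,
                             window: int = DEFAULT_SCAN_WINDOW,
                             background: np.ndarray | None = None,
                             index: MotifAffectIndex | None = None) -> pd.Series:
    """Number of observed mutations affecting (gaining or losing) each category."""
    if index is not None:
        utr_idx = {u.utr_id: i for i, u in enumerate(index.utrome)}
        totals = np.zeros(len(CATEGORIES), dtype=int)
        for rec in mutations.itertuples(index=False):
            ui = utr_idx[rec.utr_id]
            cls = classify_context(index.utrome[ui], int(rec.offset), rec.ref, rec.alt)
            totals += index.affect_flags(ui, int(rec.offset), cls)
        return pd.Series(totals, index=list(CATEGORIES))
    scanned = scan_mutation_table(mutations, utrome, resources, window, background)
    return pd.Series({c: int(scanned[f"affects_{c}"].sum()) for c in CATEGORIES})


def permute_mutations(mutations: pd.DataFrame, utrome, resources,
                      n_perm: int = 10000, seed: int = 0,
                      window: int = DEFAULT_SCAN_WINDOW,
                      background: np.ndarray | None = None,
                      index: MotifAffectIndex | None = None) -> pd.DataFrame:
    """Background counts of category-affecting mutations under the context-preserving null.

    Each permutation redraws every mutation's location uniformly (with
    replacement) among UTRome positions matching its context class — same
    trinucleotide (or boundary) context, same base change — and counts how
    many of the permuted mutations alter each motif category. Per-class
    mutation counts are preserved exactly in every permutation.

    Returns a DataFrame of shape (n_perm, len(CATEGORIES)).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if index is None:
        index = MotifAffectIndex(utrome, resources, window, background)
    by_id = {u.utr_id: u for u in utrome}
    class_counts = {}
    for rec in mutations.itertuples(index=False):
        utr = by_id[rec.utr_id]
        cls = classify_context(utr, int(rec.offset), rec.ref, rec.alt)
        class_counts[cls] = class_counts.get(cls, 0) + 1

    rng = np.random.default_rng(seed)
    totals = np.zeros((n_perm, len(CATEGORIES)), dtype=np.int64)
    for cls, m in sorted(class_counts.items(), key=lambda kv: kv[0].key):
        positions, flags = index.candidates(cls)
        if len(positions) == 0:
            warnings.warn(
                f"context class {cls.key} has no matching UTRome position; "
                f"{m} mutation(s) excluded from the permutation background")
            continue
        draws = rng.integers(0, len(positions), size=(n_perm, m))
        totals += flags[draws].sum(axis=1)
    return pd.DataFrame(totals, columns=list(CATEGORIES))


@dataclass
class PermutationResult:
    """Enrichment of one motif category against the permutation background."""

    category: str
    observed_count: int
    n_perm: int
    t_statistic: float
    p_value: float
    empirical_p_enrichment: float
    empirical_p_depletion: float

    @property
    def empirical_p(self) -> float:
        """Smaller of the two one-sided empirical p values (enrichment orientation first)."""
        return min(self.empirical_p_enrichment, self.empirical_p_depletion)


def enrichment_test(observed_count: float, background_counts,
                    category: str = "", alternative: str = "two-sided") -> PermutationResult:
    """One-sample t test of the permutation background against the observed count.

    Also reports empirical p values: for enrichment
    ``(1 + #{background >= observed}) / (1 + n_perm)`` and the mirrored form
    for depletion. With a zero-variance background the t test is undefined
    (p=1 when the background equals the observed count); only the empirical
    p values are then informative.
    """
    bg = np.asarray(background_counts, dtype=float)
    n = bg.size
    if n < 2:
        raise ValueError("need at least 2 permutations for the t test")
    emp_enrich = (1 + int((bg >= observed_count).sum())) / (1 + n)
    emp_deplete = (1 + int((bg <= observed_count).sum())) / (1 + n)
    if bg.std(ddof=1) == 0:
        t_stat = np.nan
        p = 1.0 if bg[0] == observed_count else np.nan
    else:
        t_stat, p = stats.ttest_1samp(bg, popmean=observed_count,
                                      alternative=alternative)
        t_stat, p = float(t_stat), float(p)
    return PermutationResult(category, observed_count, n, t_stat, p,
                             emp_enrich, emp_deplete)


def enrichment_table(mutations, utrome, resources, n_perm: int = 10000,
                     seed: int = 0, window: int = DEFAULT_SCAN_WINDOW,
                     background: np.ndarray | None = None) -> pd.DataFrame:
    """Observed counts, t test and empirical p per category, in one table."""
    index = MotifAffectIndex(utrome, resources, window, background)
    observed = observed_category_counts(mutations, utrome, resources, index=index)
    bg = permute_mutations(mutations, utrome, resources, n_perm=n_perm,
                           seed=seed, index=index)
    rows = []
    for c in CATEGORIES:
        r = enrichment_test(observed[c], bg[c].to_numpy(), category=c)
        rows.append({
            "category": c, "observed": r.observed_count,
            "background_mean": float(bg[c].mean()),
            "t_statistic": r.t_statistic, "p_value": r.p_value,
            "empirical_p_enrichment": r.empirical_p_enrichment,
            "empirical_p_depletion": r.empirical_p_depletion,
        })
    return pd.DataFrame(rows)
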