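"""Functional-vs-passenger feature comparisons: regulatory-motif overlap,
per-base sequence conservation, GC content of the reporter window, and
externally supplied folding free energy (ΔG, kcal/mol).

Binary features (motif overlap, high conservation at score > 0.9) are
compared with a Pearson chi-square test; continuous features (GC, ΔG) with
two-tailed unpaired t tests (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import validate_dna

HIGH_CONSERVATION_THRESHOLD = 0.9  # strict: score > 0.9


def gc_content(window: str) -> float:
    """(#G + #C) / length of an A/C/G/T(/U) string."""
    s = validate_dna(window, name="window")
    return (s.count("G") + s.count("C")) / len(s)


class ConservationTrack:
    """Per-base conservation scores from a bedGraph-like table
    (chrom, start, end, score; 0-based half-open intervals)."""

    def __init__(self, table: pd.DataFrame):
        self._by_chrom = {}
        for chrom, sub in table.groupby("chrom"):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping intervals in track for {chrom}")
            self._by_chrom[chrom] = (starts, ends, sub["score"].to_numpy(dtype=float))

    @classmethod
    def from_file(cls, path) -> "ConservationTrack":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns, "
                                     f"got {len(fields)}")
                try:
                    rows.append((fields[0], int(fields[1]), int(fields[2]),
                                 float(fields[3])))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))

    def lookup(self, chrom: str, pos: int) -> float:
        """Score at a 1-based genomic position; NaN when uncovered."""
        if chrom not in self._by_chrom:
            return float("nan")
        starts, ends, scores = self._by_chrom[chrom]
        p = pos - 1  # to 0-based
        i = np.searchsorted(starts, p, side="right") - 1
        if i >= 0 and starts[i] <= p < ends[i]:
            return float(scores[i])
        return float("nan")


def conservation_lookup(track: ConservationTrack, chrom: str, pos: int):
    """(score, high_flag); high iff score strictly exceeds 0.9. Uncovered -> (NaN, False)."""
    score = track.lookup(chrom, pos)
    high = bool(np.isfinite(score) and score > HIGH_CONSERVATION_THRESHOLD)
    return score, high


@dataclass
class ComparisonResult:
    feature: str
    test: str
    statistic: float
    p_value: float
    n_functional: int
    n_passenger: int
    skipped: bool = False
    reason: str = ""


def compare_binary(functional_flags, passenger_flags, feature: str = "",
                   correction: bool = False) -> ComparisonResult:
    """Chi-square test (no continuity correction by default) on a 2x2 table of flags."""
    f = np.asarray(functional_flags, dtype=bool)
    p = np.asarray(passenger_flags, dtype=bool)
    if f.size == 0 or p.size == 0:
        return ComparisonResult(feature, "chi-square", np.nan, np.nan,
                                f.size, p.size, skipped=True, reason="empty group")
    table = np.array([[f.sum(), (~f).sum()], [p.sum(), (~p).sum()]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ComparisonResult(feature, "chi-square", np.nan, np.nan,
                                f.size, p.size, skipped=True,
                                reason=f"degenerate margin in table {table.tolist()}")
    stat, pval, _, _ = stats.chi2_contingency(table, correction=correction)
    return ComparisonResult(feature, "chi-square", float(stat), float(pval),
                            f.size, p.size)


def compare_continuous(functional_values, passenger_values, feature: str = "",
                       equal_var: bool = False) -> ComparisonResult:
    """Two-tailed unpaired t test (Welch by default) between the two groups."""
    f = np.asarray(functional_values, dtype=float)
    p = np.asarray(passenger_values, dtype=float)
    f = f[np.isfinite(f)]
    p = p[np.isfinite(p)]
    test = "welch_t" if not equal_var else "pooled_t"
    if f.size < 2 or p.size < 2:
        return ComparisonResult(feature, test, np.nan, np.nan, f.size, p.size,
                                skipped=True, reason="<2 values in a group")
    if f.std(ddof=1) == 0 and p.std(ddof=1) == 0:
        stat, pval = 0.0, 1.0
        if f.mean() != p.mean():
            stat, pval = np.inf, 0.0
    else:
        stat, pval = stats.ttest_ind(f, p, equal_var=equal_var)
    return ComparisonResult(feature, test, float(stat), float(pval), f.size, p.size)


def build_feature_table(mutations: pd.DataFrame, motif_scan: pd.DataFrame,
                        designs, track: ConservationTrack | None = None,
                        delta_g: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-mutation feature table joining motif deltas, conservation, GC and ΔG.

    ``motif_scan``: output of :func:`utrmpra.motifs.scan_mutation_table`;
    ``designs``: InsertDesign list (GC computed over each 201-nt WT window);
    ``delta_g``: optional TSV-derived table with columns mutation_key, delta_g.
    """
    affect_cols = [c for c in motif_scan.columns if c.startswith("affects_")]
    feats = motif_scan[["mutation_key"] + affect_cols].copy()
    feats["alters_motif"] = motif_scan[affect_cols].any(axis=1)
    gc_by_key = {d.mutation_key: gc_content(d.wt_seq)
                 for d in designs if not d.is_control}
    feats["gc_content"] = feats["mutation_key"].map(gc_by_key)
    if track is not None:
        pos_by_key = mutations.set_index("mutation_key")[["chrom", "pos"]]
        scores, highs = [], []
        for key in feats["mutation_key"]:
            chrom, pos = pos_by_key.loc[key]
            s, h = conservation_lookup(track, chrom, int(pos))
            scores.append(s)
            highs.append(h)
        feats["conservation"] = scores
        feats["high_conservation"] = highs
    if delta_g is not None:
        feats = feats.merge(delta_g[["mutation_key", "delta_g"]],
                            on="mutation_key", how="left")
    return feats


def compare_functional_vs_passenger(features: pd.DataFrame,
                                    class_col: str = "functional_class") -> pd.DataFrame:
    """The four feature comparisons, functional (either MPRA) vs passenger."""
    functional = features[class_col] != "passenger"
    f, p = features.loc[functional], features.loc[~functional]
    results = []
    results.append(compare_binary(f["alters_motif"], p["alters_motif"],
                                  feature="alters_motif"))
    if "high_conservation" in features.columns:
        covered_f = f.loc[f["conservation"].notna()] if "conservation" in f else f
        covered_p = p.loc[p["conservation"].notna()] if "conservation" in p else p
        results.append(compare_binary(covered_f["high_conservation"],
                                      covered_p["high_conservation"],
                                      feature="high_conservation"))
    results.append(compare_continuous(f["gc_content"], p["gc_content"],
                                      feature="gc_content"))
    if "delta_g" in features.columns:
        results.append(compare_continuous(f["delta_g"], p["delta_g"],
                                          feature="delta_g"))
    return pd.DataFrame([r.__dict__ for r in results])
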