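"""Polysome-MPRA translation-efficiency statistics.

TE per insert and replicate is the ratio of polysome CPM to total-mRNA CPM —
either (low + high polysome)/total ("total_poly") or high polysome/total
("high_poly"). Differential TE between a mutant and its WT insert is the
log2 ratio of mean TEs ("ratio of ratios"), tested with a two-sample t test
on replicate log2-TE values and corrected with Benjamini-Hochberg across all
pairs; FDR < 0.10 is called significant. This replicate-level test is a
deliberately simple, self-contained alternative to count-model approaches
such as xtail; the ``method`` tag in the output records it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TE_MODES = ("total_poly", "high_poly")
METHOD_TAG = "log_ratio_ttest_bh"


def cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Counts per million per column; ``pseudocount`` is added to raw counts first.

    Zero-sum columns are excluded with a warning.
    """
    sums = counts.sum(axis=0)
    bad = list(sums.index[sums <= 0])
    if bad:
        warnings.warn(f"excluding zero-count sample(s): {bad}")
    keep = [c for c in counts.columns if c not in bad]
    sub = counts[keep]
    return 1e6 * (sub + pseudocount).div(sub.sum(axis=0), axis=1)


def cpm_log2(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(1e6 * count / column_sum + pseudocount)."""
    sums = counts.sum(axis=0)
    bad = list(sums.index[sums <= 0])
    if bad:
        warnings.warn(f"excluding zero-count sample(s): {bad}")
    keep = [c for c in counts.columns if c not in bad]
    sub = counts[keep]
    return np.log2(1e6 * sub.div(sub.sum(axis=0), axis=1) + pseudocount)


def _fraction_columns(samples: pd.DataFrame, fraction: str) -> pd.Series:
    sub = samples.loc[samples["fraction_or_timepoint"] == fraction]
    if sub.empty:
        raise ValueError(f"no samples for fraction {fraction!r}")
    return sub.set_index("replicate")["sample_id"]


def compute_te(counts: pd.DataFrame, samples: pd.DataFrame,
               mode: str = "total_poly", pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-insert, per-replicate translation efficiency on the CPM scale.

    ``total_poly``: (low_poly CPM + high_poly CPM) / total_mRNA CPM;
    ``high_poly``: high_poly CPM / total_mRNA CPM. Replicates with zero
    total-mRNA CPM are NaN.
    """
    if mode not in TE_MODES:
        raise ValueError(f"mode must be one of {TE_MODES}")
    mat = cpm(counts, pseudocount=pseudocount)
    total = _fraction_columns(samples, "total_mRNA")
    high = _fraction_columns(samples, "high_poly")
    low = _fraction_columns(samples, "low_poly") if mode == "total_poly" else None
    reps = sorted(set(total.index) & set(high.index)
                  & (set(low.index) if low is not None else set(high.index)))
    te = {}
    for rep in reps:
        num = mat[high[rep]]
        if low is not None:
            num = num + mat[low[rep]]
        denom = mat[total[rep]]
        with np.errstate(divide="ignore", invalid="ignore"):
            te[rep] = (num / denom).where(denom > 0)
    out = pd.DataFrame(te)
    out.columns.name = "replicate"
    return out


def rna_expression_change(counts: pd.DataFrame, samples: pd.DataFrame,
                          pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-insert, per-replicate log2(total-mRNA CPM / plasmid CPM)."""
    mat = cpm(counts, pseudocount=pseudocount)
    total = _fraction_columns(samples, "total_mRNA")
    plasmid = _fraction_columns(samples, "plasmid")
    reps = sorted(set(total.index) & set(plasmid.index))
    out = {}
    for rep in reps:
        with np.errstate(divide="ignore", invalid="ignore"):
            out[rep] = np.log2(mat[total[rep]] / mat[plasmid[rep]])
    res = pd.DataFrame(out)
    res.columns.name = "replicate"
    return res


def diff_te(te: pd.DataFrame, pairs: pd.DataFrame, fdr_threshold: float = 0.10,
            equal_var: bool = False, mode: str = "total_poly") -> pd.DataFrame:
    """Differential TE calls for WT/mutant pairs.

    Per pair: log2 ratio-of-ratios = log2(mean mutant TE / mean WT TE); p from
    a two-sample t test on replicate log2-TE values; BH FDR across all pairs;
    significant at FDR < ``fdr_threshold``. Pairs with < 2 usable replicates
    on either side are reported unscored with a reason.
    """
    rows = []
    for rec in pairs.itertuples(index=False):
        wt = te.loc[rec.wt_id].dropna()
        mut = te.loc[rec.mut_id].dropna()
        wt = wt[wt > 0]
        mut = mut[mut > 0]
        row = {"mutation_key": rec.mutation_key, "wt_id": rec.wt_id,
               "mut_id": rec.mut_id, "log2fc_te": np.nan, "p": np.nan,
               "reason": ""}
        if len(wt) < 2 or len(mut) < 2:
            row["reason"] = "<2 usable replicates"
        else:
            row["log2fc_te"] = float(np.log2(mut.mean() / wt.mean()))
            lw, lm = np.log2(wt.to_numpy()), np.log2(mut.to_numpy())
            if np.std(lw, ddof=1) == 0 and np.std(lm, ddof=1) == 0:
                row["p"] = 1.0 if lw.mean() == lm.mean() else 0.0
            else:
                row["p"] = float(stats.ttest_ind(lm, lw, equal_var=equal_var)[1])
        rows.append(row)
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    scored = out["p"].notna()
    if scored.any():
        out.loc[scored, "fdr"] = multipletests(out.loc[scored, "p"],
                                               method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    out["method"] = METHOD_TAG
    out["te_mode"] = mode
    return out


def analyze_translation(counts: pd.DataFrame, samples: pd.DataFrame,
                        pairs: pd.DataFrame, mode: str = "total_poly",
                        fdr_threshold: float = 0.10,
                        pseudocount: float = 0.5) -> pd.DataFrame:
    te = compute_te(counts, samples, mode=mode, pseudocount=pseudocount)
    return diff_te(te, pairs, fdr_threshold=fdr_threshold, mode=mode)
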