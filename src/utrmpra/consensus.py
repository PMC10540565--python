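"""Multi-caller somatic variant consensus, cohort read/VAF filters,
hypermutant exclusion, and tumor mutational burden.

Variants are keyed on (chrom, pos, ref, alt, sample_id). Read/VAF cutoffs
are applied per caller record first, then consensus (>= min_callers) is
taken over the surviving records; the alternative order (consensus first)
is available via ``filter_order``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KEY_COLS = ["chrom", "pos", "ref", "alt", "sample_id"]
EVIDENCE_COLS = ["ref_reads_normal", "total_reads_tumor", "alt_reads_tumor",
                 "tumor_vaf", "normal_vaf"]


@dataclass
class CohortFilterConfig:
    """Read-support and VAF cutoffs plus consensus/hypermutant settings.

    A record is kept iff ref_reads_normal >= min_ref_reads_normal,
    total_reads_tumor >= min_total_reads_tumor, alt_reads_tumor >=
    min_alt_reads_tumor, tumor_vaf >= min_tumor_vaf and normal_vaf <=
    max_normal_vaf (all boundaries inclusive).
    """

    min_ref_reads_normal: int = 8
    min_total_reads_tumor: int = 28
    min_alt_reads_tumor: int = 10
    min_tumor_vaf: float = 0.1
    max_normal_vaf: float = 0.05
    min_callers: int = 2
    hypermutant_samples: list = field(default_factory=list)

    def __post_init__(self):
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        for name in ("min_ref_reads_normal", "min_total_reads_tumor",
                     "min_alt_reads_tumor", "min_tumor_vaf", "max_normal_vaf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: whole-exome cohort cutoffs (deep tumor coverage)
SU2C_CONFIG = CohortFilterConfig(8, 28, 10, 0.1, 0.05, 2,
                                 hypermutant_samples=["DTB-083"])
#: tumor/PDX cohort cutoffs (shallower coverage)
UW_CONFIG = CohortFilterConfig(8, 14, 5, 0.1, 0.05, 2,
                               hypermutant_samples=["10-068", "LuCaP147"])


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    for col in KEY_COLS + EVIDENCE_COLS:
        if col not in df.columns:
            raise ValueError(f"caller table missing column {col!r}")
    snv = df["ref"].str.len().eq(1) & df["alt"].str.len().eq(1)
    if not snv.all():
        import warnings
        warnings.warn(f"dropping {(~snv).sum()} non-SNV record(s); "
                      "only single-nucleotide variants are in scope")
        df = df.loc[snv]
    if (df["ref"] == df["alt"]).any():
        raise ValueError("record with ref == alt")
    return df


def apply_cohort_filters(records: pd.DataFrame, config: CohortFilterConfig) -> pd.DataFrame:
    """Keep records satisfying all five read/VAF cutoffs (boundaries inclusive)."""
    df = _validate_records(records)
    keep = (
        (df["ref_reads_normal"] >= config.min_ref_reads_normal)
        & (df["total_reads_tumor"] >= config.min_total_reads_tumor)
        & (df["alt_reads_tumor"] >= config.min_alt_reads_tumor)
        & (df["tumor_vaf"] >= config.min_tumor_vaf)
        & (df["normal_vaf"] <= config.max_normal_vaf)
    )
    return df.loc[keep].reset_index(drop=True)


def merge_callers(tables) -> pd.DataFrame:
    """Merge per-caller tables into one row per variant key.

    ``tables``: dict caller_id -> DataFrame, or list of DataFrames with a
    ``caller`` column. Output columns: the key, ``supporting_callers``
    (sorted tuple), ``n_callers``, and per-field maxima of the read evidence.
    A duplicate key within one caller's table is an input-format error.
    """
    if isinstance(tables, dict):
        frames = []
        for caller, df in tables.items():
            df = df.copy()
            df["caller"] = caller
            frames.append(df)
    else:
        frames = [df.copy() for df in tables]
        for i, df in enumerate(frames):
            if "caller" not in df.columns:
                df["caller"] = f"caller{i + 1}"
    for df in frames:
        df_ = _validate_records(df)
        dup = df_.duplicated(subset=KEY_COLS)
        if dup.any():
            bad = df_.loc[dup, KEY_COLS].iloc[0].tolist()
            raise ValueError(f"duplicate variant key within caller "
                             f"{df_['caller'].iloc[0]!r}: {bad}")
    allrec = pd.concat(frames, ignore_index=True)
    if allrec.empty:
        return pd.DataFrame(columns=KEY_COLS + ["supporting_callers", "n_callers"]
                            + EVIDENCE_COLS)
    extra = [c for c in ("region_class",) if c in allrec.columns]
    agg = {c: "max" for c in EVIDENCE_COLS}
    agg["caller"] = lambda s: tuple(sorted(s))
    for c in extra:
        agg[c] = "first"
    merged = (allrec.groupby(KEY_COLS, as_index=False, sort=True)
              .agg(agg)
              .rename(columns={"caller": "supporting_callers"}))
    merged["n_callers"] = merged["supporting_callers"].map(len)
    return merged


def consensus_retain(merged: pd.DataFrame, min_callers: int = 2) -> pd.DataFrame:
    """Variants supported by at least ``min_callers`` callers.

    The fraction of retained variants supported by all callers seen in the
    input is stored in ``result.attrs['fraction_all_callers']``.
    """
    if merged.empty:
        out = merged.copy()
        out.attrs["fraction_all_callers"] = float("nan")
        return out
    total_callers = len(set().union(*merged["supporting_callers"].map(set)))
    out = merged.loc[merged["n_callers"] >= min_callers].reset_index(drop=True)
    out.attrs["fraction_all_callers"] = (
        float((out["n_callers"] == total_callers).mean()) if len(out) else float("nan"))
    return out


def exclude_hypermutants(mutations: pd.DataFrame, config: CohortFilterConfig) -> pd.DataFrame:
    excluded = set(config.hypermutant_samples)
    if not excluded:
        return mutations.reset_index(drop=True)
    return mutations.loc[~mutations["sample_id"].isin(excluded)].reset_index(drop=True)


def consensus_pipeline(tables, config: CohortFilterConfig,
                       filter_order: str = "filter_first") -> pd.DataFrame:
    """Filters + consensus + hypermutant exclusion in the configured order.

    ``filter_order='filter_first'`` applies the read/VAF cutoffs to each
    caller's records before taking consensus (default);
    ``'consensus_first'`` merges first and filters the merged evidence.
    """
    if filter_order == "filter_first":
        if isinstance(tables, dict):
            tables = {c: apply_cohort_filters(df, config) for c, df in tables.items()}
        else:
            tables = [apply_cohort_filters(df, config) for df in tables]
        merged = merge_callers(tables)
    elif filter_order == "consensus_first":
        merged = merge_callers(tables)
        merged = apply_cohort_filters(merged, config)
    else:
        raise ValueError(f"unknown filter_order {filter_order!r}")
    retained = consensus_retain(merged, config.min_callers)
    frac = retained.attrs.get("fraction_all_callers")
    retained = exclude_hypermutants(retained, config)
    retained.attrs["fraction_all_callers"] = frac
    return retained


# ---------------------------------------------------------------------------
# Tumor mutational burden
# ---------------------------------------------------------------------------

@dataclass
class TmbResult:
    sample_id: str
    region_class: str
    mutation_count: int
    region_size_mb: float
    tmb: float


def interval_union_length(regions: pd.DataFrame) -> int:
    """Total length of the union of (chrom, start, end) intervals (0-based half-open)."""
    total = 0
    for _, sub in regions.groupby("chrom"):
        arr = sub[["start", "end"]].to_numpy()
        arr = arr[np.argsort(arr[:, 0])]
        cur_start, cur_end = None, None
        for s, e in arr:
            if cur_end is None or s > cur_end:
                if cur_end is not None:
                    total += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        if cur_end is not None:
            total += cur_end - cur_start
    return int(total)


def compute_tmb(mutations: pd.DataFrame, regions: pd.DataFrame,
                sample_id: str, region_class: str) -> TmbResult:
    """Mutations per megabase over the overlap-collapsed region set."""
    size = interval_union_length(regions)
    if size <= 0:
        raise ValueError(f"region set for {region_class} has zero total size")
    sub = mutations
    if "sample_id" in mutations.columns:
        sub = sub.loc[sub["sample_id"] == sample_id]
    if "region_class" in mutations.columns:
        sub = sub.loc[sub["region_class"] == region_class]
    count = len(sub)
    size_mb = size / 1e6
    return TmbResult(sample_id, region_class, count, size_mb, count / size_mb)
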