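"""Synthetic data with known ground truth for every pipeline stage.

Emulates (a) a 3' UTRome, optionally with planted regulatory motifs,
(b) somatic single-nucleotide mutations drawn from a chosen 288-class
context frequency table, (c) the outputs of four somatic variant callers
with configurable sensitivity and false positives, (d) IVT stability-MPRA
time-course counts following per-insert exponential decay with spike-in
scaling, and (e) polysome-fraction counts with planted translation-efficiency
shifts. All generators are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DNA_BASES, GroundTruth, UtrRecord, mutation_key, normalize_seq
from .motifs import MISSING_FLANK, ContextClass, classify_context

DEFAULT_CALLERS = ("mutect2", "strelka2", "muse", "varscan2")

STABILITY_TIMEPOINTS = (1.0, 3.0, 6.0, 12.0, 24.0)
POLYSOME_FRACTIONS = ("plasmid", "total_mRNA", "monosome", "low_poly", "high_poly")


class GenerationError(ValueError):
    """A generator was asked for something its inputs cannot provide."""


# ---------------------------------------------------------------------------
# UTRome
# ---------------------------------------------------------------------------

def gen_utrome(n_utrs: int, length_range=(200, 1200), gc: float = 0.45,
               seed: int = 0) -> list:
    """Random UTR records, one synthetic chromosome per UTR (chrSYN1..N)."""
    if n_utrs < 0:
        raise GenerationError("n_utrs must be >= 0")
    if not 0 < gc < 1:
        raise GenerationError(f"gc must be in (0, 1), got {gc}")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 1 or hi < lo:
        raise GenerationError(f"invalid length_range {length_range}")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    utrs = []
    for i in range(n_utrs):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(DNA_BASES), size=length, p=probs))
        start = int(rng.integers(1_000, 1_000_000))
        utrs.append(UtrRecord(f"UTR{i + 1:04d}", f"chrSYN{i + 1}",
                              start, start + length, "+", seq))
    return utrs


def plant_motifs(utrome, motif_specs, seed: int = 0):
    """Overwrite random non-overlapping stretches with motif sequences.

    ``motif_specs``: iterable of (motif_id, sequence, count). Returns
    (new utr list, sites DataFrame with columns utr_id, start, end, motif_id).
    """
    rng = np.random.default_rng(seed)
    seqs = {u.utr_id: list(u.sequence) for u in utrome}
    occupied = {u.utr_id: np.zeros(len(u.sequence), dtype=bool) for u in utrome}
    ids = [u.utr_id for u in utrome]
    sites = []
    for motif_id, motif_seq, count in motif_specs:
        motif_seq = normalize_seq(motif_seq)
        L = len(motif_seq)
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 1000 * count:
                raise GenerationError(
                    f"could not place {count} copies of {motif_id}; UTRome too small")
            uid = ids[rng.integers(0, len(ids))]
            n = len(seqs[uid])
            if n < L + 2:
                continue
            start = int(rng.integers(1, n - L))  # keep off the UTR ends
            if occupied[uid][start:start + L].any():
                continue
            seqs[uid][start:start + L] = list(motif_seq)
            occupied[uid][start:start + L] = True
            sites.append({"utr_id": uid, "start": start, "end": start + L,
                          "motif_id": motif_id})
            placed += 1
    new_utrs = [UtrRecord(u.utr_id, u.chrom, u.start, u.end, u.strand,
                          "".join(seqs[u.utr_id])) for u in utrome]
    return new_utrs, pd.DataFrame(sites, columns=["utr_id", "start", "end", "motif_id"])


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def _positions_by_context(utrome):
    idx = {}
    for u in utrome:
        seq = u.sequence
        n = len(seq)
        for off in range(n):
            left = seq[off - 1] if off > 0 else MISSING_FLANK
            right = seq[off + 1] if off + 1 < n else MISSING_FLANK
            idx.setdefault(left + seq[off] + right, []).append((u.utr_id, off))
    return idx


def gen_mutations(utrome, n_mut: int, context_freqs: dict | None = None,
                  planted_motif_hits: int = 0,
                  motif_sites: pd.DataFrame | None = None,
                  sample_id: str = "SYN-01", seed: int = 0):
    """Somatic SNVs drawn from a 288-class context frequency table.

    ``context_freqs`` maps class keys (e.g. ``"ACG>T"``) to probabilities
    summing to 1; None means uniform over the classes realizable in this
    UTRome. Exactly ``planted_motif_hits`` mutations are placed inside
    ``motif_sites`` spans (and flagged); the rest never overlap them.

    Returns (mutation DataFrame, GroundTruth).
    """
    if n_mut < 0:
        raise GenerationError("n_mut must be >= 0")
    if planted_motif_hits > n_mut:
        raise GenerationError("planted_motif_hits exceeds n_mut")
    rng = np.random.default_rng(seed)
    by_id = {u.utr_id: u for u in utrome}
    ctx_positions = _positions_by_context(utrome)

    site_spans = set()
    if motif_sites is not None and len(motif_sites):
        for rec in motif_sites.itertuples(index=False):
            for off in range(int(rec.start), int(rec.end)):
                site_spans.add((rec.utr_id, off))

    rows = []
    truth_sites = ([] if motif_sites is None else
                   [(r.utr_id, int(r.start), r.motif_id)
                    for r in motif_sites.itertuples(index=False)])
    motif_keys = []

    # mutations planted inside motif sites
    if planted_motif_hits:
        if len(site_spans) < planted_motif_hits:
            raise GenerationError(
                f"requested {planted_motif_hits} motif-overlapping mutations but "
                f"only {len(site_spans)} motif-site bases are available")
        span_list = sorted(site_spans)
        picks = rng.choice(len(span_list), size=planted_motif_hits, replace=False)
        for k in picks:
            uid, off = span_list[k]
            ref = by_id[uid].sequence[off]
            alt = rng.choice([b for b in DNA_BASES if b != ref])
            rows.append((uid, off, ref, str(alt), True))

    # remaining mutations drawn by context class, outside motif sites
    n_free = n_mut - planted_motif_hits
    if n_free:
        candidates = {}
        for ctx, positions in ctx_positions.items():
            free = [p for p in positions if p not in site_spans]
            if free:
                candidates[ctx] = free
        if context_freqs is None:
            # uniform over candidate mutations: weight classes by candidate count
            keys, probs = [], []
            for ctx in sorted(candidates):
                for alt in DNA_BASES:
                    if alt != ctx[1]:
                        keys.append(f"{ctx}>{alt}")
                        probs.append(len(candidates[ctx]))
            probs = np.array(probs, dtype=float)
            probs /= probs.sum()
        else:
            keys = sorted(context_freqs)
            probs = np.array([context_freqs[k] for k in keys], dtype=float)
            if not np.isclose(probs.sum(), 1.0, atol=1e-6):
                raise GenerationError("context_freqs must sum to 1")
            realizable = np.array([k.split(">")[0] in candidates for k in keys])
            if not realizable.all():
                probs = np.where(realizable, probs, 0.0)
                if probs.sum() == 0:
                    raise GenerationError("no requested context class is realizable")
                probs = probs / probs.sum()
        # draw classes one at a time; an exhausted class is redrawn so positions
        # stay unique (negligible distortion when the UTRome is large)
        pools = {ctx: list(pos) for ctx, pos in candidates.items()}
        class_draws = rng.choice(len(keys), size=4 * n_free + 100, p=probs)
        placed = 0
        for ki in class_draws:
            if placed == n_free:
                break
            ctx, alt = keys[ki].split(">")
            pool = pools.get(ctx)
            if not pool:
                continue
            j = int(rng.integers(0, len(pool)))
            uid, off = pool.pop(j)
            rows.append((uid, off, by_id[uid].sequence[off], alt, False))
            placed += 1
        if placed < n_free:
            raise GenerationError(
                f"could only place {placed} of {n_free} mutations; "
                f"UTRome too small for the requested class frequencies")

    records = []
    for uid, off, ref, alt, in_site in rows:
        u = by_id[uid]
        key = mutation_key(uid, off, ref, alt)
        if in_site:
            motif_keys.append(key)
        records.append({
            "mutation_key": key, "chrom": u.chrom, "pos": u.start + off + 1,
            "ref": ref, "alt": alt, "utr_id": uid, "offset": off,
            "sample_id": sample_id, "region_class": "3UTR",
            "in_motif_site": in_site,
        })
    columns = ["mutation_key", "chrom", "pos", "ref", "alt", "utr_id", "offset",
               "sample_id", "region_class", "in_motif_site"]
    table = pd.DataFrame(records, columns=columns)
    truth = GroundTruth(
        seed=seed,
        planted_mutations=[(r["utr_id"], r["offset"], r["ref"], r["alt"])
                           for r in records],
        planted_motif_sites=truth_sites,
        motif_overlap_keys=motif_keys,
    )
    return table, truth


def empirical_context_freqs(mutations: pd.DataFrame, utrome) -> pd.Series:
    """Observed 288-class frequencies of a mutation table."""
    by_id = {u.utr_id: u for u in utrome}
    keys = [classify_context(by_id[r.utr_id], int(r.offset), r.ref, r.alt).key
            for r in mutations.itertuples(index=False)]
    counts = pd.Series(keys).value_counts()
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Caller tables
# ---------------------------------------------------------------------------

def gen_caller_tables(mutations: pd.DataFrame, sensitivities,
                      fp_per_caller: int = 0, utrome=None,
                      callers=DEFAULT_CALLERS,
                      depth_tumor: float = 100.0, depth_normal: float = 60.0,
                      vaf_range=(0.2, 0.5), seed: int = 0):
    """Per-caller variant tables with Bernoulli sensitivity and random false positives.

    Read evidence (depths, alt reads, VAFs) is drawn once per true mutation
    and shared by every caller that reports it. False positives are drawn
    per caller at random UTRome positions disjoint from the true set.

    Returns (dict caller -> DataFrame, presence DataFrame [mutation x caller]).
    """
    if isinstance(sensitivities, dict):
        sens = {c: float(sensitivities[c]) for c in callers}
    else:
        sens = dict(zip(callers, [float(s) for s in sensitivities]))
    for c, s in sens.items():
        if not 0.0 <= s <= 1.0:
            raise GenerationError(f"sensitivity for {c} must be in [0, 1]")
    if fp_per_caller < 0:
        raise GenerationError("fp_per_caller must be >= 0")
    if fp_per_caller > 0 and utrome is None:
        raise GenerationError("utrome is required to place false positives")
    rng = np.random.default_rng(seed)

    def read_stats(n):
        t_depth = np.maximum(rng.poisson(depth_tumor, n), 1)
        true_vaf = rng.uniform(vaf_range[0], vaf_range[1], n)
        alt_reads = rng.binomial(t_depth, true_vaf)
        n_depth = np.maximum(rng.poisson(depth_normal, n), 1)
        n_alt = rng.binomial(n_depth, 0.002)
        return pd.DataFrame({
            "ref_reads_normal": n_depth - n_alt,
            "total_reads_tumor": t_depth,
            "alt_reads_tumor": alt_reads,
            "tumor_vaf": alt_reads / t_depth,
            "normal_vaf": n_alt / n_depth,
        })

    n_true = len(mutations)
    base_cols = ["chrom", "pos", "ref", "alt", "sample_id", "region_class"]
    true_tab = pd.concat(
        [mutations[base_cols].reset_index(drop=True), read_stats(n_true)], axis=1)
    true_keyset = set(zip(mutations["chrom"], mutations["pos"],
                          mutations["ref"], mutations["alt"]))

    presence = pd.DataFrame(False, index=mutations["mutation_key"], columns=list(callers))
    tables = {}
    for c in callers:
        detected = rng.random(n_true) < sens[c]
        presence[c] = detected
        parts = [true_tab.loc[detected]]
        if fp_per_caller:
            fp_rows = []
            seen = set(true_keyset)
            guard = 0
            while len(fp_rows) < fp_per_caller:
                guard += 1
                if guard > 100 * fp_per_caller:
                    raise GenerationError("could not place false positives")
                u = utrome[rng.integers(0, len(utrome))]
                off = int(rng.integers(0, len(u.sequence)))
                ref = u.sequence[off]
                alt = str(rng.choice([b for b in DNA_BASES if b != ref]))
                key = (u.chrom, u.start + off + 1, ref, alt)
                if key in seen:
                    continue
                seen.add(key)
                fp_rows.append({"chrom": key[0], "pos": key[1], "ref": ref, "alt": alt,
                                "sample_id": mutations["sample_id"].iloc[0]
                                if n_true else "SYN-01",
                                "region_class": "3UTR"})
            fp_tab = pd.concat([pd.DataFrame(fp_rows), read_stats(fp_per_caller)], axis=1)
            parts.append(fp_tab)
        tab = pd.concat(parts, ignore_index=True)
        tab.insert(0, "caller", c)
        tables[c] = tab
    return tables, presence


# ---------------------------------------------------------------------------
# Stability MPRA time course
# ---------------------------------------------------------------------------

def _sample_counts(rng, mu, noise, nb_dispersion):
    if noise == "none":
        return mu
    if noise == "poisson":
        return rng.poisson(mu).astype(float)
    if noise == "nb":
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        return rng.poisson(lam).astype(float)
    raise GenerationError(f"unknown noise model {noise!r}")


def gen_stability_counts(insert_ids, alphas, timepoints=STABILITY_TIMEPOINTS,
                         n_reps: int = 6, depth: float = 400.0,
                         spike_scale: float = 5000.0, noise: str = "poisson",
                         nb_dispersion: float = 0.1,
                         abundance_sigma: float = 0.5,
                         sample_factor_sigma: float = 0.2,
                         seed: int = 0):
    """IVT decay time-course counts: per-insert exponential decay, spike-in scaling.

    Expected count of insert i in sample (t, r) is
    ``depth * A_i * exp(-alpha_i * (t - t0)) * f_s`` where A_i is a unit-mean
    log-normal initial abundance, f_s a unit-mean log-normal per-sample
    efficiency factor (what the spike-in normalizes away), and t0 the first
    timepoint, so mean counts at the first timepoint equal ``depth``. The
    spike-in is a constant true abundance (``spike_scale``) scaled by f_s.
    ``noise='none'`` returns exact expectations (float-valued counts).

    Returns (counts DataFrame [insert x sample], samples DataFrame with
    columns sample_id, fraction_or_timepoint, replicate, spike_count).
    """
    insert_ids = list(insert_ids)
    if isinstance(alphas, dict):
        alphas = np.asarray([alphas[i] for i in insert_ids], dtype=float)
    else:
        alphas = np.asarray(alphas, dtype=float)
    if len(alphas) != len(insert_ids):
        raise GenerationError("need one alpha per insert")
    if (alphas <= 0).any():
        raise GenerationError("all decay rates must be > 0")
    timepoints = [float(t) for t in timepoints]
    if sorted(timepoints) != timepoints:
        raise GenerationError("timepoints must be ascending")
    if depth <= 0:
        raise GenerationError("depth must be > 0")
    rng = np.random.default_rng(seed)
    n = len(insert_ids)
    A = rng.lognormal(-abundance_sigma ** 2 / 2, abundance_sigma, n)
    t0 = timepoints[0]

    columns, sample_rows, data = [], [], []
    for t in timepoints:
        for r in range(1, n_reps + 1):
            sid = f"t{t:g}h_r{r}"
            if noise == "none":
                f = 1.0
                spike = spike_scale
            else:
                f = rng.lognormal(-sample_factor_sigma ** 2 / 2, sample_factor_sigma)
                spike = float(rng.poisson(spike_scale * f))
            mu = depth * A * np.exp(-alphas * (t - t0)) * f
            data.append(_sample_counts(rng, mu, noise, nb_dispersion))
            columns.append(sid)
            sample_rows.append({"sample_id": sid, "fraction_or_timepoint": t,
                                "replicate": r, "spike_count": spike})
    counts = pd.DataFrame(np.column_stack(data), index=insert_ids, columns=columns)
    counts.index.name = "insert_id"
    return counts, pd.DataFrame(sample_rows)


# ---------------------------------------------------------------------------
# Polysome MPRA
# ---------------------------------------------------------------------------

def gen_polysome_counts(insert_ids, te_multipliers=None,
                        fractions=POLYSOME_FRACTIONS, n_reps: int = 6,
                        depth: float = 300.0, noise: str = "poisson",
                        nb_dispersion: float = 0.1,
                        abundance_sigma: float = 0.5,
                        sample_factor_sigma: float = 0.2,
                        seed: int = 0):
    """Polysome-profiling counts with planted translation-efficiency multipliers.

    Plasmid and total-mRNA expected counts are ``depth * A_i``; low- and
    high-polysome expected counts are ``depth * A_i * TE_i / 2`` each (so the
    (low+high)/total ratio equals TE_i and high/total equals TE_i/2); the
    monosome fraction is ``depth * A_i / 2``. ``te_multipliers`` maps
    insert_id -> TE_i (default 1).

    Returns (counts DataFrame, samples DataFrame).
    """
    insert_ids = list(insert_ids)
    if depth <= 0:
        raise GenerationError("depth must be > 0")
    te = np.ones(len(insert_ids))
    if te_multipliers:
        for k, ins in enumerate(insert_ids):
            te[k] = float(te_multipliers.get(ins, 1.0))
    if (te <= 0).any():
        raise GenerationError("TE multipliers must be > 0")
    rng = np.random.default_rng(seed)
    A = rng.lognormal(-abundance_sigma ** 2 / 2, abundance_sigma, len(insert_ids))
    weights = {
        "plasmid": np.ones_like(A),
        "total_mRNA": np.ones_like(A),
        "monosome": 0.5 * np.ones_like(A),
        "low_poly": 0.5 * te,
        "high_poly": 0.5 * te,
    }
    columns, sample_rows, data = [], [], []
    for frac in fractions:
        if frac not in weights:
            raise GenerationError(f"unknown fraction {frac!r}")
        for r in range(1, n_reps + 1):
            sid = f"{frac}_r{r}"
            f = (1.0 if noise == "none"
                 else rng.lognormal(-sample_factor_sigma ** 2 / 2, sample_factor_sigma))
            mu = depth * A * weights[frac] * f
            data.append(_sample_counts(rng, mu, noise, nb_dispersion))
            columns.append(sid)
            sample_rows.append({"sample_id": sid, "fraction_or_timepoint": frac,
                                "replicate": r, "spike_count": np.nan})
    counts = pd.DataFrame(np.column_stack(data), index=insert_ids, columns=columns)
    counts.index.name = "insert_id"
    return counts, pd.DataFrame(sample_rows)
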