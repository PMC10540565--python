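"""IVT stability-MPRA statistics: spike-in normalization, 1h->3h and 1h->6h
decay ratios, WT-vs-mutant two-sample t tests, plateau-exponential decay
fits with half-life estimation, and the three-criterion significance call.

The decay model is ``y(t) = yf + (y0 - yf) * exp(-alpha * t)`` fitted by
nonlinear least squares from starting values y0=0.5, yf=0, alpha=0.1;
half-life = ln(2)/alpha. A WT/mutant pair is called significant iff
(A) the summed raw first-timepoint counts are >= 24 for both inserts,
(B) the 3h or the 6h decay-ratio comparison has p < 0.05 and |log2FC| > 0.3,
and (C) |log2(mutant half-life / WT half-life)| > 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

LN2 = float(np.log(2.0))

DEFAULT_STARTS = (0.5, 0.0, 0.1)  # y0, yf, alpha


@dataclass
class StabilityThresholds:
    min_first_timepoint_sum: float = 24.0   # filter A, per insert, summed over replicates
    p_threshold: float = 0.05               # filter B
    lfc_threshold: float = 0.3              # filter B, strict
    half_life_lfc_threshold: float = 0.2    # filter C, strict
    equal_var: bool = False                 # Welch by default
    scale_curves: bool = True               # rescale so the 1h mean maps to y0's start


@dataclass
class DecayFit:
    insert_id: str
    y0: float
    yplateau: float
    alpha: float
    half_life: float
    converged: bool
    rss: float
    n_points: int

    def __post_init__(self):
        if self.converged:
            assert self.alpha > 0
            assert np.isclose(self.half_life, LN2 / self.alpha, rtol=0, atol=0) or \
                self.half_life == LN2 / self.alpha


@dataclass
class StabilityCall:
    mutation_key: str
    log2fc_decay_3h: float
    log2fc_decay_6h: float
    p_3h: float
    p_6h: float
    log2fc_half_life: float
    passes_A: bool
    passes_B: bool
    passes_C: bool
    significant: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# Normalization and ratios
# ---------------------------------------------------------------------------

def spike_normalize(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's counts by that sample's spike-in count.

    Samples with a non-positive or missing spike count are excluded with a
    warning.
    """
    spikes = samples.set_index("sample_id")["spike_count"]
    missing = [c for c in counts.columns if c not in spikes.index]
    if missing:
        raise ValueError(f"samples sheet missing sample(s): {missing}")
    bad = [c for c in counts.columns
           if not np.isfinite(spikes[c]) or spikes[c] <= 0]
    if bad:
        warnings.warn(f"excluding sample(s) with non-positive spike counts: {bad}")
    keep = [c for c in counts.columns if c not in bad]
    return counts[keep].div(spikes[keep], axis=1)


def _sample_map(samples: pd.DataFrame) -> pd.DataFrame:
    s = samples.copy()
    s["timepoint"] = pd.to_numeric(s["fraction_or_timepoint"])
    return s


def decay_ratios(normalized: pd.DataFrame, samples: pd.DataFrame,
                 target_t: float) -> pd.DataFrame:
    """Per-insert, per-replicate ratio normalized(target_t) / normalized(first timepoint).

    Replicates with zero abundance at the reference timepoint yield NaN
    (dropped downstream with a warning).
    """
    s = _sample_map(samples)
    s = s.loc[s["sample_id"].isin(normalized.columns)]
    t_ref = s["timepoint"].min()
    ratios = {}
    for rep, sub in s.groupby("replicate"):
        ref_ids = sub.loc[sub["timepoint"] == t_ref, "sample_id"]
        tgt_ids = sub.loc[sub["timepoint"] == target_t, "sample_id"]
        if len(ref_ids) != 1 or len(tgt_ids) != 1:
            continue
        ref = normalized[ref_ids.iloc[0]]
        tgt = normalized[tgt_ids.iloc[0]]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = tgt / ref
        ratios[rep] = r.where(ref > 0)
    out = pd.DataFrame(ratios)
    out.columns.name = "replicate"
    if out.isna().any().any():
        warnings.warn("some replicates had zero reference-timepoint abundance; "
                      "their ratios are undefined and dropped")
    return out


def decay_test(wt_ratios, mut_ratios, equal_var: bool = False):
    """(p, log2fc) comparing mutant vs WT decay ratios across replicates.

    Two-sample t test (Welch by default); log2fc = log2(mean mutant ratio /
    mean WT ratio). Degenerate zero-variance inputs give p=1 when the means
    are equal and p=0 otherwise.
    """
    wt = np.asarray(wt_ratios, dtype=float)
    mut = np.asarray(mut_ratios, dtype=float)
    wt = wt[np.isfinite(wt)]
    mut = mut[np.isfinite(mut)]
    if wt.size < 2 or mut.size < 2:
        raise ValueError("need >= 2 replicates per side")
    log2fc = float(np.log2(mut.mean() / wt.mean())) if wt.mean() > 0 and mut.mean() > 0 \
        else float("nan")
    if wt.std(ddof=1) == 0 and mut.std(ddof=1) == 0:
        p = 1.0 if wt.mean() == mut.mean() else 0.0
    else:
        _, p = stats.ttest_ind(mut, wt, equal_var=equal_var)
        p = float(p)
    return p, log2fc


# ---------------------------------------------------------------------------
# Decay fitting
# ---------------------------------------------------------------------------

def _decay_model(t, y0, yf, alpha):
    return yf + (y0 - yf) * np.exp(-alpha * t)


def fit_decay(times, values, insert_id: str = "",
              starts=DEFAULT_STARTS, max_iterations: int = 1000) -> DecayFit:
    """Nonlinear least-squares fit of the plateau-exponential decay model.

    All (t, y) points are fitted jointly (replicates pooled). Returns a
    non-converged fit (half_life NaN) rather than raising when the optimizer
    fails, alpha comes out non-positive, or the curve is degenerate.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 3:
        return DecayFit(insert_id, np.nan, np.nan, np.nan, np.nan, False, np.nan,
                        int(t.size))
    if np.ptp(y) == 0:
        # constant (e.g. all-zero) curve: no decay information
        return DecayFit(insert_id, float(y[0]), float(y[0]), np.nan, np.nan,
                        False, 0.0, int(t.size))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _decay_model, t, y, p0=list(starts), method="lm",
                maxfev=max_iterations, xtol=1e-8, ftol=1e-8)
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return DecayFit(insert_id, np.nan, np.nan, np.nan, np.nan, False, np.nan,
                        int(t.size))
    y0, yf, alpha = (float(v) for v in popt)
    rss = float(np.sum((_decay_model(t, *popt) - y) ** 2))
    if not np.isfinite(alpha) or alpha <= 0:
        return DecayFit(insert_id, y0, yf, alpha, np.nan, False, rss, int(t.size))
    return DecayFit(insert_id, y0, yf, alpha, LN2 / alpha, True, rss, int(t.size))


def fit_all_decays(normalized: pd.DataFrame, samples: pd.DataFrame,
                   scale_curves: bool = True, starts=DEFAULT_STARTS) -> pd.DataFrame:
    """One decay fit per insert over all samples' (t, y) points.

    With ``scale_curves`` (default) each insert's normalized abundances are
    divided by its replicate-mean first-timepoint value and multiplied by the
    y0 start (0.5), anchoring the curve near the optimizer's starting point.
    Rescaling leaves alpha (and the half-life) invariant.
    """
    s = _sample_map(samples)
    s = s.loc[s["sample_id"].isin(normalized.columns)]
    order = s["sample_id"].tolist()
    t = s.set_index("sample_id").loc[order, "timepoint"].to_numpy(dtype=float)
    mat = normalized[order].to_numpy(dtype=float)
    t_ref = t.min()
    ref_cols = np.flatnonzero(t == t_ref)
    rows = []
    for i, insert_id in enumerate(normalized.index):
        y = mat[i]
        if scale_curves:
            ref_mean = y[ref_cols].mean()
            y = y / ref_mean * starts[0] if ref_mean > 0 else np.full_like(y, np.nan)
        fit = fit_decay(t, y, insert_id=str(insert_id), starts=starts)
        rows.append({"insert_id": fit.insert_id, "y0": fit.y0,
                     "yplateau": fit.yplateau, "alpha": fit.alpha,
                     "half_life": fit.half_life, "converged": fit.converged,
                     "rss": fit.rss, "n_points": fit.n_points})
    return pd.DataFrame(rows).set_index("insert_id")


# ---------------------------------------------------------------------------
# Significance calling
# ---------------------------------------------------------------------------

def first_timepoint_sums(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    """Raw counts at the earliest timepoint, summed over replicates (filter A input)."""
    s = _sample_map(samples)
    s = s.loc[s["sample_id"].isin(counts.columns)]
    first_ids = s.loc[s["timepoint"] == s["timepoint"].min(), "sample_id"]
    return counts[list(first_ids)].sum(axis=1)


def call_stability(counts: pd.DataFrame, samples: pd.DataFrame,
                   pairs: pd.DataFrame,
                   thresholds: StabilityThresholds | None = None):
    """Significance calls for WT/mutant pairs (columns wt_id, mut_id, mutation_key).

    Returns (calls DataFrame, fits DataFrame).
    """
    th = thresholds or StabilityThresholds()
    normalized = spike_normalize(counts, samples)
    fits = fit_all_decays(normalized, samples, scale_curves=th.scale_curves)
    sums1h = first_timepoint_sums(counts, samples)
    ratios = {t: decay_ratios(normalized, samples, t) for t in (3.0, 6.0)}

    calls = []
    for rec in pairs.itertuples(index=False):
        wt_id, mut_id = rec.wt_id, rec.mut_id
        reason = []
        res = {"mutation_key": rec.mutation_key,
               "log2fc_decay_3h": np.nan, "log2fc_decay_6h": np.nan,
               "p_3h": np.nan, "p_6h": np.nan, "log2fc_half_life": np.nan}
        # filter A: raw first-timepoint count sums
        passes_a = bool(sums1h[wt_id] >= th.min_first_timepoint_sum
                        and sums1h[mut_id] >= th.min_first_timepoint_sum)
        # filter B: decay-ratio tests at 3 h and 6 h
        passes_b = False
        for t in (3.0, 6.0):
            wt_r = ratios[t].loc[wt_id].dropna().to_numpy()
            mut_r = ratios[t].loc[mut_id].dropna().to_numpy()
            tag = f"{t:g}h"
            if wt_r.size < 2 or mut_r.size < 2:
                reason.append(f"<2 usable replicates at {tag}")
                continue
            p, lfc = decay_test(wt_r, mut_r, equal_var=th.equal_var)
            res[f"p_{tag}"] = p
            res[f"log2fc_decay_{tag}"] = lfc
            if p < th.p_threshold and np.isfinite(lfc) and abs(lfc) > th.lfc_threshold:
                passes_b = True
        # filter C: half-life change
        passes_c = False
        fw, fm = fits.loc[wt_id], fits.loc[mut_id]
        if not (bool(fw["converged"]) and bool(fm["converged"])):
            reason.append("decay fit did not converge on one side")
        else:
            hl_lfc = float(np.log2(fm["half_life"] / fw["half_life"]))
            res["log2fc_half_life"] = hl_lfc
            passes_c = abs(hl_lfc) > th.half_life_lfc_threshold
        res.update({"passes_A": passes_a, "passes_B": passes_b,
                    "passes_C": passes_c,
                    "significant": passes_a and passes_b and passes_c,
                    "reason": "; ".join(reason)})
        calls.append(res)
    return pd.DataFrame(calls), fits
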