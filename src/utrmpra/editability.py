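"""CRISPR base-editor feasibility filtering.

A candidate mutation is installable when (1) it is a transition — C→T and
G→A via a cytosine base editor (CBE), A→G and T→C via an adenine base editor
(ABE); (2) on the strand where the change reads C→T (CBE) or A→G (ABE) — the
strand that must carry the PAM — a PAM lies 3' of the edited base at a
distance of 13–18 nt; and (3) no bystander base of the same editable type
sits at a PAM distance in that range. Distance is counted as the number of
nucleotides strictly between the edited base and the first (protospacer-
proximal) base of the PAM, which places the edit at protospacer positions
~3–8 for a 20-nt spacer. Qualifying PAMs are ranked NGG, then NG, then the
engineered-variant PAMs, ties broken by the smaller distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import encode_seq, iupac_match_positions, normalize_seq, revcomp

TRANSITIONS = {("C", "T"), ("G", "A"), ("A", "G"), ("T", "C")}

#: PAM patterns in priority order
DEFAULT_PAMS = ("NGG", "NG", "NGAN", "NGCG", "NNGRRT", "NNNRRT")

PROTOSPACER_LENGTH = 20


@dataclass
class EditorSpec:
    """One base-editor system: edited base type, PAM repertoire, distance window."""

    editor_class: str  # "CBE" or "ABE"
    pam_patterns: tuple = DEFAULT_PAMS
    window_min: int = 13
    window_max: int = 18

    def __post_init__(self):
        if self.editor_class not in ("CBE", "ABE"):
            raise ValueError("editor_class must be CBE or ABE")
        if self.window_min > self.window_max:
            raise ValueError("window_min must be <= window_max")
        for p in self.pam_patterns:
            if set(p) - set("ACGTNR"):
                raise ValueError(f"PAM pattern {p!r} may only use A/C/G/T/N/R")

    @property
    def target_base(self) -> str:
        """Base edited on the PAM strand: C for CBE, A for ABE."""
        return "C" if self.editor_class == "CBE" else "A"


@dataclass
class EditabilityResult:
    mutation_key: str | None
    editable: bool
    editor_class: str | None = None
    strand: str | None = None
    pam_sequence: str | None = None
    pam_offset: int | None = None   # offset of the PAM's first base, input coordinates
    distance: int | None = None
    bystanders: int | None = None
    priority_rank: int | None = None
    protospacer: str | None = None
    reason: str = ""
    candidate_pams: list = field(default_factory=list)


def transition_filter(ref: str, alt: str) -> bool:
    """Keep only the four transitions a base editor can install."""
    return (normalize_seq(ref), normalize_seq(alt)) in TRANSITIONS


def resolve_strand(ref: str, alt: str):
    """(editor_class, PAM-carrying strand) for a transition given on the + strand.

    The change must read C→T (CBE) or A→G (ABE) on the strand carrying the
    PAM, so G→A and T→C send the search to the minus strand.
    """
    pair = (normalize_seq(ref), normalize_seq(alt))
    mapping = {("C", "T"): ("CBE", "+"), ("G", "A"): ("CBE", "-"),
               ("A", "G"): ("ABE", "+"), ("T", "C"): ("ABE", "-")}
    if pair not in mapping:
        raise ValueError(f"{ref}>{alt} is not a transition; no base editor applies")
    return mapping[pair]


def find_editable_sites(locus_seq: str, mutation_offset: int, ref: str, alt: str,
                        spec: EditorSpec | None = None) -> EditabilityResult:
    """Editability verdict for one mutation within its locus sequence.

    ``locus_seq`` is given 5'→3' on the + strand and must contain the
    mutation with enough flank for the distance window plus the longest PAM
    on both sides. ``spec`` defaults to the editor class implied by the base
    change with the full PAM repertoire.
    """
    seq = normalize_seq(locus_seq)
    ref = normalize_seq(ref)
    alt = normalize_seq(alt)
    key = f"{mutation_offset}:{ref}>{alt}"
    if not transition_filter(ref, alt):
        return EditabilityResult(key, False, reason="not a transition")
    if seq[mutation_offset] != ref:
        raise ValueError(f"locus has {seq[mutation_offset]} at offset "
                         f"{mutation_offset}, mutation ref is {ref}")
    editor_class, strand = resolve_strand(ref, alt)
    spec = spec or EditorSpec(editor_class)
    if spec.editor_class != editor_class:
        return EditabilityResult(key, False, editor_class=editor_class, strand=strand,
                                 reason=f"change requires {editor_class}, spec is "
                                        f"{spec.editor_class}")
    max_pam_len = max(len(p) for p in spec.pam_patterns)
    need = spec.window_max + 1 + max_pam_len
    if mutation_offset < need or len(seq) - mutation_offset - 1 < need:
        raise ValueError(f"locus must extend >= {need} nt on both sides of the "
                         f"mutation (window_max + PAM length)")

    # work on the PAM-carrying strand with the edit at position m
    if strand == "+":
        work = seq
        m = mutation_offset
    else:
        work = revcomp(seq)
        m = len(seq) - 1 - mutation_offset
    codes = encode_seq(work)
    assert work[m] == spec.target_base

    candidates = []
    for rank, pattern in enumerate(spec.pam_patterns):
        starts = iupac_match_positions(codes, pattern)
        for p in starts:
            d = int(p) - m - 1  # bases strictly between edit and first PAM base
            if not spec.window_min <= d <= spec.window_max:
                continue
            lo = int(p) - spec.window_max - 1
            hi = int(p) - spec.window_min - 1
            window = work[lo:hi + 1]
            bystanders = sum(1 for j, b in enumerate(window, start=lo)
                             if b == spec.target_base and j != m)
            candidates.append((rank, d, int(p), pattern, bystanders))
    candidates.sort(key=lambda c: (c[0], c[1]))
    clean = [c for c in candidates if c[4] == 0]
    if not clean:
        reason = ("no PAM at 13-18 nt" if not candidates
                  else "all qualifying PAMs have bystander edits")
        return EditabilityResult(key, False, editor_class=editor_class,
                                 strand=strand, reason=reason,
                                 candidate_pams=candidates)
    rank, d, p, pattern, bystanders = clean[0]
    pam_seq = work[p:p + len(pattern)]
    protospacer = work[max(0, p - PROTOSPACER_LENGTH):p]
    pam_offset = p if strand == "+" else len(seq) - 1 - p  # first PAM base, + coords
    return EditabilityResult(key, True, editor_class=editor_class, strand=strand,
                             pam_sequence=pam_seq, pam_offset=int(pam_offset),
                             distance=d, bystanders=0, priority_rank=rank,
                             protospacer=protospacer, candidate_pams=candidates)


def filter_candidates(mutations: pd.DataFrame, utrome,
                      effect_col: str = "effect_size",
                      significance_col: str = "significant") -> pd.DataFrame:
    """Editable subset of significant mutations, ranked by PAM priority then effect size.

    ``mutations`` needs columns utr_id, offset, ref, alt plus the significance
    flag; the UTR sequence serves as the locus.
    """
    by_id = {u.utr_id: u for u in utrome}
    rows = []
    for rec in mutations.itertuples(index=False):
        if significance_col in mutations.columns and not getattr(rec, significance_col):
            continue
        if not transition_filter(rec.ref, rec.alt):
            continue
        utr = by_id[rec.utr_id]
        try:
            res = find_editable_sites(utr.sequence, int(rec.offset), rec.ref, rec.alt)
        except ValueError:
            continue  # insufficient flank within the UTR
        if not res.editable:
            continue
        row = {c: getattr(rec, c) for c in mutations.columns}
        row.update({"editor_class": res.editor_class, "strand": res.strand,
                    "pam_sequence": res.pam_sequence, "pam_offset": res.pam_offset,
                    "distance": res.distance, "priority_rank": res.priority_rank,
                    "protospacer": res.protospacer})
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    sort_cols = ["priority_rank"]
    ascending = [True]
    if effect_col in out.columns:
        out["_abs_effect"] = out[effect_col].abs()
        sort_cols.append("_abs_effect")
        ascending.append(False)
    out = out.sort_values(sort_cols, ascending=ascending).drop(
        columns=["_abs_effect"], errors="ignore").reset_index(drop=True)
    return out
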