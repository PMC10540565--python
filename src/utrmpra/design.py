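"""MPRA reporter library design: paired WT/mutant 201-nt 3' UTR windows
around each mutation, plus control sequences.

The insert window is the 100 bases upstream and 100 bases downstream of the
mutated position, on the sense strand. Mutations closer than 100 nt to a UTR
boundary use supplied flanking genomic sequence when available, else the
window is shifted to stay inside the UTR (length preserved, mutation
off-center, offset recorded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core import mutation_key, normalize_seq, validate_dna
from .io import read_fasta, write_fasta

INSERT_LENGTH = 201
FLANK = 100

CONTROL_CATEGORIES = ("miRNA_seed_control", "repressor_activator_control",
                      "element_dose_control")


class DesignError(ValueError):
    pass


@dataclass
class InsertDesign:
    """A WT/mutant reporter pair (or a single control sequence).

    ``mutation_offset_in_insert`` is 1-based; 101 for a full centered window.
    Controls carry ``mutation_key=None`` and ``mut_seq=None``.
    """

    insert_id: str
    mutation_key: str | None
    wt_seq: str
    mut_seq: str | None
    mutation_offset_in_insert: int | None
    utr_id: str | None = None
    chrom: str | None = None
    window_start: int | None = None  # genomic, 0-based half-open
    window_end: int | None = None
    control_category: str | None = None

    @property
    def is_control(self) -> bool:
        return self.mutation_key is None

    def __post_init__(self):
        self.wt_seq = validate_dna(self.wt_seq, name=f"{self.insert_id} WT")
        if len(self.wt_seq) != INSERT_LENGTH:
            raise DesignError(
                f"{self.insert_id}: insert must be {INSERT_LENGTH} nt, "
                f"got {len(self.wt_seq)}")
        if self.mut_seq is not None:
            self.mut_seq = validate_dna(self.mut_seq, name=f"{self.insert_id} MUT")
            if len(self.mut_seq) != INSERT_LENGTH:
                raise DesignError(f"{self.insert_id}: mutant insert length mismatch")
            diffs = [i for i, (a, b) in enumerate(zip(self.wt_seq, self.mut_seq))
                     if a != b]
            if len(diffs) != 1:
                raise DesignError(
                    f"{self.insert_id}: WT and mutant must differ at exactly one "
                    f"position, found {len(diffs)}")
            if self.mutation_offset_in_insert != diffs[0] + 1:
                raise DesignError(
                    f"{self.insert_id}: recorded mutation offset "
                    f"{self.mutation_offset_in_insert} does not match the edited "
                    f"position {diffs[0] + 1}")


def design_insert_pair(utr, offset: int, ref: str, alt: str,
                       insert_id: str | None = None,
                       left_flank: str = "", right_flank: str = "") -> InsertDesign:
    """201-nt WT/mutant pair centered (when possible) on the mutation.

    ``left_flank``/``right_flank``: genomic sequence adjoining the UTR start
    and end, used when the mutation is within 100 nt of a boundary. Without
    flanks the window is shifted inside the UTR.
    """
    seq = utr.sequence
    ref = normalize_seq(ref)
    alt = normalize_seq(alt)
    if not 0 <= offset < len(seq):
        raise DesignError(f"mutation offset {offset} outside {utr.utr_id}")
    if seq[offset] != ref:
        raise DesignError(
            f"{utr.utr_id}:{offset}: UTR has {seq[offset]}, mutation ref is {ref}")
    left_flank = normalize_seq(left_flank) if left_flank else ""
    right_flank = normalize_seq(right_flank) if right_flank else ""

    ext = left_flank + seq + right_flank
    ext_off = offset + len(left_flank)
    a = ext_off - FLANK
    b = ext_off + FLANK + 1
    if a < 0 or b > len(ext):
        # shift the window to fit within the available sequence
        a = min(max(a, 0), len(ext) - INSERT_LENGTH)
        b = a + INSERT_LENGTH
        if a < 0:
            raise DesignError(
                f"{utr.utr_id}: only {len(ext)} nt available; cannot build a "
                f"{INSERT_LENGTH}-nt insert (supply flanking sequence)")
    wt = ext[a:b]
    pos_in_insert = ext_off - a
    mut = wt[:pos_in_insert] + alt + wt[pos_in_insert + 1:]
    key = mutation_key(utr.utr_id, offset, ref, alt)
    # genomic coordinates of the window (may extend past the UTR into flanks)
    gstart = utr.start - len(left_flank) + a
    return InsertDesign(
        insert_id=insert_id or key,
        mutation_key=key,
        wt_seq=wt,
        mut_seq=mut,
        mutation_offset_in_insert=pos_in_insert + 1,
        utr_id=utr.utr_id,
        chrom=utr.chrom,
        window_start=gstart,
        window_end=gstart + INSERT_LENGTH,
    )


def design_library(mutations: pd.DataFrame, utrome, flanks: dict | None = None) -> list:
    """One WT/mutant pair per mutation row (columns utr_id, offset, ref, alt)."""
    by_id = {u.utr_id: u for u in utrome}
    flanks = flanks or {}
    designs = []
    for k, rec in enumerate(mutations.itertuples(index=False)):
        utr = by_id[rec.utr_id]
        lf, rf = flanks.get(rec.utr_id, ("", ""))
        designs.append(design_insert_pair(
            utr, int(rec.offset), rec.ref, rec.alt,
            insert_id=f"ins{k + 1:05d}", left_flank=lf, right_flank=rf))
    return designs


def add_controls(control_specs) -> list:
    """Control inserts from (control_id, sequence, category) triples."""
    controls = []
    for control_id, seq, category in control_specs:
        if category not in CONTROL_CATEGORIES:
            raise DesignError(f"unknown control category {category!r}; "
                              f"expected one of {CONTROL_CATEGORIES}")
        seq = validate_dna(seq, name=control_id)
        if len(seq) != INSERT_LENGTH:
            raise DesignError(
                f"control {control_id} must be {INSERT_LENGTH} nt, got {len(seq)}")
        controls.append(InsertDesign(
            insert_id=control_id, mutation_key=None, wt_seq=seq, mut_seq=None,
            mutation_offset_in_insert=None, control_category=category))
    return controls


def library_sequences(designs):
    """Yield (sequence_id, sequence) for every library member (2 per pair, 1 per control)."""
    for d in designs:
        if d.is_control:
            yield d.insert_id, d.wt_seq
        else:
            yield f"{d.insert_id}_WT", d.wt_seq
            yield f"{d.insert_id}_MUT", d.mut_seq


def check_sequence_collisions(designs) -> list:
    """Sequence-identical library members (warning list; real libraries may collide)."""
    seen = {}
    collisions = []
    for sid, seq in library_sequences(designs):
        if seq in seen:
            collisions.append((seen[seq], sid))
        else:
            seen[seq] = sid
    return collisions


def write_library(designs, fasta_path, tsv_path) -> None:
    """FASTA of all member sequences + design table mapping ids to mutations."""
    ids = [d.insert_id for d in designs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise DesignError(f"duplicate insert ids: {dup}")
    collisions = check_sequence_collisions(designs)
    if collisions:
        warnings.warn(f"{len(collisions)} sequence collision(s) in library: "
                      f"{collisions[:5]}")
    write_fasta(library_sequences(designs), fasta_path)
    columns = ["insert_id", "mutation_key", "is_control", "control_category",
               "mutation_offset_in_insert", "utr_id", "chrom", "window_start",
               "window_end"]
    rows = []
    for d in designs:
        rows.append({
            "insert_id": d.insert_id,
            "mutation_key": d.mutation_key if d.mutation_key else "",
            "is_control": d.is_control,
            "control_category": d.control_category or "",
            "mutation_offset_in_insert":
                d.mutation_offset_in_insert if d.mutation_offset_in_insert else "",
            "utr_id": d.utr_id or "", "chrom": d.chrom or "",
            "window_start": "" if d.window_start is None else d.window_start,
            "window_end": "" if d.window_end is None else d.window_end,
        })
    pd.DataFrame(rows, columns=columns).to_csv(tsv_path, sep="\t", index=False)


def read_library(fasta_path, tsv_path) -> list:
    """Inverse of :func:`write_library`."""
    seqs = read_fasta(fasta_path)
    table = pd.read_csv(tsv_path, sep="\t", keep_default_na=False)
    designs = []
    for rec in table.itertuples(index=False):
        if bool(rec.is_control):
            designs.append(InsertDesign(
                insert_id=rec.insert_id, mutation_key=None,
                wt_seq=seqs[rec.insert_id], mut_seq=None,
                mutation_offset_in_insert=None,
                control_category=rec.control_category or None))
        else:
            designs.append(InsertDesign(
                insert_id=rec.insert_id, mutation_key=rec.mutation_key,
                wt_seq=seqs[f"{rec.insert_id}_WT"],
                mut_seq=seqs[f"{rec.insert_id}_MUT"],
                mutation_offset_in_insert=int(rec.mutation_offset_in_insert),
                utr_id=rec.utr_id or None, chrom=rec.chrom or None,
                window_start=int(rec.window_start) if rec.window_start != "" else None,
                window_end=int(rec.window_end) if rec.window_end != "" else None))
    return designs


def design_pairs_table(designs) -> pd.DataFrame:
    """Pair table (pair_id, mutation_key, wt_id, mut_id) for the MPRA statistics stages."""
    rows = [{"pair_id": d.insert_id, "mutation_key": d.mutation_key,
             "wt_id": f"{d.insert_id}_WT", "mut_id": f"{d.insert_id}_MUT"}
            for d in designs if not d.is_control]
    return pd.DataFrame(rows, columns=["pair_id", "mutation_key", "wt_id", "mut_id"])
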