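"""Shared sequence primitives and domain records.

Sequences are handled as DNA strings (A/C/G/T) in sense-strand (mRNA)
orientation; RNA input is accepted anywhere and U is treated as T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHN", "TGCAYRMKVBHDN")

# IUPAC nucleotide codes -> the set of bases they match
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i


class SequenceError(ValueError):
    """A sequence violates the expected alphabet or structure."""


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def validate_dna(seq: str, *, name: str = "sequence") -> str:
    s = normalize_seq(seq)
    if not s:
        raise SequenceError(f"{name} is empty")
    if set(s) - set(DNA_BASES):
        bad = sorted(set(s) - set(DNA_BASES))
        raise SequenceError(f"{name} contains non-ACGT characters: {bad}")
    return s


def revcomp(seq: str) -> str:
    return normalize_seq(seq).translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string to uint8 indices (A=0, C=1, G=2, T=3)."""
    codes = _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise SequenceError("sequence contains non-ACGT characters")
    return codes


def gc_fraction(seq: str) -> float:
    s = validate_dna(seq)
    return (s.count("G") + s.count("C")) / len(s)


def iupac_match_positions(seq_codes: np.ndarray, pattern: str) -> np.ndarray:
    """0-based start positions where ``pattern`` (IUPAC) matches the encoded sequence."""
    pattern = normalize_seq(pattern)
    L = len(pattern)
    if L == 0 or L > seq_codes.size:
        return np.empty(0, dtype=np.int64)
    allowed = np.zeros((L, 4), dtype=bool)
    for j, code in enumerate(pattern):
        try:
            for b in IUPAC[code]:
                allowed[j, _BASE_INDEX[b]] = True
        except KeyError:
            raise SequenceError(f"unknown IUPAC code {code!r} in pattern {pattern!r}")
    windows = np.lib.stride_tricks.sliding_window_view(seq_codes, L)
    ok = allowed[np.arange(L)[None, :], windows].all(axis=1)
    return np.flatnonzero(ok)


@dataclass(frozen=True)
class UtrRecord:
    """One 3' UTR: genomic interval (0-based, half-open) plus its sense-strand sequence."""

    utr_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.utr_id}: sequence length {len(self.sequence)} != "
                f"end - start = {self.end - self.start}"
            )
        object.__setattr__(self, "sequence", validate_dna(self.sequence, name=self.utr_id))

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Planted truth behind a synthetic dataset, for downstream validation."""

    seed: int
    planted_mutations: list = field(default_factory=list)   # (utr_id, offset, ref, alt)
    planted_motif_sites: list = field(default_factory=list)  # (utr_id, offset, motif_id)
    motif_overlap_keys: list = field(default_factory=list)   # mutation keys placed in motif sites
    alphas: dict = field(default_factory=dict)               # insert_id -> true decay rate (1/h)
    te_multipliers: dict = field(default_factory=dict)       # insert_id -> true TE multiplier
    caller_params: dict = field(default_factory=dict)


def mutation_key(utr_id: str, offset: int, ref: str, alt: str) -> str:
    return f"{utr_id}:{offset}:{ref}>{alt}"
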