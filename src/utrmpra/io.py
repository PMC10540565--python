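"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Bio.SeqIO; everything else is TSV (pandas) or a simple
block-structured PWM text format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import UtrRecord


def write_fasta(records, path) -> None:
    """``records``: iterable of (id, sequence) pairs."""
    seqs = [SeqRecord(Seq(seq), id=str(name), description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_utrome(utrs, fasta_path, bed_path) -> None:
    """Write UTR sequences (FASTA) and coordinates (BED6, 0-based half-open)."""
    write_fasta(((u.utr_id, u.sequence) for u in utrs), fasta_path)
    with open(bed_path, "w") as fh:
        for u in utrs:
            fh.write(f"{u.chrom}\t{u.start}\t{u.end}\t{u.utr_id}\t0\t{u.strand}\n")


def read_utrome(fasta_path, bed_path) -> list:
    seqs = read_fasta(fasta_path)
    utrs = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            utrs.append(UtrRecord(name, chrom, int(start), int(end), strand, seqs[name]))
    return utrs


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_counts(counts: pd.DataFrame, samples: pd.DataFrame, counts_path, samples_path) -> None:
    counts.to_csv(counts_path, sep="\t", index=True, index_label="insert_id")
    samples.to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path, samples_path):
    counts = pd.read_csv(counts_path, sep="\t", index_col="insert_id")
    samples = pd.read_csv(samples_path, sep="\t")
    return counts, samples


def write_pwms(pwms: dict, path) -> None:
    """One motif per block: '>id<TAB>category<TAB>source' then four rows A/C/G/T of probabilities."""
    with open(path, "w") as fh:
        for motif_id, (category, source, matrix) in pwms.items():
            matrix = np.asarray(matrix, dtype=float)
            fh.write(f">{motif_id}\t{category}\t{source}\n")
            for row, base in zip(matrix, "ACGT"):
                fh.write(base + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_pwms(path) -> dict:
    """Inverse of :func:`write_pwms`; returns {motif_id: (category, source, 4xL array)}."""
    pwms = {}
    with open(path) as fh:
        block = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                fields = line[1:].split("\t")
                motif_id = fields[0]
                category = fields[1] if len(fields) > 1 else "RBP_PWM"
                source = fields[2] if len(fields) > 2 else ""
                block = {"id": motif_id, "category": category, "source": source, "rows": {}}
                pwms[motif_id] = block
            else:
                base, *vals = line.split("\t")
                block["rows"][base] = [float(v) for v in vals]
    out = {}
    for motif_id, block in pwms.items():
        matrix = np.array([block["rows"][b] for b in "ACGT"])
        out[motif_id] = (block["category"], block["source"], matrix)
    return out


def read_seed_list(path) -> pd.DataFrame:
    """miRNA seed list TSV: mirna_id, seed_sequence, expression_rank."""
    df = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "seed_sequence", "expression_rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"seed list missing columns: {sorted(missing)}")
    return df


def read_conservation_track(path) -> pd.DataFrame:
    """bedGraph-like TSV with columns chrom, start, end, score (0-based half-open)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "score"])
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["score"] = df["score"].astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed conservation track {path}: {exc}") from exc
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
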