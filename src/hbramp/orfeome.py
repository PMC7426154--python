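"""Reading CDS collections, quality control, and the left-aligned codon matrix.

An ORFeome is the complete set of coding sequences (CDSs) of a genome,
supplied as a multi-FASTA with one record per gene.  Before positional
analysis each CDS must pass quality control: its length must be divisible
by 3 and, after removal of the start codon, it must still cover the full
analysis window (100 or 250 codons) with no ambiguous base inside that
window.  Retained CDSs are left-aligned from the 5' end into a codon
matrix whose column ``j`` holds every CDS's codon at original position
``j + 2`` (position 1 is the start codon, which never enters any analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import CODON_INDEX

__all__ = [
    "Orfeome",
    "CodonMatrix",
    "CdsComposition",
    "read_orfeome",
    "qc_filter",
    "build_codon_matrix",
    "composition",
    "encode_cds",
    "encode_full",
]

_VALID = set("ACGT")


@dataclass
class Orfeome:
    """Ordered collection of (cds_id, DNA sequence) pairs."""

    ids: list[str]
    seqs: list[str]
    provenance: str = ""

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")
        dupes = pd.Index(self.ids)[pd.Index(self.ids).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate CDS id: {dupes[0]!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.seqs))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for cid, seq in self:
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def read_orfeome(path, provenance: str | None = None) -> Orfeome:
    """Load a multi-FASTA of CDSs: uppercased, whitespace-free, U mapped to T.

    Raises on an empty file and on duplicate record ids.
    """
    path = Path(path)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper().replace("U", "T"))
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    return Orfeome(ids, seqs, provenance or str(path))


def qc_filter(orfeome: Orfeome, n_positions: int = 100) -> tuple[Orfeome, pd.DataFrame]:
    """Apply CDS quality control for an analysis window of ``n_positions`` codons.

    A CDS is retained iff its length is divisible by 3, it has at least
    ``n_positions + 1`` codons (the start codon is removed before analysis),
    and no ambiguous base occurs within the analyzed window (codons 2 to
    ``n_positions + 1``).

    Returns the filtered ORFeome and a rejection log with columns
    (cds_id, reason).  Raises if nothing survives.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    keep_ids, keep_seqs, rejects = [], [], []
    for cid, seq in orfeome:
        if len(seq) % 3 != 0:
            rejects.append((cid, "length not divisible by 3"))
            continue
        if len(seq) // 3 < n_positions + 1:
            rejects.append((cid, f"fewer than {n_positions} codons after start removal"))
            continue
        window = seq[3 : 3 * (n_positions + 1)]
        if not _VALID.issuperset(window):
            rejects.append((cid, "ambiguous base in analyzed window"))
            continue
        keep_ids.append(cid)
        keep_seqs.append(seq)
    log = pd.DataFrame(rejects, columns=["cds_id", "reason"])
    if not keep_ids:
        raise ValueError("empty ORFeome after QC")
    return Orfeome(keep_ids, keep_seqs, orfeome.provenance), log


@dataclass
class CodonMatrix:
    """Left-aligned codon-index matrix over the analysis window.

    ``codes[i, j]`` is the codon index (0..63) of CDS ``i`` at original
    codon position ``j + position_offset``; ``position_offset`` is 2
    because the start codon is dropped.
    """

    cds_ids: list[str]
    codes: np.ndarray  # (n_cds, n_positions) int
    position_offset: int = 2

    @property
    def n_positions(self) -> int:
        return self.codes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        """Original codon positions of the columns (2, 3, ...)."""
        return np.arange(self.n_positions) + self.position_offset

    def __len__(self) -> int:
        return self.codes.shape[0]

    def row_codons(self, i: int) -> list[str]:
        from .genetic_code import CODONS

        return [CODONS[k] for k in self.codes[i]]

    def to_tsv(self, path) -> None:
        from .genetic_code import CODONS

        arr = np.array(CODONS)[self.codes]
        df = pd.DataFrame(arr, index=self.cds_ids, columns=[f"P{p}" for p in self.positions])
        df.to_csv(path, sep="\t", index_label="cds_id")


def encode_cds(seq: str, *, ambiguous: dict[str, int] | None = None) -> np.ndarray:
    """Encode a CDS (start codon removed) as codon indices.

    Codons containing non-ACGT characters receive stable indices >= 64,
    one per distinct codon string (``ambiguous`` registry, grown in place),
    so that each stays a fixed singleton under synonymous shuffling.
    """
    if len(seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    body = seq[3:]
    out = np.empty(len(body) // 3, dtype=np.int64)
    for j in range(out.size):
        codon = body[3 * j : 3 * j + 3]
        idx = CODON_INDEX.get(codon)
        if idx is None:
            if ambiguous is None:
                raise ValueError(f"ambiguous codon {codon!r} at position {j + 2}")
            idx = ambiguous.setdefault(codon, 64 + len(ambiguous))
        out[j] = idx
    return out


def encode_full(orfeome: Orfeome) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Pad-encode all CDSs (start codon removed) into one matrix.

    Returns (codes, lengths, ambiguous_registry); padding value is -1.
    """
    amb: dict[str, int] = {}
    rows = [encode_cds(s, ambiguous=amb) for s in orfeome.seqs]
    lengths = np.array([r.size for r in rows])
    codes = np.full((len(rows), int(lengths.max())), -1, dtype=np.int64)
    for i, r in enumerate(rows):
        codes[i, : r.size] = r
    return codes, lengths, amb


def build_codon_matrix(orfeome: Orfeome, n_positions: int = 100) -> CodonMatrix:
    """Left-align QC-passed CDSs into a matrix of ``n_positions`` codons.

    The start codon is removed first: column 0 is original position 2.
    """
    codes = np.empty((len(orfeome), n_positions), dtype=np.int64)
    for i, (cid, seq) in enumerate(orfeome):
        row = encode_cds(seq[: 3 * (n_positions + 1)])
        if row.size < n_positions:
            raise ValueError(f"CDS {cid!r} shorter than window; run qc_filter first")
        codes[i] = row[:n_positions]
    return CodonMatrix(list(orfeome.ids), codes)


@dataclass
class CdsComposition:
    """Length and GC statistics of one CDS.

    gc1/gc2/gc3 are GC fractions at codon positions 1/2/3; the ratio
    gc3/gc serves as a mutational-bias indicator.
    """

    length_nt: int
    gc: float
    gc1: float
    gc2: float
    gc3: float

    @property
    def mutational_bias(self) -> float:
        return self.gc3 / self.gc


def composition(seq: str) -> CdsComposition:
    """GC content overall and per codon sub-position of one CDS."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if len(seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_gc = (arr == b"G") | (arr == b"C")
    gcs = [float(is_gc[k::3].mean()) for k in range(3)]
    return CdsComposition(
        length_nt=len(seq),
        gc=float(is_gc.mean()),
        gc1=gcs[0],
        gc2=gcs[1],
        gc3=gcs[2],
    )
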