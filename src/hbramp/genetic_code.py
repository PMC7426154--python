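"""Genetic code, per-codon hydrogen-bond accounting, and codon classification.

A codon of double-stranded DNA holds one Watson-Crick pair per base:
A:T pairs form two hydrogen bonds, G:C pairs three.  Every codon therefore
carries between 6 (e.g. TTA) and 9 (e.g. GCG) hydrogen bonds, and synonymous
codon choice can trade bonds away: within the leucine family the count drops
from 8 (CTG) to 6 (TTA), a 25% reduction, the largest the standard code
allows.

Codons with 6-7 bonds are called *cheap*, codons with 8-9 bonds *expensive*:
unwinding cheap codons during transcription costs less energy.

The standard genetic code (NCBI translation table 1) is taken from
Biopython.  Codons are indexed 0..63 in TCAG order with the third base
cycling fastest (TTT, TTC, TTA, TTG, TCT, ...), the conventional order of
codon-usage and tRNA-adaptation tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "CODONS",
    "CODON_INDEX",
    "STOP",
    "CodonTable",
    "STANDARD_TABLE",
    "hbond_count",
    "hbond_class",
    "relative_hbond",
    "scaled_hbond",
    "max_synonymous_reduction",
]

#: hydrogen bonds of the base pair each nucleotide forms in dsDNA
HBOND_PER_BASE = {"A": 2, "T": 2, "G": 3, "C": 3}

#: symbol used for stop codons
STOP = "*"

_BASES = "TCAG"

#: the 64 codons in TCAG order, third base fastest
CODONS: tuple[str, ...] = tuple(
    a + b + c for a, b, c in itertools.product(_BASES, repeat=3)
)

#: codon string -> index 0..63
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}


class AmbiguousCodonError(ValueError):
    """Raised when a codon contains a base outside {A, C, G, T}."""


def normalize_codon(codon: str) -> str:
    """Uppercase a codon and map U to T; raise on ambiguity.

    Raises
    ------
    AmbiguousCodonError
        If the normalized codon is not three characters over {A,C,G,T}.
    """
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in HBOND_PER_BASE for b in c):
        raise AmbiguousCodonError(f"ambiguous codon: {codon!r}")
    return c


def _standard_codon_to_aa() -> dict[str, str]:
    table = _BioCodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    # Biopython's forward_table omits stops; everything else is present.
    assert len(mapping) == 64
    return mapping


@dataclass(frozen=True)
class CodonTable:
    """Genetic code plus hydrogen-bond bookkeeping.

    Attributes
    ----------
    codon_to_aa : dict
        All 64 codons mapped to one-letter amino acid or ``"*"`` for stop.
    hbond_per_base : dict
        Base -> bonds of its Watson-Crick pair (A=T=2, G=C=3).
    synonym_families : dict
        Amino acid (or ``"*"``) -> frozenset of its codons.  Stop codons
        form their own family and are excluded from degenerate-amino-acid
        queries such as :func:`max_synonymous_reduction`.
    """

    codon_to_aa: dict[str, str] = field(default_factory=_standard_codon_to_aa)
    hbond_per_base: dict[str, int] = field(default_factory=lambda: dict(HBOND_PER_BASE))

    def __post_init__(self):
        fams: dict[str, set[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            fams.setdefault(aa, set()).add(codon)
        object.__setattr__(
            self, "synonym_families", {aa: frozenset(cs) for aa, cs in fams.items()}
        )
        # vectorized lookups, indexed by codon index 0..63
        hb = np.array([self.hbond_count(c) for c in CODONS], dtype=np.int64)
        object.__setattr__(self, "hbond_by_index", hb)
        aas = sorted(self.synonym_families)  # '*' sorts first
        aa_ids = {aa: i for i, aa in enumerate(aas)}
        object.__setattr__(self, "aa_order", aas)
        object.__setattr__(
            self,
            "aa_id_by_index",
            np.array([aa_ids[self.codon_to_aa[c]] for c in CODONS], dtype=np.int64),
        )
        object.__setattr__(self, "cheap_by_index", hb <= 7)

    synonym_families: dict[str, frozenset] = field(init=False)
    hbond_by_index: np.ndarray = field(init=False)
    aa_id_by_index: np.ndarray = field(init=False)
    aa_order: list = field(init=False)
    cheap_by_index: np.ndarray = field(init=False)

    # -- per-codon valuations -------------------------------------------------

    def hbond_count(self, codon: str) -> int:
        """Hydrogen bonds in a codon: the sum of its three per-base counts."""
        c = normalize_codon(codon)
        return sum(self.hbond_per_base[b] for b in c)

    def hbond_class(self, codon: str) -> str:
        """``"cheap"`` for 6-7 bonds, ``"expensive"`` for 8-9."""
        return "cheap" if self.hbond_count(codon) <= 7 else "expensive"

    def relative_hbond(self, codon: str) -> float:
        """Bond count divided by the maximum within the codon's synonym family.

        Defined for amino-acid-coding codons only.
        """
        c = normalize_codon(codon)
        aa = self.codon_to_aa[c]
        if aa == STOP:
            raise ValueError(f"stop codon {c} has no amino-acid family")
        fam_max = max(self.hbond_count(s) for s in self.synonym_families[aa])
        return self.hbond_count(c) / fam_max

    def scaled_hbond(self, codon: str) -> float | None:
        """Bond count centered and scaled within the synonym family.

        Uses the sample standard deviation over the family's codons.
        Returns ``None`` for families without spread (Met, Trp, and stops
        with equal counts), where the value is undefined.
        """
        c = normalize_codon(codon)
        aa = self.codon_to_aa[c]
        if aa == STOP:
            raise ValueError(f"stop codon {c} has no amino-acid family")
        counts = np.array(sorted(self.hbond_count(s) for s in self.synonym_families[aa]), float)
        if counts.size < 2 or np.ptp(counts) == 0:
            return None
        return float((self.hbond_count(c) - counts.mean()) / counts.std(ddof=1))

    def max_synonymous_reduction(self) -> float:
        """Largest percent reduction in bond count achievable synonymously.

        max over degenerate amino acids of 100*(1 - min/max family bonds);
        25.0 for the standard code (attained by leucine).
        """
        best = 0.0
        for aa, fam in self.synonym_families.items():
            if aa == STOP or len(fam) < 2:
                continue
            counts = [self.hbond_count(c) for c in fam]
            best = max(best, 100.0 * (1.0 - min(counts) / max(counts)))
        return best

    def encode(self, codon: str) -> int:
        """Codon string -> index 0..63."""
        return CODON_INDEX[normalize_codon(codon)]


#: the shared standard-code instance used throughout the package
STANDARD_TABLE = CodonTable()


# module-level conveniences bound to the standard code
def hbond_count(codon: str) -> int:
    return STANDARD_TABLE.hbond_count(codon)


def hbond_class(codon: str) -> str:
    return STANDARD_TABLE.hbond_class(codon)


def relative_hbond(codon: str) -> float:
    return STANDARD_TABLE.relative_hbond(codon)


def scaled_hbond(codon: str) -> float | None:
    return STANDARD_TABLE.scaled_hbond(codon)


def max_synonymous_reduction() -> float:
    return STANDARD_TABLE.max_synonymous_reduction()
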