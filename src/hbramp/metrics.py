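"""Per-codon valuations for positional profiling: RSCU, CAI, tAI, mRNA structure.

RSCU (relative synonymous codon usage) is a codon's observed count divided
by the mean count of its synonyms; CAI weights divide RSCU by the family
maximum.  Both are computed from the codon-usage table of the whole input
ORFeome (an optional reference set can be supplied instead).

tAI (tRNA adaptation index) weights derive from tRNA gene copy numbers
(tGCN): a codon's absolute adaptiveness is the sum over recognizing
anticodons of (1 - s) * tGCN, where s is the selective constraint of the
codon:anticodon wobble pair.  The nine s values are, in order: the four
Watson-Crick third-position pairs T:A, C:G, A:T, G:C, then the wobble pairs
T:G, C:A(I), A:A(I), G:T, and finally the bacterial lysidine pairing of ATA
(applied when ``sking=1``, i.e. Bacteria/Archaea).  Weights are the
adaptiveness values normalized by their maximum; codons with zero coverage
receive the geometric mean of the nonzero weights.

The mRNA-structure adapter parses per-base unpaired probabilities produced
by an external RNA-folding tool (window-averaged partition-function output
in the "_lunp" tabular dialect); it never runs the tool itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import CODONS, CODON_INDEX, STOP, STANDARD_TABLE
from .profiles import PositionalProfile, positional_profile

__all__ = [
    "CodonWeights",
    "TrnaPool",
    "UnpairedProfile",
    "rscu",
    "cai_weights",
    "tai_weights",
    "read_trna_pool",
    "read_unpaired_probabilities",
    "positional_metric",
    "S_PROKARYOTE",
]

#: default selective-constraint vector (override via TrnaPool.s_vector;
#: published variants differ between domains of life)
S_PROKARYOTE = (0.0, 0.0, 0.0, 0.0, 0.41, 0.28, 0.9999, 0.68, 0.89)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CodonWeights:
    """A named per-codon valuation.

    ``weight`` maps the 61 sense codons to nonnegative values; codons
    containing an undetermined nucleotide are assigned ``ambiguous_value``
    (1, meaning "no bias") when applied to sequences.
    """

    metric_name: str
    weight: dict[str, float]
    ambiguous_value: float = 1.0
    flagged: list[str] = field(default_factory=list)

    def vector(self, stop_value: float | None = None) -> np.ndarray:
        """Length-64 vector indexed by codon index.

        Codons without a weight (stops, for usage-based metrics) receive
        ``stop_value``, defaulting to the no-bias ``ambiguous_value``.
        """
        fill = self.ambiguous_value if stop_value is None else stop_value
        return np.array([self.weight.get(c, fill) for c in CODONS])


def codon_usage(orfeome, drop_start: bool = True) -> dict[str, int]:
    """Codon counts over all CDSs of an ORFeome (start codons excluded)."""
    counts = dict.fromkeys(CODONS, 0)
    for _, seq in orfeome:
        start = 3 if drop_start else 0
        for j in range(start, len(seq) - len(seq) % 3, 3):
            codon = seq[j : j + 3]
            if codon in counts:
                counts[codon] += 1
    return counts


def rscu(orfeome_or_counts) -> CodonWeights:
    """Relative synonymous codon usage from an ORFeome or a usage table.

    For codon c in a family of k synonyms, RSCU = count(c) / mean family
    count; family means are 1 by construction.  Amino acids absent from
    the input get RSCU 1 for all their codons and are flagged.
    """
    counts = (
        dict(orfeome_or_counts)
        if isinstance(orfeome_or_counts, dict)
        else codon_usage(orfeome_or_counts)
    )
    weights: dict[str, float] = {}
    flagged: list[str] = []
    for aa, fam in STANDARD_TABLE.synonym_families.items():
        if aa == STOP:
            continue
        fam = sorted(fam)
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            weights.update({c: 1.0 for c in fam})
            flagged.append(aa)
            continue
        mean = total / len(fam)
        weights.update({c: counts.get(c, 0) / mean for c in fam})
    return CodonWeights("rscu", weights, flagged=flagged)


def cai_weights(rscu_weights: CodonWeights) -> CodonWeights:
    """CAI relative adaptiveness: RSCU divided by the family maximum."""
    weights: dict[str, float] = {}
    for aa, fam in STANDARD_TABLE.synonym_families.items():
        if aa == STOP:
            continue
        fam = sorted(fam)
        fam_max = max(rscu_weights.weight[c] for c in fam)
        if fam_max == 0:
            weights.update({c: 1.0 for c in fam})
            continue
        weights.update({c: rscu_weights.weight[c] / fam_max for c in fam})
    return CodonWeights("cai", weights, flagged=list(rscu_weights.flagged))


@dataclass
class TrnaPool:
    """tRNA gene copy numbers by anticodon (DNA alphabet, 5'->3').

    ``sking`` is 1 for Bacteria/Archaea (enables the lysidine pathway for
    the ATA codon) and 0 for eukaryotes.
    """

    tgcn: dict[str, int]
    s_vector: tuple = S_PROKARYOTE
    sking: int = 1

    def __post_init__(self):
        if len(self.s_vector) != 9:
            raise ValueError("s_vector must have nine entries")
        self.tgcn = {k.upper().replace("U", "T"): int(v) for k, v in self.tgcn.items()}
        if any(v < 0 for v in self.tgcn.values()):
            raise ValueError("tGCN must be >= 0")


def read_trna_pool(path, **kwargs) -> TrnaPool:
    """Read a TSV with columns (anticodon, tgcn)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "anticodon" not in cols or "tgcn" not in cols:
        raise ValueError(f"tRNA pool TSV {path} needs columns (anticodon, tgcn)")
    return TrnaPool(dict(zip(df[cols["anticodon"]], df[cols["tgcn"]])), **kwargs)


def tai_weights(pool: TrnaPool) -> CodonWeights:
    """tAI codon weights from a tRNA pool via the standard wobble recursion.

    Codons are walked in boxes of four (third base T, C, A, G); within each
    box the perfectly matching anticodon contributes with the Watson-Crick
    constraint and one wobble anticodon contributes with its wobble
    constraint (G:U wobble for T- and G-ending codons, inosine for C- and
    A-ending codons).  ATG keeps only its dedicated initiator/elongator
    match, and under ``sking=1`` ATA is read by the lysidine-modified tRNA.
    Weights are normalized over the 61 sense codons.
    """
    p = 1.0 - np.asarray(pool.s_vector)
    # tGCN of the perfectly matching anticodon, in codon order
    t = np.array([pool.tgcn.get(_revcomp(c), 0) for c in CODONS], dtype=float)
    W = np.zeros(64)
    for i in range(0, 64, 4):
        W[i + 0] = p[0] * t[i + 0] + p[4] * t[i + 1]  # NNT: WC + G:U wobble
        W[i + 1] = p[1] * t[i + 1] + p[5] * t[i + 0]  # NNC: WC + inosine
        W[i + 2] = p[2] * t[i + 2] + p[6] * t[i + 0]  # NNA: WC + inosine
        W[i + 3] = p[3] * t[i + 3] + p[7] * t[i + 2]  # NNG: WC + U:G wobble
    W[CODON_INDEX["ATG"]] = p[3] * t[CODON_INDEX["ATG"]]
    if pool.sking == 1:
        W[CODON_INDEX["ATA"]] = p[8]
    sense = [c for c in CODONS if STANDARD_TABLE.codon_to_aa[c] != STOP]
    w = {c: W[CODON_INDEX[c]] for c in sense}
    w_max = max(w.values())
    if w_max == 0:
        raise ValueError("empty tRNA pool coverage: all adaptiveness values are zero")
    w = {c: v / w_max for c, v in w.items()}
    zeros = [c for c, v in w.items() if v == 0]
    if zeros:
        nz = np.array([v for v in w.values() if v > 0])
        gm = float(np.exp(np.mean(np.log(nz))))
        w.update({c: gm for c in zeros})
    return CodonWeights("tai", w, flagged=zeros)


@dataclass
class UnpairedProfile:
    """Per-base and per-codon probabilities of being unpaired in the mRNA.

    The per-codon unpaired probability is the mean over its three bases;
    the structure-formation probability is its complement.
    """

    base_unpaired: np.ndarray

    def __post_init__(self):
        self.base_unpaired = np.asarray(self.base_unpaired, dtype=float)
        if np.any((self.base_unpaired < 0) | (self.base_unpaired > 1)):
            raise ValueError("unpaired probabilities must lie in [0, 1]")

    @property
    def codon_unpaired(self) -> np.ndarray:
        n = self.base_unpaired.size // 3
        return self.base_unpaired[: 3 * n].reshape(n, 3).mean(axis=1)

    @property
    def codon_structure(self) -> np.ndarray:
        return 1.0 - self.codon_unpaired


def read_unpaired_probabilities(path, mode: str = "containing") -> UnpairedProfile:
    """Parse a per-position unpaired-probability table ("_lunp" dialect).

    Each data row is: position i, then the probabilities that the stretch
    of length u ending at i (u = 1..u_max) is unpaired; missing values are
    "NA".  The per-base unpaired probability is the mean over

    - ``mode="containing"`` (default): all finite entries whose stretch
      contains the base, or
    - ``mode="ending"``: the finite entries of the base's own row
      (stretches ending at the base).
    """
    if mode not in ("containing", "ending"):
        raise ValueError("mode must be 'containing' or 'ending'")
    rows: dict[int, np.ndarray] = {}
    width = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                i = int(parts[0])
                vals = np.array([np.nan if v.upper() == "NA" else float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed table at line {ln}: {exc}") from None
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{path}: probability outside [0, 1] at line {ln}")
            rows[i] = vals
            width = max(width, vals.size)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    n = max(rows)
    if mode == "ending":
        base = np.full(n, np.nan)
        for i, vals in rows.items():
            base[i - 1] = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
        return UnpairedProfile(np.nan_to_num(base, nan=0.0))
    sums = np.zeros(n)
    counts = np.zeros(n)
    for i, vals in rows.items():
        for u, v in enumerate(vals, start=1):
            if np.isfinite(v):
                lo = max(i - u, 0)  # stretch covers bases (i-u+1)..i, 1-based
                sums[lo:i] += v
                counts[lo:i] += 1
    with np.errstate(invalid="ignore"):
        base = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return UnpairedProfile(base)


def positional_metric(
    matrix, weights: CodonWeights, n_boot: int = 1000, seed=0
) -> PositionalProfile:
    """Positional profile of a codon-weight table over a codon matrix."""
    return positional_profile(
        matrix,
        weights.vector(),
        n_boot=n_boot,
        seed=seed,
        metric_name=weights.metric_name,
    )
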