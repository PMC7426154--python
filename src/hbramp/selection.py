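"""Synonymous-shuffling null model and position-wise selection statistics.

The null model asks: if each CDS kept its amino-acid sequence and its
codon composition but scattered its synonymous codons randomly along its
length, what per-position hydrogen-bond totals would the ORFeome show?
Shuffling is applied to full-length CDSs (synonyms can move into and out
of the analysis window); 200 shuffled ORFeomes yield the expected total E
and its standard deviation sigma at every position.

Against that null, per position:

    z^2     = ((O - E) / sigma)^2          (chi^2 = sum of z^2)
    chigram = (O - E) / E                  (the "hanging chi-gram"; sign
                                            gives the direction of selection)

with min-max-normalized z^2 and centered-and-scaled chi-gram variants for
cross-ORFeome comparison.  O is the per-position SUM of hydrogen bonds
over CDSs.  Positions with sigma = 0 (nothing for shuffling to move)
contribute z^2 = 0 and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import CODON_INDEX, STANDARD_TABLE
from .orfeome import Orfeome, CodonMatrix, encode_full

__all__ = [
    "SelectionProfile",
    "shuffle_synonymous",
    "null_distribution",
    "observed_totals",
    "selection_profile",
    "ramp_of_selection",
    "min_max",
]

_PAD_AA = np.int64(10**6)


def _aa_ids_for(codes: np.ndarray) -> np.ndarray:
    """Synonym-family ids for padded codon codes.

    Standard codons map to their amino-acid family (stops form their own
    family); ambiguous codons (codes >= 64) and padding (-1) are singleton
    families and therefore fixed points of the shuffle.
    """
    aa = np.where(codes >= 0, codes, _PAD_AA)
    std = codes >= 0
    amb = codes >= 64
    aa[std & ~amb] = STANDARD_TABLE.aa_id_by_index[codes[std & ~amb]]
    aa[amb] = 100 + codes[amb]  # one family per distinct ambiguous codon
    return aa


class _GroupShuffler:
    """Uniform within-(row, synonym-family) permutations of a codon matrix.

    Slots of each group are enumerated once in positional order; each
    draw orders the group's values by iid random keys (a uniform random
    permutation per group) and writes them back into the slots.  The
    composite sort key packs the group id into the high and a random
    32-bit integer into the low half of an int64, so one argsort per
    draw suffices.
    """

    def __init__(self, codes: np.ndarray, aa: np.ndarray):
        self.codes = codes
        self.shape = codes.shape
        flat_aa = aa.ravel()
        n, L = codes.shape
        rows = np.repeat(np.arange(n, dtype=np.int64), L)
        _, compact = np.unique(flat_aa, return_inverse=True)
        n_groups = int(compact.max()) + 1
        self._base = (rows * n_groups + compact) << 32
        self._slots = np.argsort(self._base, kind="stable")
        self._flat = codes.ravel()

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        key = self._base + rng.integers(0, 1 << 32, size=self._base.size, dtype=np.int64)
        out = np.empty_like(self._flat)
        out[self._slots] = self._flat[np.argsort(key, kind="stable")]
        return out.reshape(self.shape)


def _shuffle_codes(codes: np.ndarray, aa: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One uniform within-(row, synonym-family) permutation of ``codes``."""
    return _GroupShuffler(codes, aa).draw(rng)


def shuffle_synonymous(seq, rng: np.random.Generator):
    """Shuffle synonymous codons within one codon sequence.

    ``seq`` is a list of codon strings or a DNA string of whole codons
    (no start-codon handling: pass exactly what should be shuffled).
    The amino-acid sequence and the codon multiset are preserved; stop
    codons and single-codon families are fixed points.
    """
    as_string = isinstance(seq, str)
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)] if as_string else list(seq)
    codes = np.array([CODON_INDEX.get(c.upper().replace("U", "T"), -99) for c in codons])
    # map unknown codons to singleton families via their position
    aa = np.where(
        codes >= 0,
        STANDARD_TABLE.aa_id_by_index[np.maximum(codes, 0)],
        1000 + np.arange(codes.size),
    )
    out = list(codons)
    for fam in np.unique(aa):
        idx = np.flatnonzero(aa == fam)
        if idx.size > 1:
            perm = rng.permutation(idx.size)
            for k, j in enumerate(idx):
                out[j] = codons[idx[perm[k]]]
    return "".join(out) if as_string else out


def observed_totals(matrix: CodonMatrix) -> np.ndarray:
    """Per-position sum of hydrogen bonds over all CDSs."""
    return STANDARD_TABLE.hbond_by_index[matrix.codes].sum(axis=0).astype(float)


def null_distribution(
    orfeome: Orfeome,
    n_positions: int = 100,
    n_sims: int = 200,
    seed: int | np.random.Generator | None = 0,
    mode: str = "full",
    return_sims: bool = False,
):
    """Monte-Carlo (E, sigma) of per-position hydrogen-bond totals.

    ``mode="full"`` (default) shuffles synonymous codons over each CDS's
    entire length and re-windows to the first ``n_positions`` analyzed
    codons; ``mode="window"`` shuffles within the window only (sensitivity
    check).  Requires a QC-passed ORFeome so the window is unambiguous.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2 (sigma undefined otherwise)")
    if mode not in ("full", "window"):
        raise ValueError("mode must be 'full' or 'window'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes, lengths, amb = encode_full(orfeome)
    if lengths.min() < n_positions:
        raise ValueError("ORFeome contains CDSs shorter than the window; run qc_filter")
    if mode == "window":
        codes = codes[:, :n_positions]
    aa = _aa_ids_for(codes)
    hb = np.concatenate([STANDARD_TABLE.hbond_by_index, np.zeros(max(len(amb), 0) + 1)])
    shuffler = _GroupShuffler(codes, aa)
    totals = np.empty((n_sims, n_positions))
    for s in range(n_sims):
        win = shuffler.draw(rng)[:, :n_positions]
        if np.any(win >= 64):
            raise ValueError("ambiguous codon entered the analysis window during shuffling")
        totals[s] = hb[win].sum(axis=0)
    E = totals.mean(axis=0)
    sigma = totals.std(axis=0, ddof=1)
    if return_sims:
        return E, sigma, totals
    return E, sigma


def min_max(values: np.ndarray) -> np.ndarray:
    """Min-max normalization y = (x - min) / (max - min); zeros if constant."""
    values = np.asarray(values, dtype=float)
    span = values.max() - values.min()
    if span == 0:
        return np.zeros_like(values)
    return (values - values.min()) / span


@dataclass
class SelectionProfile:
    """Observed vs. shuffled-null hydrogen-bond totals per codon position."""

    positions: np.ndarray
    O: np.ndarray
    E: np.ndarray
    sigma: np.ndarray
    z_sq: np.ndarray
    chigram: np.ndarray
    normalized_z_sq: np.ndarray
    scaled_chigram: np.ndarray
    chi_sq_total: float
    sigma_zero_positions: list = field(default_factory=list)
    denominator: str = "E"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions.astype(int),
                "O": self.O,
                "E": self.E,
                "sigma": self.sigma,
                "z_sq": self.z_sq,
                "chigram": self.chigram,
                "normalized_z_sq": self.normalized_z_sq,
                "scaled_chigram": self.scaled_chigram,
            }
        )

    def to_tsv(self, path, header_lines=None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def selection_profile(
    O: np.ndarray,
    E: np.ndarray,
    sigma: np.ndarray,
    positions: np.ndarray | None = None,
    denominator: str = "E",
) -> SelectionProfile:
    """Selection statistics from observed totals and the shuffling null.

    ``denominator`` selects the chi-gram scale: ``"E"`` (the literal
    (O-E)/E, default) or ``"sqrtE"`` ((O-E)/sqrt(E)).
    """
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (O.shape == E.shape == sigma.shape):
        raise ValueError("O, E, sigma shapes disagree")
    if np.any(E == 0):
        raise ValueError("E = 0 at some position (empty null?)")
    if denominator not in ("E", "sqrtE"):
        raise ValueError("denominator must be 'E' or 'sqrtE'")
    if positions is None:
        positions = np.arange(O.size) + 2
    zero = sigma == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero, 0.0, (O - E) / np.where(zero, 1.0, sigma))
    z_sq = z**2
    chigram = (O - E) / (E if denominator == "E" else np.sqrt(E))
    sd = chigram.std(ddof=1) if chigram.size > 1 else 0.0
    scaled = (chigram - chigram.mean()) / sd if sd > 0 else np.zeros_like(chigram)
    return SelectionProfile(
        positions=np.asarray(positions),
        O=O,
        E=E,
        sigma=sigma,
        z_sq=z_sq,
        chigram=chigram,
        normalized_z_sq=min_max(z_sq),
        scaled_chigram=scaled,
        chi_sq_total=float(z_sq.sum()),
        sigma_zero_positions=[int(p) for p in np.asarray(positions)[zero]],
        denominator=denominator,
    )


def ramp_of_selection(profile: SelectionProfile, n_head: int = 15) -> dict:
    """5'-end vs. remainder summary of the selection profile.

    Reports mean normalized z^2 and mean chi-gram within the first
    ``n_head`` analyzed positions against the rest, plus the sign of the
    5' chi-gram (negative = selection toward fewer hydrogen bonds).
    """
    m = profile.positions.size
    if m < 20:
        raise ValueError("selection profile must cover at least 20 positions")
    head = slice(0, n_head)
    tail = slice(n_head, m)
    head_chigram = float(profile.chigram[head].mean())
    return {
        "n_head": n_head,
        "head_mean_normalized_z_sq": float(profile.normalized_z_sq[head].mean()),
        "tail_mean_normalized_z_sq": float(profile.normalized_z_sq[tail].mean()),
        "head_mean_chigram": head_chigram,
        "tail_mean_chigram": float(profile.chigram[tail].mean()),
        "head_chigram_sign": int(np.sign(head_chigram)),
        "chi_sq_total": profile.chi_sq_total,
    }
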