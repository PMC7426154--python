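"""Synthetic ORFeomes with a known, implanted hydrogen-bond ramp.

The generator produces CDS collections whose *population* mean hydrogen-bond
count at analyzed position x follows a chosen target curve mu(x) — either
the bounded-exponential ramp (carrying capacity A, rate B, initial content
C, all in bonds/codon) or a flat control.  At each position an amino acid
is drawn from ``aa_frequencies`` and its codon from the exponentially
tilted family distribution

    P(codon | aa, theta) proportional to exp(theta * hbond(codon)),

with theta solved per position (by bracketed root finding) so that the
expected bond count over the amino-acid pool equals mu(x).  Exponential
tilting is the maximum-entropy family satisfying a mean constraint, which
is exactly — and only — what the target curve asserts.  Downstream of the
ramp window codons are drawn uniformly among synonyms (theta = 0).

Operon tables and expression compendia with configurable ground-truth
effects (lower 5' bond content for operon-leading CDSs; negative coupling
of abundance to 5' bond content) complete the study design.

Everything is reproducible bit-for-bit from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .genetic_code import CODONS, STOP, STANDARD_TABLE
from .orfeome import Orfeome
from .ramp import bounded_exponential

__all__ = [
    "GeneratorSpec",
    "generate_orfeome",
    "generate_operons",
    "generate_expression",
    "feasible_interval",
]

_AAS = sorted(aa for aa in STANDARD_TABLE.synonym_families if aa != STOP)
_FAMS = {
    aa: sorted(STANDARD_TABLE.synonym_families[aa]) for aa in _AAS
}
_FAM_H = {aa: np.array([STANDARD_TABLE.hbond_count(c) for c in fam], float) for aa, fam in _FAMS.items()}


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth description of a synthetic ORFeome.

    ramp: (A, B, C) of the bounded exponential in bonds/codon, or None for
    a flat target at ``flat_mu``.  ``cds_length_codons`` counts the
    prepended ATG; ``ramp_window`` positions after the start follow the
    target curve, any remainder is untilted.
    """

    n_cds: int = 500
    cds_length_codons: int = 101
    ramp: tuple[float, float, float] | None = (7.9, 0.3, 7.0)
    flat_mu: float = 7.5
    ramp_window: int = 100
    aa_frequencies: dict[str, float] | None = None  # default: uniform over 20
    seed: int = 0

    def __post_init__(self):
        if self.n_cds < 1:
            raise ValueError("n_cds must be >= 1")
        if self.cds_length_codons < 2:
            raise ValueError("cds_length_codons must cover the start codon plus one")
        if self.ramp is not None:
            A, B, C = self.ramp
            if not (6.0 <= C <= A <= 9.0):
                raise ValueError("ramp must satisfy 6 <= C <= A <= 9 (bonds/codon)")

    def aa_probs(self) -> tuple[list[str], np.ndarray]:
        if self.aa_frequencies is None:
            return _AAS, np.full(len(_AAS), 1.0 / len(_AAS))
        aas = sorted(self.aa_frequencies)
        p = np.array([self.aa_frequencies[a] for a in aas], float)
        if np.any(p < 0) or p.sum() <= 0:
            raise ValueError("invalid amino-acid frequencies")
        return aas, p / p.sum()

    def mu(self, x: np.ndarray) -> np.ndarray:
        """Target mean bond count at analyzed position x (x=0 first codon after start)."""
        x = np.asarray(x, float)
        if self.ramp is None:
            return np.full_like(x, self.flat_mu)
        A, B, C = self.ramp
        return bounded_exponential(x, A, B, C)


def feasible_interval(aas: list[str], p: np.ndarray) -> tuple[float, float]:
    """Open interval of achievable mean bond counts for an amino-acid pool."""
    lo = float(sum(p[i] * _FAM_H[a].min() for i, a in enumerate(aas)))
    hi = float(sum(p[i] * _FAM_H[a].max() for i, a in enumerate(aas)))
    return lo, hi


def _tilted_mean(theta: float, aas, p) -> float:
    m = 0.0
    for i, a in enumerate(aas):
        h = _FAM_H[a]
        w = np.exp(theta * (h - h.max()))
        m += p[i] * float((h * w).sum() / w.sum())
    return m


def solve_theta(mu: float, aas, p, margin: float = 1e-6, clamp: bool = False) -> float:
    """Tilt parameter matching a target mean bond count for the pool.

    The requested mean is clamped ``margin`` inside the achievable
    interval; values outside the interval raise with the feasible range
    unless ``clamp`` is set (used for implanted effect shifts, which are
    saturating by design).
    """
    lo, hi = feasible_interval(aas, p)
    if not lo <= mu <= hi and not clamp:
        raise ValueError(
            f"target mean {mu:.4f} bonds/codon outside the achievable interval ({lo:.4f}, {hi:.4f})"
        )
    mu = float(np.clip(mu, lo + margin, hi - margin))
    neutral = _tilted_mean(0.0, aas, p)
    if abs(mu - neutral) < 1e-12:
        return 0.0
    lo_t, hi_t = -1.0, 1.0
    while _tilted_mean(lo_t, aas, p) > mu:
        lo_t *= 2
    while _tilted_mean(hi_t, aas, p) < mu:
        hi_t *= 2
    return float(optimize.brentq(lambda t: _tilted_mean(t, aas, p) - mu, lo_t, hi_t, xtol=1e-12))


def _position_distribution(theta: float, aas, p) -> np.ndarray:
    """64-long codon sampling distribution for one position."""
    probs = np.zeros(64)
    for i, a in enumerate(aas):
        h = _FAM_H[a]
        w = np.exp(theta * (h - h.max()))
        w /= w.sum()
        for codon, pw in zip(_FAMS[a], w):
            probs[CODONS.index(codon)] = p[i] * pw
    return probs


def generate_orfeome(spec: GeneratorSpec) -> tuple[Orfeome, dict]:
    """Draw an ORFeome from a generator spec; returns (Orfeome, ground truth).

    The ground-truth record holds the target curve, per-position tilt
    parameters theta_x, and the seed.
    """
    rng = np.random.default_rng(spec.seed)
    aas, p = spec.aa_probs()
    n_analyzed = spec.cds_length_codons - 1
    window = min(spec.ramp_window, n_analyzed)
    mu = spec.mu(np.arange(window))
    thetas = np.array([solve_theta(m, aas, p) for m in mu])
    theta_all = np.concatenate([thetas, np.zeros(n_analyzed - window)])

    # one 64-way distribution per position; identical thetas share a row
    codes = np.empty((spec.n_cds, n_analyzed), dtype=np.int64)
    cache: dict[float, np.ndarray] = {}
    for x, th in enumerate(theta_all):
        cum = cache.get(th)
        if cum is None:
            cum = np.cumsum(_position_distribution(th, aas, p))
            cum[-1] = 1.0
            cache[th] = cum
        codes[:, x] = np.searchsorted(cum, rng.random(spec.n_cds), side="right")

    codon_arr = np.array(CODONS)
    seqs = ["ATG" + "".join(codon_arr[row]) for row in codes]
    ids = [f"cds_{i + 1:05d}" for i in range(spec.n_cds)]
    truth = {
        "ramp": list(spec.ramp) if spec.ramp is not None else None,
        "flat_mu": None if spec.ramp is not None else spec.flat_mu,
        "mu": mu.tolist(),
        "theta": theta_all.tolist(),
        "seed": spec.seed,
        "n_cds": spec.n_cds,
        "cds_length_codons": spec.cds_length_codons,
    }
    return Orfeome(ids, seqs, provenance=f"synthetic(seed={spec.seed})"), truth


def generate_operons(
    orfeome: Orfeome,
    spec: GeneratorSpec,
    sizes: list[int] | None = None,
    n_operons: int = 50,
    first_position_delta: float = 0.0,
    delta_window: int = 20,
    seed: int | None = None,
):
    """Assign CDSs to operons; optionally implant a leading-CDS 5' effect.

    Operon sizes are taken from ``sizes`` or drawn as 2 + Poisson(1)
    (matching the empirical preponderance of 2-3-CDS operons).  When
    ``first_position_delta`` > 0, every operon-leading CDS is regenerated
    with target mu(x) - delta over the first ``delta_window`` analyzed
    positions, emulating reduced unwinding cost at the start of the
    transcription unit.

    Returns (OperonTable, Orfeome) — the ORFeome is the input one unless
    leading CDSs were regenerated.
    """
    from .strata import OperonTable

    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    if sizes is None:
        sizes = list(2 + rng.poisson(1.0, size=n_operons))
    if sum(sizes) > len(orfeome):
        raise ValueError(
            f"operon sizes sum to {sum(sizes)} but the ORFeome has {len(orfeome)} CDSs"
        )
    rows = []
    cursor = 0
    first_ids = []
    for k, size in enumerate(sizes, start=1):
        for pos in range(1, int(size) + 1):
            cid = orfeome.ids[cursor]
            rows.append({"cds_id": cid, "operon_id": f"op_{k:04d}", "position": pos})
            if pos == 1:
                first_ids.append(cursor)
            cursor += 1
    table = OperonTable(pd.DataFrame(rows))

    if first_position_delta > 0:
        aas, p = spec.aa_probs()
        n_analyzed = spec.cds_length_codons - 1
        window = min(spec.ramp_window, n_analyzed)
        mu = spec.mu(np.arange(window)).copy()
        mu[: min(delta_window, window)] -= first_position_delta
        thetas = [solve_theta(m, aas, p, clamp=True) for m in mu]
        theta_all = np.concatenate([thetas, np.zeros(n_analyzed - window)])
        codon_arr = np.array(CODONS)
        seqs = list(orfeome.seqs)
        cums = [None] * len(theta_all)
        for i in first_ids:
            body = []
            for x, th in enumerate(theta_all):
                if cums[x] is None:
                    c = np.cumsum(_position_distribution(th, aas, p))
                    c[-1] = 1.0
                    cums[x] = c
                body.append(codon_arr[int(np.searchsorted(cums[x], rng.random(), side="right"))])
            seqs[i] = "ATG" + "".join(body)
        orfeome = Orfeome(list(orfeome.ids), seqs, orfeome.provenance + "+operon_delta")
    return table, orfeome


def generate_expression(
    orfeome: Orfeome,
    n_experiments: int = 16,
    coupling: float = 0.0,
    cds_sd: float = 1.0,
    replicate_sd: float = 0.25,
    head_codons: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normal RPKM table (cds x experiment) with optional 5'-hbond coupling.

    Each CDS gets a latent log-abundance ~ N(0, cds_sd^2) minus
    ``coupling`` times the z-score of its mean bond count over the first
    ``head_codons`` analyzed codons; each experiment adds independent
    N(0, replicate_sd^2) noise before exponentiation.
    """
    if n_experiments < 1:
        raise ValueError("need at least one experiment")
    rng = np.random.default_rng(seed)
    from .orfeome import encode_cds

    head = np.array(
        [
            STANDARD_TABLE.hbond_by_index[encode_cds(s)[:head_codons]].mean()
            for s in orfeome.seqs
        ]
    )
    z = (head - head.mean()) / head.std() if head.std() > 0 else np.zeros_like(head)
    latent = rng.normal(0.0, cds_sd, size=len(orfeome)) - coupling * z
    noise = (
        rng.normal(0.0, replicate_sd, size=(len(orfeome), n_experiments))
        if replicate_sd > 0
        else np.zeros((len(orfeome), n_experiments))
    )
    log_rpkm = latent[:, None] + noise
    return pd.DataFrame(
        np.exp(log_rpkm),
        index=pd.Index(orfeome.ids, name="cds_id"),
        columns=[f"exp_{j + 1:02d}" for j in range(n_experiments)],
    )
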