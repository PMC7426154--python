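"""RSCU / CAI / tAI weights and the mRNA unpaired-probability adapter."""

import numpy as np
import pytest

from hbramp import (
    Orfeome,
    build_codon_matrix,
    cai_weights,
    positional_metric,
    read_unpaired_probabilities,
    rscu,
    tai_weights,
)
from hbramp.genetic_code import CODONS, STANDARD_TABLE, STOP
from hbramp.metrics import S_PROKARYOTE, TrnaPool, read_trna_pool

# ---------------------------------------------------------------------------
# RSCU / CAI


def test_rscu_lysine_example():
    w = rscu({"AAA": 3, "AAG": 1})
    assert w.weight["AAA"] == pytest.approx(1.5)
    assert w.weight["AAG"] == pytest.approx(0.5)


def test_rscu_uniform_family_is_one():
    counts = {c: 5 for c in STANDARD_TABLE.synonym_families["L"]}
    w = rscu(counts)
    assert all(w.weight[c] == pytest.approx(1.0) for c in counts)


def test_rscu_family_sums_and_absent_amino_acids(rng):
    counts = {c: int(rng.integers(0, 50)) for c in CODONS if STANDARD_TABLE.codon_to_aa[c] not in (STOP, "W")}
    counts = {c: v for c, v in counts.items() if v > 0}
    w = rscu(counts)
    # brute-force recount per family, independently of the implementation
    for aa, fam in STANDARD_TABLE.synonym_families.items():
        if aa == STOP:
            continue
        fam = sorted(fam)
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            assert aa in w.flagged
            assert all(w.weight[c] == 1.0 for c in fam)
            continue
        assert sum(w.weight[c] for c in fam) == pytest.approx(len(fam))
        for c in fam:
            assert w.weight[c] == pytest.approx(counts.get(c, 0) / (total / len(fam)))


def test_cai_from_lysine_rscu():
    w = cai_weights(rscu({"AAA": 3, "AAG": 1}))
    assert w.weight["AAA"] == pytest.approx(1.0)
    assert w.weight["AAG"] == pytest.approx(1 / 3)


def test_cai_family_max_is_one_and_weights_in_unit_interval(rng):
    counts = {c: int(rng.integers(1, 100)) for c in CODONS if STANDARD_TABLE.codon_to_aa[c] != STOP}
    w = cai_weights(rscu(counts))
    for aa, fam in STANDARD_TABLE.synonym_families.items():
        if aa == STOP:
            continue
        vals = [w.weight[c] for c in fam]
        assert max(vals) == pytest.approx(1.0)
        assert all(0 < v <= 1 for v in vals)


# ---------------------------------------------------------------------------
# tAI


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _reference_tai(pool: TrnaPool) -> dict:
    """Independent tAI implementation by explicit wobble-pair enumeration.

    Walks anticodon-by-anticodon: an anticodon reads a codon when positions
    35/36 pair Watson-Crick with codon bases 2/1 and the (anticodon base 34,
    codon base 3) pair appears in the constraint table.
    """
    s = pool.s_vector
    pair_s = {  # (anticodon wobble base, codon third base) -> constraint
        ("A", "T"): s[0], ("G", "C"): s[1], ("T", "A"): s[2], ("C", "G"): s[3],
        ("G", "T"): s[4], ("A", "C"): s[5], ("A", "A"): s[6], ("T", "G"): s[7],
    }
    wc = {"A": "T", "T": "A", "G": "C", "C": "G"}
    W = dict.fromkeys(CODONS, 0.0)
    for anticodon, copies in pool.tgcn.items():
        for codon in CODONS:
            if codon == "ATG":
                continue  # handled below: initiator pairing only
            if wc[anticodon[1]] != codon[1] or wc[anticodon[2]] != codon[0]:
                continue
            key = (anticodon[0], codon[2])
            if key in pair_s:
                W[codon] += (1 - pair_s[key]) * copies
    W["ATG"] = (1 - s[3]) * pool.tgcn.get("CAT", 0)
    if pool.sking == 1:
        W["ATA"] = 1 - s[8]
    sense = [c for c in CODONS if STANDARD_TABLE.codon_to_aa[c] != STOP]
    mx = max(W[c] for c in sense)
    w = {c: W[c] / mx for c in sense}
    nz = [v for v in w.values() if v > 0]
    gm = float(np.exp(np.mean(np.log(nz))))
    return {c: (v if v > 0 else gm) for c, v in w.items()}


def test_tai_single_perfect_anticodon_gets_weight_one():
    pool = TrnaPool({"TTT": 1}, s_vector=(0,) * 9, sking=0)  # reads AAA
    w = tai_weights(pool)
    assert w.weight["AAA"] == pytest.approx(1.0)


def test_tai_relative_weights_and_geometric_mean_fill():
    # GGC anticodon (reads GCC WC, GCT by G:U wobble with s=0.41)
    pool = TrnaPool({"GGC": 2, "TGC": 1}, sking=0)
    w = tai_weights(pool)
    nonzero = {c: v for c, v in w.weight.items() if c not in w.flagged}
    assert max(nonzero.values()) == pytest.approx(1.0)
    gm = np.exp(np.mean(np.log([v for v in nonzero.values()])))
    filled = [v for c, v in w.weight.items() if c in w.flagged]
    assert filled and all(v == pytest.approx(float(gm)) for v in filled)


def test_tai_matches_independent_reference_on_ten_anticodon_pool():
    pool = TrnaPool(
        {
            "TTT": 2,  # AAA (Lys)
            "CTT": 1,  # AAG (Lys)
            "GGC": 3,  # GCC (Ala)
            "TGC": 2,  # GCA (Ala)
            "GAA": 4,  # TTC (Phe)
            "CAT": 6,  # ATG (Met)
            "GAT": 1,  # ATC (Ile)
            "CCA": 2,  # TGG (Trp)
            "TCC": 1,  # GGA (Gly)
            "GCG": 1,  # CGC (Arg)
        },
        s_vector=S_PROKARYOTE,
        sking=1,
    )
    ours = tai_weights(pool).weight
    ref = _reference_tai(pool)
    assert set(ours) == set(ref)
    for codon in ours:
        assert ours[codon] == pytest.approx(ref[codon], abs=1e-12), codon


def test_tai_empty_pool_errors():
    with pytest.raises(ValueError, match="coverage"):
        tai_weights(TrnaPool({"TTT": 0}, sking=0))


def test_trna_pool_tsv_reader(tmp_path):
    path = tmp_path / "pool.tsv"
    path.write_text("anticodon\ttgcn\nTTT\t2\nGAA\t4\n")
    pool = read_trna_pool(path)
    assert pool.tgcn == {"TTT": 2, "GAA": 4}


# ---------------------------------------------------------------------------
# unpaired-probability adapter


def _write_lunp(path, rows):
    lines = ["#unpaired probabilities", " #i$\tl=1\t2\t3"]
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def test_unpaired_all_ones_gives_structure_zero(tmp_path):
    path = _write_lunp(tmp_path / "a_lunp", [[1, 1.0], [2, 1.0, 1.0], [3, 1.0, 1.0, 1.0]])
    prof = read_unpaired_probabilities(path)
    assert prof.base_unpaired == pytest.approx([1.0, 1.0, 1.0])
    assert prof.codon_structure == pytest.approx([0.0])


def test_codon_value_is_mean_of_its_bases(tmp_path):
    path = _write_lunp(tmp_path / "b_lunp", [[1, 0.2], [2, 0.4], [3, 0.6]])
    prof = read_unpaired_probabilities(path, mode="ending")
    assert prof.codon_unpaired == pytest.approx([0.4])
    assert prof.codon_structure == pytest.approx([0.6])


def test_containing_mode_averages_spans_covering_each_base(tmp_path):
    # rows: (position, l=1, l=2); base 1 is covered by (1,l1), (2,l2)
    path = _write_lunp(tmp_path / "c_lunp", [[1, 0.2, "NA"], [2, 0.4, 0.8]])
    prof = read_unpaired_probabilities(path, mode="containing")
    assert prof.base_unpaired[0] == pytest.approx((0.2 + 0.8) / 2)
    assert prof.base_unpaired[1] == pytest.approx((0.4 + 0.8) / 2)


def test_unpaired_rejects_bad_probabilities_and_malformed_rows(tmp_path):
    path = _write_lunp(tmp_path / "d_lunp", [[1, 1.5]])
    with pytest.raises(ValueError, match="outside"):
        read_unpaired_probabilities(path)
    bad = tmp_path / "e_lunp"
    bad.write_text("1\t0.2\nnot-a-number\tx\n")
    with pytest.raises(ValueError, match="line 2"):
        read_unpaired_probabilities(bad)


# ---------------------------------------------------------------------------
# positional application


def test_all_one_weights_give_flat_profile(ramped_matrix):
    from hbramp.metrics import CodonWeights

    w = CodonWeights("ones", {c: 1.0 for c in CODONS if STANDARD_TABLE.codon_to_aa[c] != STOP})
    prof = positional_metric(ramped_matrix, w, n_boot=20, seed=0)
    assert prof.mean == pytest.approx(np.ones(100))


def test_cai_profile_lies_in_unit_interval(ramped_matrix, toy_orfeome):
    orf = Orfeome(
        ids=[f"g{i}" for i in range(len(ramped_matrix))],
        seqs=["ATG" + "".join(ramped_matrix.row_codons(i)) for i in range(len(ramped_matrix))],
    )
    w = cai_weights(rscu(orf))
    prof = positional_metric(ramped_matrix, w, n_boot=20, seed=0)
    assert np.all((0 < prof.mean) & (prof.mean <= 1))
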