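import numpy as np
import pytest

from hbramp import GeneratorSpec, Orfeome, build_codon_matrix, generate_orfeome, qc_filter


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture
def toy_orfeome():
    """Three short hand-built CDSs (start codon + 4 codons each)."""
    return Orfeome(
        ids=["g1", "g2", "g3"],
        seqs=[
            "ATG" + "AAAAAGTTATTG",  # Lys Lys Leu Leu
            "ATG" + "GGTGGCGGGTGG",  # Gly Gly Gly Trp
            "ATG" + "TTAGCGCTGAAC",  # Leu Ala Leu Asn
        ],
        provenance="toy",
    )


@pytest.fixture
def ramped_matrix():
    """Codon matrix of a small synthetic ORFeome with an implanted ramp."""
    spec = GeneratorSpec(n_cds=400, cds_length_codons=101, ramp=(7.9, 0.3, 7.0), seed=11)
    orf, _ = generate_orfeome(spec)
    kept, _ = qc_filter(orf, 100)
    return build_codon_matrix(kept, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
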