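import numpy as np
import pytest

import trtile

SNIPPET_ALLELE = "ACCTTGACCTTGACCTTTG"
SNIPPET_MOTIFS = ["ACCTTG"]


@pytest.fixture
def snippet_decomposition():
    return trtile.decompose(SNIPPET_ALLELE, SNIPPET_MOTIFS, allele_id="demo")


@pytest.fixture
def snippet_mapping(snippet_decomposition):
    return trtile.build_mapping([snippet_decomposition], 1)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def random_instance(rng, max_len=15, max_motifs=3, max_motif_len=5):
    """A small decomposition instance: (sequence, motif list)."""
    x = random_dna(rng, int(rng.integers(1, max_len + 1)))
    motifs = []
    for _ in range(int(rng.integers(1, max_motifs + 1))):
        m = random_dna(rng, int(rng.integers(1, max_motif_len + 1)))
        if m not in motifs:
            motifs.append(m)
    return x, motifs


@pytest.fixture
def small_panel(tmp_path):
    """A simulated 12-allele panel with groups, written to disk."""
    params = trtile.SimParams(
        motifs=("ACGTTG", "ACGTAG"),
        copy_number_range=(4, 9),
        substitution_rate=0.02,
        indel_rate=0.005,
        n_alleles=12,
        groups=("AFR", "EUR", "EAS"),
        seed=11,
    )
    alleles = trtile.simulate_alleles(params)
    fasta = tmp_path / "panel.fasta"
    ann = tmp_path / "panel_groups.tsv"
    trtile.write_fasta(alleles, fasta)
    trtile.write_annotations_tsv(alleles, ann)
    return {"params": params, "alleles": alleles, "fasta": fasta, "ann": ann}
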