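import numpy as np
import pytest

import intronevo as ie


@pytest.fixture(scope="session")
def abcb1_matrix():
    return ie.load_abcb1_matrix()


@pytest.fixture(scope="session")
def angiosperm_tree():
    return ie.load_angiosperm_tree()


def make_planted_set(rng, n=50, length=1000, noise=0.1, plant="TGTAACATGNNA"):
    """Random sequences each carrying one noisy copy of the plant.

    'N' positions draw a random base; every position is additionally
    replaced by a random base with probability ``noise``.  Returns
    (sequences, true offsets).
    """
    seqs, offsets = [], []
    for _ in range(n):
        arr = rng.integers(4, size=length)
        off = int(rng.integers(0, length - len(plant) + 1))
        for w, ch in enumerate(plant):
            b = int(rng.integers(4)) if ch == "N" else "ACGT".index(ch)
            if noise and rng.random() < noise:
                b = int(rng.integers(4))
            arr[off + w] = b
        seqs.append("".join("ACGT"[b] for b in arr))
        offsets.append(off)
    return seqs, offsets


@pytest.fixture
def planted_set():
    return make_planted_set


def make_gene(rng, n_introns=3, exon_len=(40, 90), intron_len=(20, 70)):
    """A random GT..AG gene; returns (genomic, cdna, exon intervals)."""
    bases = "ACGT"
    exons = [
        "".join(rng.choice(list(bases), size=rng.integers(*exon_len)))
        for _ in range(n_introns + 1)
    ]
    introns = []
    for _ in range(n_introns):
        mid = "".join(rng.choice(list(bases), size=rng.integers(*intron_len) - 4))
        introns.append("GT" + mid + "AG")
    genomic, coords, pos = [], [], 0
    for i, ex in enumerate(exons):
        genomic.append(ex)
        coords.append((pos, pos + len(ex)))
        pos += len(ex)
        if i < n_introns:
            genomic.append(introns[i])
            pos += len(introns[i])
    return "".join(genomic), "".join(exons), coords


@pytest.fixture
def random_gene():
    return make_gene
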