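import numpy as np
import pytest

from chemreprog.synthetic import simulate_genome_annotation

# -- independent oracles shared by unit and acceptance tests ---------------

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(seq, offset):
    """Codon-by-codon table-lookup translation oracle."""
    pep = []
    for i in range(offset, len(seq) - 2, 3):
        aa = CODON_TABLE[seq[i:i + 3]]
        if aa == "*":
            return "".join(pep), True
        pep.append(aa)
    return "".join(pep), False


def oracle_running_sum_es(metrics, hit_mask, weight=1.0):
    """Literal position-by-position GSEA running sum."""
    n = len(metrics)
    m = hit_mask.sum()
    w = np.abs(metrics) ** weight if weight != 0 else np.ones(n)
    nr = w[hit_mask].sum()
    running, best = 0.0, 0.0
    for i in range(n):
        if hit_mask[i]:
            running += (w[i] / nr) if nr > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


def oracle_naive_bh(pvals):
    """O(m^2) literal BH step-up."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * pvals[i] / rank_from_top)
        adj[i] = running_min
    return adj


@pytest.fixture(scope="session")
def annotation():
    """A 20-gene synthetic annotation shared across tests (fixed seed)."""
    return simulate_genome_annotation(seed=7, n_genes=20)


@pytest.fixture(scope="session")
def transcripts_by_id(annotation):
    return {t.transcript_id: t for t in annotation.transcripts}


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
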