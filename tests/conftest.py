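import numpy as np
import pytest

from mitocub.codes import CODON_INDEX, CODONS, get_code
from mitocub.seqio import CodonCounts


@pytest.fixture(scope="session")
def std_code():
    return get_code(1)


@pytest.fixture(scope="session")
def t4_code():
    return get_code(4)


def make_counts(codon_counts: dict[str, int], species="sp", gene="g") -> CodonCounts:
    """Build a CodonCounts from a {codon: count} dict (DNA alphabet)."""
    counts = np.zeros(64, dtype=np.int64)
    for codon, k in codon_counts.items():
        counts[CODON_INDEX[codon.replace("U", "T")]] += k
    return CodonCounts(species=species, gene=gene, counts=counts)


def random_counts(rng: np.random.Generator, code, n_codons=300,
                  species="sp", gene="g", alpha=0.6) -> CodonCounts:
    """Random sense-codon counts with a Dirichlet-ish skew."""
    sense = [c for c in CODONS if code.codon_to_aa[c] != "*"]
    probs = rng.dirichlet(np.full(len(sense), alpha))
    draw = rng.multinomial(n_codons, probs)
    counts = np.zeros(64, dtype=np.int64)
    for c, k in zip(sense, draw):
        counts[CODON_INDEX[c]] = k
    return CodonCounts(species=species, gene=gene, counts=counts)
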