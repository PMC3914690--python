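import numpy as np
import pytest

from degenome import simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_pair():
    """Moderate ancestor/derived pair with every event type, shared across
    tests to amortize simulation cost."""
    cfg = simulate.AncestorConfig(genome_length=120_000, n_genes=90, seed=2)
    ancestor, meta = simulate.generate_ancestor(cfg)
    library = simulate.make_is_library(2)
    params = simulate.DegenerationParams(
        p_pseudo=0.4, n_is_insertions=15, n_inversions=2,
        n_translocations=1, n_deletions=2, n_duplications=1,
        duplication_length=13_476, duplication_subs=13, duplication_indels=4,
        mu=0.004, rrna_n_subs=40, seed=2)
    derived, ledger = simulate.degenerate(ancestor, params, library, meta)
    return {"ancestor": ancestor, "meta": meta, "derived": derived,
            "ledger": ledger, "library": library, "params": params,
            "config": cfg}


def random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """Valid ORF: ATG + sense codons + TAA."""
    body = rng.choice(simulate.SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
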