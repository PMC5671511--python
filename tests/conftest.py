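import numpy as np
import pytest

from codonlab import (
    CdsSimConfig,
    CodonCounts,
    count_codons,
    pool_counts,
    simulate_cds_set,
    standard_code,
)


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_sim():
    """The reference planted-bias simulation: 200 background + 20 biased genes,
    5 planted families, 5x preference boost."""
    cfg = CdsSimConfig(
        n_genes=220,
        biased_subset_size=20,
        bias_strength=5.0,
        biased_families=("E", "F", "K", "N", "Q"),
        seed=2017,
    )
    records, truth = simulate_cds_set(cfg)
    counts = {r.id: count_codons(r) for r in records}
    group = pool_counts([counts[g] for g in sorted(truth.biased_gene_ids)])
    background = pool_counts(list(counts.values()))
    return records, truth, counts, group, background


def random_counts(rng, max_count=50) -> CodonCounts:
    """A random codon count vector over the sense codons."""
    code = standard_code()
    codons = list(code.sense_codons)
    raw = rng.integers(0, max_count + 1, size=len(codons))
    return CodonCounts.from_mapping(dict(zip(codons, (int(x) for x in raw))))
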