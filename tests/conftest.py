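import numpy as np
import pandas as pd
import pytest

from capriscan.popio import GenotypePanel, PopulationMap


def make_panel(genotypes, positions=None, chrom="1", haplotypes=None,
               samples=None, ref="A", alt="G"):
    """Build a small panel from a genotype matrix (rows = samples)."""
    G = np.asarray(genotypes, dtype=np.int8)
    n, m = G.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    variants = pd.DataFrame({
        "chrom": [chrom] * m,
        "pos": np.asarray(positions, dtype=int),
        "ref": [ref] * m,
        "alt": [alt] * m,
    })
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n)]
    hap = None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8)
    return GenotypePanel(samples=samples, variants=variants, genotypes=G,
                         haplotypes=hap, phased=hap is not None)


def make_hap_panel(haplotypes, positions=None, chrom="1", samples=None):
    """Panel from a phased haplotype matrix (2 rows per sample)."""
    H = np.asarray(haplotypes, dtype=np.int8)
    G = H[0::2] + H[1::2]
    return make_panel(G, positions, chrom, haplotypes=H, samples=samples)


@pytest.fixture
def two_pop_map():
    return PopulationMap({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_panel(rng, n_samples=6, n_snps=20, missing_rate=0.0, span=200_000):
    """Random genotype panel with sorted unique positions."""
    pos = np.sort(rng.choice(span, size=n_snps, replace=False) + 1)
    freqs = rng.uniform(0.05, 0.95, n_snps)
    G = rng.binomial(2, freqs[None, :], size=(n_samples, n_snps)).astype(np.int8)
    if missing_rate > 0:
        G[rng.random(G.shape) < missing_rate] = -1
    return make_panel(G, pos)
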