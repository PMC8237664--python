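import numpy as np
import pandas as pd
import pytest

from hircus.genotypes import MISSING, PseudohaploidMatrix, SitePanel


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_930)


def make_panel(n_sites: int, n_chroms: int = 4, chrom_bp: int = 100_000_000):
    """A synthetic transversion panel with evenly spaced coordinates."""
    per = n_sites // n_chroms
    chrom = np.repeat([f"chr{i+1}" for i in range(n_chroms)], per)
    pos = np.tile(np.linspace(1, chrom_bp, per).astype(np.int64), n_chroms)
    sites = pd.DataFrame(
        {"chrom": chrom[:n_sites], "pos": pos[:n_sites], "ref": "A", "alt": "T"}
    )
    return SitePanel(sites)


def haploidize(genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One sampled allele per site from diploid dosages (error-free)."""
    g = np.asarray(genotypes)
    return rng.binomial(1, g / 2.0).astype(np.int8)


def matrix_from_genotypes(genotypes, samples, rng, n_chroms=4):
    """Pseudohaploid matrix built by one-allele sampling of diploid truth."""
    g = np.vstack(genotypes)
    calls = haploidize(g, rng)
    panel = make_panel(g.shape[1], n_chroms=n_chroms)
    return PseudohaploidMatrix(calls, tuple(samples), panel)
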