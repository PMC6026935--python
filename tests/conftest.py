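"""Shared fixtures: hand-built toy datasets and one reusable simulation."""

import numpy as np
import pandas as pd
import pytest

from divscan import (
    GenotypeMatrix,
    PopulationMap,
    SimConfig,
    simulate_dataset,
)
from divscan.demography import ParameterSet


def make_gm(genotypes, chrom="chr1", start=100, spacing=1000, locus_per_site=True,
            individuals=None):
    """Build a GenotypeMatrix from a (n_ind, n_sites) genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_sites = g.shape
    individuals = individuals or [f"I{i:02d}" for i in range(n_ind)]
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": [start + spacing * j for j in range(n_sites)],
        "ref": ["A"] * n_sites,
        "alt": ["T"] * n_sites,
        "locus_id": [f"L{j}" if locus_per_site else "L0" for j in range(n_sites)],
        "snp_idx": [0 if locus_per_site else j for j in range(n_sites)],
    })
    return GenotypeMatrix(individuals, sites, g)


@pytest.fixture
def toy_popmap():
    """Six sampling sites, two life-history types (study layout)."""
    def build(individuals, n_ferox=2):
        brown_sites = ["LNF", "GRU", "MCF", "SLA", "TAG"]
        site, life = {}, {}
        brown = individuals[:-n_ferox] if n_ferox else individuals
        for i, ind in enumerate(brown):
            site[ind] = brown_sites[i % len(brown_sites)]
            life[ind] = "benthivorous"
        for ind in individuals[len(brown):]:
            site[ind] = "KER"
            life[ind] = "ferox"
        return PopulationMap(site=site, life_history=life)
    return build


SMALL_CHROMS = tuple((f"chr{i}", 10_000_000) for i in range(1, 7))


@pytest.fixture(scope="session")
def scadm_dataset():
    """One reusable study-scale-demography simulation (~6k loci, 6 chroms)."""
    cfg = SimConfig(model="SCadm", params=ParameterSet.point_estimates(),
                    n_brown=20, n_ferox=8, n_loci=12_000, missingness=0.12,
                    chrom_lengths=SMALL_CHROMS, seed=42)
    return simulate_dataset(cfg)
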