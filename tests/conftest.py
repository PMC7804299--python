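import numpy as np
import pytest

from facemodkit import genoprep, shapemod, synthgen


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic cohort shared across tests.

    n = 400 individuals, 64 landmarks, 3 hierarchy levels (7 segments),
    20 genes of 3-6 low-frequency variants. n >= 400 matters: with fewer
    individuals MAC >= 4 forces MAF >= 1% and the variant filters become
    mutually exclusive.
    """
    cfg = synthgen.SynthConfig(
        n_individuals=400,
        n_landmarks=64,
        n_levels=3,
        n_genes=20,
        variants_per_gene=(3, 6),
        maf_range=(0.005, 0.009),
        seed=4,
    )
    return synthgen.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_phenotypes(small_dataset):
    """Hierarchy + adjusted module phenotypes for the shared cohort."""
    hier, phens, qc = shapemod.phenotype_modules(
        small_dataset.faces,
        small_dataset.covariates,
        n_levels=3,
        n_perm=30,
        seed=7,
    )
    return hier, phens, qc


@pytest.fixture(scope="session")
def small_genes(small_dataset):
    g, _ = genoprep.filter_variants(small_dataset.genotypes)
    return genoprep.group_by_gene(g, small_dataset.gene_map)
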