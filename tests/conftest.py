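import numpy as np
import pandas as pd
import pytest

from microsplit import AbundanceMatrix, Lineage
from microsplit.synth import PlantedBlock, PlantedCoupling, SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_taxa_matrix(rng):
    """6 samples x 5 taxa, positive log-normal abundances."""
    data = pd.DataFrame(
        np.exp(rng.standard_normal((6, 5))),
        index=[f"s{i}" for i in range(6)],
        columns=[f"taxon_{c}" for c in "abcde"],
    )
    return AbundanceMatrix(data, "taxon")


@pytest.fixture
def family_lineages():
    return {
        "g__Bacteroides": Lineage(
            {"kingdom": "Bacteria", "phylum": "Bacteroidetes",
             "family": "Bacteroidaceae", "genus": "Bacteroides"}
        ),
        "g__Blautia": Lineage(
            {"kingdom": "Bacteria", "phylum": "Firmicutes",
             "family": "Lachnospiraceae", "genus": "Blautia"}
        ),
        "g__Roseburia": Lineage(
            {"kingdom": "Bacteria", "phylum": "Firmicutes",
             "family": "Lachnospiraceae", "genus": "Roseburia"}
        ),
    }


@pytest.fixture
def planted_config():
    """Small planted configuration used across pipeline tests."""
    cfg = SynthConfig(
        n_samples_per_group=20,
        groups=("CDT", "CDS"),
        n_taxa=10,
        n_kos=20,
        n_modules=4,
        noise_sd=0.05,
        seed=7,
    )
    taxa = cfg.taxon_labels()
    mods = cfg.module_labels()
    return SynthConfig(
        n_samples_per_group=20,
        groups=("CDT", "CDS"),
        n_taxa=10,
        planted_blocks=(PlantedBlock(tuple(taxa[:3]), 0.97),),
        n_kos=20,
        n_modules=4,
        planted_couplings=(PlantedCoupling(taxa[0], mods[0], 0.8),),
        noise_sd=0.05,
        seed=7,
    )


@pytest.fixture
def planted_data(planted_config):
    return generate(planted_config)
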