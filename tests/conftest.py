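"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from sysgen import (GeneticMap, GenotypeMatrix, PlantedCisGene, PlantedModule,
                    PlantedTraitQTL, SimConfig, build_grid, simulate_study)


@pytest.fixture(scope="session")
def toy_map() -> GeneticMap:
    """Two chromosomes, a handful of markers with known cM/bp coordinates."""
    rows = [
        ("m1", "A09", 0.0, 1_000_000),
        ("m2", "A09", 10.0, 5_000_000),
        ("m3", "A09", 25.0, 12_000_000),
        ("m4", "A09", 40.0, 20_000_000),
        ("m5", "C08", 0.0, 2_000_000),
        ("m6", "C08", 20.0, 9_000_000),
    ]
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp"]))


@pytest.fixture(scope="session")
def toy_genotypes(toy_map) -> GenotypeMatrix:
    rng = np.random.default_rng(11)
    values = rng.integers(0, 2, size=(40, 6)).astype(float)
    return GenotypeMatrix(values, [f"L{i:02d}" for i in range(40)], toy_map)


@pytest.fixture(scope="session")
def study_config() -> SimConfig:
    """A planted end-to-end study: hub-driven module, cis gene, trait QTL."""
    return SimConfig(
        n_lines=200, n_transcripts=300, seed=7,
        modules=(PlantedModule(50, "A01_m025", loading=0.8, hub_r2=0.5),),
        cis_genes=(PlantedCisGene("cis", "A02_m020", r2=0.3),),
        trait_qtl=(PlantedTraitQTL("module:1", 0.25),
                   PlantedTraitQTL("A03_m030", 0.1)),
        expression_scale="log2",
    )


@pytest.fixture(scope="session")
def study(study_config):
    """(genotypes, gmap, expression, traits, truth) for the planted study."""
    return simulate_study(study_config)


@pytest.fixture(scope="session")
def study_grid(study):
    _, gmap, *_ = study
    return build_grid(gmap, step=1.0)
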