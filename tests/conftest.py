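from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from gfblup import (
    GenotypePanel,
    RunConfig,
    SimulationConfig,
    run_within_population,
    simulate_feature_map,
    simulate_genotypes,
    simulate_phenotypes,
)

DATA_DIR = Path(__file__).resolve().parents[1] / "data"


def make_panel(dosages, chrom=None, pos=None, populations=None, ids=None):
    """Small hand-rolled panel for unit tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = np.arange(1, m + 1) * 100 if pos is None else np.asarray(pos)
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypePanel(
        ids=np.array([f"i{i}" for i in range(n)], dtype=object) if ids is None else ids,
        populations=np.array(["pop"] * n, dtype=object) if populations is None else populations,
        variants=variants,
        dosages=dosages,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated population with feature map and phenotypes (light)."""
    cfg = SimulationConfig(
        n_individuals=300, n_variants=1200, n_chromosomes=3, n_populations=1,
        n_genes=60, n_terms=10, h2=0.4, feature_share=0.3, seed=42,
    )
    panels = simulate_genotypes(cfg)
    panel = panels["popA"]
    fmap, gene_table = simulate_feature_map(panel, cfg)
    phen, truth = simulate_phenotypes(panels, fmap, cfg)
    return {"cfg": cfg, "panel": panel, "fmap": fmap,
            "gene_table": gene_table, "phen": phen, "truth": truth}


@pytest.fixture(scope="session")
def within_run():
    """Full within-population experiment with a planted enriched term.

    One population of 1500 animals, 5000 variants, 30 feature terms with the
    first enriched at a 0.3 share of genetic variance; birth-year split.
    Shared between the pipeline tests and the recovery suite.
    """
    cfg = SimulationConfig(
        n_individuals=1500, n_variants=5000, n_chromosomes=5, n_populations=1,
        n_genes=300, n_terms=30, h2=0.4, feature_share=0.3, seed=20260101,
    )
    rc = RunConfig(sim=cfg, seed=20260101, n_permutations=1000)
    report, log = run_within_population(rc)
    return {"cfg": cfg, "report": report, "log": log}
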