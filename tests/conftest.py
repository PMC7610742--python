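import numpy as np
import pytest

from gwaspeaks.synthetic_cohort import SimConfig, simulate_cohort
from gwaspeaks.variants import GeneticMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def flat_map():
    """1 cM/Mb map covering chromosomes 1, 2 and X."""
    gmap = GeneticMap()
    for chrom in ("1", "2", "X"):
        gmap.add_chromosome(chrom, [1.0, 200e6], [1e-6, 200.0])
    return gmap


@pytest.fixture(scope="session")
def small_cohort():
    """Session-wide small simulated cohort (genotypes, map, phenotypes, truth)."""
    cfg = SimConfig(
        n_female=300,
        n_male=300,
        variants_per_chromosome={"1": 60, "X": 60},
        n_phenotypes=4,
        seed=11,
    )
    dosages, gmap, pheno, conf, truth = simulate_cohort(cfg)
    return {
        "config": cfg,
        "dosages": dosages,
        "gmap": gmap,
        "pheno": pheno,
        "confounds": conf,
        "truth": truth,
    }
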