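import numpy as np
import pytest

from urbangen.geno_io import GenotypeDataset, Individual, LocusDef
from urbangen.synthetic_data import SimConfig, draw_site_frequencies, simulate_colonies


@pytest.fixture
def toy_dataset() -> GenotypeDataset:
    """Two sites x two loci, one missing call, mixed sexes."""
    panel = [LocusDef("LA"), LocusDef("LB")]
    inds = [
        Individual("f1", "Bombus test", "CC", genotype={"LA": (154, 158), "LB": (100, 102)}),
        Individual("f2", "Bombus test", "CC", genotype={"LA": (154, 154), "LB": (100, 100)}),
        Individual("f3", "Bombus test", "ED", genotype={"LB": (102, 104)}),
        Individual(
            "m1", "Bombus test", "ED", sex="male", caste="male",
            genotype={"LA": (158,), "LB": (104,)},
        ),
    ]
    return GenotypeDataset(panel=panel, individuals=inds)


@pytest.fixture
def clean_colonies():
    """Error-free colony-structured dataset with truth, 2 sites."""
    cfg = SimConfig(
        n_sites=2,
        colonies_per_site=12,
        workers_per_colony_mean=2.5,
        n_loci=12,
        alleles_per_locus=8,
        seed=11,
    )
    freqs = draw_site_frequencies(cfg)
    ds, truth = simulate_colonies(cfg, freqs)
    return cfg, ds, truth


def make_females(genotypes, species="B", site="S1", prefix="f"):
    """Individuals from a list of {locus: call} dicts."""
    return [
        Individual(f"{prefix}{k + 1}", species, site, genotype=dict(g))
        for k, g in enumerate(genotypes)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


# Published colony-density chain for five bumble bee species at four sites
# (counts N_i sampled, N_g genotyped, N_nr families detected; expected N_ns
# and N_c to 1 decimal, None = dash where N_g <= 15).  N_i/N_g of 0 encode
# cells where no females were reported.
DENSITY_TABLE = [
    # species, site, N_i, N_g, N_nr, N_ns, N_c
    ("B. auricomus", "CC", 56, 54, 54, 56.0, 84.0),
    ("B. auricomus", "CW", 0, 0, None, None, None),
    ("B. auricomus", "ED", 39, 38, 36, 36.9, 55.4),
    ("B. auricomus", "SNR", 44, 38, 36, 41.7, 62.5),
    ("B. bimaculatus", "CC", 1, 1, None, None, None),
    ("B. bimaculatus", "CW", 72, 70, 64, 65.8, 98.7),
    ("B. bimaculatus", "ED", 49, 49, 46, 46.0, 69.0),
    ("B. bimaculatus", "SNR", 38, 34, 33, 36.9, 55.3),
    ("B. griseocollis", "CC", 45, 45, 45, 45.0, 67.5),
    ("B. griseocollis", "CW", 12, 12, None, None, None),
    ("B. griseocollis", "ED", 61, 56, 54, 58.8, 88.2),
    ("B. griseocollis", "SNR", 34, 32, 32, 34.0, 51.0),
    ("B. impatiens", "CC", 53, 48, 45, 49.7, 74.5),
    ("B. impatiens", "CW", 42, 42, 41, 41.0, 61.5),
    ("B. impatiens", "ED", 71, 64, 58, 64.3, 96.5),
    ("B. impatiens", "SNR", 41, 39, 35, 36.8, 55.2),
    ("B. pensylvanicus", "CC", 39, 38, 28, 28.7, 43.1),
    ("B. pensylvanicus", "CW", 5, 5, None, None, None),
    ("B. pensylvanicus", "ED", 19, 16, 11, 13.1, 19.6),
    ("B. pensylvanicus", "SNR", 53, 52, 44, 44.8, 67.3),
]
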