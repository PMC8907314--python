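"""Male ploidy classification from multilocus heterozygosity.

In haplodiploids, normal males are haploid and can never be heterozygous;
a male scored heterozygous at several microsatellite loci is a diploid male,
the product of a fertilized egg homozygous at the complementary sex
determination locus and therefore an inbreeding signal.  The classifier
applies the conventional hard rule: a male is diploid when three or more of
his successfully genotyped loci are heterozygous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geno_io import MALE, GenotypeDataset, Individual

__all__ = [
    "count_het_loci",
    "classify_male",
    "summarize_diploidy",
    "false_diploid_rate",
]

MIN_HET_DEFAULT = 3


def count_het_loci(male: Individual) -> int:
    """Number of typed loci with two distinct alleles; missing loci excluded.

    Raises on a male with zero typed loci (counted among sampled but not
    among genotyped males).
    """
    if not male.genotype:
        raise ValueError(f"{male.id}: no typed loci")
    return sum(
        1 for call in male.genotype.values() if len(call) == 2 and call[0] != call[1]
    )


def classify_male(male: Individual, min_het: int = MIN_HET_DEFAULT) -> str:
    """``"diploid"`` iff the heterozygous-locus count reaches ``min_het``."""
    return "diploid" if count_het_loci(male) >= min_het else "haploid"


def summarize_diploidy(
    ds: GenotypeDataset, min_het: int = MIN_HET_DEFAULT
) -> pd.DataFrame:
    """Per species x site and global male-diploidy table.

    Columns: ``N_i`` males sampled (including genotyping failures recorded
    as individuals without typed loci), ``N_g`` successfully genotyped,
    ``N_d`` diploid under the >= ``min_het`` heterozygous-loci rule,
    ``percent`` = 100 * N_d / N_g rounded to 2 decimals (NaN when N_g = 0),
    and ``indeterminate``: genotyped males typed at fewer than ``min_het``
    loci, which the hard rule can only ever call haploid.
    """
    males = ds.males()
    species_order = sorted({m.species for m in males}) if males else []
    sites = sorted({m.site for m in males}) if males else []
    rows = []
    for species in species_order:
        cohort = [m for m in males if m.species == species]
        for site in [*sites, None]:
            group = [m for m in cohort if site is None or m.site == site]
            n_i = len(group)
            genotyped = [m for m in group if m.genotype]
            n_g = len(genotyped)
            n_d = sum(1 for m in genotyped if classify_male(m, min_het) == "diploid")
            indeterminate = sum(
                1 for m in genotyped if len(m.genotype) < min_het
            )
            rows.append(
                {
                    "species": species,
                    "site": site if site is not None else "Global",
                    "N_i": n_i,
                    "N_g": n_g,
                    "N_d": n_d if n_g else np.nan,
                    "percent": round(100.0 * n_d / n_g, 2) if n_g else np.nan,
                    "indeterminate": indeterminate,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["species", "site", "N_i", "N_g", "N_d", "percent", "indeterminate"],
    )


def false_diploid_rate(het_probs, min_het: int = MIN_HET_DEFAULT) -> float:
    """Closed-form chance a haploid male is misclassified as diploid.

    A haploid male can only appear heterozygous at a locus through a scoring
    error.  Given per-locus probabilities that an error makes the locus read
    heterozygous (a scalar is broadcast as a binomial), the false-diploid
    rate is the exact tail P(#het loci >= min_het), computed by the
    Poisson-binomial recursion.  At zero error the rate is exactly 0.
    """
    probs = np.atleast_1d(np.asarray(het_probs, dtype=float))
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("het probabilities must be in [0, 1]")
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return float(pmf[min_het:].sum())
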