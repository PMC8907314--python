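"""Weir–Cockerham F-statistics and rarefaction-standardized allelic richness.

Implements the classic variance-components estimators of population
differentiation (theta, i.e. F_ST) and inbreeding (f, i.e. F_IS) for
multiallelic codominant loci with unequal sample sizes, multilocus ratios of
summed components, percentile bootstrap confidence intervals over loci, and
the hypergeometric rarefaction estimator of allelic richness.

Conventions: only diploid females enter the F-statistic computations (the
analyses these estimators serve run on one-sister-per-colony female data);
negative estimates are reported as computed, never truncated at zero; sites
with fewer than ``min_pop`` retained genotypes are excluded from theta / f /
per-site richness (global richness keeps them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .geno_io import FEMALE, GenotypeDataset, Individual

__all__ = [
    "PopGenSummary",
    "wc_components",
    "multilocus_fstats",
    "bootstrap_ci",
    "rarefied_ar",
    "popgen_summary",
]

MIN_POP_DEFAULT = 25


# ---------------------------------------------------------------------------
# Weir–Cockerham variance components
# ---------------------------------------------------------------------------

def _site_arrays(
    inds: Sequence[Individual], locus: str
) -> dict[str, list[tuple[int, int]]]:
    per_site: dict[str, list[tuple[int, int]]] = {}
    for ind in inds:
        call = ind.call(locus)
        if call is not None and len(call) == 2:
            per_site.setdefault(ind.site, []).append((call[0], call[1]))
    return per_site


def wc_components(
    ds: GenotypeDataset | Sequence[Individual], locus: str
) -> tuple[float, float, float, bool]:
    """Variance components (a, b, c) for one locus, summed over alleles.

    ``a`` is the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals, computed with the standard n_c
    weighting for unequal sample sizes from per-site allele frequencies and
    observed heterozygote frequencies.  Returns ``(a, b, c, monomorphic)``;
    a monomorphic locus yields (0, 0, 0, True) and should be excluded from
    ratio estimates.  Only diploid female genotypes contribute.
    """
    inds = (
        [i for i in ds.individuals if i.sex == FEMALE]
        if isinstance(ds, GenotypeDataset)
        else [i for i in ds if i.sex == FEMALE]
    )
    per_site = {s: g for s, g in _site_arrays(inds, locus).items() if len(g) >= 2}
    if len(per_site) < 2:
        raise ValueError(
            f"{locus}: need >= 2 sites with >= 2 typed diploid females"
        )
    sites = sorted(per_site)
    n = np.array([len(per_site[s]) for s in sites], dtype=float)
    r = len(sites)
    alleles = sorted({a for s in sites for g in per_site[s] for a in g})
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0, True

    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p = np.array(
            [
                sum(g.count(allele) for g in map(list, per_site[s])) / (2 * len(per_site[s]))
                for s in sites
            ]
        )
        h = np.array(
            [
                sum(1 for g in per_site[s] if (allele in g) and g[0] != g[1])
                / len(per_site[s])
                for s in sites
            ]
        )
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum, False


def _per_locus_components(
    ds: GenotypeDataset | Sequence[Individual], loci: Sequence[str]
) -> dict[str, tuple[float, float, float]]:
    comps: dict[str, tuple[float, float, float]] = {}
    for locus in loci:
        try:
            a, b, c, mono = wc_components(ds, locus)
        except ValueError:
            continue
        if not mono:
            comps[locus] = (a, b, c)
    return comps


def multilocus_fstats(
    ds: GenotypeDataset | Sequence[Individual], loci: Sequence[str] | None = None
) -> tuple[float, float]:
    """Multilocus theta (F_ST) and f (F_IS) as ratios of summed components.

    ``theta = sum(a) / sum(a + b + c)`` and ``f = 1 - sum(c) / sum(b + c)``,
    sums running over alleles and polymorphic loci.
    """
    if loci is None:
        loci = (
            ds.locus_names
            if isinstance(ds, GenotypeDataset)
            else sorted({l for i in ds for l in i.genotype})
        )
    comps = _per_locus_components(ds, loci)
    if not comps:
        raise ValueError("no polymorphic loci with sufficient data")
    a = sum(v[0] for v in comps.values())
    b = sum(v[1] for v in comps.values())
    c = sum(v[2] for v in comps.values())
    theta = a / (a + b + c)
    f = 1.0 - c / (b + c)
    return theta, f


def bootstrap_ci(
    ds: GenotypeDataset | Sequence[Individual],
    statistic: str = "theta",
    n_boot: int = 1000,
    seed: int = 0,
    loci: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Percentile 95% CI by resampling loci with replacement.

    ``statistic`` is ``"theta"`` or ``"f"``.  Because the estimator is a
    ratio of locus sums, loci are the natural resampling unit.
    """
    if loci is None:
        loci = (
            ds.locus_names
            if isinstance(ds, GenotypeDataset)
            else sorted({l for i in ds for l in i.genotype})
        )
    comps = _per_locus_components(ds, loci)
    names = sorted(comps)
    if len(names) < 2:
        raise ValueError("bootstrap requires >= 2 polymorphic loci")
    arr = np.array([comps[l] for l in names])  # (L, 3)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(names), size=(n_boot, len(names)))
    sums = arr[idx].sum(axis=1)  # (n_boot, 3)
    a, b, c = sums[:, 0], sums[:, 1], sums[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        if statistic == "theta":
            vals = a / (a + b + c)
        elif statistic == "f":
            vals = 1.0 - c / (b + c)
        else:
            raise ValueError("statistic must be 'theta' or 'f'")
    vals = vals[np.isfinite(vals)]
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

def rarefied_ar_locus(counts: Sequence[int], g: int) -> float:
    """Expected distinct alleles in a random subsample of ``g`` gene copies.

    ``AR = sum_a [1 - C(N - N_a, g) / C(N, g)]`` for allele copy counts
    ``N_a`` with ``N = sum(N_a)``; exact hypergeometric expectation.
    """
    counts = [int(c) for c in counts if c > 0]
    n_total = sum(counts)
    if g < 1:
        raise ValueError("g must be >= 1")
    if n_total < g:
        raise ValueError(f"locus has {n_total} gene copies < depth {g}")
    denom = comb(n_total, g)
    return float(
        sum(1.0 - comb(n_total - na, g) / denom if n_total - na >= g else 1.0
            for na in counts)
    )


def rarefied_ar(
    ds: GenotypeDataset,
    stratum: Sequence[Individual] | None = None,
    g: int = 2,
    loci: Sequence[str] | None = None,
) -> pd.Series:
    """Per-locus rarefied allelic richness at gene-copy depth ``g``.

    Loci with fewer than ``g`` typed gene copies in the stratum are excluded
    (reported as NaN).  Use ``.mean()`` / ``.sem()`` on the result for the
    conventional mean ± SE over loci.
    """
    inds = list(stratum) if stratum is not None else list(ds.individuals)
    loci = list(loci) if loci is not None else ds.locus_names
    vals = {}
    for locus in loci:
        counts = ds.allele_counts(locus, inds)
        n_total = sum(counts.values())
        if n_total < g or n_total == 0:
            vals[locus] = np.nan
        else:
            vals[locus] = rarefied_ar_locus(list(counts.values()), g)
    return pd.Series(vals, name=f"AR(g={g})")


# ---------------------------------------------------------------------------
# Species-level summary
# ---------------------------------------------------------------------------

@dataclass
class PopGenSummary:
    """Multilocus F-statistics with CIs and rarefied allelic richness."""

    species: str
    theta: float
    f: float
    theta_ci95: tuple[float, float]
    f_ci95: tuple[float, float]
    per_locus_components: dict[str, tuple[float, float, float]]
    ar_per_site: dict[str, tuple[float, float]]  # site -> (mean, SE)
    ar_global: tuple[float, float]
    g_sub: int
    g_glob: int
    excluded_sites: list[dict] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {"species": self.species}
        for site, (m, se) in sorted(self.ar_per_site.items()):
            row[f"AR_{site}"] = f"{m:.2f} ({se:.2f})"
        row["AR_global"] = f"{self.ar_global[0]:.2f} ({self.ar_global[1]:.2f})"
        row["F_ST (95% CI)"] = (
            f"{self.theta:.3f} ({self.theta_ci95[0]:.3f} to {self.theta_ci95[1]:.3f})"
        )
        row["F_IS (95% CI)"] = (
            f"{self.f:.3f} ({self.f_ci95[0]:.3f} to {self.f_ci95[1]:.3f})"
        )
        return row


def _sem(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if len(values) < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def popgen_summary(
    ds: GenotypeDataset,
    species: str,
    min_pop: int = MIN_POP_DEFAULT,
    g_sub: int | None = None,
    g_glob: int | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> PopGenSummary:
    """Per-species population-genetic summary on deduplicated female data.

    Sites with fewer than ``min_pop`` genotyped females are excluded from
    the F-statistics and per-site richness (recorded in ``excluded_sites``)
    but retained in the global richness.  Rarefaction depths default to
    twice the smallest included site size (``g_sub``) and twice the species
    total (``g_glob``), i.e. they are computed from the data at hand.
    """
    females = [i for i in ds.individuals if i.species == species and i.sex == FEMALE]
    if not females:
        raise ValueError(f"no females for species {species}")
    by_site: dict[str, list[Individual]] = {}
    for ind in females:
        by_site.setdefault(ind.site, []).append(ind)
    included, excluded = {}, []
    for site, members in sorted(by_site.items()):
        if len(members) < min_pop:
            excluded.append(
                {"site": site, "n": len(members), "reason": f"< {min_pop} samples"}
            )
        else:
            included[site] = members
    if len(included) < 2:
        raise ValueError(
            f"{species}: fewer than 2 sites with >= {min_pop} genotypes"
        )
    kept = [i for s in included.values() for i in s]
    loci = [l for l in ds.locus_names if any(i.is_typed(l) for i in kept)]
    theta, f = multilocus_fstats(kept, loci)
    theta_ci = bootstrap_ci(kept, "theta", n_boot=n_boot, seed=seed, loci=loci)
    f_ci = bootstrap_ci(kept, "f", n_boot=n_boot, seed=seed + 1, loci=loci)
    comps = _per_locus_components(kept, loci)

    if g_sub is None:
        g_sub = 2 * min(len(m) for m in included.values())
    if g_glob is None:
        g_glob = 2 * len(females)
    ar_site = {}
    for site, members in included.items():
        series = rarefied_ar(ds, members, g=g_sub, loci=loci)
        ar_site[site] = (float(series.mean()), _sem(series.to_numpy()))
    glob = rarefied_ar(ds, females, g=g_glob, loci=loci)
    ar_global = (float(glob.mean()), _sem(glob.to_numpy()))
    return PopGenSummary(
        species=species,
        theta=theta,
        f=f,
        theta_ci95=theta_ci,
        f_ci95=f_ci,
        per_locus_components=comps,
        ar_per_site=ar_site,
        ar_global=ar_global,
        g_sub=g_sub,
        g_glob=g_glob,
        excluded_sites=excluded,
    )
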