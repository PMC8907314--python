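"""Haplodiploid colony-structured genotype and body-size simulator.

The generator emulates the statistical structure the downstream analyses
assume for urban bumble bee populations:

* monogynous / monoandrous colonies — one diploid queen mated to a single
  haploid drone, so sampled workers are full sisters (r = 0.75);
* several sites whose allele frequencies diverge by pure binomial drift from
  a common base frequency vector, calibrated so the expected differentiation
  equals a requested F_ST via ``1 - (1 - 1/(2*Ne))**t``;
* single-locus complementary sex determination (csd): fertilized eggs that
  are homozygous at the csd locus develop as diploid males, so diploid-male
  frequency rises with queen–drone relatedness (inbreeding);
* an observation model with per-allele mistyping, a hidden null allele per
  locus (null homozygotes read as missing, null heterozygotes as visible-
  allele homozygotes), and whole-locus genotyping failure;
* Gaussian worker body size with per-(species, site) means, a colony random
  effect shared by sisters, and residual noise.

All randomness flows from ``SimConfig.seed`` through deterministically
spawned substreams, so a run is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .geno_io import FEMALE, MALE, GenotypeDataset, Individual, LocusDef

__all__ = [
    "SimConfig",
    "BodySizeConfig",
    "SiteFrequencies",
    "SimTruth",
    "draw_site_frequencies",
    "simulate_colonies",
    "apply_observation_model",
    "simulate_body_size",
    "simulate_dataset",
    "solve_drift_generations",
]

DRIFT_NE = 1000  # effective size used when converting target F_ST to drift time


@dataclass
class BodySizeConfig:
    """Gaussian body-size model: site mean + colony effect + residual (mm)."""

    base_mean: float = 4.5
    site_means: Mapping[tuple[str, str], float] | None = None  # (species, site) -> mm
    colony_sd: float = 0.25
    residual_sd: float = 0.35

    def mean_for(self, species: str, site: str) -> float:
        if self.site_means is not None and (species, site) in self.site_means:
            return self.site_means[(species, site)]
        return self.base_mean


@dataclass
class SimConfig:
    """Configuration of one synthetic study.

    Defaults mirror the field design the analyses target: four sites, tens of
    colonies per site each contributing a small number of netted workers, a
    panel of 12 polymorphic loci with ~8 alleles, and noise rates switched
    off (noise is an explicit scenario choice, not a baseline).
    """

    n_sites: int = 4
    colonies_per_site: int = 40
    workers_per_colony_mean: float = 1.5  # zero-truncated Poisson mean parameter
    males_per_colony_mean: float = 0.0
    n_loci: int = 12
    alleles_per_locus: int = 8
    base_freq_concentration: float = 1.0
    target_fst: float = 0.0
    csd_allele_count: int = 10
    mistype_rate: float = 0.0
    null_allele_freq: float | Mapping[str, float] = 0.0
    failure_rate: float = 0.0
    body_size: BodySizeConfig = field(default_factory=BodySizeConfig)
    species: str = "Bombus sim"
    site_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mistype_rate", "failure_rate", "target_fst"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.colonies_per_site < 1:
            raise ValueError("colonies_per_site must be >= 1")
        if self.csd_allele_count < 2:
            raise ValueError("csd_allele_count must be >= 2")
        if self.base_freq_concentration <= 0:
            raise ValueError("base_freq_concentration must be > 0")

    def sites(self) -> list[str]:
        if self.site_names is not None:
            if len(self.site_names) != self.n_sites:
                raise ValueError("site_names length must equal n_sites")
            return list(self.site_names)
        return [f"S{i + 1}" for i in range(self.n_sites)]

    def null_freq_for(self, locus: str) -> float:
        if isinstance(self.null_allele_freq, Mapping):
            return float(self.null_allele_freq.get(locus, 0.0))
        return float(self.null_allele_freq)

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream derived from the master seed."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**32)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage_key,))
        )


@dataclass
class SiteFrequencies:
    """Per-site, per-locus allele frequency vectors and their realized F_ST."""

    locus_names: list[str]
    base: dict[str, np.ndarray]  # locus -> (K,) base frequencies
    per_site: dict[str, dict[str, np.ndarray]]  # site -> locus -> (K,)
    csd_base: np.ndarray
    csd_per_site: dict[str, np.ndarray]
    realized_fst: float
    ne: int
    generations: int


@dataclass
class Colony:
    colony_id: str
    site: str
    queen: dict[str, tuple[int, int]]
    drone: dict[str, int]
    queen_csd: tuple[int, int]
    drone_csd: int


@dataclass
class SimTruth:
    """Generator-side ground truth used by recovery tests."""

    frequencies: SiteFrequencies
    colonies: dict[str, Colony]
    family_of: dict[str, str]  # sampled female id -> colony id
    ploidy_of: dict[str, int]  # sampled male id -> 1 or 2
    colonies_sampled: dict[str, int]  # site -> number of distinct sampled colonies
    body_size_means: dict[tuple[str, str], float] = field(default_factory=dict)


def solve_drift_generations(target_fst: float, ne: int = DRIFT_NE) -> int:
    """Generations t with 1 - (1 - 1/(2*Ne))**t closest to ``target_fst``."""
    if target_fst <= 0:
        return 0
    t = math.log(1.0 - target_fst) / math.log(1.0 - 1.0 / (2 * ne))
    return max(1, int(round(t)))


def _parametric_fst(per_locus_site_freqs: list[np.ndarray]) -> float:
    """Ratio-of-sums F_ST of known frequency vectors across sites.

    Each array is (n_sites, K).  Uses the unbiased among-site variance of
    each allele frequency over its expectation p̄(1-p̄), summed over alleles
    and loci.
    """
    num = 0.0
    den = 0.0
    for freqs in per_locus_site_freqs:
        pbar = freqs.mean(axis=0)
        var = freqs.var(axis=0, ddof=1)
        num += var.sum()
        den += (pbar * (1.0 - pbar)).sum()
    return num / den if den > 0 else 0.0


def _drift(
    base: np.ndarray, ne: int, t: int, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Independently drift ``base`` (K,) in each site for t generations."""
    freqs = np.tile(base, (n_sites, 1))
    for _ in range(t):
        counts = rng.multinomial(2 * ne, freqs)
        freqs = counts / (2.0 * ne)
    return freqs


def draw_site_frequencies(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> SiteFrequencies:
    """Draw base allele frequencies and drift them apart to the target F_ST.

    Base frequencies per locus are Dirichlet(concentration); each site then
    drifts independently for ``t`` binomial generations of ``2*Ne`` gene
    copies, with ``Ne`` fixed and ``t`` chosen so the expected fixation index
    ``1 - (1 - 1/(2Ne))**t`` matches ``cfg.target_fst``.  ``target_fst = 0``
    returns identical site vectors (no drift).
    """
    rng = rng if rng is not None else cfg.rng("frequencies")
    sites = cfg.sites()
    locus_names = [f"L{i + 1:02d}" for i in range(cfg.n_loci)]
    t = solve_drift_generations(cfg.target_fst)
    base: dict[str, np.ndarray] = {}
    per_site: dict[str, dict[str, np.ndarray]] = {s: {} for s in sites}
    stacks = []
    for name in locus_names:
        p = rng.dirichlet(np.full(cfg.alleles_per_locus, cfg.base_freq_concentration))
        base[name] = p
        drifted = _drift(p, DRIFT_NE, t, cfg.n_sites, rng)
        stacks.append(drifted)
        for k, s in enumerate(sites):
            per_site[s][name] = drifted[k]
    csd_base = np.full(cfg.csd_allele_count, 1.0 / cfg.csd_allele_count)
    csd_drifted = _drift(csd_base, DRIFT_NE, t, cfg.n_sites, rng)
    realized = _parametric_fst(stacks) if t > 0 else 0.0
    return SiteFrequencies(
        locus_names=locus_names,
        base=base,
        per_site=per_site,
        csd_base=csd_base,
        csd_per_site={s: csd_drifted[k] for k, s in enumerate(sites)},
        realized_fst=realized,
        ne=DRIFT_NE,
        generations=t,
    )


def _ztpoisson(mean: float, rng: np.random.Generator) -> int:
    """Zero-truncated Poisson draw (rejection; mean parameter of the parent)."""
    if mean <= 0:
        return 1
    while True:
        k = rng.poisson(mean)
        if k > 0:
            return int(k)


def _sample_allele(freqs: np.ndarray, rng: np.random.Generator) -> int:
    # allele codes are 1-based bin indices scaled to look like bp lengths
    return int(rng.choice(len(freqs), p=freqs)) + 1


def simulate_colonies(
    cfg: SimConfig, freqs: SiteFrequencies, rng: np.random.Generator | None = None
) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate colonies and the sampled workers/males they contribute.

    Per colony: queen = two alleles per locus from the site frequencies,
    drone = one allele per locus.  Every sampled worker inherits the drone
    allele plus one random queen allele at each locus.  The csd locus is
    transmitted the same way; a sampled male is, with probability
    P(csd homozygote | parents), a fertilized diploid male, otherwise a
    haploid son of the queen.
    """
    rng = rng if rng is not None else cfg.rng("colonies")
    allele_offset = 100  # shift codes into a fragment-length-like range
    panel = [LocusDef(name=n) for n in freqs.locus_names]
    individuals: list[Individual] = []
    colonies: dict[str, Colony] = {}
    family_of: dict[str, str] = {}
    ploidy_of: dict[str, int] = {}
    colonies_sampled: dict[str, int] = {}

    for site in cfg.sites():
        site_freqs = freqs.per_site[site]
        csd_freqs = freqs.csd_per_site[site]
        sampled_here: set[str] = set()
        for c in range(cfg.colonies_per_site):
            cid = f"{site}-C{c + 1:03d}"
            queen = {
                locus: (
                    _sample_allele(site_freqs[locus], rng) + allele_offset,
                    _sample_allele(site_freqs[locus], rng) + allele_offset,
                )
                for locus in freqs.locus_names
            }
            drone = {
                locus: _sample_allele(site_freqs[locus], rng) + allele_offset
                for locus in freqs.locus_names
            }
            queen_csd = (
                _sample_allele(csd_freqs, rng),
                _sample_allele(csd_freqs, rng),
            )
            drone_csd = _sample_allele(csd_freqs, rng)
            colony = Colony(cid, site, queen, drone, queen_csd, drone_csd)
            colonies[cid] = colony

            n_workers = _ztpoisson(cfg.workers_per_colony_mean, rng)
            for w in range(n_workers):
                wid = f"{cid}-F{w + 1}"
                genotype = {
                    locus: tuple(
                        sorted(
                            (
                                queen[locus][rng.integers(2)],
                                drone[locus],
                            )
                        )
                    )
                    for locus in freqs.locus_names
                }
                individuals.append(
                    Individual(
                        id=wid,
                        species=cfg.species,
                        site=site,
                        sex=FEMALE,
                        caste="worker",
                        genotype=genotype,
                    )
                )
                family_of[wid] = cid
                sampled_here.add(cid)

            if cfg.males_per_colony_mean > 0:
                n_males = int(rng.poisson(cfg.males_per_colony_mean))
            else:
                n_males = 0
            # probability a fertilized egg is csd-homozygous given the parents
            p_dm = sum(a == drone_csd for a in queen_csd) / 2.0
            for m in range(n_males):
                mid = f"{cid}-M{m + 1}"
                if rng.random() < p_dm:
                    genotype = {
                        locus: tuple(
                            sorted((queen[locus][rng.integers(2)], drone[locus]))
                        )
                        for locus in freqs.locus_names
                    }
                    ploidy_of[mid] = 2
                else:
                    genotype = {
                        locus: (queen[locus][rng.integers(2)],)
                        for locus in freqs.locus_names
                    }
                    ploidy_of[mid] = 1
                individuals.append(
                    Individual(
                        id=mid,
                        species=cfg.species,
                        site=site,
                        sex=MALE,
                        caste="male",
                        genotype=genotype,
                    )
                )
        colonies_sampled[site] = len(sampled_here)

    ds = GenotypeDataset(panel=panel, individuals=individuals)
    ds.log(
        f"simulate_colonies: {cfg.n_sites} sites x {cfg.colonies_per_site} colonies, "
        f"{len(individuals)} individuals, target_fst={cfg.target_fst}"
    )
    truth = SimTruth(
        frequencies=freqs,
        colonies=colonies,
        family_of=family_of,
        ploidy_of=ploidy_of,
        colonies_sampled=colonies_sampled,
    )
    return ds, truth


def apply_observation_model(
    ds: GenotypeDataset, cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeDataset:
    """Overlay mistyping, null alleles, and genotyping failure on true calls.

    Independently per allele copy: with probability ``mistype_rate`` the copy
    is replaced by a frequency-weighted draw from its site's allele pool;
    with probability ``null_allele_freq(locus)`` the copy is a null.  A
    diploid call with two nulls (or a haploid call with one) becomes missing;
    one null leaves an apparent homozygote for the visible allele.  Finally
    the whole-locus call fails (missing) with probability ``failure_rate``.
    All rates zero returns an identical dataset.
    """
    rng = rng if rng is not None else cfg.rng("observation")
    site_pools: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    def pool(site: str, locus: str):
        key = (site, locus)
        if key not in site_pools:
            counts = ds.allele_counts(
                locus, [i for i in ds.individuals if i.site == site]
            )
            alleles = np.array(sorted(counts))
            weights = np.array([counts[a] for a in alleles], dtype=float)
            site_pools[key] = (alleles, weights / weights.sum())
        return site_pools[key]

    out_individuals = []
    for ind in ds.individuals:
        genotype: dict[str, tuple[int, ...]] = {}
        for locus, call in ind.genotype.items():
            if cfg.failure_rate > 0 and rng.random() < cfg.failure_rate:
                continue
            null_p = cfg.null_freq_for(locus)
            observed: list[int] = []
            dropped = 0
            for allele in call:
                if null_p > 0 and rng.random() < null_p:
                    dropped += 1
                    continue
                if cfg.mistype_rate > 0 and rng.random() < cfg.mistype_rate:
                    alleles, probs = pool(ind.site, locus)
                    allele = int(rng.choice(alleles, p=probs))
                observed.append(allele)
            if not observed:
                continue
            if len(call) == 2 and dropped == 1:
                observed = [observed[0], observed[0]]  # null heterozygote
            genotype[locus] = tuple(sorted(observed)) if len(observed) == 2 else (
                observed[0],
            )
        out_individuals.append(replace(ind, genotype=genotype))
    out = GenotypeDataset(
        panel=list(ds.panel), individuals=out_individuals, provenance=list(ds.provenance)
    )
    out.log(
        "apply_observation_model: "
        f"mistype={cfg.mistype_rate}, null={cfg.null_allele_freq}, "
        f"failure={cfg.failure_rate}"
    )
    return out


def simulate_body_size(
    truth: SimTruth,
    cfg: SimConfig,
    ds: GenotypeDataset,
    rng: np.random.Generator | None = None,
) -> GenotypeDataset:
    """Attach thorax widths to sampled workers (site mean + colony + residual).

    Colony effects are shared by colony-mates; widths are truncated at zero
    (irrelevant at realistic means ~4.5 mm and sds ~0.3 mm).
    """
    rng = rng if rng is not None else cfg.rng("bodysize")
    bs = cfg.body_size
    colony_effect: dict[str, float] = {}
    for ind in ds.individuals:
        if ind.sex != FEMALE or ind.id not in truth.family_of:
            continue
        cid = truth.family_of[ind.id]
        if cid not in colony_effect:
            colony_effect[cid] = (
                rng.normal(0.0, bs.colony_sd) if bs.colony_sd > 0 else 0.0
            )
        mean = bs.mean_for(ind.species, ind.site)
        truth.body_size_means[(ind.species, ind.site)] = mean
        resid = rng.normal(0.0, bs.residual_sd) if bs.residual_sd > 0 else 0.0
        ind.thorax_width = max(1e-9, mean + colony_effect[cid] + resid)
    ds.log("simulate_body_size: widths attached")
    return ds


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Full generator chain: frequencies -> colonies -> noise -> body size."""
    freqs = draw_site_frequencies(cfg)
    ds, truth = simulate_colonies(cfg, freqs)
    ds = apply_observation_model(ds, cfg)
    ds = simulate_body_size(truth, cfg, ds)
    return ds, truth
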