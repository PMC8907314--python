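"""Genotype quality-control ladder.

Order of operations follows the analysis narrative: per-species missingness
filtering (loci first, then individuals), null-allele screening (heterozygote
deficit, Chakraborty-style), sibship inference (elsewhere), one-sister-per-
colony deduplication, linkage-disequilibrium pruning, and Hardy–Weinberg
reporting.  Every drop is recorded with a machine-readable reason in a
:class:`QCReport`, so the retained panel is replayable from the report alone.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .geno_io import FEMALE, GenotypeDataset, Individual

if TYPE_CHECKING:  # pragma: no cover
    from .sibship_density import SibshipPartition

__all__ = [
    "QCReport",
    "filter_missingness",
    "estimate_null_freq",
    "filter_null_loci",
    "hwe_test",
    "ld_test_and_prune",
    "dedupe_sisters",
]


@dataclass
class QCReport:
    """Machine-readable record of every QC decision."""

    dropped_individuals: list[dict] = field(default_factory=list)
    dropped_loci: list[dict] = field(default_factory=list)
    ld_pairs: list[dict] = field(default_factory=list)
    hwe: list[dict] = field(default_factory=list)
    retained_panel: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def merge(self, other: "QCReport") -> "QCReport":
        self.dropped_individuals.extend(other.dropped_individuals)
        self.dropped_loci.extend(other.dropped_loci)
        self.ld_pairs.extend(other.ld_pairs)
        self.hwe.extend(other.hwe)
        self.retained_panel.update(other.retained_panel)
        self.warnings.extend(other.warnings)
        return self

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=1, default=float, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _species_strata(ds: GenotypeDataset) -> dict[str, list[Individual]]:
    strata: dict[str, list[Individual]] = {}
    for ind in ds.individuals:
        strata.setdefault(ind.species, []).append(ind)
    return strata


def _drop_loci_for_species(
    ds: GenotypeDataset, to_drop: dict[str, set[str]]
) -> GenotypeDataset:
    """Blank calls at species-specific dropped loci (the panel is shared)."""
    from dataclasses import replace

    out = []
    for ind in ds.individuals:
        dropped = to_drop.get(ind.species, set())
        if dropped and any(l in ind.genotype for l in dropped):
            genotype = {l: c for l, c in ind.genotype.items() if l not in dropped}
            out.append(replace(ind, genotype=genotype))
        else:
            out.append(ind)
    return GenotypeDataset(
        panel=list(ds.panel), individuals=out, provenance=list(ds.provenance)
    )


def filter_missingness(
    ds: GenotypeDataset, threshold: float = 0.20
) -> tuple[GenotypeDataset, QCReport]:
    """Drop loci then individuals with >= ``threshold`` genotyping failure.

    Applied per species: first loci whose missing-call fraction across that
    species reaches the threshold, then individuals whose missing fraction
    over the *retained* loci reaches it.  The boundary is inclusive (a 20%
    failure rate is dropped at the default threshold).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    report = QCReport()
    loci = ds.locus_names
    drop_loci: dict[str, set[str]] = {}
    retained: dict[str, list[str]] = {}
    for species, members in _species_strata(ds).items():
        if not members:
            report.warnings.append(f"{species}: empty stratum skipped")
            continue
        dropped = set()
        for locus in loci:
            miss = sum(0 if i.is_typed(locus) else 1 for i in members) / len(members)
            if miss >= threshold:
                dropped.add(locus)
                report.dropped_loci.append(
                    {
                        "species": species,
                        "locus": locus,
                        "reason": "missingness",
                        "missing_fraction": miss,
                    }
                )
        drop_loci[species] = dropped
        retained[species] = [l for l in loci if l not in dropped]
    ds2 = _drop_loci_for_species(ds, drop_loci)

    keep_ids = []
    for ind in ds2.individuals:
        panel = retained.get(ind.species, loci)
        if not panel:
            report.warnings.append(
                f"{ind.species}: no loci retained, individuals kept untyped"
            )
            keep_ids.append(ind.id)
            continue
        miss = (len(panel) - ind.n_typed(panel)) / len(panel)
        if miss >= threshold:
            report.dropped_individuals.append(
                {
                    "id": ind.id,
                    "species": ind.species,
                    "reason": "missingness",
                    "missing_fraction": miss,
                }
            )
        else:
            keep_ids.append(ind.id)
    out = ds2.subset(keep_ids)
    out.provenance = list(ds.provenance)
    out.log(
        f"filter_missingness: threshold={threshold}, dropped "
        f"{len(report.dropped_loci)} species-locus pairs, "
        f"{len(report.dropped_individuals)} individuals"
    )
    report.retained_panel = retained
    return out, report


def _unbiased_expected_het(counts: dict[int, int]) -> float:
    """Nei's unbiased expected heterozygosity from gene-copy counts."""
    n_copies = sum(counts.values())
    if n_copies < 2:
        return 0.0
    p2 = sum((c / n_copies) ** 2 for c in counts.values())
    return (n_copies / (n_copies - 1)) * (1.0 - p2)


def estimate_null_freq(
    ds: GenotypeDataset, locus: str, stratum: Sequence[Individual] | None = None
) -> tuple[float, bool]:
    """Heterozygote-deficit null-allele estimate r = (He - Ho) / (He + Ho).

    He is the unbiased expected heterozygosity from allele frequencies, Ho
    the observed heterozygote fraction among typed diploids.  Negative
    values (heterozygote excess) are permitted.  Returns ``(estimate,
    monomorphic_flag)``; a monomorphic locus yields 0 with the flag set.
    """
    inds = [
        i
        for i in (stratum if stratum is not None else ds.individuals)
        if i.call(locus) is not None and len(i.call(locus)) == 2
    ]
    if len(inds) < 2:
        raise ValueError(f"{locus}: need >= 2 typed diploid individuals")
    counts = ds.allele_counts(locus, inds)
    if len(counts) < 2:
        return 0.0, True
    he = _unbiased_expected_het(dict(counts))
    ho = sum(1 for i in inds if i.call(locus)[0] != i.call(locus)[1]) / len(inds)
    if he + ho == 0:
        return 0.0, True
    return (he - ho) / (he + ho), False


def filter_null_loci(
    ds: GenotypeDataset, threshold: float = 0.25
) -> tuple[GenotypeDataset, QCReport]:
    """Drop loci per species whose null-allele estimate reaches ``threshold``.

    The boundary is inclusive (an estimate of exactly 0.25 is dropped at the
    default).  Intended to run before sibship reconstruction.
    """
    report = QCReport()
    drop: dict[str, set[str]] = {}
    for species, members in _species_strata(ds).items():
        diploids = [i for i in members if i.sex == FEMALE]
        dropped = set()
        for locus in ds.locus_names:
            typed = [
                i
                for i in diploids
                if i.call(locus) is not None and len(i.call(locus)) == 2
            ]
            if len(typed) < 2:
                continue
            r, mono = estimate_null_freq(ds, locus, typed)
            if not mono and r >= threshold:
                dropped.add(locus)
                report.dropped_loci.append(
                    {
                        "species": species,
                        "locus": locus,
                        "reason": "null_allele",
                        "null_estimate": r,
                    }
                )
        drop[species] = dropped
        report.retained_panel[species] = [
            l for l in ds.locus_names if l not in dropped
        ]
    out = _drop_loci_for_species(ds, drop)
    out.log(
        f"filter_null_loci: threshold={threshold}, dropped "
        f"{len(report.dropped_loci)} species-locus pairs"
    )
    return out, report


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (Monte-Carlo)
# ---------------------------------------------------------------------------

def _log_array_prob(het_count: int, genotype_counts: np.ndarray, allele_counts: np.ndarray) -> float:
    """Log conditional probability of a genotype array given allele counts.

    Levene's distribution: P = n! * prod(c_a!) * 2^h / ((2n)! * prod(n_g!)).
    """
    n = genotype_counts.sum()
    return float(
        gammaln(n + 1)
        + gammaln(allele_counts + 1).sum()
        + het_count * np.log(2.0)
        - gammaln(2 * n + 1)
        - gammaln(genotype_counts + 1).sum()
    )


def _array_stats(pairs: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """Heterozygote count, genotype multiplicities, allele counts of pairs (n,2)."""
    ordered = np.sort(pairs, axis=1)
    het = int((ordered[:, 0] != ordered[:, 1]).sum())
    _, genotype_counts = np.unique(ordered, axis=0, return_counts=True)
    _, allele_counts = np.unique(ordered.ravel(), return_counts=True)
    return het, genotype_counts, allele_counts


def hwe_test(
    ds: GenotypeDataset,
    locus: str,
    stratum: Sequence[Individual] | None = None,
    n_perm: int = 1999,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact Hardy–Weinberg test for one locus.

    The statistic is the Levene conditional probability of the observed
    genotype array given the allele counts; the null distribution comes from
    randomly re-pairing the observed allele multiset.  The p-value carries
    the +1 correction, ``p = (1 + #{perm prob <= observed}) / (1 + n_perm)``,
    so it never returns 0.  Monomorphic loci return 1 by convention.
    """
    inds = [
        i
        for i in (stratum if stratum is not None else ds.individuals)
        if i.call(locus) is not None and len(i.call(locus)) == 2
    ]
    if len(inds) < 5:
        raise ValueError(f"{locus}: need >= 5 typed individuals")
    pairs = np.array([i.call(locus) for i in inds])
    copies = pairs.ravel().copy()
    if len(np.unique(copies)) < 2:
        return 1.0
    het, gcounts, acounts = _array_stats(pairs)
    obs_logp = _log_array_prob(het, gcounts, acounts)
    rng = np.random.default_rng(seed)
    hits = 0
    tol = 1e-10
    for _ in range(n_perm):
        rng.shuffle(copies)
        perm_pairs = copies.reshape(-1, 2)
        h, g, a = _array_stats(perm_pairs)
        if _log_array_prob(h, g, a) <= obs_logp + tol:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Linkage disequilibrium: permutation G-test and component pruning
# ---------------------------------------------------------------------------

def _g_statistic(table: np.ndarray) -> float:
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def _joint_genotype_codes(
    inds: Sequence[Individual], locus_a: str, locus_b: str
) -> tuple[np.ndarray, np.ndarray]:
    codes_a: dict[tuple, int] = {}
    codes_b: dict[tuple, int] = {}
    ia, ib = [], []
    for i in inds:
        ca, cb = i.call(locus_a), i.call(locus_b)
        if ca is None or cb is None:
            continue
        ia.append(codes_a.setdefault(tuple(sorted(ca)), len(codes_a)))
        ib.append(codes_b.setdefault(tuple(sorted(cb)), len(codes_b)))
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def _ld_pair_p(
    ia: np.ndarray, ib: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    ka, kb = ia.max() + 1, ib.max() + 1
    table = np.zeros((ka, kb))
    np.add.at(table, (ia, ib), 1.0)
    g_obs = _g_statistic(table)
    hits = 0
    ib_perm = ib.copy()
    for _ in range(n_perm):
        rng.shuffle(ib_perm)
        t = np.zeros((ka, kb))
        np.add.at(t, (ia, ib_perm), 1.0)
        if _g_statistic(t) >= g_obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def ld_test_and_prune(
    ds: GenotypeDataset,
    alpha: float = 0.05,
    n_perm: int = 499,
    seed: int = 0,
) -> tuple[GenotypeDataset, QCReport]:
    """Test every locus pair for LD per species; collapse linked groups.

    The statistic is a G-test on the joint genotype contingency table with a
    permutation null (one locus's genotypes shuffled across individuals).
    Connected components of significantly linked pairs (raw p < ``alpha``)
    are collapsed to a single retained locus: the member with the least
    missingness, ties broken lexicographically by name.  Pairs with fewer
    than 5 jointly typed individuals are skipped and recorded untested.
    """
    report = QCReport()
    rng = np.random.default_rng(seed)
    drop: dict[str, set[str]] = {}
    for species, members in sorted(_species_strata(ds).items()):
        females = [i for i in members if i.sex == FEMALE]
        loci = [l for l in ds.locus_names if any(i.is_typed(l) for i in females)]
        edges: list[tuple[str, str]] = []
        for la, lb in itertools.combinations(loci, 2):
            ia, ib = _joint_genotype_codes(females, la, lb)
            if len(ia) < 5:
                report.ld_pairs.append(
                    {
                        "species": species,
                        "locus_a": la,
                        "locus_b": lb,
                        "p": None,
                        "tested": False,
                    }
                )
                continue
            p = _ld_pair_p(ia, ib, n_perm, rng)
            report.ld_pairs.append(
                {
                    "species": species,
                    "locus_a": la,
                    "locus_b": lb,
                    "p": p,
                    "tested": True,
                }
            )
            if p < alpha:
                edges.append((la, lb))
        # connected components over significant pairs
        parent = {l: l for l in loci}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for la, lb in edges:
            ra, rb = find(la), find(lb)
            if ra != rb:
                parent[ra] = rb
        components: dict[str, list[str]] = {}
        for l in loci:
            components.setdefault(find(l), []).append(l)
        dropped = set()
        for comp in components.values():
            if len(comp) < 2:
                continue

            def missingness(locus: str) -> float:
                return sum(0 if i.is_typed(locus) else 1 for i in females) / len(
                    females
                )

            keep = min(comp, key=lambda l: (missingness(l), l))
            for l in comp:
                if l != keep:
                    dropped.add(l)
                    report.dropped_loci.append(
                        {
                            "species": species,
                            "locus": l,
                            "reason": "linkage_disequilibrium",
                            "retained_component_member": keep,
                        }
                    )
        drop[species] = dropped
        report.retained_panel[species] = [
            l for l in ds.locus_names if l not in dropped
        ]
    out = _drop_loci_for_species(ds, drop)
    out.log(
        f"ld_test_and_prune: alpha={alpha}, n_perm={n_perm}, dropped "
        f"{len(report.dropped_loci)} species-locus pairs"
    )
    return out, report


def dedupe_sisters(
    ds: GenotypeDataset, partition: "SibshipPartition", seed: int = 0
) -> GenotypeDataset:
    """Retain one randomly chosen sister per inferred colony; males untouched.

    ``partition`` must cover every female in ``ds``; a female absent from it
    raises a ValueError naming her id.
    """
    rng = np.random.default_rng(seed)
    family_of = partition.family_of
    families: dict[str, list[str]] = {}
    for ind in ds.females():
        fam = family_of.get(ind.id)
        if fam is None:
            raise ValueError(f"female {ind.id} absent from sibship partition")
        families.setdefault(fam, []).append(ind.id)
    chosen = set()
    for fam in sorted(families):
        members = sorted(families[fam])
        chosen.add(members[rng.integers(len(members))])
    keep = [
        i.id for i in ds.individuals if i.sex != FEMALE or i.id in chosen
    ]
    out = ds.subset(keep)
    out.log(
        f"dedupe_sisters: {len(families)} families, retained {len(chosen)} females"
    )
    return out
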