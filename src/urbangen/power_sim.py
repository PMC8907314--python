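"""Drift-based power simulation for tests of genetic differentiation.

Answers the design question: given this many subpopulations, samples, loci
and alleles, what is the probability of rejecting the null hypothesis of no
differentiation when the true F_ST has a given value?  The mechanism mirrors
the classic drift-based simulation design: subpopulations diverge from a
common base frequency vector by ``t`` generations of multinomial resampling
of ``2*Ne`` gene copies, with ``t`` chosen so the expected fixation index
``1 - (1 - 1/(2*Ne))**t`` equals the target F_ST; per replicate, allele
counts are sampled at the study sample sizes and tested for heterogeneity
with (a) per-locus Pearson chi-square statistics summed over loci, and (b)
per-locus exact tests (Fisher for 2x2, otherwise Monte-Carlo over tables
with fixed margins) combined across loci by the -2*sum(log p) chi-square
rule.  Setting ``t = 0`` (target 0) estimates the type-I error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .synthetic_data import DRIFT_NE, solve_drift_generations

__all__ = [
    "PowerConfig",
    "PowerResult",
    "expected_fst",
    "drift_frequencies",
    "differentiation_test",
    "estimate_power",
]


def expected_fst(ne: int, t: int) -> float:
    """Expected fixation index after t generations of drift at size Ne."""
    return 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** t


@dataclass
class PowerConfig:
    """Design of one power simulation.

    ``base_freqs`` is a list of per-locus frequency vectors; alternatively
    set ``n_loci``/``alleles_per_locus`` to draw near-uniform vectors.
    Either ``target_fst`` (with ``t`` solved at fixed Ne) or ``t`` directly
    may be given; when both are given they must agree to 1e-9.
    """

    n_subpops: int = 4
    sample_sizes: Sequence[int] = (40, 40, 40, 40)
    base_freqs: list[np.ndarray] | None = None
    n_loci: int = 10
    alleles_per_locus: int = 8
    ne: int = DRIFT_NE
    t: int | None = None
    target_fst: float | None = None
    n_reps: int = 500
    alpha: float = 0.05
    test: str = "chi2_sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sample_sizes) != self.n_subpops:
            raise ValueError("sample_sizes length must equal n_subpops")
        if self.t is None and self.target_fst is None:
            raise ValueError("give target_fst or t")
        if self.t is not None and self.target_fst is not None:
            if abs(expected_fst(self.ne, self.t) - self.target_fst) > 1e-9:
                raise ValueError("target_fst and (Ne, t) disagree")
        if self.t is None:
            self.t = solve_drift_generations(self.target_fst, self.ne)

    def resolve_base_freqs(self, rng: np.random.Generator) -> list[np.ndarray]:
        if self.base_freqs is not None:
            return [np.asarray(p, dtype=float) for p in self.base_freqs]
        freqs = []
        for _ in range(self.n_loci):
            # near-uniform: uniform with mild Dirichlet jitter so that every
            # allele segregates but no locus is artificially symmetric
            p = rng.dirichlet(np.full(self.alleles_per_locus, 50.0))
            freqs.append(p)
        return freqs


@dataclass
class PowerResult:
    power: float
    mc_se: float
    n_reps: int
    alpha: float
    test: str
    p_values: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "power": self.power,
            "mc_se": self.mc_se,
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "test": self.test,
        }


def drift_frequencies(
    base_freqs: Sequence[np.ndarray],
    ne: int,
    t: int,
    n_subpops: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Independently drift each locus in each subpopulation for t generations.

    Returns one (n_subpops, K) array per locus; ``t = 0`` replicates the
    base frequencies unchanged.
    """
    out = []
    for p in base_freqs:
        freqs = np.tile(np.asarray(p, dtype=float), (n_subpops, 1))
        for _ in range(t):
            counts = rng.multinomial(2 * ne, freqs)
            freqs = counts / (2.0 * ne)
        out.append(freqs)
    return out


def _chi2_sum_p(tables: Sequence[np.ndarray]) -> float:
    stat = 0.0
    df = 0
    for table in tables:
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            continue  # monomorphic in the sample: uninformative
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        stat += float(((table - expected) ** 2 / expected).sum())
        df += (table.shape[0] - 1) * (table.shape[1] - 1)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def _log_table_prob(table: np.ndarray) -> float:
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _fisher_locus_p(
    table: np.ndarray, rng: np.random.Generator, n_mc: int = 999
) -> float:
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or table.shape[0] < 2:
        return 1.0
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    obs = _log_table_prob(table)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0), seed=rng)
    samples = dist.rvs(n_mc)
    logps = np.array([_log_table_prob(s) for s in np.atleast_3d(samples)])
    hits = int((logps <= obs + 1e-9).sum())
    return (1 + hits) / (1 + n_mc)


def _fisher_combined_p(
    tables: Sequence[np.ndarray], rng: np.random.Generator, n_mc: int = 999
) -> float:
    ps = [
        _fisher_locus_p(t, rng, n_mc)
        for t in tables
        if t[:, t.sum(axis=0) > 0].shape[1] >= 2
    ]
    if not ps:
        return 1.0
    stat = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.sf(stat, 2 * len(ps)))


def differentiation_test(
    tables: Sequence[np.ndarray],
    method: str = "chi2_sum",
    rng: np.random.Generator | None = None,
    n_mc: int = 999,
) -> float:
    """Combined p-value for allele-count heterogeneity across subpopulations.

    ``tables``: one subpopulation x allele count table per locus.  Loci
    monomorphic in the sample are excluded.  ``chi2_sum`` sums Pearson
    statistics and degrees of freedom over loci; ``fisher_combined`` uses
    per-locus exact p-values (Fisher for 2x2, Monte-Carlo for larger
    tables) combined with the -2*sum(log p) chi-square rule.
    """
    tables = [np.asarray(t, dtype=float) for t in tables]
    if any(t.shape[0] < 2 for t in tables):
        raise ValueError("need >= 2 subpopulations")
    if method == "chi2_sum":
        return _chi2_sum_p(tables)
    if method == "fisher_combined":
        if rng is None:
            rng = np.random.default_rng(0)
        return _fisher_combined_p(tables, rng, n_mc)
    raise ValueError(f"unknown test method {method!r}")


def _sample_tables(
    freqs: Sequence[np.ndarray], sample_sizes: Sequence[int], rng: np.random.Generator
) -> list[np.ndarray]:
    """Allele-count tables from multinomial sampling of 2n gene copies."""
    tables = []
    for locus_freqs in freqs:
        rows = [
            rng.multinomial(2 * n, locus_freqs[k])
            for k, n in enumerate(sample_sizes)
        ]
        tables.append(np.array(rows))
    return tables


def estimate_power(cfg: PowerConfig) -> PowerResult:
    """Monte-Carlo power: fraction of replicates with p < alpha.

    Each replicate drifts fresh subpopulation frequencies, samples genotype
    counts at the configured sizes, and applies the configured test.
    """
    rng = np.random.default_rng(cfg.seed)
    base = cfg.resolve_base_freqs(rng)
    rejections = 0
    p_values = np.empty(cfg.n_reps)
    for rep in range(cfg.n_reps):
        drifted = drift_frequencies(base, cfg.ne, cfg.t, cfg.n_subpops, rng)
        tables = _sample_tables(drifted, cfg.sample_sizes, rng)
        p = differentiation_test(tables, cfg.test, rng=rng, n_mc=499)
        p_values[rep] = p
        if p < cfg.alpha:
            rejections += 1
    power = rejections / cfg.n_reps
    mc_se = math.sqrt(power * (1.0 - power) / cfg.n_reps)
    return PowerResult(
        power=power,
        mc_se=mc_se,
        n_reps=cfg.n_reps,
        alpha=cfg.alpha,
        test=cfg.test,
        p_values=p_values,
    )
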