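"""Full-sib family inference under haplodiploidy and the colony-density chain.

Bumble bee colonies are monogynous and monoandrous: one diploid queen mated
to a single haploid drone, so workers are full sisters sharing the paternal
allele at every locus and a maternal allele with probability 1/2.  Sampled
same-site conspecific females are partitioned into full-sib families by a
deterministic agglomerative maximum-likelihood clustering: starting from
singletons, the merge that maximally increases the total partition
log-likelihood is accepted, provided the pairwise full-sib posterior of the
linking pair reaches an admission threshold (default 0.95, mirroring the
conventional sibship-reconstruction configuration), until no admissible merge
improves the likelihood.

The family likelihood integrates the member genotypes over one queen
(diploid, Hardy–Weinberg at the supplied allele frequencies) and one drone
(haploid at the same frequencies), with each observed allele independently
mistyped to a frequency-weighted random allele with probability ``error_rate``
(default 0.05, the conventional genotyping-error assumption).

From the partition, the colony-density chain per species x site is::

    N_nr  (families detected)
    N_ns = (N_nr / N_g) * N_i          # standardized for genotyping success
    N_c  = 4.5 * N * n * m / (1 + 2m)  # Crozier effective colony number

which for monogyny/monoandry (n = m = 1) simplifies to ``N_c = 1.5 * N_ns``.
Chain values are reported to 1 decimal but always computed from unrounded
intermediates; sites with 15 or fewer successfully genotyped females are
skipped (no N_ns / N_c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geno_io import FEMALE, GenotypeDataset, Individual

__all__ = [
    "SibshipPartition",
    "ColonyDensityRecord",
    "pair_fullsib_llr",
    "infer_partition",
    "standardize_colony_count",
    "crozier_nc",
    "density_record",
    "density_from_counts",
    "plug_in_frequencies",
]

SKIP_MAX_GENOTYPED = 15  # N_g at or below this: no density estimate


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

class _Engine:
    """Per-locus tensors for family likelihoods under the haplodiploid model.

    For each locus with K alleles and frequency vector p, and each female i,
    ``A_i[a, d] = P(observed call | maternal allele a, paternal allele d)``
    under the mistyping model ``P(obs o | true t) = (1-e)*[o==t] + e*p_o``.
    A family's per-locus likelihood tensor over (queen allele 1, queen
    allele 2, drone allele) is the elementwise product of member factors
    ``0.5 * (A_i[q1, d] + A_i[q2, d])``; contracting with the parental prior
    ``p ⊗ p ⊗ p`` gives the probability of the members' calls given one
    queen and one drone.
    """

    def __init__(
        self,
        females: Sequence[Individual],
        freqs: Mapping[str, Mapping[int, float]],
        error_rate: float,
    ) -> None:
        self.females = list(females)
        self.error_rate = float(error_rate)
        self.loci = sorted(freqs)
        for ind in females:
            for locus in ind.genotype:
                if locus not in freqs:
                    raise ValueError(
                        f"allele frequencies missing for locus {locus} "
                        f"(present in {ind.id})"
                    )
        self.alleles: dict[str, list[int]] = {}
        self.p: dict[str, np.ndarray] = {}
        self.mistype: dict[str, np.ndarray] = {}
        self.w: dict[str, np.ndarray] = {}
        for locus in self.loci:
            alleles = sorted(freqs[locus])
            p = np.array([freqs[locus][a] for a in alleles], dtype=float)
            if p.sum() <= 0:
                raise ValueError(f"{locus}: degenerate frequency vector")
            p = p / p.sum()
            k = len(alleles)
            m = self.error_rate * np.tile(p[:, None], (1, k))
            m[np.diag_indices(k)] += 1.0 - self.error_rate
            self.alleles[locus] = alleles
            self.p[locus] = p
            self.mistype[locus] = m  # m[obs, true]
            self.w[locus] = p[:, None, None] * p[None, :, None] * p[None, None, :]

    def obs_matrix(self, ind: Individual, locus: str) -> np.ndarray | None:
        """A[a, d] for one female at one locus; None when untyped."""
        call = ind.call(locus)
        if call is None:
            return None
        idx = {a: i for i, a in enumerate(self.alleles[locus])}
        try:
            obs = [idx[a] for a in call]
        except KeyError as exc:
            raise ValueError(
                f"{ind.id}: allele {exc.args[0]} at {locus} absent from the "
                "frequency support"
            ) from None
        m = self.mistype[locus]
        if len(obs) == 1:
            x = obs[0]
            # haploid observation of the maternal-paternal pair is not used
            # for female sibship; treat as ambiguous single-copy observation
            return 0.5 * (m[x][:, None] + m[x][None, :])
        x, y = obs
        a_mat = m[x][:, None] * m[y][None, :]
        if x != y:
            a_mat = a_mat + m[y][:, None] * m[x][None, :]
        return a_mat

    def singleton_state(self, ind: Individual) -> list[tuple[np.ndarray, float] | None]:
        state = []
        for locus in self.loci:
            a_mat = self.obs_matrix(ind, locus)
            if a_mat is None:
                state.append(None)
            else:
                tensor = 0.5 * (a_mat[:, None, :] + a_mat[None, :, :])
                state.append((tensor, 0.0))
        return state

    @staticmethod
    def merge_states(s1, s2):
        out = []
        for t1, t2 in zip(s1, s2):
            if t1 is None:
                out.append(t2)
            elif t2 is None:
                out.append(t1)
            else:
                tensor = t1[0] * t2[0]
                scale = float(tensor.max())
                logscale = t1[1] + t2[1]
                if scale > 0:
                    tensor = tensor / scale
                    logscale += math.log(scale)
                out.append((tensor, logscale))
        return out

    def log_likelihood(self, state) -> float:
        total = 0.0
        for locus, entry in zip(self.loci, state):
            if entry is None:
                continue
            tensor, logscale = entry
            val = float((self.w[locus] * tensor).sum())
            if val <= 0.0:
                return -math.inf
            total += logscale + math.log(val)
        return total

    def merged_log_likelihood(self, s1, s2) -> float:
        return self.log_likelihood(self.merge_states(s1, s2))


def plug_in_frequencies(
    females: Sequence[Individual], loci: Sequence[str]
) -> dict[str, dict[int, float]]:
    """Observed allele frequencies among the given females (plug-in)."""
    freqs: dict[str, dict[int, float]] = {}
    for locus in loci:
        counts: dict[int, int] = {}
        for ind in females:
            call = ind.call(locus)
            if call is None:
                continue
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        if total > 0:
            freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
    return freqs


def pair_fullsib_llr(
    f1: Individual,
    f2: Individual,
    freqs: Mapping[str, Mapping[int, float]],
    error_rate: float = 0.05,
) -> float:
    """Log-likelihood ratio of full-sib versus unrelated for two females.

    Summed over the loci typed in both; -inf when the genotypes are
    impossible for full sisters at zero error rate.  Raises when the pair
    shares no typed locus.
    """
    shared = [l for l in freqs if f1.is_typed(l) and f2.is_typed(l)]
    if not shared:
        raise ValueError(f"{f1.id}/{f2.id}: no shared typed loci")
    sub = {l: freqs[l] for l in shared}
    eng = _Engine([f1, f2], sub, error_rate)
    s1, s2 = eng.singleton_state(f1), eng.singleton_state(f2)
    return eng.merged_log_likelihood(s1, s2) - eng.log_likelihood(
        s1
    ) - eng.log_likelihood(s2)


@dataclass
class SibshipPartition:
    """Assignment of females to inferred full-sib families (colonies)."""

    family_of: dict[str, str]
    pair_posterior: dict[frozenset, float] = field(default_factory=dict)
    error_rate: float = 0.05
    threshold: float = 0.95
    log_likelihood: float = float("nan")

    @property
    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for ind_id, fam in self.family_of.items():
            fams.setdefault(fam, []).append(ind_id)
        return {f: sorted(m) for f, m in sorted(fams.items())}

    @property
    def n_families(self) -> int:
        return len(set(self.family_of.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.family_of.items())
        return pd.DataFrame(rows, columns=["id", "family_id"])


def infer_partition(
    females: GenotypeDataset | Sequence[Individual],
    freqs: Mapping[str, Mapping[int, float]] | None = None,
    error_rate: float = 0.05,
    threshold: float = 0.95,
    seed: int = 0,
) -> SibshipPartition:
    """Agglomerative maximum-likelihood sibship clustering of females.

    Families start as singletons; at each step the merge that maximally
    increases the total partition log-likelihood is accepted, but only if
    the best linking pair across the two families has a full-sib posterior
    (uniform prior over {full-sib, unrelated}) of at least ``threshold``.
    Clustering stops when no admissible merge improves the likelihood.
    Ties are broken by the smallest member id, so the result is
    deterministic; ``seed`` is accepted for interface symmetry.

    When ``freqs`` is None, plug-in allele frequencies are estimated once
    from the same females.
    """
    if isinstance(females, GenotypeDataset):
        inds = [i for i in females.individuals if i.sex == FEMALE]
    else:
        inds = [i for i in females if i.sex == FEMALE]
    if not inds:
        raise ValueError("no females to partition")
    inds = sorted(inds, key=lambda i: i.id)
    loci = sorted({l for i in inds for l in i.genotype})
    if freqs is None:
        freqs = plug_in_frequencies(inds, loci)
    eng = _Engine(inds, freqs, error_rate)

    states = {i.id: eng.singleton_state(ind) for i, ind in zip(inds, inds)}
    logls = {iid: eng.log_likelihood(s) for iid, s in states.items()}
    members: dict[str, list[str]] = {i.id: [i.id] for i in inds}

    # pairwise LLRs / posteriors for the admission gate
    ids = [i.id for i in inds]
    pair_llr: dict[frozenset, float] = {}
    pair_post: dict[frozenset, float] = {}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            key = frozenset((ids[a], ids[b]))
            llr = eng.merged_log_likelihood(states[ids[a]], states[ids[b]]) - (
                logls[ids[a]] + logls[ids[b]]
            )
            pair_llr[key] = llr
            pair_post[key] = 1.0 / (1.0 + math.exp(-llr)) if llr < 700 else 1.0

    def gain(fa: str, fb: str) -> float:
        return eng.merged_log_likelihood(states[fa], states[fb]) - (
            logls[fa] + logls[fb]
        )

    gains: dict[tuple[str, str], float] = {}
    fams = sorted(members)
    for a in range(len(fams)):
        for b in range(a + 1, len(fams)):
            key = tuple(sorted((fams[a], fams[b])))
            gains[key] = pair_llr[frozenset(key)]  # singleton gain == pair LLR

    tol = 1e-9
    while True:
        best_key: tuple[str, str] | None = None
        best_gain = tol
        for key in sorted(gains):
            g = gains[key]
            if g <= best_gain:
                continue
            fa, fb = key
            post = max(
                pair_post[frozenset((i, j))]
                for i in members[fa]
                for j in members[fb]
            )
            if post >= threshold:
                best_key, best_gain = key, g
        if best_key is None:
            break
        fa, fb = best_key
        merged = eng.merge_states(states[fa], states[fb])
        new_id = min(fa, fb)
        dead = max(fa, fb)
        states[new_id] = merged
        logls[new_id] = eng.log_likelihood(merged)
        members[new_id] = sorted(members[fa] + members[fb])
        del states[dead], logls[dead], members[dead]
        gains = {
            k: v for k, v in gains.items() if fa not in k and fb not in k
        }
        for other in members:
            if other == new_id:
                continue
            key = tuple(sorted((new_id, other)))
            gains[key] = gain(*key)

    family_of: dict[str, str] = {}
    for k, fam_root in enumerate(sorted(members)):
        fid = f"F{k + 1:04d}"
        for iid in members[fam_root]:
            family_of[iid] = fid
    total_logl = sum(logls.values())
    return SibshipPartition(
        family_of=family_of,
        pair_posterior=pair_post,
        error_rate=error_rate,
        threshold=threshold,
        log_likelihood=total_logl,
    )


# ---------------------------------------------------------------------------
# Colony-density chain
# ---------------------------------------------------------------------------

def standardize_colony_count(n_nr: float, n_g: int, n_i: int) -> float:
    """Detected colonies standardized for genotyping success, unrounded.

    ``N_ns = (N_nr / N_g) * N_i``.  The reporting layer rounds to 1 decimal.
    """
    if n_g < 1:
        raise ValueError("N_g must be >= 1")
    if not n_nr <= n_g <= n_i:
        raise ValueError("require N_nr <= N_g <= N_i")
    return (n_nr / n_g) * n_i


def crozier_nc(n_detected: float, n_queens: int = 1, m_matings: int = 1) -> float:
    """Crozier effective colony number ``N_c = 4.5*N*n*m / (1 + 2m)``.

    For monogynous, monoandrous species (n = m = 1) this is ``1.5 * N``.
    Computed from the unrounded detected-colony count.
    """
    if n_detected < 0:
        raise ValueError("N must be >= 0")
    if n_queens < 1 or m_matings < 1:
        raise ValueError("n and m must be >= 1")
    return 4.5 * n_detected * n_queens * m_matings / (1.0 + 2.0 * m_matings)


@dataclass
class ColonyDensityRecord:
    """The N_i -> N_g -> N_nr -> N_ns -> N_c chain for one species x site."""

    species: str
    site: str
    n_i: int
    n_g: int
    n_nr: int | None
    n_ns: float | None
    n_c: float | None
    skipped: bool

    def as_row(self) -> dict:
        r1 = lambda x: None if x is None else round(x, 1)  # noqa: E731
        return {
            "species": self.species,
            "site": self.site,
            "N_i": self.n_i,
            "N_g": self.n_g,
            "N_nr": self.n_nr,
            "N_ns": r1(self.n_ns),
            "N_c": r1(self.n_c),
            "skipped": self.skipped,
        }


def density_record(
    species: str,
    site: str,
    n_i: int,
    n_g: int,
    n_nr: int | None,
    skip_threshold: int = SKIP_MAX_GENOTYPED,
) -> ColonyDensityRecord:
    """Build one density record, applying the N_g <= 15 skip rule."""
    if n_g > n_i:
        raise ValueError("N_g cannot exceed N_i")
    if n_g <= skip_threshold or n_nr is None:
        return ColonyDensityRecord(species, site, n_i, n_g, n_nr, None, None, True)
    n_ns = standardize_colony_count(n_nr, n_g, n_i)
    return ColonyDensityRecord(
        species, site, n_i, n_g, n_nr, n_ns, crozier_nc(n_ns), False
    )


def density_from_counts(
    counts: pd.DataFrame, skip_threshold: int = SKIP_MAX_GENOTYPED
) -> pd.DataFrame:
    """Complete the density chain for a table of (species, site, N_i, N_g, N_nr).

    Returns the input columns plus ``N_ns`` and ``N_c`` rounded to 1 decimal
    (NaN where skipped) and a ``skipped`` flag.  ``N_nr`` may be NaN for
    strata where sibship reconstruction was not run.
    """
    rows = []
    for _, row in counts.iterrows():
        n_nr = row["N_nr"]
        n_nr = None if pd.isna(n_nr) else int(n_nr)
        rec = density_record(
            str(row["species"]),
            str(row["site"]),
            int(row["N_i"]),
            int(row["N_g"]),
            n_nr,
            skip_threshold,
        )
        rows.append(rec.as_row())
    return pd.DataFrame(rows)
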