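"""QC ladder: missingness, null alleles, HWE, LD pruning, sister dedup."""

import itertools

import numpy as np
import pytest

from urbangen.geno_io import GenotypeDataset, Individual, LocusDef
from urbangen.qc import (
    dedupe_sisters,
    estimate_null_freq,
    filter_missingness,
    filter_null_loci,
    hwe_test,
    ld_test_and_prune,
)
from urbangen.sibship_density import SibshipPartition
from urbangen.synthetic_data import (
    SimConfig,
    apply_observation_model,
    draw_site_frequencies,
    simulate_colonies,
)

from conftest import make_females


def _dataset(genotypes, loci, **kwargs):
    return GenotypeDataset(
        panel=[LocusDef(l) for l in loci],
        individuals=make_females(genotypes, **kwargs),
    )


class TestMissingness:
    def test_boundary_twenty_percent_is_dropped(self):
        """An individual missing exactly 2 of 10 loci (20%) is discarded."""
        loci = [f"L{k}" for k in range(10)]
        full = {l: (1, 2) for l in loci}
        partial = {l: (1, 2) for l in loci[:8]}  # missing 2/10 = 20%
        ds = _dataset([full] * 8 + [partial], loci)
        out, report = filter_missingness(ds, threshold=0.20)
        assert len(out.individuals) == 8
        assert report.dropped_individuals[0]["id"] == "f9"
        assert report.dropped_individuals[0]["missing_fraction"] == pytest.approx(0.2)

    def test_fully_typed_dataset_untouched(self):
        loci = ["LA", "LB"]
        ds = _dataset([{l: (1, 2) for l in loci}] * 5, loci)
        out, report = filter_missingness(ds)
        assert len(out.individuals) == 5
        assert not report.dropped_loci and not report.dropped_individuals

    def test_loci_dropped_before_individuals(self):
        """A bad locus is removed first, rescuing individuals typed elsewhere."""
        loci = ["LA", "LB", "LC", "LD", "LE"]
        genos = []
        for k in range(10):
            g = {l: (1, 2) for l in loci}
            if k < 4:
                del g["LA"]  # 40% missing at LA -> locus dropped
            genos.append(g)
        ds = _dataset(genos, loci)
        out, report = filter_missingness(ds, threshold=0.20)
        assert [d["locus"] for d in report.dropped_loci] == ["LA"]
        assert len(out.individuals) == 10  # nobody dropped once LA is gone

    def test_simulated_high_failure_locus_dropped(self):
        cfg = SimConfig(
            n_sites=1, colonies_per_site=100, workers_per_colony_mean=1.0,
            n_loci=5, seed=31, failure_rate=0.0,
        )
        freqs = draw_site_frequencies(cfg)
        ds, _ = simulate_colonies(cfg, freqs)
        cfg_fail = SimConfig(**{**cfg.__dict__, "failure_rate": 0.3})
        # apply failure only to L01 by blanking other loci's noise
        rng = np.random.default_rng(1)
        for ind in ds.individuals:
            if rng.random() < 0.3:
                ind.genotype.pop("L01", None)
        out, report = filter_missingness(ds, threshold=0.20)
        assert any(d["locus"] == "L01" for d in report.dropped_loci)

    def test_idempotent(self):
        loci = [f"L{k}" for k in range(10)]
        genos = [
            {l: (1, 2) for l in loci[: 10 - (k % 4)]} for k in range(20)
        ]
        ds = _dataset(genos, loci)
        once, _ = filter_missingness(ds, 0.20)
        twice, _ = filter_missingness(once, 0.20)
        assert [i.id for i in twice.individuals] == [i.id for i in once.individuals]
        assert [i.genotype for i in twice.individuals] == [
            i.genotype for i in once.individuals
        ]


class TestNullAlleles:
    def test_ho_equals_he_gives_zero(self):
        # 2 alleles at 50/50 with half the individuals heterozygous:
        # He_unbiased = (2n/(2n-1)) * 0.5 slightly above 0.5, so use exact Ho
        genos = [{"LA": (1, 2)}, {"LA": (1, 2)}, {"LA": (1, 1)}, {"LA": (2, 2)}]
        ds = _dataset(genos, ["LA"])
        r, mono = estimate_null_freq(ds, "LA")
        he = (8 / 7) * 0.5
        expected = (he - 0.5) / (he + 0.5)
        assert not mono
        assert r == pytest.approx(expected)

    def test_total_heterozygote_deficit_gives_one(self):
        genos = [{"LA": (1, 1)}] * 3 + [{"LA": (2, 2)}] * 3
        r, mono = estimate_null_freq(_dataset(genos, ["LA"]), "LA")
        assert r == pytest.approx(1.0)
        assert not mono

    def test_monomorphic_flagged_zero(self):
        genos = [{"LA": (5, 5)}] * 4
        r, mono = estimate_null_freq(_dataset(genos, ["LA"]), "LA")
        assert r == 0.0 and mono

    def test_filter_boundary_inclusive(self):
        """A locus at exactly the threshold is dropped; just below, retained."""
        genos = [{"LA": (1, 2)}] * 3 + [{"LA": (1, 1)}] * 4 + [{"LA": (2, 2)}] * 3
        ds = _dataset(genos, ["LA"])
        r, _ = estimate_null_freq(ds, "LA")
        dropped, rep1 = filter_null_loci(ds, threshold=r)
        assert [d["locus"] for d in rep1.dropped_loci] == ["LA"]
        kept, rep2 = filter_null_loci(ds, threshold=r + 1e-9)
        assert not rep2.dropped_loci

    def test_drop_probability_increases_with_null_freq(self):
        def drop_rate(null_freq):
            hits = 0
            for seed in range(15):
                cfg = SimConfig(
                    n_sites=1, colonies_per_site=120,
                    workers_per_colony_mean=1.0, n_loci=1,
                    alleles_per_locus=10, seed=900 + seed,
                    null_allele_freq=null_freq,
                )
                ds, _ = simulate_colonies(cfg, draw_site_frequencies(cfg))
                obs = apply_observation_model(ds, cfg)
                _, report = filter_null_loci(obs, threshold=0.25)
                hits += bool(report.dropped_loci)
            return hits / 15

        assert drop_rate(0.35) > drop_rate(0.05)


def _exact_hwe_p(pairs):
    """Brute-force exact p: enumerate all perfect pairings of labelled copies."""
    from math import lgamma

    copies = [a for pair in pairs for a in pair]

    def pairings(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for k in range(len(rest)):
            pair = (first, rest[k])
            for tail in pairings(rest[:k] + rest[k + 1 :]):
                yield [pair] + tail

    def log_prob(array):
        # Levene conditional probability of the genotype array
        from collections import Counter

        n = len(array)
        geno = Counter(tuple(sorted(g)) for g in array)
        alle = Counter(a for g in array for a in g)
        h = sum(1 for g in array if g[0] != g[1])
        val = lgamma(n + 1) + h * np.log(2.0) - lgamma(2 * n + 1)
        val += sum(lgamma(c + 1) for c in alle.values())
        val -= sum(lgamma(c + 1) for c in geno.values())
        return val

    obs = log_prob(pairs)
    total = hits = 0
    for pairing in pairings(copies):
        total += 1
        if log_prob(pairing) <= obs + 1e-10:
            hits += 1
    return hits / total


class TestHWE:
    def test_monomorphic_returns_one(self):
        ds = _dataset([{"LA": (3, 3)}] * 6, ["LA"])
        assert hwe_test(ds, "LA", seed=0) == 1.0

    def test_matches_exhaustive_pairing_enumeration(self):
        """Two-allele, n=5: Monte-Carlo p agrees with full enumeration."""
        pairs = [(1, 1), (1, 1), (1, 2), (2, 2), (2, 2)]
        exact = _exact_hwe_p(pairs)
        ds = _dataset([{"LA": g} for g in pairs], ["LA"])
        p = hwe_test(ds, "LA", n_perm=20000, seed=5)
        # +1-corrected MC estimate of the exact permutation p-value
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert p == pytest.approx(exact, abs=4 * se + 1e-4)

    def test_size_close_to_nominal_on_hwe_data(self):
        """Empirical rejection rate at alpha=0.05 on null (HWE) loci."""
        rng = np.random.default_rng(8)
        freqs = np.array([0.35, 0.3, 0.2, 0.1, 0.05])
        rejections = 0
        n_loci = 250
        for k in range(n_loci):
            draws = rng.choice(5, size=(40, 2), p=freqs) + 1
            genos = [{"LA": tuple(sorted(map(int, d)))} for d in draws]
            ds = _dataset(genos, ["LA"])
            if hwe_test(ds, "LA", n_perm=199, seed=k) < 0.05:
                rejections += 1
        rate = rejections / n_loci
        assert abs(rate - 0.05) < 0.03  # ±2 MC s.e. band


class TestLD:
    def test_duplicated_locus_collapsed(self, rng):
        draws = rng.choice(6, size=(60, 2)) + 1
        genos = []
        for d in draws:
            call = tuple(sorted(map(int, d)))
            genos.append({"LA": call, "LB": call, "LC": tuple(
                sorted(map(int, rng.choice(6, size=2) + 1))
            )})
        ds = _dataset(genos, ["LA", "LB", "LC"])
        out, report = ld_test_and_prune(ds, n_perm=299, seed=1)
        dropped = {d["locus"] for d in report.dropped_loci}
        assert dropped in ({"LA"}, {"LB"})  # exactly one copy removed
        assert report.retained_panel["B"] == sorted(
            set(["LA", "LB", "LC"]) - dropped
        )

    def test_component_chain_retains_single_locus(self, rng):
        """Three mutually linked loci collapse to exactly one."""
        draws = rng.choice(6, size=(60, 2)) + 1
        genos = [
            {"LA": tuple(sorted(map(int, d))), "LB": tuple(sorted(map(int, d))),
             "LC": tuple(sorted(map(int, d)))}
            for d in draws
        ]
        ds = _dataset(genos, ["LA", "LB", "LC"])
        out, report = ld_test_and_prune(ds, n_perm=299, seed=2)
        assert len(report.retained_panel["B"]) == 1
        assert len({d["locus"] for d in report.dropped_loci}) == 2

    def test_small_pairs_recorded_untested(self):
        genos = [{"LA": (1, 2), "LB": (3, 4)}] * 3
        ds = _dataset(genos, ["LA", "LB"])
        out, report = ld_test_and_prune(ds, seed=0)
        assert report.ld_pairs[0]["tested"] is False
        assert not report.dropped_loci


class TestDedupe:
    def _partition(self, fams):
        return SibshipPartition(family_of=fams)

    def test_singleton_families_unchanged(self, rng):
        genos = [{"LA": (1, 2)}] * 4
        ds = _dataset(genos, ["LA"])
        part = self._partition({f"f{k + 1}": f"F{k}" for k in range(4)})
        out = dedupe_sisters(ds, part, seed=3)
        assert len(out.females()) == 4

    def test_one_female_kept_per_family_and_deterministic(self):
        genos = [{"LA": (1, 2)}] * 30
        ds = _dataset(genos, ["LA"])
        fams = {f"f{k + 1}": f"F{k % 10}" for k in range(30)}  # 10 families of 3
        out1 = dedupe_sisters(ds, self._partition(fams), seed=7)
        out2 = dedupe_sisters(ds, self._partition(fams), seed=7)
        assert len(out1.females()) == 10
        assert [i.id for i in out1.individuals] == [i.id for i in out2.individuals]
        assert len({fams[i.id] for i in out1.females()}) == 10

    def test_uncovered_female_raises(self):
        ds = _dataset([{"LA": (1, 2)}] * 2, ["LA"])
        with pytest.raises(ValueError, match="f2"):
            dedupe_sisters(ds, self._partition({"f1": "F0"}), seed=0)
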