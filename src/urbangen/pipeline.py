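"""End-to-end orchestration: ingest/simulate -> QC -> sibship -> density ->
F-statistics / allelic richness -> male ploidy -> body size -> report bundle.

Stage order and every filter decision are logged; all stage RNGs derive
deterministically from the master seed, so a run is byte-reproducible.
Stage outputs are written as individual files so any stage can be re-run or
bypassed in isolation (e.g. the density chain can be completed from an
externally supplied table of sampled/genotyped/detected counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import body_size as bs
from . import fstats, ploidy, qc
from .geno_io import FEMALE, GenotypeDataset, read_genepop, read_genotype_table
from .sibship_density import (
    SKIP_MAX_GENOTYPED,
    density_from_counts,
    density_record,
    infer_partition,
    plug_in_frequencies,
)
from .synthetic_data import SimConfig, simulate_dataset

__all__ = ["RunConfig", "run", "density_from_counts"]


@dataclass
class RunConfig:
    """All stage parameters with the study's conventional defaults."""

    input_genepop: str | None = None
    input_table: str | None = None
    table_schema: dict | str | None = None
    metadata: str | None = None
    sim: SimConfig | None = None

    missing_threshold: float = 0.20
    null_threshold: float = 0.25
    sibship_error_rate: float = 0.05
    sibship_threshold: float = 0.95
    ld_alpha: float = 0.05
    ld_n_perm: int = 499
    min_pop: int = 25
    density_skip_max: int = SKIP_MAX_GENOTYPED
    min_workers: int = 15
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    outdir: str = "urbangen_out"

    def stage_seed(self, stage: str) -> int:
        key = int.from_bytes(stage.encode(), "little") % (2**32)
        return int(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)).generate_state(
                1
            )[0]
            % (2**31)
        )


def _load_input(config: RunConfig) -> GenotypeDataset:
    if config.sim is not None:
        ds, _ = simulate_dataset(config.sim)
        return ds
    if config.input_genepop:
        return read_genepop(config.input_genepop, config.metadata)
    if config.input_table:
        if config.table_schema is None:
            raise ValueError("input_table requires table_schema")
        return read_genotype_table(config.input_table, config.table_schema)
    raise ValueError("RunConfig needs an input file or a SimConfig")


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict.

    Bundle keys: ``density`` (colony-density chain table), ``ploidy``
    (male-diploidy table), ``popgen`` (per-species F-statistics and
    richness), ``contrasts`` (body-size LS-means contrasts), ``qc_report``,
    and ``log``.  Everything is also written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    ds = _load_input(config)
    log.append(f"input: {len(ds.individuals)} individuals, "
               f"{len(ds.panel)} loci, species={ds.species()}")

    # --- QC ladder -------------------------------------------------------
    ds, miss_report = qc.filter_missingness(ds, config.missing_threshold)
    ds, null_report = qc.filter_null_loci(ds, config.null_threshold)
    report = miss_report.merge(null_report)
    log.append("qc: missingness + null-allele filters applied")

    # --- sibship + density per species x site ---------------------------
    density_rows = []
    family_of: dict[str, str] = {}
    pre_qc_counts: dict[tuple[str, str], int] = {}
    for ind in _load_input(config).individuals:  # N_i counts sampled females
        if ind.sex == FEMALE:
            key = (ind.species, ind.site)
            pre_qc_counts[key] = pre_qc_counts.get(key, 0) + 1
    for species in sorted(ds.species()):
        for site in sorted({i.site for i in ds.individuals if i.species == species}):
            females = [
                i
                for i in ds.individuals
                if i.species == species and i.site == site and i.sex == FEMALE
            ]
            n_i = pre_qc_counts.get((species, site), len(females))
            n_g = len(females)
            if n_g == 0:
                continue
            # sibship is inferred even below the density skip threshold,
            # because the sister dedup still needs the partition
            partition = infer_partition(
                females,
                error_rate=config.sibship_error_rate,
                threshold=config.sibship_threshold,
                seed=config.stage_seed(f"sibship:{species}:{site}"),
            )
            for iid, fam in partition.family_of.items():
                family_of[iid] = f"{species}|{site}|{fam}"
            rec = density_record(
                species, site, n_i, n_g,
                partition.n_families,
                config.density_skip_max,
            )
            density_rows.append(rec.as_row())
    density = pd.DataFrame(density_rows)
    log.append(f"sibship+density: {len(density_rows)} species-site cells")

    # --- one sister per colony ------------------------------------------
    from .sibship_density import SibshipPartition

    global_partition = SibshipPartition(family_of=family_of)
    ds = qc.dedupe_sisters(ds, global_partition, seed=config.stage_seed("dedupe"))
    log.append(f"dedupe: {len(ds.females())} females retained")

    # --- LD prune + HWE report ------------------------------------------
    ds, ld_report = qc.ld_test_and_prune(
        ds, alpha=config.ld_alpha, n_perm=config.ld_n_perm,
        seed=config.stage_seed("ld"),
    )
    report = report.merge(ld_report)
    hwe_seed = config.stage_seed("hwe")
    for species in sorted(ds.species()):
        members = [i for i in ds.individuals if i.species == species]
        for locus in ds.locus_names:
            typed = [
                i for i in members
                if i.call(locus) is not None and len(i.call(locus)) == 2
            ]
            if len(typed) < 5:
                continue
            p = qc.hwe_test(ds, locus, typed, n_perm=499, seed=hwe_seed)
            report.hwe.append({"species": species, "locus": locus, "p": p})
    log.append("ld+hwe: reported")

    # --- F-statistics and allelic richness ------------------------------
    # rarefaction depths from the data: twice the smallest included site
    # size across species, twice the smallest species total
    site_sizes, species_totals = [], []
    for species in ds.species():
        females = [i for i in ds.females() if i.species == species]
        by_site: dict[str, int] = {}
        for i in females:
            by_site[i.site] = by_site.get(i.site, 0) + 1
        included = [n for n in by_site.values() if n >= config.min_pop]
        site_sizes.extend(included)
        if females:
            species_totals.append(len(females))
    g_sub = 2 * min(site_sizes) if site_sizes else None
    g_glob = 2 * min(species_totals) if species_totals else None

    popgen = {}
    for species in sorted(ds.species()):
        try:
            summary = fstats.popgen_summary(
                ds, species,
                min_pop=config.min_pop, g_sub=g_sub, g_glob=g_glob,
                n_boot=config.n_boot, seed=config.stage_seed(f"boot:{species}"),
            )
        except ValueError as exc:
            log.append(f"popgen: {species} skipped ({exc})")
            continue
        popgen[species] = summary
    log.append(f"popgen: {len(popgen)} species summarized")

    # --- male ploidy -----------------------------------------------------
    ploidy_table = ploidy.summarize_diploidy(ds)
    log.append(f"ploidy: {len(ds.males())} males classified")

    # --- body size -------------------------------------------------------
    measurements = pd.DataFrame(
        [
            {
                "id": i.id,
                "species": i.species,
                "site": i.site,
                "thorax_width": i.thorax_width,
            }
            for i in ds.females()
            if i.thorax_width is not None
        ]
    )
    size_result = None
    if len(measurements) and measurements["species"].nunique() >= 2:
        try:
            size_result = bs.analyze_body_size(
                measurements, min_workers=config.min_workers, alpha=config.alpha
            )
            log.append(
                f"body size: {len(size_result.contrasts)} contrasts, "
                f"alpha_bonferroni={size_result.alpha_bonferroni:.5f}"
            )
        except ValueError as exc:
            log.append(f"body size skipped: {exc}")
    else:
        log.append("body size skipped: insufficient measurements")

    # --- write bundle ----------------------------------------------------
    density.to_csv(outdir / "density.csv", index=False)
    ploidy_table.to_csv(outdir / "ploidy.csv", index=False)
    popgen_rows = [s.as_row() for s in popgen.values()]
    pd.DataFrame(popgen_rows).to_csv(outdir / "popgen.csv", index=False)
    with open(outdir / "popgen.json", "w") as fh:
        json.dump(
            {
                sp: {
                    "theta": s.theta,
                    "f": s.f,
                    "theta_ci95": s.theta_ci95,
                    "f_ci95": s.f_ci95,
                    "ar_per_site": {k: list(v) for k, v in s.ar_per_site.items()},
                    "ar_global": list(s.ar_global),
                    "g_sub": s.g_sub,
                    "g_glob": s.g_glob,
                    "excluded_sites": s.excluded_sites,
                }
                for sp, s in popgen.items()
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    if size_result is not None:
        size_result.contrasts.to_csv(outdir / "contrasts.csv", index=False)
    report.to_json(outdir / "qc_report.json")
    (outdir / "provenance.log").write_text("\n".join(log + ds.provenance) + "\n")

    return {
        "density": density,
        "ploidy": ploidy_table,
        "popgen": popgen,
        "body_size": size_result,
        "qc_report": report,
        "log": log,
    }
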