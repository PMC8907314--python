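"""Data model and file I/O for multilocus microsatellite genotype data.

The central container is :class:`GenotypeDataset`: a panel of microsatellite
loci plus a list of individuals, each carrying per-locus allele calls and
metadata (species, site, sex, caste, optional thorax width).  Allele codes are
integer fragment lengths in base pairs; no binning or rounding is performed at
read time — binning belongs to the upstream fragment-scoring step.

Two interchange formats are supported:

* GenePop 4.x text files (2- or 3-digit allele dialect, ``POP`` separators,
  ``0000``/``000000`` missing).  GenePop has no haploid encoding for
  diploid-coded loci, so haploid males are exported as homozygotes together
  with a JSON sidecar manifest (``<path>.ploidy.json``) listing their ids;
  the reader consumes the manifest transparently, making round-trips lossless.
* A tabular CSV dialect with a user-configurable column-name schema, matching
  the layout of typical supplementary genotype tables.  Haploid males may be
  given in a single allele column.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LocusDef",
    "Individual",
    "GenotypeDataset",
    "GenotypeFormatError",
    "read_genepop",
    "write_genepop",
    "read_genotype_table",
    "write_genotype_table",
    "verify_species_bins",
]

FEMALE = "female"
MALE = "male"

#: Default site labels of the urban-gradient study design (configurable, not
#: hard-coded anywhere in the analysis code).
DEFAULT_SITES = ("CC", "CW", "ED", "SNR")


class GenotypeFormatError(ValueError):
    """Raised on malformed genotype files or schema violations."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus.

    Parameters
    ----------
    name:
        Unique text label within a panel.
    allele_universe:
        Optional set of permitted integer allele codes (fragment lengths, bp).
    species_bins:
        Optional map ``species -> permitted allele set`` used to verify
        species identifications (alleles of an individual should fall inside
        its species' bin).
    """

    name: str
    allele_universe: frozenset[int] | None = None
    species_bins: Mapping[str, frozenset[int]] | None = None

    def __post_init__(self) -> None:
        if self.allele_universe is not None and any(
            a <= 0 for a in self.allele_universe
        ):
            raise ValueError(f"locus {self.name}: allele codes must be positive")


@dataclass
class Individual:
    """One sampled bee with its multilocus genotype and metadata.

    ``genotype`` maps locus name to an allele-call tuple: length 2 for a
    diploid call, length 1 for a haploid (male) call.  Missing loci are simply
    absent from the mapping.
    """

    id: str
    species: str
    site: str
    sex: str = FEMALE
    caste: str = "worker"
    genotype: dict[str, tuple[int, ...]] = field(default_factory=dict)
    thorax_width: float | None = None
    forage_genus: str | None = None

    def call(self, locus: str) -> tuple[int, ...] | None:
        return self.genotype.get(locus)

    def is_typed(self, locus: str) -> bool:
        return locus in self.genotype

    def n_typed(self, loci: Iterable[str]) -> int:
        return sum(1 for l in loci if l in self.genotype)

    def validate(self, panel_names: set[str]) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"{self.id}: sex must be female or male")
        if self.thorax_width is not None and not self.thorax_width > 0:
            raise ValueError(f"{self.id}: thorax_width must be positive")
        for locus, call in self.genotype.items():
            if locus not in panel_names:
                raise ValueError(f"{self.id}: call at unknown locus {locus}")
            if any(a <= 0 for a in call):
                raise ValueError(f"{self.id}: non-positive allele at {locus}")
            if self.sex == FEMALE and len(call) != 2:
                raise ValueError(
                    f"{self.id}: female must carry 0 or 2 alleles at {locus}"
                )
            if len(call) not in (1, 2):
                raise ValueError(f"{self.id}: bad call arity at {locus}")


@dataclass
class GenotypeDataset:
    """Individuals x loci allele calls plus provenance of applied filters."""

    panel: list[LocusDef]
    individuals: list[Individual]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [l.name for l in self.panel]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in panel")

    # -- accessors ---------------------------------------------------------
    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    def locus(self, name: str) -> LocusDef:
        for l in self.panel:
            if l.name == name:
                return l
        raise KeyError(name)

    def females(self) -> list[Individual]:
        return [i for i in self.individuals if i.sex == FEMALE]

    def males(self) -> list[Individual]:
        return [i for i in self.individuals if i.sex == MALE]

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.individuals:
            seen.setdefault(i.species, None)
        return list(seen)

    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.individuals:
            seen.setdefault(i.site, None)
        return list(seen)

    def subset(self, ids: Iterable[str]) -> "GenotypeDataset":
        keep = set(ids)
        return GenotypeDataset(
            panel=list(self.panel),
            individuals=[i for i in self.individuals if i.id in keep],
            provenance=list(self.provenance),
        )

    def slice(
        self, species: str | None = None, site: str | None = None
    ) -> "GenotypeDataset":
        inds = [
            i
            for i in self.individuals
            if (species is None or i.species == species)
            and (site is None or i.site == site)
        ]
        return GenotypeDataset(
            panel=list(self.panel), individuals=inds, provenance=list(self.provenance)
        )

    def allele_counts(
        self, locus: str, individuals: Sequence[Individual] | None = None
    ) -> Counter:
        """Gene-copy counts per allele (diploids contribute 2, haploids 1)."""
        cnt: Counter = Counter()
        for ind in individuals if individuals is not None else self.individuals:
            call = ind.call(locus)
            if call is not None:
                cnt.update(call)
        return cnt

    def allele_freqs(
        self, locus: str, individuals: Sequence[Individual] | None = None
    ) -> dict[int, float]:
        cnt = self.allele_counts(locus, individuals)
        total = sum(cnt.values())
        if total == 0:
            return {}
        return {a: c / total for a, c in sorted(cnt.items())}

    def validate(self) -> None:
        names = set(self.locus_names)
        ids = [i.id for i in self.individuals]
        if len(set(ids)) != len(ids):
            dup = [k for k, v in Counter(ids).items() if v > 1]
            raise ValueError(f"duplicate individual ids: {dup}")
        for ind in self.individuals:
            ind.validate(names)

    def log(self, message: str) -> None:
        self.provenance.append(message)


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------

_MISSING = {"0000", "000000"}


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".ploidy.json")


def read_genepop(
    path: str | Path, metadata_path: str | Path | None = None
) -> GenotypeDataset:
    """Read a GenePop 4.x file into a :class:`GenotypeDataset`.

    POP blocks map to sites ``pop1 .. popK`` unless ``metadata_path`` (a CSV
    with an ``id`` column and optional ``species``, ``site``, ``sex``,
    ``caste``, ``thorax_width``, ``forage_genus`` columns) overrides the
    metadata per individual.  A ploidy sidecar manifest written by
    :func:`write_genepop`, if present, restores haploid male calls.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise GenotypeFormatError("GenePop file must have a title and locus lines")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for tok in lines[i].split(","):
            tok = tok.strip()
            if tok:
                locus_names.append(tok)
        i += 1
    if not locus_names:
        raise GenotypeFormatError("no locus names before first POP")

    panel = [LocusDef(name=n) for n in locus_names]
    individuals: list[Individual] = []
    pop_index = 0
    width: int | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        if raw.strip().lower() == "pop":
            pop_index += 1
            continue
        if "," not in raw:
            raise GenotypeFormatError(
                f"line {lineno + 1}: expected 'id , genotypes' (no comma found)"
            )
        ident, geno_part = raw.split(",", 1)
        ident = ident.strip()
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise GenotypeFormatError(
                f"line {lineno + 1} ({ident}): {len(tokens)} genotype fields, "
                f"expected {len(locus_names)}"
            )
        genotype: dict[str, tuple[int, ...]] = {}
        for locus, tok in zip(locus_names, tokens):
            if not re.fullmatch(r"\d+", tok) or len(tok) not in (4, 6):
                raise GenotypeFormatError(
                    f"line {lineno + 1} ({ident}): bad allele width in '{tok}'"
                )
            if width is None:
                width = len(tok) // 2
            elif len(tok) // 2 != width:
                raise GenotypeFormatError(
                    f"line {lineno + 1} ({ident}): mixed allele widths"
                )
            if tok in _MISSING:
                continue
            a1, a2 = int(tok[:width]), int(tok[width:])
            if a1 == 0 or a2 == 0:
                continue  # half-missing call treated as missing
            genotype[locus] = (a1, a2)
        individuals.append(
            Individual(
                id=ident,
                species="unknown",
                site=f"pop{pop_index}",
                sex=FEMALE,
                caste="worker",
                genotype=genotype,
            )
        )

    ds = GenotypeDataset(panel=panel, individuals=individuals)

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        manifest = json.loads(sidecar.read_text())
        haploid_calls: dict[str, list[str]] = manifest.get("haploid_calls", {})
        for ind in ds.individuals:
            loci = haploid_calls.get(ind.id)
            if not loci:
                continue
            ind.sex = MALE
            ind.caste = "male"
            for locus in loci:
                call = ind.genotype.get(locus)
                if call is None:
                    continue
                if len(call) == 2 and call[0] != call[1]:
                    raise GenotypeFormatError(
                        f"{ind.id}: haploid manifest but heterozygous call "
                        f"at {locus}"
                    )
                ind.genotype[locus] = (call[0],)

    if metadata_path is not None:
        _apply_metadata(ds, metadata_path)
    ds.log(f"read_genepop: {Path(path).name}, {len(ds.individuals)} individuals")
    return ds


def _apply_metadata(ds: GenotypeDataset, metadata_path: str | Path) -> None:
    with open(metadata_path, newline="") as fh:
        rows = {r["id"]: r for r in csv.DictReader(fh)}
    for ind in ds.individuals:
        row = rows.get(ind.id)
        if row is None:
            continue
        ind.species = row.get("species") or ind.species
        ind.site = row.get("site") or ind.site
        sex = row.get("sex")
        if sex:
            ind.sex = sex
        caste = row.get("caste")
        if caste:
            ind.caste = caste
        tw = row.get("thorax_width")
        if tw:
            ind.thorax_width = float(tw)
        fg = row.get("forage_genus")
        if fg:
            ind.forage_genus = fg
        if ind.sex == MALE:
            for locus, call in list(ind.genotype.items()):
                if len(call) == 2 and call[0] == call[1]:
                    ind.genotype[locus] = (call[0],)


def write_genepop(
    ds: GenotypeDataset, path: str | Path, title: str = "urbangen export"
) -> None:
    """Write the dataset as a 3-digit GenePop file, POP blocks grouped by site.

    Haploid calls are exported as homozygotes; their ids go to a
    ``<path>.ploidy.json`` sidecar so that the round-trip is lossless.
    """
    for ind in ds.individuals:
        for locus, call in ind.genotype.items():
            if any(a > 999 for a in call):
                raise GenotypeFormatError(
                    f"{ind.id}: allele code > 999 at {locus}; "
                    "3-digit GenePop dialect cannot encode it"
                )
    lines = [title]
    lines.extend(ds.locus_names)
    site_order: dict[str, list[Individual]] = {}
    for ind in ds.individuals:
        site_order.setdefault(ind.site, []).append(ind)
    haploid_calls: dict[str, list[str]] = {}
    for site, members in site_order.items():
        lines.append("POP")
        for ind in members:
            fields = []
            for locus in ds.locus_names:
                call = ind.call(locus)
                if call is None:
                    fields.append("000000")
                elif len(call) == 1:
                    fields.append(f"{call[0]:03d}{call[0]:03d}")
                    haploid_calls.setdefault(ind.id, []).append(locus)
                else:
                    fields.append(f"{call[0]:03d}{call[1]:03d}")
            lines.append(f"{ind.id} , " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
    sidecar = _sidecar_path(path)
    if haploid_calls:
        sidecar.write_text(json.dumps({"haploid_calls": haploid_calls}, indent=1))
    elif sidecar.exists():
        sidecar.unlink()


# ---------------------------------------------------------------------------
# Tabular CSV dialect
# ---------------------------------------------------------------------------

_META_KEYS = ("id", "species", "site", "sex", "caste", "thorax_width", "forage_genus")


def default_schema(loci: Sequence[str]) -> dict:
    """Column-name schema used by :func:`write_genotype_table`."""
    return {
        "id": "id",
        "species": "species",
        "site": "site",
        "sex": "sex",
        "caste": "caste",
        "thorax_width": "thorax_width",
        "forage_genus": "forage_genus",
        "loci": {name: [f"{name}.1", f"{name}.2"] for name in loci},
    }


def _load_schema(schema) -> dict:
    if isinstance(schema, (str, Path)):
        import yaml

        with open(schema) as fh:
            return yaml.safe_load(fh)
    return dict(schema)


def read_genotype_table(path: str | Path, schema) -> GenotypeDataset:
    """Read a CSV genotype table under a column-name ``schema`` map.

    The schema maps logical fields (``id``, ``species``, ``site``, ``sex``,
    optional ``caste``/``thorax_width``/``forage_genus``) to column names and
    carries a ``loci`` map ``locus -> [column] | [column_a, column_b]``.
    Blank allele cells are missing calls, never allele 0; a single non-blank
    allele column for a male is a haploid call.
    """
    schema = _load_schema(schema)
    loci_map: Mapping[str, Sequence[str]] = schema["loci"]
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = [schema[k] for k in ("id", "species", "site", "sex")]
        required += [c for cols in loci_map.values() for c in cols]
        missing_cols = [c for c in required if c not in header]
        if missing_cols:
            raise GenotypeFormatError(f"missing mapped columns: {missing_cols}")
        individuals = []
        for row in reader:
            genotype: dict[str, tuple[int, ...]] = {}
            for locus, cols in loci_map.items():
                vals = [row[c].strip() for c in cols]
                alleles = [int(float(v)) for v in vals if v]
                if not alleles:
                    continue
                sex = row[schema["sex"]].strip()
                if len(alleles) == 1 and sex != MALE:
                    continue  # lone allele for a diploid: unusable, treat missing
                genotype[locus] = tuple(alleles)
            tw_col = schema.get("thorax_width")
            tw = row[tw_col].strip() if tw_col and tw_col in row else ""
            fg_col = schema.get("forage_genus")
            fg = row[fg_col].strip() if fg_col and fg_col in row else ""
            caste_col = schema.get("caste")
            caste = row[caste_col].strip() if caste_col and caste_col in row else ""
            sex = row[schema["sex"]].strip()
            individuals.append(
                Individual(
                    id=row[schema["id"]].strip(),
                    species=row[schema["species"]].strip(),
                    site=row[schema["site"]].strip(),
                    sex=sex,
                    caste=caste or ("male" if sex == MALE else "worker"),
                    genotype=genotype,
                    thorax_width=float(tw) if tw else None,
                    forage_genus=fg or None,
                )
            )
    panel = [LocusDef(name=n) for n in loci_map]
    ds = GenotypeDataset(panel=panel, individuals=individuals)
    ds.log(f"read_genotype_table: {Path(path).name}, {len(individuals)} individuals")
    return ds


def write_genotype_table(
    ds: GenotypeDataset, path: str | Path, schema=None
) -> dict:
    """Export the dataset as CSV; returns the schema used (for re-reading)."""
    schema = _load_schema(schema) if schema is not None else default_schema(
        ds.locus_names
    )
    loci_map = schema["loci"]
    header = [schema[k] for k in _META_KEYS if schema.get(k)]
    for cols in loci_map.values():
        header.extend(cols)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for ind in ds.individuals:
            row = [
                ind.id,
                ind.species,
                ind.site,
                ind.sex,
                ind.caste,
                "" if ind.thorax_width is None else repr(ind.thorax_width),
                ind.forage_genus or "",
            ]
            for locus, cols in loci_map.items():
                call = ind.call(locus)
                vals = ["" for _ in cols]
                if call is not None:
                    for k, a in enumerate(call):
                        vals[k] = str(a)
                row.extend(vals)
            writer.writerow(row)
    return schema


# ---------------------------------------------------------------------------
# Species-bin verification
# ---------------------------------------------------------------------------

def verify_species_bins(ds: GenotypeDataset):
    """Report individuals whose alleles fall outside their species' bins.

    Returns a pandas DataFrame with columns ``individual``, ``species``,
    ``locus``, ``allele``; empty when every allele is inside its bin.  Loci
    without bins for an individual's species are skipped.  The dataset is not
    modified.
    """
    import pandas as pd

    rows = []
    for locus in ds.panel:
        bins = locus.species_bins or {}
        for ind in ds.individuals:
            call = ind.call(locus.name)
            if call is None:
                continue
            permitted = bins.get(ind.species)
            if permitted is None:
                continue
            for allele in call:
                if allele not in permitted:
                    rows.append(
                        {
                            "individual": ind.id,
                            "species": ind.species,
                            "locus": locus.name,
                            "allele": allele,
                        }
                    )
    return pd.DataFrame(rows, columns=["individual", "species", "locus", "allele"])
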