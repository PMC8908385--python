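"""Data model and readers/writers for genotype tables, population metadata
and aligned sequences, plus exports to STRUCTURE and GenAlEx layouts.

Native genotype format is a tidy long CSV, one row per individual x locus:

    individual_id,population,species,locus,alleles

where ``alleles`` is a semicolon-separated list of integer fragment sizes
(bp) and an empty field marks a missing locus.  Allele order is
canonicalised ascending on write, so write o read is the identity on
canonical files.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenotypeDataset",
    "IndividualRecord",
    "PopulationMeta",
    "PopulationInfo",
    "SequenceAlignment",
    "SequenceRecord",
    "ParseError",
    "read_genotypes",
    "write_genotypes",
    "read_population_meta",
    "write_population_meta",
    "bin_allele_sizes",
    "read_fasta_alignment",
    "export_structure",
    "write_genalex",
]

MAX_ALLELES = 8  # octoploid sporophyte ceiling


class ParseError(ValueError):
    """Malformed input file; message carries the file line number."""


@dataclass
class IndividualRecord:
    individual_id: str
    population: str
    species: str
    loci: dict[str, frozenset[int] | None]


@dataclass
class GenotypeDataset:
    """Multilocus genotypes with unknown allele dosage (sets of sizes)."""

    individuals: list[IndividualRecord]
    locus_names: list[str]

    def __post_init__(self) -> None:
        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")

    @property
    def population_codes(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def by_population(self) -> dict[str, list[IndividualRecord]]:
        out: dict[str, list[IndividualRecord]] = {}
        for ind in self.individuals:
            out.setdefault(ind.population, []).append(ind)
        return out


@dataclass
class PopulationInfo:
    population_code: str
    country: str = ""
    lat: float = math.nan
    lon: float = math.nan
    cluster_label: str | None = None
    species_label: str = ""


@dataclass
class PopulationMeta:
    populations: list[PopulationInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [p.population_code for p in self.populations]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate population codes in metadata")
        for p in self.populations:
            if not math.isnan(p.lat) and not (-90.0 <= p.lat <= 90.0):
                raise ValueError(f"{p.population_code}: latitude {p.lat} out of range")
            if not math.isnan(p.lon) and not (-180.0 <= p.lon <= 180.0):
                raise ValueError(f"{p.population_code}: longitude {p.lon} out of range")

    def __iter__(self):
        return iter(self.populations)

    @property
    def codes(self) -> list[str]:
        return [p.population_code for p in self.populations]

    def cluster_of(self) -> dict[str, str | None]:
        return {p.population_code: p.cluster_label for p in self.populations}

    def species_of(self) -> dict[str, str]:
        return {p.population_code: p.species_label for p in self.populations}


@dataclass
class SequenceRecord:
    id: str
    location_code: str
    sequence: str


@dataclass
class SequenceAlignment:
    records: list[SequenceRecord]

    @property
    def length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0


_GENOTYPE_HEADER = ["individual_id", "population", "species", "locus", "alleles"]


def read_genotypes(path, meta: PopulationMeta | None = None) -> GenotypeDataset:
    """Read the tidy long genotype CSV.

    When ``meta`` is given, population codes are validated against it.
    Duplicate (individual, locus) rows are an error; repeated allele sizes
    within a cell are deduplicated with a warning.
    """
    cells: dict[str, dict[str, frozenset[int] | None]] = {}
    ind_meta: dict[str, tuple[str, str]] = {}
    locus_names: dict[str, None] = {}
    known_pops = set(meta.codes) if meta is not None else None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != _GENOTYPE_HEADER:
            raise ParseError(
                f"{path}: line 1: expected header {','.join(_GENOTYPE_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 fields, got {len(row)}")
            ind_id, pop, species, locus, alleles_str = (c.strip() for c in row)
            if known_pops is not None and pop not in known_pops:
                raise ParseError(f"{path}: line {lineno}: unknown population {pop!r}")
            if ind_id in ind_meta and ind_meta[ind_id] != (pop, species):
                raise ParseError(
                    f"{path}: line {lineno}: individual {ind_id!r} re-declared with "
                    "different population/species"
                )
            ind_meta.setdefault(ind_id, (pop, species))
            locus_names.setdefault(locus, None)
            cell = cells.setdefault(ind_id, {})
            if locus in cell:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate row for ({ind_id!r}, {locus!r})"
                )
            if alleles_str == "":
                cell[locus] = None
                continue
            tokens = [t for t in alleles_str.split(";") if t.strip()]
            sizes: list[int] = []
            for tok in tokens:
                try:
                    size = int(tok)
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: malformed allele size {tok!r}"
                    ) from None
                if size <= 0:
                    raise ParseError(f"{path}: line {lineno}: non-positive allele size {size}")
                sizes.append(size)
            distinct = frozenset(sizes)
            if len(distinct) < len(sizes):
                warnings.warn(
                    f"{path}: line {lineno}: repeated allele sizes deduplicated", stacklevel=2
                )
            if len(distinct) > MAX_ALLELES:
                raise ParseError(
                    f"{path}: line {lineno}: {len(distinct)} distinct alleles exceeds "
                    f"the maximum of {MAX_ALLELES}"
                )
            cell[locus] = distinct
    loci = list(locus_names)
    individuals = [
        IndividualRecord(
            individual_id=ind_id,
            population=ind_meta[ind_id][0],
            species=ind_meta[ind_id][1],
            loci={locus: cells[ind_id].get(locus) for locus in loci},
        )
        for ind_id in cells
    ]
    return GenotypeDataset(individuals=individuals, locus_names=loci)


def write_genotypes(ds: GenotypeDataset, path) -> None:
    """Write the tidy CSV; alleles canonicalised ascending."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_GENOTYPE_HEADER)
        for ind in ds.individuals:
            for locus in ds.locus_names:
                obs = ind.loci.get(locus)
                alleles = "" if obs is None else ";".join(str(a) for a in sorted(obs))
                writer.writerow([ind.individual_id, ind.population, ind.species, locus, alleles])


_META_HEADER = ["population_code", "country", "lat", "lon", "cluster_label", "species_label"]


def read_population_meta(path) -> PopulationMeta:
    pops: list[PopulationInfo] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _META_HEADER:
            raise ParseError(f"{path}: expected header {','.join(_META_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                lat = float(row["lat"]) if row["lat"].strip() else math.nan
                lon = float(row["lon"]) if row["lon"].strip() else math.nan
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: malformed coordinate") from None
            pops.append(
                PopulationInfo(
                    population_code=row["population_code"].strip(),
                    country=row["country"].strip(),
                    lat=lat,
                    lon=lon,
                    cluster_label=row["cluster_label"].strip() or None,
                    species_label=row["species_label"].strip(),
                )
            )
    return PopulationMeta(populations=pops)


def write_population_meta(meta: PopulationMeta, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_META_HEADER)
        for p in meta:
            writer.writerow(
                [
                    p.population_code,
                    p.country,
                    "" if math.isnan(p.lat) else repr(p.lat),
                    "" if math.isnan(p.lon) else repr(p.lon),
                    p.cluster_label or "",
                    p.species_label,
                ]
            )


def bin_allele_sizes(raw_sizes, repeat_unit: int, offset: int) -> list[int]:
    """Snap fractional fragment sizes to the repeat-unit grid
    {offset + k * repeat_unit, k >= 0}; ties broken toward the smaller size.
    """
    if repeat_unit < 1:
        raise ValueError(f"repeat_unit must be >= 1, got {repeat_unit}")
    out: list[int] = []
    for raw in raw_sizes:
        if raw < 0:
            raise ValueError(f"negative allele size {raw}")
        r = (raw - offset) / repeat_unit
        k = math.ceil(r - 0.5)  # round half down
        k = max(k, 0)
        out.append(offset + k * repeat_unit)
    return out


def read_fasta_alignment(path, location_of=None) -> SequenceAlignment:
    """Read an aligned FASTA; all records must share one length.

    ``location_of`` maps a record id/description to a sampling-location
    code.  Default: a ``location=CODE`` token in the description if present,
    else the id prefix before the first underscore.
    """
    records: list[SequenceRecord] = []
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ParseError(
                f"{path}: record {rec.id!r} has length {len(seq)}, expected {length} "
                "(ragged alignment)"
            )
        if location_of is not None:
            loc = location_of(rec)
        else:
            loc = ""
            for token in rec.description.split():
                if token.startswith("location="):
                    loc = token.split("=", 1)[1]
                    break
            if not loc:
                loc = rec.id.split("_")[0]
        records.append(SequenceRecord(id=rec.id, location_code=loc, sequence=seq))
    if length is None:
        raise ParseError(f"{path}: no FASTA records found")
    return SequenceAlignment(records=records)


def write_fasta_alignment(aln: SequenceAlignment, path) -> None:
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.id} location={rec.location_code}\n{rec.sequence}\n")


def _cycled_rows(alleles: tuple[int, ...] | None, m: int, missing_fill: bool):
    """The m allele copies STRUCTURE/GenAlEx see for one cell.

    Unknown dosage is filled by cycling the observed alleles (ascending) up
    to m copies; with ``missing_fill`` the copies beyond the observed ones
    are coded missing instead.
    """
    if alleles is None or len(alleles) == 0:
        return [None] * m
    ordered = sorted(alleles)
    if len(ordered) > m:
        raise ValueError(
            f"{len(ordered)} observed alleles exceed assumed ploidy {m}; recode first"
        )
    if missing_fill:
        return list(ordered) + [None] * (m - len(ordered))
    return [ordered[i % len(ordered)] for i in range(m)]


def export_structure(ds: GenotypeDataset, coding, path, missing_fill: bool = False) -> None:
    """Write a STRUCTURE input file at the coding's assumed ploidy m.

    Layout (no header row, whitespace-delimited): m rows per individual,
    each row ``<individual_id> <pop_index>`` followed by one allele copy per
    locus; missing data coded -9.  Population indices are 1-based in the
    order populations first appear in the dataset.
    """
    m = coding.assumed_ploidy
    pop_index = {pop: i + 1 for i, pop in enumerate(ds.population_codes)}
    with open(path, "w") as fh:
        for ind in ds.individuals:
            rows: list[list[int | None]] = [[] for _ in range(m)]
            for locus in ds.locus_names:
                copies = _cycled_rows(coding.retained(ind.individual_id, locus), m, missing_fill)
                for r in range(m):
                    rows[r].append(copies[r])
            for r in range(m):
                cells = " ".join("-9" if a is None else str(a) for a in rows[r])
                fh.write(f"{ind.individual_id} {pop_index[ind.population]} {cells}\n")


def write_genalex(ds: GenotypeDataset, coding, path, title: str = "mixopop export") -> None:
    """Write a GenAlEx-style codominant CSV at the coding's assumed ploidy.

    Row 1: n_loci, n_samples, n_pops, then per-population sample sizes.
    Row 2: title, then (blank, blank, pop names aligned with the sizes).
    Row 3: "Ind", "Pop", then each locus name followed by m-1 blanks.
    Data rows: individual id, population, m allele columns per locus
    (missing coded 0, dosage filled by cycling).
    """
    m = coding.assumed_ploidy
    pops = ds.population_codes
    by_pop = ds.by_population()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            [len(ds.locus_names), len(ds.individuals), len(pops)] + [len(by_pop[p]) for p in pops]
        )
        writer.writerow([title, "", ""] + pops)
        header = ["Ind", "Pop"]
        for locus in ds.locus_names:
            header.append(locus)
            header.extend([""] * (m - 1))
        writer.writerow(header)
        for pop in pops:
            for ind in by_pop[pop]:
                row: list = [ind.individual_id, pop]
                for locus in ds.locus_names:
                    copies = _cycled_rows(
                        coding.retained(ind.individual_id, locus), m, missing_fill=False
                    )
                    row.extend(0 if a is None else a for a in copies)
                writer.writerow(row)


def dataset_from_simulation(sim) -> tuple[GenotypeDataset, PopulationMeta]:
    """Convert a SimDataset into the generic genotype + metadata containers."""
    individuals = [
        IndividualRecord(
            individual_id=ind.individual_id,
            population=ind.population_code,
            species=ind.species_label,
            loci={
                locus: ind.observed[j] for j, locus in enumerate(sim.locus_names)
            },
        )
        for ind in sim.individuals
    ]
    ds = GenotypeDataset(individuals=individuals, locus_names=list(sim.locus_names))
    seen: dict[str, PopulationInfo] = {}
    for ind in sim.individuals:
        if ind.population_code not in seen:
            seen[ind.population_code] = PopulationInfo(
                population_code=ind.population_code,
                cluster_label=ind.cluster_code,
                species_label=ind.species_label,
            )
    meta = PopulationMeta(populations=list(seen.values()))
    return ds, meta
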