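"""Tables, metadata, configuration and run manifests.

All tabular inputs are tab-separated text with a header row and ``.`` as the
decimal mark. Abundance tables are taxon-major (rows are taxa, columns are
samples); counts and proportions are both accepted and every table is
normalised to per-sample relative abundance on load. A dense BIOM-format JSON
reader is provided behind the same return contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("microhi")

TAXONOMIC_LEVELS = ("species", "genus", "family", "OTU")
ECOTYPES = ("filter-feeding", "scraper-feeding", "omnivorous", "carnivorous")

NORMALISATION_TOL = 1e-9


class MicrohiError(ValueError):
    """Base class for all validation and format errors raised here."""


class FormatError(MicrohiError):
    """Structurally malformed input (duplicate ids, bad columns, ...)."""


class ValidationError(MicrohiError):
    """Well-formed input violating a domain invariant."""


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Taxon x sample relative-abundance matrix tagged with a taxonomic level.

    ``data`` holds taxa on the index and samples on the columns; every column
    sums to one within :data:`NORMALISATION_TOL`.
    """

    data: pd.DataFrame
    level: str = "species"

    def __post_init__(self) -> None:
        if self.level not in TAXONOMIC_LEVELS:
            raise ValidationError(f"unknown taxonomic level: {self.level!r}")
        validate_abundance_frame(self.data)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, samples: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[:, list(samples)].copy(), self.level)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, level: str = "species") -> "AbundanceTable":
        """Build a table from counts or proportions, normalising per sample."""
        return cls(normalize_columns(frame), level)


def validate_abundance_frame(frame: pd.DataFrame) -> None:
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate taxon identifiers: {dupes}")
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample identifiers: {dupes}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("abundance table contains non-numeric entries")
    if np.isnan(values).any():
        raise FormatError("abundance table contains missing values")
    if (values < 0).any():
        raise ValidationError("abundance table contains negative entries")
    sums = values.sum(axis=0)
    bad = np.abs(sums - 1.0) > NORMALISATION_TOL
    if bad.any():
        names = [str(frame.columns[i]) for i in np.flatnonzero(bad)]
        raise ValidationError(f"sample columns do not sum to 1: {names}")


def normalize_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its total; all-zero columns are rejected."""
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError("abundance table contains missing values")
    if (values < 0).any():
        raise ValidationError("abundance table contains negative entries")
    sums = values.sum(axis=0)
    zero = sums <= 0
    if zero.any():
        names = [str(frame.columns[i]) for i in np.flatnonzero(zero)]
        raise ValidationError(f"all-zero sample columns: {names}")
    out = frame.astype(float).div(sums, axis=1)
    out.index = frame.index.astype(str)
    out.columns = frame.columns.astype(str)
    return out


def read_abundance_table(path: str | Path, level: str = "species") -> AbundanceTable:
    """Read a taxon-major TSV (or dense BIOM JSON) and normalise it.

    The TSV layout is: first column taxon ids, header row sample ids. A file
    whose first non-blank character is ``{`` is parsed as dense BIOM JSON.
    """
    path = Path(path)
    head = path.read_text().lstrip()[:1]
    if head == "{":
        frame = _read_biom_json(path)
    else:
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise FormatError(f"duplicate sample identifiers: {dupes}")
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon identifiers: {dupes}")
        if frame.columns.has_duplicates:
            dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes}")
    return AbundanceTable.from_dataframe(frame, level)


def _read_biom_json(path: Path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    if doc.get("matrix_type") != "dense":
        raise FormatError("only dense BIOM JSON matrices are supported")
    taxa = [str(r["id"]) for r in doc["rows"]]
    samples = [str(c["id"]) for c in doc["columns"]]
    if len(set(taxa)) != len(taxa):
        raise FormatError("duplicate taxon identifiers in BIOM file")
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample identifiers in BIOM file")
    data = np.asarray(doc["data"], dtype=float)
    if data.shape != (len(taxa), len(samples)):
        raise FormatError("BIOM data shape does not match row/column metadata")
    return pd.DataFrame(data, index=taxa, columns=samples)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    frame = table.data.copy()
    frame.index.name = "taxon"
    frame.to_csv(path, sep="\t", float_format="%.12g")


def collapse_taxa(table: AbundanceTable, groups: Mapping[str, str], level: str) -> AbundanceTable:
    """Sum taxon rows into coarser groups (e.g. species -> genus).

    Taxa missing from ``groups`` keep their own identifier.
    """
    mapper = {t: groups.get(t, t) for t in table.taxa}
    collapsed = table.data.groupby(by=mapper, sort=True).sum()
    return AbundanceTable(collapsed, level)


# ---------------------------------------------------------------------------
# Phenotype annotation map
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ("pathogenic", "mobile", "stress")


@dataclass
class PhenotypeMap:
    """Per-taxon weights in [0, 1] for the three health-negative phenotypes.

    Columns: ``pathogenic`` (Potentially Pathogenic), ``mobile`` (Contains
    Mobile Elements), ``stress`` (Stress Tolerant). Binary maps are the
    special case weight ∈ {0, 1}.
    """

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.weights.columns]
        if missing:
            raise FormatError(f"phenotype map missing columns: {missing}")
        if self.weights.index.has_duplicates:
            dupes = self.weights.index[self.weights.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxa in phenotype map: {dupes}")
        vals = self.weights[list(PHENOTYPE_COLUMNS)].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("phenotype map contains missing weights")
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("phenotype weights must lie in [0, 1]")
        self.weights = self.weights[list(PHENOTYPE_COLUMNS)].astype(float)
        self.weights.index = self.weights.index.astype(str)

    @property
    def taxa(self) -> list[str]:
        return list(self.weights.index)

    def badness(self) -> pd.Series:
        """Mean of the three phenotype weights; the per-taxon penalty in the
        health index (a sample's index is 1 minus its abundance-weighted
        badness)."""
        return self.weights.mean(axis=1)


def read_phenotype_map(path: str | Path) -> PhenotypeMap:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return PhenotypeMap(frame)


def write_phenotype_map(pmap: PhenotypeMap, path: str | Path) -> None:
    frame = pmap.weights.copy()
    frame.index.name = "taxon"
    frame.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """One record per sample: provenance plus host morphometrics for gut
    samples (weight in grams, body length in centimetres)."""

    sample_id: str
    source: str  # "gut" | "water"
    species: str = ""
    ecotype: str = ""
    site: str = ""
    year: int = 0
    weight_g: float | None = None
    length_cm: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("gut", "water"):
            raise ValidationError(
                f"sample {self.sample_id}: source must be gut or water, got {self.source!r}"
            )
        if self.source == "gut":
            if not self.species:
                raise ValidationError(f"gut sample {self.sample_id} lacks a species")
            if self.ecotype not in ECOTYPES:
                raise ValidationError(
                    f"gut sample {self.sample_id}: unknown ecotype {self.ecotype!r}"
                )
        else:
            if self.species or self.ecotype:
                raise ValidationError(
                    f"water sample {self.sample_id} must not carry species/ecotype"
                )
        if (self.weight_g is None) != (self.length_cm is None):
            raise ValidationError(
                f"sample {self.sample_id}: weight and length must be present together"
            )
        if self.weight_g is not None and (self.weight_g <= 0 or self.length_cm <= 0):
            raise ValidationError(f"sample {self.sample_id}: non-positive weight/length")

    @property
    def unit(self) -> str:
        """Site-year aggregation unit key."""
        return f"{self.site}|{self.year}"


METADATA_COLUMNS = (
    "sample_id",
    "source",
    "species",
    "ecotype",
    "site",
    "year",
    "weight_g",
    "length_cm",
)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str})
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    records = []
    for row in frame.itertuples(index=False):
        weight = None if pd.isna(row.weight_g) else float(row.weight_g)
        length = None if pd.isna(row.length_cm) else float(row.length_cm)
        records.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                source=str(row.source),
                species="" if pd.isna(row.species) else str(row.species),
                ecotype="" if pd.isna(row.ecotype) else str(row.ecotype),
                site="" if pd.isna(row.site) else str(row.site),
                year=0 if pd.isna(row.year) else int(row.year),
                weight_g=weight,
                length_cm=length,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in metadata")
    return records


def metadata_frame(records: Iterable[SampleMetadata]) -> pd.DataFrame:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return frame.set_index("sample_id", drop=False)


def write_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def check_ids_match(table: AbundanceTable, records: Sequence[SampleMetadata]) -> None:
    """Cross-check that every table sample has a metadata record."""
    known = {r.sample_id for r in records}
    missing = [s for s in table.samples if s not in known]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")


# ---------------------------------------------------------------------------
# Community structure
# ---------------------------------------------------------------------------


@dataclass
class CommunityStructure:
    """Fish community census: individuals counted per species. The counts act
    as weights when species-level health indices are averaged up to the
    community or ecotype level."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for species, count in self.counts.items():
            c = int(count)
            if c < 0:
                raise ValidationError(f"negative count for species {species}")
            clean[str(species)] = c
        if sum(clean.values()) <= 0:
            raise ValidationError("community structure has zero total count")
        self.counts = clean

    def weights(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {s: c / total for s, c in self.counts.items()}


def read_community(path: str | Path) -> CommunityStructure:
    frame = pd.read_csv(path, sep="\t")
    if not {"species", "count"}.issubset(frame.columns):
        raise FormatError("community table needs 'species' and 'count' columns")
    return CommunityStructure(dict(zip(frame["species"].astype(str), frame["count"])))


def write_community(community: CommunityStructure, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"species": list(community.counts), "count": list(community.counts.values())}
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All analysis knobs in one place; every stage reads from here.

    The screening thresholds (``slope_min`` 0.1, ``r2_min`` 0.6, ``lda_min``
    3.0, ``alpha`` 0.05) follow the study design this pipeline implements.
    """

    level: str = "species"
    # dysbiosis rule
    strategy: str = "branch"  # "branch" (pure-subtree) or "cut" (flat clusters)
    linkage: str = "average"
    cut_q: float = 75.0
    min_conspecifics: int = 3
    purity_min: float = 0.6
    # screening thresholds
    slope_min: float = 0.1
    r2_min: float = 0.6
    lda_min: float = 3.0
    alpha: float = 0.05
    min_env_mean: float = 1e-4
    key_ecotypes_required: int = 3
    key_exclude_ecotypes: tuple[str, ...] = ("omnivorous",)
    bh_correction: bool = False
    renormalize_ratios: bool = True
    unit: str = "site-year"
    lda_bootstrap: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        for name in ("slope_min", "r2_min", "lda_min", "purity_min", "cut_q"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.min_conspecifics < 1:
            raise ValidationError("min_conspecifics must be >= 1")


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` text file into a :class:`RunConfig`."""
    values: dict[str, object] = {}
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"config line {lineno}: expected key = value")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in fields:
            raise FormatError(f"config line {lineno}: unknown key {key!r}")
        ftype = fields[key].type
        if ftype == "bool":
            values[key] = _BOOL[val.lower()]
        elif ftype == "int":
            values[key] = int(val)
        elif ftype == "float":
            values[key] = float(val)
        elif ftype.startswith("tuple"):
            values[key] = tuple(v.strip() for v in val.split(",") if v.strip())
        else:
            values[key] = val
    return RunConfig(**values)


def write_config(config: RunConfig, path: str | Path) -> None:
    lines = []
    for f in dataclasses.fields(RunConfig):
        value = getattr(config, f.name)
        if isinstance(value, tuple):
            value = ",".join(value)
        lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_manifest(
    command: str,
    config: RunConfig,
    seed: int | None,
    inputs: Mapping[str, str | Path],
) -> str:
    """Deterministic record of a run: command, config, seed and input
    checksums. Contains no wall-clock information so identical runs produce
    identical manifests."""
    doc = {
        "command": command,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in sorted(inputs.items())
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True, default=list) + "\n"


def write_manifest(
    command: str,
    config: RunConfig,
    seed: int | None,
    inputs: Mapping[str, str | Path],
    path: str | Path,
) -> None:
    text = run_manifest(command, config, seed, inputs)
    Path(path).write_text(text)
    logger.info("run manifest written to %s", path)
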