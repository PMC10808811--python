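"""Synthetic paired gut/water microbiome cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised and validated without real data:

* each fish species has a healthy baseline gut microHI (defaults centred on
  0.71) realised through a species-specific core composition;
* a dysbiotic subpopulation (default prevalence 0.30) has its index
  depressed by a fixed gap (default 0.13, i.e. 0.71 healthy vs 0.58
  unhealthy) *and* a displaced composition, because the dendrogram
  classifier and the score are distinct readouts;
* water samples per site-year unit are drawn around a base composition
  whose phenotype-weighted microHI exactly equals the unit's target
  (defaults spanning 0.6-0.9);
* environment-to-gut coupling acts on composition: a gut sample mixes its
  species core with the local water base at a rate set by the ecotype's
  coupling coefficient beta (default 0.5 for carnivorous fish, 0
  elsewhere), so microHI coupling emerges instead of being injected;
* designated "spiked" health-negative taxa enter dysbiotic guts in
  proportion to their local water abundance, making them recoverable by the
  correlation + differential-abundance cascade.

Compositions are Dirichlet draws around the constructed base vectors
(concentration 50 by default, moderate overdispersion). Because the health
index is linear in composition, base vectors with an exact target index can
always be solved as mixtures of phenotype-free and phenotype-carrying
profiles; infeasible targets raise a parameter error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_config import (
    AbundanceTable,
    CommunityStructure,
    MicrohiError,
    PhenotypeMap,
    SampleMetadata,
    write_abundance_table,
    write_community,
    write_metadata,
    write_phenotype_map,
)


class ParameterError(MicrohiError):
    """Simulation parameters that cannot be realised."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    ecotype: str
    n_samples: int
    baseline: float  # healthy gut microHI target
    fulton_k: float = 1.1


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are the study conditions."""

    species: tuple[SpeciesSpec, ...]
    sites: tuple[str, ...] = ("S1", "S2", "S3", "S4")
    years: tuple[int, ...] = (2021, 2022)
    env_microhi: tuple[float, ...] | None = None  # per site-year unit
    water_per_unit: tuple[int, ...] | int = 4
    n_taxa: int = 150
    n_linked: int = 100
    n_spiked: int = 3
    spike_gain: float = 4.0
    spike_water_range: tuple[float, float] = (0.001, 0.045)
    dysbiosis_prevalence: float = 0.30
    dysbiosis_gap: float = 0.13
    dysbiosis_mix: float = 0.7
    background_mix: float = 0.02
    coupling_efficiency: float = 0.5  # water mass fraction acquired per unit beta
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "carnivorous": 0.5,
            "filter-feeding": 0.0,
            "scraper-feeding": 0.0,
            "omnivorous": 0.0,
        }
    )
    concentration: float = 50.0
    fulton_cv: float = 0.03
    fulton_unhealthy_drop: float = 0.04
    community_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.dysbiosis_prevalence <= 1:
            raise ParameterError("dysbiosis prevalence must lie in [0, 1]")
        if self.n_spiked > self.n_linked or self.n_linked > self.n_taxa:
            raise ParameterError("need n_spiked <= n_linked <= n_taxa")
        for spec in self.species:
            if not 0 < spec.baseline < 1:
                raise ParameterError(f"baseline for {spec.name} must lie in (0, 1)")
            if spec.baseline - self.dysbiosis_gap <= 0:
                raise ParameterError(
                    f"dysbiosis gap {self.dysbiosis_gap} exceeds baseline of {spec.name}"
                )

    @property
    def units(self) -> list[tuple[str, int]]:
        return list(product(self.sites, self.years))

    def unit_env_targets(self) -> np.ndarray:
        units = self.units
        if self.env_microhi is not None:
            if len(self.env_microhi) != len(units):
                raise ParameterError(
                    f"env_microhi needs {len(units)} values, got {len(self.env_microhi)}"
                )
            return np.asarray(self.env_microhi, dtype=float)
        return np.linspace(0.60, 0.90, len(units))

    def water_counts(self) -> list[int]:
        units = self.units
        if isinstance(self.water_per_unit, int):
            return [self.water_per_unit] * len(units)
        if len(self.water_per_unit) != len(units):
            raise ParameterError("water_per_unit length must match the unit count")
        return [int(c) for c in self.water_per_unit]


def default_params() -> SimulationParams:
    """Balanced eight-species cohort, two species per ecotype, 200 gut
    samples, eight site-year units. Species baselines are paired around the
    anchor healthy mean of 0.71."""
    pairs = [
        ("carnivorous", 0.64, 0.78),
        ("filter-feeding", 0.66, 0.76),
        ("scraper-feeding", 0.68, 0.74),
        ("omnivorous", 0.70, 0.72),
    ]
    species = []
    i = 1
    for ecotype, low, high in pairs:
        for baseline in (low, high):
            species.append(SpeciesSpec(f"Sp{i:02d}", ecotype, 25, baseline, 1.0 + 0.05 * i))
            i += 1
    return SimulationParams(species=tuple(species))


def screening_params(n_per_species: int = 225) -> SimulationParams:
    """Cohort sized for screening-recovery experiments.

    Correlation screening and ecotype-level regression operate on site-year
    group means, so their recovery experiments need stable unit means:
    twelve site-year units, thirty water samples per unit (the water
    sampling depth of the surveys this emulates) and enough gut samples per
    species that binomial prevalence noise does not swamp the between-unit
    signal.
    """
    params = default_params()
    return replace(
        params,
        species=tuple(replace(s, n_samples=n_per_species) for s in params.species),
        years=(2020, 2021, 2022),
        water_per_unit=30,
    )


#: Wild-fish community of the middle-Yangtze survey: (label, ecotype, count).
_YANGTZE_SPECIES = (
    ("L.crassilabris", "carnivorous", 31),
    ("L.longirostris", "carnivorous", 41),
    ("P.vachelli", "carnivorous", 4),
    ("P.nitidus", "carnivorous", 11),
    ("P.fulvidraco", "carnivorous", 16),
    ("P.tenuis", "carnivorous", 6),
    ("S.meridionalis", "carnivorous", 2),
    ("H.molitrix", "filter-feeding", 4),
    ("A.nobilis", "filter-feeding", 5),
    ("C.heterodon", "omnivorous", 35),
    ("X.argentea", "scraper-feeding", 14),
    ("S.chuatsi", "carnivorous", 9),
    ("S.kneri", "carnivorous", 5),
    ("C.brachygnathus", "carnivorous", 31),
)

PRESETS = ("middle-yangtze-2022", "two-year")


def emulate_study_shape(preset: str) -> SimulationParams:
    """Parameter presets echoing the field survey's sampling shape.

    ``middle-yangtze-2022``: 14 species in four ecotypes, 214 gut samples,
    one site-year with 30 water samples at env microHI 0.71.
    ``two-year``: the same community over two site-years, env microHI 0.71
    (30 water samples) and 0.83 (13 water samples).
    """
    baselines = np.linspace(0.62, 0.80, len(_YANGTZE_SPECIES))
    species = tuple(
        SpeciesSpec(name, ecotype, count, round(float(b), 4), 1.0 + 0.02 * k)
        for k, ((name, ecotype, count), b) in enumerate(zip(_YANGTZE_SPECIES, baselines))
    )
    if preset == "middle-yangtze-2022":
        return SimulationParams(
            species=species,
            sites=("Jiangan",),
            years=(2022,),
            env_microhi=(0.71,),
            water_per_unit=30,
        )
    if preset == "two-year":
        return SimulationParams(
            species=species,
            sites=("Jiangan",),
            years=(2020, 2022),
            env_microhi=(0.83, 0.71),
            water_per_unit=(13, 30),
        )
    raise ParameterError(f"unknown preset {preset!r}; choose from {PRESETS}")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    status: dict[str, str]  # sample -> healthy | unhealthy
    baselines: dict[str, float]
    betas: dict[str, float]
    spiked_taxa: list[str]
    env_microhi: dict[str, float]  # unit key -> target
    sample_unit: dict[str, str]
    healthy_mean: float
    unhealthy_mean: float


@dataclass
class SimulatedDataset:
    gut: AbundanceTable
    water: AbundanceTable
    phenotypes: PhenotypeMap
    metadata: list[SampleMetadata]
    community: CommunityStructure
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Generator internals
# ---------------------------------------------------------------------------


def _taxon_names(n_taxa: int) -> list[str]:
    # three species-level taxa per genus, five per family
    return [f"f{i // 5:02d}.g{i // 3:03d}.s{i:03d}" for i in range(n_taxa)]


def taxonomy_maps(taxa: Sequence[str]) -> tuple[dict[str, str], dict[str, str]]:
    """Genus and family grouping maps parsed from generated taxon ids."""
    genus = {t: t.split(".")[1] for t in taxa}
    family = {t: t.split(".")[0] for t in taxa}
    return genus, family


def _support_profile(
    rng: np.random.Generator,
    n_taxa: int,
    pool: np.ndarray,
    size: int,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Random composition supported on ``size`` taxa drawn from ``pool``."""
    size = min(size, pool.size)
    p = None
    if bias is not None:
        p = bias[pool] / bias[pool].sum()
    chosen = rng.choice(pool, size=size, replace=False, p=p)
    weights = rng.dirichlet(np.full(size, 2.0))
    if bias is not None:
        weights = weights * bias[chosen]
        weights = weights / weights.sum()
    profile = np.zeros(n_taxa)
    profile[chosen] = weights
    return profile


def _solve_mixture(
    target_badness: float,
    good: np.ndarray,
    bad: np.ndarray,
    badness: np.ndarray,
    context: str,
) -> np.ndarray:
    """Mixture of a phenotype-free and a phenotype-carrying profile whose
    abundance-weighted badness equals the target exactly."""
    b_bad = float(badness @ bad)
    if target_badness < -1e-9:
        raise ParameterError(f"{context}: target badness {target_badness:.3f} below 0")
    if b_bad <= 0 or target_badness > 0.97 * b_bad:
        raise ParameterError(
            f"{context}: target badness {target_badness:.3f} infeasible for a "
            f"profile with maximum badness {b_bad:.3f}; the annotation map "
            "cannot express this health index"
        )
    x = max(target_badness, 0.0) / b_bad
    return (1.0 - x) * good + x * bad


def simulate_dataset(params: SimulationParams, seed: int = 0) -> SimulatedDataset:
    """Generate one paired gut/water cohort; fixed seed, fixed bytes."""
    rng = np.random.default_rng(seed)
    n_taxa = params.n_taxa
    taxa = _taxon_names(n_taxa)

    # --- phenotype annotations -------------------------------------------
    linked = np.arange(params.n_linked)
    good = np.arange(params.n_linked, n_taxa)
    spiked = linked[: params.n_spiked]
    weights = np.zeros((n_taxa, 3))
    for t in linked[params.n_spiked :]:
        row = (rng.random(3) < 0.6) * rng.uniform(0.4, 1.0, 3)
        if not row.any():
            row[int(rng.integers(3))] = rng.uniform(0.4, 1.0)
        weights[t] = row
    weights[spiked] = 0.9
    badness = weights.mean(axis=1)

    # taxon pools: spiked and a water-borne pool live in the water column;
    # the gut pool builds species cores; ten phenotype-free taxa are
    # reserved as the dysbiosis companion flora
    n_water_pool = min(30, params.n_linked - params.n_spiked)
    water_pool = linked[params.n_spiked : params.n_spiked + n_water_pool]
    gut_pool = linked[params.n_spiked + n_water_pool :]
    if gut_pool.size < 10:
        raise ParameterError("too few phenotype-linked taxa for species cores")
    n_companion = min(10, good.size // 3)
    companions = good[-n_companion:]
    core_good = good[:-n_companion]

    # --- shared profiles --------------------------------------------------
    p_water_good = _support_profile(rng, n_taxa, core_good, 15)
    p_water_bad = _support_profile(rng, n_taxa, water_pool, water_pool.size, bias=badness**2)
    p_filler = _support_profile(rng, n_taxa, gut_pool, min(25, gut_pool.size), bias=badness**2)
    p_companion = _support_profile(rng, n_taxa, companions, companions.size)
    b_filler = float(badness @ p_filler)

    # --- water bases per site-year unit ----------------------------------
    units = params.units
    unit_keys = [f"{site}|{year}" for site, year in units]
    env_targets = params.unit_env_targets()
    b_env = 1.0 - env_targets
    lo, hi = params.spike_water_range
    spike_water = rng.uniform(lo, hi, size=(params.n_spiked, len(units)))
    water_bases = []
    for u, key in enumerate(unit_keys):
        contrib = float(badness[spiked] @ spike_water[:, u])
        if contrib > 0.95 * b_env[u]:
            spike_water[:, u] *= 0.95 * b_env[u] / contrib
            contrib = float(badness[spiked] @ spike_water[:, u])
        spike_vec = np.zeros(n_taxa)
        spike_vec[spiked] = spike_water[:, u]
        b_wb = float(badness @ p_water_bad)
        x = (b_env[u] - contrib) / b_wb
        rest = 1.0 - spike_water[:, u].sum() - x
        if x < 0 or x > 0.97 or rest < 0:
            raise ParameterError(
                f"unit {key}: environmental microHI target {env_targets[u]:.2f} "
                "infeasible with the current annotation map"
            )
        water_bases.append(spike_vec + x * p_water_bad + rest * p_water_good)

    # --- species cores ----------------------------------------------------
    mean_b_env = float(b_env.mean())
    cores: dict[str, np.ndarray] = {}
    mix_rate: dict[str, float] = {}
    for spec in params.species:
        if spec.ecotype not in params.beta:
            raise ParameterError(f"no coupling beta for ecotype {spec.ecotype!r}")
        m = params.background_mix + params.coupling_efficiency * params.beta[spec.ecotype]
        if not 0 <= m < 1:
            raise ParameterError(f"total mixing rate {m} for {spec.name} outside [0, 1)")
        mix_rate[spec.name] = m
        p_good = _support_profile(rng, n_taxa, core_good, 20)
        p_bad = _support_profile(rng, n_taxa, gut_pool, min(25, gut_pool.size), bias=badness**2)
        b_core = ((1.0 - spec.baseline) - m * mean_b_env) / (1.0 - m)
        cores[spec.name] = _solve_mixture(
            b_core, p_good, p_bad, badness, f"species {spec.name}"
        )

    # --- samples ----------------------------------------------------------
    floor = 1e-6
    conc = params.concentration
    columns: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    status: dict[str, str] = {}
    sample_unit: dict[str, str] = {}
    f = params.dysbiosis_mix

    gut_index = 0
    for si, spec in enumerate(params.species):
        m = mix_rate[spec.name]
        for i in range(spec.n_samples):
            u = (i + si) % len(units)
            site, year = units[u]
            sample_id = f"g{gut_index:04d}"
            gut_index += 1
            healthy_base = (1.0 - m) * cores[spec.name] + m * water_bases[u]
            dysbiotic = rng.random() < params.dysbiosis_prevalence
            if dysbiotic:
                b_hb = float(badness @ healthy_base)
                b_target = (1.0 - spec.baseline) + params.dysbiosis_gap
                b_req = (b_target - (1.0 - f) * b_hb) / f
                spike = params.spike_gain * spike_water[:, u]
                contrib = float(badness[spiked] @ spike)
                if contrib > 0.9 * b_req:
                    spike *= 0.9 * b_req / contrib
                    contrib = float(badness[spiked] @ spike)
                x = (b_req - contrib) / b_filler
                rest = 1.0 - spike.sum() - x
                if x < 0 or rest < 0:
                    raise ParameterError(
                        f"species {spec.name}: dysbiotic microHI target "
                        f"{spec.baseline - params.dysbiosis_gap:.2f} infeasible"
                    )
                spike_vec = np.zeros(n_taxa)
                spike_vec[spiked] = spike
                dys_profile = spike_vec + x * p_filler + rest * p_companion
                base = (1.0 - f) * healthy_base + f * dys_profile
            else:
                base = healthy_base
            columns[sample_id] = rng.dirichlet(conc * base + floor)
            status[sample_id] = "unhealthy" if dysbiotic else "healthy"
            sample_unit[sample_id] = unit_keys[u]

            length = float(np.clip(rng.normal(20.0, 2.0), 10.0, 32.0))
            k = spec.fulton_k * (1.0 + rng.normal(0.0, params.fulton_cv))
            if dysbiotic:
                k *= 1.0 - params.fulton_unhealthy_drop
            metadata.append(
                SampleMetadata(
                    sample_id=sample_id,
                    source="gut",
                    species=spec.name,
                    ecotype=spec.ecotype,
                    site=site,
                    year=year,
                    weight_g=round(k * length**3 / 100.0, 4),
                    length_cm=round(length, 4),
                )
            )

    water_columns: dict[str, np.ndarray] = {}
    water_index = 0
    for u, (site, year) in enumerate(units):
        for _ in range(params.water_counts()[u]):
            sample_id = f"w{water_index:03d}"
            water_index += 1
            water_columns[sample_id] = rng.dirichlet(conc * water_bases[u] + floor)
            sample_unit[sample_id] = unit_keys[u]
            metadata.append(
                SampleMetadata(sample_id=sample_id, source="water", site=site, year=year)
            )

    # --- assemble ---------------------------------------------------------
    gut_table = AbundanceTable.from_dataframe(
        pd.DataFrame(columns, index=taxa), level="species"
    )
    water_table = AbundanceTable.from_dataframe(
        pd.DataFrame(water_columns, index=taxa), level="species"
    )
    pmap = PhenotypeMap(
        pd.DataFrame(weights, index=taxa, columns=["pathogenic", "mobile", "stress"])
    )
    counts = params.community_counts or {
        spec.name: spec.n_samples * 10 for spec in params.species
    }
    community = CommunityStructure(dict(counts))
    baselines = {spec.name: spec.baseline for spec in params.species}
    n_per = np.array([spec.n_samples for spec in params.species], dtype=float)
    base_arr = np.array([spec.baseline for spec in params.species])
    healthy_mean = float((n_per * base_arr).sum() / n_per.sum())
    truth = GroundTruth(
        status=status,
        baselines=baselines,
        betas=dict(params.beta),
        spiked_taxa=[taxa[t] for t in spiked],
        env_microhi=dict(zip(unit_keys, env_targets.tolist())),
        sample_unit=sample_unit,
        healthy_mean=healthy_mean,
        unhealthy_mean=healthy_mean - params.dysbiosis_gap,
    )
    return SimulatedDataset(gut_table, water_table, pmap, metadata, community, truth)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write every emitted table plus the ground truth as TSV/JSON text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_abundance_table(dataset.gut, outdir / "gut_abundance.tsv")
    write_abundance_table(dataset.water, outdir / "water_abundance.tsv")
    write_phenotype_map(dataset.phenotypes, outdir / "phenotypes.tsv")
    write_metadata(dataset.metadata, outdir / "metadata.tsv")
    write_community(dataset.community, outdir / "community.tsv")
    truth_rows = pd.DataFrame(
        {
            "sample_id": list(dataset.truth.status),
            "status": list(dataset.truth.status.values()),
            "unit": [dataset.truth.sample_unit[s] for s in dataset.truth.status],
        }
    )
    truth_rows.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    summary = {
        "baselines": dataset.truth.baselines,
        "betas": dataset.truth.betas,
        "spiked_taxa": dataset.truth.spiked_taxa,
        "env_microhi": dataset.truth.env_microhi,
        "healthy_mean": dataset.truth.healthy_mean,
        "unhealthy_mean": dataset.truth.unhealthy_mean,
    }
    (outdir / "truth.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
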