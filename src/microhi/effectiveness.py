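"""Health-label vs score comparisons and host-environment coupling.

Relates the dendrogram-based health labels to the gut microHI (and Fulton's
condition) at the community, species and ecotype levels, computes
species-specific healthy baselines, aggregates them to community or ecotype
values weighted by the fish community structure, and regresses gut microHI
on water environmental microHI over site-year aggregation units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rank_sum_test, significance_stars
from .io_config import CommunityStructure, ValidationError

logger = logging.getLogger("microhi")


# ---------------------------------------------------------------------------
# Healthy vs unhealthy group comparisons
# ---------------------------------------------------------------------------


def compare_groups(
    values: pd.Series,
    labels: pd.Series,
    meta: pd.DataFrame,
    unit: str = "community",
) -> pd.DataFrame:
    """Healthy-vs-unhealthy comparison of a per-sample quantity.

    ``values`` is any per-sample score (gut microHI, Fulton's K); ``labels``
    maps the same samples to healthy/unhealthy. ``unit`` groups the
    comparison: ``community`` (one row), ``species`` or ``ecotype``. Each row
    carries group sizes, means, their difference and a two-sided rank-sum
    p-value with star annotation; a one-sided group yields p = NaN.
    """
    samples = values.index.intersection(labels.index)
    if len(samples) == 0:
        raise ValidationError("no samples shared between values and labels")
    vals = values.loc[samples]
    labs = labels.loc[samples]
    if unit == "community":
        groups = {"community": samples}
    elif unit in ("species", "ecotype"):
        key = meta.loc[samples, unit]
        groups = {
            f"{unit}:{name}": samples[key == name] for name in sorted(key.unique())
        }
    else:
        raise ValidationError(f"unknown comparison unit {unit!r}")

    rows = []
    for name, members in groups.items():
        healthy = vals.loc[members][labs.loc[members] == "healthy"]
        unhealthy = vals.loc[members][labs.loc[members] == "unhealthy"]
        mean_h = float(healthy.mean()) if len(healthy) else np.nan
        mean_u = float(unhealthy.mean()) if len(unhealthy) else np.nan
        if len(healthy) and len(unhealthy):
            p = rank_sum_test(healthy.to_numpy(), unhealthy.to_numpy()).p_value
        else:
            p = np.nan
        rows.append(
            {
                "unit": name,
                "n_healthy": int(len(healthy)),
                "n_unhealthy": int(len(unhealthy)),
                "mean_healthy": mean_h,
                "mean_unhealthy": mean_u,
                "delta": mean_h - mean_u,
                "test_p": p,
                "significance": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)


def species_baselines(
    values: pd.Series, labels: pd.Series, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-species baseline: mean gut microHI over healthy conspecifics.

    Species without a single healthy sample are omitted with a warning.
    """
    samples = values.index.intersection(labels.index)
    healthy = samples[labels.loc[samples] == "healthy"]
    rows = []
    for species in sorted(meta.loc[samples, "species"].unique()):
        members = healthy[meta.loc[healthy, "species"] == species]
        if len(members) == 0:
            logger.warning("species %s has no healthy samples; baseline omitted", species)
            continue
        rows.append(
            {
                "species": species,
                "baseline": float(values.loc[members].mean()),
                "n": int(len(members)),
            }
        )
    return pd.DataFrame(rows, columns=["species", "baseline", "n"])


# ---------------------------------------------------------------------------
# Community-structure weighting
# ---------------------------------------------------------------------------


def weighted_community_microhi(
    means: Mapping[str, float], community: CommunityStructure
) -> float:
    """Community-level index: species means weighted by each species' share
    of individuals in the fish community. Zero-count species contribute
    nothing; weighted species missing from ``means`` are an error."""
    active = {s: c for s, c in community.counts.items() if c > 0}
    missing = sorted(s for s in active if s not in means)
    if missing:
        raise ValidationError(f"species in community without scores: {missing}")
    total = sum(active.values())
    return float(sum(c / total * means[s] for s, c in active.items()))


def ecotype_microhi(
    means: Mapping[str, float],
    community: CommunityStructure,
    species_ecotype: Mapping[str, str],
) -> dict[str, float]:
    """Community weighting restricted to each ecotype, weights renormalised
    within the ecotype. Ecotypes with no scored species are omitted."""
    out: dict[str, float] = {}
    ecotypes = sorted({species_ecotype[s] for s in means if s in species_ecotype})
    for eco in ecotypes:
        counts = {
            s: c
            for s, c in community.counts.items()
            if c > 0 and species_ecotype.get(s) == eco and s in means
        }
        if not counts:
            logger.warning("ecotype %s has no scored species; omitted", eco)
            continue
        out[eco] = weighted_community_microhi(means, CommunityStructure(counts))
    return out


# ---------------------------------------------------------------------------
# Environment -> gut regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    unit_label: str
    n_points: int
    slope: float
    intercept: float
    r2: float
    p: float
    flag: str  # "ok" | "underdetermined" | "degenerate"


def fit_env_gut_regression(
    points: Sequence[tuple[float, float]], unit_label: str = ""
) -> RegressionResult:
    """Ordinary least squares of gut microHI on water environmental microHI.

    ``points`` are (env, gut) pairs, one per aggregation unit. Fewer than
    three points flags the result underdetermined; zero variance in the env
    values flags it degenerate.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        return RegressionResult(unit_label, n, np.nan, np.nan, np.nan, np.nan, "underdetermined")
    env, gut = pts[:, 0], pts[:, 1]
    if np.ptp(env) == 0:
        return RegressionResult(unit_label, n, np.nan, np.nan, np.nan, np.nan, "degenerate")
    if np.ptp(gut) == 0:
        return RegressionResult(unit_label, n, 0.0, float(gut[0]), 0.0, 1.0, "ok")
    fit = stats.linregress(env, gut)
    return RegressionResult(
        unit_label,
        n,
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        float(fit.pvalue),
        "ok",
    )


def env_gut_points(
    gut_scores: pd.Series,
    water_scores: pd.Series,
    meta: pd.DataFrame,
    community: CommunityStructure,
    species: Sequence[str] | None = None,
    healthy_only: bool = True,
    labels: pd.Series | None = None,
) -> list[tuple[float, float]]:
    """Build (env microHI, community-weighted gut microHI) regression points,
    one per site-year unit.

    The env value of a unit is the mean water microHI over its water
    samples; the gut value is the community-structure-weighted average of
    per-species mean gut microHI within the unit (optionally healthy samples
    only, given ``labels``). Units lacking either side are skipped.
    """
    meta = meta.copy()
    meta["unit"] = meta["site"].astype(str) + "|" + meta["year"].astype(str)
    gut_meta = meta.loc[meta.index.intersection(gut_scores.index)]
    water_meta = meta.loc[meta.index.intersection(water_scores.index)]
    if healthy_only:
        if labels is None:
            raise ValidationError("healthy_only requires labels")
        keep = labels.index[labels == "healthy"]
        gut_meta = gut_meta.loc[gut_meta.index.intersection(keep)]
    if species is not None:
        gut_meta = gut_meta[gut_meta["species"].isin(list(species))]

    points = []
    for unit in sorted(water_meta["unit"].unique()):
        env = float(water_scores.loc[water_meta.index[water_meta["unit"] == unit]].mean())
        members = gut_meta.index[gut_meta["unit"] == unit]
        if len(members) == 0:
            continue
        by_species = (
            gut_scores.loc[members].groupby(gut_meta.loc[members, "species"]).mean()
        )
        counts = {
            s: community.counts.get(s, 0)
            for s in by_species.index
            if community.counts.get(s, 0) > 0
        }
        if not counts:
            continue
        gut = weighted_community_microhi(
            by_species.to_dict(), CommunityStructure(counts)
        )
        points.append((env, gut))
    return points


def ecotype_regressions(
    gut_scores: pd.Series,
    water_scores: pd.Series,
    meta: pd.DataFrame,
    community: CommunityStructure,
    labels: pd.Series | None = None,
    healthy_only: bool = True,
) -> pd.DataFrame:
    """Env-gut regression at the community level and within each ecotype."""
    gut_meta = meta.loc[meta.index.intersection(gut_scores.index)]
    rows = []
    units = [("community", None)] + [
        (f"ecotype:{e}", sorted(gut_meta.loc[gut_meta["ecotype"] == e, "species"].unique()))
        for e in sorted(gut_meta["ecotype"].unique())
        if e
    ]
    for label, species in units:
        pts = env_gut_points(
            gut_scores,
            water_scores,
            meta,
            community,
            species=species,
            healthy_only=healthy_only,
            labels=labels,
        )
        res = fit_env_gut_regression(pts, unit_label=label)
        rows.append(
            {
                "unit": res.unit_label,
                "n_points": res.n_points,
                "slope": res.slope,
                "intercept": res.intercept,
                "r2": res.r2,
                "p": res.p,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(rows)
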