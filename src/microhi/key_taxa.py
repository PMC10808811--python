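"""Key health-impacting taxa: correlation screen + differential abundance.

A taxon is a *key* water-borne health risk when it survives the whole
cascade:

1. phenotype-linked — carries at least one health-negative phenotype weight
   and is present in the data;
2. correlated — its mean abundance in the gut sample group tracks its mean
   abundance in the water sample group across site-year units (r² above
   ``r2_min``);
3. positive — the regression slope exceeds ``slope_min``;
4. differential — significantly more abundant in unhealthy than healthy
   hosts (Kruskal-Wallis p below ``alpha`` and LEfSe-style LDA effect size
   at least ``lda_min``) in at least ``k`` of the considered ecotypes.

Survivor counts are monotone non-increasing along the cascade because each
stage conjoins one more condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._stats import rank_sum_test
from .io_config import AbundanceTable, PhenotypeMap, RunConfig

logger = logging.getLogger("microhi")

LDA_SCALE = 1e6  # abundances are rescaled to a per-sample total of 10^6


# ---------------------------------------------------------------------------
# Stage 1: phenotype-linked taxa
# ---------------------------------------------------------------------------


def phenotype_linked_taxa(
    tables: AbundanceTable | Sequence[AbundanceTable], pmap: PhenotypeMap
) -> list[str]:
    """Taxa with any phenotype weight > 0 and nonzero abundance somewhere."""
    if isinstance(tables, AbundanceTable):
        tables = [tables]
    weighted = set(pmap.weights.index[(pmap.weights > 0).any(axis=1)])
    present: set[str] = set()
    for table in tables:
        mask = (table.values > 0).any(axis=1)
        present.update(np.asarray(table.taxa)[mask])
    return sorted(weighted & present)


# ---------------------------------------------------------------------------
# Stage 2: environment-gut abundance correlation
# ---------------------------------------------------------------------------


def _unit_means(table: AbundanceTable, meta: pd.DataFrame, taxa: Sequence[str]) -> pd.DataFrame:
    """Mean relative abundance per site-year unit (rows) and taxon (columns)."""
    sub = meta.loc[meta.index.intersection(table.samples)]
    units = sub["site"].astype(str) + "|" + sub["year"].astype(str)
    frame = table.data.reindex(list(taxa)).fillna(0.0)
    frame = frame.loc[:, sub.index]
    return frame.T.groupby(units).mean()


def env_gut_correlation(
    gut: AbundanceTable,
    water: AbundanceTable,
    meta: pd.DataFrame,
    taxa: Sequence[str],
    r2_min: float = 0.6,
    slope_min: float = 0.1,
    min_env_mean: float = 1e-4,
) -> pd.DataFrame:
    """Per-taxon least squares of gut group mean on water group mean.

    Both groups are aggregated to site-year unit means; only units present
    in both tables form regression points. Taxa whose mean water abundance
    is below ``min_env_mean`` cannot plausibly originate from the water
    column and are excluded from the correlated flag. Fewer than three
    shared units flags every record insufficient.
    """
    gut_means = _unit_means(gut, meta, taxa)
    water_means = _unit_means(water, meta, taxa)
    shared = gut_means.index.intersection(water_means.index)
    n_units = len(shared)
    out = pd.DataFrame(index=pd.Index(list(taxa), name="taxon"))
    if n_units < 3:
        out["env_gut_slope"] = np.nan
        out["env_gut_r2"] = np.nan
        out["n_units"] = n_units
        out["water_mean"] = np.nan
        out["correlated"] = False
        out["positive"] = False
        out["insufficient"] = True
        return out

    X = water_means.loc[shared, list(taxa)].to_numpy()  # units x taxa
    Y = gut_means.loc[shared, list(taxa)].to_numpy()
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    xc = X - x_mean
    yc = Y - y_mean
    var_x = (xc**2).sum(axis=0)
    var_y = (yc**2).sum(axis=0)
    cov = (xc * yc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(var_x > 0, cov / np.where(var_x > 0, var_x, 1.0), np.nan)
        r2 = np.where(
            (var_x > 0) & (var_y > 0),
            cov**2 / np.where(var_x * var_y > 0, var_x * var_y, 1.0),
            0.0,
        )
    out["env_gut_slope"] = slope
    out["env_gut_r2"] = r2
    out["n_units"] = n_units
    out["water_mean"] = x_mean
    detectable = x_mean >= min_env_mean
    out["correlated"] = detectable & (r2 > r2_min)
    out["positive"] = detectable & (slope > slope_min)
    out["insufficient"] = False
    return out


# ---------------------------------------------------------------------------
# Stage 3: Kruskal-Wallis + LDA effect size per ecotype
# ---------------------------------------------------------------------------


def lefse_lda_scores(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_boot: int = 30,
    subsample: float = 2 / 3,
) -> np.ndarray:
    """LEfSe-style LDA effect sizes for two classes.

    ``X`` is samples x features on the 10^6 scale, ``y`` binary. Each
    bootstrap round fits a linear discriminant on a 2/3 subsample of each
    class; a feature's effect is the average of its class-mean difference
    and its contribution to the class separation along the discriminant
    axis, and the score is log10(1 + |effect|). The median over rounds is
    returned. Scores of ~2-5 correspond to abundance shifts of roughly
    0.01%-10% of a community.
    """
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if idx0.size < 2 or idx1.size < 2:
        return np.full(X.shape[1], np.nan)
    scores = np.zeros((n_boot, X.shape[1]))
    for b in range(n_boot):
        take0 = rng.choice(idx0, size=max(2, int(np.ceil(subsample * idx0.size))), replace=False)
        take1 = rng.choice(idx1, size=max(2, int(np.ceil(subsample * idx1.size))), replace=False)
        rows = np.concatenate([take0, take1])
        Xb = X[rows].astype(float)
        # tiny relative jitter keeps the within-class scatter nonsingular
        Xb = Xb + rng.normal(0.0, np.maximum(np.abs(Xb) * 1e-4, 1e-7))
        yb = y[rows]
        delta = Xb[yb == 1].mean(axis=0) - Xb[yb == 0].mean(axis=0)
        try:
            lda = LinearDiscriminantAnalysis(solver="svd", store_covariance=False)
            lda.fit(Xb, yb)
            w = lda.scalings_[:, 0]
            norm = np.linalg.norm(w)
            w = w / norm if norm > 0 else w
            proj_gap = float((Xb[yb == 1] @ w).mean() - (Xb[yb == 0] @ w).mean())
            effect = 0.5 * (np.abs(w * proj_gap) + np.abs(delta))
        except Exception:  # singular fit: fall back to the mean difference
            effect = np.abs(delta)
        scores[b] = np.log10(1.0 + np.abs(effect))
    return np.median(scores, axis=0)


def kw_lda_differential(
    table: AbundanceTable,
    labels: pd.Series,
    meta: pd.DataFrame,
    ecotype: str,
    taxa: Sequence[str] | None = None,
    alpha: float = 0.05,
    lda_min: float = 3.0,
    n_boot: int = 30,
    seed: int = 0,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Healthy-vs-unhealthy differential abundance within one ecotype.

    Per taxon: a Kruskal-Wallis (rank-sum) p-value on relative abundance, a
    LEfSe-style LDA score computed on abundances scaled to a 10^6 total for
    the taxa passing the p threshold, and the direction of the group-mean
    difference. ``differential`` requires p < alpha, LDA >= lda_min and is
    reported alongside the direction. An ecotype with a single group leaves
    every taxon untestable (all-NaN).
    """
    if taxa is None:
        taxa = table.taxa
    gut_meta = meta.loc[meta.index.intersection(table.samples)]
    members = gut_meta.index[gut_meta["ecotype"] == ecotype]
    members = members.intersection(labels.index)
    status = labels.loc[members]
    healthy = members[status == "healthy"]
    unhealthy = members[status == "unhealthy"]

    out = pd.DataFrame(index=pd.Index(list(taxa), name="taxon"))
    out["kw_p"] = np.nan
    out["lda_score"] = np.nan
    out["direction"] = "none"
    out["differential"] = False
    if len(healthy) == 0 or len(unhealthy) == 0:
        logger.warning(
            "ecotype %s lacks a healthy or unhealthy group; taxa untestable", ecotype
        )
        out["untestable"] = True
        return out
    out["untestable"] = False

    data = table.data.reindex(list(taxa)).fillna(0.0)
    H = data.loc[:, healthy].to_numpy()
    U = data.loc[:, unhealthy].to_numpy()
    pvals = np.empty(len(taxa))
    for i in range(len(taxa)):
        pvals[i] = rank_sum_test(H[i], U[i]).p_value
    if bh_correction:
        from scipy.stats import false_discovery_control

        pvals = false_discovery_control(pvals)
    out["kw_p"] = pvals
    mean_h = H.mean(axis=1)
    mean_u = U.mean(axis=1)
    out["direction"] = np.where(
        mean_u > mean_h, "up-in-unhealthy", np.where(mean_h > mean_u, "up-in-healthy", "none")
    )

    passing = np.flatnonzero(pvals < alpha)
    if passing.size:
        X = np.vstack([H.T, U.T])[:, passing] * LDA_SCALE
        y = np.concatenate([np.zeros(H.shape[1], dtype=int), np.ones(U.shape[1], dtype=int)])
        rng = np.random.default_rng(seed)
        lda = lefse_lda_scores(X, y, rng, n_boot=n_boot)
        scores = np.full(len(taxa), np.nan)
        scores[passing] = lda
        out["lda_score"] = scores
    out["differential"] = (
        (out["kw_p"] < alpha) & (out["lda_score"] >= lda_min)
    ).fillna(False)
    return out


# ---------------------------------------------------------------------------
# Stage 4: the cascade
# ---------------------------------------------------------------------------


@dataclass
class KeyTaxaReport:
    """Per-taxon screen records, thresholds used and per-stage survivors."""

    records: pd.DataFrame
    thresholds: dict
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def key_taxa(self) -> list[str]:
        return sorted(self.records.index[self.records["key"]])


def key_taxa_cascade(
    records: pd.DataFrame,
    ecotypes_tested: Sequence[str],
    k_required: int = 3,
    thresholds: dict | None = None,
) -> KeyTaxaReport:
    """Combine screen stages into the final key-taxon set.

    ``records`` must carry ``phenotype_linked``, ``correlated``,
    ``positive`` and per-ecotype ``differential_<e>`` / ``direction_<e>``
    columns. A taxon is key when it is phenotype-linked, correlated,
    positive, and differential with direction up-in-unhealthy in at least
    ``k_required`` of the tested ecotypes.
    """
    records = records.copy()
    if len(records) == 0:
        empty = pd.DataFrame(
            columns=["phenotype_linked", "correlated", "positive", "n_ecotypes_up", "differential", "key"]
        )
        return KeyTaxaReport(
            empty,
            thresholds or {},
            {
                "phenotype_linked": 0,
                "correlated": 0,
                "positive": 0,
                "differential": 0,
                "key": 0,
            },
        )
    up = np.zeros(len(records), dtype=int)
    for eco in ecotypes_tested:
        diff = records.get(f"differential_{eco}")
        direction = records.get(f"direction_{eco}")
        if diff is None or direction is None:
            continue
        up += (
            diff.fillna(False).to_numpy(dtype=bool)
            & (direction == "up-in-unhealthy").to_numpy()
        )
    records["n_ecotypes_up"] = up
    linked = records["phenotype_linked"].to_numpy(dtype=bool)
    correlated = linked & records["correlated"].to_numpy(dtype=bool)
    positive = correlated & records["positive"].to_numpy(dtype=bool)
    differential = positive & (up >= k_required)
    records["differential"] = differential
    records["key"] = differential
    counts = {
        "phenotype_linked": int(linked.sum()),
        "correlated": int(correlated.sum()),
        "positive": int(positive.sum()),
        "differential": int(differential.sum()),
        "key": int(records["key"].sum()),
    }
    logger.info("key-taxa cascade survivors: %s", counts)
    return KeyTaxaReport(records, thresholds or {}, counts)


def screen_key_taxa(
    gut: AbundanceTable,
    water: AbundanceTable,
    pmap: PhenotypeMap,
    labels: pd.Series,
    meta: pd.DataFrame,
    config: RunConfig | None = None,
) -> KeyTaxaReport:
    """Run the full cascade on one dataset and return the report."""
    config = config or RunConfig()
    linked = phenotype_linked_taxa([gut, water], pmap)
    if not linked:
        return key_taxa_cascade(pd.DataFrame(), [], config.key_ecotypes_required)

    records = env_gut_correlation(
        gut,
        water,
        meta,
        linked,
        r2_min=config.r2_min,
        slope_min=config.slope_min,
        min_env_mean=config.min_env_mean,
    )
    records.insert(0, "phenotype_linked", True)

    gut_meta = meta.loc[meta.index.intersection(gut.samples)]
    ecotypes = [
        e
        for e in sorted(gut_meta["ecotype"].unique())
        if e and e not in config.key_exclude_ecotypes
    ]
    for eco in ecotypes:
        diff = kw_lda_differential(
            gut,
            labels,
            meta,
            eco,
            taxa=linked,
            alpha=config.alpha,
            lda_min=config.lda_min,
            n_boot=config.lda_bootstrap,
            seed=config.seed,
            bh_correction=config.bh_correction,
        )
        records[f"kw_p_{eco}"] = diff["kw_p"]
        records[f"lda_{eco}"] = diff["lda_score"]
        records[f"direction_{eco}"] = diff["direction"]
        records[f"differential_{eco}"] = diff["differential"]

    thresholds = {
        "r2_min": config.r2_min,
        "slope_min": config.slope_min,
        "lda_min": config.lda_min,
        "alpha": config.alpha,
        "k_required": config.key_ecotypes_required,
        "ecotypes_tested": ecotypes,
    }
    return key_taxa_cascade(
        records, ecotypes, config.key_ecotypes_required, thresholds
    )
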