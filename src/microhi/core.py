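"""Microbiota health index (microHI) and Fulton's condition factor.

The microHI of a sample is the mean of the complements of three
health-negative phenotype abundance ratios:

    microHI = ((1 - Pm) + (1 - Po) + (1 - Pp)) / 3

where Pm, Po and Pp are the relative-abundance fractions of taxa that carry
mobile elements, tolerate oxidative stress, and are potentially pathogenic.
A sample composed entirely of phenotype-free taxa scores 1; a sample
saturated with all three phenotypes scores 0.

Taxa absent from the phenotype annotation map are treated as unclassified
and excluded, with the ratios renormalised over the covered abundance; the
covered fraction is always reported so the information loss stays visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import AbundanceTable, PhenotypeMap, ValidationError

logger = logging.getLogger("microhi")

#: phenotype-map column -> ratio symbol
_RATIO_OF_COLUMN = {"mobile": "Pm", "stress": "Po", "pathogenic": "Pp"}

LOW_COVERAGE_WARNING = 0.5


@dataclass
class MicroHIRecord:
    """Per-sample phenotype ratios and health index."""

    sample_id: str
    Pm: float
    Po: float
    Pp: float
    microHI: float
    classified_fraction: float


def compute_phenotype_ratios(
    table: AbundanceTable, pmap: PhenotypeMap, renormalize: bool = True
) -> pd.DataFrame:
    """Abundance-weighted phenotype ratios per sample.

    For each sample the ratio for a phenotype is the sum over mapped taxa of
    relative abundance times the taxon's phenotype weight. With
    ``renormalize`` (the default) the ratios are divided by the abundance
    covered by the map, mirroring the exclusion of unclassified sequences;
    without it they are left on the full-sample scale.

    Returns a frame indexed by sample with columns ``Pm``, ``Po``, ``Pp``
    and ``classified_fraction``.
    """
    weights = pmap.weights.reindex(table.taxa)
    covered_mask = ~weights["pathogenic"].isna().to_numpy()
    weights = weights.fillna(0.0)

    abundance = table.values  # taxa x samples
    covered = abundance[covered_mask, :].sum(axis=0)
    zero = covered <= 0
    if zero.any():
        names = [table.samples[i] for i in np.flatnonzero(zero)]
        raise ValidationError(
            f"samples with zero abundance covered by the phenotype map: {names}"
        )

    out = pd.DataFrame(index=pd.Index(table.samples, name="sample_id"))
    denom = covered if renormalize else np.ones_like(covered)
    for column, symbol in _RATIO_OF_COLUMN.items():
        numer = weights[column].to_numpy() @ abundance
        out[symbol] = numer / denom
    out = out[["Pm", "Po", "Pp"]]
    out["classified_fraction"] = covered

    low = int((covered < LOW_COVERAGE_WARNING).sum())
    if low:
        logger.warning(
            "%d sample(s) have less than %.0f%% of abundance covered by the "
            "phenotype map; their ratios rest on a minority of the community",
            low,
            100 * LOW_COVERAGE_WARNING,
        )
    return out


def compute_microhi(Pm, Po, Pp):
    """Health index from the three phenotype ratios (scalar or array).

    Raises a domain error for inputs outside [0, 1].
    """
    Pm, Po, Pp = (np.asarray(p, dtype=float) for p in (Pm, Po, Pp))
    for name, arr in (("Pm", Pm), ("Po", Po), ("Pp", Pp)):
        if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
            raise ValidationError(f"{name} must lie in [0, 1]")
    result = ((1.0 - Pm) + (1.0 - Po) + (1.0 - Pp)) / 3.0
    if result.ndim == 0:
        return float(result)
    return result


def score_samples(
    table: AbundanceTable, pmap: PhenotypeMap, renormalize: bool = True
) -> pd.DataFrame:
    """Phenotype ratios plus microHI for every sample in the table."""
    ratios = compute_phenotype_ratios(table, pmap, renormalize=renormalize)
    ratios["microHI"] = compute_microhi(
        ratios["Pm"].to_numpy(), ratios["Po"].to_numpy(), ratios["Pp"].to_numpy()
    )
    return ratios[["Pm", "Po", "Pp", "microHI", "classified_fraction"]]


def fulton_condition(weight_g, length_cm):
    """Fulton's condition factor K = m / L^3 * 100 (weight in g, length in cm).

    Under these units K is near 1 for a fusiform fish in good condition.
    """
    m = np.asarray(weight_g, dtype=float)
    L = np.asarray(length_cm, dtype=float)
    if (m <= 0).any() or (L <= 0).any() or np.isnan(m).any() or np.isnan(L).any():
        raise ValidationError("weight and length must be positive")
    K = m / L**3 * 100.0
    if K.ndim == 0:
        return float(K)
    return K
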