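# microhi

A tested, reusable pipeline for assessing the health of wild aquatic
animals from microbiome data. It is built for metagenomics practitioners
who have 16S relative-abundance tables for host gut samples and water
environmental (eDNA) samples, plus a taxon-level phenotype annotation, and
who want a non-invasive, community-to-ecotype-level readout of host health.

## The index

The microbiota health index of a sample is the mean complement of three
health-negative phenotype abundance ratios:

```
microHI = ((1 − Pm) + (1 − Po) + (1 − Pp)) / 3
```

where `Pm`, `Po`, `Pp` are the relative-abundance fractions of taxa that
contain mobile elements, tolerate oxidative stress, and are potentially
pathogenic. Phenotype membership comes from a user-supplied taxon → weight
map (BugBase-style annotations; binary or fractional weights in [0, 1]).
Taxa absent from the map are treated as unclassified and excluded, with
ratios renormalised over the covered abundance.

Around the index, the pipeline provides:

* **Dysbiosis detection** — gut samples are clustered by Bray–Curtis
  dissimilarity with average linkage at the species, genus and family
  levels; samples falling outside their species' "normal branch" (the
  coherent conspecific clade, operationalised as the subtree maximising
  net conspecific support × persistence) are labelled disordered, with a
  majority consensus across levels. Host condition (Fulton's
  `K = m / L³ × 100`) provides an independent growth-status check.
* **Effectiveness analysis** — healthy/unhealthy comparisons of gut
  microHI and Fulton's K at community, species and ecotype levels
  (two-sided rank-sum tests), species-specific healthy baselines,
  community-structure-weighted aggregation, and OLS regression of gut
  microHI on water environmental microHI over site-year units.
* **Key-taxon screen** — a cascade that intersects phenotype-linked taxa
  with an environment–gut abundance correlation screen (r² > 0.6, slope
  > 0.1) and Kruskal–Wallis + LDA-effect-size differential abundance
  between healthy and unhealthy hosts per ecotype (p < 0.05, LDA ≥ 3).
* **Synthetic cohorts** — a generator that emulates the statistical
  structure of a wild-fish survey (species-specific baselines, a ~30%
  dysbiotic subpopulation, site-year water quality, ecotype-specific
  environment→gut coupling, spiked water-borne health-negative taxa) with
  full ground truth, so every stage is testable end to end.

## Worked example

```python
import pandas as pd
import microhi as mh

cohort = mh.simulate_dataset(mh.default_params(), seed=1)
meta = mh.metadata_frame(cohort.metadata)

scores = mh.score_samples(cohort.gut, cohort.phenotypes)
print(scores.head(3).round(3))
```

```
              Pm     Po     Pp  microHI  classified_fraction
sample_id
g0000      0.358  0.405  0.309    0.643                  1.0
g0001      0.514  0.550  0.549    0.462                  1.0
g0002      0.358  0.340  0.339    0.654                  1.0
```

Each row is one gut sample: its three phenotype ratios, the resulting
health index, and the abundance fraction the annotation map covered.
Classify the cohort and compare the groups:

```python
genus, family = mh.taxonomy_maps(cohort.gut.taxa)
tables = {"species": cohort.gut,
          "genus": mh.collapse_taxa(cohort.gut, genus, "genus"),
          "family": mh.collapse_taxa(cohort.gut, family, "family")}
labels = mh.classify_multilevel(tables, meta)["consensus"]
print((labels == "unhealthy").sum(), "of", len(labels), "disordered")

print(mh.compare_groups(scores["microHI"], labels, meta).round(3))
```

```
53 of 200 disordered
     unit  n_healthy  n_unhealthy  mean_healthy  mean_unhealthy  delta  test_p significance
community        147           53          0.71           0.577  0.133     0.0           **
```

The dendrogram-based labels recover a disordered subpopulation of about a
quarter of the cohort, whose mean gut microHI (0.58) sits well below the
healthy mean (0.71) — the gap the generator was configured with. On a
larger survey-shaped cohort, regressing community- and ecotype-level gut
microHI on water environmental microHI shows the coupling pattern:

```python
big = mh.simulate_dataset(mh.screening_params(n_per_species=96), seed=1)
meta2 = mh.metadata_frame(big.metadata)
gut = mh.score_samples(big.gut, big.phenotypes)["microHI"]
water = mh.score_samples(big.water, big.phenotypes)["microHI"]
labels2 = pd.Series(big.truth.status)
print(mh.ecotype_regressions(gut, water, meta2, big.community,
                             labels=labels2)[["unit", "slope", "r2"]].round(3))
```

```
                   unit  slope    r2
              community  0.107 0.719
    ecotype:carnivorous  0.304 0.766
 ecotype:filter-feeding  0.016 0.014
     ecotype:omnivorous  0.054 0.210
ecotype:scraper-feeding  0.054 0.146
```

Only the carnivorous ecotype — the one the generator couples to the water
column — passes the slope > 0.1, r² > 0.6 screen; the community-level
correlation is positive throughout. The key-taxon cascade on the same
cohort narrows ~98 phenotype-linked taxa down to exactly the three spiked
water-borne taxa (`cascade: 98 → 16 → 3 → 3 → 3`).

A command-line interface mirrors these stages (`microhi simulate | score |
classify | analyze | key-taxa`, each with `--config`, `--seed`, `--out`);
every invocation writes a deterministic run manifest, and identical
config + seed reproduces byte-identical outputs.

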