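# Methods

## The health index

The microbiota health index of a sample is
`microHI = ((1 − Pm) + (1 − Po) + (1 − Pp)) / 3`, where `Pm`, `Po`, `Pp`
are abundance-weighted sums over a taxon → phenotype weight map (mobile
elements, oxidative-stress tolerance, potential pathogenicity; weights in
[0, 1], binary maps being a special case). The index is linear in
composition, which the whole package leans on: any target index can be
realised as a mixture of phenotype-free and phenotype-carrying profiles,
and mixing two communities mixes their indices with the same weights.

Taxa absent from the annotation map are treated as unclassified and
dropped, with the ratios renormalised over the covered abundance. The
covered fraction is reported for every sample and a warning is logged when
it falls below 50%, so the information loss is never silent. The
renormalisation can be switched off (`renormalize_ratios` in `RunConfig`),
in which case the ratios stay on the full-sample scale; the default
renormalises, because an index meant to be compared across samples should
not be diluted by how much of each sample the annotation happened to
cover.

Fulton's condition factor `K = m / L³ × 100` uses grams and centimetres —
the convention under which K is near 1 for a fusiform fish — and serves as
an independent growth-status covariate, not as part of the index.

## Dysbiosis detection

Gut samples are clustered by Bray–Curtis dissimilarity
(`Σ|a−b| / Σ(a+b)`) with average linkage. The UPGMA implementation is
hand-rolled (the problem sizes are a few hundred leaves) so that ties
break deterministically toward the lexicographically smallest cluster
pair; it is verified in the tests against a naive recompute-from-scratch
agglomeration and against an established library implementation.

Labelling rests on one anchor assumption: most individuals of a species
carry a normal gut microbiota, so conspecifics concentrate in a coherent
"normal branch" of the dendrogram and samples outside it are disordered.
The default operationalisation (`strategy = "branch"`) selects, for each
species with at least `min_conspecifics` (3) samples, the subtree with at
least that many conspecifics and conspecific purity ≥ `purity_min` (0.6)
that maximises *net support × persistence*:

* net support = conspecifics − intruders, so a branch only grows while it
  gains more conspecifics than strangers and a tight pure cluster cannot
  be beaten by a diluted ancestor;
* persistence = parent merge height − own merge height, i.e. how long the
  subtree survives before being absorbed. A genuine conspecific branch is
  strongly separated from the rest of the forest and persists long,
  whereas subclades inside a mixed disordered region are absorbed almost
  immediately. The product keeps the call anchored on the coherent
  conspecific clade even when, by sampling accident, disordered
  conspecifics outnumber normal ones in a cohort.

A flat-cut variant (`strategy = "cut"`) is retained for comparison: cut at
the `cut_q`-th percentile (75) of merge heights and take the plurality
cluster. It is not the default because most merges in a dendrogram are
within-cluster, so a fixed percentile tends to land inside coherent
groups and split them; the subtree rule needs no cut height at all.

Species with fewer than `min_conspecifics` samples cannot anchor a branch
and are judged against ecotype-similar neighbours: such a sample is
healthy when its nearest ancestor branch with at least `min_conspecifics`
members is dominated (≥ `purity_min`) by gut samples of its own ecotype.

Classification runs at the species, genus and family levels and the final
label is the majority vote; a tie (possible only with an even number of
levels) resolves to healthy, following the anchor assumption. Everything
in this module is deterministic — identical inputs replay to identical
labels.

## Effectiveness analysis

Healthy/unhealthy comparisons of per-sample quantities (gut microHI,
Fulton's K) are run at the community, species and ecotype levels with a
two-sided Mann–Whitney/Wilcoxon rank-sum test — the two-group
specialisation of the Kruskal–Wallis test. The null distribution is
enumerated exactly (tie-safe) whenever the pooled sample has ≤ 16
observations, and uses the tie-corrected normal approximation otherwise.
Stars follow the usual convention (`*` p < 0.05, `**` p < 0.01). No
multiple-testing correction is applied across species by default, matching
raw-star reporting; a Benjamini–Hochberg switch exists in `RunConfig`.

Species baselines are means of the gut index over healthy conspecifics
only. Community and ecotype values are weighted averages of species means,
the weight being each species' share of individuals in the fish community
census; ecotype weights renormalise within the ecotype.

Environment→gut coupling is quantified by OLS of gut microHI on water
environmental microHI, one point per site-year unit: the env value is the
unit's mean water-sample index, the gut value the community-weighted
average of per-species means within the unit (healthy samples only by
default, since baselines are the quantity being coupled). Fewer than three
points flags the fit underdetermined; zero env variance flags it
degenerate. The site-year unit is a configuration choice — nothing in the
method depends on it beyond there being enough units to regress over.

## Key-taxon screen

The cascade conjoins four conditions, so survivor counts are monotone by
construction:

1. *phenotype-linked*: any phenotype weight > 0 and nonzero abundance;
2. *correlated*: per-taxon OLS of gut group mean on water group mean over
   site-year units with r² > 0.6;
3. *positive*: slope > 0.1;
4. *differential*: Kruskal–Wallis p < 0.05 **and** LDA effect size ≥ 3
   with direction up-in-unhealthy in ≥ 3 ecotypes (the omnivorous ecotype
   is excluded from the count by default, configurable).

Taxa whose mean water abundance falls below `min_env_mean` (1e-4) are
excluded from the correlated flag: a taxon effectively absent from the
water column cannot plausibly originate there, and regressing on its
near-zero water variance would produce numerically meaningless slopes.

The LDA effect size follows the LEfSe recipe: abundances scaled to a
10⁶ total, 30 bootstrap rounds over 2/3 class subsamples, a linear
discriminant fitted per round (with a tiny relative jitter to keep the
within-class scatter nonsingular), a per-feature effect equal to the mean
of its class-mean difference and its contribution to the class separation
along the discriminant axis, score = log10(1 + |effect|), and the median
over rounds. On this scale a score of 3 corresponds to an absolute
abundance shift of roughly 0.1% of a community, which is what makes the
≥ 3 threshold meaningful. The factorial/subclass machinery of the original
recipe is not reproduced: the design here is one factor (health status)
within each ecotype.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with full ground truth. All compositions are Dirichlet draws around
constructed base vectors (concentration 50, moderate overdispersion — a
standard compositional noise model). Because the index is linear in
composition, every base vector is solved exactly for its target index as a
mixture of a phenotype-free profile and a phenotype-carrying profile;
targets the annotation map cannot express raise a parameter error.

Default study conditions (chosen once, anchored to the survey this
emulates):

* 150 taxa, 100 of them phenotype-linked, 3 designated "spiked"
  health-negative taxa; a generated three-level taxonomy (species →
  genus → family) for the multi-level classifier;
* eight species, two per ecotype, healthy baselines paired around a mean
  of 0.71; 25 gut samples each (200 total) in the default cohort;
* dysbiosis prevalence 0.30 (per-sample Bernoulli), index depression 0.13
  (0.71 healthy vs 0.58 unhealthy); a dysbiotic sample mixes 30% of its
  healthy base with 70% of a dysbiosis profile, so the composition is
  displaced *and* the index depressed — the classifier and the score are
  distinct readouts;
* water per site-year unit targets spanning 0.60–0.90 (the two survey
  presets pin 0.71 and 0.83); spiked-taxon water shares drawn per unit
  from U(0.001, 0.045);
* coupling: a gut sample mixes its species core with the local water base
  at rate `background (0.02) + 0.5 × β(ecotype)`, β defaulting to 0.5 for
  carnivorous fish and 0 elsewhere. Coupling therefore acts on
  composition and the index coupling *emerges* (linearity gives an
  expected ecotype regression slope equal to the mixing rate, ≈ 0.27 for
  carnivorous). The efficiency factor of 0.5 encodes that even a strongly
  coupled gut remains dominated by host-selected flora; without it,
  water-driven variation overwhelms species identity at coarse taxonomic
  levels and conspecifics fragment by site-year, which no field survey of
  gut communities shows;
* dysbiotic guts acquire the spiked taxa in proportion to their local
  water abundance (gain 4), which is what makes them recoverable by the
  correlation screen; the rest of the dysbiosis profile is a shared
  phenotype-carrying filler plus a reserved phenotype-free "companion"
  flora;
* Fulton's K: healthy condition factor per species with 3% CV, depressed
  4% in dysbiotic fish — a real but small growth-status difference;
* `emulate_study_shape` presets reproduce the survey's sampling shape:
  14 species in four ecotypes, 214 gut samples, 30 water samples at env
  microHI 0.71 (one-year preset) plus a 13-sample 0.83 year (two-year
  preset).

What the generator does **not** emulate: sequencing noise and read-depth
variation, taxonomic misassignment, phylogenetic correlation among taxa,
seasonal/within-site structure, and any ecological interaction beyond the
linear mixing above. Passing recovery tests therefore demonstrates that
the pipeline's inference machinery is correct under its own assumptions,
not that those assumptions hold for any particular real survey.

## Experiment sizing

Screening stages operate on site-year group means, so their recovery
experiments are sized for stable unit means rather than for raw sample
counts: `screening_params` uses twelve site-year units, thirty water
samples per unit (the water sampling depth of the surveys emulated) and
96 (ecotype-regression) or 225 (key-taxon cascade) gut samples per
species. The numbers come from a variance budget: unit means over few
samples attenuate regressions toward zero (noise in the water means acts
as errors-in-variables; binomial prevalence noise and Dirichlet
overdispersion inflate the gut means), and these sizes keep the
attenuated r² comfortably above the 0.6 screen for truly coupled taxa
while leaving uncoupled taxa far below it. The classifier and group-mean
checks use the default 200-sample cohort.

## Numerical choices and degenerate inputs

* Normalisation tolerance 1e-9 on column sums; symmetric-matrix tolerance
  1e-12; all-zero sample columns are rejected by name.
* Deterministic tie-breaks everywhere: lexicographic merge order in the
  linkage, smallest-id branch/cluster selection, sorted species and unit
  iteration. Identical config + seed reproduces byte-identical outputs,
  including from the CLI (run manifests contain checksums, never
  wall-clock time).
* Rank tests on constant pooled data return p = 1 (every split is equally
  extreme). Regressions with fewer than three points or zero predictor
  variance are flagged rather than fitted. Single-group ecotypes leave
  all taxa untestable rather than silently dropping the stage.
* Dirichlet parameters get a 1e-6 floor so zero-mass taxa stay drawable;
  the induced bias (~1e-4 relative) is far below every tolerance used.

## Known limitations

* The branch rule assumes disordered samples are *displaced* — a dysbiosis
  that shifts the index without moving the composition away from the
  conspecific clade is invisible to it (and to any clustering-based
  detector).
* When a species is genuinely majority-disordered and its disordered
  samples form their own long-lived clade, the persistence heuristic can
  no longer identify the normal branch from topology alone.
* The LDA effect size reproduces the published recipe's scale and
  threshold behaviour but not its factorial subclass handling.
* With a single site-year unit (the one-year survey preset) the
  regression stages are structurally underdetermined and are flagged as
  such rather than computed.
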