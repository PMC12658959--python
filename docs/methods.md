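# Methods

`depthfd` implements a depth-gradient analysis of demersal fish communities:
from per-individual stereo-video transect observations to taxonomic
diversity, permutational composition tests, a categorical life-history trait
space, functional-entity redundancy metrics, distance-based functional
diversity, and the FUSE conservation-priority index. Because real expedition
data of this kind are rarely published in full, the package ships a
first-class synthetic survey generator that emulates the statistical
structure such surveys exhibit; every downstream stage is exercised and
tested against it.

## Survey processing

Observations are rows of `(transect_id, taxon, id_level, length_cm)`.
Processing follows the field protocol for stereo-video belt transects:

- **Length correction.** Stereo-camera miscalibration biases lengths
  multiplicatively. For an underestimation fraction *u* the corrector is
  1/(1 − u), reported at two decimals (u = 0.46 → ×1.85) and applied only to
  calibration-flagged transects.
- **Missing lengths** are filled by the mean of measured conspecifics on the
  same transect. When no conspecific was measured there, the species mean
  within the same atoll is used (logged); an individual with no measured
  conspecific anywhere stays in abundance but contributes nothing to biomass
  (logged). The fallback chain past the same-transect rule is this package's
  choice, made to avoid silent data loss.
- **Biomass** uses W = a·L^b (L in cm, W in g) with species-specific
  constants. Taxa resolved only to genus/order inherit the constants of the
  most abundant resolved member of their group in the same transect, then in
  the same *location* — interpreted here as atoll × depth band — then
  study-wide. Ties break by study-wide abundance, then lexicographic label:
  an arbitrary but reproducible rule.
- **Densities** are standardized per 100 m² of transect area
  (length × width; 250 × 5 m by default, shorter transects supported).
  Unresolved taxa keep their own matrix columns: they count toward
  abundance/biomass totals but never toward richness or composition.
- **Species complexes** that cannot be separated on video are collapsed
  under a group label before analysis; the operation is idempotent and
  rejects ambiguous double memberships.

## Taxonomic diversity and composition

Per-transect richness (species-level columns only) and densities are
compared across depth bands — a fixed categorical factor — with a
Kruskal–Wallis test (midranks, tie correction, χ² approximation) and
pairwise two-sided Mann–Whitney tests, exact by enumeration when both
groups have ≤ 8 observations without ties, otherwise normal-approximated
with tie and continuity corrections. Families of pairwise p-values are
adjusted by Benjamini–Hochberg.

Composition uses Bray–Curtis dissimilarity on square-root-transformed
abundances (two all-zero transects get distance 0, logged), PCoA by Gower
double-centering (negative eigenvalues are dropped from coordinates and
their magnitude reported), one-way PERMANOVA (pseudo-F from total and
within-group sums of squared distances; with a single factor, type-III
partial sums of squares reduce to this form), and PERMDISP. PERMDISP embeds
the distance matrix with real and imaginary PCoA axes and uses the
Anderson-corrected distance to the group centroid
(√max(0, d²_real − d²_imag)); the permutation scheme permutes group labels
of those centroid distances. Published implementations instead permute
least-squares residuals; on balanced designs the two agree closely, but
this is a documented deviation risk. Permutation p-values always use
(b + 1)/(m + 1) and are reproducible bit-for-bit given a seed; 9999
permutations is the default.

## Trait space

Eight categorical traits encode life-history strategy: age at first
maturity, generation time, maximum length, minimum population doubling time
(resilience proxy), fishing vulnerability, water-column position, preferred
temperature range, and vertical home range. Continuous-to-categorical bin
thresholds (e.g. maximum length at 15/30/50/80/150 cm) are configuration
with documented defaults; all analyses are bin-agnostic.

- **Correlation pruning.** Ordered traits are screened pairwise with
  Kendall's τ-b on rank encodings (pairwise-complete species); while any
  |τ| > 0.8, the member with more missing cells is dropped (tie: the later
  trait in the declared order). Unordered traits are exempt — τ is
  undefined on unordered modalities. Pruning runs before imputation so the
  missingness tie-break uses the raw table and discarded columns are never
  imputed.
- **Imputation** is a missForest-style iteration: initialize missing cells
  at column modes, revisit columns in order of increasing missingness, fit
  a 100-tree random-forest classifier of each column on one-hot encodings
  of all others, re-predict its missing cells, and stop when the proportion
  of changed imputations rises, returning the previous iterate. Out-of-bag
  misclassification gives the PFC error estimate; NRMSE is 0 for
  all-categorical tables. IUCN categories DD and NE are treated as missing
  and imputed alongside the traits, with genus available as a
  predictor-only column (taxonomic signal).
- **Gower distance** over the pruned, imputed table: unordered traits
  contribute 0/1, ordered traits |rank_i − rank_j|/(k − 1) with evenly
  spaced ranks (Podani-style ordinal handling — the choice is ours), and
  the distance is the unweighted mean contribution.
- **Embedding.** PCoA of the Gower matrix; the working trait space uses the
  first 4 positive axes by default. Embedding quality per dimensionality is
  the mAD index: mean absolute deviation between Gower distances and
  embedded Euclidean distances rescaled to share the same maximum; the best
  dimensionality is the argmin, ties to the smaller m.

## Functional metrics

- **Functional entities (FEs)** are unique post-pruning trait combinations.
  For S species across K FEs of sizes n_k: redundancy FRed = S/K,
  vulnerability FVul = 100·|{n_k = 1}|/K, over-redundancy
  FOR = 100·Σ max(0, n_k − FRed)/S. FOR uses the species-in-excess
  convention; the total-membership variant is a one-line change and the
  excess form matches the metric's methodological lineage.
- **FRic** is the convex-hull volume of the community in the m-axis space,
  standardized by the pool hull volume. It requires more species than axes;
  transects with fewer than 5 species are excluded from FRic/FDis/FEve (the
  alpha filter), and degenerate point sets are reported as undefined, never
  silently zero.
- **FDis** is the abundance-weighted mean distance to the abundance-weighted
  community centroid.
- **FEve** is the Villéger evenness along the community's minimum spanning
  tree (Prim with lexicographic tie-breaks, so the tree is unique):
  branch weights length/(w_i + w_j), partial weights capped at 1/(S − 1).
- **FSpe** is each species' distance to the unweighted pool centroid,
  scaled so the pool maximum is 1; community FSpe is the abundance-weighted
  mean over members. The pool is every species observed across the study.
- **FUn** is the mean distance to the k = 5 nearest pool neighbours, scaled
  so the pool maximum is 1 (k is configurable; 5 is the metric family's
  default).
- **FUSE** combines the scaled indices with the IUCN threat rank GE
  (LC = 0, NT = 1, VU = 2, EN = 3, CR = 4):

      FUSE = ln(1 + FUn·GE) + ln(1 + FSpe·GE)

  so least-concern species score 0 and the index is nondecreasing in every
  argument. The ranking table annotates each species with commercial value,
  habitat class from its shallowest band of occurrence (< 30 m shallow,
  30–150 m mesophotic, > 150 m deep; the 30-m band is classified
  mesophotic), number of atolls of occurrence, and mean density per
  1250 m² (one 250 × 5 m transect) over occupied transects.

## The synthetic survey generator

The generator emulates the study conditions the analysis assumes, not any
particular reef:

- **Design:** 7 depth bands (2–5, 10, 30, 60, 120, 250, 500 m; the 2–5 m
  band is represented by the numeric value 4) × 5 atolls × 3 replicate
  transects of 250 × 5 m.
- **Species pool:** 300 species, each with a centre band and a vertical
  home range of 1–3 adjacent bands. Trait vectors come from per-band
  archetype libraries drawn from band-restricted modality windows: the
  window narrows with depth (habitat filtering), so deep specialists occupy
  fewer distinct trait combinations; archetype sharing within shallow bands
  creates trait redundancy. Generation time and doubling time track the
  age-at-maturity rank with occasional ±1 jitter, giving the correlation
  screen its target. IUCN threat probability rises with body size, and 15%
  of species are unevaluated (DD/NE). About 3% of species are resolvable
  only to genus, always sharing a genus with a resolvable species so
  surrogate constants exist.
- **Observations:** per transect, each band-affiliated species is present
  with probability set by the band's expected richness (peaking at 10 m,
  minimum at 250 m: 22/32/26/16/9/6/7 by band). Counts are
  negative-binomial (gamma–Poisson, dispersion 0.8) with band-specific
  means; lengths are log-normal around the species' typical length (σ =
  0.25 log units); 5% of lengths are missing; 40% of submersible (≥ 60 m)
  transects are calibration-flagged and store lengths × (1 − 0.46).
- **Seeding:** one base seed; each species, transect and stage derives an
  independent stream by hashing its identifier (CRC32 into a SeedSequence),
  so enlarging the design never changes existing draws and all outputs are
  byte-for-byte reproducible.

What the generator does *not* emulate: bathymetric or spatial structure,
atoll-level community differences, observation-distance detection bias, or
empirically calibrated abundance spreads — the per-band distributions are
pattern-calibrated to the qualitative depth profile only. Passing pattern
tests therefore shows the pipeline recovers structure a survey of this
shape contains; it says nothing about effect sizes in any real survey.

## Numerical choices and degenerate inputs

- Permutation p-values: (b + 1)/(m + 1), never exactly 0.
- All-equal data: Kruskal–Wallis returns H = 0, p = 1; an all-zero distance
  matrix gives PERMANOVA F = 0, p = 1.
- PCoA eigenvalues below 1e-9 × scale are treated as zero; negative axes
  are retained separately for PERMDISP's corrected distances.
- Convex-hull volumes use Qhull; affinely dependent communities are
  undefined (reported), and FEve is undefined below 3 species.
- Mann–Whitney switches from exact enumeration to the normal approximation
  at n > 8 per group or in the presence of ties.
- The imputer caps at 10 sweeps; convergence in practice takes 2–4.

## Problem sizes

Default analyses run on the 300-species, 105-transect synthetic survey.
The test suite runs the full pipeline at 199 permutations and the
imputation benchmark at 10 seeded repetitions of a 300 × 8 table; these
sizes keep the whole suite a few minutes long while leaving every
qualitative conclusion unchanged at 9999 permutations (the library
default).

## Known limitations

- PERMDISP's permutation scheme (label permutation of centroid distances)
  is simpler than the residual permutation of published implementations.
- The FOR gloss is ambiguous in the literature; both conventions are
  implemented but only the excess form is surfaced by the pipeline.
- Kendall τ p-values use the no-tie normal variance; with heavy ties the
  statistic is exact but the p-value is approximate (the pipeline uses the
  statistic, not the p-value, for metric correlations).
- The generator's trait–depth filtering is a modality-window model; real
  habitat filtering is continuous and trait-correlated in ways a window
  cannot express.
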