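# depthfd

Depth-gradient taxonomic and functional diversity analysis for demersal
fish transect surveys.

Tropical reef fish communities below conventional diving depth — in
mesophotic coral ecosystems (~30–150 m), the rariphotic zone (~150–300 m)
and upper bathyal waters — are chronically under-surveyed, and their
vulnerability to disturbance is poorly quantified. `depthfd` is a tested
pipeline for the analysis that question requires: it turns per-individual
stereo-video transect observations (species, length) into standardized
abundance and biomass densities, tests how richness and community
composition change across depth bands, builds a categorical life-history
trait space, and measures how much functional redundancy buffers each
depth zone against species loss. It is written for quantitative community
ecologists working with belt-transect fish survey data — or, absent such
data, with the package's own synthetic survey generator.

## The metrics at its core

Species are partitioned into **functional entities** (FEs): unique
combinations of categorical trait modalities. For an assemblage of S
species across K FEs of sizes n_k:

- functional redundancy FRed = S/K,
- functional vulnerability FVul = 100 · |{k : n_k = 1}|/K,
- functional over-redundancy FOR = 100 · Σ_k max(0, n_k − FRed)/S.

In a PCoA embedding of Gower distances between trait vectors (4 axes by
default) the package computes convex-hull **functional richness** (FRic,
standardized by the pool hull), abundance-weighted **dispersion** (FDis),
minimum-spanning-tree **evenness** (FEve), **specialization** (FSpe,
distance to the pool centroid, scaled to max 1) and **uniqueness** (FUn,
mean distance to the 5 nearest neighbours, scaled to max 1). Together with
the IUCN threat rank GE (LC = 0 … CR = 4) these yield the
conservation-priority index

    FUSE = ln(1 + FUn·GE) + ln(1 + FSpe·GE).

Composition analysis uses square-root Bray–Curtis dissimilarity, PCoA,
one-way PERMANOVA and PERMDISP with seeded label permutations, and
Kruskal–Wallis / Mann–Whitney / Benjamini–Hochberg univariate tests — all
implemented from first principles and validated in the test suite against
scipy, statsmodels, scikit-bio and brute-force enumeration oracles.

## Worked example

```python
from depthfd import correction_factor, fuse
from depthfd.fd import ge_from_iucn
from depthfd.pipeline import PipelineConfig, run_all

# stereo-video calibration: a 46% length underestimation -> x1.85
print(correction_factor(0.46))                      # 1.85

# FUSE from published uniqueness/specialization/threat inputs
print(round(fuse(0.44, 0.91, ge_from_iucn("CR")), 2))   # 2.55
print(round(fuse(0.49, 0.73, ge_from_iucn("EN")), 2))   # 2.06

# full pipeline on a synthetic 300-species, 105-transect survey
res = run_all(PipelineConfig(seed=42, n_permutations=999), "out/")
fd = res["fd"]["community_fd"]
print(fd.groupby("depth_band_m")[["species_count", "FRed", "FVul",
                                  "FRic"]].mean().round(2))
```

which prints

```
              species_count  FRed   FVul  FRic
depth_band_m
4                     22.80  1.17  85.47  0.31
10                    30.00  1.22  81.72  0.36
30                    21.47  1.16  84.47  0.19
60                    16.13  1.13  87.78  0.05
120                    9.33  1.10  90.54  0.02
250                    4.27  1.02  97.78  0.00
500                    7.87  1.10  90.31  0.00
```

Mean per-transect species richness and functional richness peak at 10 m
and fall monotonically to the 250-m band; the deep bands (120–500 m) have
higher functional vulnerability (more single-species FEs) and lower
redundancy than the shallow reef bands — the depth-vulnerability pattern
the pipeline is designed to detect. The same run reports the composition
test (`PERMANOVA pseudo-F = 5.40, p = 0.0010`: distinct communities by
depth), the redundancy–vulnerability association
(`tau(FRed, FVul) = -0.91`), the trait-imputation error (out-of-bag
PFC = 0.21 on this synthetic table) and the FUSE ranking of the pool
(`res["fd"]["fuse_ranking"]`).

A command-line interface mirrors the stages:

```bash
depthfd simulate --seed 1 --n-species 300 --out survey/
depthfd process --obs survey/observations.csv --meta survey/transects.csv \
    --constants survey/lw_constants.csv --out survey/
depthfd taxdiv --matrix survey/abundance_matrix.csv --meta survey/transects.csv \
    --perms 9999 --seed 1 --out survey/
depthfd run-all --seed 1 --out survey/
depthfd fuse --fun 0.44 --fspe 0.91 --iucn CR
```

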