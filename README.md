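# ionvox

Voxel-neighborhood analysis of multiplexed secondary-ion-beam (SIMS /
NanoSIMS) image stacks.

High-resolution ion-beam imaging rasters a cell with a focused primary
beam and records, pixel by pixel and plane by plane, the counts of
secondary ions from isotope-tagged antibodies (19F, 81Br, 127I, 197Au),
endogenous elements (12C, 31P) and natively detectable drugs (cisplatin
via 194Pt). The result is a multichannel 3D count volume at tens-of-nm
lateral resolution. `ionvox` turns such volumes — or synthetic phantoms
with known ground truth — into quantitative statements about subnuclear
organisation:

* **Denoising** sparse low-current channels with a k-nearest-neighbor
  density filter (signal = dense counts, noise = sparse counts).
* **Voxelisation**: 3D sliding windows summarised by per-channel mean
  counts, with z-score, log2-pseudocount or per-FOV percentile
  normalisation and a global clip normalisation for the drug channel.
* **Neighborhoods**: Ward clustering of voxel profiles (directly or on a
  Barnes-Hut t-SNE plane) into subcellular neighborhoods — nucleolus,
  nuclear speckles, hetero-/euchromatin, lamina, cytoplasm — with
  reproducible merging of fine clusters and map rendering.
* **Interaction testing**: neighborhoods A and B "interact" where voxel
  centers lie within r = 5 px (Euclidean, 3D). Observed pair counts are
  compared with a label-shuffle null:

      p = (#{permutations beyond observed} + 1) / (n_perm + 1)
      log2 FE = log2( observed / mean permuted count )

  giving one-sided p-values per tail and a signed significance graph.
* **Drug quantification**: per-neighborhood count distributions and
  drug-positive voxel fractions per field of view, compared across
  treatment conditions with an exact two-sided Wilcoxon rank-sum test.
* **Splicing scores** from exon/intron fragment counts: per-gene binomial
  GLM (condition as covariate), Benjamini–Hochberg selection, and the
  immature-enrichment score
  `IE = log2(Σ_treat exon/intron / Σ_ctrl exon/intron)`.
* **Metrology**: 84–16% knife-edge lateral resolution (2σ for a Gaussian
  edge), ion-yield/resolution tradeoff fits, axial sputter-rate and
  isotope-barcode capacity calculators.

A first-class synthetic-data module generates Poisson-count phantoms with
parametric subcellular structures, per-structure drug partitioning and
voxel-exact ground-truth labels, plus negative-binomial exon/intron count
tables — so every stage of the pipeline is testable end to end without
instrument data. See `docs/methods.md` for models, assumptions and
parameter choices.

## Worked example

```python
import numpy as np
from ionvox import synth, pipeline, quantify, interactions

# a single-cell phantom: cytoplasm, euchromatin, heterochromatin blobs,
# two nucleoli, speckles; drug (194Pt) enriched 3x in speckles
config = synth.nuclear_phantom_config(dims=(20, 300, 300), seed=3)
volume, truth = synth.generate_nuclear_phantom(config)

# high-resolution recipe: (10,10,5) windows at step (5,5,3), log2 counts,
# Ward clustering into 5 neighborhoods
preset = pipeline.get_preset("iterative", border=20, sample_n=3000,
                             k_initial=5)
table, model = pipeline.run_pipeline([volume], preset, seed=1,
                                     truth_labels=[truth.label_volume])
print(model.summary())

drug = quantify.channel_distribution_by_neighborhood(
    table, model.labels, "194Pt")
print(drug.round(2))

coords = table[["center_x", "center_y", "center_z"]].to_numpy()
res = interactions.permutation_test(
    coords, model.labels,
    interactions.InteractionConfig(radius=5, n_perm=1000, seed=2))
print(interactions.significant_edges(res, alpha=0.05))
```

The model summary reports

```
NeighborhoodModel: 5 initial -> 5 final neighborhoods, 3000 voxels,
channels ['197Au', '81Br', '31P', '19F', '127I', '194Pt']
voxels per neighborhood: 1: 585, 2: 356, 3: 1658, 4: 224, 5: 177
              197Au   81Br    31P    19F   127I  194Pt
1            -0.958 -0.950  2.075 -0.987  0.242  1.004
2             0.465  1.061  4.367  5.333  2.232  1.084
3             0.944  0.923  4.542 -0.001  4.775  1.250
4             5.213  1.838  4.395  0.105  3.064  2.380
5             0.889  5.024  5.539  0.790  2.229  0.029
```

— profiles are log2 mean counts, so neighborhood 1 is cytoplasm (low in
everything nuclear), 2 is nucleolar (high 19F/nucleolin), 3 euchromatin
(high 127I/H3K27Ac), 4 speckle (high 197Au/SC35) and 5 heterochromatin
(high 81Br/H3K9me3, top 31P). The drug table confirms the built-in 3x
speckle enrichment — neighborhood 4 has the top mean (2.38 vs 1.0–1.25
elsewhere, log2 scale) and drug-depleted heterochromatin is lowest (0.03):

```
   neighborhood     n  mean  median   q25   q75
3             4   224  2.38    2.55  2.25  2.59   <- speckle: top drug
4             5   177  0.03    0.02 -0.68  0.65   <- heterochromatin
```

The significance graph shows every structure strongly self-associating
(diagonal edges, sign +1, e.g. `4 4 +1 weight 3.50 p 0.000999` — the
permutation floor 1/1001) and all cross-neighborhood pairs depleted
(sign −1). Exact numbers vary with the seeds; the structure of the output
does not.

The same stages are scriptable from the shell:

```sh
ionvox simulate --kind nuclear --dims 20,300,300 --seed 3 --out phantom/
ionvox run --preset iterative --input phantom/ --seed 1 --out run/
ionvox interact --voxels run/voxels.tsv --out run/interactions.tsv
ionvox metrology --barcode 7 3
```

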