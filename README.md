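# seedtrace

Quantify brain connectivity strength against Monte-Carlo chance nulls, in two
modalities that share one statistical idea: *is the observed connectivity of a
target larger than it would be if connections were allocated at random?*

The package is built for studies that triangulate a network node — e.g. a
salience-network node in ventrolateral prefrontal cortex — from (1) retrograde
tract-tracing cell counts in cytoarchitectonic areas and (2) seed-based
resting-state fMRI connectivity with anatomical masks (such as dorsal anterior
cingulate and anterior insula masks). Its audience is systems/translational
neuroanatomists and neuroimagers who need the two arms analysed with matched,
reproducible chance statistics.

## The statistics

**Tracing arm.** For one injection case, the connectivity strength of area
*i* is the fraction of all labeled cells found there,

```
CS_i = c_i / c_total
```

The chance level of `CS_i` is a multinomial Monte-Carlo null: all `c_total`
cells are re-assigned to areas with probability proportional to area volume,
CS is recomputed, and the procedure repeats (10^6 draws by default). An area
is *above chance* when its observed CS exceeds the upper bound of the central
95% interval of its null. Replicate injections are compared by the Spearman
rank correlation of their CS profiles (permutation p-value).

**Imaging arm.** A spherical seed's mean time series is Pearson-correlated
with every brain voxel; correlations are Fisher-transformed, `z = arctanh(r)`.
The seed-to-mask connectivity strength is the mean of `|z|` over the mask.
Its chance level comes from permuting the voxel `z` values uniformly across
the brain volume and recomputing the mask strength; flagging again uses the
central 95% interval. Seed-to-seed matrices use Fisher-z of the pairwise
seed-series correlations.

Both arms run on synthetic data from the built-in generators: multinomial
cell counts with planted per-area enrichment, and 4D BOLD composed of
band-limited latent network signals plus white noise inside an ellipsoidal
brain, so every stage is testable without any data download.

## Worked example

```python
from seedtrace import (AnalysisConfig, make_demo_layout, run_demo)

layout = make_demo_layout(rng_seed=3)          # synthetic two-arm study
cfg = AnalysisConfig(out_dir="demo_out", n_reps=2000, rng_seed=3)
summary = run_demo(cfg, layout)
print(summary["tracing"]["flagged"])
print(summary["fc"]["top_seed_per_mask"])
```

prints

```
{'caudal_47_12_case1': ['24'], 'caudal_47_12_case2': ['24'], 'control_case': []}
{'dACC': 'caudal_47_12', 'AI': 'caudal_47_12'}
```

i.e. in both replicate "injections" exactly the planted (3x-enriched) area 24
is above chance and no area is flagged in the control case, while in the
imaging arm the seed planted inside the synthetic salience-like network ranks
top against both the dACC-like and AI-like masks. `demo_out/` contains the
per-(case, group) and per-(seed, mask) tables with CS / strength, null mean,
sd, CI bounds, flags and excess ratios, the cross-case Spearman table, the
seed-to-seed matrix, and a manifest (config hash + seed + versions) that
makes the run bit-reproducible.

The same analyses run from the shell on files:

```
seedtrace simulate --out-dir sim --rng-seed 3
seedtrace fc --bold sim/bold.nii.gz --brain-mask sim/brain_mask.nii.gz \
    --seeds sim/seeds.csv --mask dACC=sim/mask_dACC.nii.gz \
    --mask AI=sim/mask_AI.nii.gz --tr 2.0 --out-dir fc_out
seedtrace tracing --parcellation sim/parcellation.csv \
    --counts sim/cell_counts.csv --out-dir tracing_out
```

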