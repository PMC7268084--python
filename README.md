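# neurofuse

Multimodal neuroimaging classification toolkit: six MRI-derived feature
sets (voxel-wise gray/white matter maps, KL-divergence morphological
similarity networks, ReHo, ALFF, Pearson functional connectomes), linear
SVMs with Platt-calibrated probabilities, soft-voting fusion tuned by
double-nested stratified cross-validation, permutation inference,
pooled / site-stratified / cross-site evaluation, and weight-based region
attribution. A synthetic multi-site cohort generator with known
ground-truth effects makes the whole pipeline runnable and testable
without downloading any data.

## Layout

| Module | Contents |
| --- | --- |
| `neurofuse.synthetic` | atlas + multimodal multi-site cohort generation, NIfTI/TSV serialization, YAML effect configs |
| `neurofuse.structural` | Gaussian smoothing, voxel-feature vectorization, per-region KDE densities, exp(−symmetrized-KL) similarity networks |
| `neurofuse.functional` | framewise displacement, Friston-24, detrend + band-pass + nuisance cleaning with FD censoring, ReHo (Kendall's W, 26 neighbours), ALFF, ROI Pearson connectomes |
| `neurofuse.confounds` | Gaussian-process age/sex confound regression fitted on controls only |
| `neurofuse.ensemble` | calibrated linear SVMs, nested C grid search, integer soft-voting coefficient search on cached probabilities, outer stratified CV, permutation tests, pooled/stratified/cross-site modes |
| `neurofuse.reporting` | region attribution from linear weights, top-k region tables, decimal summary aggregation (dataset averages, modality means) |
| `neurofuse.pipeline` | cohort → per-measure feature tables (GM, WM, StructM, ReHo, ALFF, FuncM) |

## CLI

```bash
# write a synthetic two-site cohort (NIfTI + TSV) with ground truth recorded
neurofuse simulate --out cohort/ --n-per-group 20 --regions 12 \
    --shape 16,16,16 --timepoints 120 --seed 1 --sites siteA,siteB

# combined six-measure soft-voting classification, 10-fold nested CV
neurofuse classify --cohort cohort/ --measures gm,wm,structm,reho,alff,funcm \
    --mode combined --folds 10 --seed 1 --out results.json

# permutation inference and cross-site transfer
neurofuse permute --cohort cohort/ --measures funcm --n-perm 99 --seed 1
neurofuse cross-site --cohort cohort/ --train-site siteA --test-site siteB
```

Effect sizes and noise scales for `simulate` can be supplied as YAML via
`--effects-config` (top-level keys `effects:` and `noise:` mirroring
`EffectSpec` / `NoiseSpec` fields).

## Conventions worth knowing

- Motion files store translations in mm and rotations in **radians**;
  framewise displacement converts rotations on a 50 mm sphere.
- ReHo/ALFF maps are standardized by their in-brain mean (post-division
  mean exactly 1); connectivity matrices are vectorized as the upper
  triangle excluding the diagonal, row-major.
- Summary tables round half-away-from-zero at 2 decimals, computed in
  decimal arithmetic so printed two-decimal inputs aggregate exactly.
- Tie rules in model selection are explicit: smaller C, lexicographically
  smallest coefficient vector, patient on fused-score ties.
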