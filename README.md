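# rinan

Activation-network / relatively-inert-network analysis of resting-state
fMRI.

## What problem this addresses

When a resting-state network is extracted by ICA, analysis usually keeps
only the voxels whose z-scored map exceeds a threshold — the *activation
network* (AN) — and ignores the sub-threshold remainder of the same
component, the *relatively inert network* (RIN). That remainder covers most
of the brain and can carry weak, diffuse signal of its own. `rinan` is for
researchers who want to test, on their own data or on fully controlled
synthetic cohorts, whether RIN dynamics add information: it estimates
networks at the group and subject level, splits each network into AN and
RIN with separately estimated time courses, compares the resulting
functional network connectivity (FNC) between groups, and benchmarks four
FNC feature sets in a diagnostic classifier.

## The model

Data follow the spatial ICA model `X = A S`: the `n_time x n_voxels` BOLD
matrix is a linear mix of spatially independent sources. Group maps come
from temporal-concatenation group ICA (per-subject PCA, stacking, group
PCA, Infomax with ICASSO stability selection; MDL order estimation).
Subject maps are re-estimated with the group maps as spatial references by
maximising, over a unit-norm unmixing vector `w`,

    F(w) = a * K(w) + (1 - a) * C(w),        0 < a < 1

where `K = (2/pi) * arctan(Q)` squashes the negentropy proxy
`Q(w) = (E[G(Y)] - E[G(z)])^2` of the component `Y = w' X~` and
`C(w) = E[Y R]` is the correlation with the reference `R`. The component
time course is the z-score-weighted voxel mean `T = (1/V) sum_v y_v f_v`.

Each network is then split at a threshold `mu` (default 3) on its
statistic map: voxels strictly above `mu` form the AN (`d_v = 1`), the rest
the RIN, with time courses

    T_act = (1/Va) sum_v y_v d_v f_v,     T_ine = (1/Ve) sum_v y_v (1-d_v) f_v,

which reconstruct the full-network time course exactly:
`Va*T_act + Ve*T_ine = V*T`. For 8 networks the AN+RIN ("AllFNC") Pearson
connectivity matrix is 16 x 16; group differences are tested per element
with Welch t-tests on Fisher-transformed correlations under
Benjamini-Hochberg FDR, and classification compares `OriginalFNC`,
`ActFNC`, `InertFNC` and `AllFNC` features through XGBoost feature
selection and a cross-validated linear SVM on repeated stratified 70/30
splits.

A built-in simulator generates multi-subject cohorts from the same mixing
model with known core (AN) / halo (RIN) structure and known group-level
connectivity differences, so every stage has an exact oracle. See
`docs/methods.md` for all modelling choices.

## Worked example

Simulate a 30-subject cohort (15 per group) in which group 1 differs from
group 0 only in two RIN-RIN (halo-halo) connectivity edges planted at
r = 0.6, then run the full pipeline:

```python
from rinan.pipeline import RunConfig, SimulateSection, run_pipeline

cfg = RunConfig(seed=0, classify_repeats=20,
    simulate=SimulateSection(grid_dims=(10, 10, 10), n_subjects_per_group=15,
        noise_sd=0.2, planted_edges=[(8, 9, 0.6), (10, 11, 0.6)]))
res = run_pipeline(cfg)
print(res.comparison.summary())          # FDR-significant FNC edges
print(res.classification.summary())      # strategy comparison
```

The significant-edge table finds the planted differences on the `_i`
(RIN) rows with direction `+1` (group 1 stronger), at much larger |t| than
any incidental edge:

```
               edge         t            p            q  direction
source0_i-source1_i 19.776846 3.751513e-17 2.250908e-15          1
source2_i-source3_i 26.102573 4.286675e-21 5.144010e-19          1
...
```

and the classifier comparison shows the headline effect — features that
include RIN connectivity recover the group difference that the original
(unsplit) network connectivity largely misses:

```
   strategy  mean_accuracy  mean_sensitivity  mean_specificity  mean_f1
OriginalFNC          0.622             0.620             0.620    0.617
     ActFNC          0.406             0.392             0.465    0.331
   InertFNC          0.967             0.932             1.000    0.962
     AllFNC          0.961             0.943             0.980    0.957
```

`OriginalFNC` sits near chance because the planted halo correlations are
diluted by the core-dominated full-network time courses, while `InertFNC`
and `AllFNC` classify almost perfectly from the RIN time courses.

The same workflow runs from the shell:

```bash
rinan config --init > run.yaml     # all defaults, editable
rinan run-all --config run.yaml --out results/
rinan sweep-mu --config run.yaml --out results/   # mu in {1,2,3,4}
```

Real data enter as ordinary NIfTI files: set `bold_paths`, `mask_path` and
`group_labels` in the config (inputs are assumed preprocessed and
spatially normalised).

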