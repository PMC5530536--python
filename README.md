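# ankle-ssm

Statistical shape modeling of the 2-D lateral ankle, with cluster-robust
association analysis.

Weight-bearing lateral ankle radiographs can be summarized by a fixed set
of 68 landmark points placed on the distal tibia, talus, calcaneus and
navicular. This package implements the full analysis chain used to relate
such landmark data to clinical covariates in epidemiological cohorts:

1. **Landmark I/O and validation** — TPS landmark files, a delimited
   metadata table (participant, side, injury history, race, sex, BMI,
   Kellgren–Lawrence grade, 0–10 symptom score dichotomized at > 0), left
   ankles mirrored to right orientation so both sides can share one model.
2. **Generalized Procrustes analysis (GPA)** — translation, centroid-size
   and rotation are removed iteratively until the consensus shape is
   stable; reflections are never fitted.
3. **Point-distribution shape model** — PCA of the aligned coordinate
   vectors: mean shape x̄ plus orthonormal modes φ_k with variances λ_k.
   Modes are retained by the parsimony rule *smallest leading set
   explaining ≥ 80 % of shape variance, each member explaining ≥ 1 %*.
   Any shape is x̄ + Σ_k b_k φ_k; mode scores b_k / √λ_k are standardized
   per-SD shape variables, and mean ± k·SD outlines visualize each mode.
4. **Cluster-robust logistic regression** — injury (or race) on all
   retained mode scores simultaneously, by IRLS maximum likelihood, with
   the sandwich covariance over participant clusters (two ankles of one
   person are not independent) scaled by G/(G−1); odds-ratio tables with
   Wald 95 % CIs, minimally and fully adjusted (age, BMI, race, sex, KLG,
   symptoms).
5. **Reader repeatability** — per-landmark placement distances in mm,
   percentages within 1 / 1.5 / 2 mm, and ICC(2,1) (two-way random
   effects, absolute agreement) for mode scores between readings.
6. **Synthetic cohorts with known truth** — a stylized 68-point ankle
   template, smooth orthonormal deformation modes, nuisance similarity
   transforms and digitization noise, bilateral ankles with within-person
   correlation, race-linked mode-1 shift, and injury assigned by a
   logistic model on mode scores — the ground truth for every recovery and
   calibration test.

Intended users: musculoskeletal epidemiologists and morphometricians who
want a transparent, fully tested 2-D landmark pipeline whose statistical
behavior (coverage, confounding, repeatability) can be audited against a
generator with known truth.

## Worked example

```python
import ankle_ssm as A

spec = A.SyntheticSpec(seed=42)            # ~200 participants, ~10% bilateral
dataset, truth = A.simulate_cohort(spec)

configs = [A.mirror_left_to_right(c) if c.side == "left" else c
           for c in dataset.configurations]
ds = A.ShapeDataset(scheme=dataset.scheme, configurations=configs,
                    metadata=dataset.metadata)
aligned = A.generalized_procrustes(ds)
results = A.ShapePCA(aligned, ds.scheme).fit()
print("retained modes:", [m + 1 for m in results.retained])
print(results.summary().head(4).round(3))

or1, or2 = A.run_injury_models(results.scores, ds.metadata_frame())
print(or1.head(3)[["predictor", "odds_ratio", "ci_lower", "ci_upper"]])
```

prints

```
retained modes: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
 mode  pct_explained  cum_pct  retained
    1         19.215   19.215      True
    2         12.613   31.828      True
    3          8.582   40.410      True
    4          7.963   48.373      True
predictor  odds_ratio  ci_lower  ci_upper
    mode1       1.472     1.074     2.017
    mode2       0.789     0.575     1.082
    mode3       0.969     0.695     1.350
```

Fourteen fitted modes reach 80 % of shape variance on this cohort of 216
ankles. Mode 1 — on which the generator placed a true per-SD injury odds
ratio — comes out at OR 1.47 (95 % CI 1.07–2.02) per SD of shape, flagged
significant; null modes straddle 1. Adding a repeat reading with 0.5 mm
placement noise,

```python
repeat = A.simulate_repeat_readings(dataset, 0.5, seed=43)
rep = A.repeatability_report(dataset.configurations, repeat.configurations)
print(rep.pct_within)   # {1.0: 86.4, 1.5: 98.9, 2.0: 100.0}
```

86 % of points fall within 1 mm, matching the Rayleigh closed form
1 − e^(−2) ≈ 86.5 % for that noise level.

The same pipeline runs from the shell:

```sh
ankle-ssm simulate --seed 42 --out cohort/ --repeat-sd 0.5
ankle-ssm fit --tps cohort/cohort.tps --metadata cohort/metadata.csv \
              --repeat-tps cohort/cohort_repeat.tps --out bundle/
ankle-ssm figures --model bundle/shape_model.json --modes 1,6 --k-sd 2
```

producing a report bundle: alignment log, variance table, retained-mode
list, descriptive (Table-1-style) cohort table, minimally/fully adjusted
odds-ratio tables, race-model table, repeatability report, mode figures
and a machine-readable manifest.

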