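# petcog

Causal region selection and cognitive-score regression from region-wise
FDG-PET SUV features.

The package implements a two-stage analysis for three-group (AD / MCI / NC)
FDG-PET cohorts:

1. **Causal stage** — verify age/gender as confounders with Fisher-Z
   conditional-independence tests and the PC algorithm, estimate each brain
   region's backdoor-adjusted direct effect on cognitive (MMSE) and
   functional (FAQ) scores with a linear estimator, rank regions, take the
   union of whole-cohort and per-group top-k lists, and validate the result
   with placebo (within-region shuffle) tests and counterfactual
   do-intervention curves.
2. **Prediction stage** — regress the scores on the causally selected
   regions plus demographics with a feature-wise-attention + transformer-
   encoder network (trained with AdamW, Huber loss and gradient clipping,
   implemented on a small in-repo numpy autodiff engine).

Because the original study's clinical data is access-controlled, the
package ships a synthetic-cohort generator with known causal ground truth
(region effects, confounder loadings, per-group score distributions) plus
synthetic dynamic-PET volume/atlas fixtures for the SUV-extraction path.
These are first-class, tested modules and the substrate for all benchmarks.

## Layout

| module                | purpose |
|-----------------------|---------|
| `petcog.synth`        | synthetic cohorts + PET fixtures with ground truth |
| `petcog.suv`          | SUV conversion, atlas region means, frame averaging |
| `petcog.discover`     | Fisher-Z test, PC skeleton, orientation, confounder report |
| `petcog.effects`      | backdoor OLS effects, ranking, selection, overlap |
| `petcog.refute`       | placebo shuffles, counterfactual curves |
| `petcog.regressor`    | attention/transformer regressor, split/train/evaluate |
| `petcog.autodiff`     | minimal reverse-mode autodiff + AdamW |
| `petcog.pipeline`     | end-to-end orchestration and run reports |
| `petcog.cli`          | `petcog` command-line interface |

## CLI

```bash
petcog simulate --n-per-group 96 --n-regions 120 --seed 1 --out cohort.csv
petcog discover --cohort cohort.csv --n-regions 12 --out confounders.json
petcog estimate --cohort cohort.csv --outcome mmse --k 30 --out effects.csv
petcog refute --cohort cohort.csv --outcome mmse --regions Angular_L \
    --n-permutations 100 --out placebo.csv
petcog counterfactual --cohort cohort.csv --outcome mmse \
    --region Angular_L --scope AD --out curve.csv
petcog train --cohort cohort.csv --target mmse --out model.npz
petcog run-all --outdir run/ --seed 1          # full pipeline on synthetic data
petcog extract --volume pet.nii.gz --atlas atlas.nii.gz \
    --dose 370 --weight 74 --out features.csv  # SUV features from NIfTI
```

Cohort tables are plain CSV (`subject_id, age, gender, group, <120 AAL2
region columns>, mmse, faq`); graphs export as edge lists / GML; reports as
JSON; model checkpoints as `.npz`.

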