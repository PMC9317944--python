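# facesym

Landmark-based facial-symmetry features and palsy severity classification.

The package implements a complete, testable pipeline for assessing unilateral
facial palsy from 2-D facial landmarks:

1. **Renumbering** — a standard 68-point facial landmark set is reduced to the
   51 key points of interest (face-contour points dropped) via an editable
   mapping file (`src/facesym/data/mapping_68_to_51.csv`).
2. **Tilt correction** — a closed-form similarity transform rotates the
   landmarks about the outer-eye-corner midpoint so the eye line is level.
3. **Features** — 28 named distances plus two average eyebrow heights feed
   29 symmetry features (angles, slopes, max left/right ratios). A perfectly
   symmetric, level face is the fixed point: pairwise-max features equal 1,
   horizontal angles and slopes equal 0. The distance endpoints live in an
   editable definition file (`src/facesym/data/distances.csv`) validated for
   left/right mirror homology at load time.
4. **Regions** — regional projections for partial-occlusion analysis:
   full face (29 features), eyes (19), mouth (15).
5. **Synthetic data** — a mirror-symmetric face template with parameterized
   unilateral droop (healthy / slight / strong), Gaussian jitter and global
   pose, so every downstream stage is testable without any real database.
6. **Classification** — four classifier presets (MLP, SVM-RBF, 1-NN,
   multinomial logistic regression; `src/facesym/data/presets.yaml`),
   stratified 5-fold cross-validation repeated 10 times, and the seven
   confusion-matrix statistics (accuracy, recall, precision, F1, TNR, FNR,
   FPR) with mean ± std over repeats.
7. **I/O** — landmark CSV/JSON, feature CSV, and dense ARFF export that
   round-trips through `scipy.io.arff`.

Image-based landmark acquisition (face detector + shape predictor) is
supported only through a pluggable adapter protocol (`facesym.adapters`);
the core package has no computer-vision dependency.

## CLI

```bash
# features from one landmark file (68- or 51-point CSV/JSON)
facesym extract --landmarks face.csv --region eyes --out features.csv

# deterministic synthetic dataset (landmarks + features + manifest)
facesym synth --seed 7 --n-per-class 19 --task detect --out out/

# full cross-validated experiment from a YAML config
facesym run --config experiment.yaml --out results/

# ARFF export and report pretty-printing
facesym export-arff --features features.csv --relation demo --out demo.arff
facesym report --summary results/summary.json
```

A minimal experiment config:

```yaml
task: detect            # detect | two_level | three_level
region: face            # face | eyes | mouth
preset: exp1_face       # see src/facesym/data/presets.yaml
family: SVM             # MLP | SVM | KNN | MNLR
k: 5
repeats: 10
seed: 0
synthetic: {n_per_class: 19, images_per_subject: 20, rng_seed: 0}
```

## Library sketch

```python
from facesym import (renumber_landmarks, tilt_correct, extract_features,
                     select_region, make_template)
from facesym.synthetic import SyntheticConfig, generate_subjects
from facesym.evaluate import assemble_experiment, get_preset, repeated_kfold

lm51 = tilt_correct(renumber_landmarks(lm68))
fv = extract_features(lm51)              # 29 features
eyes = select_region(fv, "eyes")         # 19 features

subjects = generate_subjects(SyntheticConfig(n_per_class=19, rng_seed=0))
ds = assemble_experiment(subjects, task="detect", region="face", augment=True)
report = repeated_kfold(ds, get_preset("exp1_face", "SVM"), k=5, repeats=10)
print(report.mean.Acc, report.std.Acc)
```

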