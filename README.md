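# graspadl

Classification of activities-of-daily-living (ADL) tasks from skeletal
hand-tracking recordings, based on grasp shape alone.

The pipeline takes per-trial matrices of `n_frames x 84` coordinate values
(palm center, three orthonormal palm basis vectors, and finger joint
positions, in millimeters at 30 fps), normalizes them into a palm-anchored
hand coordinate system (removing gross arm motion), extracts geometric /
time-domain / frequency-domain grasp features, and evaluates RBF-SVM and CNN
classifiers with 5-fold cross-validation.  A synthetic hand-kinematics
generator provides fully reproducible test data, so the entire pipeline runs
without any external dataset.

## Components

| Module | Purpose |
| --- | --- |
| `graspadl.hand_model` | structured hand frame, the flat 84-value layout, task vocabulary |
| `graspadl.trial` / `trial_io` | trial container, plain-text trial files and multi-trial bundles |
| `graspadl.preprocess` | rigid transforms, GCS→HCS change of basis, median filtering |
| `graspadl.features` | hand-length normalizer M; AFA, ATD, DPUV, NPTD, JA, FHA, FTE; windowed MAV/RMS/VAR/WL; windowed DFT magnitudes; assembly + standardization |
| `graspadl.classify` / `metrics` | stratified / group-aware folds, RBF-SVM evaluation, macro metrics |
| `graspadl.cnn` | the small-grid CNN (conv 16/32/32, 2×2 kernels, BN, ReLU, two maxpools, 50% dropout; SGD lr 0.01, 20 epochs, batch 40) implemented directly on NumPy with full backpropagation |
| `graspadl.synthetic` | grasp archetypes, forward kinematics, trial/dataset generation |

The CNN is implemented in NumPy (no deep-learning framework is required at
runtime); its gradients are verified against finite differences in the test
suite.

## CLI

```sh
# 1. generate a synthetic bundle (8 tasks x subjects x trials)
graspadl simulate --subjects 6 --trials-per-task 2 --jitter 0.015 --noise 2.5 \
    --seed 11 --out data/raw

# 2. change basis into the hand frame and median-filter (window 5 = 1/6 s)
graspadl preprocess --in data/raw --out data/hcs --median-window 5

# 3. feature extraction (any of AFA,ATD,DPUV,NPTD,JA,FHA,FTE,MAV,RMS,VAR,WL,DFT)
graspadl featurize --in data/hcs --features JA,NPTD,MAV --window 15 \
    --dft-bins 8 --out data/features.tsv

# 4. cross-validated evaluation
graspadl train-eval --features data/features.tsv --model svm --folds 5 \
    --split rows --seed 17 --report reports/ja_nptd_mav_svm
```

`--split rows` stratifies individual samples across folds; `--split trials`
keeps all samples of a trial in one fold (stricter, avoids the optimism of
splitting frames of one recording across train and test).

## Data formats

A trial file is comma-separated text: `# key=value` header lines
(`subject_id`, `task_label`, `trial_index`, `fps`, `coordinate_frame`,
`layout_version`) followed by one 84-column row per frame.  A bundle is a
directory of trial files plus `manifest.tsv` (file, metadata, calibration
flag).  The 84-value layout is documented in `graspadl/hand_model.py`; the
exact ordering of the 28 tracked points is a documented convention of this
package, since only the total count is fixed by the upstream data
description.
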