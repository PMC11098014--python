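# dancekin

Interpretable kinematic featurization and genre classification of full-body
3D dance pose sequences.

Dance genres — Breakdance, House, Krump, Popping and their kin — differ in
ways audiences can feel but that are hard to formalize. `dancekin` encodes a
pose sequence (an `N x 17 x 3` array of COCO-17 joint positions at a fixed
frame rate, as distributed in motion-capture keypoint datasets such as
AIST++) as **17 macroscopic, human-understandable movement features**, and
builds a genre classifier and analysis suite on top of that encoding. It is
aimed at movement scientists, dance researchers and machine-learning
practitioners who want interpretable, lightweight models of full-body motion
rather than deep spatio-temporal networks.

## The encoding

All features derive from two primitives. The sacrum is approximated as the
hip midpoint, `SP_i = (P_i,lhip + P_i,rhip) / 2`, and derivatives are
forward finite differences with Savitzky–Golay smoothing after each stage:

```
SV_i = (P_{i+1} - P_i) / ΔT          velocity
SA_i = (SV_{i+1} - SV_i) / ΔT        acceleration
SJ_i = (SA_{i+1} - SA_i) / ΔT        jerk
```

The 17 features fall into four categories:

| category | features |
| --- | --- |
| sacrum (5) | planar speed mean, height SD, jerkiness `mean‖SJ_i‖`, bounce frequency, bounce regularity |
| extremities (4) | wrist and ankle acceleration means, ankle height mean and SD above the floor |
| angular momentum (6) | mean and SD of `‖L_ij‖` where `L_ij = R_ij × V_ij`, `R_ij = P_ij - SP_i`; horizontal rotation (vertical component); per-axis sharp-movement peak rates |
| expandedness (2) | mean and SD of `D_ij = ‖R_ij‖` |

An augmented 20-feature registry appends per-axis rates of prominent
autocorrelation peaks of the angular-momentum trace (rhythmic uniformity).

On top of the encoding, `classify` fits linear baselines (ridge,
perceptron) and a budgeted model-zoo search whose candidates are combined
by greedy weighted ensembling, `ŷ = Σ w_i h_i(X)`, minimizing multiclass
log loss `f = -(1/M) Σ_m Σ_k y_mk log p_mk` on an inner validation split.
`analyze` provides an LSA/truncated-SVD genre similarity embedding,
Shapley-value and permutation feature importance, per-genre fingerprints
(mean vector + feature-correlation matrix), and confusion-matrix
comparison against external studies (e.g. human raters). `motionsim` is a
parametric stick-figure simulator whose dials (bounce, spin, limb
oscillation, expandedness scale, sharp jerk events, noise) have closed-form
feature expectations, giving the whole pipeline analytic ground truth.

## Worked example

```python
from dancekin.motionsim import MotionSpec, generate_motion, expected_features
from dancekin.features import extract_features
from dancekin.kinematics import SmoothingConfig

spec = MotionSpec(duration=10, bounce_amplitude=0.05, bounce_frequency=2.0)
seq = generate_motion(spec)                     # 600 frames x 17 joints x 3
fv = extract_features(seq, smoothing=SmoothingConfig(enabled=False))
exp = expected_features(spec)
print(f"jerkiness  measured {fv.values['sacrum_jerkiness']:.2f}"
      f"  closed form {exp['sacrum_jerkiness']:.2f}")
print(f"height SD  measured {fv.values['sacrum_height_sd']:.4f}"
      f"  closed form {exp['sacrum_height_sd']:.4f}")
```

prints

```
jerkiness  measured 62.42  closed form 63.17
height SD  measured 0.0354  closed form 0.0354
```

A 5 cm, 2 Hz vertical bounce has jerk amplitude `A(2πf)³`; its mean
magnitude is `A(2πf)³·(2/π) ≈ 63.2 m/s³`, and the discrete pipeline
recovers it to ~1%. The height SD of a sinusoid is `A/√2 ≈ 0.0354 m`.

The same works end to end from the shell:

```bash
dancekin simulate --out poses/ --n-per-genre 12 --seed 0
dancekin run --out artifacts/ --seed 0 --n-per-genre 12
```

which writes a feature table, train/test split, fitted ensemble report
(accuracy, per-class precision/recall/F1, confusion matrix) and the LSA
embedding under `artifacts/`.

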