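# protonsct

MRI-only proton therapy planning needs a CT that does not exist: treatment
targets are contoured on MRI, but proton dose calculation requires Hounsfield
units to derive stopping powers.  `protonsct` implements, at desk scale, the
full chain for studying that substitution — synthesising a CT from MRI with a
mutual-information conditional GAN and then asking the question that actually
matters for protons: *how different are the doses computed on the real and the
synthetic CT, nominally and under treatment uncertainty?*

The package is aimed at researchers in medical image synthesis and proton
therapy physics who want a transparent, fully seeded, CPU-scale testbed for
the method and its evaluation protocol, exercised on procedurally generated
paired head phantoms (no patient data required).

## The model

The generator G is a 2D U-Net mapping a max-normalised MRI slice y to a
CT-like image G(y) in [0, 1]; the discriminator D is a strided convolutional
classifier scoring (y, x) pairs.  Training alternates the usual adversarial
update of D with a generator update whose synthesis term is the mutual
information between the real CT x and the synthesised image,

    MI(x, G(y)) = H(x) + H(G(y)) − H(x, G(y)),

estimated from a soft-binned joint histogram (triangular kernel), which makes
MI differentiable in G(y).  The generator loss is

    L_G = −λ_MI · MI(x, G(y)) + λ_adv · (−log D(y, G(y))),

with λ_MI = λ_adv = 1 by default and a documented pure-MI mode (λ_adv = 0).
MI is invariant to how intensities are labelled, so it tolerates training
pairs that are *not* rigidly aligned — the property that removes MRI-to-CT
registration from the training pipeline; the adversarial term pins the
intensity scale.  Synthetic CTs are evaluated in image space (mean absolute
HU error over the body contour) and dosimetrically: an opposed-beam
spread-out-Bragg-peak plan normalised to a 60 Gy prescription is computed on
CT and sCT with an analytic HU→RSP→WEPL→Bragg dose model, and DVH metrics
(D95, D5, D2, Dmean, in % of prescription) are compared across a robustness
protocol — the 21-scenario worst-case grid (±3 mm, ±3%) and a 100-scenario
Monte-Carlo test with σ_setup = 3 mm / 2.5 = 1.2 mm (Van Herk) and
σ_range = 2.4% / 1.5 = 1.6%, discarding the 10% most extreme scenarios and
reading worst-case metrics off the DVH-band borders.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

Train the synthesis model on 20 phantoms and evaluate a held-out subject:

```python
from protonsct import (PhantomSpec, make_cohort, MISynthesisGAN, TrainConfig,
                       MIConfig)
from protonsct.sct_eval import evaluate_sct

cohort = make_cohort(PhantomSpec(), 22, seed=123)
train, held = cohort[:20], cohort[20:]

model = MISynthesisGAN(train, mi_cfg=MIConfig(n_bins=16))
fit = model.fit(TrainConfig.phantom_scale(seed=0))

sct = fit.predict_sct(held[0].mri)
mae, _ = evaluate_sct(held[0].ct, sct)
print(f"held-out MAE: {mae:.1f} HU")
```

```
held-out MAE: 279.2 HU
```

After the 30-epoch desk-scale training the synthetic CT reproduces the
phantom CT to ~280 HU mean absolute error over the body contour; for scale,
the best constant-HU image scores ~568 HU and an untrained generator ~620 HU.
The residual error concentrates at the skull and air-cavity interfaces —
exactly where clinical sCT methods struggle too — and feeding this desk-scale
sCT into the proton dose chain produces correspondingly large DVH differences
(tens of percent for CTV D95): a 280 HU image error is *not* proton-ready,
which is precisely the kind of statement the dosimetric evaluation exists to
make quantitative.

To see the robustness protocol itself at work it is clearer to use a
controlled synthetic-CT error — the whole skull shifted by +200 HU, a typical
magnitude and location for sCT bone errors:

```python
from protonsct import make_plan, RobustnessEvaluation, RobustSettings
from protonsct.phantom import LABEL_BONE
from protonsct.dvh import diff_table

s = held[0]
plan = make_plan(s.ct, s.masks["CTV"], prescription=60.0)
sct = s.ct.copy(); sct.data[s.labels == LABEL_BONE] += 200.0
rois = {"CTV": s.masks["CTV"], "brainstem": s.masks["brainstem"]}
settings = RobustSettings(n_scenarios=100, seed=0)
res_ct = RobustnessEvaluation(plan, s.ct, rois, settings).run()
res_sct = RobustnessEvaluation(plan, sct, rois, settings).run()
print(res_ct.summary())
print(diff_table(res_ct.nominal, res_sct.nominal).round(2))
print(diff_table(res_ct.worst, res_sct.worst).round(2))
```

```
Robustness evaluation
=====================
scenarios evaluated : 101
scenarios retained  : 91 (retain fraction 0.9)

metric            nominal      worst   (% of prescription)
       CTV D95        90.7       81.9
       CTV D5        107.0      112.2
       CTV D2        107.2      112.4
       CTV Dmean     100.0      107.2
 brainstem D95         8.5        3.6
 brainstem D5         39.0       42.4
 brainstem D2         39.1       42.4
 brainstem Dmean      24.4       32.2
                  diff_pct
roi       metric
CTV       D95         1.83
          D5          1.00
          D2          1.00
          Dmean       1.62
brainstem D95         0.17
          D5          0.33
          D2          0.33
          Dmean       0.03
                  diff_pct
roi       metric
CTV       D95         2.00
          D5          0.83
          D2          0.67
          Dmean       1.07
brainstem D95         0.10
          D5          0.17
          D2          0.17
          Dmean       0.24
```

Reading: the +200 HU skull error shortens the proton range through bone and
costs 1.8% of the prescription in nominal CTV coverage (D95); in the worst
retained uncertainty scenario the difference grows to 2.0%.  Organ-at-risk
metrics move by a few tenths of a percent.  The whole comparison — 101
scenario dose computations per image, scenario rejection, DVH-bands and
worst-case extraction — runs in a few seconds per image on one CPU.

A command-line interface mirrors the library
(`protonsct generate-phantoms | train | synthesize | evaluate-image | plan |
dose | robustness | run-all`); `protonsct run-all --seed 0 --out out/` runs
the whole study and writes the difference tables as CSV.

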