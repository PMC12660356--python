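# fcaunet

A toolkit for classifying polycystic ovary syndrome (PCOS) in ovarian
ultrasound images with a **Feature Fusion Context Attention U-Net
(FCAU-Net)** and a **fuzzy contrast enhancement (FCE)** preprocessing
chain.  It is aimed at researchers studying attention architectures and
contrast enhancement for low-quality medical ultrasound: every stage —
phantom simulation, cropping/augmentation, enhancement, training,
evaluation, explainability, statistics — is an importable, seeded,
tested library function with a thin CLI on top.

On ultrasound, a polycystic ovary shows many small peripheral follicles
("string of pearls") while a healthy ovary shows a few larger ones.
The package ships a seeded phantom generator that reproduces exactly
this class structure (speckled background, dark elliptical ovary,
hypoechoic follicle discs, ground-truth masks), so the entire pipeline
runs and is validated end-to-end without any clinical data.

## The method

**Fuzzy contrast enhancement.**  Gray levels `gl ∈ [gl_min, gl_max]`
are fuzzified into memberships

    μ(gl) = [1 + (gl_max − gl)/FD]^(−FE)

with exponential and denominational fuzzifiers `FE`, `FD`; the
intensification operator `Γ(μ) = 2μ²` (μ ≤ ½) / `1 − 2(1−μ)²` (μ > ½)
pushes memberships away from the 0.5 crossover, and defuzzification
maps them back around a crossover level `n`:

    Ψ(μ) = n − (n − gl_min)(1 − 2μ)   for μ ≤ ½
    Ψ(μ) = n + (gl_max − n)(2μ − 1)   for μ > ½

The composition `Ψ∘Γ∘Φ` is a monotone lookup table.  Global histogram
equalization and a clip-limited adaptive variant (CLAHE, clip fraction
`Q` of the tile pixel count) are provided for comparison, and a scene
intensity model `Int = SR + L_α (1 − e^{−βd})` selects the brightest
candidate.

**FCAU-Net.**  A four-stage encoder/decoder with attention-gated skip
connections and a Feature Fusion Context (FFC) module at the
bottleneck.  The FFC applies channel attention (row-softmax of the
C×C Gram matrix of channel-flattened features) and position attention
(softmax over pairwise pixel affinities), each with a learnable scale
`β` and residual; a quarter-scale companion map is then fused through
position/context convolution blocks as

    OFM = (pos₁(F) ⊙ con₂(F)) + 4 · Upsample(con₁(F¼) ⊙ pos₂(F¼))

A global-pool classification head outputs healthy/infected
probabilities; an optional 1×1-conv mask head predicts follicle
regions.  Ablation switches reconstruct the variant lattice from plain
U-Net to the full model.

**Evaluation.**  Confusion-matrix metrics, ROC/PR curves, a seeded
k-fold harness with fold aggregation, Grad-CAM heatmaps scored against
ground-truth masks (IoU, Dice, pointing-game accuracy, energy-based
localization), paired t-tests and the McNemar test.

## Worked example

```python
import numpy as np
from fcaunet.synthetic import generate_dataset, PhantomSpec, low_contrast_fixture
from fcaunet.preprocess import split_dataset
from fcaunet.types import SplitPlan
from fcaunet.model import build_fcau_net, ModelConfig, TrainParams, train_model, predict
from fcaunet import enhance as en, evaluation as ev

fx = low_contrast_fixture()                      # dark, narrow-band image
print('brightness HE    %.1f%%' % en.brightness_percent(en.equalize_histogram(fx)))
print('brightness CLAHE %.1f%%' % en.brightness_percent(en.clahe(fx)))
print('brightness FCE   %.1f%%' % en.brightness_percent(en.fce(fx)))

data = generate_dataset(24, PhantomSpec(), seed=7)   # 48 phantoms with masks
tr, va, te = split_dataset(data, SplitPlan(test_fraction=0.25, val_fraction=0.2, seed=0))
model = build_fcau_net(ModelConfig(base_channels=8, seed=0))
model, hist = train_model(model, tr, va,
                          TrainParams(epochs=30, early_stop_val_acc=1.0), seed=0)
y = np.array([0 if s.label == 'healthy' else 1 for s in te])
labels, probs, _ = predict(model, te)
cm = ev.confusion(y, labels)
print('epochs trained   %d' % len(hist))
print('test confusion   tp=%d fp=%d fn=%d tn=%d' % (cm.tp, cm.fp, cm.fn, cm.tn))
print('test accuracy    %.1f%%' % ev.classification_metrics(cm)['accuracy'])
```

prints

```
brightness HE    20.6%
brightness CLAHE 29.6%
brightness FCE   95.4%
epochs trained   15
test confusion   tp=6 fp=0 fn=0 tn=6
test accuracy    100.0%
```

The brightness lines show the qualitative ordering the enhancement
chain is designed for: on a dark, narrow-band image the fuzzy enhancer
lifts mean brightness far above both histogram-equalization variants.
The confusion matrix shows the small network separating the two
phantom classes perfectly on the held-out originals — the easy-mode
classes are separable by construction (disjoint follicle counts), so
anything well below 100% signals a pipeline defect, not a hard
problem.

The same pipeline is available from the shell:

```bash
fcau simulate --n-per-class 24 --seed 7 --out runs/raw
fcau preprocess --in runs/raw --out runs/prep --no-augment --seed 0
fcau enhance --in runs/prep --out runs/fce --method fce
fcau train --data runs/fce --out runs/ckpt --seed 0
fcau evaluate --ckpt runs/ckpt.npz --data runs/fce --out runs/report.json
```

plus `crossval`, `explain`, `ttest` and an end-to-end `pipeline`
subcommand.

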