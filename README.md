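# svcikit

Identification of subcortical vascular cognitive impairment (SVCI) from
diffusion-tensor scalar maps, with individual-level multidomain cognitive
risk profiling.

## The problem

Subcortical ischemic vascular disease (SIVD) is common in aging populations;
roughly half of affected patients progress to SVCI. Separating the two
usually requires a full neuropsychological battery (MMSE, MoCA, Immediate
and Delayed Recall, TMT-A, TMT-B), which is slow and often impractical.
`svcikit` implements an imaging-only alternative for researchers working
with DTI: the four diffusion scalar maps (FA, MD, AD, RD) on a common grid
are enough to (a) classify SVCI vs SIVD, (b) localize the white-matter
regions driving the decision, and (c) stratify each patient's risk across
six cognitive domains.

## What it computes

1. **Classifier.** A 3D densely-connected network over any of the 15
   channel combinations of {FA, MD, AD, RD}: four dense blocks (one
   bottleneck dense layer each, growth *g* feature maps), three
   convolution + stride-2 average-pool transitions, global average pooling,
   dropout 0.5, and a two-way softmax giving the SVCI probability
   `p(SVCI | x)`. Training: cross-entropy, Adam (weight decay 1e-3), cosine
   annealed learning rate, on-the-fly intensity/flip/zoom augmentation,
   stratified 80/20 split with 5-fold CV on the training side.
2. **Cross-site adaptation.** Domain-adversarial training (DANN): a domain
   classifier attached to the pooled features through a gradient-reversal
   layer (identity forward, gradient scaled by −λ backward), with
   λ(p) = 2/(1+e^(−5p)) − 1 on training progress p and total loss
   `L_cls + α (L_dom_src + L_dom_tgt)`, α = 0.1. Target labels are never
   read.
3. **Saliency.** Guided backpropagation (relevance gated at every rectifier
   by positive pre-activation *and* positive incoming gradient), a voxel-wise
   one-sample t-test across patients, and family-wise correction by
   Gaussian-random-field theory (expected Euler characteristic), projected
   onto a white-matter atlas as ranked contribution weights.
4. **Cognition mapping.** Voxel-wise mutual information (bits, joint
   histogram) between scalar maps and each cognitive score, with
   permutation-based significance and GRF correction; Dice/Jaccard/SSIM/
   Jensen–Shannon similarity between the six MI maps.
5. **Risk profiling.** The global SSIM between each patient's saliency map
   and each scale's MI map; per scale, 1-D K-means (K from the elbow of the
   log within-cluster dispersion) into low/moderate/high risk, compared with
   Kruskal–Wallis and Dunn's test (Bonferroni), plus an 80%-subsample
   stability analysis.

A synthetic cohort generator (two diagnosis groups × two sites, planted
focal lesions that lower FA and raise diffusivities, lesion-linked scores
with clinical sign conventions, scanner-like site effects) gives every stage
a ground truth, so the whole workflow is testable without patient data.

The compute backend (`svcikit.nn`) is a compact numpy layer library —
3D convolution, batch norm, pooling, dropout, Adam — with the two hooks the
science needs: guided-mode rectifier backprop and gradient reversal.

## Worked example

```python
import numpy as np
from svcikit import io as vio, synthetic
from svcikit.densenet import (DenseNetConfig, TrainConfig, build_model,
                              predict_proba, split_and_cv, train)
from svcikit.evaluate import auc_trapezoid

cfg = synthetic.SyntheticConfig(grid_shape=(16, 16, 16), n_per_cell=30,
                                n_regions=8, lesion_regions=(1, 2, 3), seed=1)
records, atlas = synthetic.generate_cohort(cfg)
labels = np.array([r.group == "SVCI" for r in records], int)
site = np.array([r.site for r in records])
internal = np.where(site == "internal")[0]

x = vio.normalize_intensity(
    vio.stack_combination([r.volumes for r in records], ("FA", "MD")))
split = split_and_cv(labels[internal], seed=0)
model = build_model(DenseNetConfig(in_channels=2, init_filters=24, growth=12))
train(model, x[internal[split["train"]]], labels[internal[split["train"]]],
      TrainConfig(epochs=25, lr=1e-3, seed=0))
probs = predict_proba(model, x[internal[split["test"]]])
auc, _, _ = auc_trapezoid(probs, labels[internal[split["test"]]])
print(f"held-out AUC = {auc:.3f}")
```

This prints `held-out AUC = 0.944` (12-subject internal test set): the
network recovers the planted 1-SD lesion effect from the FA-MD combination.
Downstream, `svcikit.saliency.guided_backprop` + `grf_correct` localize the
signal (group saliency mask vs planted lesion Dice ≈ 0.58 in the acceptance
run), and `svcikit.profiling.subject_scale_ssim` + `kmeans_stratify` rank
patients by lesion burden (SSIM vs planted tier Spearman ρ ≈ 0.8).

There is also a thin CLI: `svcikit simulate --out dir/ --seed 1` writes a
NIfTI cohort; `svcikit run --out dir/` executes the configured stages.

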