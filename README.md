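# msrn — multi-scale sparse residual networks for retinal OCT

`msrn` is a research package for **multi-label disease classification of
retinal OCT B-scans**: one scan may simultaneously show age-related
macular degeneration (AMD, drusen deposits), epiretinal membrane (ERM, a
thin scar-tissue film on the inner retinal surface) and macular edema
(ME, intraretinal fluid cavities), or be Normal. It is written for
researchers who want a transparent, dependency-light reference
implementation of the architecture family, its training and evaluation
protocol, and an inspectable synthetic data source — the clinical
dataset this line of work was developed on is private.

The package provides:

* the **SRN** (sparse residual network) family — lightweight 6-block CNNs
  (8/10/12 conv layers; 1.80/1.96/2.59 M parameters) built from two design
  principles: *kernel factorization* (a 5×5 convolution → two 3×3
  convolutions, 18/25 of the parameters, 25/18 cheaper per position) and
  *residual learning* (per-block skips, 1×1 projections at channel
  transitions);
* **MS-SRN** — a two-branch multi-scale model (448 px local + 224 px
  global branch, independent trunks, fused 1024-d feature, 5.18 M
  parameters) for lesions that are only evident at a particular scale;
* the multi-label sigmoid cross-entropy loss
  `L = −(1/C) Σᵢ yᵢ log ŷᵢ + (1−yᵢ) log(1−ŷᵢ)`;
* per-class and micro-averaged Acc/Sen/Spe, exact-match ("patient-level")
  accuracy, and Student t-test seed comparisons;
* Grad-CAM heatmaps, including per-branch maps for the multi-scale model;
* a **seedable OCT phantom generator** (layered retina, speckle, three
  lesion types with ground-truth boxes) so every stage is testable;
* a small **pure-NumPy network core** (im2col convolutions, manual
  backprop, SGD with momentum) — no deep-learning framework required.

The network stack and training loop are CPU-scale by design; see
`docs/methods.md` for the model details and the problem sizes the test
suite uses.

## Worked example

Parameter and multiply–accumulate summary of the model family
(`macs` at a 224×224 input for the single-scale variants):

```
$ msrn summarize --variants 8,10,12 --ms 224,448 --resnets 18,101 --input-side 224
name,params_M,macs
SRN-8,1.8,839747584
SRN-10,1.96,1070958592
SRN-12,2.59,1302169600
MS-SRN(224+448),5.18,6510841856
ResNet-18,11.18,
ResNet-101,42.51,
```

The three SRN depths round to 1.80/1.96/2.59 M learnable parameters, the
two-branch multi-scale model to 5.18 M — about half a ResNet-18 and 6.1%
of a ResNet-101 with the same 4-way head. MAC counts are raw
multiply–accumulates (k²·C_in·C_out·positions) and are not comparable to
"FLOPs" figures from other toolchains.

End-to-end on synthetic data — a desk-scale run (64 px inputs, 16
epochs) that finishes in minutes on one CPU:

```
$ msrn generate --n 600 --seed 1 --side 128 --out data/
wrote 600 phantoms to data
  amd     123
  erm     171
  me      55
  normal  313

$ msrn train --manifest data/manifest.csv --variant 8-layer --sizes 64 \
      --seeds 0,1,2 --epochs 16 --batch-size 16 --lr 0.015 --no-augment \
      --eval-every 2 --out runs/srn8
micro_accuracy: 90.62 ± 7.68
micro_sensitivity: 78.03 ± 14.39
micro_specificity: 95.40 ± 5.23

$ msrn evaluate --checkpoint runs/srn8/checkpoint_seed0.npz \
      --manifest data/manifest.csv --out runs/eval
[64] muAcc=0.9671 muSen=0.9139 muSpe=0.9873 patient=0.4933

$ msrn gradcam --checkpoint runs/srn8/checkpoint_seed0.npz \
      --image data/phantom_00007.png --cls me --out cams/
cams/phantom_00007_cam_me.png
```

The train aggregate is the across-seed `mean ± std` on the percent
scale, computed on each seed's held-out 20% split; the evaluate line
re-scores one checkpoint on the full manifest (`patient` is exact-match
accuracy — every label bit must be right, which is why it is much lower
than the micro metrics). Seed-to-seed spread is large at this tiny
problem size. Every run writes a `run_record.json` with the resolved
configuration and seeds.

Library use mirrors the CLI:

```python
from msrn import build_srn, srn_config, count_parameters

net = build_srn(srn_config("12-layer"), seed=0)
print(count_parameters(net).parameter_count)   # 2588772
```

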