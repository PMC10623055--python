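# pcgnet

Segmentation of multiple structures in 2-D grayscale medical-image slices,
aimed at the hard regime of *organs-at-risk* contouring in head-and-neck CT:
a handful of large structures (brainstem, mandible, parotid) next to very
small ones (optic nerve, optic chiasm — well under 0.5% of the pixels), with
labeled data scarce and imaging protocols drifting between institutions.

The package implements PCG-Net, a parallel-encoder graph-fusion network,
together with its training recipes, evaluation metrics, and a synthetic
phantom generator that stands in for the (private) clinical datasets:

- **Parallel encoder** — a depth-2 nested-U CNN branch for local detail and a
  **gated axial transformer** branch for global context. Axial attention
  factorises self-attention into height/width passes (O(HW·(H+W)) instead of
  O((HW)²)); learned positional tables r_q, r_k, r_v enter the logits and
  values through learned scalar gates G_Q, G_K, G_V1, G_V2:

      logit(j,w) = q_j·k_w/√d + G_Q·q_j·r_q[j,w] + G_K·k_w·r_k[j,w]
      y_j = Σ_w softmax_w(logit) · (G_V1·v_w + G_V2·r_v[j,w])

- **Cascade graph module (CGM)** at every skip level: dilated-convolution
  node sets from both branches, intra-/inter-set edge maps from linear pair
  sums (α·first + β·second), sigmoid-gated messages and a convolutional GRU
  node update; after t steps the fused map feeds the decoder.
- **Progressive refinement decoder** — four prediction branches, each σ_i(γ_i)
  with the upsampled previous feature concatenated and added elementwise;
  deep supervision at all scales.
- **Focal-dice loss** l_DF = l_DSC + α·l_Focal (α=2, β=η=1) over soft
  confusion counts, designed for extreme foreground/background imbalance.
- **Siamese contrastive pretraining** of the encoder on unlabeled images with
  the stop-gradient negative-cosine loss L = ½S(p1, sg z2) + ½S(p2, sg z1),
  then weight transfer into the segmentation network.
- **Metrics**: per-structure DSC, Jaccard, Hausdorff distance and average
  symmetric surface distance (mm), in the usual per-organ / mean /
  small-volume-mean table layout, plus GLCM texture features for dataset
  heterogeneity diagnostics.

Everything runs on plain numpy with reverse-mode autodiff (`autograd`) — no
GPU framework required; see `docs/methods.md` for the architecture details,
numerics, and the desk-scale study conditions.

## Worked example

Train the full (level-5) variant on synthetic phantoms and evaluate on a
held-out set — about four minutes on one CPU:

```python
import numpy as np
from pcgnet import PhantomConfig, generate_dataset, PCGNetSegmenter
from pcgnet.metrics import evaluate_label_map, aggregate_reports

cfg = PhantomConfig(image_size=64, seed=0)
train = generate_dataset(48, cfg, "train")
val = generate_dataset(16, cfg, "val")

est = PCGNetSegmenter(level="level5", image_size=64, heads=(1, 1, 2, 2), epochs=15, seed=0)
est.fit(np.stack([s.image for s in train]), np.stack([s.label for s in train]),
        np.stack([s.image for s in val]), np.stack([s.label for s in val]))
print(f"best validation mean DSC: {est.best_val_dsc_:.3f}")

test = generate_dataset(8, cfg, "test")
pred = est.predict(np.stack([s.image for s in test]))
rows = [evaluate_label_map(pred[i], test[i].label, 6, spacing=1.0) for i in range(8)]
report = aggregate_reports(rows, num_classes=6, small_structures=(4, 5))
for name, row in report.per_structure.items():
    print(f"{name}: DSC={row['dsc']:.3f}  Jaccard={row['jaccard']:.3f}  "
          f"HD={row['hd']:.2f} mm  ASSD={row['assd']:.2f} mm")
print(f"mean DSC: {report.mean['dsc']:.3f}; small-volume mean DSC: {report.mean_small['dsc']:.3f}")
```

Output:

```
best validation mean DSC: 0.754
structure_1: DSC=0.964  Jaccard=0.931  HD=1.00 mm  ASSD=0.26 mm
structure_2: DSC=0.979  Jaccard=0.959  HD=1.00 mm  ASSD=0.19 mm
structure_3: DSC=0.966  Jaccard=0.935  HD=1.00 mm  ASSD=0.21 mm
structure_4: DSC=0.883  Jaccard=0.794  HD=1.10 mm  ASSD=0.22 mm
structure_5: DSC=0.000  Jaccard=0.000  HD=nan mm  ASSD=nan mm
mean DSC: 0.758; small-volume mean DSC: 0.441
```

Structures 1–3 are the large organs (superellipse phantoms with distinct
intensity bands, each a few percent of the image); structures 4 and 5 are
the optic-nerve/chiasm-like targets. Structure 4 (~16 px) is segmented well;
structure 5 (~8 px and deliberately the lowest-contrast structure) is below
what this CPU-scale model detects in 15 epochs — its HD/ASSD are undefined
(NaN, flagged) because the predicted mask is empty. This is exactly the
size/contrast imbalance the focal-dice loss and the fusion architecture
target, and `docs/methods.md` discusses where the desk-scale detection floor
comes from. DSC/Jaccard measure volume overlap in [0, 1]; HD and ASSD
measure worst-case and average boundary disagreement in millimetres
(1 px = 1 mm here).

The estimators follow sklearn conventions (`get_params`/`set_params`/
`clone`, fitted attributes with trailing underscores), and a CLI wraps the
same machinery:

```bash
pcgnet make-phantoms --n 48 --size 48 --split train --out-dir data/
pcgnet pretrain --data data/ --epochs 10 --out encoder.npz
pcgnet train --data data/ --level level5 --init contrastive:encoder.npz --out model.npz
pcgnet evaluate --ckpt model.npz --data data/ --report report.json
pcgnet predict --ckpt model.npz --in data/test_0000_image.png --out pred.png
```

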