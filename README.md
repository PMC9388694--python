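# octskin

Few-label transfer segmentation of **epidermis and scab in skin OCT**, with
en-face epidermal thickness mapping.

Epidermal thickness is a key readout for assessing skin conditions (wound
healing, burns, inflammatory disease), and optical coherence tomography (OCT)
can measure it non-invasively — if the epidermis can be segmented reliably.
Expert annotation of clinical volumes is scarce, while annotated data from
rodent models is abundant; but rodent and human skin differ sharply (rodent
epidermis < 25 μm, human > 50 μm, with different layer contrast), so a model
trained on one does not transfer directly to the other.

`octskin` implements a semisupervised answer to that domain shift:

1. **Pretrain** a multitask U-Net — shared encoder `A_s`, a 3-class object
   head `A_O` (background / epidermis / scab) and a contour head `A_C`
   (boundary band) — on the source domain, minimizing
   `L_total = λ·ψ(θ) − Σ_x log N_o(x, l_o(x)) − Σ_x log N_c(x, l_c(x))`.
2. **Fine-tune** on the target domain with only *one or three labeled
   B-scans per volume*, minimizing the per-pixel mean cross-entropy
   `L_transfer = −mean_x Σ_c y_c log p_c` from the pretrained parameters.
3. **Infer**: fuse the object and contour probability maps into masks,
   and reduce them to per-A-line epidermal thickness
   (`thickness = lower − upper`, 8 μm/px by default).

Segmentation quality is evaluated with IoU, Dice (`DSC = 2·IoU/(1+IoU)`),
average symmetric surface distance (ASSD) and Hausdorff distance (HD, μm).
Because no clinical data ships with the package, a synthetic phantom
generator provides both domains with analytic ground truth: layered
speckle B-scans whose source/target presets encode the thin/thick,
high/low-contrast shift.  The network layers and their backpropagation are
implemented directly in numpy (validated against finite differences), so
everything runs deterministically on a CPU.

## Worked example

```python
import numpy as np
from octskin import MultitaskUNetSegmenter
from octskin.experiments import make_domain_volumes
from octskin.infer import mean_thickness, thickness_map
from octskin.train import select_labeled_subset

source  = make_domain_volumes("source", 4, 8, base_seed=1000)  # rodent-like
target  = make_domain_volumes("target", 8, 8, base_seed=1100)  # human-like
heldout = make_domain_volumes("target", 8, 4, base_seed=1200)

est = MultitaskUNetSegmenter(epochs=30, random_state=1)
est.fit(np.concatenate([v.images for v in source]),
        np.concatenate([v.class_masks for v in source]))
print(f"pretraining loss: {est.loss_trace_[0]:.1f} -> {est.loss_trace_[-1]:.1f}")

X_held = np.concatenate([v.images for v in heldout])
y_held = np.concatenate([v.class_masks for v in heldout])
print(f"baseline epidermis Dice on target domain: {est.score(X_held, y_held):.3f}")

subset = select_labeled_subset(target, 1, seed=1)   # one label per volume
X_ft = np.concatenate([v.images[subset[v.volume_id]] for v in target])
y_ft = np.concatenate([v.class_masks[subset[v.volume_id]] for v in target])
est.finetune(X_ft, y_ft, learning_rate=1e-4, epochs=50)
print(f"method #1 epidermis Dice on target domain: {est.score(X_held, y_held):.3f}")

tmap = est.thickness(heldout[0].images)
mean_um, sd_um, n = mean_thickness(tmap)
truth_um, _, _ = mean_thickness(thickness_map(heldout[0].class_masks))
print(f"volume {heldout[0].volume_id}: mean epidermal thickness "
      f"{mean_um:.1f} +/- {sd_um:.1f} um over {n} A-lines (truth {truth_um:.1f} um)")
```

Output:

```
pretraining loss: 7104.5 -> 785.6
baseline epidermis Dice on target domain: 0.251
method #1 epidermis Dice on target domain: 0.843
volume target-00: mean epidermal thickness 67.7 +/- 16.9 um over 256 A-lines (truth 72.4 um)
```

Reading it: the model pretrained on thin, high-contrast source phantoms
collapses on the thick, low-contrast target domain (Dice 0.25); fine-tuning
with a single labeled B-scan per volume recovers Dice 0.84; and the derived
mean epidermal thickness of a held-out volume lands within ~5 μm (under one
pixel) of the analytic truth.

## Command line

The same pipeline is scriptable via the `octskin` umbrella command:

```bash
octskin phantom  --domain target --session S1 --n-bscans 16 --seed 3 --out ph0/
octskin pretrain --manifest source.csv --epochs 30 --seed 0 --out pretrained.npz
octskin finetune --checkpoint pretrained.npz --manifest target.csv \
                 --strategy method1 --epochs 50 --lr 1e-4 --out tuned.npz
octskin segment  --checkpoint tuned.npz --volume ph0/volume.tiff --out masks.tiff
octskin thickness --masks masks.tiff --pitch-um 8 --out map.tiff --csv stats.csv
octskin evaluate --pred preds/ --gt truths/ --out report.csv
octskin report   --manifest target.csv
```

Every command records a provenance JSON (config + seeds) next to its output.

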