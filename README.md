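# priorseg

Fully automated multiclass brain-tissue segmentation for T1-weighted
MRI, built around a 3-D U-Net that takes a registration-derived
**spatial prior** as a second input channel.  The package is aimed at
people building or studying segmentation pipelines for *clinical*
material — heterogeneous scanners, low tissue contrast, lesions — where
intensity alone is unreliable and an atlas-propagated prior stabilizes
the small, low-contrast classes (deep gray matter, brainstem).

Everything is testable end to end without clinical data: a synthetic
phantom module generates template + subject cohorts (six tissue
compartments, controllable deep-gray/WM contrast, bias field, noise,
random smooth anatomy and head pose, T1-hypointense lesions in white or
gray matter) that emulate the statistical structure of a clinical
cohort.

## The method in brief

Voxels get one of six tissue labels (1 CSF, 2 cortical GM, 3 WM, 4 deep
GM, 5 brainstem, 6 cerebellum) or background 0.  The pipeline is

```
skull strip → crop → resample to cube → z-score → spatial prior → U-Net → native space
```

* **Network** — 4-down/4-up encoder–decoder with residual context and
  localization modules, 3×3×3 kernels, instance norm + leaky ReLU, and
  deep supervision by summed upsampled side outputs.
* **Losses** — multi-label soft Dice (6 sigmoid channels, background by
  the rule "no probability > 0.5 ⇒ background"), categorical
  cross-entropy, and median-frequency-weighted cross-entropy with
  weights `w_i = median(n_b)/median(n_i)` (7 softmax channels).
* **Prior** — rigid → affine → deformable registration of the subject
  T1 to a template; the template segmentation is warped back with
  smoothed-label interpolation (σ = 0.2 vox) and fed to the network as
  one channel.  The same warped labels serve as the
  registration-to-atlas baseline.
* **Evaluation** — per-tissue Dice, volume similarity
  `1 − |V_X−V_Y|/(V_X+V_Y)`, directed 95th-percentile Hausdorff distance
  in mm, intra-lesion accuracy (WM-lesion voxels predicted as WM;
  GM-lesion voxels as cortical or deep GM), and two-sample Z tests with
  the |Z| > 2.5 rule.
* **Transfer** — fine-tuning from a checkpoint, including a
  leave-one-out protocol (train n−2 / validate 1 / predict the held-out
  subject) for porting to an externally labeled dataset, with a
  harmonizer for 10-class external label schemes.

The networks run on a small NumPy autodiff engine written for this
package (gradients verified against finite differences), so the whole
stack is deterministic on a single CPU at desk scale.  Registration is
delegated to SimpleITK behind the package's own transform-chain
interface.  See `docs/methods.md` for the full model description,
parameter defaults and limitations.

## Worked example

```python
import numpy as np
from priorseg.phantom import PhantomSpec, generate_cohort
from priorseg.pipeline import prepare_samples, evaluate_samples
from priorseg.training import TrainConfig, net_config_for_loss, train
from priorseg.metrics import dice
from priorseg.grid import TISSUE_CLASSES

spec = PhantomSpec()                       # 64-cube phantom, default conditions
template, subjects = generate_cohort(spec, 12, seed=11, fractions=(0.667, 0, 0.333))
samples = prepare_samples(subjects, cube=32, use_prior=True, template=template)
train_s = [s for s in samples if s["split"] == "train"]
test_s  = [s for s in samples if s["split"] == "test"]

baseline = np.mean([[dice(s["prior"], s["labels"], c) for c in TISSUE_CLASSES]
                    for s in test_s])
print(f"registration-only baseline, overall Dice: {baseline:.3f}")

cfg = TrainConfig(loss="dice", use_prior=True, max_epochs=150,
                  augment=True, initial_lr=0.002, seed=0)
net_cfg = net_config_for_loss("dice", in_channels=2, base_filters=8, input_shape=32)
result = train(train_s, net_cfg, cfg)
report = evaluate_samples(result.model, test_s)
print(f"trained network, overall Dice: {report['summary']['overall_dice_mean']:.3f}")
```

prints (≈6 minutes on one CPU):

```
registration-only baseline, overall Dice: 0.703
trained network, overall Dice: 0.813
```

The registration prior alone is a crude segmenter (overall Dice ~0.70);
the prior-augmented network trained on eight phantom subjects beats it
in every tissue class on the held-out subjects, the ordering the method
is designed to produce.

A CLI wraps the same functionality: `priorseg phantom make-cohort`,
`priorseg prior build`, `priorseg train`, `priorseg segment`,
`priorseg evaluate` (see `--help` on each).

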