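# virtualstain

Label-free imaging keeps cells unperturbed, but bright-field microscopy
barely shows nuclei — let alone whether a nucleus is healthy or
fragmenting in apoptosis. `virtualstain` learns to translate a
multi-slice bright-field z-stack into the fluorescent nuclei image a DNA
stain would give, while *simultaneously* segmenting every pixel into
healthy / apoptotic / background. It is aimed at cell biologists and
image-analysis researchers who want stain-free apoptosis readouts, and
at method developers studying attention-augmented image-to-image GANs.

## The model

The core is a conditional GAN whose generator has one shared encoder and
two decoders: an image path ending in Tanh (2 channels: healthy,
apoptotic nuclei) and a mask path ending in SoftMax (3 classes — one
more channel than the image path, for background). The translation is
the probability-gated product

&nbsp;&nbsp;&nbsp;&nbsp;T(x)ᶜ = G_img(x)ᶜ · G_mask(x)ᶜ,  c ∈ {healthy, apoptotic}.

**Cross-attention modules** between the decoders' up-sampling layers let
the segmentation path hand long-range spatial structure to the image
path: queries come from the image features, keys/values from the mask
features, with SAGAN-style γ-residuals (identity at initialization) and
spectral normalization everywhere. A 4-digit binary *placement code*
says which of the 4 decoder intervals carry attention ("0011" = the two
intervals with the largest feature maps). A PatchGAN discriminator
scores bright-field/fluorescence pairs patchwise. The generator
objective is

&nbsp;&nbsp;&nbsp;&nbsp;L = L_adv + λ·[α·L1 + (1−α)·(1−SSIM)] + w(e)·CE(mask),

with λ = 100, α = 0.5 and a dynamic mask weight w(e) that starts at 250
and decays 10% every 1,500 epochs to a floor of 2.5, so segmentation
converges first and then cedes priority to image synthesis.

The package also implements the full ground-truth preparation pipeline
(per-slice normalization, max projection, CLAHE, iterated
Gaussian/median filtering, Otsu + marker-controlled watershed, and a
variance-based healthy/apoptotic split of the segmented nuclei), a
seeded synthetic-scene generator so everything runs without downloads,
nucleus-level detection/classification scoring, and slice-count
experiment harnesses. The networks run on a compact NumPy autodiff
engine built into the package — everything trains and evaluates on one
CPU at desk scale.

## Worked example

```python
from virtualstain import (GeneratorConfig, TrainConfig, TranslationGAN,
                          generate_dataset, score_detection)
from virtualstain.synthetic import desk_scene_config
from virtualstain.autograd import Tensor

dataset = generate_dataset(16, desk_scene_config(seed=0))
model = TranslationGAN(
    dataset,
    GeneratorConfig(placement="0011", input_slices=13, base_channels=8, seed=0),
    train_config=TrainConfig(batch_size=2, lr_G=2e-3, lr_D=2e-3, epochs=30, seed=0),
)
result = model.fit()
print(result.summary())

generator = result.restore_best()
generator.eval()
for i in dataset.split["test"]:
    scene = dataset.scenes[i]
    out = generator(Tensor(scene.bright_field[None]))
    report = score_detection(out.mask.data[0], scene.instances)
    print(f"held-out scene {i}: accuracy={report.accuracy:.2f}, "
          f"false_neg={report.false_negative_rate:.2f}, "
          f"misclass={report.misclassification_rate:.2f}")
```

prints (about two minutes on one CPU):

```
Bright-field → fluorescence translation GAN
==============================================
variant            dual
placement code     0011
attention modules  2
parameters (G)     1,344,341
epochs run         30
best epoch         29
best val MAE       0.0203
final loss_D       1.4029
final loss_G       62.3926
final val SSIM     0.8191
final val PSNR     21.30 dB

held-out scene 15: accuracy=0.60, false_neg=0.40, misclass=0.00
```

Best validation MAE of 0.020 on the [0,1] intensity scale and SSIM 0.82
mean the translated fluorescence closely tracks the target; on the
held-out scene the model detects and correctly state-classifies 3 of 5
nuclei after only 30 epochs (chance on matched nuclei is 1/3), missing
two and misclassifying none. Full-scale training runs thousands of
epochs.

## Command line

```bash
virtualstain simulate --n-scenes 16 --out data/ --seed 0
virtualstain train --data data/ --out run/ --placement 0011
virtualstain translate --checkpoint run/checkpoint.npz --input stack.tif --out out/
virtualstain evaluate --pred-mask out/class_mask.png \
    --truth-labels data/scene_0000_labels.tif --truth-states states.tsv
virtualstain slice-experiment --mode fixed_depth --out slices.tsv
virtualstain preprocess --fluorescent zstack.tif --bright-field bf.tif --out prep/
```

Stacks travel as multi-page TIFF; class masks as PNG (black =
background, gray = healthy, white = apoptotic); reports as
tab-delimited text. A single YAML file can configure every module.

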