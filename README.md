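# usborder

Evaluation and explainability toolkit for ultrasound segmentation that
treats anatomical borders the way clinicians do: part of every annotated
boundary follows a visible, strongly reflecting tissue interface
(**distinct** border), and the rest is interpolated from anatomical
knowledge where the image gives no edge evidence (**completed** border).
Scoring these two parts separately reveals whether a network actually
reads interface evidence or leans on shape priors — a distinction that a
single Dice number hides.

## Method

Given an image `I` and an expert border mask `B`, the distinct border is
the element-wise (Hadamard) product of the border with a binary edge map
of the image:

```
B_distinct = Thres(I * K_smooth * K_sobel) ⊙ B,     B_completed = B \ B_distinct
```

i.e. Gaussian smoothing, Sobel gradient magnitude, and a threshold (Otsu
on the max-normalized gradient by default). The two parts always
partition the border.

Prediction quality is decomposed over the reference (ground-truth)
border: a reference-border voxel is a true positive when a predicted
border voxel lies within a small Chebyshev tolerance, giving per-case
percentages `B_TP = B_Distinct + B_Completed` (exactly additive).
Standard per-class metrics — Dice, 95th-percentile Hausdorff distance in
mm, and normalized surface distance — are computed alongside.

Model decisions are explained with **Seg-Grad-CAM**: for a class `c` and
a pixel set `Y^c` (a distinct border, a completed border, the
background, or a whole structure), the localization map is

```
L^c = ReLU( Σ_f [ (1/wh) Σ_ij ∂Y^c/∂A^f_ij ] · A^f )
```

with `A^f` the feature maps of a chosen convolutional layer and the
bracket the global average pooling of the gradients.

Because real ultrasound datasets are large and slow to obtain, the
package ships a synthetic **speckle phantom** generator whose
distinct/completed decomposition is known by construction (bright,
depth-attenuated interface bands; engineered signal-dropout sectors;
multiplicative log-normal speckle) plus tiny numpy segmentation models
(an affine model with closed-form gradients, and a trainable miniature
encoder–decoder) that satisfy the model-adapter contract.

## Worked example

```python
import numpy as np
from usborder import (PhantomSpec, generate_phantom, compute_edge_map,
                      split_all_classes, reference_border_fractions,
                      simulate_prediction, extract_border, tp_decomposition)

case = generate_phantom(PhantomSpec(dropout_fraction=0.4, seed=0))
edges = compute_edge_map(case.image)
pred = simulate_prediction(case.labels, "elastic_jitter", 6, seed=0)

for split in split_all_classes(case.labels, edges):
    d, c = reference_border_fractions(split)
    row = tp_decomposition(split, extract_border(pred, split.class_id),
                           match_tolerance=1)
    print(f"class {split.class_id}: reference {d:5.1f}/{c:5.1f}  "
          f"TP {row.tp_total_pct:5.1f} = {row.tp_distinct_pct:5.1f} "
          f"+ {row.tp_completed_pct:5.1f}")
```

prints

```
class 1: reference  61.0/ 39.0  TP  54.5 =  31.2 +  23.4
class 2: reference  60.4/ 39.6  TP  99.1 =  60.4 +  38.7
class 3: reference  45.9/ 54.1  TP  90.6 =  42.4 +  48.2
```

Each phantom structure was designed with 40% of its border in dropout
sectors; the image-driven reference split measures roughly the designed
fractions per class (the per-class spread reflects each blob's geometry).
The warped prediction recovers between 55% and 99% of the reference
border depending on how the displacement field hit each structure, and
the distinct + completed columns sum to the total exactly.

The same pipeline runs from the shell:

```
usborder phantom --n 10 --out data/
usborder split  --image data/phantom_000_image.nii.gz \
                --labels data/phantom_000_labels.nii.gz --out split/
usborder metrics --gt gt/ --pred pred/ --image img/ --out report/
usborder cam --image ... --labels ... --model small_unet.npz \
             --target distinct --class-id 1 --out cam/
usborder validate --report report/
```

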