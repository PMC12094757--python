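# fracim

Fractional-order convolution masks and region-adaptive enhancement for
single-channel (grayscale) medical images — ultrasound, CT, MRI, X-ray —
with a full-reference quality-metric stack (PSNR, SSIM, CNR) and a seeded
phantom generator so every stage is testable without clinical data.

## The method

Classical gradient operators (Sobel, Prewitt, Laplacian-of-Gaussian)
either mute fine texture or amplify noise. Fractional differentiation of
order α ∈ (0, 1] interpolates between the identity (α → 0) and the first
difference (α = 1), which lets a filter boost mid-frequency texture while
leaving smooth anatomy almost untouched.

The masks here come from the Grünwald–Letnikov (GL) discretization of the
Atangana–Baleanu fractional integral. With the normalization function

    M(α) = 1 − α + α / Γ(α)

the first four series terms give the mask weights

    ρ0 = 1/M(α),   ρ1 = α/(2M(α)),
    ρ2 = (α³ − α²)/(2M(α)),   ρ3 = (α² − α⁴)/(6M(α)).

From ρ0 and ρ1 the package builds, for each of eight compass directions:
3×3 **directional** masks (ρ0 center, ρ1 at the neighbor), **scaled**
masks (the weight spread evenly over the neighborhood), antisymmetric
zero-sum **bidirectional** masks (difference of opposite scaled masks),
and a combined 5×5 **composite** mask that is 180°-antisymmetric and
zero-sum for every α. Each mask family exists in a `canonical` variant
(symmetry-consistent construction; the default) and an `as_printed`
variant that reproduces the original published tables verbatim,
irregularities included.

Enhancement is region-adaptive: a Sobel gradient-magnitude map is split
into smooth / texture / edge regions by two thresholds (the mean gradient,
and the mean of gradients above it), one mask is built per region at that
region's order (defaults α = 0.4 / 0.6 / 0.8), and the scaled response is
added back:

    enhanced = clip(image + λ · response, 0, 255)

## Worked example

```python
import numpy as np
from fracim import (
    PhantomSpec, generate_phantom, enhance, segment_regions,
    rho_coefficients, composite_mask_5x5, psnr, ssim,
)

print(rho_coefficients(0.5).as_tuple())
# (1.2786173882220704, 0.3196543470555176, -0.0799135867638794, 0.039956793381939706)

img, labels = generate_phantom(PhantomSpec(seed=0))   # 128x128, noisy
regions = segment_regions(img)
print(round(regions.t1, 2), round(regions.t2, 2))
# 46.72 171.95
print(round(float(np.mean(regions.labels == labels)), 3))
# 0.925

out = enhance(img)                                    # adaptive, 5x5 composite
print(round(psnr(img, out), 2), round(ssim(img, out)[0], 3))
# 15.84 0.269
```

The ρ tuple is the coefficient set at α = 0.5 (ρ0 = 1/M, and the α = 1
limit would be (1, 0.5, 0, 0)). The two thresholds split the gradient
image into the three regions, which recover the phantom's ground-truth
layout on 92.5 % of pixels. The PSNR/SSIM pair measures how strongly the
default enhancement perturbs its input — texture and edges move, smooth
plateaus stay.

The same pipeline is available from the shell:

```
fracim phantom p.png --seed 0
fracim enhance p.png out.png --alpha-edge 0.8 --mask-kind composite
fracim metrics p.png out.png
fracim masks --alpha 0.5 --kind composite
fracim bench sweep.csv --alphas 0.4,0.6,0.8
```

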