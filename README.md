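# unls — two-phase kidney segmentation for DCE-MRI

Dynamic contrast-enhanced MRI of transplanted kidneys produces, per
patient, a series of ~80 rapidly acquired 2-D scans whose tissue
intensities change as the contrast agent perfuses. Delineating the kidney
in every frame is the prerequisite for renal-function assessment, and it is
hard precisely where it matters most: in the low-contrast pre-enhancement
frames. Pixel-wise CNN segmenters learn the intensity statistics well but
not the organ's shape, so they leave false-positive islands in the
background and false-negative holes inside the kidney.

`unls` implements a two-phase remedy aimed at researchers in medical image
analysis:

1. **Phase 1** supplies a per-pixel kidney probability map
   *U<sub>L</sub>(x, y)* (*L* ∈ {K, B}, *U<sub>K</sub> + U<sub>B</sub> = 1*)
   — from a CNN, a two-class Gaussian intensity posterior, or a synthetic
   oracle with controlled corruption.
2. **Phase 2** refines it with a level set contour (zero level of φ,
   positive inside the kidney) that minimises

   *E(φ) = λ₁ ∫ δ<sub>ε</sub>(φ) |∇φ| + λ₂ ∫ [V<sub>ε</sub>(φ) U_B P_B +
   (1 − V<sub>ε</sub>(φ)) U_K P_K]*

   where *V<sub>ε</sub>*, *δ<sub>ε</sub>* are the sin/cos-regularised
   Heaviside and Dirac functions and *P<sub>L</sub>(x, y)* is a **Bayesian
   probabilistic shape prior** built from *N* co-registered expert
   segmentations. With pseudo-count β and *O(x, y)* the number of labels
   seen at a pixel, disputed pixels (*O* = 2) get
   *P<sub>L</sub> = (N<sub>L</sub> + β)/(N + 2β)* and unanimous pixels
   (*O* = 1) get *N/(N + 1)* for the seen and *1/(N + 1)* for the unseen
   label — never a degenerate 0 or 1, so the prior can always veto a
   confident-but-misplaced probability map. Gradient descent evolves

   *φ ← φ + τ δ<sub>ε</sub>(φ) [λ₁ div(∇φ/|∇φ|) + λ₂ U_K P_K − λ₂ U_B P_B]*.

Defaults: λ₁ = λ₂ = 6, ε = 1.5, τ = 0.8, β = 1.

Because clinical DCE-MRI data cannot be redistributed, the package ships a
first-class phantom simulator: bean-shaped kidneys, gamma-variate
enhancement kinetics, static background structures, Gaussian noise, and
probability-map corruption that mimics CNN failure modes.

## Worked example

```python
import unls
from unls.levelset import InitSpec
from unls.phantom import CorruptionConfig
from unls.pipeline import pick_frame, run_case
from unls.prior import build_prior_from_cohort

base = unls.PhantomConfig(image_size=(128, 128), n_frames=20,
                          semi_axes=(30, 17), t0=4, alpha=3.0, beta_t=0.5,
                          sigma2=0.01)
cohort = unls.make_cohort(12, base, seed=42)
prior, reference = build_prior_from_cohort(
    [pick_frame(s.frames) for s in cohort],
    [s.truth for s in cohort], beta=1.0)

test = unls.make_cohort(2, base, seed=7)[0]
image = pick_frame(test.frames)
u = unls.corrupt_probability_map(
    test.truth, CorruptionConfig(n_fp_blobs=3, n_fn_holes=2,
                                 boundary_blur_sigma=1.0,
                                 label_noise_level=0.15, rng_seed=0))
baseline = u.threshold(0.5)
mask, diag = run_case(image, u, prior, reference,
                      InitSpec("circle", center=(15, 15), radius=8))
print(f"baseline (threshold 0.5): DS={unls.dice(baseline, test.truth):.3f} "
      f"HD95={unls.hd95(baseline, test.truth):.1f} px")
print(f"two-phase level set:      DS={unls.dice(mask, test.truth):.3f} "
      f"HD95={unls.hd95(mask, test.truth):.1f} px "
      f"({diag.iterations} iterations, converged={diag.converged})")
```

prints

```
baseline (threshold 0.5): DS=0.892 HD95=22.3 px
two-phase level set:      DS=0.994 HD95=1.0 px (25 iterations, converged=True)
```

The probability map alone scores Dice 0.892 because three planted
false-positive blobs and two holes corrupt it; the shape-prior level set
removes every blob, fills the holes, and tightens the 95th-percentile
Hausdorff distance from 22.3 px to a single pixel — the same mechanism that
makes the method robust on real low-contrast frames.

A `unls` command-line tool wraps the same workflow:
`unls phantom`, `unls prior build`, `unls probmap`, `unls segment`,
`unls evaluate`, `unls run`, `unls baseline` (see `unls --help`).

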