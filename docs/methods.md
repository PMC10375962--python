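# Methods

## Model

The segmentation target is a single transplanted kidney in a 2-D DCE-MRI
slice. A level set function φ(x, y) represents the contour implicitly
(φ > 0 kidney, φ < 0 background, φ = 0 on the contour). The energy

E(φ) = λ₁ L(φ) + λ₂ Eu(φ),
L(φ) = Σ δ_ε(φ) |∇φ|,
Eu(φ) = Σ [ V_ε(φ) U_B P_B + (1 − V_ε(φ)) U_K P_K ]

couples two per-pixel probability fields: the phase-1 map U_L (what the
image looks like) and the shape prior P_L (where the kidney is expected).
V_ε is the regularised Heaviside — 0 below −ε, 1 above +ε, and
½ + φ/2ε + sin(πφ/ε)/2π inside the band — and δ_ε = dV_ε/dφ its
regularised Dirac. Minimisation is plain fixed-step gradient descent,

φ ← φ + τ δ_ε(φ) [ λ₁ div(∇φ/|∇φ|) + λ₂ U_K P_K − λ₂ U_B P_B ].

The data force at a pixel is the sign of U_K P_K − U_B P_B: both the image
evidence and the shape prior must agree for the pixel to be claimed. The
length term λ₁ div(∇φ/|∇φ|) shrinks high-curvature structure; with the
default weights it collapses isolated islands of radius up to roughly
λ₁ / (λ₂ max(U_K P_K, U_B P_B)) pixels — this, not connected-component
post-processing, is what removes false-positive blobs whose prior support
is weak, and the package deliberately applies no largest-component cleanup
so the tests exercise the mechanism itself.

Parameters (all dimensionless, pixel units): λ₁ = λ₂ = 6 (term weights),
ε = 1.5 (band half-width of the regularised Heaviside), τ = 0.8 (descent
step), β = 1 (prior pseudo-count). These are the fixed setting used
throughout; none are tuned per case. The solver works on the unit grid —
physical pixel spacing enters only the evaluation metrics.

## Shape prior

P_L is estimated from N binary expert masks co-registered to one reference
subject. Registration maximises normalised cross-correlation with a 3-level
multi-resolution gradient-descent search (SimpleITK), seeded by
centroid-and-second-moment alignment; masks follow their image's transform
with nearest-neighbour resampling, and pixels warped in from outside the
field of view count as background. Moment mass is intensity above the
median, so flat background and zero-filled resampling borders do not swamp
the structures; when the second-moment axes are nearly isotropic
(eigenvalue ratio < 1.2) the initial rotation is taken as zero, because the
axis angle is then meaningless. The returned transform never scores below
its initialisation — if the optimiser ends worse, the initialisation is
returned with a warning.

With N_K(x, y) the kidney count at a pixel and O(x, y) ∈ {1, 2} the number
of labels observed there:

* O = 2: P_L = (N_L + β)/(N + 2β) — Laplace smoothing when β = 1;
* O = 1: the observed label gets N/(N + 1), the unseen label 1/(N + 1).

Both branches are the literal two-factor estimate (smoothed frequency ×
generality factor N/(N + l − O), l = 2); the probabilities sum to 1 by
construction and are strictly inside (0, 1) for every β > 0 and N ≥ 2.
This strict interiority is the point of the Bayesian estimate over a raw
frequency model: a pixel unanimously labelled background in training still
has P_K = 1/(N + 1) > 0, and — more importantly — P_K < 1 everywhere means
a spurious CNN detection far from the kidney's support faces
U_B P_B > U_K P_K and is vetoed.

The prior is serialised as counts plus metadata and recomputed on load, so
no float-format quantisation enters.

## Evolution dynamics and numerical choices

* **Initialisation.** `init_phi` returns the exact signed distance to the
  seed contour (closed form for circles, Euclidean distance transform for
  masks, with a half-pixel offset centring the zero level on the mask
  boundary). Inside `segment` the initial field is clamped to
  [−ε/2, +ε/2] (flag `clamp_init`, default on): every pixel then starts
  inside the active band, so the first iterations decide each pixel by its
  own data force and the outcome does not depend on where the seed contour
  was placed. Without the clamp, δ_ε(φ₀) = 0 away from the seed and a
  far-off initialisation could never reach the kidney.
* **Re-initialisation.** Every `reinit_every` = 5 iterations φ is reset to
  the signed distance of its current sign pattern. This preserves the
  labels exactly but keeps the band travelling with the contour; without it
  the interior of a spurious blob freezes at |φ| > ε before the curvature
  flow can erode it, and holes likewise persist. Re-initialisation
  reparametrises φ (the length term of a signed-distance profile differs
  from that of an evolved profile), so the energy is a strict Lyapunov
  function only between re-initialisations; diagnostics record the full
  series. `reinit_every = 0` gives the pure fixed-band descent, whose
  energy is non-increasing to within 0.1% of its initial value on every
  phantom case in the suite.
* **Stopping.** Converged when fewer than 0.01% of pixels flip sign for 10
  consecutive iterations, or when the sign pattern at a re-initialisation
  checkpoint repeats any of the previous 20 checkpoints — the boundary can
  dither in a short limit cycle locked to the re-initialisation cadence,
  and a revisited state under these deterministic dynamics means the
  contour is stationary. Cap: 1000 iterations.
* **Curvature.** Central differences with replicate (Neumann) boundaries;
  the gradient norm is safeguarded as sqrt(|∇φ|² + η²), η = 1e−8, so flat
  regions return 0 rather than noise.
* **Quadrature.** Energies are plain pixel sums; any pixel-area constant is
  absorbed by λ₁, λ₂.
* **Degenerate inputs.** Constant images cannot be normalised or
  registered (typed errors); empty masks make HD95 undefined (typed error)
  while Dice/IoU of two empty masks is 1 by convention; a non-finite φ
  aborts the evolution with diagnostics.

## Segmentation space

A test image is registered to the prior's reference frame. By default the
*prior* is then resampled into the image's native frame (bilinear on the
probabilities, clipped to the prior's own value range so strict
interiority survives; out-of-view pixels get the background-only value)
and the contour evolves in native space. The alternative mode resamples
the image and U into prior space and carries the final mask back through
the inverse transform with nearest-neighbour interpolation. Native-space
evolution is the default because it never resamples a binary mask, so no
boundary-quantisation loss enters the result; the prior-space mode remains
available (`segmentation_space="prior"`) for workflows that want all
contours in one atlas frame.

## Phantom study conditions

The simulator stands in for clinical data that cannot be shipped. One
subject is: a 256×256 (tests and the acceptance study use 128×128 to keep
runtimes in seconds) frame series, T = 80 by default (20 in the studies),
containing a bean-shaped kidney — a rotated ellipse, semi-axes (60, 34)
full scale or (30, 17) at 128², with a medial notch of depth 0.35·b
emulating the renal hilum — over a static background of base tissue plus
two organ-like structures. Kidney intensity follows
baseline + amplitude · g(t) with g a peak-normalised gamma-variate (shape
α = 3, rate 0.15/frame full scale, 0.5/frame in the studies; arrival frame
t₀ = 8 full scale, 4 in the studies): the standard parametric form for
first-pass contrast kinetics. Pre-arrival frames carry the baseline
exactly, making the first frames genuinely low-contrast. Zero-mean
Gaussian noise of variance 0.01 (0.01/0.02/0.05 are the canonical levels)
is added to [0,1]-scale intensities. Cohorts jitter centre (±8 px), axes
(±5 px), orientation (±10°), notch, baseline, amplitude and arrival frame
per subject.

Corrupted probability maps emulate CNN failure modes: disk-shaped
false-positive blobs (radius 4–9 px) planted in the background at least
3 px from the kidney, false-negative holes (radius 3–6 px) strictly inside
it, uniform label noise (amplitude 0.15 in the refinement study), and a
1 px Gaussian boundary blur. Disks are placed sequentially from a seeded
generator, so corruption is monotone in the disk count and every study is
reproducible.

What the phantom does **not** emulate: Rician noise statistics, partial
volume and bias fields, respiratory motion, anatomically realistic abdomens
or multi-organ context, and CNN errors that correlate with anatomy rather
than being geometrically planted. Passing phantom studies therefore shows
that the machinery is correct and that the refinement mechanism works as
designed — not that clinical accuracy at any particular level is attained
on real scanners.

## CNN provider

The phase-2 engine depends only on the probability-map contract, so the
core library carries no deep-learning dependency. The trainable provider is
a compact NumPy encoder–decoder network (paired 3×3 convolutions + ReLU,
2×2 max-pooling, nearest-neighbour up-sampling with skip concatenation,
1×1 sigmoid head) with hand-written backpropagation, Adam, binary
cross-entropy, and plateau learning-rate decay (×0.9 after 10 stale
epochs). It targets desk-scale runs — tens of 64×64 phantoms for a handful
of epochs — where it cleanly beats the all-background pixel accuracy;
dropout is omitted at this scale. The full-scale configuration (depth-4
encoder, 64 base filters, dropout 0.5, 200 epochs, initial learning rate
1e−4) is expressible in `CnnConfig`, and `build_model` additionally
describes the denser variant whose deepest encoder block has three densely
connected stages and whose skips are fused by a bidirectional
convolutional LSTM; that variant is available as an inspectable
architecture description, not as a trainable model in this backend. The
12-fold augmentation of a training pair is: one random translation (±10%
of the image size), rotations of −90°/−45°/+45°/+90°/180°, vertical and
horizontal flips, Gaussian noise at variances 0.01/0.02/0.05 (image only),
and one combined random translation + flip; the allocation across families
is this package's choice and is configurable.

## Evaluation

Dice = 2|A∩B|/(|A|+|B|), IoU = |A∩B|/|A∪B| (identity DS = 2·IU/(1+IU) is
property-tested), and HD95 = max of the two directed 95th percentiles
(linear-interpolation percentiles) of Euclidean, spacing-weighted
boundary-to-boundary distances, boundaries being foreground pixels with a
background 4-neighbour — the dominant dialect in medical-segmentation
benchmarking. Cohorts report mean ± sample standard deviation (n−1);
single-case cohorts report std 0 and are flagged. Pixel spacing defaults
to 1 mm and is configurable; phantom distances are reported in pixels.

## Known limitations

* Registration failure propagates directly into the prior and the
  segmentation; only affine misalignment is modelled, and a grossly
  misaligned prior will veto the true kidney.
* The two-region formulation segments exactly one kidney per image.
* The energy landscape argument for initialisation invariance is
  empirical (verified over seeded studies), not a convexity proof.
* The stopping rule's cycle detection assumes deterministic dynamics; any
  stochastic force term would require a different criterion.
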