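"""Synthetic DCE-MRI kidney phantoms.

This module emulates the kind of data the segmentation method is designed
for: per-subject series of ~80 rapidly acquired 256x256 scans in which a
bean-shaped transplanted kidney enhances after contrast-agent arrival while
surrounding tissues stay static. It provides

* a bean-shaped kidney mask (rotated ellipse with a medial notch),
* a time series whose kidney intensity follows a gamma-variate enhancement
  curve (the standard parametric model of first-pass contrast kinetics),
  with additive Gaussian noise on [0,1]-normalised intensities,
* corrupted probability maps that mimic CNN failure modes (false-positive
  blobs in the background, false-negative holes inside the kidney, boundary
  blur, label noise),
* cohorts of geometrically jittered subjects for shape-prior construction.

Every operation is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, LabelMask, ProbabilityMap, DCESequence

__all__ = ["PhantomConfig", "CorruptionConfig", "make_kidney_shape",
           "make_dce_sequence", "corrupt_probability_map", "make_cohort",
           "gamma_variate", "DEFAULT_VARIABILITY"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, enhancement and noise parameters of one synthetic subject.

    The enhancement curve is ``baseline + amplitude * g(t)`` inside the
    kidney, where ``g`` is a gamma-variate with shape ``alpha``, rate
    ``beta_t`` (per frame) and arrival frame ``t0``, normalised so its peak
    (at ``t0 + alpha/beta_t``) equals 1. Noise variance ``sigma2`` is applied
    to [0,1]-scale intensities; 0.01/0.02/0.05 are the canonical levels.
    """

    image_size: tuple[int, int] = (256, 256)
    n_frames: int = 80
    center: tuple[float, float] | None = None   # (row, col); None = image centre
    semi_axes: tuple[float, float] = (60.0, 34.0)  # (a, b) in pixels, a >= b
    angle_deg: float = 25.0
    notch_depth: float = 0.35                   # fraction of b carved out medially
    baseline: float = 0.35
    amplitude: float = 0.45
    alpha: float = 3.0
    beta_t: float = 0.15
    t0: int = 8
    sigma2: float = 0.01
    rng_seed: int = 0

    def __post_init__(self):
        rows, cols = self.image_size
        a, b = self.semi_axes
        if min(a, b) < 4:
            raise ValueError("semi-axes must be at least 4 pixels")
        if not (0 <= self.notch_depth < 1):
            raise ValueError("notch_depth must lie in [0, 1)")
        if self.t0 < 1:
            raise ValueError("t0 must be >= 1")
        if self.alpha <= 0 or self.beta_t <= 0:
            raise ValueError("gamma-variate parameters must be positive")
        if self.sigma2 < 0:
            raise ValueError("noise variance must be non-negative")
        cy, cx = self.effective_center
        reach = max(a, b) + 2.0
        if (cy - reach < 0 or cy + reach > rows - 1
                or cx - reach < 0 or cx + reach > cols - 1):
            raise ValueError("kidney geometry exceeds image bounds "
                             "(needs a 2-pixel margin)")

    @property
    def effective_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)

    @property
    def peak_frame(self) -> float:
        """Time of peak enhancement, t0 + alpha / beta_t (in frames)."""
        return self.t0 + self.alpha / self.beta_t


@dataclass(frozen=True)
class CorruptionConfig:
    """Probability-map corruption mimicking CNN segmentation errors."""

    n_fp_blobs: int = 0
    fp_blob_radius: tuple[float, float] = (4.0, 9.0)
    n_fn_holes: int = 0
    fn_hole_radius: tuple[float, float] = (3.0, 6.0)
    boundary_blur_sigma: float = 0.0
    label_noise_level: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_fp_blobs < 0 or self.n_fn_holes < 0:
            raise ValueError("blob/hole counts must be non-negative")
        if min(self.fp_blob_radius) < 0 or min(self.fn_hole_radius) < 0:
            raise ValueError("radii must be non-negative")
        if self.boundary_blur_sigma < 0:
            raise ValueError("blur sigma must be non-negative")
        if not (0 <= self.label_noise_level < 0.5):
            raise ValueError("label_noise_level must lie in [0, 0.5)")


def gamma_variate(t: np.ndarray | float, t0: float, alpha: float,
                  beta_t: float) -> np.ndarray:
    """Peak-normalised gamma-variate enhancement curve.

    g(t) = ((t-t0) beta/alpha)^alpha * exp(alpha - beta (t-t0)) for t >= t0,
    0 before arrival; the peak g = 1 occurs at t = t0 + alpha/beta.
    """
    t = np.asarray(t, dtype=np.float64)
    dt = np.maximum(t - t0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(dt > 0,
                     (dt * beta_t / alpha) ** alpha * np.exp(alpha - beta_t * dt),
                     0.0)
    return g


def make_kidney_shape(cfg: PhantomConfig) -> LabelMask:
    """Rasterise the bean-shaped kidney of ``cfg``.

    A rotated ellipse with semi-axes (a, b); a disk of radius
    ``notch_depth * b`` centred on the medial long edge is carved out to
    produce the renal-hilum concavity. The result is a single 4-connected
    component.
    """
    rows, cols = cfg.image_size
    a, b = cfg.semi_axes
    cy, cx = cfg.effective_center
    theta = np.deg2rad(cfg.angle_deg)

    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    # kidney frame: u along the long axis, v along the short axis
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    if cfg.notch_depth > 0:
        rho = cfg.notch_depth * b
        notch = u ** 2 + (v - b) ** 2 <= rho ** 2
        inside &= ~notch

    mask = inside.astype(np.uint8)
    n_comp = ndimage.label(mask)[1]
    if n_comp != 1:
        raise ValueError(f"kidney shape is not a single component (got {n_comp})")
    return LabelMask(mask)


def _static_background(cfg: PhantomConfig) -> np.ndarray:
    """Base tissue plus two static non-kidney structures."""
    rows, cols = cfg.image_size
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    img = np.full((rows, cols), 0.22)
    # "liver-like" ellipse in the upper-left quadrant
    ly, lx = rows * 0.22, cols * 0.24
    liver = ((yy - ly) / (rows * 0.16)) ** 2 + ((xx - lx) / (cols * 0.18)) ** 2 <= 1.0
    img[liver] = 0.42
    # "spine-like" disk at the bottom centre
    sy, sx = rows * 0.86, cols * 0.5
    spine = (yy - sy) ** 2 + (xx - sx) ** 2 <= (0.06 * min(rows, cols)) ** 2
    img[spine] = 0.6
    return img


def make_dce_sequence(cfg: PhantomConfig) -> DCESequence:
    """Simulate one subject's dynamic series with its ground-truth mask."""
    truth = make_kidney_shape(cfg)
    kidney = truth.as_bool()
    background = _static_background(cfg)
    rng = np.random.default_rng(cfg.rng_seed)

    t = np.arange(1, cfg.n_frames + 1)
    enh = cfg.baseline + cfg.amplitude * gamma_variate(t, cfg.t0, cfg.alpha, cfg.beta_t)

    sigma = float(np.sqrt(cfg.sigma2))
    frames = []
    for i in range(cfg.n_frames):
        img = background.copy()
        img[kidney] = enh[i]
        if sigma > 0:
            img = img + rng.normal(0.0, sigma, size=img.shape)
        frames.append(ImageGrid(img))
    return DCESequence(frames=frames, truth=truth,
                       subject_id=f"phantom_{cfg.rng_seed}")


def _place_disks(rng: np.random.Generator, allowed: np.ndarray, n: int,
                 radius_range: tuple[float, float], what: str) -> np.ndarray:
    """Plant ``n`` disjoint disks whose 3-px-dilated supports lie in ``allowed``.

    Centres are drawn uniformly from the feasible set (pixels whose distance
    to the complement of the remaining free region exceeds radius + 3), so
    placement never fails when geometrically possible. Disks are sampled
    sequentially: the first k disks are identical across runs that differ
    only in ``n``, making corruption monotone in the count.
    """
    rows, cols = allowed.shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    free = allowed.copy()
    free[0, :] = free[-1, :] = free[:, 0] = free[:, -1] = False
    planted = np.zeros_like(allowed)
    for _ in range(n):
        r = rng.uniform(*radius_range)
        dist = ndimage.distance_transform_edt(free)
        candidates = np.argwhere(dist > r + 3)
        if len(candidates) == 0:
            raise ValueError(f"no room left to place a {what} disk "
                             f"(radius {r:.1f})")
        cy, cx = candidates[rng.integers(len(candidates))]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        planted |= d2 <= r ** 2
        free &= d2 > (r + 3) ** 2
    return planted


def corrupt_probability_map(truth: LabelMask,
                            ccfg: CorruptionConfig) -> ProbabilityMap:
    """Emulate a CNN probability map with planted errors.

    Starting from U_K = truth: plant ``n_fp_blobs`` high-probability disks in
    the background (disjoint from the kidney dilated by 3 px and from each
    other), carve ``n_fn_holes`` low-probability disks strictly inside the
    kidney, add uniform label noise, Gaussian-blur, and clip to [0, 1]. A
    zero-corruption config returns the truth exactly.
    """
    rng = np.random.default_rng(ccfg.rng_seed)
    kid = truth.as_bool()
    u = kid.astype(np.float64)

    if ccfg.n_fp_blobs > 0:
        blobs = _place_disks(rng, ~kid, ccfg.n_fp_blobs,
                             ccfg.fp_blob_radius, "false-positive")
        u[blobs] = 1.0
    if ccfg.n_fn_holes > 0:
        holes = _place_disks(rng, kid, ccfg.n_fn_holes,
                             ccfg.fn_hole_radius, "false-negative")
        u[holes] = 0.0
    if ccfg.label_noise_level > 0:
        u = u + rng.uniform(-ccfg.label_noise_level, ccfg.label_noise_level,
                            size=u.shape)
    if ccfg.boundary_blur_sigma > 0:
        u = ndimage.gaussian_filter(u, ccfg.boundary_blur_sigma)
    return ProbabilityMap(np.clip(u, 0.0, 1.0), truth.spacing)


# per-parameter jitter half-widths used by make_cohort when none are given
DEFAULT_VARIABILITY: dict[str, float] = {
    "center_px": 8.0,
    "axes_px": 5.0,
    "angle_deg": 10.0,
    "notch_depth": 0.08,
    "baseline": 0.04,
    "amplitude": 0.08,
    "t0_frames": 2.0,
}


def make_cohort(n_subjects: int, base_cfg: PhantomConfig,
                variability: dict[str, float] | None = None,
                seed: int = 0) -> list[DCESequence]:
    """Generate a cohort of subjects with jittered geometry and enhancement.

    Each subject's parameters are drawn uniformly within +/- the given
    half-widths around ``base_cfg``; per-subject noise streams are spawned
    from ``seed`` so the cohort is fully deterministic.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    var = DEFAULT_VARIABILITY if variability is None else variability
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2 ** 31 - 1, size=n_subjects)

    cohort = []
    for i in range(n_subjects):
        jr = np.random.default_rng(subject_seeds[i])

        def jit(half_width: float) -> float:
            return float(jr.uniform(-half_width, half_width))

        cy, cx = base_cfg.effective_center
        a, b = base_cfg.semi_axes
        cfg = replace(
            base_cfg,
            center=(cy + jit(var.get("center_px", 0)),
                    cx + jit(var.get("center_px", 0))),
            semi_axes=(max(8.0, a + jit(var.get("axes_px", 0))),
                       max(6.0, b + jit(var.get("axes_px", 0)))),
            angle_deg=base_cfg.angle_deg + jit(var.get("angle_deg", 0)),
            notch_depth=float(np.clip(
                base_cfg.notch_depth + jit(var.get("notch_depth", 0)), 0.0, 0.9)),
            baseline=base_cfg.baseline + jit(var.get("baseline", 0)),
            amplitude=base_cfg.amplitude + jit(var.get("amplitude", 0)),
            t0=max(1, int(round(base_cfg.t0 + jit(var.get("t0_frames", 0))))),
            rng_seed=int(subject_seeds[i]),
        )
        seq = make_dce_sequence(cfg)
        seq.subject_id = f"subject_{i:02d}"
        cohort.append(seq)
    return cohort
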