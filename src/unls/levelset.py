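"""Probability-and-prior driven level set segmentation (phase 2).

The contour is the zero level of a scalar field phi, positive inside the
kidney and negative in the background. Evolution minimises

    E(phi) = lambda1 * L(phi) + lambda2 * Eu(phi)

where the length term L(phi) = sum delta_eps(phi) |grad phi| keeps the
contour smooth and Eu couples the phase-1 probability map U_L with the
Bayesian shape prior P_L:

    Eu(phi) = sum [ V_eps(phi) U_B P_B + (1 - V_eps(phi)) U_K P_K ].

V_eps and delta_eps are the sin/cos-regularised Heaviside and Dirac
functions with support width eps; gradient descent gives the update

    phi <- phi + tau * delta_eps(phi) *
           [ lambda1 * div(grad phi / |grad phi|)
             + lambda2 * U_K P_K - lambda2 * U_B P_B ].

Because delta_eps vanishes for |phi| > eps, updates are confined to a band
around the contour: pixels outside the band are bit-identical between
iterates. Defaults follow the fixed setting lambda1 = lambda2 = 6,
eps = 1.5, tau = 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, LabelMask, ProbabilityMap, require_same_geometry
from .prior import ShapePrior

__all__ = ["LevelSetParams", "LevelSetField", "InitSpec", "heaviside_eps",
           "dirac_eps", "curvature", "energy", "evolve_step", "init_phi",
           "segment", "SegmentationDiagnostics"]


@dataclass(frozen=True)
class LevelSetParams:
    """Evolution parameters. ``lambda1``/``lambda2`` weight the length and
    data terms, ``eps`` is the Heaviside regularisation width (pixels),
    ``tau`` the descent step. Convergence: fewer than ``change_tol_frac`` of
    the pixels flip sign for ``k_converged`` consecutive iterations."""

    lambda1: float = 6.0
    lambda2: float = 6.0
    eps: float = 1.5
    tau: float = 0.8
    max_iters: int = 1000
    k_converged: int = 10
    change_tol_frac: float = 1e-4   # fraction of pixels allowed to still flip
    eta: float = 1e-8               # curvature denominator safeguard
    clamp_init: bool = True         # clamp phi0 into the active band
    reinit_every: int = 5           # 0 = never re-initialise to signed distance

    def __post_init__(self):
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda1 and lambda2 must be positive")
        if self.eps <= 0 or self.tau <= 0 or self.eta <= 0:
            raise ValueError("eps, tau and eta must be positive")
        if self.max_iters < 1 or self.k_converged < 1:
            raise ValueError("max_iters and k_converged must be >= 1")


@dataclass
class LevelSetField:
    """The implicit contour: phi > 0 inside the kidney, < 0 outside."""

    phi: np.ndarray
    iteration: int = 0

    def __post_init__(self):
        phi = np.asarray(self.phi, dtype=np.float64)
        if not np.all(np.isfinite(phi)):
            raise ValueError("phi must be finite")
        self.phi = phi

    @property
    def shape(self) -> tuple[int, int]:
        return self.phi.shape

    def to_mask(self, spacing=(1.0, 1.0)) -> LabelMask:
        return LabelMask((self.phi > 0).astype(np.uint8), spacing)


@dataclass(frozen=True)
class InitSpec:
    """Initial contour: a circle, a rectangle, or an arbitrary seed mask.

    circle: center=(row, col), radius in pixels.
    rectangle: corners=((r0, c0), (r1, c1)), inclusive-exclusive.
    from_mask: mask = LabelMask seed.
    """

    shape: str = "circle"
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 10.0
    corners: tuple[tuple[int, int], tuple[int, int]] | None = None
    mask: LabelMask | None = None


def heaviside_eps(phi, eps: float):
    """Regularised Heaviside V_eps: 0 below -eps, 1 above +eps, and
    1/2 + phi/(2 eps) + sin(pi phi / eps)/(2 pi) inside the band.
    Continuous and non-decreasing."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    phi = np.asarray(phi, dtype=np.float64)
    mid = 0.5 + phi / (2 * eps) + np.sin(np.pi * phi / eps) / (2 * np.pi)
    out = np.where(phi > eps, 1.0, np.where(phi < -eps, 0.0, mid))
    return out if out.ndim else float(out)


def dirac_eps(phi, eps: float):
    """Regularised Dirac delta_eps = dV_eps/dphi: zero outside the band,
    (1 + cos(pi phi / eps)) / (2 eps) inside. Even, maximal at phi = 0."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    phi = np.asarray(phi, dtype=np.float64)
    mid = (1.0 + np.cos(np.pi * phi / eps)) / (2 * eps)
    out = np.where(np.abs(phi) > eps, 0.0, mid)
    return out if out.ndim else float(out)


def _grad(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences with replicate (Neumann) boundaries."""
    gy, gx = np.gradient(phi)
    return gy, gx


def curvature(phi: np.ndarray, eta: float = 1e-8) -> np.ndarray:
    """div(grad phi / |grad phi|) with a safeguarded norm.

    Central differences, replicate boundaries; the gradient magnitude is
    regularised as sqrt(|grad phi|^2 + eta^2) so flat regions yield 0
    instead of dividing by zero.
    """
    gy, gx = _grad(phi)
    norm = np.sqrt(gx * gx + gy * gy + eta * eta)
    ny, nx = gy / norm, gx / norm
    div = np.gradient(ny, axis=0) + np.gradient(nx, axis=1)
    return div


def _check_geometry(u: ProbabilityMap, prior: ShapePrior, phi: np.ndarray):
    if u.shape != phi.shape or prior.shape != phi.shape:
        from .grid import GeometryError
        raise GeometryError(
            f"geometry mismatch: phi {phi.shape}, U {u.shape}, prior {prior.shape}")


def energy(field: LevelSetField, u: ProbabilityMap, prior: ShapePrior,
           params: LevelSetParams) -> tuple[float, float, float]:
    """Discrete (E_total, E_length, E_data) by plain pixel-sum quadrature."""
    phi = field.phi
    _check_geometry(u, prior, phi)
    gy, gx = _grad(phi)
    grad_mag = np.sqrt(gx * gx + gy * gy)
    e_length = float(np.sum(dirac_eps(phi, params.eps) * grad_mag))
    v = heaviside_eps(phi, params.eps)
    e_data = float(np.sum(v * u.p_background * prior.p_background
                          + (1.0 - v) * u.p_kidney * prior.p_kidney))
    e_total = params.lambda1 * e_length + params.lambda2 * e_data
    return e_total, e_length, e_data


def evolve_step(field: LevelSetField, u: ProbabilityMap, prior: ShapePrior,
                params: LevelSetParams) -> LevelSetField:
    """One gradient-descent update of phi.

    The delta_eps prefactor confines the update to the band |phi| <= eps;
    outside it phi is returned bit-identical.
    """
    phi = field.phi
    _check_geometry(u, prior, phi)
    delta = dirac_eps(phi, params.eps)
    force = (params.lambda1 * curvature(phi, params.eta)
             + params.lambda2 * u.p_kidney * prior.p_kidney
             - params.lambda2 * u.p_background * prior.p_background)
    new_phi = phi + params.tau * delta * force
    if not np.all(np.isfinite(new_phi)):
        raise FloatingPointError(
            f"non-finite phi at iteration {field.iteration + 1}: "
            f"min={np.nanmin(new_phi)}, max={np.nanmax(new_phi)}")
    return LevelSetField(new_phi, field.iteration + 1)


def init_phi(spec: InitSpec, shape: tuple[int, int]) -> LevelSetField:
    """Signed distance to the initial contour (positive inside), computed by
    exact Euclidean distance transforms of the seed region."""
    rows, cols = shape
    if spec.shape == "circle":
        cy, cx = spec.center
        if not (0 <= cy < rows and 0 <= cx < cols) or spec.radius <= 0:
            raise ValueError("circle out of bounds or non-positive radius")
        yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
        phi = spec.radius - np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        return LevelSetField(phi)
    if spec.shape == "rectangle":
        (r0, c0), (r1, c1) = spec.corners
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise ValueError("rectangle out of bounds")
        inside = np.zeros(shape, dtype=bool)
        inside[r0:r1, c0:c1] = True
    elif spec.shape == "from_mask":
        if spec.mask is None:
            raise ValueError("from_mask spec needs a mask")
        if spec.mask.shape != shape:
            raise ValueError("seed mask shape mismatch")
        inside = spec.mask.as_bool()
    else:
        raise ValueError(f"unknown init shape {spec.shape!r}")
    if not inside.any() or inside.all():
        raise ValueError("seed region must be a proper subset of the image")
    d_out = ndimage.distance_transform_edt(~inside)
    d_in = ndimage.distance_transform_edt(inside)
    # positive inside, negative outside; 0.5 px offset centres the zero
    # level on the mask boundary
    phi = np.where(inside, d_in - 0.5, -(d_out - 0.5))
    return LevelSetField(phi)


@dataclass
class SegmentationDiagnostics:
    """Per-iteration record of one segmentation run."""

    e_total: list = field(default_factory=list)
    e_length: list = field(default_factory=list)
    e_data: list = field(default_factory=list)
    changed_pixels: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def segment(image: ImageGrid, u: ProbabilityMap, prior: ShapePrior,
            init: InitSpec, params: LevelSetParams | None = None,
            ) -> tuple[LabelMask, SegmentationDiagnostics]:
    """Run the full contour evolution and return the segmentation.

    All inputs must live on one geometry (the prior's reference frame;
    aligning a native-space image there is the caller's job). The initial
    field is the signed distance of ``init``; with ``clamp_init`` (default)
    it is clamped to [-eps/2, +eps/2] so the whole image starts inside the
    active band — this is what makes the result independent of where the
    contour is initialised, since the probability-and-prior force then
    decides every pixel rather than only those near the seed contour.

    Every ``reinit_every`` iterations (default 5) phi is re-initialised to
    the signed distance of its current sign pattern. This preserves the
    labels but keeps the active band travelling with the contour, which is
    what lets the curvature term collapse spurious high-probability islands
    and fill holes whose interiors would otherwise leave the band and
    freeze. Set ``reinit_every=0`` for the pure fixed-band gradient descent.

    Stops when fewer than ``change_tol_frac`` of the pixels flip sign for
    ``k_converged`` consecutive iterations, when the label pattern at a
    re-initialisation checkpoint repeats a recent checkpoint (a stationary
    or dithering contour), or at ``max_iters``.
    """
    params = params or LevelSetParams()
    require_same_geometry(image, u)
    field_ = init_phi(init, image.shape)
    if params.clamp_init:
        half = params.eps / 2.0
        field_ = LevelSetField(np.clip(field_.phi, -half, half))

    diag = SegmentationDiagnostics()
    n_pixels = image.shape[0] * image.shape[1]
    change_tol = params.change_tol_frac * n_pixels
    e0 = energy(field_, u, prior, params)
    diag.e_total.append(e0[0])
    diag.e_length.append(e0[1])
    diag.e_data.append(e0[2])

    quiet = 0
    checkpoint_history: list[bytes] = []
    for _ in range(params.max_iters):
        prev_sign = field_.phi > 0
        field_ = evolve_step(field_, u, prior, params)
        at_checkpoint = (params.reinit_every
                         and field_.iteration % params.reinit_every == 0)
        if at_checkpoint:
            # the boundary can dither in a short limit cycle locked to the
            # re-initialisation cadence; a label pattern identical to a
            # recent checkpoint means the contour is stationary
            sign = field_.phi > 0
            digest = sign.tobytes()
            if digest in checkpoint_history:
                diag.converged = True
            checkpoint_history = (checkpoint_history + [digest])[-20:]
            if sign.any() and not sign.all():
                mask = LabelMask(sign.astype(np.uint8))
                field_ = LevelSetField(
                    init_phi(InitSpec("from_mask", mask=mask), image.shape).phi,
                    field_.iteration)
        et, el, ed = energy(field_, u, prior, params)
        changed = int(np.count_nonzero((field_.phi > 0) != prev_sign))
        diag.e_total.append(et)
        diag.e_length.append(el)
        diag.e_data.append(ed)
        diag.changed_pixels.append(changed)
        quiet = quiet + 1 if changed < change_tol else 0
        if quiet >= params.k_converged:
            diag.converged = True
        if diag.converged:
            break
    diag.iterations = field_.iteration
    return field_.to_mask(image.spacing), diag
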