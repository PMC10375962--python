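"""Affine registration of images to a reference frame.

The shape prior is built in the coordinate frame of one reference subject,
so every training mask — and at segmentation time every test image — must
first be affinely aligned to that frame. Alignment maximises normalised
cross-correlation (NCC) with a 3-level multi-resolution gradient-descent
search (SimpleITK's registration framework), initialised by
centroid-and-second-moment alignment.

Transform semantics
-------------------
An :class:`AffineTransform` maps *reference-space* points to *moving-space*
points (the resampling convention): ``p_mov = A @ p_ref + t`` with points in
``(x, y) = (col, row)`` order. ``apply_to_image(moving)`` therefore produces
the moving image resampled onto the reference grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .grid import ImageGrid, LabelMask

__all__ = ["AffineTransform", "register_affine", "warp_mask", "ncc",
           "RegistrationWarning"]


class RegistrationWarning(UserWarning):
    """Optimiser did not improve on the moment-based initialisation."""


@dataclass(frozen=True)
class AffineTransform:
    """2-D affine map ``p_mov = A @ p_ref + t`` on (x, y) = (col, row) points."""

    matrix: np.ndarray      # 2x2
    translation: np.ndarray  # length 2, (t_x, t_y)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        t = np.asarray(self.translation, dtype=np.float64).reshape(2)
        if abs(np.linalg.det(m)) <= 1e-8:
            raise ValueError("affine linear part is (near-)singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: maps p -> self(other(p))."""
        return AffineTransform(self.matrix @ other.matrix,
                               self.matrix @ other.translation + self.translation)

    def apply_to_points(self, pts_xy: np.ndarray) -> np.ndarray:
        return pts_xy @ self.matrix.T + self.translation

    def _rowcol_parts(self) -> tuple[np.ndarray, np.ndarray]:
        # convert the (x, y) action to (row, col) index order for scipy
        swap = np.array([[0.0, 1.0], [1.0, 0.0]])
        return swap @ self.matrix @ swap, self.translation[::-1]

    def apply_to_image(self, moving: ImageGrid, order: int = 1) -> ImageGrid:
        """Resample ``moving`` onto the reference grid (bilinear by default)."""
        m_rc, off_rc = self._rowcol_parts()
        out = ndimage.affine_transform(moving.pixels, m_rc, offset=off_rc,
                                       order=order, mode="constant", cval=0.0)
        return ImageGrid(out, moving.spacing)

    def apply_to_mask(self, mask: LabelMask) -> LabelMask:
        """Resample a mask with nearest-neighbour interpolation (stays binary).

        Pixels mapped from outside the moving field of view become background.
        """
        m_rc, off_rc = self._rowcol_parts()
        out = ndimage.affine_transform(mask.labels, m_rc, offset=off_rc,
                                       order=0, mode="constant", cval=0)
        return LabelMask(out.astype(np.uint8), mask.spacing)

    @property
    def params(self) -> np.ndarray:
        """The 6 coefficients (a11, a12, a21, a22, tx, ty)."""
        return np.concatenate([self.matrix.ravel(), self.translation])


def warp_mask(mask: LabelMask, t: AffineTransform) -> LabelMask:
    """Functional alias for :meth:`AffineTransform.apply_to_mask`."""
    return t.apply_to_mask(mask)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised cross-correlation of two equal-shape arrays."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _moments(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Intensity centroid (x, y) and second-moment covariance of an image.

    Mass is intensity above the median, so flat background (and zero-filled
    borders of resampled images) does not swamp the structures of interest.
    """
    w = np.clip(img - np.median(img), 0.0, None)
    if w.sum() <= 0:
        w = img - img.min()
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot compute moments of a constant image")
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]].astype(np.float64)
    cx = (w * xx).sum() / total
    cy = (w * yy).sum() / total
    dx, dy = xx - cx, yy - cy
    cov = np.array([[(w * dx * dx).sum(), (w * dx * dy).sum()],
                    [(w * dx * dy).sum(), (w * dy * dy).sum()]]) / total
    return np.array([cx, cy]), cov


def _moment_init(moving: np.ndarray, reference: np.ndarray) -> AffineTransform:
    """Centroid-and-second-moment alignment used to seed the search.

    The linear part is a rotation-and-scale matching the principal axes of
    the two intensity distributions (rotation chosen closest to identity,
    resolving the pi-ambiguity of principal axes); the translation matches
    centroids.
    """
    c_mov, cov_mov = _moments(moving)
    c_ref, cov_ref = _moments(reference)

    def principal(cov):
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals_m, vecs_m = principal(cov_mov)
    vals_r, vecs_r = principal(cov_ref)
    if vals_m[0] < 1.2 * vals_m[1] or vals_r[0] < 1.2 * vals_r[1]:
        dtheta = 0.0  # nearly isotropic mass: the axis angle is meaningless
    else:
        angle_m = np.arctan2(vecs_m[1, 0], vecs_m[0, 0])
        angle_r = np.arctan2(vecs_r[1, 0], vecs_r[0, 0])
        dtheta = angle_m - angle_r
        # principal axes are only defined up to pi; pick the rotation nearest 0
        dtheta = (dtheta + np.pi / 2) % np.pi - np.pi / 2
    scale = float(np.sqrt(np.sqrt((vals_m[0] * vals_m[1])
                                  / (vals_r[0] * vals_r[1]))))
    rot = np.array([[np.cos(dtheta), -np.sin(dtheta)],
                    [np.sin(dtheta), np.cos(dtheta)]])
    a = scale * rot
    t = c_mov - a @ c_ref
    return AffineTransform(a, t)


def _to_sitk(img: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(img.astype(np.float32))


def _from_sitk_affine(tx: sitk.AffineTransform) -> AffineTransform:
    m = np.array(tx.GetMatrix()).reshape(2, 2)
    c = np.array(tx.GetCenter())
    t = np.array(tx.GetTranslation())
    # p' = M (p - c) + c + t   ==>   flat form A p + (c + t - M c)
    return AffineTransform(m, c + t - m @ c)


def register_affine(moving: ImageGrid, reference: ImageGrid,
                    max_iterations: int = 200,
                    shrink_factors: tuple[int, ...] = (4, 2, 1),
                    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0),
                    ) -> tuple[AffineTransform, ImageGrid]:
    """Affinely register ``moving`` to ``reference`` by maximising NCC.

    Multi-resolution (3 levels by default) gradient-descent search seeded by
    centroid-and-second-moment alignment. The returned transform is
    guaranteed not to score below the moment initialisation: if the
    optimiser ends up worse, the initialisation is returned with a
    :class:`RegistrationWarning`.

    Returns ``(transform, warped)`` with ``warped`` the moving image
    resampled onto the reference grid by bilinear interpolation.
    """
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must share size")
    if np.ptp(moving.pixels) == 0 or np.ptp(reference.pixels) == 0:
        raise ValueError("cannot register constant images")

    init = _moment_init(moving.pixels, reference.pixels)

    fixed_img = _to_sitk(reference.pixels)
    moving_img = _to_sitk(moving.pixels)
    tx0 = sitk.AffineTransform(2)
    tx0.SetMatrix(tuple(init.matrix.ravel()))
    tx0.SetTranslation(tuple(init.translation))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=max_iterations,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SetInitialTransform(tx0, inPlace=False)

    candidates = [init]
    try:
        final = reg.Execute(fixed_img, moving_img)
        aff = sitk.AffineTransform(2)
        if final.GetTransformEnum() == sitk.sitkComposite:
            final = final.GetNthTransform(final.GetNumberOfTransforms() - 1)
        aff.SetMatrix(final.GetParameters()[:4])
        aff.SetTranslation(final.GetParameters()[4:6])
        aff.SetCenter(final.GetFixedParameters()[:2])
        candidates.append(_from_sitk_affine(aff))
    except RuntimeError as exc:  # optimiser failure: fall back to the init
        warnings.warn(f"registration optimiser failed ({exc}); "
                      "returning moment initialisation", RegistrationWarning)

    scored = [(ncc(t.apply_to_image(moving).pixels, reference.pixels), t)
              for t in candidates]
    best_score, best = max(scored, key=lambda st: st[0])
    if len(scored) > 1 and best is candidates[0]:
        warnings.warn("optimiser did not improve on moment initialisation",
                      RegistrationWarning)
    return best, best.apply_to_image(moving)
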