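"""Core raster types shared across the package.

All rasters are 2-D, row-major, 0-based. The convention throughout the
package is that ``(x, y)`` image coordinates map to ``(col, row)`` array
indices; every public array attribute is indexed ``[row, col]``.

Physical pixel size is carried as ``spacing = (row_mm, col_mm)`` and
defaults to 1 mm/pixel. It only enters distance-valued metrics; the level
set solver works on the unit grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "LabelMask", "ProbabilityMap", "DCESequence", "GeometryError"]

MIN_SIDE = 8


class GeometryError(ValueError):
    """Raised when rasters that must share a geometry do not."""


def _check_2d(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got ndim={arr.ndim} "
                         "(multi-channel and volumetric rasters are not supported)")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise ValueError(f"{name} must be at least {MIN_SIDE}x{MIN_SIDE}, got {arr.shape}")
    return arr


def _check_spacing(spacing) -> tuple[float, float]:
    r, c = float(spacing[0]), float(spacing[1])
    if r <= 0 or c <= 0:
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return (r, c)


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D scalar intensity raster with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray of float, shape (height, width)
        Intensity values in arbitrary units; must be finite.
    spacing : (row_mm, col_mm)
        Physical pixel size in millimetres, default (1.0, 1.0).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        px = _check_2d(self.pixels, "pixels").astype(np.float64, copy=False)
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def same_geometry(self, other) -> bool:
        return self.shape == other.shape and self.spacing == other.spacing


@dataclass(frozen=True)
class LabelMask:
    """A binary per-pixel labelling: 1 = kidney, 0 = background."""

    labels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        lab = _check_2d(self.labels, "labels")
        uniq = np.unique(lab)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be exactly in {{0, 1}}, got {uniq[:5]}")
        object.__setattr__(self, "labels", lab.astype(np.uint8))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def same_geometry(self, other) -> bool:
        return self.shape == other.shape and self.spacing == other.spacing

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel kidney probability U_K in [0, 1].

    The background probability is implied, U_B = 1 - U_K, so the
    normalisation sum_L U_L = 1 holds structurally.
    """

    p_kidney: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        p = _check_2d(self.p_kidney, "p_kidney").astype(np.float64, copy=False)
        if not np.all(np.isfinite(p)):
            raise ValueError("probabilities must be finite")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError(
                f"probabilities must lie in [0, 1], got range [{p.min()}, {p.max()}]")
        object.__setattr__(self, "p_kidney", p)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def p_background(self) -> np.ndarray:
        return 1.0 - self.p_kidney

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_kidney.shape

    def same_geometry(self, other) -> bool:
        return self.shape == other.shape and self.spacing == other.spacing

    def threshold(self, level: float = 0.5) -> LabelMask:
        """Binarise at ``level`` (the phase-1 baseline segmentation)."""
        return LabelMask((self.p_kidney > level).astype(np.uint8), self.spacing)


@dataclass
class DCESequence:
    """A dynamic contrast-enhanced series: T frames plus one truth mask."""

    frames: list = field(default_factory=list)
    truth: LabelMask | None = None
    subject_id: str = ""

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("a DCE sequence needs at least one frame")
        geom = self.frames[0]
        for f in self.frames[1:]:
            if not geom.same_geometry(f):
                raise GeometryError("all frames must share one geometry")
        if self.truth is not None and not geom.same_geometry(self.truth):
            raise GeometryError("truth mask must share the frame geometry")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


def require_same_geometry(*rasters) -> None:
    """Raise GeometryError unless every raster shares shape and spacing."""
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_geometry(r):
            raise GeometryError(
                f"geometry mismatch: {first.shape}/{first.spacing} vs {r.shape}/{r.spacing}")
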