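"""Bayesian probabilistic shape prior for the kidney.

The prior P_L(x, y) encodes, per pixel of a common reference frame, the
probability of the kidney (L = K) and background (L = B) labels, estimated
from N co-registered expert segmentations with Bayesian pseudo-count
smoothing. Unlike a first-order (empirical-frequency) shape model, the
estimate never degenerates to probability 0 or 1, even at pixels labelled
identically in every training image — which is precisely what lets the data
term of the level set veto confident-but-wrong CNN output away from the
kidney's support.

Estimation rule (l = 2 labels, O(x, y) = number of labels observed at the
pixel, N_L = count of label L, beta > 0 a pseudo-count):

* both labels seen (O = 2):
      P_L = (N_L + beta) / (N + 2 beta)
  (the generality factor N / (N + l - O) equals 1 here);
* one label seen (O = 1): the observed label gets
      P_obs = ((N_obs + beta) / (N + beta)) * (N / (N + 1)) = N / (N + 1)
  and the unseen label gets
      P_unseen = (1 / (l - O)) * (1 - N / (N + l - O)) = 1 / (N + 1).

With beta = 1 and O = 2 the rule reduces to Laplace smoothing,
P_K = (N_K + 1) / (N + 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .grid import ImageGrid, LabelMask, ProbabilityMap, require_same_geometry
from .registration import AffineTransform, register_affine
from . import io as _io

__all__ = ["ShapePrior", "build_shape_prior", "build_prior_from_cohort",
           "align_to_prior", "map_mask_to_native", "save_prior", "load_prior",
           "shape_prior_probability"]

N_LABELS = 2


@dataclass(frozen=True)
class ShapePrior:
    """Per-pixel kidney/background prior probabilities plus provenance."""

    p_kidney: np.ndarray          # P_K(x, y)
    n_images: int                 # N
    beta: float
    counts_kidney: np.ndarray     # N_K(x, y), integer raster
    reference_id: str = ""
    spacing: tuple[float, float] = (1.0, 1.0)
    transforms: dict | None = None  # subject_id -> AffineTransform used

    def __post_init__(self):
        p = np.asarray(self.p_kidney, dtype=np.float64)
        if p.min() <= 0.0 or p.max() >= 1.0:
            raise ValueError("shape prior probabilities must be strictly in (0, 1)")
        object.__setattr__(self, "p_kidney", p)

    @property
    def p_background(self) -> np.ndarray:
        return 1.0 - self.p_kidney

    @property
    def observed(self) -> np.ndarray:
        """O(x, y): 2 where both labels occur in training, else 1."""
        nk = self.counts_kidney
        return np.where((nk > 0) & (nk < self.n_images), 2, 1).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_kidney.shape

    def same_geometry(self, other) -> bool:
        return self.shape == other.shape and self.spacing == other.spacing

    def as_probability_map(self) -> ProbabilityMap:
        return ProbabilityMap(self.p_kidney, self.spacing)


def shape_prior_probability(n_kidney: np.ndarray | int, n_images: int,
                            beta: float) -> np.ndarray:
    """Vectorised Bayesian estimate of P_K from kidney counts.

    Applies the two-branch rule documented in the module docstring.
    """
    nk = np.asarray(n_kidney, dtype=np.float64)
    n = float(n_images)
    both_seen = (nk > 0) & (nk < n)
    # O = 2 branch (second factor N/(N + l - O) = 1)
    p_both = (nk + beta) / (n + 2.0 * beta)
    # O = 1 branch: observed label N/(N+1), unseen label 1/(N+1)
    p_all_kidney = n / (n + 1.0)
    p_no_kidney = 1.0 / (n + 1.0)
    return np.where(both_seen, p_both,
                    np.where(nk == n, p_all_kidney, p_no_kidney))


def build_shape_prior(aligned_masks: list[LabelMask], beta: float = 1.0,
                      reference_id: str = "", transforms: dict | None = None,
                      ) -> ShapePrior:
    """Estimate the prior from N >= 2 co-registered binary masks."""
    n = len(aligned_masks)
    if n < 2:
        raise ValueError("need at least 2 aligned masks")
    if beta <= 0:
        raise ValueError("beta must be positive")
    require_same_geometry(*aligned_masks)
    counts = np.zeros(aligned_masks[0].shape, dtype=np.int64)
    for m in aligned_masks:
        counts += m.labels
    p_k = shape_prior_probability(counts, n, beta)
    return ShapePrior(p_kidney=p_k, n_images=n, beta=beta,
                      counts_kidney=counts, reference_id=reference_id,
                      spacing=aligned_masks[0].spacing, transforms=transforms)


def build_prior_from_cohort(images: list[ImageGrid], masks: list[LabelMask],
                            beta: float = 1.0, reference_index: int = 0,
                            subject_ids: list[str] | None = None,
                            ) -> tuple[ShapePrior, ImageGrid]:
    """Full prior-construction workflow from unaligned training subjects.

    The subject at ``reference_index`` (the first by default) provides the
    reference frame; every other subject's image is affinely registered to
    it and its mask warped (nearest-neighbour) by the same transform.
    Returns the prior and the reference image (needed later to align test
    images into prior space).
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up")
    ids = subject_ids or [f"subject_{i:02d}" for i in range(len(images))]
    reference = images[reference_index]
    aligned, transforms = [], {}
    for i, (img, msk) in enumerate(zip(images, masks)):
        if i == reference_index:
            t = AffineTransform.identity()
        else:
            t, _ = register_affine(img, reference)
        transforms[ids[i]] = t
        aligned.append(t.apply_to_mask(msk))
    prior = build_shape_prior(aligned, beta=beta,
                              reference_id=ids[reference_index],
                              transforms=transforms)
    return prior, reference


def align_to_prior(test: ImageGrid, prior: ShapePrior, reference: ImageGrid,
                   ) -> tuple[AffineTransform, ImageGrid]:
    """Register a test image into the prior's reference frame.

    The returned transform maps prior-space points to test-space points; a
    segmentation produced in prior space is carried back to native space by
    :func:`map_mask_to_native`, which resamples through the transform's
    inverse with nearest-neighbour interpolation.
    """
    if not prior.same_geometry(reference):
        raise ValueError("prior and reference image must share geometry")
    return register_affine(test, reference)


def map_mask_to_native(mask_prior_space: LabelMask, t: AffineTransform,
                       ) -> LabelMask:
    """Carry a prior-space segmentation back to the test image's own frame.

    ``t`` is the transform returned by :func:`align_to_prior` (prior -> test
    points used for resampling the test image into prior space); the native
    mask is obtained by resampling through its inverse.
    """
    return t.inverse().apply_to_mask(mask_prior_space)


# -- serialization ------------------------------------------------------------

def save_prior(prior: ShapePrior, out_dir: str | Path) -> None:
    """Write P_K as float TIFF plus a YAML sidecar with N, beta, counts and
    per-subject transform coefficients."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_image(ImageGrid(prior.p_kidney, prior.spacing), out / "p_kidney.tif")
    np.savetxt(out / "counts_kidney.txt", prior.counts_kidney, fmt="%d")
    meta = {
        "n_images": int(prior.n_images),
        "beta": float(prior.beta),
        "reference_id": prior.reference_id,
        "spacing": [float(s) for s in prior.spacing],
        "transforms": {
            sid: [float(v) for v in t.params]
            for sid, t in (prior.transforms or {}).items()
        },
    }
    (out / "prior.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_prior(in_dir: str | Path) -> ShapePrior:
    d = Path(in_dir)
    meta = yaml.safe_load((d / "prior.yaml").read_text())
    counts = np.loadtxt(d / "counts_kidney.txt", dtype=np.int64)
    n, beta = int(meta["n_images"]), float(meta["beta"])
    # probabilities are recomputed from counts: exact, no float-format loss
    p_k = shape_prior_probability(counts, n, beta)
    transforms = {
        sid: AffineTransform(np.array(v[:4]).reshape(2, 2), np.array(v[4:6]))
        for sid, v in (meta.get("transforms") or {}).items()
    }
    return ShapePrior(p_kidney=p_k, n_images=n, beta=beta,
                      counts_kidney=counts,
                      reference_id=meta.get("reference_id", ""),
                      spacing=tuple(meta.get("spacing", (1.0, 1.0))),
                      transforms=transforms)
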