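"""Raster I/O for images, masks and probability maps.

Supported formats: 8/16-bit grayscale PNG and TIFF, 32-bit float TIFF, and
single-slice NIfTI (.nii/.nii.gz). Everything is strictly 2-D: multi-channel
and volumetric inputs are rejected with a typed error, since the method
segments one 2-D DCE-MRI slice at a time.

Reading rules
-------------
* ``intensity`` — returned exactly as stored; no implicit normalisation.
* ``mask`` — the file must contain exactly two distinct values; foreground is
  pixels equal to the larger one.
* ``probability`` — integer-typed files are rescaled to [0, 1] by the dtype
  maximum; float files are taken as-is and must already lie in [0, 1].
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from PIL import Image

from .grid import ImageGrid, LabelMask, ProbabilityMap, DCESequence

__all__ = ["read_image", "write_image", "normalize_intensity", "FormatError",
           "write_subject", "read_subject"]


class FormatError(ValueError):
    """Unsupported or malformed image file."""


_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_RASTER_SUFFIXES = (".png", ".tif", ".tiff") + _NIFTI_SUFFIXES


def _suffix(path: str | Path) -> str:
    name = str(path).lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(name)[1]


def _load_array(path: Path) -> tuple[np.ndarray, tuple[float, float]]:
    """Load a raw 2-D array plus (row, col) spacing from any supported file."""
    sfx = _suffix(path)
    if sfx not in _RASTER_SUFFIXES:
        raise FormatError(f"unsupported format {sfx!r} for {path}")
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if sfx in _NIFTI_SUFFIXES:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise FormatError(f"{path}: expected a single 2-D slice, got shape {arr.shape}")
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]), float(zooms[1]))
        return arr, spacing
    if sfx == ".png":
        with Image.open(path) as im:
            if im.mode not in ("L", "I", "I;16", "F"):
                raise FormatError(f"{path}: multi-channel PNG not supported (mode {im.mode})")
            arr = np.asarray(im)
    else:  # tiff
        arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 2-D grayscale, got shape {arr.shape}")
    return arr, (1.0, 1.0)


def read_image(path: str | Path, kind: str = "intensity",
               spacing: tuple[float, float] | None = None):
    """Read a raster file as a typed object.

    Parameters
    ----------
    path : str or Path
    kind : {"intensity", "mask", "probability"}
    spacing : optional (row_mm, col_mm) override; NIfTI headers provide a
        default, PNG/TIFF default to 1 mm/pixel.
    """
    arr, file_spacing = _load_array(Path(path))
    sp = spacing if spacing is not None else file_spacing
    if kind == "intensity":
        return ImageGrid(arr.astype(np.float64), sp)
    if kind == "mask":
        values = np.unique(arr)
        if len(values) != 2:
            raise FormatError(
                f"{path}: mask not binary ({len(values)} distinct values)")
        return LabelMask((arr == values.max()).astype(np.uint8), sp)
    if kind == "probability":
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
        else:
            arr = arr.astype(np.float64)
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise FormatError(f"{path}: probability values outside [0, 1]")
        return ProbabilityMap(arr, sp)
    raise ValueError(f"unknown kind {kind!r}")


def write_image(obj, path: str | Path) -> None:
    """Write a typed raster to ``path``; format chosen by extension.

    Masks round-trip bit-exactly in every format. Floats written to integer
    formats are quantised (documented bound: half an integer step); float
    TIFF/NIfTI store the array as 32-bit float.
    """
    path = Path(path)
    sfx = _suffix(path)
    if sfx not in _RASTER_SUFFIXES:
        raise FormatError(f"unsupported format {sfx!r} for {path}")
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")

    if isinstance(obj, LabelMask):
        arr = (obj.labels * 255).astype(np.uint8) if sfx == ".png" \
            else obj.labels.astype(np.uint8)
        spacing = obj.spacing
    elif isinstance(obj, ProbabilityMap):
        if sfx == ".png":
            arr = np.rint(obj.p_kidney * 255).astype(np.uint8)
        else:
            arr = obj.p_kidney.astype(np.float32)
        spacing = obj.spacing
    elif isinstance(obj, ImageGrid):
        if sfx == ".png":
            raise FormatError("refusing to write float intensities to PNG; "
                              "use TIFF or NIfTI")
        arr = obj.pixels.astype(np.float32)
        spacing = obj.spacing
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")

    if sfx in _NIFTI_SUFFIXES:
        affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(arr, affine), str(path))
    elif sfx == ".png":
        Image.fromarray(arr).save(str(path))
    else:
        tifffile.imwrite(str(path), arr)


def normalize_intensity(img: ImageGrid) -> ImageGrid:
    """Min–max rescale intensities to span [0, 1]. Idempotent; a constant
    image has no contrast to rescale and raises ValueError."""
    lo, hi = img.pixels.min(), img.pixels.max()
    if hi - lo == 0:
        raise ValueError("cannot normalize a constant image")
    return ImageGrid((img.pixels - lo) / (hi - lo), img.spacing)


# -- subject directory convention --------------------------------------------
# frames named frame_<t>.<ext> with t zero-padded from 1, truth mask truth.<ext>

def write_subject(seq: DCESequence, out_dir: str | Path, ext: str = "tif") -> None:
    """Write a DCE sequence into a subject directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(2, len(str(seq.n_frames)))
    for t, frame in enumerate(seq.frames, start=1):
        write_image(frame, out / f"frame_{t:0{width}d}.{ext}")
    if seq.truth is not None:
        write_image(seq.truth, out / f"truth.{ext}")


def read_subject(subject_dir: str | Path) -> DCESequence:
    """Read a subject directory back into a DCE sequence."""
    d = Path(subject_dir)
    frame_files = sorted(p for p in d.iterdir() if p.name.startswith("frame_"))
    if not frame_files:
        raise FileNotFoundError(f"no frame_* files in {d}")
    frames = [read_image(p, "intensity") for p in frame_files]
    truth_files = [p for p in d.iterdir() if p.name.startswith("truth.")]
    truth = read_image(truth_files[0], "mask") if truth_files else None
    return DCESequence(frames=frames, truth=truth, subject_id=d.name)
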