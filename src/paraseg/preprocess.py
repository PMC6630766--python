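"""Preprocessing chain: load/convert, enhance contrast, resize, exclude.

The chain mirrors a typical clinical preparation of axial MR slices:
DICOM/PNG/JPEG files are converted to [0, 1] grayscale (pixel spacing taken
from DICOM metadata when present), contrast is normalised (min–max by
default, CLAHE optionally), resolution is unified to a square target side
(bilinear for images, nearest-neighbour for masks so they stay binary, with
pixel spacing rescaled to conserve the physical field of view), and records
are excluded when the target touches the image border or — optionally —
when the image is too blurred (variance-of-Laplacian criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import laplace
from skimage import exposure, transform

from .records import ImageRecord

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Fallback pixel spacing (mm) when no metadata and no override is given;
#: the record is flagged via ``spacing_is_default``.
DEFAULT_SPACING_MM = 0.7


@dataclass(frozen=True)
class PreprocessConfig:
    target_side: int = 512
    contrast_method: str = "minmax"   # "minmax" | "clahe" | "none"
    border_contact_margin: int = 1
    blur_exclusion_threshold: float | None = None  # variance of Laplacian

    def __post_init__(self) -> None:
        if self.target_side <= 0:
            raise ValueError("target_side must be positive")
        if self.contrast_method not in ("minmax", "clahe", "none"):
            raise ValueError("contrast_method must be minmax, clahe or none")


def load_and_convert(path, spacing_override: float | None = None) -> ImageRecord:
    """Load a DICOM/PNG/JPEG file as a [0, 1] grayscale record.

    Pixel spacing priority: DICOM PixelSpacing metadata, then
    ``spacing_override``, then :data:`DEFAULT_SPACING_MM` (flagged).
    Multi-frame DICOMs are rejected: the pipeline operates on 2-D slices.
    """
    from pathlib import Path
    path = Path(path)
    suffix = path.suffix.lower()
    spacing = None
    if suffix in (".dcm", ".dicom"):
        import pydicom
        ds = pydicom.dcmread(path)
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise ValueError(f"{path}: multi-frame DICOM; 2-D slices only")
        arr = ds.pixel_array.astype(np.float64)
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a 2-D grayscale DICOM frame")
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            spacing = float(ps[1])  # column spacing = physical pixel width
    else:
        import imageio.v3 as iio
        arr = iio.imread(path).astype(np.float64)
        if arr.ndim == 3:
            arr = arr[..., :3] @ _LUMA   # luminance of an RGB image
    lo, hi = float(arr.min()), float(arr.max())
    image = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if spacing is None and spacing_override is not None:
        spacing = float(spacing_override)
    flagged = spacing is None
    return ImageRecord(image=image,
                       spacing_w=DEFAULT_SPACING_MM if flagged else spacing,
                       identifier=path.stem, spacing_is_default=flagged)


def enhance_contrast(record: ImageRecord, cfg: PreprocessConfig) -> ImageRecord:
    """Contrast enhancement on the image only; masks pass through untouched.

    ``minmax`` maps the observed range to [0, 1]; a constant image is
    returned unchanged (there is no contrast to stretch). ``clahe`` applies
    contrast-limited adaptive histogram equalisation.
    """
    img = record.image
    if cfg.contrast_method == "minmax":
        lo, hi = float(img.min()), float(img.max())
        out = (img - lo) / (hi - lo) if hi > lo else img
    elif cfg.contrast_method == "clahe":
        out = exposure.equalize_adapthist(np.clip(img, 0.0, 1.0))
    else:
        out = img
    return record.copy_with(image=out)


def resize_to_target(record: ImageRecord, cfg: PreprocessConfig) -> ImageRecord:
    """Unify resolution to ``target_side`` square.

    Bilinear interpolation for the image, nearest-neighbour plus
    re-binarisation for masks. Pixel spacing is rescaled per axis so the
    physical field of view is conserved:
    ``spacing_out * target_side = spacing_in * original_side``.
    """
    h, w = record.image.shape
    t = cfg.target_side
    if (h, w) == (t, t):
        return record
    image = transform.resize(record.image, (t, t), order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
    kwargs = {"image": image}
    for name in ("mask_mf", "mask_es"):
        m = getattr(record, name)
        if m is not None:
            mr = transform.resize(m.astype(float), (t, t), order=0, mode="edge",
                                  anti_aliasing=False, preserve_range=True)
            kwargs[name] = (mr > 0.5).astype(np.uint8)
    spacing_h_in = record.spacing_h if record.spacing_h is not None else record.spacing_w
    spacing_w_out = record.spacing_w * (w / t)
    spacing_h_out = spacing_h_in * (h / t)
    kwargs["spacing_w"] = spacing_w_out
    kwargs["spacing_h"] = None if np.isclose(spacing_h_out, spacing_w_out) else spacing_h_out
    return record.copy_with(**kwargs)


def variance_of_laplacian(image: np.ndarray) -> float:
    """Sharpness score: variance of the Laplacian response."""
    return float(laplace(np.asarray(image, dtype=np.float64)).var())


def _touches_border(mask: np.ndarray, margin: int) -> bool:
    if margin <= 0:
        return False
    m = mask > 0
    return bool(m[:margin, :].any() or m[-margin:, :].any()
                or m[:, :margin].any() or m[:, -margin:].any())


def exclusion_filter(records: list[ImageRecord], cfg: PreprocessConfig
                     ) -> tuple[list[ImageRecord], list[tuple[ImageRecord, str]]]:
    """Split records into (kept, rejected-with-reason).

    A record is rejected when any mask pixel lies within
    ``border_contact_margin`` of the image edge, or — if a threshold is
    configured — when its variance-of-Laplacian sharpness falls below
    ``blur_exclusion_threshold``. Records without masks cannot be
    border-checked; they are kept and flagged ``unfiltered`` in ``meta``.
    """
    kept: list[ImageRecord] = []
    rejected: list[tuple[ImageRecord, str]] = []
    for rec in records:
        if (cfg.blur_exclusion_threshold is not None
                and variance_of_laplacian(rec.image) < cfg.blur_exclusion_threshold):
            rejected.append((rec, "blurred"))
            continue
        if not rec.has_masks:
            rec = rec.copy_with(meta={**rec.meta, "unfiltered": True})
            kept.append(rec)
            continue
        touches = any(_touches_border(m, cfg.border_contact_margin)
                      for m in (rec.mask_mf, rec.mask_es) if m is not None)
        if touches:
            rejected.append((rec, "border_contact"))
        else:
            kept.append(rec)
    return kept, rejected


def preprocess(records: list[ImageRecord], cfg: PreprocessConfig
               ) -> tuple[list[ImageRecord], list[tuple[ImageRecord, str]]]:
    """Full chain: contrast, resize, exclusion. Returns (kept, rejected)."""
    staged = [resize_to_target(enhance_contrast(r, cfg), cfg) for r in records]
    return exclusion_filter(staged, cfg)
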