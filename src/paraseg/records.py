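"""The unit of data flowing through the pipeline: one slice with metadata."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class ImageRecord:
    """One grayscale axial slice plus pixel spacing and optional masks.

    Attributes
    ----------
    image:
        2-D float array of gray intensities in [0, 1].
    spacing_w:
        Physical side length of a pixel in mm (the ``w`` of the
        area formula ``A = F * (w * L)**2``). Must be positive.
    spacing_h:
        Row spacing in mm; ``None`` means isotropic (equal to ``spacing_w``).
        Only differs after resizing a non-square image.
    mask_mf, mask_es:
        Optional strictly-binary {0, 1} masks for the multifidus and
        erector spinae, same shape as ``image``.
    identifier:
        Unique string naming the slice.
    spacing_is_default:
        True when no spacing metadata was available and a fallback value
        was assumed.
    """

    image: np.ndarray
    spacing_w: float = 0.7
    mask_mf: np.ndarray | None = None
    mask_es: np.ndarray | None = None
    identifier: str = ""
    spacing_h: float | None = None
    spacing_is_default: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        if not self.spacing_w > 0:
            raise ValueError("spacing_w must be positive")
        for name in ("mask_mf", "mask_es"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m)
            if m.shape != self.image.shape:
                raise ValueError(f"{name} shape {m.shape} != image shape {self.image.shape}")
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"{name} must be strictly binary 0/1")
            setattr(self, name, m.astype(np.uint8))

    def mask(self, target: str) -> np.ndarray | None:
        """Return the mask for ``target`` in {'mf', 'es'}."""
        if target not in ("mf", "es"):
            raise ValueError("target must be 'mf' or 'es'")
        return self.mask_mf if target == "mf" else self.mask_es

    @property
    def has_masks(self) -> bool:
        return self.mask_mf is not None or self.mask_es is not None

    def copy_with(self, **kwargs) -> "ImageRecord":
        return replace(self, **kwargs)
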