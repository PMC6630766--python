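"""Synthetic axial-MR-like phantoms with known muscle masks.

Real paraspinal-muscle slices are hard to segment for three reasons: the
muscle boundary is fuzzy, the gray-level histogram of muscle overlaps the
background's, and muscle shape varies strongly between samples. The
generator reproduces each difficulty with an explicit knob so the rest of
the pipeline can be exercised, end to end, without any clinical data:

* ``boundary_fuzz_sigma`` — Gaussian blur (in px) applied to the rendered
  intensity image (never to the masks), washing out mask edges;
* ``intensity_overlap`` — in [0, 1]; 0 gives well-separated target and
  background gray distributions, 1 makes them nearly coincide (the mean
  separation shrinks and the per-pixel noise grows with the knob);
* ``shape_variability`` — the scale of smooth random radial perturbation
  and placement jitter of the muscle blobs.

Each phantom contains a small bright central blob standing in for the
spinous process, one bilateral pair of blobs adjacent to it (the
multifidus-like target, ``mask_mf``) and one more lateral pair (the
erector-spinae-like target, ``mask_es``). Blob placement guarantees a
clearance of ``border_margin`` pixels from the image border, mirroring the
exclusion of slices whose target touches the black border.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .records import ImageRecord

# Rendered mean gray levels. The target/background separation is
# 0.05 + 0.40 * (1 - intensity_overlap); per-pixel noise sigma is
# 0.03 + 0.05 * intensity_overlap.
_BG_MEAN = 0.35
_SPINE_MEAN = 0.95
_MAX_SEP = 0.40
_MIN_SEP = 0.05


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters; identical config + seed gives identical output."""

    image_side: int = 512
    pixel_spacing_mm: float = 0.7
    n_images: int = 10
    seed: int = 0
    boundary_fuzz_sigma: float = 1.5
    intensity_overlap: float = 0.35
    shape_variability: float = 0.25
    border_margin: int = 8

    def __post_init__(self) -> None:
        if self.image_side < 32 or self.image_side % 16 != 0:
            raise ValueError(
                f"image_side must be >= 32 and a multiple of 16 (the encoder "
                f"downsamples 4x), got {self.image_side}")
        if not 0.0 <= self.intensity_overlap <= 1.0:
            raise ValueError("intensity_overlap must lie in [0, 1]")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")

    @classmethod
    def easy(cls, **kw) -> "PhantomConfig":
        """A low-difficulty condition: crisp edges, well-separated grays."""
        kw.setdefault("boundary_fuzz_sigma", 0.5)
        kw.setdefault("intensity_overlap", 0.1)
        kw.setdefault("shape_variability", 0.1)
        return cls(**kw)


def _blob_mask(side: int, cy: float, cx: float, ry: float, rx: float,
               angle: float, fourier: np.ndarray) -> np.ndarray:
    """Rasterise one smoothly perturbed ellipse.

    The boundary radius is modulated by a low-order Fourier series in the
    polar angle; coefficient magnitudes are clipped so the radius never
    deviates more than 50%, keeping areas bounded.
    """
    yy, xx = np.mgrid[0:side, 0:side]
    dy = yy - cy
    dx = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / rx
    v = (-sa * dx + ca * dy) / ry
    r = np.hypot(u, v)
    theta = np.arctan2(v, u)
    mod = np.zeros_like(theta)
    for k, (a, b) in enumerate(fourier, start=2):
        mod += a * np.cos(k * theta) + b * np.sin(k * theta)
    mod = np.clip(mod, -0.35, 0.35)
    return (r <= 1.0 + mod).astype(np.uint8)


def _sample_fourier(rng: np.random.Generator, scale: float, orders: int = 4) -> np.ndarray:
    ks = np.arange(2, 2 + orders, dtype=float)
    return rng.normal(0.0, scale / ks[:, None], size=(orders, 2))


def _generate_one(cfg: PhantomConfig, rng: np.random.Generator,
                  identifier: str) -> ImageRecord:
    side = cfg.image_side
    s = cfg.shape_variability
    margin = cfg.border_margin
    cy0 = side * (0.5 + 0.04 * s * rng.normal())
    cx0 = side * 0.5

    def jitter(base: float, rel: float) -> float:
        return base * (1.0 + rel * s * rng.normal())

    # spinous-process surrogate: small bright central blob
    spine = _blob_mask(side, cy0, cx0, jitter(0.045 * side, 0.3),
                       jitter(0.03 * side, 0.3), rng.uniform(0, np.pi),
                       _sample_fourier(rng, 0.2 * s))

    def bilateral_pair(offset_frac: float, ry_frac: float, rx_frac: float) -> np.ndarray:
        pair = np.zeros((side, side), dtype=np.uint8)
        for sign in (-1.0, 1.0):
            ry = np.clip(jitter(ry_frac * side, 0.3), 0.03 * side, 0.13 * side)
            rx = np.clip(jitter(rx_frac * side, 0.3), 0.03 * side, 0.13 * side)
            off = jitter(offset_frac * side, 0.15)
            cx = cx0 + sign * off
            cy = cy0 + side * 0.03 * s * rng.normal()
            rmax = max(ry, rx) * 1.35  # radial modulation is clipped at +35%
            cx = float(np.clip(cx, margin + rmax, side - 1 - margin - rmax))
            cy = float(np.clip(cy, margin + rmax, side - 1 - margin - rmax))
            pair |= _blob_mask(side, cy, cx, ry, rx,
                               rng.normal(0, 0.3) * np.pi * s,
                               _sample_fourier(rng, s))
        return pair

    def in_bounds(m: np.ndarray) -> bool:
        frac = m.mean()
        return 0.01 < frac < 0.4

    def carve(m: np.ndarray, other: np.ndarray) -> np.ndarray:
        # keep distinct structures >= 2 px apart by carving a thin gap where
        # they would touch — the fascia-like boundary between adjacent
        # muscles; apparent merging in the image is then produced by the
        # fuzz/overlap knobs, never by the geometry itself
        return m & ~binary_dilation(other > 0, iterations=2) & 1

    # resample geometry until both targets hold a plausible area fraction
    for _ in range(60):
        mask_mf = carve(bilateral_pair(0.12, 0.085, 0.06), spine)
        mask_es = bilateral_pair(0.30, 0.095, 0.08)
        mask_es = carve(carve(mask_es, spine), mask_mf)
        if in_bounds(mask_mf) and in_bounds(mask_es):
            break
    else:  # pragma: no cover - essentially unreachable at sane settings
        raise RuntimeError("could not place muscle blobs within area bounds")

    sep = _MIN_SEP + _MAX_SEP * (1.0 - cfg.intensity_overlap)
    fg_mean = _BG_MEAN + sep
    mu = np.full((side, side), _BG_MEAN)
    mu += 0.03 * gaussian_filter(rng.normal(size=(side, side)), side / 16.0) * (side / 16.0)
    mu[(mask_mf | mask_es) > 0] = fg_mean
    mu[spine > 0] = _SPINE_MEAN
    if cfg.boundary_fuzz_sigma > 0:
        mu = gaussian_filter(mu, cfg.boundary_fuzz_sigma)
    noise_sigma = 0.03 + 0.05 * cfg.intensity_overlap
    img = mu + rng.normal(0.0, noise_sigma, size=(side, side))
    img = np.clip(img, 0.0, 1.0)
    return ImageRecord(image=img.astype(np.float64),
                       spacing_w=cfg.pixel_spacing_mm,
                       mask_mf=mask_mf, mask_es=mask_es,
                       identifier=identifier)


def generate_phantoms(config: PhantomConfig) -> list[ImageRecord]:
    """Generate ``config.n_images`` phantoms, deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    return [_generate_one(config, rng, f"phantom_{i:04d}")
            for i in range(config.n_images)]


def write_fixture_set(records: list[ImageRecord], directory,
                      provenance: dict | None = None) -> Path:
    """Write records as PNGs plus a CSV manifest; returns the manifest path.

    Images are 8-bit grayscale, masks 0/255. Loading the files back through
    the manifest reader reproduces the masks exactly. When ``provenance``
    is given (e.g. the generating config and seed), it is written alongside
    the manifest as ``manifest_provenance.json`` together with the tool
    version and a config hash.
    """
    from . import io as pio  # local import: io depends on records only

    if not records:
        raise ValueError("cannot write an empty record set")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        img_path = directory / f"{rec.identifier}.png"
        pio.write_gray_png(img_path, rec.image)
        row = {"identifier": rec.identifier,
               "image_path": img_path.name,
               "mf_mask_path": "", "es_mask_path": "",
               "spacing_mm": repr(rec.spacing_w)}
        for key, mask in (("mf_mask_path", rec.mask_mf),
                          ("es_mask_path", rec.mask_es)):
            if mask is not None:
                mpath = directory / f"{rec.identifier}_{key.split('_')[0]}.png"
                pio.write_mask_png(mpath, mask)
                row[key] = mpath.name
        rows.append(row)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=[
            "identifier", "image_path", "mf_mask_path", "es_mask_path", "spacing_mm"])
        writer.writeheader()
        writer.writerows(rows)
    if provenance is not None:
        import json

        from . import __version__
        block = {"tool_version": __version__,
                 "config_hash": pio.config_hash(provenance), **provenance}
        (directory / "manifest_provenance.json").write_text(
            json.dumps(block, indent=2))
    return manifest
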