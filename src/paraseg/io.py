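"""Readers and writers: PNG images/masks, CSV manifests, checkpoints, inference.

All writes are atomic (write to a temporary sibling, then ``os.replace``) so
an interrupted run never leaves a partial file that would pass validation.
Probability maps are stored as 16-bit grayscale PNG (``round(p * 65535)``),
which is lossless at the resolution needed for 0.5-thresholding; masks are
8-bit 0/255 PNG.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .records import ImageRecord

MANIFEST_COLUMNS = ["identifier", "image_path", "mf_mask_path",
                    "es_mask_path", "spacing_mm"]


def _atomic_write(path: Path, write_fn) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        write_fn(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_gray_png(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    _atomic_write(Path(path), lambda p: iio.imwrite(
        p, np.round(arr * 255.0).astype(np.uint8), extension=".png"))


def write_mask_png(path, mask: np.ndarray) -> None:
    """Write a binary {0,1} mask as a 0/255 8-bit PNG."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    _atomic_write(Path(path), lambda p: iio.imwrite(p, arr, extension=".png"))


def write_prob_png(path, prob: np.ndarray) -> None:
    """Write a [0, 1] probability map as 16-bit PNG."""
    arr = np.round(np.clip(np.asarray(prob), 0.0, 1.0) * 65535.0).astype(np.uint16)
    _atomic_write(Path(path), lambda p: iio.imwrite(p, arr, extension=".png"))


def read_prob_png(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.dtype != np.uint16:
        raise ValueError(f"{path}: expected a 16-bit probability PNG")
    return arr.astype(np.float64) / 65535.0


def read_mask_png(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


@dataclass
class Manifest:
    """Validated table of dataset rows plus the directory they live in."""

    frame: pd.DataFrame
    root: Path

    def __len__(self) -> int:
        return len(self.frame)

    def load_records(self) -> list[ImageRecord]:
        from .preprocess import load_and_convert
        records = []
        for _, row in self.frame.iterrows():
            rec = load_and_convert(self.root / row.image_path,
                                   spacing_override=float(row.spacing_mm))
            masks = {}
            for col, field in (("mf_mask_path", "mask_mf"),
                               ("es_mask_path", "mask_es")):
                val = row[col]
                if isinstance(val, str) and val:
                    masks[field] = read_mask_png(self.root / val)
            records.append(rec.copy_with(identifier=str(row.identifier), **masks))
        return records


def read_manifest(path) -> Manifest:
    """Read and validate a CSV manifest (see ``MANIFEST_COLUMNS``)."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    dupes = frame.identifier[frame.identifier.duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate identifiers: {sorted(dupes)}")
    for i, val in enumerate(frame.spacing_mm):
        try:
            s = float(val)
        except ValueError:
            raise ValueError(
                f"{path}: row {i}: column spacing_mm is not numeric: {val!r}")
        if not s > 0:
            raise ValueError(f"{path}: row {i}: spacing_mm must be positive")
    root = path.parent
    problems = []
    for i, row in frame.iterrows():
        for col in ("image_path", "mf_mask_path", "es_mask_path"):
            val = row[col]
            if col == "image_path" or val:
                if not (root / val).exists():
                    problems.append(f"row {i}: missing file {val}")
    if problems:
        raise FileNotFoundError(f"{path}: " + "; ".join(problems))
    return Manifest(frame=frame, root=root)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: dict[str, np.ndarray], config: dict,
                    extra: dict | None = None) -> None:
    """Save model weights (npz) with a sidecar JSON echoing the config."""
    path = Path(path)
    if path.suffix != ".npz":
        raise ValueError("checkpoint path must end in .npz")
    _atomic_write(path, lambda p: np.savez(p, **state))
    sidecar = {"network_config": config, **(extra or {})}
    _atomic_write(path.with_suffix(".json"),
                  lambda p: p.write_text(json.dumps(sidecar, indent=2)))


def load_checkpoint(path):
    """Return (state_dict, sidecar_dict)."""
    path = Path(path)
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return state, sidecar


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# batch inference
# ---------------------------------------------------------------------------

def predict(checkpoint_path, manifest: Manifest, out_dir, threshold: float = 0.5,
            target_side: int | None = None) -> pd.DataFrame:
    """Run a trained model over a manifest and write probability/mask PNGs.

    For each record, writes ``<id>_prob.png`` (16-bit probability map) and
    ``<id>_mask.png`` (0/255 binarisation at ``threshold``), plus a JSON run
    log recording the config hash. Returns a table of output paths.
    """
    from .network import NetworkConfig, build_network, predict_proba
    from .preprocess import PreprocessConfig, resize_to_target

    state, sidecar = load_checkpoint(checkpoint_path)
    cfg = NetworkConfig.from_dict(sidecar["network_config"])
    model = build_network(cfg)
    model.load_state_dict(state)
    side = target_side or cfg.input_side
    pcfg = PreprocessConfig(target_side=side)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = manifest.load_records()
    rows = []
    for rec in records:
        if rec.image.shape != (side, side):
            rec = resize_to_target(rec, pcfg)
        prob = predict_proba(model, rec.image)[0]
        prob_path = out_dir / f"{rec.identifier}_prob.png"
        mask_path = out_dir / f"{rec.identifier}_mask.png"
        write_prob_png(prob_path, prob)
        write_mask_png(mask_path, prob >= threshold)
        rows.append({"identifier": rec.identifier,
                     "prob_path": str(prob_path), "mask_path": str(mask_path),
                     "spacing_mm": rec.spacing_w})
    log = {"config_hash": config_hash(sidecar["network_config"]),
           "seed": sidecar.get("seed"),
           "threshold": threshold, "n_images": len(rows)}
    _atomic_write(out_dir / "predict_log.json",
                  lambda p: p.write_text(json.dumps(log, indent=2)))
    return pd.DataFrame(rows)
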