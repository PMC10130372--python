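"""File IO: grayscale TIFF/PNG channel images, 0/255 PNG masks, cohort
CSVs and YAML parameter sidecars."""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .types import ChannelImage, TissueMask

__all__ = [
    "save_channel",
    "load_channel",
    "save_mask",
    "load_mask",
    "save_float_map",
    "save_params_yaml",
    "load_yaml",
    "write_specimen",
    "write_cohort",
]


def save_channel(path, img: ChannelImage) -> None:
    """Write a channel as 16-bit grayscale TIFF (intensities clipped to
    the uint16 range)."""
    arr = np.clip(np.rint(img.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def load_channel(path, channel: str = "other", pixel_size: float = 20.0) -> ChannelImage:
    """Read an 8/16-bit grayscale TIFF or PNG as a ChannelImage."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an accidental RGB read
        arr = arr[..., 0]
    return ChannelImage(pixels=arr.astype(float), channel=channel, pixel_size=pixel_size)


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(str(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask(path) -> np.ndarray:
    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def save_float_map(path, values: np.ndarray) -> None:
    """Write a concentration map as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))


def _plain(obj):
    if is_dataclass(obj):
        return _plain(asdict(obj))
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_params_yaml(path, params) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(params), fh, sort_keys=True)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_specimen(outdir, specimen) -> Path:
    """Write one synthetic specimen's channels and truth masks."""
    outdir = Path(outdir) / specimen.specimen_id
    outdir.mkdir(parents=True, exist_ok=True)
    save_channel(outdir / "nuclear.tif", specimen.channels["nuclear"])
    save_channel(outdir / "marker_a.tif", specimen.channels["marker_a"])
    save_channel(outdir / "marker_b.tif", specimen.channels["marker_b"])
    save_mask(outdir / "tissue_truth.png", specimen.tissue.mask)
    save_mask(outdir / "cancer_annotation.png", specimen.cancer_annotation)
    save_mask(outdir / "truth_signal_a.png", specimen.truth_signal["marker_a"].mask)
    save_mask(outdir / "truth_signal_b.png", specimen.truth_signal["marker_b"].mask)
    return outdir


def write_cohort(outdir, bundle, params=None) -> Path:
    """Write a synthetic cohort: per-specimen images, the outcome table
    and a YAML echo of the generating parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for spec in bundle.specimens:
        write_specimen(outdir / "specimens", spec)
    cols = ["specimen_id", "time", "event", "het_truth"]
    bundle.outcomes[cols].to_csv(outdir / "cohort.csv", index=False)
    if params is not None:
        save_params_yaml(outdir / "params.yaml", params)
    return outdir
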