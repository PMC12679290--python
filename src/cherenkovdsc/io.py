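"""Grid and result file formats.

2-D grids travel as 16-bit grayscale TIFF (min-max scaled with the scale
recorded in a JSON sidecar), PNG, or plain CSV; masks and difference maps as
PNG with the 0/128/255 encoding for -1/0/+1.  Everything else (presets,
sweep results, manifests) is JSON, and experiment configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "read_grid",
    "sidecar_path",
    "write_difference_png",
    "write_grid_csv",
    "write_grid_tiff",
    "write_mask_png",
]

_U16_MAX = 65535


def sidecar_path(path) -> Path:
    """JSON sidecar next to a grid file (``image.tif`` -> ``image.tif.json``)."""
    p = Path(path)
    return p.with_name(p.name + ".json")


def write_grid_tiff(path, values: np.ndarray, spacing_mm: float | None = None) -> None:
    """Write a float grid as min-max scaled 16-bit TIFF plus a JSON sidecar.

    The sidecar records ``offset`` and ``scale`` such that
    ``float = offset + scale * uint16`` recovers the original values.
    """
    values = np.asarray(values, dtype=float)
    lo = float(values.min())
    hi = float(values.max())
    scale = (hi - lo) / _U16_MAX if hi > lo else 1.0
    scaled = np.round((values - lo) / scale).astype(np.uint16)
    tifffile.imwrite(str(path), scaled)
    meta = {"offset": lo, "scale": scale, "shape": list(values.shape)}
    if spacing_mm is not None:
        meta["spacing_mm"] = spacing_mm
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def write_grid_csv(path, values: np.ndarray) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), delimiter=",", fmt="%.8g")


def read_grid(path) -> tuple[np.ndarray, dict]:
    """Load a 2-D grid from TIFF/PNG/CSV, applying any JSON sidecar rescale.

    Returns ``(values, metadata)`` with values as float64.
    """
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        values = np.asarray(tifffile.imread(str(p)), dtype=float)
    elif suffix == ".png":
        values = np.asarray(Image.open(p).convert("I"), dtype=float)
    elif suffix in (".csv", ".txt"):
        values = np.loadtxt(p, delimiter=",", dtype=float)
    else:
        raise ValueError(f"unsupported grid format {suffix!r} (use TIFF, PNG or CSV)")
    if values.ndim != 2:
        raise ValueError(f"{p} does not contain a 2-D grid")
    meta: dict = {}
    sc = sidecar_path(p)
    if sc.exists():
        meta = json.loads(sc.read_text())
        values = meta.get("offset", 0.0) + meta.get("scale", 1.0) * values
    return values, meta


def write_mask_png(path, mask: np.ndarray) -> None:
    """Binary mask as an 8-bit PNG (0 = outside, 255 = inside)."""
    arr = np.asarray(mask, dtype=bool).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def write_difference_png(path, diff: np.ndarray) -> None:
    """Signed ternary difference map as PNG: -1 -> 0, 0 -> 128, +1 -> 255."""
    diff = np.asarray(diff)
    if not np.isin(diff, (-1, 0, 1)).all():
        raise ValueError("difference map must contain only -1, 0, +1")
    lut = np.array([0, 128, 255], dtype=np.uint8)
    Image.fromarray(lut[diff.astype(np.int16) + 1], mode="L").save(path)


def read_difference_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.int16)
    out = np.zeros(arr.shape, dtype=np.int8)
    out[arr >= 192] = 1
    out[arr < 64] = -1
    return out
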