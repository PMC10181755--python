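"""Reading and writing holograms, maps and metadata.

Holograms travel as four single-channel TIFFs named ``ccd1.tif`` .. ``ccd4.tif``
(8/16-bit unsigned integer or 32-bit float) with a JSON sidecar recording the
camera-to-phase-shift mapping, seed and scale.  Integer images are normalized
to [0, 1] by the dtype full scale on read; the arctangent reconstruction is a
ratio, so a common scale factor cancels.  Phase and thickness maps are 32-bit
float TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .forward import PHASE_SHIFTS, HologramSet

__all__ = [
    "HologramFormatError",
    "write_hologram_set",
    "read_hologram_set",
    "write_map",
    "read_map",
]

_CHANNELS = (1, 2, 3, 4)


class HologramFormatError(ValueError):
    """Missing channel, inconsistent dimensions or unsupported pixel format."""


def write_hologram_set(
    holos: HologramSet,
    directory: str | Path,
    bit_depth: int = 16,
    metadata: dict | None = None,
) -> list[Path]:
    """Write the four holograms as unsigned-integer TIFFs plus a JSON sidecar.

    Intensities are clipped to [0, 1] and scaled to the full range of the
    requested integer ``bit_depth`` (8 or 16); ``bit_depth=0`` writes 32-bit
    float images unscaled.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for ccd in _CHANNELS:
        img = holos.images[ccd]
        if bit_depth == 0:
            data = img.astype(np.float32)
        elif bit_depth in (8, 16):
            full = 2**bit_depth - 1
            dtype = np.uint8 if bit_depth == 8 else np.uint16
            data = np.round(np.clip(img, 0.0, 1.0) * full).astype(dtype)
        else:
            raise ValueError(f"unsupported bit_depth {bit_depth}; use 8, 16 or 0 (float)")
        p = directory / f"ccd{ccd}.tif"
        tifffile.imwrite(p, data)
        paths.append(p)
    meta = {
        "phase_shift_of": {str(c): holos.phase_shift_of[c] for c in _CHANNELS},
        "pixel_size_um": holos.pixel_size,
        "bit_depth": bit_depth,
    }
    if metadata:
        meta.update(metadata)
    with open(directory / "metadata.json", "w") as f:
        json.dump(meta, f, indent=1)
    return paths


def read_hologram_set(source: str | Path | dict[int, str | Path]) -> HologramSet:
    """Read four single-channel TIFFs into a :class:`HologramSet`.

    ``source`` is either a directory containing ``ccd1.tif`` .. ``ccd4.tif``
    (plus optional ``metadata.json``) or an explicit mapping channel -> path.
    Unsigned-integer images are scaled to [0, 1] by the dtype full scale;
    float images pass through unchanged.
    """
    meta: dict = {}
    if isinstance(source, dict):
        paths = {int(c): Path(p) for c, p in source.items()}
    else:
        d = Path(source)
        paths = {c: d / f"ccd{c}.tif" for c in _CHANNELS}
        mp = d / "metadata.json"
        if mp.exists():
            with open(mp) as f:
                meta = json.load(f)
    missing = [c for c in _CHANNELS if c not in paths or not paths[c].exists()]
    if missing:
        raise HologramFormatError(f"missing hologram channel(s): {missing}")
    images = {}
    for c in _CHANNELS:
        arr = tifffile.imread(paths[c])
        if arr.ndim != 2:
            raise HologramFormatError(f"channel {c}: expected a single-channel 2-D image, got shape {arr.shape}")
        if arr.dtype in (np.uint8, np.uint16):
            images[c] = arr.astype(float) / float(np.iinfo(arr.dtype).max)
        elif np.issubdtype(arr.dtype, np.floating):
            images[c] = arr.astype(float)
        else:
            raise HologramFormatError(f"channel {c}: unsupported pixel type {arr.dtype}")
    shapes = {im.shape for im in images.values()}
    if len(shapes) != 1:
        raise HologramFormatError(f"channel dimensions differ: {shapes}")
    shifts = dict(PHASE_SHIFTS)
    if "phase_shift_of" in meta:
        shifts = {int(c): float(v) for c, v in meta["phase_shift_of"].items()}
    return HologramSet(images, shifts, pixel_size=meta.get("pixel_size_um"))


def write_map(values: np.ndarray, path: str | Path, **tags) -> Path:
    """Write a floating-point map (phase, thickness, mask) as float32 TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32), metadata=tags or None)
    return path


def read_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)
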