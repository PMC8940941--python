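"""Lossless stack I/O: 8-bit grayscale multi-page TIFF + JSON sidecars.

The canonical on-disk stack format is an 8-bit grayscale multi-page TIFF
(one page per frame, order preserved); scene/run metadata — ROI masks as
run-length encodings, true traces, seeds — travels in a JSON sidecar next to
the TIFF.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "write_stack",
    "read_stack",
    "write_sidecar",
    "read_sidecar",
    "mask_to_rle",
    "rle_to_mask",
    "file_sha256",
]


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (T, H, W) stack as 8-bit grayscale multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (T, H, W)")
    data = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF back as a (T, H, W) uint8 array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def mask_to_rle(mask: np.ndarray) -> dict:
    """Run-length encode a binary mask (C-order runs of True pixels)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    diffs = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = []
    lengths = []
    run_open = bool(flat[0]) if flat.size else False
    if run_open:
        starts.append(0)
    for d in diffs:
        if run_open:
            lengths.append(int(d + 1 - starts[-1]))
        else:
            starts.append(int(d + 1))
        run_open = not run_open
    if run_open:
        lengths.append(int(flat.size - starts[-1]))
    return {"shape": list(mask.shape), "starts": starts, "lengths": lengths}


def rle_to_mask(rle: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(rle["shape"])), dtype=bool)
    for s, l in zip(rle["starts"], rle["lengths"]):
        flat[s : s + l] = True
    return flat.reshape(rle["shape"])


def write_sidecar(path: str | Path, meta: dict) -> None:
    Path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
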