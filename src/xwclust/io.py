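"""PNG and array I/O helpers.

Images travel through the pipeline as float arrays in [0, 1] (H, W, 3);
on disk they are 8-bit RGB PNGs. Masks are single-channel {0, 255} PNGs.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as an 8-bit RGB PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (np.round(arr * 255.0)).astype(np.uint8))


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit image back into float [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3].astype(np.float64) / 255.0


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
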