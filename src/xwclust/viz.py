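"""Explanation overlays and image galleries.

Overlays follow the usual saliency semantics: green where a region supports
the pathological prediction, red where it argues against it, with blend
opacity (brightness) proportional to importance magnitude. Zero-importance
pixels show the unmodified image.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DimensionError, ParameterError
from .occlusion import ImportanceMap


@dataclasses.dataclass(frozen=True)
class OverlayStyle:
    positive_color: tuple[float, float, float] = (0.0, 1.0, 0.0)
    negative_color: tuple[float, float, float] = (1.0, 0.0, 0.0)
    max_alpha: float = 1.0
    gamma: float = 1.0  # alpha = |value|**gamma * max_alpha

    def __post_init__(self):
        if not 0.0 <= self.max_alpha <= 1.0:
            raise ParameterError("max_alpha must lie in [0, 1]")
        if self.gamma <= 0:
            raise ParameterError("gamma must be > 0")


def render_overlay(
    image: np.ndarray,
    explanation: ImportanceMap | np.ndarray,
    style: OverlayStyle | None = None,
) -> np.ndarray:
    """Alpha-blend green (positive) and red (negative) saliency onto an image."""
    style = style or OverlayStyle()
    values = explanation.values if isinstance(explanation, ImportanceMap) else explanation
    image = np.asarray(image, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if image.shape[:2] != values.shape:
        raise DimensionError("image and explanation shapes disagree")
    pos = np.clip(values, 0.0, 1.0)
    neg = np.clip(-values, 0.0, 1.0)
    a_pos = (pos ** style.gamma * style.max_alpha)[..., None]
    a_neg = (neg ** style.gamma * style.max_alpha)[..., None]
    green = np.asarray(style.positive_color)
    red = np.asarray(style.negative_color)
    out = image * (1.0 - a_pos) + green * a_pos
    out = out * (1.0 - a_neg) + red * a_neg
    return np.clip(out, 0.0, 1.0)


def tile_gallery(images: list[np.ndarray], n_cols: int = 5, pad: int = 2) -> np.ndarray:
    """Tile equally sized images into one canvas (white padding)."""
    if not images:
        raise ParameterError("no images to tile")
    h, w = images[0].shape[:2]
    n_rows = (len(images) + n_cols - 1) // n_cols
    canvas = np.ones((n_rows * (h + pad) + pad, n_cols * (w + pad) + pad, 3))
    for i, img in enumerate(images):
        r, c = divmod(i, n_cols)
        top = pad + r * (h + pad)
        left = pad + c * (w + pad)
        canvas[top:top + h, left:left + w] = img
    return canvas
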