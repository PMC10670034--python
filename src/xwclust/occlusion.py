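"""Occlusion-based attribution with signed normalization and power-law smoothing.

The attribution of a pixel is the average drop in the classifier's pathology
probability when gray patches covering that pixel are slid over the image:
with a patch grid P_1..P_N and reference probability f(I),

    Y_j = (1 / |J|) * sum_{i in J} ( f(I) - g(I, P_i) ),      J = {i : j in P_i},

where g(I, P) is f applied to the image with the patch region replaced by the
neutral gray C (128/255 per channel). Positive Y_j means occluding pixel j
lowers the pathology probability — the pixel supports the pathological call.

Raw maps are normalized to [-1, 1] (positives by the max positive, negatives by
the absolute minimum) and then sharpened by a two-branch smoothing function

    S(x, theta, sigma) = x^sigma / theta^(sigma-1)              if x <= theta
                         1 - (1-x)^sigma / (1-theta)^(sigma-1)  otherwise

which suppresses values below the offset theta and amplifies those above;
sigma >= 1 sets the transition sharpness. S fixes 0, theta and 1, is continuous
at theta, and is strictly increasing on [0, 1]. Negative values are smoothed by
magnitude with the sign restored, keeping the positive/negative semantics of
the overlay visualizations symmetric.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .errors import DimensionError, DomainError, ParameterError

#: Neutral occlusion gray: 128 on the 8-bit scale, exactly.
DEFAULT_GRAY = 128.0 / 255.0

Rect = tuple[int, int, int, int]  # (top, left, height, width)


@dataclasses.dataclass(frozen=True)
class PatchGrid:
    """Sliding-patch layout: every image pixel is covered by >= 1 patch."""

    height: int
    width: int
    patch_h: int
    patch_w: int
    stride: int
    rects: tuple[Rect, ...]

    @property
    def n_patches(self) -> int:
        return len(self.rects)


@dataclasses.dataclass(frozen=True)
class SmoothParams:
    """Offset theta in (0, 1) and strength sigma >= 1 of the smoothing curve."""

    theta: float = 0.1
    sigma: float = 8.0

    def __post_init__(self):
        if not 0.0 < self.theta < 1.0:
            raise ParameterError("theta must lie in (0, 1)")
        if self.sigma < 1.0:
            raise ParameterError("sigma must be >= 1")


@dataclasses.dataclass
class ImportanceMap:
    """Per-pixel attribution with a processing-stage tag.

    ``stage`` is one of 'raw', 'normalized', 'smoothed'; ``f_ref`` records the
    unoccluded classifier probability f(I) the differences refer to.
    """

    values: np.ndarray
    stage: str
    f_ref: float | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def shape(self):
        return self.values.shape


def default_patch_and_stride(side: int) -> tuple[int, int]:
    """Default geometry when unspecified: patch ~ side/3.5, stride = patch/4
    (224 -> 64/16, 64 -> 18/4)."""
    patch = max(2, int(round(side / 3.5)))
    return patch, max(1, int(round(patch / 4)))


def make_patch_grid(h: int, w: int, patch_h: int, patch_w: int, stride: int) -> PatchGrid:
    """Regular grid of patch positions at multiples of ``stride``, augmented
    with a final row/column clamped flush to the bottom/right edges whenever the
    regular grid would leave pixels uncovered."""
    if patch_h > h or patch_w > w:
        raise DimensionError("patch larger than image")
    if patch_h < 1 or patch_w < 1 or stride < 1:
        raise ParameterError("patch sides and stride must be >= 1")
    if stride > min(patch_h, patch_w):
        raise ParameterError(
            "stride must not exceed the patch side, or interior pixels "
            "would never be occluded")
    tops = list(range(0, h - patch_h + 1, stride))
    if tops[-1] != h - patch_h:
        tops.append(h - patch_h)
    lefts = list(range(0, w - patch_w + 1, stride))
    if lefts[-1] != w - patch_w:
        lefts.append(w - patch_w)
    rects = tuple((t, l, patch_h, patch_w) for t in tops for l in lefts)
    return PatchGrid(h, w, patch_h, patch_w, stride, rects)


def occlude(image: np.ndarray, rect: Rect, gray: float = DEFAULT_GRAY) -> np.ndarray:
    """Copy of ``image`` with all channels inside ``rect`` set to ``gray``."""
    top, left, ph, pw = rect
    h, w = image.shape[:2]
    if ph < 1 or pw < 1:
        raise DimensionError("zero-area occlusion rectangle")
    if top < 0 or left < 0 or top + ph > h or left + pw > w:
        raise DimensionError("occlusion rectangle outside image")
    out = np.array(image, dtype=np.float64, copy=True)
    out[top:top + ph, left:left + pw, :] = gray
    return out


def _as_batch_predictor(classifier) -> Callable[[Sequence[np.ndarray]], np.ndarray]:
    if hasattr(classifier, "predict_proba_many"):
        return lambda images: np.asarray(classifier.predict_proba_many(images),
                                         dtype=np.float64)
    if hasattr(classifier, "predict_proba"):
        fn = classifier.predict_proba
    else:
        fn = classifier
    return lambda images: np.array([float(fn(im)) for im in images])


def attribution_map(
    classifier,
    image: np.ndarray,
    grid: PatchGrid | None = None,
    gray: float = DEFAULT_GRAY,
    batch_size: int = 64,
) -> ImportanceMap:
    """Raw occlusion attribution map.

    ``classifier`` may be a :class:`~xwclust.classifier.ClassifierHandle` or
    any callable image -> probability. f(I) is evaluated once and reused for
    every patch; occluded variants are evaluated in batches, which cannot
    change the result (evaluation is pure). Each raw value is a mean of
    probability differences and therefore lies in [-1, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    if grid is None:
        ph, s = default_patch_and_stride(min(h, w))
        grid = make_patch_grid(h, w, ph, ph, s)
    if (grid.height, grid.width) != (h, w):
        raise DimensionError("grid was built for a different image size")

    predict = _as_batch_predictor(classifier)
    f_ref = float(predict([image])[0])

    diff_sum = np.zeros((h, w))
    count = np.zeros((h, w))
    rects = grid.rects
    for start in range(0, len(rects), batch_size):
        chunk = rects[start:start + batch_size]
        probs = predict([occlude(image, r, gray) for r in chunk])
        for rect, g in zip(chunk, probs):
            top, left, ph, pw = rect
            diff_sum[top:top + ph, left:left + pw] += f_ref - g
            count[top:top + ph, left:left + pw] += 1.0
    if np.any(count == 0):
        raise DimensionError("patch grid does not cover every pixel")
    values = diff_sum / count
    return ImportanceMap(values=values, stage="raw", f_ref=f_ref,
                         meta=dict(patch_h=grid.patch_h, patch_w=grid.patch_w,
                                   stride=grid.stride, gray=gray,
                                   n_patches=grid.n_patches))


def normalize_importance(imp: ImportanceMap) -> ImportanceMap:
    """Scale positives by the maximum positive and negatives by the absolute
    minimum, independently, so the map spans [-1, 1]; zeros pass through.
    Idempotent and invariant to positive rescaling of the input."""
    if imp.stage not in ("raw", "normalized"):
        raise ParameterError(f"cannot normalize a {imp.stage!r}-stage map")
    y = np.array(imp.values, dtype=np.float64, copy=True)
    pos_max = y.max(initial=0.0)
    neg_min = y.min(initial=0.0)
    if pos_max > 0:
        y[y > 0] /= pos_max
    if neg_min < 0:
        y[y < 0] /= -neg_min
    return ImportanceMap(values=y, stage="normalized", f_ref=imp.f_ref,
                         meta=dict(imp.meta))


def smooth_value(x, params: SmoothParams | None = None, *,
                 theta: float | None = None, sigma: float | None = None):
    """Two-branch smoothing curve S(x, theta, sigma) on [0, 1].

    S(x) = x^sigma / theta^(sigma-1) for x <= theta, else
    1 - (1-x)^sigma / (1-theta)^(sigma-1). Accepts scalars or arrays; raises
    :class:`DomainError` outside [0, 1].
    """
    if params is None:
        params = SmoothParams(theta=0.1 if theta is None else theta,
                              sigma=8.0 if sigma is None else sigma)
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise DomainError("smoothing input must lie in [0, 1]")
    th, sg = params.theta, params.sigma
    low = np.power(x, sg) / th ** (sg - 1.0)
    high = 1.0 - np.power(1.0 - x, sg) / (1.0 - th) ** (sg - 1.0)
    out = np.where(x <= th, low, high)
    return float(out) if out.ndim == 0 else out


def smooth_map(imp: ImportanceMap, params: SmoothParams | None = None) -> ImportanceMap:
    """Apply the smoothing curve elementwise to a normalized map, by magnitude
    with sign restored: x >= 0 -> S(x), x < 0 -> -S(|x|)."""
    if imp.stage != "normalized":
        raise ParameterError("smooth_map expects a normalized-stage map")
    params = params or SmoothParams()
    y = imp.values
    out = np.sign(y) * smooth_value(np.abs(y), params)
    meta = dict(imp.meta, theta=params.theta, sigma=params.sigma)
    return ImportanceMap(values=out, stage="smoothed", f_ref=imp.f_ref, meta=meta)


def explain(
    classifier,
    image: np.ndarray,
    grid: PatchGrid | None = None,
    gray: float = DEFAULT_GRAY,
    params: SmoothParams | None = None,
) -> ImportanceMap:
    """Full explanation: attribution -> signed normalization -> smoothing."""
    raw = attribution_map(classifier, image, grid=grid, gray=gray)
    return smooth_map(normalize_importance(raw), params or SmoothParams())
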