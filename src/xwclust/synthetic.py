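"""Pseudo-real dataset generation for explanation-weighted clustering experiments.

The generator emulates endoscopic (gastrointestinal mucosa) imagery at desk scale:
smooth low-frequency pink/red textured backgrounds, an optional green
picture-in-picture (PiP) navigation inset in the bottom-left corner acting as a
confounder, and a pathological class built from the *same* backgrounds with a
single colored geometric overlay (yellow rectangle, blue ellipse, or an irregular
pink "blob" standing in for a polyp). Because the overlay location is known, the
ground-truth explanation of every pathological image is its mask.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon
from skimage.transform import resize as _resize
from skimage.transform import rotate as _rotate

from . import io as xio
from .errors import DimensionError, ParameterError, PlacementError

#: An image is a (H, W, 3) float array with values in [0, 1].
RawImage = np.ndarray

SHAPE_KINDS = ("rectangle", "ellipse", "blob")

#: Named shape presets usable in palettes (kind, RGB color in [0, 1]).
SHAPE_PRESETS = {
    "yellow_rect": ("rectangle", (1.0, 1.0, 0.0)),
    "blue_ellipse": ("ellipse", (0.10, 0.25, 0.90)),
    "pink_blob": ("blob", (0.95, 0.55, 0.75)),
}


@dataclasses.dataclass(frozen=True)
class ShapeSpec:
    """Geometry and color of a single synthetic pathology overlay.

    ``size_fraction`` is (width, height) as fractions of the image dimensions;
    ``position`` is the fractional (cx, cy) center, cx along width and cy along
    height measured from the top-left corner; ``rotation`` is degrees
    counter-clockwise.
    """

    kind: str
    color: tuple[float, float, float]
    size_fraction: tuple[float, float]
    position: tuple[float, float] = (0.5, 0.5)
    rotation: float = 0.0

    def __post_init__(self):
        if self.kind not in SHAPE_KINDS:
            raise ParameterError(f"unknown shape kind {self.kind!r}")
        if not all(0.0 < f < 1.0 for f in self.size_fraction):
            raise ParameterError("size fractions must lie in (0, 1)")


def generate_background(
    height: int, width: int, seed=0, with_pip: bool = False
) -> RawImage:
    """Procedural mucosa-like background: low-frequency correlated noise in a
    pink/red palette, plus fine-grain texture.

    If ``with_pip``, a green-dominated rectangle (the ScopeGuide-style inset)
    occupies the bottom-left region. Deterministic for a fixed ``seed`` (an int
    or a sequence of ints).
    """
    if height < 8 or width < 8:
        raise DimensionError(f"image dimensions must be >= 8, got {height}x{width}")
    rng = np.random.default_rng(seed)
    coarse = rng.random((6, 6, 3))
    field = _resize(coarse, (height, width, 3), order=3, mode="reflect",
                    anti_aliasing=False)
    field = np.clip(field, 0.0, 1.0)
    img = np.empty((height, width, 3), dtype=np.float64)
    img[..., 0] = 0.55 + 0.40 * field[..., 0]   # red dominates
    img[..., 1] = 0.18 + 0.30 * field[..., 1]
    img[..., 2] = 0.22 + 0.32 * field[..., 2]
    img += rng.normal(0.0, 0.015, size=img.shape)  # fine grain
    if with_pip:
        ph = max(2, int(round(0.28 * height)))
        pw = max(2, int(round(0.28 * width)))
        sub = field[height - ph:, :pw, 1]
        img[height - ph:, :pw, 0] = 0.05 + 0.10 * sub
        img[height - ph:, :pw, 1] = 0.45 + 0.35 * sub
        img[height - ph:, :pw, 2] = 0.08 + 0.12 * sub
    return np.clip(img, 0.0, 1.0)


def _blob_vertices(rc, cc, a, b, rotation_deg, rng, n_vertices=72):
    """Polygon vertices of a deformed ellipse with smooth boundary perturbation.

    The radial modulation is a low-order Fourier series clipped to (0.70, 1.00]
    so the blob never exceeds the nominal ellipse bounding box.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    mod = np.ones_like(t)
    for m in range(2, 6):
        mod += rng.normal(0.0, 0.06) * np.cos(m * t) + rng.normal(0.0, 0.06) * np.sin(m * t)
    mod = np.clip(mod, 0.70, 1.00)
    x = a * mod * np.cos(t)
    y = b * mod * np.sin(t)
    phi = np.deg2rad(rotation_deg)
    xr = x * np.cos(phi) - y * np.sin(phi)
    yr = x * np.sin(phi) + y * np.cos(phi)
    return rc + yr, cc + xr


def rasterize_shape(spec: ShapeSpec, height: int, width: int, rng_seed=0) -> np.ndarray:
    """Boolean mask of the shape on an ``height x width`` canvas.

    Raises :class:`PlacementError` if any shape pixel falls outside the frame.
    """
    w_px = max(1, int(round(spec.size_fraction[0] * width)))
    h_px = max(1, int(round(spec.size_fraction[1] * height)))
    cc = spec.position[0] * width
    rc = spec.position[1] * height
    if spec.kind == "rectangle" and spec.rotation == 0.0:
        top = int(round(rc - h_px / 2.0))
        left = int(round(cc - w_px / 2.0))
        if top < 0 or left < 0 or top + h_px > height or left + w_px > width:
            raise PlacementError("rectangle exceeds image bounds")
        mask = np.zeros((height, width), dtype=bool)
        mask[top:top + h_px, left:left + w_px] = True
        return mask
    if spec.kind == "rectangle":
        hw, hh = w_px / 2.0, h_px / 2.0
        corners = np.array([[-hw, -hh], [hw, -hh], [hw, hh], [-hw, hh]])
        phi = np.deg2rad(spec.rotation)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        pts = corners @ rot.T
        rr, cc_ = _draw_polygon(rc + pts[:, 1], cc + pts[:, 0])
    elif spec.kind == "ellipse":
        # point-in-ellipse test on pixel centers (inclusive boundary tracks
        # the continuous area pi*a*b closely even for small shapes)
        a, b = w_px / 2.0, h_px / 2.0
        phi = np.deg2rad(spec.rotation)
        ext_r = np.hypot(a * np.sin(phi), b * np.cos(phi))
        ext_c = np.hypot(a * np.cos(phi), b * np.sin(phi))
        if rc - ext_r < -0.5 or rc + ext_r > height - 0.5 or \
                cc - ext_c < -0.5 or cc + ext_c > width - 0.5:
            raise PlacementError("ellipse exceeds image bounds")
        rows, cols = np.mgrid[0:height, 0:width]
        dy, dx = rows - rc, cols - cc
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    else:  # blob
        rng = np.random.default_rng(rng_seed)
        vr, vc = _blob_vertices(rc, cc, w_px / 2.0, h_px / 2.0, spec.rotation, rng)
        rr, cc_ = _draw_polygon(vr, vc)
    if rr.size == 0:
        raise PlacementError("shape rasterized to zero pixels")
    if rr.min() < 0 or cc_.min() < 0 or rr.max() >= height or cc_.max() >= width:
        raise PlacementError(f"{spec.kind} exceeds image bounds")
    mask = np.zeros((height, width), dtype=bool)
    mask[rr, cc_] = True
    return mask


def overlay_shape(
    image: RawImage, spec: ShapeSpec, rng_seed=0
) -> tuple[RawImage, np.ndarray]:
    """Paint ``spec`` onto a copy of ``image``.

    Pixels inside the shape are replaced by ``spec.color``; the returned binary
    mask marks exactly the replaced pixels. ``rng_seed`` only affects the blob
    kind (boundary perturbation).
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    mask = rasterize_shape(spec, h, w, rng_seed=rng_seed)
    out = image.copy()
    out[mask] = np.asarray(spec.color, dtype=np.float64)
    return out, mask


def crop_and_resize(image: RawImage, target_side: int) -> RawImage:
    """Square crop anchored at the bottom-left corner, then resize.

    The full shorter dimension is retained; excess rows are discarded from the
    top and excess columns from the right (so a 4:5 landscape-height frame loses
    20% from the top, keeping any bottom-left inset). Bilinear resampling; a
    no-op when the crop already has the target side.
    """
    if target_side < 1:
        raise DimensionError("target_side must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    side = min(h, w)
    cropped = image[h - side:, :side]
    if side == target_side:
        return cropped.copy()
    out = _resize(cropped, (target_side, target_side, 3), order=1, mode="reflect",
                  anti_aliasing=side > target_side)
    return np.clip(out, 0.0, 1.0)


def augment(image: RawImage, rng_seed=0, max_rotation: float = 90.0) -> RawImage:
    """Training-time augmentation: each flip with probability 0.5, then a
    rotation by an angle drawn uniformly from [0, max_rotation) degrees with
    reflect-padded fill (no black corners for the classifier to exploit).

    With ``max_rotation=0`` only the flips apply, so the pixel multiset (and
    hence the mean intensity) is exactly preserved.
    """
    rng = np.random.default_rng(rng_seed)
    image = np.asarray(image, dtype=np.float64)
    if image.shape[0] != image.shape[1]:
        raise DimensionError("augment expects a square image")
    out = image
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    angle = rng.uniform(0.0, max_rotation) if max_rotation > 0 else 0.0
    if angle > 0.0:
        out = _rotate(out, angle, mode="reflect", order=1, preserve_range=True)
    return np.clip(np.ascontiguousarray(out), 0.0, 1.0)


@dataclasses.dataclass
class DatasetManifest:
    """Index of a generated dataset: one row per image.

    Columns: image_path, mask_path (empty for healthy), label
    ('healthy'/'pathological'), subtype ('none' or a palette name), split
    ('train'/'val'/'test'), seed (per-record RNG stream id), pip (bool).
    Paths are relative to ``root``.
    """

    frame: pd.DataFrame
    root: Path

    def split(self, tag: str) -> pd.DataFrame:
        return self.frame[self.frame["split"] == tag].reset_index(drop=True)

    def load_image(self, row) -> RawImage:
        return xio.load_image(self.root / row["image_path"])

    def load_mask(self, row) -> np.ndarray:
        if not row["mask_path"]:
            raise ValueError("record has no mask (healthy image)")
        return xio.load_mask(self.root / row["mask_path"])

    def save(self) -> None:
        self.frame.to_csv(self.root / "manifest.csv", index=False)
        xio.save_json(self.root / "manifest.json",
                      self.frame.to_dict(orient="records"))

    @classmethod
    def load(cls, root: str | Path) -> "DatasetManifest":
        root = Path(root)
        frame = pd.read_csv(root / "manifest.csv", keep_default_na=False)
        frame["pip"] = frame["pip"].astype(bool)
        return cls(frame=frame, root=root)


def _split_tags(n: int, splits: Sequence[float], rng) -> np.ndarray:
    """Random split assignment with largest-remainder rounding of sizes."""
    fracs = np.asarray(splits, dtype=float)
    if fracs.size != 3 or not np.isclose(fracs.sum(), 1.0):
        raise ParameterError("splits must be three fractions summing to 1")
    sizes = np.floor(fracs * n).astype(int)
    rem = fracs * n - sizes
    for i in np.argsort(-rem)[: n - sizes.sum()]:
        sizes[i] += 1
    tags = np.repeat(np.array(["train", "val", "test"]), sizes)
    rng.shuffle(tags)
    return tags


def build_dataset(
    out_dir: str | Path,
    n_total: int,
    pathology_rate: float = 0.5,
    shape_palette: Sequence[str] = ("yellow_rect", "blue_ellipse"),
    size_fraction_range: tuple[float, float] = (0.20, 0.25),
    splits: Sequence[float] = (0.64, 0.16, 0.20),
    seed: int = 0,
    side: int = 64,
    pip_rate: float = 0.3,
    stratified: bool = False,
    background_dir: str | Path | None = None,
) -> DatasetManifest:
    """Generate a healthy/pathological image dataset with ground-truth masks.

    Exactly ``round(n_total * pathology_rate)`` images are pathological; each
    carries one shape drawn from ``shape_palette`` (independent uniform draws by
    default, exact per-subtype counts with ``stratified=True``). Pathological
    backgrounds reuse the healthy generator with the same per-record seed, so an
    image pair differs only inside the mask. Splits are assigned per
    (label, subtype) stratum so all classes appear in every split. If
    ``background_dir`` is given, backgrounds are drawn (with wrap-around) from
    the PNG/JPEG files there, cropped and resized, instead of the procedural
    generator.
    """
    if n_total < 4:
        raise ParameterError("n_total must be >= 4")
    if not 0.0 < pathology_rate < 1.0:
        raise ParameterError("pathology_rate must be in (0, 1)")
    if len(shape_palette) < 1:
        raise ParameterError("shape_palette must contain at least one shape")
    lo, hi = size_fraction_range
    if not (0.0 < lo <= hi < 1.0):
        raise ParameterError("invalid size_fraction_range")

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng([seed, 0xD5])
    n_path = int(round(n_total * pathology_rate))
    labels = np.array(["healthy"] * (n_total - n_path) + ["pathological"] * n_path)

    n_shapes = len(shape_palette)
    subtypes = np.array(["none"] * n_total, dtype=object)
    if stratified:
        reps = [n_path // n_shapes + (1 if i < n_path % n_shapes else 0)
                for i in range(n_shapes)]
        pool = np.repeat(np.asarray(shape_palette, dtype=object), reps)
        master.shuffle(pool)
        subtypes[n_total - n_path:] = pool
    else:
        subtypes[n_total - n_path:] = master.choice(
            np.asarray(shape_palette, dtype=object), size=n_path)

    backgrounds = None
    if background_dir is not None:
        backgrounds = sorted(
            p for p in Path(background_dir).iterdir()
            if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if not backgrounds:
            raise ParameterError(f"no images found in {background_dir}")

    # Stratified split assignment: every (label, subtype) stratum split separately.
    split_tags = np.empty(n_total, dtype=object)
    for key in dict.fromkeys(zip(labels, subtypes)):
        idx = np.flatnonzero([(l, s) == key for l, s in zip(labels, subtypes)])
        split_tags[idx] = _split_tags(idx.size, splits, master)

    records = []
    for i in range(n_total):
        rec_rng = np.random.default_rng([seed, 1, i])
        pip = bool(rec_rng.random() < pip_rate)
        if backgrounds is None:
            img = generate_background(side, side, seed=[seed, 2, i], with_pip=pip)
        else:
            img = crop_and_resize(xio.load_image(backgrounds[i % len(backgrounds)]), side)
        mask_path = ""
        if labels[i] == "pathological":
            kind, color = SHAPE_PRESETS[subtypes[i]]
            wf = rec_rng.uniform(lo, hi)
            hf = rec_rng.uniform(lo, hi)
            # uniform center keeping the shape fully inside the frame
            w_px = int(round(wf * side)) + 2
            h_px = int(round(hf * side)) + 2
            cx = rec_rng.uniform(w_px / 2 / side, 1.0 - w_px / 2 / side)
            cy = rec_rng.uniform(h_px / 2 / side, 1.0 - h_px / 2 / side)
            spec = ShapeSpec(kind=kind, color=color, size_fraction=(wf, hf),
                             position=(cx, cy))
            img, mask = overlay_shape(img, spec, rng_seed=[seed, 3, i])
            mask_path = f"masks/{i:05d}.png"
            xio.save_mask(out_dir / mask_path, mask)
        image_path = f"images/{i:05d}.png"
        xio.save_image(out_dir / image_path, img)
        records.append(dict(image_path=image_path, mask_path=mask_path,
                            label=labels[i], subtype=subtypes[i],
                            split=split_tags[i], seed=i, pip=pip))

    frame = pd.DataFrame.from_records(records)
    manifest = DatasetManifest(frame=frame, root=out_dir)
    manifest.save()
    return manifest
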