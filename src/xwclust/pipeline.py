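"""End-to-end orchestration of the four-step discovery procedure.

Step 1 trains a healthy-vs-pathological classifier; Step 2 computes occlusion
explanations for every image the classifier calls pathological; Step 3 forms
explanation-weighted images; Step 4 clusters them and scores the clusters.
Each stage persists its outputs, and Step 4 can be re-run standalone from the
persisted Step-3 outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as xio
from .classifier import ClassifierHandle, TrainConfig, train_classifier
from .clustering import (KSelection, assign_unseen, rand_index, reduce_features,
                         select_k, weight_image)
from .errors import ParameterError
from .occlusion import (DEFAULT_GRAY, SmoothParams, explain, make_patch_grid)
from .synthetic import DatasetManifest, build_dataset
from .viz import render_overlay, tile_gallery


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a full run from a single seed."""

    seed: int = 0
    # dataset
    n_total: int = 500
    side: int = 64
    pathology_rate: float = 0.5
    shape_palette: Sequence[str] = ("yellow_rect", "blue_ellipse")
    size_fraction_range: tuple[float, float] = (0.20, 0.25)
    splits: Sequence[float] = (0.64, 0.16, 0.20)
    pip_rate: float = 0.3
    stratified: bool = False
    background_dir: str | None = None
    data_dir: str | None = None  # reuse an existing dataset instead of generating
    # training
    arch: str = "small_cnn"
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    # explanation
    patch: int = 16
    stride: int = 8
    theta: float = 0.1
    sigma: float = 8.0
    gray: float = DEFAULT_GRAY
    # clustering
    k_min: int = 2
    k_max: int = 6
    svd_variance: float = 0.9
    svd_cap: int = 32
    n_restarts: int = 10
    l2_normalize: bool = True  # L2-normalize penultimate features row-wise
    dihedral_features: bool = True  # average features over the 8 flips/rotations
    recenter_weighted: bool = True  # shift each cut-out's mass centroid to center

    def validate(self) -> None:
        if self.k_max < self.k_min or self.k_min < 2:
            raise ParameterError("need 2 <= k_min <= k_max")
        if self.patch < 1 or self.stride < 1:
            raise ParameterError("patch and stride must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        train = TrainConfig(**raw.pop("train", {}))
        return cls(train=train, **raw)


def explain_and_weight(
    handle: ClassifierHandle,
    manifest: DatasetManifest,
    config: RunConfig,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Steps 2-3: explanations and weighted images for every image classified
    pathological (probability >= 0.5), across all splits.

    Writes per-image float32 ``.npy`` arrays (explanation and weighted image),
    a JSON sidecar with the XAI settings, and an index table
    ``weighted/index.csv``; returns that table.
    """
    out_dir = Path(out_dir)
    (out_dir / "explanations").mkdir(parents=True, exist_ok=True)
    (out_dir / "weighted").mkdir(parents=True, exist_ok=True)
    side = handle.input_side
    grid = make_patch_grid(side, side, config.patch, config.patch, config.stride)
    params = SmoothParams(theta=config.theta, sigma=config.sigma)

    rows = []
    frame = manifest.frame
    images = [manifest.load_image(r) for _, r in frame.iterrows()]
    probas = handle.predict_proba_many(images)
    for (idx, rec), image, proba in zip(frame.iterrows(), images, probas):
        if proba < 0.5:
            continue
        imp = explain(handle, image, grid=grid, gray=config.gray, params=params)
        weighted = weight_image(image, imp)
        exp_path = f"explanations/{rec['seed']:05d}.npy"
        w_path = f"weighted/{rec['seed']:05d}.npy"
        np.save(out_dir / exp_path, imp.values.astype(np.float32))
        np.save(out_dir / w_path, weighted.astype(np.float32))
        rows.append(dict(id=int(rec["seed"]), split=rec["split"],
                         label=rec["label"], subtype=rec["subtype"],
                         proba=float(proba), explanation_path=exp_path,
                         weighted_path=w_path))
    xio.save_json(out_dir / "explanations" / "settings.json",
                  dict(patch=config.patch, stride=config.stride,
                       theta=config.theta, sigma=config.sigma, gray=config.gray,
                       n_patches=grid.n_patches))
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "weighted" / "index.csv", index=False)
    return table


def _recenter_mass(image: np.ndarray) -> np.ndarray:
    """Translate a weighted image so its intensity centroid sits at the
    frame center (circular shift; the surround is black, so nothing of
    consequence wraps)."""
    mass = image.sum(axis=2)
    total = mass.sum()
    if total <= 0:
        return image
    ys, xs = np.mgrid[0:image.shape[0], 0:image.shape[1]]
    cy = (ys * mass).sum() / total
    cx = (xs * mass).sum() / total
    shift = (int(round(image.shape[0] / 2 - cy)),
             int(round(image.shape[1] / 2 - cx)))
    return np.roll(image, shift, axis=(0, 1))


def _dihedral_orbit_features(handle: ClassifierHandle, image: np.ndarray) -> np.ndarray:
    """Mean penultimate features over the image's 8 dihedral transforms."""
    orbit = []
    for k in range(4):
        rot = np.rot90(image, k)
        orbit.append(np.ascontiguousarray(rot))
        orbit.append(np.ascontiguousarray(rot[:, ::-1]))
    return handle.features_many(orbit).mean(axis=0)


def embed_weighted_images(
    handle: ClassifierHandle,
    work_dir: str | Path,
    rows: pd.DataFrame,
    config: RunConfig,
) -> np.ndarray:
    """Embedding of persisted weighted images used by the clustering stage.

    The cut-out's position and orientation are nuisance variation for
    subtype content — a shape near the frame edge otherwise embeds
    differently from the same shape at the center — so by default each
    weighted image is translated to put its mass centroid at the frame
    center and the penultimate features are averaged over its 8 dihedral
    transforms. Rows are then L2-normalized: the norm of a
    global-average-pooled embedding tracks the total surviving explanation
    mass, again a nuisance factor; the direction carries the color/texture
    content the clusters should be built on.
    """
    work_dir = Path(work_dir)
    imgs = [np.load(work_dir / p).astype(np.float64)
            for p in rows["weighted_path"]]
    if config.recenter_weighted:
        imgs = [_recenter_mass(im) for im in imgs]
    if config.dihedral_features:
        feats = np.stack([_dihedral_orbit_features(handle, im) for im in imgs])
    else:
        feats = handle.features_many(imgs)
    if config.l2_normalize:
        norms = np.linalg.norm(feats, axis=1, keepdims=True)
        feats = feats / np.maximum(norms, 1e-12)
    return feats


def cluster_stage(
    handle: ClassifierHandle,
    work_dir: str | Path,
    config: RunConfig,
    feature_handle: ClassifierHandle | None = None,
) -> dict:
    """Step 4, runnable standalone from persisted Step-3 outputs.

    Fits SVD + K-means (silhouette-selected K) on the pathological-classified
    train+val weighted images, assigns the held-out (test-split) ones by
    nearest centroid, and scores both against the true subtype when present.
    ``feature_handle`` overrides the embedding model (e.g. an untrained
    network for a baseline-features comparison).
    """
    work_dir = Path(work_dir)
    table = pd.read_csv(work_dir / "weighted" / "index.csv", keep_default_na=False)
    embed = feature_handle or handle
    fit_rows = table[table["split"].isin(["train", "val"])].reset_index(drop=True)
    held_rows = table[table["split"] == "test"].reset_index(drop=True)
    if len(fit_rows) < config.k_max + 1:
        raise ParameterError("too few pathological-classified images to cluster")

    def load_feats(rows: pd.DataFrame) -> np.ndarray:
        return embed_weighted_images(embed, work_dir, rows, config)

    fit_feats = load_feats(fit_rows)
    reduced = reduce_features(fit_feats, variance_fraction=config.svd_variance,
                              cap=config.svd_cap, row_ids=fit_rows["id"].tolist())
    selection: KSelection = select_k(
        reduced, k_min=config.k_min, k_max=config.k_max,
        seed=config.seed, n_restarts=config.n_restarts,
        truth=fit_rows["subtype"].tolist())
    best = selection.best

    out = dict(
        k_star=selection.k_star,
        table=selection.table.to_dict(orient="records"),
        n_fit=len(fit_rows), n_heldout=len(held_rows),
        svd_dim=reduced.n_cols,
        svd_explained=float(reduced.explained_variance_ratio.sum()),
        silhouette=best.silhouette, davies_bouldin=best.davies_bouldin,
        sizes=best.sizes,
        rand_insample=rand_index(fit_rows["subtype"].tolist(), best.labels),
    )
    if len(held_rows):
        held_reduced = reduced.transform(load_feats(held_rows))
        held_labels = assign_unseen(best, held_reduced)
        out["rand_heldout"] = rand_index(held_rows["subtype"].tolist(), held_labels)
        held_rows = held_rows.assign(cluster=held_labels)
    fit_rows = fit_rows.assign(cluster=best.labels)
    cluster_dir = work_dir / "cluster"
    cluster_dir.mkdir(exist_ok=True)
    np.save(cluster_dir / "features.npy", reduced.values.astype(np.float32))
    pd.concat([fit_rows, held_rows]).to_csv(cluster_dir / "labels.csv", index=False)
    xio.save_json(cluster_dir / "cluster.json",
                  dict(out, centroids=best.centroids.tolist(),
                       labels=best.labels.tolist()))
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute gen -> train -> explain -> weight -> cluster and write a
    summary (JSON + Markdown report + overlay gallery). Fully reproducible
    from (config, seed)."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.data_dir is not None:
        manifest = DatasetManifest.load(config.data_dir)
    else:
        manifest = build_dataset(
            out_dir / "data", n_total=config.n_total,
            pathology_rate=config.pathology_rate,
            shape_palette=config.shape_palette,
            size_fraction_range=tuple(config.size_fraction_range),
            splits=tuple(config.splits), seed=config.seed, side=config.side,
            pip_rate=config.pip_rate, stratified=config.stratified,
            background_dir=config.background_dir)
    timings["generate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    train_cfg = dataclasses.replace(config.train, seed=config.seed)
    handle = train_classifier(manifest, arch=config.arch, config=train_cfg)
    handle.save(out_dir / "model")
    timings["train"] = time.perf_counter() - t0

    # held-out accuracy of the classifier itself
    test_rows = manifest.split("test")
    test_imgs = [manifest.load_image(r) for _, r in test_rows.iterrows()]
    test_pred = handle.predict_proba_many(test_imgs) >= 0.5
    test_true = (test_rows["label"] == "pathological").to_numpy()
    test_acc = float((test_pred == test_true).mean())

    t0 = time.perf_counter()
    table = explain_and_weight(handle, manifest, config, out_dir)
    timings["explain"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cluster_out = cluster_stage(handle, out_dir, config)
    timings["cluster"] = time.perf_counter() - t0

    # overlay gallery of the first few explained images
    sample = table.head(10)
    tiles = []
    for _, rec in sample.iterrows():
        img = xio.load_image(
            out_dir / "data" / f"images/{rec['id']:05d}.png"
        ) if config.data_dir is None else None
        exp = np.load(out_dir / rec["explanation_path"]).astype(np.float64)
        if img is not None:
            tiles.append(render_overlay(img, exp))
    if tiles:
        xio.save_image(out_dir / "gallery.png", tile_gallery(tiles))

    summary = dict(
        seed=config.seed, n_total=config.n_total, side=config.side,
        shape_palette=list(config.shape_palette),
        val_f1=handle.history[-1]["val_f1"] if handle.history else None,
        best_val_f1=max((h["val_f1"] for h in handle.history), default=None),
        test_accuracy=test_acc, n_explained=len(table),
        timings={k: round(v, 2) for k, v in timings.items()},
        **cluster_out)
    xio.save_json(out_dir / "summary.json", summary)
    _write_report(out_dir / "report.md", summary)
    return summary


def _write_report(path: Path, s: dict) -> None:
    lines = [
        "# Explanation-weighted clustering run",
        "",
        f"- images: {s['n_total']} at {s['side']}x{s['side']}, "
        f"subtypes: {', '.join(s['shape_palette'])}",
        f"- classifier best validation F1: {s['best_val_f1']}, "
        f"held-out accuracy: {s['test_accuracy']:.3f}",
        f"- images explained (classified pathological): {s['n_explained']}",
        f"- selected K*: {s['k_star']} "
        f"(silhouette {s['silhouette']:.3f}, Davies-Bouldin {s['davies_bouldin']:.3f})",
        f"- Rand vs. true subtype, in-sample: {s['rand_insample']:.3f}",
    ]
    if "rand_heldout" in s:
        lines.append(
            f"- Rand vs. true subtype, held-out assignment: {s['rand_heldout']:.3f}")
    lines.append(f"- cluster sizes: {s['sizes']}")
    lines.append(f"- stage timings (s): {json.dumps(s['timings'])}")
    path.write_text("\n".join(lines) + "\n")
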