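"""Comparison segmenters: multi-level Otsu thresholding and K-means.

Both baselines see only the processed intensities (K-means additionally a
7x7 local-std texture feature), never the scarring-likelihood cascade, and
map their three output groups onto serous/neovascular/fibrous by ascending
mean intensity.  They exist for side-by-side evaluation against the
kernel-cascade classifier on phantoms with known composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus

from .classify import ClassMap, TissueClass
from .filters import std_filter
from .io import PedMask
from .preprocess import ProcessedImage

__all__ = [
    "BaselineResult",
    "multiotsu_thresholds",
    "otsu_classify",
    "kmeans_classify",
    "compare_methods",
]

_TISSUE_ORDER = (TissueClass.SEROUS, TissueClass.NEOVASCULAR, TissueClass.FIBROUS)


@dataclass
class BaselineResult:
    method: str
    cmap: ClassMap
    params: dict = field(default_factory=dict)


def _labels_from_groups(mask: np.ndarray, group: np.ndarray, order: np.ndarray) -> ClassMap:
    """Assign tissue classes to integer groups ranked by ``order`` (ascending)."""
    labels = np.full(mask.shape, int(TissueClass.BACKGROUND), dtype=np.int8)
    flat = np.full(group.shape, int(TissueClass.BACKGROUND), dtype=np.int8)
    for rank, g in enumerate(np.argsort(order)):
        flat[group == g] = int(_TISSUE_ORDER[min(rank, 2)])
    labels[mask] = flat
    return ClassMap(labels=labels)


def multiotsu_thresholds(vals: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Two thresholds maximizing Otsu's between-class variance (3 classes).

    The ``nbins``-bin histogram of ``vals`` is searched over every
    threshold pair via prefix sums in double precision; a pair (i, j)
    means class bins [0..i], [i+1..j], [j+1..end], and the returned
    thresholds are the bin centers at i and j.  The prefix-sum search is
    algebraically identical to the exhaustive two-loop scan.
    """
    vals = np.asarray(vals, dtype=np.float64).ravel()
    hist, edges = np.histogram(vals, bins=nbins, range=(vals.min(), vals.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    # extended precision and cancellation-free segment sums: near-optimal
    # threshold pairs can be tied to ~1e-16, so the argmax must be resolved
    # well below that
    w = hist.astype(np.longdouble) / hist.sum()
    wm = w * centers.astype(np.longdouble)

    head_w = np.cumsum(w)  # class 0: bins [0..i]
    head_m = np.cumsum(wm)
    tail_w = np.cumsum(w[::-1])[::-1]  # suffix sums: bins [j..end]
    tail_m = np.cumsum(wm[::-1])[::-1]

    def _term(wk: np.ndarray, mk: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(wk > 0, mk * mk / np.where(wk > 0, wk, 1.0), 0.0)

    best = (-np.inf, 0, 1)
    for i in range(nbins - 2):
        j = np.arange(i + 1, nbins - 1)
        mid_w = np.cumsum(w[i + 1 : nbins - 1])  # class 1: bins [i+1..j]
        mid_m = np.cumsum(wm[i + 1 : nbins - 1])
        sigma = (
            _term(head_w[i], head_m[i])
            + _term(mid_w, mid_m)
            + _term(tail_w[j + 1], tail_m[j + 1])
        )
        jm = int(np.argmax(sigma))
        if sigma[jm] > best[0]:
            best = (sigma[jm], i, int(j[jm]))
    _, i, j = best
    return centers[[i, j]]


def otsu_classify(i0: ProcessedImage, mask: PedMask, nbins: int = 256) -> BaselineResult:
    """Three-level Otsu thresholding of the in-mask intensity histogram.

    Two thresholds t1 < t2 maximize the between-class variance of the
    ``nbins``-bin histogram of in-mask intensities; pixels are serous below
    t1, neovascular in [t1, t2) and fibrous at or above t2.  Degenerate
    histograms (fewer distinct values than classes) collapse to fewer
    classes with a warning.
    """
    if mask.n_pixels < 10:
        raise ValueError("otsu_classify needs a mask of >= 10 pixels")
    vals = (i0.values if isinstance(i0, ProcessedImage) else np.asarray(i0))[mask.mask]
    n_unique = len(np.unique(vals))
    if n_unique < 3:
        warnings.warn("in-mask histogram has fewer than 3 distinct levels; classes collapse")
        if n_unique == 1:
            thresholds = np.array([])
            group = np.zeros(vals.shape, dtype=int)
        else:
            t = float(np.unique(vals).mean())
            thresholds = np.array([t])
            group = (vals >= t).astype(int)
        order = [np.inf if not (group == g).any() else vals[group == g].mean() for g in range(3)]
        cmap = _labels_from_groups(mask.mask, group, np.asarray(order))
        return BaselineResult("otsu", cmap, {"thresholds": thresholds.tolist(), "nbins": nbins})
    thresholds = multiotsu_thresholds(vals, nbins=nbins)
    group = np.digitize(vals, thresholds)  # <t1 -> 0, [t1,t2) -> 1, >=t2 -> 2
    cmap = _labels_from_groups(mask.mask, group, np.arange(3))
    return BaselineResult("otsu", cmap, {"thresholds": list(map(float, thresholds)), "nbins": nbins})


def _lloyd(features: np.ndarray, centers: np.ndarray, max_iter: int = 300, tol: float = 1e-10):
    """Plain Lloyd iterations; returns (labels, centers, inertia history).

    Exposing the per-iteration objective lets callers verify the descent
    property directly.  Returns an empty-cluster flag so the caller can
    restart.
    """
    k = len(centers)
    inertias: list[float] = []
    labels = np.zeros(len(features), dtype=int)
    for _ in range(max_iter):
        d2 = ((features[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertias.append(float(d2[np.arange(len(features)), labels].sum()))
        counts = np.bincount(labels, minlength=k)
        if (counts == 0).any():
            return labels, centers, inertias, True
        new_centers = np.stack(
            [features[labels == j].mean(axis=0) for j in range(k)]
        )
        shift = ((new_centers - centers) ** 2).sum()
        centers = new_centers
        if shift <= tol:
            break
    return labels, centers, inertias, False


def kmeans_classify(
    i0: ProcessedImage,
    mask: PedMask,
    seed: int = 0,
    texture_kernel: int = 7,
    max_restarts: int = 5,
) -> BaselineResult:
    """K-means (k=3) on (intensity, local std) features inside the mask.

    Uses k-means++ initialization with the given seed and Lloyd iterations;
    clusters are relabeled to serous/neovascular/fibrous by ascending mean
    intensity.  Empty clusters trigger re-initialization up to
    ``max_restarts`` times, after which a warning is issued.
    """
    if mask.n_pixels < 3:
        raise ValueError("kmeans_classify needs a mask of >= 3 pixels")
    values = i0.values if isinstance(i0, ProcessedImage) else np.asarray(i0, dtype=float)
    min_dim = min(values.shape)
    if min_dim < 3:  # image too small for any texture window
        texture = np.zeros_like(values)
    else:
        k_tex = min(texture_kernel, min_dim if min_dim % 2 == 1 else min_dim - 1)
        texture = std_filter(values, k_tex)
    features = np.column_stack([values[mask.mask], texture[mask.mask]])

    rng_seed = seed
    labels = centers = inertias = None
    for attempt in range(max_restarts + 1):
        centers0, _ = kmeans_plusplus(features, n_clusters=3, random_state=rng_seed + attempt)
        labels, centers, inertias, empty = _lloyd(features, centers0)
        if not empty:
            break
    else:  # pragma: no cover - defensive
        pass
    if empty:
        warnings.warn("k-means converged with an empty cluster after restarts")
    cmap = _labels_from_groups(mask.mask, labels, centers[:, 0])
    return BaselineResult(
        "kmeans",
        cmap,
        {
            "seed": seed,
            "centers": centers.tolist(),
            "inertia_history": inertias,
            "texture_kernel": texture_kernel,
        },
    )


def compare_methods(truth: ClassMap, candidates: dict[str, ClassMap]) -> pd.DataFrame:
    """Per-method accuracy, per-class recall and confusion counts.

    Rows: one per (method, truth class) plus an ``overall`` row per method.
    Confusion counts are over mask pixels only.
    """
    mask = truth.mask
    t = truth.labels[mask]
    rows = []
    classes = [TissueClass.SEROUS, TissueClass.NEOVASCULAR, TissueClass.FIBROUS]
    for name, cand in candidates.items():
        if cand.labels.shape != truth.labels.shape:
            raise ValueError(f"shape mismatch for candidate {name!r}")
        c = cand.labels[mask]
        for cls in classes:
            sel = t == cls
            recall = float((c[sel] == cls).mean()) if sel.any() else np.nan
            confusion = {
                f"pred_{p.name.lower()}": int(((t == cls) & (c == p)).sum()) for p in classes
            }
            rows.append({"method": name, "truth_class": cls.name.lower(), "recall": recall, **confusion})
        rows.append(
            {
                "method": name,
                "truth_class": "overall",
                "recall": float((c == t).mean()),
                **{f"pred_{p.name.lower()}": int((c == p).sum()) for p in classes},
            }
        )
    return pd.DataFrame(rows)
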