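"""Three-way pixel classification and PED composition indices.

Each in-mask pixel is labeled from its scarring likelihood I7:

* serous       -- I7 exactly 0 (the dark-neighborhood gate fired, or the
                  aggregated score clipped at 0),
* neovascular  -- 0 < I7 < G_T2,
* fibrous      -- I7 >= G_T2 (the tie at G_T2 is fibrous by default).

The composition indices PEDCI-S/N/F are the per-class pixel fractions of
the total PED area; absolute areas convert counts to mm^2 through the
axial and transverse pixel scales.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import PipelineConfig
from .filters import LikelihoodMap
from .io import PedMask
from .preprocess import ProcessedImage

__all__ = [
    "TissueClass",
    "ClassMap",
    "PedciResult",
    "SizeGateResult",
    "classify_pixels",
    "compute_pedci",
    "ped_size_filter",
    "render_overlay",
    "class_intensity_distributions",
    "batch_summary",
]


class TissueClass(enum.IntEnum):
    BACKGROUND = 0
    SEROUS = 1
    NEOVASCULAR = 2
    FIBROUS = 3


# Overlay palette: serous red, neovascular blue, fibrous green.
CLASS_COLORS = {
    TissueClass.SEROUS: (255, 0, 0),
    TissueClass.NEOVASCULAR: (0, 0, 255),
    TissueClass.FIBROUS: (0, 255, 0),
}


@dataclass
class ClassMap:
    """Per-pixel tissue labels; background exactly off the PED mask."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.isin(self.labels, [int(c) for c in TissueClass]).all():
            raise ValueError("labels contain values outside the tissue classes")

    @property
    def mask(self) -> np.ndarray:
        return self.labels != TissueClass.BACKGROUND

    def count(self, cls: TissueClass) -> int:
        return int((self.labels == cls).sum())


@dataclass
class PedciResult:
    """Composition indices, pixel counts and absolute areas for one PED."""

    pedci_s: float
    pedci_n: float
    pedci_f: float
    n_serous: int
    n_neovascular: int
    n_fibrous: int
    n_total: int
    area_serous_mm2: float
    area_neovascular_mm2: float
    area_fibrous_mm2: float
    area_total_mm2: float
    source_id: str = ""

    @property
    def present_serous(self) -> bool:
        return self.n_serous > 0

    @property
    def present_neovascular(self) -> bool:
        return self.n_neovascular > 0

    @property
    def present_fibrous(self) -> bool:
        return self.n_fibrous > 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            present_serous=self.present_serous,
            present_neovascular=self.present_neovascular,
            present_fibrous=self.present_fibrous,
        )
        return d


@dataclass
class SizeGateResult:
    included: bool
    reason: str  # "", "height", "width" or "height,width"
    height_um: float
    width_um: float


def classify_pixels(
    l7: LikelihoodMap,
    mask: PedMask | None = None,
    gt2: float = 0.6,
    tie_break: str = "fibrous",
) -> ClassMap:
    """Band the likelihood map into serous / neovascular / fibrous labels."""
    if not (0.0 < gt2 <= 1.0):
        raise ValueError(f"gt2 must be in (0, 1], got {gt2}")
    m = mask.mask if mask is not None else l7.mask
    v = l7.values
    labels = np.full(v.shape, int(TissueClass.BACKGROUND), dtype=np.int8)
    if tie_break == "fibrous":
        fib = v >= gt2
    elif tie_break == "neovascular":
        fib = v > gt2
    else:
        raise ValueError(f"tie_break must be 'fibrous' or 'neovascular', got {tie_break!r}")
    labels[m & (v == 0.0)] = TissueClass.SEROUS
    labels[m & fib] = TissueClass.FIBROUS
    labels[m & (labels == TissueClass.BACKGROUND)] = TissueClass.NEOVASCULAR
    return ClassMap(labels=labels)


def compute_pedci(
    cmap: ClassMap,
    cfg: PipelineConfig | None = None,
    source_id: str = "",
) -> PedciResult:
    """Composition indices and absolute areas from a class map.

    Indices are pixel-count fractions of the mask; areas are
    ``count * axial_scale_um * transverse_scale_um * 1e-6`` mm^2.
    """
    cfg = cfg or PipelineConfig()
    n_s = cmap.count(TissueClass.SEROUS)
    n_n = cmap.count(TissueClass.NEOVASCULAR)
    n_f = cmap.count(TissueClass.FIBROUS)
    n_total = n_s + n_n + n_f
    if n_total == 0:
        raise ValueError("class map has no in-mask pixels")
    px_mm2 = cfg.axial_scale_um * cfg.transverse_scale_um * 1e-6
    return PedciResult(
        pedci_s=n_s / n_total,
        pedci_n=n_n / n_total,
        pedci_f=n_f / n_total,
        n_serous=n_s,
        n_neovascular=n_n,
        n_fibrous=n_f,
        n_total=n_total,
        area_serous_mm2=n_s * px_mm2,
        area_neovascular_mm2=n_n * px_mm2,
        area_fibrous_mm2=n_f * px_mm2,
        area_total_mm2=n_total * px_mm2,
        source_id=source_id,
    )


def ped_size_filter(mask: PedMask, cfg: PipelineConfig | None = None) -> SizeGateResult:
    """Apply the minimum physical-extent rule (100 um height and width).

    Extents come from the mask bounding box: height spans rows scaled by
    the axial pixel size, width spans columns scaled by the transverse one.
    """
    cfg = cfg or PipelineConfig()
    r0, r1, c0, c1 = mask.bounding_box()
    height_um = (r1 - r0 + 1) * cfg.axial_scale_um
    width_um = (c1 - c0 + 1) * cfg.transverse_scale_um
    reasons = []
    if height_um < cfg.min_ped_extent_um:
        reasons.append("height")
    if width_um < cfg.min_ped_extent_um:
        reasons.append("width")
    return SizeGateResult(
        included=not reasons,
        reason=",".join(reasons),
        height_um=height_um,
        width_um=width_um,
    )


def render_overlay(
    i0: ProcessedImage | np.ndarray,
    cmap: ClassMap,
    alpha: float = 0.45,
    outline: bool = True,
) -> np.ndarray:
    """Alpha-blend class colors over the grayscale image; returns uint8 RGB.

    Serous is red, neovascular blue, fibrous green; the PED boundary is
    outlined in white when ``outline`` is set.
    """
    values = i0.values if isinstance(i0, ProcessedImage) else np.asarray(i0, dtype=float)
    if values.shape != cmap.labels.shape:
        raise ValueError("image and class map shapes differ")
    base = np.clip(values, 0, 1)
    rgb = np.repeat((base * 255).astype(np.uint8)[:, :, None], 3, axis=2).astype(float)
    for cls, color in CLASS_COLORS.items():
        sel = cmap.labels == cls
        rgb[sel] = (1 - alpha) * rgb[sel] + alpha * np.asarray(color, dtype=float)
    if outline and cmap.mask.any():
        boundary = cmap.mask & ~ndimage.binary_erosion(cmap.mask)
        rgb[boundary] = 255.0
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def class_intensity_distributions(
    i0: ProcessedImage | np.ndarray,
    cmap: ClassMap,
) -> pd.DataFrame:
    """Long-form table of processed intensities by tissue group.

    One row per in-mask pixel and group; groups are the three exclusive
    classes plus the combined ``fibrovascular`` (neovascular + fibrous)
    and ``total`` (whole PED) distributions.
    """
    values = i0.values if isinstance(i0, ProcessedImage) else np.asarray(i0, dtype=float)
    if values.shape != cmap.labels.shape:
        raise ValueError("image and class map shapes differ")
    groups = {
        "serous": cmap.labels == TissueClass.SEROUS,
        "neovascular": cmap.labels == TissueClass.NEOVASCULAR,
        "fibrous": cmap.labels == TissueClass.FIBROUS,
        "fibrovascular": np.isin(cmap.labels, [TissueClass.NEOVASCULAR, TissueClass.FIBROUS]),
        "total": cmap.mask,
    }
    frames = [
        pd.DataFrame({"group": name, "intensity": values[sel]})
        for name, sel in groups.items()
    ]
    return pd.concat(frames, ignore_index=True)


def batch_summary(results: list[PedciResult]) -> pd.DataFrame:
    """Cohort summary across eyes.

    For each component: the number of eyes in which it is present,
    mean +- SD and median of the absolute area over present-only eyes,
    and mean +- SD plus range of the index over all eyes.  The total PED
    area is summarized over all eyes.  SD is the sample SD (0 for n = 1).
    """
    if not results:
        raise ValueError("batch_summary needs at least one result")

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    rows = []
    comps = [
        ("serous", "pedci_s", "area_serous_mm2", "present_serous"),
        ("neovascular", "pedci_n", "area_neovascular_mm2", "present_neovascular"),
        ("fibrous", "pedci_f", "area_fibrous_mm2", "present_fibrous"),
    ]
    for name, idx_attr, area_attr, pres_attr in comps:
        indices = np.array([getattr(r, idx_attr) for r in results])
        present_areas = np.array(
            [getattr(r, area_attr) for r in results if getattr(r, pres_attr)]
        )
        rows.append(
            {
                "component": name,
                "n_eyes": len(results),
                "n_present": len(present_areas),
                "area_mean_mm2": float(present_areas.mean()) if len(present_areas) else np.nan,
                "area_sd_mm2": _sd(present_areas) if len(present_areas) else np.nan,
                "area_median_mm2": float(np.median(present_areas)) if len(present_areas) else np.nan,
                "pedci_mean": float(indices.mean()),
                "pedci_sd": _sd(indices),
                "pedci_min": float(indices.min()),
                "pedci_max": float(indices.max()),
            }
        )
    totals = np.array([r.area_total_mm2 for r in results])
    rows.append(
        {
            "component": "total",
            "n_eyes": len(results),
            "n_present": len(results),
            "area_mean_mm2": float(totals.mean()),
            "area_sd_mm2": _sd(totals),
            "area_median_mm2": float(np.median(totals)),
            "pedci_mean": 1.0,
            "pedci_sd": 0.0,
            "pedci_min": 1.0,
            "pedci_max": 1.0,
        }
    )
    return pd.DataFrame(rows)
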