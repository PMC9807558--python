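"""End-to-end PED analysis: from B-scan + segmentation to a PEDCI result."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baselines import kmeans_classify, otsu_classify
from .classify import (
    ClassMap,
    PedciResult,
    SizeGateResult,
    classify_pixels,
    compute_pedci,
    ped_size_filter,
)
from .config import PipelineConfig
from .filters import FilterStack, LikelihoodMap, scarring_likelihood
from .io import BScan, PedMask, PedPolygon, rasterize
from .preprocess import ProcessedImage, preprocess

__all__ = ["AnalysisResult", "analyze"]


@dataclass
class AnalysisResult:
    i0: ProcessedImage
    likelihood: LikelihoodMap | None
    stack: FilterStack | None
    cmap: ClassMap
    pedci: PedciResult
    size_gate: SizeGateResult
    method: str

    def to_json_dict(self, cfg: PipelineConfig) -> dict:
        d = self.pedci.to_dict()
        d.update(
            method=self.method,
            included=self.size_gate.included,
            exclusion_reason=self.size_gate.reason,
            height_um=self.size_gate.height_um,
            width_um=self.size_gate.width_um,
            gt1=cfg.gt1,
            gt2=cfg.gt2,
        )
        return d


def analyze(
    scan: BScan,
    segmentation: PedPolygon | PedMask,
    cfg: PipelineConfig | None = None,
    method: str = "pedci",
    shadow_compensation: bool = True,
    kmeans_seed: int = 0,
) -> AnalysisResult:
    """Run the full pipeline on one scan.

    ``method`` selects the classifier: the kernel-cascade scarring
    likelihood (``"pedci"``, default) or one of the comparison baselines
    (``"otsu"``, ``"kmeans"``).  The size gate is evaluated but does not
    abort the analysis; callers decide what to do with excluded PEDs.
    """
    cfg = cfg or PipelineConfig()
    mask = segmentation if isinstance(segmentation, PedMask) else rasterize(segmentation, scan.shape)
    if mask.shape != scan.shape:
        raise ValueError("mask shape differs from scan shape")
    cfg = cfg.with_overrides(
        axial_scale_um=scan.axial_scale_um, transverse_scale_um=scan.transverse_scale_um
    )
    size_gate = ped_size_filter(mask, cfg)
    i0 = preprocess(scan, shadow_compensation=shadow_compensation, epsilon=cfg.epsilon)

    likelihood: LikelihoodMap | None = None
    stack: FilterStack | None = None
    if method == "pedci":
        likelihood, stack = scarring_likelihood(i0, mask, cfg)
        cmap = classify_pixels(likelihood, mask, gt2=cfg.gt2, tie_break=cfg.tie_break)
    elif method == "otsu":
        cmap = otsu_classify(i0, mask).cmap
    elif method == "kmeans":
        cmap = kmeans_classify(i0, mask, seed=kmeans_seed).cmap
    else:
        raise ValueError(f"unknown method {method!r}")

    pedci = compute_pedci(cmap, cfg, source_id=scan.source_id)
    return AnalysisResult(
        i0=i0,
        likelihood=likelihood,
        stack=stack,
        cmap=cmap,
        pedci=pedci,
        size_gate=size_gate,
        method=method,
    )
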