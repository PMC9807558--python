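"""The kernel cascade producing the pixel-wise scarring likelihood.

The method rests on one observation about sub-RPE tissue on OCT: serous
fluid is dark and uniform, fibrous scar is bright and uniform, and
neovascular tissue is mid-bright but locally heterogeneous (hyporeflective
vascular pockets inside a hyperreflective matrix).  The cascade turns this
into a per-pixel score in [0, 1]:

    I1 = AVG(I0, 7)            local mean
    I2 = STD(I0, 7)            local sample standard deviation
    I3 = I2 / (I1 + eps)       local coefficient of variation
    I4 = I0 - I3               intensity penalized by heterogeneity
    I5 = AVG(I4, 11)           aggregated score
    I6 = AVG(I0, 9)            serous gate statistic
    I7 = 0              where I6 <  G_T1      (dark neighborhood: serous)
       = clip(I5, 0, 1) where I6 >= G_T1

High I7 means homogeneous and bright (fibrous scar); low-but-positive
means dim or heterogeneous (neovascular); exactly 0 means the serous gate
fired.  All filters use symmetric mirror reflection at borders, and the
whole cascade runs on the padded bounding box of the PED mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .io import PedMask
from .preprocess import ProcessedImage

__all__ = [
    "FilterStack",
    "LikelihoodMap",
    "pad_region",
    "avg_filter",
    "std_filter",
    "scarring_likelihood",
]


@dataclass
class FilterStack:
    """Intermediate images I1..I6 over the padded PED bounding box."""

    i1: np.ndarray
    i2: np.ndarray
    i3: np.ndarray
    i4: np.ndarray
    i5: np.ndarray
    i6: np.ndarray
    kernels: tuple[int, int, int]  # (small, mid, large)
    offset: tuple[int, int]  # padded (0,0) in image coordinates


@dataclass
class LikelihoodMap:
    """Scarring likelihood I7 on mask pixels; NaN marks undefined pixels."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        inside = self.values[self.mask]
        if not np.all(np.isfinite(inside)):
            raise ValueError("likelihood contains non-finite in-mask values")
        if inside.min() < 0 or inside.max() > 1:
            raise ValueError("likelihood must lie in [0, 1] inside the mask")

    def in_mask(self) -> np.ndarray:
        """The in-mask likelihood values as a 1-D array."""
        return self.values[self.mask]


def pad_region(
    img: np.ndarray | ProcessedImage,
    mask: PedMask,
    pad: int,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Extract the mask's bounding box extended by ``pad`` on all sides.

    The extension is filled with true image content where it stays inside
    the image and with mirror reflection (edge pixel not repeated,
    ``r' = 2*edge - r``) where it leaves it.  Returns the padded grid and
    the image coordinates of its (0, 0) corner, which may be negative.
    """
    values = img.values if isinstance(img, ProcessedImage) else np.asarray(img, dtype=float)
    if values.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if pad >= min(values.shape):
        raise ValueError(f"pad {pad} too large for image of shape {values.shape}")
    r0, r1, c0, c1 = mask.bounding_box()
    padded_full = np.pad(values, pad, mode="reflect") if pad else values
    region = padded_full[r0 : r1 + 1 + 2 * pad, c0 : c1 + 1 + 2 * pad]
    return np.ascontiguousarray(region), (r0 - pad, c0 - pad)


def _check_kernel(k: int) -> None:
    if k % 2 == 0 or k < 3:
        raise ValueError(f"kernel size must be odd and >= 3, got {k}")


def avg_filter(grid: np.ndarray, k: int) -> np.ndarray:
    """k x k moving average with mirror-reflected borders."""
    _check_kernel(k)
    grid = np.asarray(grid, dtype=np.float64)
    if min(grid.shape) < k:
        raise ValueError(f"grid of shape {grid.shape} smaller than kernel {k}")
    return ndimage.uniform_filter(grid, size=k, mode="mirror")


def std_filter(grid: np.ndarray, k: int) -> np.ndarray:
    """k x k moving sample standard deviation (n-1) with mirrored borders."""
    _check_kernel(k)
    grid = np.asarray(grid, dtype=np.float64)
    if min(grid.shape) < k:
        raise ValueError(f"grid of shape {grid.shape} smaller than kernel {k}")
    # center on the global mean to limit cancellation in m2 - m1^2
    centered = grid - grid.mean()
    m1 = ndimage.uniform_filter(centered, size=k, mode="mirror")
    m2 = ndimage.uniform_filter(centered * centered, size=k, mode="mirror")
    n = k * k
    var = np.maximum(m2 - m1 * m1, 0.0) * (n / (n - 1))
    return np.sqrt(var)


def scarring_likelihood(
    i0: ProcessedImage,
    mask: PedMask,
    cfg: PipelineConfig | None = None,
    pad: int | None = None,
) -> tuple[LikelihoodMap, FilterStack]:
    """Run the I0 -> I7 cascade on the PED region.

    ``pad`` defaults to ``kernel_large//2 + kernel_small//2`` (8 for the
    default 7/9/11 kernels) so that every in-box value of the aggregated
    score is computed from real neighborhood content rather than from the
    border reflection of an already-filtered stage.
    """
    cfg = cfg or PipelineConfig()
    min_pad = cfg.kernel_large // 2
    if pad is None:
        pad = cfg.kernel_large // 2 + cfg.kernel_small // 2
    if pad < min_pad:
        raise ValueError(f"pad must be >= {min_pad} for an {cfg.kernel_large}x{cfg.kernel_large} kernel")
    if i0.shape != mask.shape:
        raise ValueError("image and mask shapes differ")

    region, (row_off, col_off) = pad_region(i0, mask, pad)
    i1 = avg_filter(region, cfg.kernel_small)
    i2 = std_filter(region, cfg.kernel_small)
    i3 = i2 / (i1 + cfg.epsilon)
    i4 = region - i3
    i5 = avg_filter(i4, cfg.kernel_large)
    i6 = avg_filter(region, cfg.kernel_mid)
    for name, arr in (("I1", i1), ("I2", i2), ("I3", i3), ("I4", i4), ("I5", i5), ("I6", i6)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite values in cascade stage {name}")

    i7_box = np.where(i6 < cfg.gt1, 0.0, np.clip(i5, 0.0, 1.0))

    values = np.full(mask.shape, np.nan)
    rows, cols = np.nonzero(mask.mask)
    values[rows, cols] = i7_box[rows - row_off, cols - col_off]
    stack = FilterStack(
        i1=i1, i2=i2, i3=i3, i4=i4, i5=i5, i6=i6,
        kernels=(cfg.kernel_small, cfg.kernel_mid, cfg.kernel_large),
        offset=(row_off, col_off),
    )
    return LikelihoodMap(values=values, mask=mask.mask.copy()), stack
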