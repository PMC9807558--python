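"""B-scan pre-processing: linear normalization and shadow compensation.

OCT exports vary in overall brightness, so each scan is min-max normalized
to [0, 1].  Overlying vessels and fluid attenuate the beam and cast shadows
over the sub-RPE region of interest; compensation rescales each pixel by
the residual signal energy remaining below it in its own A-scan (depth
column), which brightens shadowed depths relative to their neighbors.
The output of both steps is the original processed image I0 that the
filter cascade consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BScan

__all__ = ["ProcessedImage", "normalize_linear", "compensate_shadows", "preprocess"]


@dataclass
class ProcessedImage:
    """A [0, 1] intensity grid with provenance flags."""

    values: np.ndarray
    normalized: bool = False
    compensated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ProcessedImage.values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ProcessedImage.values must be finite")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("ProcessedImage.values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _minmax(values: np.ndarray) -> np.ndarray:
    lo = values.min()
    hi = values.max()
    if hi == lo:
        return np.zeros_like(values, dtype=np.float64)
    return (values - lo) / (hi - lo)


def normalize_linear(scan: BScan | np.ndarray) -> ProcessedImage:
    """Min-max normalize a scan to [0, 1] (a constant image maps to zeros)."""
    values = scan.pixels if isinstance(scan, BScan) else np.asarray(scan, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot normalize non-finite intensities")
    return ProcessedImage(values=_minmax(values.astype(np.float64)), normalized=True)


def compensate_shadows(
    img: ProcessedImage,
    exponent: float = 2.0,
    renormalize: bool = True,
    epsilon: float = 1e-8,
) -> ProcessedImage:
    """Energy-based per-A-scan shadow compensation.

    Each pixel at depth ``z`` of a column is divided by twice the residual
    energy below it, ``2 * sum_{z' >= z} img[z']**exponent + epsilon``.
    Because the factor depends only on content at and below the pixel,
    two columns identical below a depth get identical compensated values
    there regardless of what lies above.

    Near the bottom of the scan the residual energy vanishes and the
    factor diverges -- an intrinsic artifact of energy-based compensation.
    With ``renormalize`` (default) the result is therefore clipped at its
    99.5th percentile before the linear rescale to [0, 1], so a handful of
    blown-up bottom pixels cannot crush the dynamic range of the retina;
    without ``renormalize`` the result is only divided by its maximum,
    preserving ratios between pixels.
    """
    if exponent <= 0:
        raise ValueError(f"exponent must be positive, got {exponent}")
    v = img.values
    # cumulative energy from the bottom of each A-scan, inclusive of z
    residual = np.cumsum((v**exponent)[::-1, :], axis=0)[::-1, :]
    out = v / (2.0 * residual + epsilon)
    if renormalize:
        hi = np.percentile(out, 99.5)
        out = _minmax(np.minimum(out, hi) if hi > 0 else out)
    elif out.max() > 1.0:
        out = out / out.max()
    return ProcessedImage(values=out, normalized=img.normalized and renormalize, compensated=True)


def preprocess(
    scan: BScan,
    shadow_compensation: bool = True,
    exponent: float = 2.0,
    epsilon: float = 1e-8,
) -> ProcessedImage:
    """Normalize and (optionally) shadow-compensate a B-scan into I0."""
    img = normalize_linear(scan)
    if shadow_compensation:
        img = compensate_shadows(img, exponent=exponent, renormalize=True, epsilon=epsilon)
    return img
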