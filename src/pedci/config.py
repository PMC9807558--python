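"""Pipeline configuration.

All thresholds and physical scales used across the pipeline live in
:class:`PipelineConfig`.  The two global thresholds control classification:
``gt1`` gates hyporeflective (serous) regions on the 9x9 local mean, and
``gt2`` splits the remaining scarring-likelihood scores into neovascular
(below) and fibrous (at or above).  Physical pixel scales default to the
4 um axial / 7 um transverse sampling of clinical high-definition SD-OCT.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, kernel sizes and physical scales for PED analysis.

    Parameters
    ----------
    gt1:
        Serous gate on the 9x9 local mean of the processed image; pixels
        whose local mean falls below it get scarring likelihood 0.
        Must satisfy ``0 <= gt1 < 1``.
    gt2:
        Neovascular/fibrous split on the scarring likelihood, in ``(0, 1]``.
        Likelihood at or above ``gt2`` is fibrous (ties fibrous by default;
        see ``tie_break``).
    kernel_small, kernel_mid, kernel_large:
        Odd window sizes of the averaging/std filter cascade
        (local-heterogeneity pair, serous-gate mean, final aggregation).
    axial_scale_um, transverse_scale_um:
        Physical size of one pixel along rows / columns, in micrometres.
    min_ped_extent_um:
        Minimum bounding-box height and width (um) for a PED to be analysed.
    epsilon:
        Guard added to denominators so all-zero windows stay finite.
    shadow_exponent:
        Contrast exponent of the energy-based shadow compensation.
    tie_break:
        Class assigned when likelihood equals ``gt2`` exactly:
        ``"fibrous"`` (default) or ``"neovascular"``.
    """

    gt1: float = 0.25
    gt2: float = 0.6
    kernel_small: int = 7
    kernel_mid: int = 9
    kernel_large: int = 11
    axial_scale_um: float = 4.0
    transverse_scale_um: float = 7.0
    min_ped_extent_um: float = 100.0
    epsilon: float = 1e-8
    shadow_exponent: float = 2.0
    tie_break: str = "fibrous"

    def __post_init__(self) -> None:
        if not (0.0 <= self.gt1 < 1.0):
            raise ValueError(f"gt1 must be in [0, 1), got {self.gt1}")
        if not (0.0 < self.gt2 <= 1.0):
            raise ValueError(f"gt2 must be in (0, 1], got {self.gt2}")
        for name in ("kernel_small", "kernel_mid", "kernel_large"):
            k = getattr(self, name)
            if k < 3 or k % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {k}")
        if self.axial_scale_um <= 0 or self.transverse_scale_um <= 0:
            raise ValueError("pixel scales must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.tie_break not in ("fibrous", "neovascular"):
            raise ValueError(f"tie_break must be 'fibrous' or 'neovascular', got {self.tie_break!r}")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file plus keyword overrides.

    Unknown YAML keys raise; ``None``-valued overrides are ignored so CLI
    flags can be passed through unconditionally.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        valid = set(PipelineConfig.__dataclass_fields__)
        unknown = set(loaded) - valid
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        data = loaded
    cfg = PipelineConfig(**data)
    return cfg.with_overrides(**overrides)
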