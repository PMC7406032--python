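"""Pipeline configuration.

Every free parameter of the counting pipeline lives here.  The source
protocol fixes the *order* of operations but leaves most magnitudes (blur
widths, threshold strategy, diameter gates) to be optimized per instrument;
those defaults are exposed and documented below.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Optional

import yaml

from .errors import ConfigurationError

_THRESHOLD_METHODS = ("otsu",)
_DECLUMP_METHODS = ("none", "watershed")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the per-plate counting pipeline.

    Parameters
    ----------
    log_gain_k:
        Gain of the normalized log contrast transform
        ``out = log(1 + k*in) / log(1 + k)``.  ``k = 255`` reduces to the
        classic 8-bit log mapping.
    well_smooth_sigma:
        Gaussian sigma (px) applied before well detection so only the large
        well structure survives thresholding.
    well_threshold:
        Global threshold method for well detection (``"otsu"``).
    well_min_diameter_frac:
        Minimum equivalent diameter of the well object as a fraction of the
        short image side; objects below the gate are not wells.
    erosion_px:
        Mask contraction radius in px, or ``None`` for automatic
        (1% of the fitted well radius, at least 3 px).
    illum_smooth_sigma:
        Gaussian sigma (px) smoothing the estimated illumination field.
        Must stay well below the mosaic tile pitch or the tile-periodic
        component of the field is lost and the grid artifact survives
        correction.
    illum_floor_eps:
        Lower clamp of the normalized illumination gain; bounds the
        amplification of the division step by ``1/eps``.
    denoise_sigma:
        Mild Gaussian blur (px) applied after correction.
    nucleus_diameter_px:
        ``(min, max)`` equivalent-diameter gate for accepted objects.
    nucleus_threshold:
        Threshold method over in-mask pixels (``"otsu"``).
    manual_threshold:
        Optional fixed absolute threshold in [0, 1]; overrides the automatic
        method when set (the protocol's "manually optimized" setting).
    declump:
        ``"watershed"`` splits over-size components by distance-transform
        watershed before the size gate; ``"none"`` disables splitting.
    ovoid_eccentricity_max:
        Well-object eccentricity above which the OVOID QC flag is raised.
    min_mask_area_frac:
        Mask area below this fraction of the frame raises LOW_MASK_AREA.
    rng_seed:
        Seed for any stochastic step (none in the default pipeline; kept for
        reproducibility of optional extensions).
    """

    log_gain_k: float = 255.0
    well_smooth_sigma: float = 25.0
    well_threshold: str = "otsu"
    well_min_diameter_frac: float = 0.5
    erosion_px: Optional[int] = None
    illum_smooth_sigma: float = 15.0
    illum_floor_eps: float = 0.05
    denoise_sigma: float = 1.0
    nucleus_diameter_px: tuple[float, float] = (5.0, 20.0)
    nucleus_threshold: str = "otsu"
    manual_threshold: Optional[float] = None
    declump: str = "watershed"
    ovoid_eccentricity_max: float = 0.25
    min_mask_area_frac: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.log_gain_k <= 0:
            raise ConfigurationError("log_gain_k must be > 0")
        if self.well_smooth_sigma <= 0 or self.illum_smooth_sigma <= 0:
            raise ConfigurationError("smoothing sigmas must be > 0")
        if not (0 < self.well_min_diameter_frac <= 1):
            raise ConfigurationError("well_min_diameter_frac must be in (0, 1]")
        if not (0 < self.illum_floor_eps < 1):
            raise ConfigurationError("illum_floor_eps must be in (0, 1)")
        if self.denoise_sigma < 0:
            raise ConfigurationError("denoise_sigma must be >= 0")
        dmin, dmax = self.nucleus_diameter_px
        if not (0 < dmin < dmax):
            raise ConfigurationError("nucleus_diameter_px must satisfy 0 < min < max")
        if self.well_threshold not in _THRESHOLD_METHODS:
            raise ConfigurationError(f"unknown well_threshold {self.well_threshold!r}")
        if self.nucleus_threshold not in _THRESHOLD_METHODS:
            raise ConfigurationError(
                f"unknown nucleus_threshold {self.nucleus_threshold!r}"
            )
        if self.declump not in _DECLUMP_METHODS:
            raise ConfigurationError(f"unknown declump method {self.declump!r}")
        if self.erosion_px is not None and self.erosion_px < 0:
            raise ConfigurationError("erosion_px must be >= 0 or None")
        if self.manual_threshold is not None and not (
            0 <= self.manual_threshold <= 1
        ):
            raise ConfigurationError("manual_threshold must be in [0, 1]")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "nucleus_diameter_px" in d and d["nucleus_diameter_px"] is not None:
            d["nucleus_diameter_px"] = tuple(d["nucleus_diameter_px"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


def auto_erosion_px(radius: float) -> int:
    """Default mask contraction: 1% of the fitted well radius, at least 3 px."""
    return max(3, int(round(0.01 * radius)))
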