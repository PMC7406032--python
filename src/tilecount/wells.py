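"""Locating and masking the circular growth area of each well.

The well wall fluoresces as a bright halo ring, so the well is found the way
one finds any object: smooth heavily until only the largest structure
survives, threshold, keep the component that passes a large-object size
gate, and fill its interior.  A circle fit plus a radial intensity profile
then separate the growth disc from the halo so the returned mask covers the
growth area without the wall.  Geometric anomalies (ovoid-compressed frames,
shrunken masks) are flagged, not auto-corrected: the upstream acquisition
fault is the thing to fix, and downstream the honest action is to mark the
well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .config import PipelineConfig, auto_erosion_px
from .errors import ContractError, LowMaskAreaError, NoWellFoundError
from .io import QC_LOW_MASK_AREA, QC_OVOID, TiledWellImage
from .synth import GroundTruth


@dataclass
class WellMask:
    """Boolean growth-area region with its fitted disc geometry."""

    mask: np.ndarray
    center: tuple[float, float]
    radius: float
    eccentricity: float
    erosion_applied_px: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ContractError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def disc_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    """Rasterized boolean disc (pixel centers at integer coordinates)."""
    h, w = shape
    rows = np.arange(h, dtype=np.float64)[:, None] - center[0]
    cols = np.arange(w, dtype=np.float64)[None, :] - center[1]
    return rows**2 + cols**2 <= radius**2


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (Kasa) circle fit to (row, col) boundary points."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        raise ContractError("circle fit needs at least 3 points")
    r, c = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * r, 2 * c, np.ones_like(r)])
    b = r**2 + c**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cy, cx, k = sol
    radius = math.sqrt(max(k + cy**2 + cx**2, 0.0))
    return float(cy), float(cx), float(radius)


def _refine_growth_radius(
    pixels: np.ndarray, center: tuple[float, float], r_out: float
) -> float:
    """Inner halo edge from the radial intensity profile about ``center``.

    The profile over the outer band rises sharply from the background level
    of the growth area to the halo plateau; the growth radius is where it
    crosses 30% of that rise, scanned inward from the halo peak.  Falls back
    to ``r_out`` when no halo rise is measurable.
    """
    h, w = pixels.shape
    rows = np.arange(h, dtype=np.float64)[:, None] - center[0]
    cols = np.arange(w, dtype=np.float64)[None, :] - center[1]
    dist = np.hypot(rows, cols)

    r_lo, r_hi = int(0.6 * r_out), int(math.ceil(1.02 * r_out))
    band = (dist >= r_lo) & (dist <= r_hi)
    idx = np.round(dist[band]).astype(int) - r_lo
    sums = np.bincount(idx, weights=pixels[band], minlength=r_hi - r_lo + 1)
    counts = np.bincount(idx, minlength=r_hi - r_lo + 1)
    with np.errstate(invalid="ignore"):
        prof = sums / np.maximum(counts, 1)

    interior = dist <= 0.8 * r_out
    bg = float(np.median(pixels[interior])) if interior.any() else 0.0
    peak_i = int(np.argmax(prof))
    peak_val = float(prof[peak_i])
    if peak_val - bg < 0.02:
        return float(r_out)
    level = bg + 0.3 * (peak_val - bg)
    for i in range(peak_i, -1, -1):
        if prof[i] <= level:
            return float(r_lo + i + 0.5)
    return float(r_out)


def detect_well(image: TiledWellImage, cfg: PipelineConfig) -> WellMask:
    """Find the growth disc of one tiled well image.

    Procedure: heavy Gaussian smoothing so only the well-scale structure
    survives, global Otsu threshold, hole filling, a large-object size gate
    (equivalent diameter >= ``well_min_diameter_frac`` of the short side),
    then a least-squares circle fit to the surviving component's boundary
    and a radial-profile refinement that strips the halo ring off the mask.
    Raises :class:`NoWellFoundError` when nothing passes the gate.
    """
    px = image.pixels
    blurred = ndimage.gaussian_filter(px, cfg.well_smooth_sigma)
    if float(blurred.max() - blurred.min()) < 1e-3:
        raise NoWellFoundError(
            f"{image.well_id}: featureless frame, no well object", 0.0
        )
    t = threshold_otsu(blurred)
    bw = ndimage.binary_fill_holes(blurred > t)
    labels = label(bw, connectivity=2)
    props = regionprops(labels)
    if not props:
        raise NoWellFoundError(f"{image.well_id}: nothing above threshold", 0.0)
    gate = cfg.well_min_diameter_frac * min(px.shape)
    candidates = [p for p in props if p.equivalent_diameter_area >= gate]
    if not candidates:
        biggest = max(p.equivalent_diameter_area for p in props)
        raise NoWellFoundError(
            f"{image.well_id}: largest object diameter {biggest:.0f}px "
            f"below gate {gate:.0f}px",
            biggest,
        )
    comp_prop = max(candidates, key=lambda p: p.area)
    comp = labels == comp_prop.label
    ecc = float(comp_prop.eccentricity)

    boundary = comp & ~ndimage.binary_erosion(comp)
    cy, cx, r_out = fit_circle(np.argwhere(boundary))
    r_inner = _refine_growth_radius(px, (cy, cx), r_out)
    radius = min(r_inner + 1.0, r_out)

    if ecc <= cfg.ovoid_eccentricity_max:
        mask = disc_mask(px.shape, (cy, cx), radius)
    else:
        # compressed/non-circular frame: contract the component itself by
        # the estimated halo thickness so the mask follows the true shape
        t_halo = int(np.clip(round(r_out - r_inner), 0, int(0.2 * r_out)))
        mask = (
            ndimage.binary_erosion(comp, structure=disk(t_halo))
            if t_halo > 0
            else comp
        )
        if not mask.any():
            mask = comp
    return WellMask(
        mask=mask, center=(cy, cx), radius=float(radius), eccentricity=ecc
    )


def erode_mask(mask: WellMask, pixels: int) -> WellMask:
    """Contract the mask with a disc structuring element of the given radius."""
    if pixels < 0:
        raise ContractError("erosion pixels must be >= 0")
    if pixels == 0:
        return mask
    eroded = ndimage.binary_erosion(mask.mask, structure=disk(pixels))
    if not eroded.any():
        raise LowMaskAreaError(
            f"erosion by {pixels}px removed the entire mask"
        )
    return WellMask(
        mask=eroded,
        center=mask.center,
        radius=max(mask.radius - pixels, 0.0),
        eccentricity=mask.eccentricity,
        erosion_applied_px=mask.erosion_applied_px + pixels,
    )


def apply_mask(
    image: TiledWellImage, mask: WellMask, fill: str = "zero"
) -> TiledWellImage:
    """Zero (or background-fill) everything outside the growth mask."""
    if mask.mask.shape != image.pixels.shape:
        raise ContractError(
            f"mask shape {mask.mask.shape} != image shape {image.pixels.shape}"
        )
    if fill == "zero":
        fill_value = 0.0
    elif fill == "background-median":
        fill_value = (
            float(np.median(image.pixels[mask.mask])) if mask.mask.any() else 0.0
        )
    else:
        raise ContractError(f"unknown fill policy {fill!r}")
    out = np.full_like(image.pixels, fill_value)
    out[mask.mask] = image.pixels[mask.mask]
    return image.with_pixels(out)


def qc_geometry(mask: WellMask, cfg: PipelineConfig) -> frozenset:
    """Advisory geometry flags: OVOID and/or LOW_MASK_AREA."""
    flags = set()
    if mask.eccentricity > cfg.ovoid_eccentricity_max:
        flags.add(QC_OVOID)
    if mask.area_px < cfg.min_mask_area_frac * mask.mask.size:
        flags.add(QC_LOW_MASK_AREA)
    return frozenset(flags)


def coverage_of_truth(mask: WellMask, truth: GroundTruth) -> float:
    """Fraction of the true growth disc covered by the detected mask."""
    true_disc = disc_mask(mask.mask.shape, truth.well_center, truth.well_radius)
    n = int(true_disc.sum())
    if n == 0:
        return 1.0
    return float((mask.mask & true_disc).sum() / n)


def _circle_overlap_area(d: float, r1: float, r2: float) -> float:
    """Exact intersection area of two discs with center distance ``d``."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    a1 = r1**2 * math.acos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * math.acos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    a3 = 0.5 * math.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return a1 + a2 - a3


def fixed_template_loss(
    truths,
    base_center: tuple[float, float],
    nominal_radius: float,
    jitter_bound: float,
    erosion_px: int | None = None,
) -> np.ndarray:
    """Growth-area loss of the rejected one-mask-fits-all strategy.

    A universal cropping template must stay inside the growth area of every
    well despite position jitter, so its radius is the nominal radius minus
    the worst-case center displacement (``jitter_bound * sqrt(2)`` for a
    per-axis bound) minus the same default contraction the adaptive pipeline
    applies.  Returns the per-well fraction of true growth disc lost,
    computed from exact circle-circle intersection areas.
    """
    margin = jitter_bound * math.sqrt(2)
    rho = nominal_radius - margin
    if erosion_px is None:
        erosion_px = auto_erosion_px(max(rho, 1.0))
    rho -= erosion_px
    if rho <= 0:
        return np.ones(len(truths))
    losses = []
    for truth in truths:
        d = math.hypot(
            truth.well_center[0] - base_center[0],
            truth.well_center[1] - base_center[1],
        )
        overlap = _circle_overlap_area(d, rho, truth.well_radius)
        losses.append(1.0 - overlap / (math.pi * truth.well_radius**2))
    return np.array(losses)
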