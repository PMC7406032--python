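"""Nucleus segmentation and counting on the enhanced, masked image.

Objects are intensity-thresholded over in-mask pixels, labeled with
8-connectivity, optionally declumped by distance-transform watershed, and
gated by equivalent diameter: everything below the gate is residual debris,
everything above is a halo remnant or condensation artifact, neither is a
nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import find_boundaries, watershed

from .config import PipelineConfig
from .errors import ContractError, ImageIOError
from .io import TiledWellImage
from .synth import GroundTruth
from .wells import WellMask


@dataclass(frozen=True)
class NucleusRecord:
    """One detected nucleus."""

    label: int
    centroid: tuple[float, float]
    area_px: int
    equivalent_diameter_px: float
    mean_intensity: float


@dataclass
class LabelImage:
    """Integer label grid; 0 is background, labels contiguous 1..n."""

    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ContractError("labels must be 2-D")


def _threshold_value(
    pixels: np.ndarray, mask: np.ndarray, cfg: PipelineConfig
) -> float:
    if cfg.manual_threshold is not None:
        return float(cfg.manual_threshold)
    vals = pixels[mask]
    if vals.size == 0:
        raise ContractError("empty mask: nothing to threshold")
    if float(vals.max() - vals.min()) < 1e-9:
        return float(vals.max())  # flat field: nothing can exceed it
    return float(threshold_otsu(vals))


def _declump_watershed(
    binary: np.ndarray, labels: np.ndarray, max_diameter: float,
    min_diameter: float
) -> np.ndarray:
    """Split components larger than the diameter gate by watershed.

    Seeds are smoothed local maxima of the distance transform; only
    over-size components are touched, small objects pass through unchanged.
    """
    out = labels.copy()
    next_label = int(labels.max()) + 1
    max_area = np.pi * (max_diameter / 2) ** 2
    for prop in regionprops(labels):
        if prop.area <= max_area:
            continue
        rmin, cmin, rmax, cmax = prop.bbox
        sub = labels[rmin:rmax, cmin:cmax] == prop.label
        dist = ndimage.distance_transform_edt(sub)
        dist_s = ndimage.gaussian_filter(dist, 1.0)
        min_dist = max(1, int(round(min_diameter)))
        peaks = peak_local_max(
            dist_s, min_distance=min_dist, labels=sub, exclude_border=False
        )
        if len(peaks) <= 1:
            continue
        markers = np.zeros_like(sub, dtype=int)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        ws = watershed(-dist_s, markers=markers, mask=sub)
        region = out[rmin:rmax, cmin:cmax]
        region[sub] = 0
        for i in range(1, int(ws.max()) + 1):
            piece = ws == i
            if piece.any():
                region[piece] = next_label
                next_label += 1
    return out


def segment_nuclei(
    image: TiledWellImage, mask: WellMask, cfg: PipelineConfig
) -> tuple[LabelImage, list[NucleusRecord]]:
    """Threshold, label, declump and gate nuclei inside the growth mask.

    Returns a relabeled (contiguous 1..n) label image and per-object records
    sorted by centroid (row, col).
    """
    if mask.mask.shape != image.pixels.shape:
        raise ContractError("mask/image shape mismatch")
    if not mask.mask.any():
        raise ContractError("empty mask")
    px = image.pixels
    t = _threshold_value(px, mask.mask, cfg)
    binary = (px > t) & mask.mask
    labels = sk_label(binary, connectivity=2)

    dmin, dmax = cfg.nucleus_diameter_px
    if cfg.declump == "watershed" and labels.max() > 0:
        labels = _declump_watershed(binary, labels, dmax, dmin)

    records: list[NucleusRecord] = []
    keep = np.zeros(int(labels.max()) + 1, dtype=bool)
    props = regionprops(labels, intensity_image=px)
    for prop in props:
        d = prop.equivalent_diameter_area
        if dmin <= d <= dmax:
            keep[prop.label] = True
            records.append(
                NucleusRecord(
                    label=prop.label,
                    centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                    area_px=int(prop.area),
                    equivalent_diameter_px=float(d),
                    mean_intensity=float(prop.intensity_mean),
                )
            )
    # contiguous relabeling in centroid order
    records.sort(key=lambda r: r.centroid)
    mapping = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    relabeled_records = []
    for new_label, rec in enumerate(records, start=1):
        mapping[rec.label] = new_label
        relabeled_records.append(
            NucleusRecord(
                label=new_label,
                centroid=rec.centroid,
                area_px=rec.area_px,
                equivalent_diameter_px=rec.equivalent_diameter_px,
                mean_intensity=rec.mean_intensity,
            )
        )
    out_labels = mapping[labels]
    return (
        LabelImage(labels=out_labels, n_objects=len(relabeled_records)),
        relabeled_records,
    )


def match_to_truth(
    records: Sequence[NucleusRecord], truth: GroundTruth, max_dist: float = 5.0
) -> tuple[int, int, int]:
    """Greedy nearest-neighbor matching of detections to true centers.

    Candidate pairs within ``max_dist`` are taken in order of increasing
    distance, each truth and each detection used at most once.  Returns
    ``(n_matched, n_missed, n_spurious)`` with
    ``n_matched + n_missed = truth count`` and
    ``n_matched + n_spurious = detection count``.
    """
    if max_dist <= 0:
        raise ContractError("max_dist must be > 0")
    det = np.array([r.centroid for r in records], dtype=np.float64).reshape(-1, 2)
    tru = truth.nucleus_centers
    if len(det) == 0 or len(tru) == 0:
        return 0, len(tru), len(det)
    diff = det[:, None, :] - tru[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    pairs = np.argwhere(dist <= max_dist)
    order = np.argsort(dist[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_det = np.zeros(len(det), dtype=bool)
    used_tru = np.zeros(len(tru), dtype=bool)
    matched = 0
    for i, j in pairs[order]:
        if not used_det[i] and not used_tru[j]:
            used_det[i] = True
            used_tru[j] = True
            matched += 1
    return matched, len(tru) - matched, len(det) - matched


def render_outlines(
    image: TiledWellImage, labels: LabelImage, path
) -> Path:
    """Write an RGB overlay PNG: source in green, object boundaries in purple."""
    if labels.labels.shape != image.pixels.shape:
        raise ContractError("labels/image shape mismatch")
    green = np.round(np.clip(image.pixels, 0, 1) * 255).astype(np.uint8)
    rgb = np.zeros(green.shape + (3,), dtype=np.uint8)
    rgb[..., 1] = green
    boundaries = find_boundaries(labels.labels, mode="inner", connectivity=1)
    rgb[boundaries] = (200, 0, 200)
    path = Path(path)
    try:
        iio.imwrite(path, rgb)
    except Exception as exc:
        raise ImageIOError(f"cannot write overlay {path}: {exc}") from exc
    return path
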