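"""Contrast enhancement and flat-field (illumination) correction.

Stitched mosaics carry a tile-periodic radial vignette that shows up as a
soft grid at tile seams; dividing by a smooth gain surface estimated from
the whole image set flattens it.  Because that division also attenuates dim
nuclear signal relative to the threshold, a normalized log contrast
transform is applied *before* correction — that ordering is the heart of
the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .errors import ConfigurationError, ContractError
from .io import TiledWellImage

import imageio.v3 as iio


@dataclass
class IlluminationField:
    """Strictly positive smooth gain surface, normalized to max 1."""

    gain: np.ndarray
    n_images_used: int
    smoothing_sigma_px: float

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=np.float64)
        if self.gain.ndim != 2:
            raise ContractError("gain must be 2-D")
        if self.gain.min() <= 0 or self.gain.max() > 1 + 1e-9:
            raise ContractError("gain values must lie in (0, 1]")


def log_transform(image: TiledWellImage, k: float = 255.0) -> TiledWellImage:
    """Normalized log contrast map ``out = log(1 + k*in) / log(1 + k)``.

    Strictly increasing, fixes 0 and 1, and boosts dim intensities; with
    ``k = 255`` it reduces to the classic 8-bit log mapping.
    """
    if k <= 0:
        raise ConfigurationError("log gain k must be > 0")
    out = np.log1p(k * image.pixels) / np.log1p(k)
    return image.with_pixels(out)


def _tile_radius_sq(shape, tile_rows: int, tile_cols: int) -> np.ndarray:
    """Squared distance to the owning tile's center, normalized by the corner."""
    h, w = shape
    th, tw = h / tile_rows, w / tile_cols
    dr = (np.arange(h, dtype=np.float64) % th) - (th - 1) / 2
    dc = (np.arange(w, dtype=np.float64) % tw) - (tw - 1) / 2
    r_corner2 = (th / 2) ** 2 + (tw / 2) ** 2
    return (dr[:, None] ** 2 + dc[None, :] ** 2) / r_corner2


def _radial_tile_profile(values: np.ndarray, u2: np.ndarray, n_bins: int = 40):
    """Median intensity per normalized tile-radius bin, pooled over all tiles."""
    u = np.sqrt(u2)
    edges = np.linspace(0, u.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(u, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    med = np.full(n_bins, np.nan)
    finite = np.isfinite(values)
    for b in range(n_bins):
        sel = (idx == b) & finite
        if sel.any():
            med[b] = np.median(values[sel])
    ok = np.isfinite(med)
    if not ok.any():
        raise ContractError("no in-mask pixels to build a radial profile from")
    return centers[ok], med[ok]


def estimate_illumination(
    images: Sequence[TiledWellImage],
    cfg: PipelineConfig,
    masks: Optional[Sequence[np.ndarray]] = None,
) -> IlluminationField:
    """Estimate the set-wide illumination gain from masked images.

    Per-pixel median across the set restricted to in-mask pixels (a median
    over many wells is robust to wells dense with cells), out-of-mask
    pixels imputed from the pooled per-tile radial profile, Gaussian
    smoothing with ``illum_smooth_sigma``, then floor and max-normalize.
    With fewer than 8 usable images the per-pixel median is noisy, so the
    field falls back to a radially symmetric per-tile quadratic fit of the
    same profile.
    """
    if not images:
        raise ContractError("estimate_illumination needs at least one image")
    shape = images[0].pixels.shape
    for im in images:
        if im.pixels.shape != shape:
            raise ContractError("all images must share one shape")
    if masks is not None:
        if len(masks) != len(images):
            raise ContractError("masks must pair with images")
        for m in masks:
            if m.shape != shape:
                raise ContractError("mask shape mismatch")

    stack = np.empty((len(images),) + shape, dtype=np.float32)
    for i, im in enumerate(images):
        px = im.pixels.astype(np.float32)
        in_mask = masks[i] if masks is not None else px > 0
        stack[i] = np.where(in_mask, px, np.nan)

    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        median = np.nanmedian(stack, axis=0)
    coverage = np.sum(~np.isnan(stack), axis=0)
    del stack
    reliable = coverage >= max(1, len(images) // 2)
    median[~reliable] = np.nan

    u2 = _tile_radius_sq(shape, images[0].tile_rows, images[0].tile_cols)
    centers, prof = _radial_tile_profile(median, u2)

    if len(images) >= 8:
        field = median
        missing = ~np.isfinite(field)
        if missing.any():
            field[missing] = np.interp(np.sqrt(u2[missing]), centers, prof)
        field = ndimage.gaussian_filter(field, cfg.illum_smooth_sigma)
    else:
        # few images: radially symmetric quadratic fit g(u) = a - b*u^2.
        # The parametric surface is noise-free, so it is not re-smoothed —
        # smoothing would round off the sharp valleys at tile seams.
        A = np.column_stack([np.ones_like(centers), centers**2])
        coef, *_ = np.linalg.lstsq(A, prof, rcond=None)
        field = coef[0] + coef[1] * u2
    peak = float(field.max())
    if peak <= 0:
        raise ContractError("degenerate illumination estimate (non-positive)")
    gain = np.clip(field / peak, cfg.illum_floor_eps, 1.0)
    return IlluminationField(
        gain=gain,
        n_images_used=len(images),
        smoothing_sigma_px=cfg.illum_smooth_sigma,
    )


def correct_illumination(
    image: TiledWellImage, field: IlluminationField
) -> TiledWellImage:
    """Divide by the gain surface (multiplicative shading model), clip to [0,1]."""
    if field.gain.shape != image.pixels.shape:
        raise ContractError(
            f"field shape {field.gain.shape} != image shape {image.pixels.shape}"
        )
    out = np.clip(image.pixels / field.gain, 0.0, 1.0)
    return image.with_pixels(out)


def denoise(image: TiledWellImage, sigma: float) -> TiledWellImage:
    """Mild Gaussian blur with reflective boundaries; ``sigma = 0`` is identity."""
    if sigma < 0:
        raise ConfigurationError("denoise sigma must be >= 0")
    if sigma == 0:
        return image
    out = ndimage.gaussian_filter(image.pixels, sigma, mode="reflect")
    return image.with_pixels(out)


def save_illumination(field: IlluminationField, path) -> Path:
    """Persist a field as 16-bit PNG plus a JSON sidecar for reuse."""
    path = Path(path)
    arr = np.round(field.gain * 65535).astype(np.uint16)
    iio.imwrite(path, arr)
    sidecar = {
        "shape": list(field.gain.shape),
        "n_images_used": field.n_images_used,
        "smoothing_sigma_px": field.smoothing_sigma_px,
    }
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh)
    return path


def load_illumination(path, floor_eps: float = 0.05) -> IlluminationField:
    """Load a persisted field; re-applies the floor after 16-bit quantization."""
    path = Path(path)
    arr = iio.imread(path).astype(np.float64) / 65535.0
    with open(path.with_suffix(".json"), "r", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    gain = np.clip(arr, floor_eps, 1.0)
    return IlluminationField(
        gain=gain,
        n_images_used=int(sidecar["n_images_used"]),
        smoothing_sigma_px=float(sidecar["smoothing_sigma_px"]),
    )


def seam_contrast(
    image_or_pixels, tile_rows: int, tile_cols: int, mask: np.ndarray | None = None
) -> float:
    """Grid-artifact statistic: |mean at tile seams - mean at tile centers|.

    Measured over a thin band along interior tile boundaries versus discs
    around tile centers; used to verify the correction stage removes the
    stitching grid.
    """
    px = (
        image_or_pixels.pixels
        if isinstance(image_or_pixels, TiledWellImage)
        else np.asarray(image_or_pixels)
    )
    h, w = px.shape
    th, tw = h / tile_rows, w / tile_cols
    band = 3
    seam = np.zeros((h, w), dtype=bool)
    for i in range(1, tile_rows):
        r = int(round(i * th))
        seam[max(0, r - band) : r + band, :] = True
    for j in range(1, tile_cols):
        c = int(round(j * tw))
        seam[:, max(0, c - band) : c + band] = True
    centers = np.zeros((h, w), dtype=bool)
    rad = int(min(th, tw) / 6)
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    for i in range(tile_rows):
        for j in range(tile_cols):
            cy, cx = (i + 0.5) * th, (j + 0.5) * tw
            centers |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
    if mask is not None:
        seam &= mask
        centers &= mask
    if not seam.any() or not centers.any():
        raise ContractError("mosaic has no interior seams to measure")
    return float(abs(px[seam].mean() - px[centers].mean()))
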