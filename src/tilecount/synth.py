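"""Synthetic tiled well-scan generator with ground truth.

Renders per-well mosaics that reproduce the artifacts a stitched plate
scanner produces: a bright circular halo where the plastic well wall
fluoresces, per-tile radial vignetting that shows up as a soft grid at tile
seams, medium autofluorescence background, bright particulate debris,
between-well exposure variation, well-position jitter, and the ovoid
y-compression failure mode.  Nuclei are isotropic Gaussian spots (at low
magnification a labeled nucleus is close to a point source) with known
centers, so the detection pipeline can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .errors import ConfigurationError, ContractError, GenerationError
from .io import PlateLayout, TiledWellImage, write_well_image


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """Study conditions for one rendered well.

    Geometry defaults describe a 4-wide x 3-high mosaic of ~300 px tiles
    (1000 x 1200 frame) holding a 420 px-radius growth disc, the scale at
    which a whole 96-well growth area fits in one low-magnification scan.
    Intensities are fractions of the detector range; the defaults give a
    visibly dim medium background (0.06), a strong well-wall halo (0.65) and
    nuclei whose peak (0.20 above background) is dim enough that the
    brightest vignetted background approaches the dimmest cells — the regime
    a log transform is meant to rescue.
    """

    image_height: int = 1000
    image_width: int = 1200
    tile_rows: int = 3
    tile_cols: int = 4
    well_center: tuple[float, float] = (500.0, 600.0)
    well_radius: float = 420.0
    halo_width: float = 35.0
    halo_intensity: float = 0.65
    background_level: float = 0.06
    vignette_strength: float = 0.30
    n_nuclei: int = 100
    nucleus_diameter_px: tuple[float, float] = (7.0, 13.0)
    nucleus_peak_intensity: float = 0.20
    n_debris: int = 10
    debris_intensity: float = 0.85
    exposure_gain: float = 1.0
    ovoid_y_scale: float = 1.0
    noise_sigma: float = 0.01
    rng_seed: int = 0
    # sampler details
    non_overlapping: bool = True
    min_separation_px: Optional[float] = None  # default 1.6 * max diameter
    nucleus_edge_margin_px: float = 20.0
    halo_edge_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.image_height < 4 or self.image_width < 4:
            raise ConfigurationError("image dimensions too small")
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ConfigurationError("tile_rows and tile_cols must be >= 1")
        if self.well_radius <= 0 or self.halo_width < 0:
            raise ConfigurationError("well_radius must be > 0, halo_width >= 0")
        if self.well_radius + self.halo_width >= min(
            self.image_height, self.image_width
        ) / 2:
            raise ConfigurationError(
                "well_radius + halo_width must fit inside half the short side"
            )
        if not (0 <= self.vignette_strength < 1):
            raise ConfigurationError("vignette_strength must be in [0, 1)")
        if self.exposure_gain <= 0:
            raise ConfigurationError("exposure_gain must be > 0")
        if not (0 < self.ovoid_y_scale <= 1):
            raise ConfigurationError("ovoid_y_scale must be in (0, 1]")
        if self.n_nuclei < 0:
            raise ConfigurationError("n_nuclei must be non-negative")
        if self.n_debris < 0:
            raise ConfigurationError("n_debris must be non-negative")
        dmin, dmax = self.nucleus_diameter_px
        if not (0 < dmin <= dmax):
            raise ConfigurationError("nucleus_diameter_px must satisfy 0 < min <= max")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        for name in ("halo_intensity", "background_level", "nucleus_peak_intensity",
                     "debris_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")

    @property
    def min_separation(self) -> float:
        """Hard-core distance between nucleus centers in non-overlap mode."""
        if self.min_separation_px is not None:
            return float(self.min_separation_px)
        return 1.6 * self.nucleus_diameter_px[1]

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticPlateSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown spec fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("well_center", "nucleus_diameter_px"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticPlateSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"spec file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


@dataclass
class GroundTruth:
    """Known truth for one rendered well (coordinates are post-compression)."""

    nucleus_centers: np.ndarray  # (n, 2) float, (row, col)
    nucleus_count: int
    well_center: tuple[float, float]
    well_radius: float
    well_id: str = "A1"
    ovoid_y_scale: float = 1.0
    image_path: str = ""

    def __post_init__(self) -> None:
        self.nucleus_centers = np.asarray(
            self.nucleus_centers, dtype=np.float64
        ).reshape(-1, 2)
        if self.nucleus_count != len(self.nucleus_centers):
            raise ContractError("nucleus_count must equal len(nucleus_centers)")


def vignette_field(
    shape: tuple[int, int], tile_rows: int, tile_cols: int, strength: float
) -> np.ndarray:
    """Per-tile radial falloff ``g = 1 - strength * (r / r_corner)**2``.

    Identical across tiles; this is the multiplicative gain surface whose
    seams form the grid artifact in a stitched mosaic.
    """
    h, w = shape
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    th, tw = h / tile_rows, w / tile_cols
    # position within the owning tile, relative to tile center
    dr = (rows % th) - (th - 1) / 2
    dc = (cols % tw) - (tw - 1) / 2
    r_corner2 = (th / 2) ** 2 + (tw / 2) ** 2
    u2 = (dr[:, None] ** 2 + dc[None, :] ** 2) / r_corner2
    return 1.0 - strength * u2


def _sample_nucleus_centers(spec: SyntheticPlateSpec, rng: np.random.Generator):
    """Dart-throwing placement inside the growth disc with a hard-core gap."""
    n = spec.n_nuclei
    if n == 0:
        return np.empty((0, 2))
    r_max = spec.well_radius - spec.nucleus_edge_margin_px
    if r_max <= 0:
        raise GenerationError("edge margin leaves no room for nuclei")
    sep = spec.min_separation if spec.non_overlapping else 0.0
    cy, cx = spec.well_center
    if sep > 0:
        # quick feasibility screen: hard discs of radius sep/2 must fit
        packing = n * math.pi * (sep / 2) ** 2 / (math.pi * r_max**2)
        if packing > 0.55:
            raise GenerationError(
                f"cannot place {n} nuclei with separation {sep:.1f}px "
                f"inside radius {r_max:.0f}px (packing {packing:.2f})"
            )
    centers: list[tuple[float, float]] = []
    # grid hash for neighbor lookups
    cell = max(sep, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    attempts = 0
    max_attempts = max(2000, 200 * n)
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"placed only {len(centers)}/{n} nuclei after "
                f"{max_attempts} attempts"
            )
        rad = r_max * math.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * math.pi)
        p = (cy + rad * math.sin(ang), cx + rad * math.cos(ang))
        if sep > 0:
            gi, gj = int(p[0] // cell), int(p[1] // cell)
            ok = True
            for ii in range(gi - 1, gi + 2):
                for jj in range(gj - 1, gj + 2):
                    for k in grid.get((ii, jj), ()):
                        q = centers[k]
                        if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < sep**2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue
            grid.setdefault((gi, gj), []).append(len(centers))
        centers.append(p)
    return np.array(centers)


def _add_gaussian_spot(img: np.ndarray, r0: float, c0: float, sigma: float,
                       peak: float) -> None:
    """Add an isotropic Gaussian profile in a local window (in place)."""
    h, w = img.shape
    half = int(math.ceil(4 * sigma))
    r_lo, r_hi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
    c_lo, c_hi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr = np.arange(r_lo, r_hi, dtype=np.float64) - r0
    cc = np.arange(c_lo, c_hi, dtype=np.float64) - c0
    img[r_lo:r_hi, c_lo:c_hi] += peak * np.exp(
        -(rr[:, None] ** 2 + cc[None, :] ** 2) / (2 * sigma**2)
    )


def render_well(spec: SyntheticPlateSpec) -> tuple[TiledWellImage, GroundTruth]:
    """Render one tiled well image and its ground truth.

    Composition: background + soft-edged halo annulus + Gaussian nuclei
    (sigma = diameter/4) + debris specks, multiplied by the per-tile
    vignette, plus zero-mean read noise, scaled by the exposure gain,
    optionally y-compressed (ovoid failure), clipped to [0, 1].
    Deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_height, spec.image_width
    cy, cx = spec.well_center

    scene = np.full((h, w), spec.background_level, dtype=np.float64)

    # halo annulus with softened edges
    if spec.halo_intensity > 0 and spec.halo_width > 0:
        rows = np.arange(h, dtype=np.float64)[:, None] - cy
        cols = np.arange(w, dtype=np.float64)[None, :] - cx
        dist = np.hypot(rows, cols)
        halo = np.where(
            (dist >= spec.well_radius) & (dist <= spec.well_radius + spec.halo_width),
            spec.halo_intensity,
            0.0,
        )
        if spec.halo_edge_sigma > 0:
            halo = ndimage.gaussian_filter(halo, spec.halo_edge_sigma)
        scene += halo

    # nuclei
    centers = _sample_nucleus_centers(spec, rng)
    dmin, dmax = spec.nucleus_diameter_px
    diameters = rng.uniform(dmin, dmax, size=len(centers))
    for (r0, c0), d in zip(centers, diameters):
        _add_gaussian_spot(scene, r0, c0, d / 4.0, spec.nucleus_peak_intensity)

    # debris specks: 1-2 px blocks anywhere in the frame
    for _ in range(spec.n_debris):
        s = int(rng.integers(1, 3))
        r0 = int(rng.integers(0, h - s + 1))
        c0 = int(rng.integers(0, w - s + 1))
        scene[r0 : r0 + s, c0 : c0 + s] += spec.debris_intensity

    if spec.vignette_strength > 0:
        scene *= vignette_field(
            (h, w), spec.tile_rows, spec.tile_cols, spec.vignette_strength
        )

    if spec.noise_sigma > 0:
        scene += rng.normal(0.0, spec.noise_sigma, size=scene.shape)

    scene *= spec.exposure_gain

    truth_centers = centers.copy()
    truth_center = (cy, cx)
    if spec.ovoid_y_scale < 1.0:
        h2 = max(2, int(round(h * spec.ovoid_y_scale)))
        f = h2 / h
        squashed = ndimage.zoom(scene, (f, 1.0), order=1, grid_mode=True,
                                mode="nearest")[:h2]
        canvas = np.full((h, w), spec.background_level * spec.exposure_gain)
        top = (h - h2) // 2
        canvas[top : top + h2] = squashed
        scene = canvas
        if len(truth_centers):
            truth_centers[:, 0] = truth_centers[:, 0] * f + top
        truth_center = (cy * f + top, cx)

    scene = np.clip(scene, 0.0, 1.0)
    image = TiledWellImage(
        pixels=scene,
        bit_depth=16,
        tile_rows=spec.tile_rows,
        tile_cols=spec.tile_cols,
    )
    truth = GroundTruth(
        nucleus_centers=truth_centers,
        nucleus_count=len(truth_centers),
        well_center=truth_center,
        well_radius=spec.well_radius,
        ovoid_y_scale=spec.ovoid_y_scale,
    )
    return image, truth


def render_plate(
    base_spec: SyntheticPlateSpec,
    jitter: float = 0.0,
    per_well_counts: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    layout: PlateLayout = PlateLayout(),
    exposure_jitter: float = 0.0,
) -> list[tuple[TiledWellImage, GroundTruth]]:
    """Render a full plate with per-well center jitter.

    Each well's center is the base center plus an independent uniform offset
    in [-jitter, +jitter] per axis.  The shared ``seed`` expands into
    per-well sub-seeds as ``seed + well_index`` so any single well can be
    re-rendered without the rest of the plate.  ``per_well_counts`` overrides
    ``n_nuclei`` for the named wells; ``exposure_jitter`` (fractional)
    emulates residual exposure variation between wells.
    """
    if jitter < 0:
        raise ConfigurationError("jitter must be >= 0")
    well_ids = layout.well_ids()
    if per_well_counts:
        unknown = set(per_well_counts) - set(well_ids)
        if unknown:
            raise ConfigurationError(
                f"per_well_counts references unknown wells: {sorted(unknown)}"
            )
    out = []
    cy, cx = base_spec.well_center
    for idx, well_id in enumerate(well_ids):
        sub_seed = seed + idx
        rng = np.random.default_rng(sub_seed)
        dy = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
        dx = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
        gain = base_spec.exposure_gain
        if exposure_jitter > 0:
            gain *= 1.0 + rng.uniform(-exposure_jitter, exposure_jitter)
        n = (
            per_well_counts[well_id]
            if per_well_counts and well_id in per_well_counts
            else base_spec.n_nuclei
        )
        spec_w = replace(
            base_spec,
            rng_seed=sub_seed,
            well_center=(cy + dy, cx + dx),
            exposure_gain=gain,
            n_nuclei=n,
        )
        image, truth = render_well(spec_w)
        image.well_id = well_id
        truth.well_id = well_id
        out.append((image, truth))
    return out


def write_plate(
    pairs: Sequence[tuple[TiledWellImage, GroundTruth]],
    out_dir,
    plate_id: str = "plate1",
    timepoint: float = 0.0,
    bit_depth: int = 8,
) -> Path:
    """Emit per-well PNGs plus a ground-truth CSV; returns the truth CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for image, truth in pairs:
        name = f"{plate_id}_day{int(timepoint):02d}_{truth.well_id}.png"
        path = out_dir / name
        image.plate_id = plate_id
        image.timepoint = float(timepoint)
        write_well_image(image, path, bit_depth=bit_depth)
        truth.image_path = str(path)
        rows.append(
            (
                truth.well_id,
                truth.nucleus_count,
                f"{truth.well_center[0]:.2f}",
                f"{truth.well_center[1]:.2f}",
                f"{truth.well_radius:.2f}",
                str(path),
            )
        )
    truth_path = out_dir / "truth.csv"
    with open(truth_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("well_id,n_nuclei,center_row,center_col,radius,image_path\n")
        for row in rows:
            fh.write(",".join(str(v) for v in row) + "\n")
    return truth_path


def simulate_growth_counts(
    n0: float,
    doubling_days: float,
    timepoints: Sequence[float],
    n_wells: int,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Exponential-growth count series with multiplicative noise.

    Returns an ``(n_wells, len(timepoints))`` integer array drawn as
    ``N_t = n0 * 2**(t / doubling_days) * (1 + U(-noise, +noise))``.
    """
    if doubling_days <= 0 or n0 <= 0:
        raise ConfigurationError("n0 and doubling_days must be > 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=np.float64)
    ideal = n0 * 2.0 ** (t / doubling_days)
    noise = 1.0 + rng.uniform(-noise_frac, noise_frac, size=(n_wells, t.size))
    return np.maximum(1, np.round(ideal[None, :] * noise)).astype(int)
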