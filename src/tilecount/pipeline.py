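"""Whole-plate orchestration: cropping, log transformation, counting.

Stage order is fixed: read -> detect well -> contract mask -> apply mask ->
log transform -> estimate illumination over the whole set -> correct ->
denoise -> segment nuclei -> write outputs.  A well whose growth area cannot
be found yields a flagged zero-count row; it never aborts the plate.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .config import PipelineConfig, auto_erosion_px
from .detect import LabelImage, NucleusRecord, render_outlines, segment_nuclei
from .enhance import (
    IlluminationField,
    correct_illumination,
    denoise,
    estimate_illumination,
    log_transform,
    save_illumination,
)
from .errors import NoWellFoundError, RunError
from .io import (
    DEFAULT_FILENAME_PATTERN,
    QC_NO_WELL_FOUND,
    TiledWellImage,
    WellCountRecord,
    parse_well_filename,
    read_well_image,
    write_counts_csv,
)
from .wells import WellMask, apply_mask, detect_well, erode_mask, qc_geometry

log = logging.getLogger(__name__)


@dataclass
class WellResult:
    """Everything the pipeline produced for one well."""

    record: WellCountRecord
    mask: Optional[WellMask] = None
    labels: Optional[LabelImage] = None
    nuclei: list[NucleusRecord] = field(default_factory=list)
    enhanced: Optional[TiledWellImage] = None


@dataclass
class RunManifest:
    """Reproducibility sidecar of one plate run."""

    config: dict
    inputs: list[dict]
    version: str
    rng_seed: int
    stage_seconds: dict
    warnings: list[str]

    def to_json(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
        return path


def _erosion_for(cfg: PipelineConfig, mask: WellMask) -> int:
    return cfg.erosion_px if cfg.erosion_px is not None else auto_erosion_px(
        mask.radius
    )


def count_plate(
    images: Sequence[TiledWellImage],
    cfg: PipelineConfig,
    skip_log: bool = False,
    skip_correction: bool = False,
    illum: Optional[IlluminationField] = None,
) -> tuple[list[WellResult], Optional[IlluminationField]]:
    """Run the counting pipeline on an in-memory image set.

    ``skip_log`` / ``skip_correction`` disable single stages (the ablations
    whose failure modes motivated the pipeline); ``illum`` supplies a
    precomputed illumination field instead of estimating one from this set.
    """
    prepared: list[tuple[TiledWellImage, Optional[WellMask], frozenset]] = []
    for image in images:
        try:
            mask = detect_well(image, cfg)
        except NoWellFoundError as exc:
            log.warning("%s: %s", image.well_id, exc)
            prepared.append((image, None, frozenset({QC_NO_WELL_FOUND})))
            continue
        mask = erode_mask(mask, _erosion_for(cfg, mask))
        flags = qc_geometry(mask, cfg)
        masked = apply_mask(image, mask, fill="zero")
        enhanced = masked if skip_log else log_transform(masked, cfg.log_gain_k)
        prepared.append((enhanced, mask, flags))

    usable = [(im, m) for im, m, _ in prepared if m is not None]
    field_used = illum
    if not skip_correction and field_used is None and usable:
        field_used = estimate_illumination(
            [im for im, _ in usable], cfg, masks=[m.mask for _, m in usable]
        )

    # finish enhancement per well, then fix one threshold for the whole set:
    # the counting threshold is optimized once per batch (as the protocol's
    # manual optimization is), which keeps sparse wells from collapsing the
    # per-well statistic.
    finished: list[tuple[TiledWellImage, Optional[WellMask], frozenset]] = []
    for enhanced, mask, flags in prepared:
        if mask is not None:
            if not skip_correction and field_used is not None:
                enhanced = correct_illumination(enhanced, field_used)
            enhanced = denoise(enhanced, cfg.denoise_sigma)
        finished.append((enhanced, mask, flags))

    seg_cfg = cfg
    n_usable = sum(1 for _, m, _ in finished if m is not None)
    if (
        cfg.manual_threshold is None
        and cfg.nucleus_threshold == "otsu"
        and n_usable >= 2
    ):
        from skimage.filters import threshold_otsu

        samples = []
        for img, m, _ in finished:
            if m is None:
                continue
            vals = img.pixels[m.mask]
            stride = max(1, vals.size // 100_000)
            samples.append(vals[::stride].astype(np.float32))
        pooled = np.concatenate(samples)
        if float(pooled.max() - pooled.min()) > 1e-9:
            seg_cfg = cfg.with_overrides(
                manual_threshold=float(threshold_otsu(pooled))
            )

    results: list[WellResult] = []
    for stagewise, mask, flags in finished:
        if mask is None:
            results.append(
                WellResult(
                    record=WellCountRecord(
                        plate_id=stagewise.plate_id,
                        well_id=stagewise.well_id,
                        timepoint=stagewise.timepoint,
                        count=0,
                        qc_flags=flags,
                        mask_area_px=0,
                    )
                )
            )
            continue
        labels, nuclei = segment_nuclei(stagewise, mask, seg_cfg)
        results.append(
            WellResult(
                record=WellCountRecord(
                    plate_id=stagewise.plate_id,
                    well_id=stagewise.well_id,
                    timepoint=stagewise.timepoint,
                    count=labels.n_objects,
                    qc_flags=flags,
                    mask_area_px=mask.area_px,
                ),
                mask=mask,
                labels=labels,
                nuclei=nuclei,
                enhanced=stagewise,
            )
        )
    return results, field_used


def count_single_well(
    image: TiledWellImage,
    cfg: PipelineConfig,
    skip_log: bool = False,
    skip_correction: bool = False,
    illum: Optional[IlluminationField] = None,
) -> WellResult:
    """One-well convenience wrapper around :func:`count_plate`."""
    results, _ = count_plate(
        [image], cfg, skip_log=skip_log, skip_correction=skip_correction,
        illum=illum,
    )
    return results[0]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_plate(
    input_dir,
    cfg: PipelineConfig,
    out_dir,
    pattern: str = DEFAULT_FILENAME_PATTERN,
    channel_policy: str = "green",
    strict_qc: bool = False,
    debug_images: bool = False,
    per_object: bool = False,
    illum_save=None,
    illum_load=None,
) -> tuple[list[WellCountRecord], RunManifest]:
    """Process every parseable well image in ``input_dir``.

    Writes ``counts.csv`` and ``manifest.json`` into ``out_dir`` (plus
    optional per-object CSVs and overlay PNGs).  Returns the records and the
    manifest.  Raises :class:`RunError` if no input parses.
    """
    from .errors import ImageIOError, MetadataError

    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    images: list[TiledWellImage] = []
    inputs_meta: list[dict] = []
    rejected: list[str] = []
    failed_records: list[WellCountRecord] = []
    for path in sorted(input_dir.glob("*.png")) + sorted(input_dir.glob("*.PNG")):
        try:
            img = read_well_image(path, channel_policy=channel_policy,
                                  pattern=pattern)
        except MetadataError as exc:
            rejected.append(path.name)
            warnings.append(f"rejected {path.name}: {exc}")
            continue
        except ImageIOError as exc:
            # identity is known from the filename: keep a flagged zero row so
            # one corrupt file never silently drops a well
            try:
                plate, well, tp = parse_well_filename(path.name, pattern)
            except MetadataError:
                rejected.append(path.name)
                warnings.append(f"rejected {path.name}: {exc}")
                continue
            warnings.append(f"unreadable {path.name}: {exc}")
            failed_records.append(
                WellCountRecord(
                    plate_id=plate, well_id=well, timepoint=tp, count=0,
                    qc_flags=frozenset({QC_NO_WELL_FOUND}), mask_area_px=0,
                )
            )
            continue
        images.append(img)
        inputs_meta.append(
            {
                "path": str(path),
                "sha256": _sha256(path),
                "plate_id": img.plate_id,
                "well_id": img.well_id,
                "timepoint": img.timepoint,
            }
        )
    timings["read"] = time.perf_counter() - t0
    if not images and not failed_records:
        raise RunError(
            f"no parseable well images in {input_dir}; rejected: {rejected}"
        )

    illum = None
    if illum_load is not None:
        from .enhance import load_illumination

        illum = load_illumination(illum_load, floor_eps=cfg.illum_floor_eps)

    t0 = time.perf_counter()
    results, field_used = count_plate(images, cfg, illum=illum)
    timings["count"] = time.perf_counter() - t0

    if illum_save is not None and field_used is not None:
        save_illumination(field_used, illum_save)

    records = [r.record for r in results] + failed_records
    if strict_qc:
        n_flagged = sum(1 for r in records if r.qc_flags)
        if n_flagged:
            warnings.append(f"{n_flagged} wells carry QC flags")

    t0 = time.perf_counter()
    write_counts_csv(records, out_dir / "counts.csv")
    if per_object:
        with open(out_dir / "objects.csv", "w", encoding="utf-8") as fh:
            fh.write(
                "well_id,label,centroid_row,centroid_col,area_px,"
                "equivalent_diameter_px,mean_intensity\n"
            )
            for res in results:
                for n in res.nuclei:
                    fh.write(
                        f"{res.record.well_id},{n.label},"
                        f"{n.centroid[0]:.2f},{n.centroid[1]:.2f},"
                        f"{n.area_px},{n.equivalent_diameter_px:.3f},"
                        f"{n.mean_intensity:.5f}\n"
                    )
    if debug_images:
        for img, res in zip(images, results):
            if res.labels is not None:
                render_outlines(
                    img, res.labels, out_dir / f"overlay_{res.record.well_id}.png"
                )
    timings["write"] = time.perf_counter() - t0

    manifest = RunManifest(
        config=cfg.to_dict(),
        inputs=inputs_meta,
        version=__version__,
        rng_seed=cfg.rng_seed,
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
        warnings=warnings,
    )
    manifest.to_json(out_dir / "manifest.json")
    return records, manifest
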