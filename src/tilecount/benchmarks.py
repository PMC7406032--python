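"""Paired ablation experiments that justify the pipeline's two key stages.

Each harness renders a synthetic well whose ground truth is known, runs the
full pipeline and the variant with one stage removed, and reports the paired
outcome: skipping illumination correction makes the stitching grid count as
objects; skipping the log transform leaves dim nuclei below the working
threshold after correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from skimage.filters import threshold_otsu

from .config import PipelineConfig
from .detect import match_to_truth
from .pipeline import count_single_well
from .synth import SyntheticPlateSpec, render_well


@dataclass(frozen=True)
class GridAblation:
    """Counts with and without illumination correction on one vignetted well."""

    truth_count: int
    count_corrected: int
    count_uncorrected: int


def grid_necessity(
    seed: int,
    cfg: PipelineConfig = PipelineConfig(),
    vignette_strength: float = 0.4,
    n_nuclei: int = 100,
    base_spec: SyntheticPlateSpec = SyntheticPlateSpec(),
) -> GridAblation:
    """Paired count on one well with a strong stitching-grid artifact."""
    spec = replace(
        base_spec,
        vignette_strength=vignette_strength,
        n_nuclei=n_nuclei,
        rng_seed=seed,
    )
    image, truth = render_well(spec)
    full = count_single_well(image, cfg)
    ablated = count_single_well(image, cfg, skip_correction=True)
    return GridAblation(
        truth_count=truth.nucleus_count,
        count_corrected=full.record.count,
        count_uncorrected=ablated.record.count,
    )


@dataclass(frozen=True)
class LogAblation:
    """Recall of dim nuclei with and without the log transform.

    Both arms are thresholded at the same absolute value, calibrated once
    (Otsu) on the full log->correct pipeline output — the counting
    threshold is optimized once for the working pipeline and then held
    fixed, as a batch protocol does.
    """

    truth_count: int
    recall_log: float
    recall_nolog: float
    threshold: float


def log_necessity(
    seed: int,
    cfg: PipelineConfig = PipelineConfig(),
    peak: float = 0.15,
    background: float = 0.05,
    n_nuclei: int = 100,
    base_spec: SyntheticPlateSpec = SyntheticPlateSpec(),
    match_dist: float = 5.0,
) -> LogAblation:
    """Paired recall on one well with dim nuclei (peak over background)."""
    spec = replace(
        base_spec,
        nucleus_peak_intensity=peak,
        background_level=background,
        n_nuclei=n_nuclei,
        rng_seed=seed,
    )
    image, truth = render_well(spec)

    reference = count_single_well(image, cfg)
    if reference.mask is None:
        raise RuntimeError("well not found in reference arm")
    vals = reference.enhanced.pixels[reference.mask.mask]
    threshold = float(threshold_otsu(vals))

    fixed_cfg = cfg.with_overrides(manual_threshold=threshold)
    arm_log = count_single_well(image, fixed_cfg)
    arm_nolog = count_single_well(image, fixed_cfg, skip_log=True)

    n = truth.nucleus_count
    matched_log, _, _ = match_to_truth(arm_log.nuclei, truth, match_dist)
    matched_nolog, _, _ = match_to_truth(arm_nolog.nuclei, truth, match_dist)
    return LogAblation(
        truth_count=n,
        recall_log=matched_log / n if n else 1.0,
        recall_nolog=matched_nolog / n if n else 1.0,
        threshold=threshold,
    )
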