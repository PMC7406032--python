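"""Growth statistics from per-well counts.

Counts become population doublings (PD = log2 of fold change versus each
well's own first scan) and replicate wells are summarized as mean ± sample
SD per condition and timepoint.  Also provides the circular-ROI background
intensity measurement used to compare imaging media.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import AggregationError, ContractError, UndefinedPDError
from .io import TiledWellImage, WellCountRecord

log = logging.getLogger(__name__)


@dataclass
class GrowthCurve:
    """Mean ± SD population-doubling trajectory of one replicate group."""

    condition: str
    timepoints: list[float]
    mean_pd: list[float]
    sd_pd: list[float]
    n_replicates: int
    baseline_timepoint: float

    def __post_init__(self) -> None:
        if not (len(self.timepoints) == len(self.mean_pd) == len(self.sd_pd)):
            raise ContractError("curve arrays must share one length")


def population_doublings(count_t: int, count_0: int) -> float:
    """log2 fold change in cell count; 3.0 means the population doubled thrice."""
    if count_t <= 0 or count_0 <= 0:
        raise UndefinedPDError(
            f"population doublings undefined for counts ({count_t}, {count_0})"
        )
    return math.log2(count_t / count_0)


def build_growth_curves(
    records: Sequence[WellCountRecord],
    groups: Mapping[str, Sequence[str]],
    baseline: Optional[float] = None,
    strict_qc: bool = False,
) -> list[GrowthCurve]:
    """Aggregate well counts into per-condition PD curves.

    Each well's PD is computed against its own count at the baseline
    timepoint (default: the earliest timepoint present).  Wells with a
    non-positive baseline count are excluded with a logged warning; with
    ``strict_qc`` any well carrying a QC flag on any record is excluded.
    Mean and sample SD (n-1 denominator) are taken across replicate wells.
    """
    from .io import normalize_well_id

    by_well: dict[tuple[str, str], dict[float, WellCountRecord]] = {}
    flagged_wells: set[str] = set()
    for r in records:
        by_well.setdefault((r.plate_id, r.well_id), {})[r.timepoint] = r
        if r.qc_flags:
            flagged_wells.add(r.well_id)

    all_t = sorted({r.timepoint for r in records})
    if not all_t:
        raise AggregationError("no records to aggregate")
    if baseline is None:
        baseline = all_t[0]

    curves: list[GrowthCurve] = []
    for condition, wells in groups.items():
        wanted = {normalize_well_id(w) for w in wells}
        series: list[dict[float, float]] = []
        for (plate, well), by_t in by_well.items():
            if well not in wanted:
                continue
            if strict_qc and well in flagged_wells:
                log.warning(
                    "%s: well %s excluded (QC flags under strict mode)",
                    condition, well,
                )
                continue
            base_rec = by_t.get(baseline)
            if base_rec is None or base_rec.count <= 0:
                log.warning(
                    "%s: well %s excluded (missing or zero baseline count)",
                    condition, well,
                )
                continue
            series.append(
                {
                    t: population_doublings(rec.count, base_rec.count)
                    for t, rec in by_t.items()
                    if rec.count > 0
                }
            )
        if not series:
            raise AggregationError(
                f"condition {condition!r}: no usable wells after exclusions"
            )
        timepoints = sorted({t for s in series for t in s})
        mean_pd, sd_pd = [], []
        for t in timepoints:
            vals = np.array([s[t] for s in series if t in s])
            mean_pd.append(float(vals.mean()))
            sd_pd.append(float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        curves.append(
            GrowthCurve(
                condition=condition,
                timepoints=[float(t) for t in timepoints],
                mean_pd=mean_pd,
                sd_pd=sd_pd,
                n_replicates=len(series),
                baseline_timepoint=float(baseline),
            )
        )
    return curves


def fit_doublings_per_day(curve: GrowthCurve) -> float:
    """Least-squares slope of mean PD versus time (doublings per day)."""
    t = np.asarray(curve.timepoints)
    y = np.asarray(curve.mean_pd)
    if len(t) < 2:
        raise ContractError("need at least two timepoints to fit a slope")
    return float(np.polyfit(t, y, 1)[0])


def measure_roi_background(
    image: TiledWellImage, center: tuple[float, float], radius: float
) -> tuple[float, float]:
    """Mean and sample SD of intensities within a circular ROI.

    ``radius = 0`` degenerates to the single pixel nearest the center (SD 0).
    The circle must lie fully inside the frame.
    """
    h, w = image.pixels.shape
    cy, cx = center
    if radius < 0:
        raise ContractError("radius must be >= 0")
    if (
        cy - radius < -0.5
        or cx - radius < -0.5
        or cy + radius > h - 0.5
        or cx + radius > w - 0.5
    ):
        raise ContractError("ROI circle extends outside the image")
    rows = np.arange(h, dtype=np.float64)[:, None] - cy
    cols = np.arange(w, dtype=np.float64)[None, :] - cx
    sel = rows**2 + cols**2 <= radius**2
    if not sel.any():
        sel[int(round(cy)), int(round(cx))] = True
    vals = image.pixels[sel]
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def curves_to_csv(curves: Sequence[GrowthCurve], path) -> None:
    """Write curves as CSV: condition, timepoint, mean_pd, sd_pd, n."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("condition,timepoint,mean_pd,sd_pd,n\n")
        for c in curves:
            for t, m, s in zip(c.timepoints, c.mean_pd, c.sd_pd):
                fh.write(
                    f"{c.condition},{t:g},{m:.6f},{s:.6f},{c.n_replicates}\n"
                )


def plot_curves(curves: Sequence[GrowthCurve], path) -> None:
    """Mean ± SD band plot of each condition's PD trajectory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        t = np.asarray(c.timepoints)
        m = np.asarray(c.mean_pd)
        s = np.asarray(c.sd_pd)
        (line,) = ax.plot(t, m, marker="o", label=f"{c.condition} (n={c.n_replicates})")
        ax.fill_between(t, m - s, m + s, alpha=0.25, color=line.get_color())
    ax.set_xlabel("time (days)")
    ax.set_ylabel("population doublings")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
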