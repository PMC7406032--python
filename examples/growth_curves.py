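"""Population-doubling growth curves from per-well counts.

Counts are converted to population doublings (PD = log2 fold change versus
each well's own first scan) and replicate wells are summarized as
mean +/- sample SD per timepoint, the standard presentation for clonal
growth assays.
"""

from tilecount import (
    WellCountRecord,
    build_growth_curves,
    simulate_growth_counts,
)
from tilecount.growth import fit_doublings_per_day

timepoints = list(range(0, 15, 2))  # scanned every 2 days for two weeks
counts = simulate_growth_counts(
    n0=100, doubling_days=2.0, timepoints=timepoints, n_wells=12,
    noise_frac=0.05, seed=5,
)
records = [
    WellCountRecord("P1", f"A{w + 1}", float(t), int(counts[w, j]))
    for w in range(12)
    for j, t in enumerate(timepoints)
]

(curve,) = build_growth_curves(
    records, groups={"control": [f"A{w}" for w in range(1, 13)]}
)
print(f"condition {curve.condition}, n = {curve.n_replicates} replicate wells")
print("day   mean PD   SD")
for t, m, s in zip(curve.timepoints, curve.mean_pd, curve.sd_pd):
    print(f"{t:>3.0f}   {m:>6.3f}  {s:>6.3f}")
slope = fit_doublings_per_day(curve)
print()
print(f"fitted rate: {slope:.3f} doublings/day "
      f"(simulated with a 2-day doubling time, i.e. 0.5/day)")
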