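"""Reconstruct comparator pseudo-IPD from published KM coordinates.

Simulates a comparator arm, renders it the way a publication reports it
(digitized curve points, a 6-monthly numbers-at-risk table, the total
event count), reconstructs subject-level data with the iterative
interval algorithm, and measures the fidelity of the round trip.
"""

import numpy as np

from survstc import (
    generate_ipd,
    guyot_reconstruct,
    km_estimate,
    km_rmst,
    render_comparator,
)

truth = generate_ipd(
    family="weibull", params={"mu": np.log(0.04), "shape": 1.1},
    n=350, censoring=(48.0, 0.02), seed=3, arm_label="comparator",
)
curve, risk, baseline = render_comparator(truth, curve_points=120, risk_interval=6.0)
print(f"published rendering: {curve.times.size} digitized points, "
      f"risk table at {risk.interval_times.astype(int).tolist()} months, "
      f"{risk.total_events} total events")

pseudo = guyot_reconstruct(curve, risk)
km_true, km_rec = km_estimate(truth), km_estimate(pseudo)
grid = np.linspace(0, truth.horizon * 0.999, 500)
max_err = np.abs(km_true.at(grid) - km_rec.at(grid)).max()

print(f"\nreconstructed {pseudo.n} subjects with {pseudo.event.sum()} events "
      f"(published: {risk.total_events})")
print(f"max |KM_reconstructed - KM_true| over follow-up: {max_err:.4f}")
print(f"RMST to 36 months - truth: {km_rmst(km_true, 36):.2f}, "
      f"reconstructed: {km_rmst(km_rec, 36):.2f} months")
# errors of ~0.01 on the survival scale are typical; the event count is
# forced to match the published total exactly
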