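#!/usr/bin/env python
"""Heart rate and pulsatile-motion (MAV) recovery.

Runs the phase chain (phasor differencing -> RPE bulk referencing ->
displacement -> spectral heart-rate estimate -> MAV) on phantoms with heart
rates drawn across the murine range, and checks the en-face MAV at the ILM
against brute-force averaging of the true displacement series.
"""

from pathlib import Path

import pandas as pd

from retipulse.evaluation import hr_recovery, mav_oracle

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

pairs = hr_recovery(n_phantoms=10, seed=0)
hr_table = pd.DataFrame(
    [{"hr_true_bpm": t, "hr_est_bpm": e, "abs_err_bpm": abs(e - t)} for t, e in pairs]
)
hr_table.to_csv(OUT / "hr_recovery.csv", index=False)
print(hr_table.round(3).to_string(index=False))
print(f"\nmax |error| {hr_table['abs_err_bpm'].max():.3f} bpm over {len(pairs)} phantoms")

mav = mav_oracle(seed=0)
mav_table = pd.DataFrame([mav])
mav_table.to_csv(OUT / "mav_oracle.csv", index=False)
print(
    f"\nMAV at ILM {mav['mav_ilm']:.3f} nm/ms vs truth-series oracle "
    f"{mav['mav_ilm_expected']:.3f} nm/ms ({100 * mav['mav_rel_err']:.2f}% off); "
    f"static phantom MAV = {mav['static_max']:.1f}; "
    f"amplitude doubling scales MAV by {mav['doubling_ratio']:.3f}."
)
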