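#!/usr/bin/env python
"""Superficial-plexus segmentation by complex OCTA.

Computes the bulk-corrected complex inter-repeat difference, projects it over
a 30 um slab below the ILM, estimates the noise floor from the vitreous, and
segments vessels at 20x the floor.  Reports Dice overlap with the phantom's
true vessel footprint and the annulus vessel-density error across seeds.
"""

from pathlib import Path

import pandas as pd

from retipulse.evaluation import svp_recovery

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

out = svp_recovery(n_seeds=10, seed=0)
table = pd.DataFrame([out])
table.to_csv(OUT / "svp_recovery.csv", index=False)
print(table.round(4).to_string(index=False))
print(
    f"\nAcross 10 seeds at 25 dB SNR: worst Dice {out['dice_min']:.3f} "
    f"(mean {out['dice_mean']:.3f}), worst annulus-density error "
    f"{out['density_err_max_pp']:.2f} percentage points; raising the threshold "
    f"multiplier from 20 to 30 added {out['monotonicity_violations']} pixels."
)
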