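#!/usr/bin/env python
"""Annular retinal-thickness mapping with and without the vascular plexus.

On a vessel phantom, computes the en-face RT map from the layer segmentation
and summarises the 0.2-0.4 mm annulus three ways: all pixels (RT), excluding
vessel pixels (RT-SVP), and vessel pixels only (RT@SVP).  dRT = RT - RT-SVP
isolates the vascular contribution to thickness.
"""

from pathlib import Path

import pandas as pd

from retipulse.evaluation import rt_recovery_and_partition

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

out = rt_recovery_and_partition(seed=0)
table = pd.DataFrame([out])
table.to_csv(OUT / "rt_variants.csv", index=False)
print(table.round(4).to_string(index=False))
print(
    f"\nAnnulus-mean RT {out['rt_mean_um']:.2f} um vs truth {out['rt_truth_um']:.2f} um "
    f"(error {out['rt_err_um']:.2f} um, one axial pixel = {out['axial_pixel_um']:.2f} um).\n"
    f"RT@SVP exceeds RT-SVP by {out['at_minus_excl_um']:.2f} um (vessel thickness bumps); "
    f"dRT = {out['delta_rt_um']:.3f} um, matching the brute-force pixel lists to "
    f"{abs(out['delta_rt_um'] - out['delta_rt_brute_um']):.1e} um."
)
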