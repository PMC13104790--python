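#!/usr/bin/env python
"""Layer-segmentation recovery study.

Segments ILM / IS-OS / RPE on seeded 25 dB phantoms with a sinusoidally
varying ILM and reports the per-surface mean absolute error in pixels.  The
contract is a mean error of at most one axial pixel per surface.
"""

from pathlib import Path

import pandas as pd

from retipulse.evaluation import segmentation_recovery

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

out = segmentation_recovery(n_seeds=10, seed=0)
table = pd.DataFrame(
    [
        {"surface": "ILM", "mae_px": out["ilm_mae"]},
        {"surface": "IS/OS", "mae_px": out["isos_mae"]},
        {"surface": "RPE", "mae_px": out["rpe_mae"]},
    ]
)
table["n_seeds"] = 10
table.to_csv(OUT / "segmentation_recovery.csv", index=False)
print(table.to_string(index=False))
print(
    f"\nWorst per-seed MAE {out['max_mae']:.3f} px; "
    f"ordering (ILM < IS/OS < RPE) violations: {out['ordering_violations']}."
)
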