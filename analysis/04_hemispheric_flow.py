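#!/usr/bin/env python
"""Hemispheric information flow and laterality.

Summarizes the four within/between-hemisphere flow quadrants
(LH->LH, LH->RH, RH->RH, RH->LH) per cohort and block, and derives the
laterality index (LH - RH) / (LH + RH) of total outflow per hemisphere.
"""

import pandas as pd

from vigilnet.hemi import laterality_index

from _common import PIPELINE_DIR, RESULTS

hif = pd.read_csv(PIPELINE_DIR / "hif.tsv", sep="\t")
quad = hif.groupby(["group", "block", "quadrant"])["mean_flow"].mean().unstack()
quad.to_csv(RESULTS / "hif_summary.tsv", sep="\t")
print("mean per-sender flow by quadrant:")
print(quad.round(4).to_string())

rows = []
for (group, block), q in quad.iterrows():
    lh_out = q["LH->LH"] + q["LH->RH"]
    rh_out = q["RH->RH"] + q["RH->LH"]
    rows.append({
        "group": group, "block": block,
        "lh_outflow": lh_out, "rh_outflow": rh_out,
        "laterality": laterality_index(lh_out, rh_out),
    })
lat = pd.DataFrame(rows)
lat.to_csv(RESULTS / "laterality.tsv", sep="\t", index=False)
print("\noutflow laterality index (positive = left-dominant):")
print(lat.round(4).to_string(index=False))
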