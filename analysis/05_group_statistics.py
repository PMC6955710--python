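#!/usr/bin/env python
"""Group statistics: level contrasts, group contrasts, electrode t-maps.

Reads the pipeline's contrast table (paired t within groups, Welch t
between groups, Holm-corrected per metric) and the per-electrode nodal
degree t-maps (|t| >= 2.5 significance criterion), and reports which
comparisons separate the cohorts.
"""

import pandas as pd

from _common import PIPELINE_DIR

contrasts = pd.read_csv(PIPELINE_DIR / "contrasts.tsv", sep="\t")
tmaps = pd.read_csv(PIPELINE_DIR / "tmaps.tsv", sep="\t")

print("Holm-significant contrasts per metric:")
for metric, sub in contrasts.groupby("metric"):
    sig = sub[sub.significant].contrast.tolist()
    print(f"  {metric}: {', '.join(sig) if sig else '(none)'}")

print("\nwithin-vigilance level contrasts (paired t):")
vig = contrasts[contrasts.contrast.str.match(r"V\d vs V\d")]
print(vig[["metric", "contrast", "t", "p", "p_holm", "significant"]]
      .round(4).to_string(index=False))

n_sig = tmaps.groupby("contrast")["significant"].sum()
print("\nelectrodes with |t| >= 2.5 on nodal degree, per contrast:")
print(n_sig.to_string())

worst = tmaps.loc[tmaps.groupby("contrast")["t"].transform(
    lambda t: t.abs() == t.abs().max())]
print("\nmost sensitive electrode per contrast:")
print(worst[["contrast", "electrode", "t"]].round(3).to_string(index=False))
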