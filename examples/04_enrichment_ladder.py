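"""The promoter-class comparison ladder on a boolean gene flag.

Four fixed comparisons — AP (pooled) vs SP, AP2 vs SP, AP3_4 vs AP2,
AP5plus vs AP3_4 — each a 2x2 Fisher exact test on flag membership, plus
per-class flag fractions. Here the flag is planted with rising frequency.
"""

import numpy as np
import pandas as pd

from promdiver import class_ladder

rng = np.random.default_rng(42)
classes = {"SP": 2000, "AP2": 1200, "AP3_4": 900, "AP5plus": 400}
planted = {"SP": 0.03, "AP2": 0.05, "AP3_4": 0.08, "AP5plus": 0.13}

rows, flags = [], {}
for cls, n in classes.items():
    for i in range(n):
        g = f"{cls}_{i}"
        rows.append({"gene_id": g, "promoter_class": cls})
        flags[g] = bool(rng.random() < planted[cls])
profiles = pd.DataFrame(rows)

result = class_ladder(flags, profiles, kind="fisher")
print(result.class_summaries.to_string(index=False))
print()
print(result.to_frame()[["label", "summary1", "summary2", "p_value", "p_display"]]
      .to_string(index=False))
# class summaries are % flagged per class; each ladder rung reports the two
# group fractions and the exact p-value for their difference — with these
# planted frequencies every rung should be significant.
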