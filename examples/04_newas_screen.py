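"""NE-WAS: screen many neighborhood measures against a binary outcome.

Simulates 400 locations with 20 standardized measures — one with a real
log-odds effect — fits one univariable logistic regression per measure, and
prints the Bonferroni-controlled screen plus the Manhattan-plot-ready
table.
"""

import numpy as np
import pandas as pd
from scipy import special

import geocontext as gc

rng = np.random.default_rng(5)
n, m = 400, 20
x = rng.normal(size=(n, m))
y = rng.binomial(1, special.expit(1.2 * x[:, 0]))  # measure_00 carries the signal
data = pd.DataFrame(x, columns=[f"measure_{i:02d}" for i in range(m)])
data["outcome"] = y

screen = gc.newas_screen(data, alpha=0.05)
top = screen.sort_values("rank").head(5)
print(top[["measure", "n", "estimate", "p_value", "assoc_strength", "bonferroni_significant"]].to_string(index=False))
print(f"\nm = {screen.attrs['m_tested']} measures tested; "
      f"Bonferroni threshold p < {screen.attrs['bonferroni_threshold']:.2e}")
print(f"{int(screen['bonferroni_significant'].sum())} measure(s) survive family-wise control; "
      "assoc_strength is -log10(p) per SD of the measure")

meta = {f"measure_{i:02d}": {"domain": "demography" if i < 10 else "safety",
                             "kind": "count" if i % 2 == 0 else "proportion"} for i in range(m)}
manhattan = gc.manhattan_table(screen, meta)
print("\nManhattan table (first rows; x_index orders measures by domain/kind group):")
print(manhattan.head(6).to_string(index=False))
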