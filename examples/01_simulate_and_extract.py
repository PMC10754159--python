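"""Render a small synthetic imaging field and extract per-cell features.

Generates ~40 cells as paired cell/nucleus label masks with a damage
channel, runs the 33-parameter morphometry on them, and compares the
extracted damage readout with the generator's ground truth.
"""

import numpy as np

from morphotype import extract_field
from morphotype import synthetic as syn

condition = syn.default_conditions()[0]  # unexposed control mixture
fields = syn.generate_population(
    syn.default_subtypes(), condition, n_cells=40, seed=1,
    output="masks", field_shape=(1200, 1200),
)

field = fields[0]
table, log = extract_field(field.cell_labels, field.nucleus_labels, field.damage)
merged = table.merge(field.truth, on="label")

print(f"extracted {log.n_extracted} cells, {table.shape[1] - 2} feature columns")
print(
    "cell area px^2: "
    f"median {table['cell_area'].median():.0f}, "
    f"range {table['cell_area'].min():.0f}-{table['cell_area'].max():.0f}"
)
err = np.abs(
    merged["gh2ax_mean_nuclear_intensity"] - merged["gh2ax_true"]
).max()
print(f"max |extracted - true| gamma-H2AX intensity: {err:.2e}")
# The damage readout is the mean nuclear pixel intensity normalized to
# [0, 1]; agreement at ~1e-5 reflects only 16-bit quantization.
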