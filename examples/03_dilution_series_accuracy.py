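"""Matrix-matched calibration curve: accuracy of imputed quantitations.

In a serial dilution of human sample into a matched background, every
peptide's expected abundance ratio versus the undiluted reference is
log2(d). This script simulates such a series, handles missing values with
each method, and reports how far the observed log ratios fall from the
expectation at each dilution.
"""

import rtimpute as rt

design = rt.mmcc_design(levels=(1.0, 0.3, 0.1, 0.07, 0.05, 0.01), replicates=3)
exp = rt.simulate_experiment(rt.SimConfig(n_peptides=40, dilutions=design, seed=9))
tables = rt.mmcc_comparison(exp)

print("median |observed - expected| log2 ratio per dilution:")
header = "  dilution  expected " + "".join(f"{m:>14}" for m in tables)
print(header)
levels = tables["rt_boundary"].index
for d in levels:
    row = f"  {d:>8.0%}  {rt.expected_log_ratio(d):8.2f} "
    for m in tables:
        row += f"{tables[m].loc[d, 'median_abs_deviation']:14.2f}"
    print(row)
print("boundary imputation integrates the actual diluted signal, so its "
      "ratios track log2(d); low-value imputation pins missing cells at the "
      "row minimum and kNN-on-quants borrows from less-diluted runs, both "
      "flattening the dilution response.")
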