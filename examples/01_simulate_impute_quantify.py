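"""Simulate a DIA experiment, impute missing RT boundaries, quantify.

Builds a small synthetic experiment with intensity-dependent (MNAR)
missingness, fills the missing chromatographic peak boundaries from the
most similar runs, and integrates the extracted ion chromatograms inside
every window — observed or imputed.
"""

import numpy as np

import rtimpute as rt

cfg = rt.SimConfig(n_runs=16, n_peptides=40, gradient_window=(5.0, 35.0), seed=5)
exp = rt.simulate_experiment(cfg)
n_cells = exp.library.shape[0] * exp.library.shape[1]
print(f"library search observed {exp.library.n_present}/{n_cells} cells "
      f"({1 - exp.library.n_present / n_cells:.0%} missing)")

result = rt.impute_boundaries(exp.library)
print(f"kNN boundary imputation filled {result.n_imputed} cells "
      f"({result.n_swapped} inverted windows repaired, "
      f"{len(result.unimputable)} cells had no donor run)")

q = rt.quantify_peptides(exp.runs, exp.transitions, result.matrix)
observed = q.values.to_numpy()[(q.provenance == "observed").to_numpy()]
rescued = q.values.to_numpy()[(q.provenance == "boundary_imputed").to_numpy()]
print(f"median observed abundance:  {np.median(observed):12.0f}")
print(f"median rescued abundance:   {np.median(rescued):12.0f}")
print("rescued quantitations sit below the observed ones because MNAR "
      "missingness preferentially hides low-abundance peptides — the "
      "imputed windows integrate real, small signals instead of guesses.")
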