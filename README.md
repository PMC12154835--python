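# rtimpute

Retention-time boundary imputation for DIA proteomics.

Missing values plague label-free DIA experiments: low-abundance peptides
escape the library search in some runs, leaving holes in the peptide × run
quantitation matrix that weaken every downstream comparison. The usual fix
— plug-in imputation (low-value, kNN, random-forest) — replaces a missing
quantitation with an estimate computed from other cells, which can dilute
signal and invent correlations.

`rtimpute` takes the other road. For a peptide missing in run *r*, it
imputes the *retention-time boundaries* of its chromatographic peak from
the most similar runs, then integrates the extracted ion chromatogram
(XIC) inside that window:

* the boundary matrix **B** has runs as samples and, per precursor, a
  start and an end feature (minutes);
* distances between runs are shared-coordinate Euclidean,
  d(x, y) = √( F/|S| · Σ_{j∈S} (x_j − y_j)² ), and each missing entry takes
  the 1/d-weighted mean of its k = 8 nearest observing runs;
* the peptide abundance is Σ over transitions of the background-subtracted
  trapezoidal XIC area within [start, end], so the filled-in value is a
  real measurement of the raw data rather than a statistical guess.

The package also ships the standard plug-in baselines (low-value,
kNN-on-quants, MissForest-style), the evaluation procedures used to compare
them (dilution-series expected-ratio deviation, hold-out MSE, Welch +
Benjamini–Hochberg differential abundance, bilinear calibration curves
with bootstrap LLOQ), a ground-truth DIA simulator, and readers/writers
for the interchange formats (boundary CSV, a BiblioSpec-style `.blib`
SQLite dialect, mzML 1.1, quant TSV — see `FORMAT.md`).

## Worked example

```python
import rtimpute as rt

# a synthetic 16-run experiment with MNAR missingness and known truth
exp = rt.simulate_experiment(
    rt.SimConfig(n_runs=16, n_peptides=40, gradient_window=(5.0, 35.0), seed=5)
)

result = rt.impute_boundaries(exp.library)        # trim 1% tails + kNN (k=8)
q = rt.quantify_peptides(exp.runs, exp.transitions, result.matrix)
```

Running `python examples/01_simulate_impute_quantify.py` (which does
exactly this) prints:

```
library search observed 431/640 cells (33% missing)
kNN boundary imputation filled 208 cells (0 inverted windows repaired, 16 cells had no donor run)
median observed abundance:       1482469
median rescued abundance:         359153
```

The rescued cells' median sits well below the observed median: under
intensity-dependent missingness the peptides that were missing are the
low-abundance ones, and integrating their (small, real) signal reflects
that — a plug-in method has to guess it. The other examples benchmark
hold-out reconstruction (`02`), dilution-series accuracy (`03`, where
boundary-imputed ratios track log2(d) within ~0.3 log2 units at ≥ 5%
dilution versus 1.5–4 for the plug-ins), and calibration-curve LLOQ
(`04`).

## Command line

A thin CLI wraps the same pipeline:

```bash
rtimpute simulate --out-dir sim --n-runs 10 --n-peptides 50 --seed 1 --mzml
rtimpute impute   --blib sim/library.blib --out-dir imp --k 8
rtimpute quantify --blib imp/imputed.blib --mzml-dir sim/mzml --out-dir quant
rtimpute evaluate --quant quant/quant.tsv --groups-file groups.tsv --out-dir eval
rtimpute all      --out-dir run1 --n-runs 10 --n-peptides 50 --seed 1
```

Exit codes: 0 ok, 2 usage, 3 validation/config, 4 I/O. Every command
writes a `manifest.json` (inputs, resolved config, seed, version) next to
its outputs; identical config + seed gives byte-identical tables.

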