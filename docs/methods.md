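# Methods

## The problem

Label-free DIA proteomics experiments report peptide quantitations as a
matrix of precursors × MS runs, and that matrix is riddled with missing
values — typically 10–60% of cells — mostly because low-abundance peptides
fail to be detected by the library search (missing not at random, MNAR),
with a smaller completely-random component (MCAR). The conventional remedy,
plug-in imputation, replaces a missing quantitation with a statistical
estimate derived from the observed cells. This package implements the
alternative: impute the *retention-time boundaries* of the missing
chromatographic peak from the runs that did observe it, then integrate the
extracted ion chromatogram (XIC) inside the imputed window. The filled-in
value is a measurement of the raw signal in the target run, not an estimate
borrowed from other cells.

## Boundary imputation

The RT-boundary matrix has one row per precursor (modified sequence +
charge) and one column per run; each cell is a (start, end) pair in
minutes, or missing. Preprocessing replaces the pooled highest and lowest
1% of boundary values with missing (both members of any touched pair),
since extreme retention times predominantly belong to contaminants eluting
in the wash phases. The trim is rank-based with floor counts over one
global pool of starts and ends; a per-run variant is available as a config
switch (`TrimConfig.per_run`) because the pooling scope is a genuine design
choice — global pooling matches the contaminant rationale and is the
default.

Imputation is distance-weighted k-nearest-neighbours with runs as samples:
the working table has one row per run and two feature columns (start, end)
per precursor. Distance between runs is the shared-coordinate Euclidean
distance rescaled by `total_features / n_shared`, the standard convention
for incomplete vectors. Each missing entry takes the inverse-distance
weighted mean of the `k = 8` nearest runs observing that feature (fewer if
fewer exist); if any selected donor lies at distance zero, only
zero-distance donors contribute, uniformly, because 1/d is undefined there.
Distance ties break by run column order so results are exactly
reproducible. Starts and ends are imputed as independent features — the
layout the boundary CSV implies — and a canonicalization pass swaps the
rare inverted windows afterwards; joint (start, end) imputation would
guarantee ordering by construction but ties the two edges' donor sets
together, and the observed inversion rate is near zero in practice. No RT
alignment is performed: with runs as samples, the nearest-neighbour search
itself selects donors with similar chromatographic behaviour.

Cells whose feature no donor observes remain missing and are reported. The
imputer never modifies observed entries.

## Quantitation

For each transition (precursor m/z → product m/z), the XIC collects one
point per MS2 spectrum whose isolation window contains the precursor m/z;
the point's intensity is the sum of peak intensities within ±20 ppm
(default) of the product m/z, zero when no peak matches. Integration over a
boundary pair is trapezoidal with linear interpolation at the exact window
edges. Background is a horizontal baseline at the lower of the two edge
intensities spanning the window, and the net area is clamped at zero — a
simple, monotone rule that yields very low (not negative, not zero-width)
quantitations for windows that contain no peak. A peptide's abundance is
the sum of its transitions' net areas, in intensity·minutes. Optional
normalization scales each run by `2^(reference − median)` of its log2
positive values, with the reference the mean of per-run medians, so all
run medians agree afterwards (dilution series are never normalized — it
would erase the ratiometric structure they exist to provide).

## Plug-in baselines

Three standard plug-in imputers operate directly on the quant matrix, for
benchmarking:

* **low value** — each missing cell receives its peptide's minimum observed
  value anywhere in the experiment (the variant benchmarked here; the
  Gaussian low-value draw used elsewhere in the literature is deliberately
  not implemented);
* **kNN on quants** — runs as samples; distances on log2 abundances (the
  scale on which intensities are comparable), imputed value the unweighted
  raw-scale mean of the peptide in the k nearest observing runs;
* **MissForest-style** — iterative random-forest regression per run
  (scikit-learn forests, 100 trees), runs visited in increasing-missingness
  order, stopping when the relative change of the imputed values rises and
  returning the previous sweep. Fits operate on the raw scale; the
  algorithm is invariant to monotone feature transforms and the low
  dynamic range within rows makes a log transform immaterial here.

## Evaluation procedures

* **Dilution-series (MMCC) deviation** — with dilution fraction d, the
  expected log2 ratio of any peptide versus the mean undiluted reference is
  log2(d). Per level we report the median observed ratio, IQR, and median
  absolute deviation from expectation; peptides without reference values
  are skipped and counted.
* **Hold-out MSE** — exactly ⌊0.2·n⌋ observed boundary pairs are masked
  uniformly at random (seeded); methods rebuild them and are scored by mean
  squared error on log2(x+1) (tolerant of zeros and matched to intensity
  dynamics; the scale is a declared choice).
* **Differential abundance** — Welch two-sample t-tests on log2 abundances
  (equal-variance variant behind a flag), Benjamini–Hochberg adjustment,
  calls at |log2 FC| > 1 and q < 0.01. Peptides with fewer than two
  observed values in either group are reported as unscorable rather than
  silently dropped.
* **Calibration curves** — a bilinear model: grid-search the turning point
  over observed concentrations, noise plateau (mean) below, least-squares
  line above, minimizing total SSE with ties resolved to the larger
  (conservative) turning point. LOD is the smallest concentration whose
  fitted response exceeds noise mean + 2·SD. LLOQ bootstraps each level's
  replicates (100 resamples), takes CV = SD/mean of the resampled means,
  and returns the smallest concentration at/above the turning point whose
  CV and all higher levels' CVs are below 20% — "not quantifiable"
  (`inf`) when none qualifies or the slope is not positive; when both are
  defined the LLOQ is floored at the LOD.

## The synthetic-data generator

Every benchmark runs on simulated experiments with known truth. The
generator emulates: Gaussian elution peaks (σ ~ U(0.05, 0.15) min) at
uniform positions in a 5–95 min gradient; a per-run affine time warp
(slope ~ N(1, 0.01), offset ~ N(0, 0.1 min)) plus per-cell apex jitter
(N(0, 0.02 min)) standing in for un-aligned LC drift; true boundaries at
apex ± 2σ; log-normal peptide abundances (log2 ~ N(20, 2)) scaled by a
per-run effect (log2 SD 0.2, i.e. ±15% loading/spray variation), a
dilution fraction in calibration mode, and mean-one log-normal measurement
noise at 10% CV. Outside dilution mode a per-(peptide, run) biological
variability term (log2 SD 0.5, ≈40% between-sample CV — typical for
tissue or plasma cohorts) separates the runs; dilution-series runs are
technical replicates of one mixed sample, so it is switched off there.
Transitions (3 per peptide) share boundaries and split the abundance by
fixed Dirichlet ratios; product m/z values are kept ≥ 0.06 apart so
synthetic transitions never cross-talk at 20 ppm. A constant-level gamma
baseline (1000 counts, ≈0.025% of a median peak apex) puts the dimmest
peptides near the detection limit, so "rescued" quantitations of truly
absent signal integrate to small but nonzero areas.

Detection follows the MNAR + MCAR mixture: a cell is missing with
probability `logistic((τ − log2 A)/s)` (τ = 19, s = 1 — about 35–40%
overall missingness, matching typical DIA cohorts) plus an independent 5%
MCAR dropout. The library matrix contains boundaries only at detected
cells.

Spectra are sampled on a DIA cycle: 4 isolation windows of 75 m/z covering
400–1000 m/z at 0.5 s dwell each, i.e. a 2 s revisit per window, giving
1.5–4.5 points per peak σ — the thin end of realistic DIA sampling. Runs
stay in memory by default (chromatograms synthesized on demand,
deterministically per seed); `to_mzml` writes real mzML 1.1 files for
end-to-end tests of the file-based path.

What the generator does **not** emulate: fragment interference and
chimeric spectra, ion mobility, peak shape asymmetry (tailing), nonlinear
RT warps, and detector saturation. Passing benchmarks on this generator
therefore demonstrate the correctness and relative behaviour of the
methods under idealized chromatography, not their absolute performance on
real data.

## Benchmark findings and known limitations

At the benchmark scale used in the acceptance suite (30–48 runs, 40–200
peptides; sizes chosen to keep each benchmark in seconds-to-minutes on one
CPU), boundary imputation recovers masked boundary pairs with a median
absolute error of ≈0.05 min and its re-integrated quantitations correlate
with truth at r ≈ 0.94; its dilution-series ratios are 3–10× closer to
log2(d) than low-value or kNN-on-quants imputation at every level ≥ 5%,
and rescued quantitations are left-skewed relative to observed ones, as
MNAR missingness predicts.

Two limitations surface consistently and are worth knowing about:

1. **Squared-error sensitivity to window misses.** Under the default
   affine warp, the ~5% of cells that combine a late-gradient elution, a
   warp-outlier run and a narrow peak receive windows that miss the peak
   entirely; each such cell contributes an (8–15 log2)² error, and the
   *mean* squared hold-out error of boundary imputation is therefore
   dominated by this tail and can exceed the plug-in baselines even while
   its median per-cell error is far smaller. Median-based summaries (or
   real chromatography with better RT reproducibility than the simulated
   1% slope SD over 90 min) favour boundary imputation.
2. **Donor scarcity under MNAR.** A peptide observed in only a handful of
   runs draws donors from whatever runs observed it, however dissimilar;
   with k = 8 and few candidates the imputed window degrades toward a
   population average. More runs, not more peptides, is what improves
   boundary imputation.
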