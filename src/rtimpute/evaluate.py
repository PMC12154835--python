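"""Evaluation procedures for imputation benchmarking.

Four quantitative lenses on imputed data:

* **Matrix-matched calibration curve (MMCC) deviation** — in a serial
  dilution of human sample into a matched non-human background, the expected
  abundance ratio of every peptide between a diluted and the undiluted run
  is known: ``log2(A / A_100) = log2(d)`` for dilution fraction d. The
  deviation of observed log ratios from that line measures quantitative
  accuracy (:func:`mmcc_deviation`).
* **Hold-out MSE** — boundary pairs removed from the library are imputed and
  re-quantified; the mean squared error against the originally observed
  quantitations, on the log2(x+1) scale, scores the reconstruction
  (:func:`holdout_mse`).
* **Differential abundance** — Welch two-sample t-tests on log2 abundances
  with Benjamini-Hochberg correction; a peptide is called at
  |log2 fold change| > 1 and q < 0.01 (:func:`differential_abundance`).
* **Calibration-curve LLOQ** — a bilinear (noise plateau + line) fit locates
  the turning point; the limit of detection comes from the noise standard
  deviation and the lower limit of quantification from bootstrap
  coefficients of variation (:func:`fit_calibration_curve`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError
from .impute import HoldoutMask
from .matrices import PrecursorKey, QuantMatrix

__all__ = [
    "DilutionDesign",
    "DAResult",
    "CalibrationFit",
    "expected_log_ratio",
    "mmcc_deviation",
    "holdout_mse",
    "bh_adjust",
    "differential_abundance",
    "fit_calibration_curve",
]

logger = logging.getLogger(__name__)

NOT_QUANTIFIABLE = float("inf")


@dataclass(frozen=True)
class DilutionDesign:
    """Map run -> dilution fraction in (0, 1]; runs at 1.0 are the undiluted
    reference against which all ratios are formed."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        for run, d in self.fractions.items():
            if not (0.0 < d <= 1.0):
                raise DesignError(f"dilution fraction for {run!r} must be in (0,1], got {d}")
        if not self.reference_runs:
            raise DesignError("design has no undiluted (d = 1) reference run")

    @property
    def reference_runs(self) -> list[str]:
        return [r for r, d in self.fractions.items() if d == 1.0]

    @property
    def levels(self) -> list[float]:
        return sorted({d for d in self.fractions.values() if d < 1.0})


@dataclass
class DAResult:
    """Per-precursor differential-abundance table plus the precursors that
    could not be scored for lack of group coverage."""

    table: pd.DataFrame  # columns: log2_fc, p_value, q_value, call
    unscorable: list[PrecursorKey] = field(default_factory=list)

    def n_called(self, direction: str) -> int:
        return int((self.table["call"] == direction).sum())


@dataclass(frozen=True)
class CalibrationFit:
    """Bilinear calibration fit: noise plateau below the turning point, a
    straight line above it. ``lloq`` is ``inf`` when not quantifiable."""

    turning_point: float
    slope: float
    intercept: float
    noise_mean: float
    noise_sd: float
    lod: float
    lloq: float

    @property
    def quantifiable(self) -> bool:
        return math.isfinite(self.lloq)


def expected_log_ratio(d: float) -> float:
    """Expected log2 abundance ratio of a run at dilution fraction d versus
    the undiluted reference: log2(d)."""
    if not (0.0 < d <= 1.0):
        raise ValueError(f"dilution fraction must be in (0, 1], got {d}")
    return math.log2(d)


def mmcc_deviation(q: QuantMatrix, design: DilutionDesign) -> pd.DataFrame:
    """Per-dilution summary of observed vs expected log ratios.

    For each peptide and non-reference run, the observed ratio is
    ``log2(abundance / mean reference abundance)``. Per dilution level the
    summary reports the median observed ratio, the interquartile range, the
    median absolute deviation from ``log2(d)``, and how many peptides were
    skipped for missing reference values.
    """
    runs = q.runs
    unknown = [r for r in runs if r not in design.fractions]
    if unknown:
        raise DesignError(f"runs without dilution fractions: {unknown}")
    ref_runs = [r for r in design.reference_runs if r in runs]
    if not ref_runs:
        raise DesignError("no reference run present in the quant matrix")
    vals = q.values
    ref_mean = vals[ref_runs].mean(axis=1, skipna=True)
    rows = []
    for level in design.levels:
        level_runs = [r for r in runs if design.fractions[r] == level]
        expected = expected_log_ratio(level)
        ratios = []
        n_skipped = 0
        for r in level_runs:
            for pep in vals.index:
                a = vals.at[pep, r]
                ref = ref_mean[pep]
                if pd.isna(ref) or ref <= 0:
                    n_skipped += 1
                    continue
                if pd.isna(a) or a <= 0:
                    continue
                ratios.append(math.log2(a / ref))
        ratios = np.asarray(ratios)
        if ratios.size:
            q1, q3 = np.percentile(ratios, [25, 75])
            rows.append(
                {
                    "dilution": level,
                    "expected_log_ratio": expected,
                    "median_log_ratio": float(np.median(ratios)),
                    "iqr": float(q3 - q1),
                    "median_abs_deviation": float(np.median(np.abs(ratios - expected))),
                    "n_ratios": int(ratios.size),
                    "n_skipped_no_reference": n_skipped,
                }
            )
        else:
            rows.append(
                {
                    "dilution": level,
                    "expected_log_ratio": expected,
                    "median_log_ratio": np.nan,
                    "iqr": np.nan,
                    "median_abs_deviation": np.nan,
                    "n_ratios": 0,
                    "n_skipped_no_reference": n_skipped,
                }
            )
    return pd.DataFrame(rows).set_index("dilution")


def holdout_mse(
    truth: QuantMatrix, imputed: QuantMatrix, mask: HoldoutMask
) -> tuple[float, int]:
    """Mean squared error over held-out cells, on the log2(x+1) scale.

    Returns (mse, number of scored cells); masked cells that are still
    missing after imputation are excluded from the mean and logged.
    """
    if len(mask) == 0:
        raise ValueError("hold-out mask is empty")
    errs = []
    n_unscored = 0
    for pep, run in mask.cells:
        t = truth.values.at[tuple(pep), run]
        v = imputed.values.at[tuple(pep), run]
        if pd.isna(t) or pd.isna(v):
            n_unscored += 1
            continue
        errs.append((math.log2(t + 1.0) - math.log2(v + 1.0)) ** 2)
    if n_unscored:
        logger.warning("%d masked cells had no scored value", n_unscored)
    if not errs:
        raise ValueError("no masked cell could be scored")
    return float(np.mean(errs)), len(errs)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def differential_abundance(
    q: QuantMatrix,
    groups: Mapping[str, str],
    fc_threshold: float = 1.0,
    q_threshold: float = 0.01,
    equal_var: bool = False,
) -> DAResult:
    """Two-group differential abundance on log2 quantitations.

    Per peptide: ``log2_fc`` is the mean log2 abundance in group A minus
    group B, the p-value comes from a two-sample t-test (Welch by default)
    on log2 values, and q-values from BH adjustment across scored peptides.
    A peptide is called up when ``log2_fc > fc_threshold`` and
    ``q < q_threshold``, down for the mirror image. Peptides with fewer than
    two observed values in either group are reported as unscorable.
    """
    labels = set(groups.values())
    if labels != {"A", "B"}:
        raise DesignError(f"groups must be labelled A and B, got {sorted(labels)}")
    a_runs = [r for r in q.runs if groups.get(r) == "A"]
    b_runs = [r for r in q.runs if groups.get(r) == "B"]
    if len(a_runs) < 2 or len(b_runs) < 2:
        raise DesignError("each group needs at least 2 runs")
    records = []
    unscorable = []
    for pep in q.values.index:
        a = q.values.loc[pep, a_runs].dropna().to_numpy(dtype=float)
        b = q.values.loc[pep, b_runs].dropna().to_numpy(dtype=float)
        a, b = a[a > 0], b[b > 0]
        if a.size < 2 or b.size < 2:
            unscorable.append(PrecursorKey(*pep))
            continue
        la, lb = np.log2(a), np.log2(b)
        fc = float(la.mean() - lb.mean())
        pval = float(stats.ttest_ind(la, lb, equal_var=equal_var).pvalue)
        if not np.isfinite(pval):  # zero variance in both groups, identical means
            pval = 1.0
        records.append({"precursor": pep, "log2_fc": fc, "p_value": pval})
    table = pd.DataFrame(records)
    if not table.empty:
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        calls = np.where(
            (table["log2_fc"] > fc_threshold) & (table["q_value"] < q_threshold),
            "up",
            np.where(
                (table["log2_fc"] < -fc_threshold) & (table["q_value"] < q_threshold),
                "down",
                "none",
            ),
        )
        table["call"] = calls
        table.index = pd.MultiIndex.from_tuples(
            table.pop("precursor"), names=["sequence", "charge"]
        )
    return DAResult(table=table, unscorable=unscorable)


def fit_calibration_curve(
    concentrations: Sequence[float],
    responses: Sequence[float],
    bootstrap_n: int = 100,
    cv_threshold: float = 0.2,
    seed: int = 0,
) -> CalibrationFit:
    """Bilinear calibration fit with bootstrap LLOQ.

    The turning point c* is grid-searched over the observed concentrations:
    responses at concentrations <= c* are modelled by their mean (the noise
    plateau) and those >= c* by a least-squares line, minimizing the total
    SSE; ties prefer the larger (more conservative) c*. The LOD is the
    smallest concentration whose fitted response exceeds
    ``noise mean + 2 * noise sd``. For the LLOQ, the replicates of each
    concentration are resampled with replacement ``bootstrap_n`` times; the
    CV is the SD over the resampled means divided by their mean, and the
    LLOQ is the smallest concentration at/above the turning point whose CV
    and all higher concentrations' CVs fall below ``cv_threshold`` — or
    ``inf`` ("not quantifiable") when no concentration qualifies or the
    fitted slope is not positive.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must align")
    if np.any(resp < 0):
        raise ValueError("responses must be >= 0")
    levels = np.unique(conc)
    if levels.size < 4:
        raise DesignError(f"need >= 4 distinct concentrations, got {levels.size}")

    best: tuple[float, float, float, float] | None = None  # sse, c*, slope, intercept
    for c_star in levels:
        linear = conc >= c_star
        if np.unique(conc[linear]).size < 2:
            continue
        noise = conc <= c_star
        noise_mean = float(resp[noise].mean())
        sse = float(np.sum((resp[noise] - noise_mean) ** 2))
        slope, intercept = np.polyfit(conc[linear], resp[linear], 1)
        sse += float(np.sum((resp[linear] - (slope * conc[linear] + intercept)) ** 2))
        if best is None or sse <= best[0] + 1e-12:
            best = (sse, float(c_star), float(slope), float(intercept))
    if best is None:  # cannot happen with >= 4 levels, kept for safety
        raise DesignError("no admissible turning point")
    _, turning_point, slope, intercept = best
    noise_resp = resp[conc <= turning_point]
    noise_mean = float(noise_resp.mean())
    noise_sd = float(noise_resp.std(ddof=1)) if noise_resp.size > 1 else 0.0

    fitted = np.where(
        levels > turning_point, slope * levels + intercept, noise_mean
    )
    above = levels[fitted > noise_mean + 2.0 * noise_sd]
    lod = float(above.min()) if above.size else NOT_QUANTIFIABLE

    if slope <= 0:
        return CalibrationFit(
            turning_point, slope, intercept, noise_mean, noise_sd, lod, NOT_QUANTIFIABLE
        )
    rng = np.random.default_rng(seed)
    cvs = {}
    for level in levels:
        reps = resp[conc == level]
        means = np.array(
            [rng.choice(reps, size=reps.size, replace=True).mean() for _ in range(bootstrap_n)]
        )
        mu = means.mean()
        cvs[level] = float(means.std(ddof=1) / mu) if mu > 0 else NOT_QUANTIFIABLE

    lloq = NOT_QUANTIFIABLE
    candidates = levels[levels >= turning_point]
    for level in sorted(candidates, reverse=True):
        if cvs[level] < cv_threshold:
            lloq = float(level)
        else:
            break
    if math.isfinite(lloq) and math.isfinite(lod):
        lloq = max(lloq, lod)  # cannot quantify below detection
    return CalibrationFit(
        turning_point, slope, intercept, noise_mean, noise_sd, lod, lloq
    )
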