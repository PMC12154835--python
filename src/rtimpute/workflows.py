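"""End-to-end pipelines composed from the library primitives.

These functions wire together the steps a user would otherwise chain by
hand — trim, impute boundaries, re-integrate chromatograms, benchmark
against plug-in imputation — and are what the command-line interface, the
examples and the acceptance script call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chrom import quantify_peptides
from .evaluate import (
    CalibrationFit,
    DilutionDesign,
    fit_calibration_curve,
    holdout_mse,
    mmcc_deviation,
)
from .impute import (
    HoldoutMask,
    ImputeConfig,
    ImputeResult,
    knn_impute_quants,
    knn_impute_rt,
    low_value_impute,
    mask_boundary_pairs,
    missforest_impute,
)
from .matrices import (
    PROV_BOUNDARY,
    PROV_OBSERVED,
    QuantMatrix,
    RTBoundaryMatrix,
    TrimConfig,
    trim_extreme_rts,
)
from .simulate import SimExperiment

__all__ = [
    "impute_boundaries",
    "HoldoutResult",
    "holdout_experiment",
    "mmcc_comparison",
    "CalibrationComparison",
    "calibration_comparison",
    "imputed_vs_observed_medians",
]


def impute_boundaries(
    library: RTBoundaryMatrix,
    trim: TrimConfig = TrimConfig(),
    impute: ImputeConfig = ImputeConfig(),
) -> ImputeResult:
    """The standard preprocessing chain: trim extreme retention times, then
    kNN-impute the missing boundary pairs."""
    trimmed = trim_extreme_rts(library, trim)
    return knn_impute_rt(trimmed, impute)


@dataclass
class HoldoutResult:
    """Hold-out benchmark outcome: per-method MSE on the masked cells
    (log2(x+1) scale) plus the matrices behind them."""

    mask: HoldoutMask
    mse: dict[str, float]
    n_scored: dict[str, int]
    reference: QuantMatrix
    quants: dict[str, QuantMatrix] = field(default_factory=dict)
    boundary_result: ImputeResult | None = None


def holdout_experiment(
    exp: SimExperiment,
    fraction: float = 0.2,
    seed: int = 0,
    impute_cfg: ImputeConfig = ImputeConfig(),
    ppm_tol: float = 20.0,
    include_missforest: bool = False,
) -> HoldoutResult:
    """Mask observed boundary pairs, rebuild them with every method, score.

    The reference values are the quantitations obtained at the original
    (library) boundaries — actual measurements, available because masking
    only hides cells that were observed. Boundary imputation refills the
    masked cells with integrated signal at imputed boundaries; plug-in
    methods refill them from the masked quant matrix.
    """
    reference = quantify_peptides(exp.runs, exp.transitions, exp.library, ppm_tol)
    masked_lib, mask = mask_boundary_pairs(exp.library, fraction, seed)

    result = knn_impute_rt(masked_lib, impute_cfg)
    q_boundary = quantify_peptides(exp.runs, exp.transitions, result.matrix, ppm_tol)

    q_obs = quantify_peptides(exp.runs, exp.transitions, masked_lib, ppm_tol)
    k_quants = min(impute_cfg.k, len(exp.library.runs) - 1)
    candidates = {
        "rt_boundary": q_boundary,
        "low_value": low_value_impute(q_obs),
        "knn_quants": knn_impute_quants(q_obs, k=k_quants),
    }
    if include_missforest:
        candidates["missforest"] = missforest_impute(q_obs, seed=seed)
    mse, n_scored = {}, {}
    for name, q in candidates.items():
        mse[name], n_scored[name] = holdout_mse(reference, q, mask)
    return HoldoutResult(
        mask=mask,
        mse=mse,
        n_scored=n_scored,
        reference=reference,
        quants=candidates,
        boundary_result=result,
    )


def mmcc_comparison(
    exp: SimExperiment,
    impute_cfg: ImputeConfig = ImputeConfig(),
    ppm_tol: float = 20.0,
) -> dict[str, pd.DataFrame]:
    """Per-method MMCC deviation tables for a dilution-series experiment.

    Requires the experiment to carry a dilution design. No normalization is
    applied: a dilution series must keep its ratiometric structure.
    """
    if exp.config.dilutions is None:
        raise ValueError("experiment has no dilution design")
    design = DilutionDesign(dict(exp.config.dilutions))
    q_obs = quantify_peptides(exp.runs, exp.transitions, exp.library, ppm_tol)
    result = knn_impute_rt(exp.library, impute_cfg)
    q_boundary = quantify_peptides(exp.runs, exp.transitions, result.matrix, ppm_tol)
    k = min(impute_cfg.k, len(exp.library.runs) - 1)
    return {
        "rt_boundary": mmcc_deviation(q_boundary, design),
        "low_value": mmcc_deviation(low_value_impute(q_obs), design),
        "knn_quants": mmcc_deviation(knn_impute_quants(q_obs, k=k), design),
    }


@dataclass
class CalibrationComparison:
    """LLOQ per peptide with library boundaries alone vs after boundary
    imputation, restricted comparison over the peptides whose low-dilution
    points were rescued by imputation."""

    per_peptide: pd.DataFrame  # columns: lloq_library, lloq_boundary, affected
    fits_library: dict[tuple, CalibrationFit]
    fits_boundary: dict[tuple, CalibrationFit]

    @property
    def affected(self) -> pd.DataFrame:
        return self.per_peptide[self.per_peptide["affected"]]

    def fraction_reduced_or_equal(self) -> float:
        aff = self.affected
        if aff.empty:
            return float("nan")
        return float((aff["lloq_boundary"] <= aff["lloq_library"]).mean())


def calibration_comparison(
    exp: SimExperiment,
    impute_cfg: ImputeConfig = ImputeConfig(),
    ppm_tol: float = 20.0,
    bootstrap_n: int = 100,
    seed: int = 0,
) -> CalibrationComparison:
    """Fit per-peptide calibration curves before and after boundary
    imputation and compare the resulting LLOQs.

    Concentrations are the dilution fractions; responses are the peptide
    quantitations of the corresponding runs. With library search alone, a
    peptide missing in a run simply has no point there; after boundary
    imputation the rescued cells contribute measured (integrated) points. A
    peptide is "affected" when imputation extended its curve downward, i.e.
    added a point below the lowest library-observed concentration. A curve
    with fewer than four observed concentration levels is not quantifiable.
    """
    if exp.config.dilutions is None:
        raise ValueError("experiment has no dilution design")
    fractions = dict(exp.config.dilutions)
    q_obs = quantify_peptides(exp.runs, exp.transitions, exp.library, ppm_tol)
    result = knn_impute_rt(exp.library, impute_cfg)
    q_boundary = quantify_peptides(exp.runs, exp.transitions, result.matrix, ppm_tol)

    def _fit(q: QuantMatrix, pep) -> CalibrationFit | None:
        conc, resp = [], []
        for run in q.runs:
            v = q.values.at[pep, run]
            if pd.isna(v):
                continue
            conc.append(fractions[run])
            resp.append(float(v))
        if len(set(conc)) < 4:
            return None
        return fit_calibration_curve(
            conc, resp, bootstrap_n=bootstrap_n, seed=seed
        )

    rows = []
    fits_lib, fits_bnd = {}, {}
    for pep in q_obs.values.index:
        f_lib = _fit(q_obs, pep)
        f_bnd = _fit(q_boundary, pep)
        fits_lib[pep], fits_bnd[pep] = f_lib, f_bnd
        prov_row = q_boundary.provenance.loc[pep]
        rescued_levels = [
            fractions[run]
            for run in q_boundary.runs
            if prov_row[run] == PROV_BOUNDARY
        ]
        observed_levels = [
            fractions[run]
            for run in q_obs.runs
            if not pd.isna(q_obs.values.at[pep, run])
        ]
        # "affected" = the curve was extended downward: at least one rescued
        # point below the lowest concentration the library search observed
        lowest_obs = min(observed_levels) if observed_levels else float("inf")
        affected = any(d < lowest_obs for d in rescued_levels)
        rows.append(
            {
                "sequence": pep[0],
                "charge": pep[1],
                "lloq_library": f_lib.lloq if f_lib else float("inf"),
                "lloq_boundary": f_bnd.lloq if f_bnd else float("inf"),
                "n_rescued": len(rescued_levels),
                "affected": affected,
            }
        )
    table = pd.DataFrame(rows).set_index(["sequence", "charge"])
    return CalibrationComparison(table, fits_lib, fits_bnd)


def imputed_vs_observed_medians(q: QuantMatrix) -> tuple[float, float]:
    """Medians of boundary-imputed and observed quantitations.

    Under intensity-dependent (MNAR) missingness, cells rescued by boundary
    imputation are drawn from the low-abundance end, so the imputed median
    should sit below the observed one.
    """
    prov = q.provenance.to_numpy()
    vals = q.values.to_numpy()
    imputed = vals[(prov == PROV_BOUNDARY) & ~np.isnan(vals)]
    observed = vals[(prov == PROV_OBSERVED) & ~np.isnan(vals)]
    if imputed.size == 0 or observed.size == 0:
        raise ValueError("need both observed and boundary-imputed cells")
    return float(np.median(imputed)), float(np.median(observed))
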