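"""Chromatogram extraction and peak integration.

Given DIA MS2 spectra, an extracted ion chromatogram (XIC) for a transition
is built by summing, in every spectrum whose precursor isolation window
contains the transition's precursor m/z, the peak intensities within a ppm
window around the product m/z. Integrating the XIC between a pair of
retention-time boundaries — observed or imputed — yields a peak area; the
peptide abundance is the background-subtracted area summed over all of the
peptide's transitions.

Background subtraction uses a horizontal baseline at the lower of the two
boundary-edge intensities, and the net area is clamped at zero; a window
containing no peak therefore integrates to a very small value rather than a
large negative one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrices import PrecursorKey, QuantMatrix, RTBoundaryMatrix

__all__ = [
    "Transition",
    "TransitionTable",
    "Chromatogram",
    "PeakArea",
    "Spectrum",
    "extract_xic",
    "integrate_peak",
    "quantify_peptides",
    "equalize_medians",
    "DEFAULT_PPM_TOL",
    "DEFAULT_ISOLATION_HALF_WIDTH",
]

logger = logging.getLogger(__name__)

DEFAULT_PPM_TOL = 20.0
# Fallback isolation half-width (m/z) when a spectrum declares a target but
# no window offsets.
DEFAULT_ISOLATION_HALF_WIDTH = 12.0


@dataclass(frozen=True)
class Transition:
    """A precursor -> product m/z pair tracing one peptide fragment."""

    precursor: PrecursorKey
    precursor_mz: float
    product_mz: float
    label: str = ""

    def __post_init__(self) -> None:
        for name, v in (("precursor_mz", self.precursor_mz), ("product_mz", self.product_mz)):
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v}")


class TransitionTable:
    """Transitions grouped by precursor; every precursor has >= 1 transition
    and (precursor, product m/z) is unique."""

    def __init__(self, transitions: Iterable[Transition]) -> None:
        self._by_precursor: dict[PrecursorKey, list[Transition]] = {}
        seen: set[tuple[PrecursorKey, float]] = set()
        for t in transitions:
            key = (t.precursor, t.product_mz)
            if key in seen:
                raise ValidationError(
                    f"duplicate transition {t.precursor} -> {t.product_mz}"
                )
            seen.add(key)
            self._by_precursor.setdefault(t.precursor, []).append(t)
        if not all(self._by_precursor.values()):
            raise ValidationError("every precursor needs at least one transition")

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_precursor.values())

    def __iter__(self):
        for ts in self._by_precursor.values():
            yield from ts

    @property
    def precursors(self) -> list[PrecursorKey]:
        return list(self._by_precursor)

    def transitions_for(self, precursor: PrecursorKey) -> list[Transition]:
        if precursor not in self._by_precursor:
            raise ValidationError(f"no transitions for precursor {precursor}")
        return list(self._by_precursor[precursor])

    def __contains__(self, precursor: PrecursorKey) -> bool:
        return precursor in self._by_precursor


@dataclass(frozen=True)
class Chromatogram:
    """An intensity-vs-time trace: strictly increasing times (minutes) and
    nonnegative intensities of equal length."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if t.shape != i.shape or t.ndim != 1:
            raise ValidationError("times and intensities must be equal-length 1-D")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if i.size and (not np.all(np.isfinite(i)) or i.min() < 0):
            raise ValidationError("intensities must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", i)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PeakArea:
    """Integration result in intensity-minutes: the raw trapezoidal area,
    the subtracted background, and the clamped net area."""

    raw_area: float
    background: float
    net_area: float


@dataclass(frozen=True)
class Spectrum:
    """One centroided MS spectrum: scan time (minutes), MS level, the
    precursor isolation window (MS2 only) and the peak arrays."""

    time_min: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    isolation_lower: float | None = None
    isolation_upper: float | None = None
    isolation_target: float | None = None

    def selects(self, precursor_mz: float) -> bool:
        if self.isolation_lower is not None and self.isolation_upper is not None:
            return self.isolation_lower <= precursor_mz <= self.isolation_upper
        if self.isolation_target is not None:
            half = DEFAULT_ISOLATION_HALF_WIDTH
            return abs(precursor_mz - self.isolation_target) <= half
        return False


class RunSource(Protocol):
    """Anything that can produce an XIC for a transition: an mzML-backed run
    or an in-memory simulated run."""

    def xic(self, transition: Transition, ppm_tol: float) -> Chromatogram: ...


def extract_xic(
    spectra: Iterable[Spectrum],
    transition: Transition,
    ppm_tol: float = DEFAULT_PPM_TOL,
    ms_level: int = 2,
) -> Chromatogram:
    """Build the XIC of a transition from a stream of spectra.

    Each spectrum of the requested MS level whose isolation window contains
    the transition's precursor m/z contributes one point; the intensity is
    the sum of peaks within ``product_mz * (1 +/- ppm_tol * 1e-6)``. Spectra
    selecting the precursor but containing no matching peak contribute zero,
    so the trace keeps its full time axis. A transition matched by several
    overlapping windows uses all matching spectra, merged on the time axis.
    """
    lo = transition.product_mz * (1.0 - ppm_tol * 1e-6)
    hi = transition.product_mz * (1.0 + ppm_tol * 1e-6)
    times: list[float] = []
    intens: list[float] = []
    for sp in spectra:
        if sp.ms_level != ms_level:
            continue
        if ms_level >= 2 and not sp.selects(transition.precursor_mz):
            continue
        mz = sp.mz
        j0, j1 = np.searchsorted(mz, (lo, hi))
        times.append(sp.time_min)
        intens.append(float(sp.intensity[j0:j1].sum()) if j1 > j0 else 0.0)
    if not times:
        logger.warning(
            "no spectra select precursor m/z %.4f; empty chromatogram",
            transition.precursor_mz,
        )
        return Chromatogram(np.array([]), np.array([]))
    order = np.argsort(times, kind="stable")
    t = np.asarray(times)[order]
    i = np.asarray(intens)[order]
    # overlapping windows can sample the same instant twice; keep the sum
    if t.size > 1 and np.any(np.diff(t) == 0):
        uniq, inv = np.unique(t, return_inverse=True)
        merged = np.zeros_like(uniq)
        np.add.at(merged, inv, i)
        t, i = uniq, merged
    return Chromatogram(t, i)


def integrate_peak(c: Chromatogram, start: float, end: float) -> PeakArea:
    """Trapezoidal integration of a chromatogram over [start, end].

    Intensities at the exact boundary times come from linear interpolation.
    The background is a horizontal baseline at ``min(I(start), I(end))``
    spanning the window; the net area is ``max(raw - background, 0)``. An
    empty chromatogram, or a window that misses its span entirely, yields
    all zeros.
    """
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    t, y = c.times, c.intensities
    if t.size == 0 or end <= t[0] or start >= t[-1]:
        return PeakArea(0.0, 0.0, 0.0)
    a, b = max(start, t[0]), min(end, t[-1])
    ia = float(np.interp(a, t, y))
    ib = float(np.interp(b, t, y))
    inner = (t > a) & (t < b)
    tt = np.concatenate([[a], t[inner], [b]])
    yy = np.concatenate([[ia], y[inner], [ib]])
    raw = float(np.trapezoid(yy, tt))
    background = min(ia, ib) * (b - a)
    net = max(raw - background, 0.0)
    return PeakArea(raw, background, net)


def quantify_peptides(
    runs: Mapping[str, RunSource],
    tt: TransitionTable,
    boundaries: RTBoundaryMatrix,
    ppm_tol: float = DEFAULT_PPM_TOL,
) -> QuantMatrix:
    """Integrate every peptide in every run within its RT boundaries.

    The abundance of peptide p in run r is the sum, over p's transitions, of
    the background-subtracted XIC area within the boundary pair of cell
    (p, r); a missing boundary yields a missing quantitation. The provenance
    flag of the boundary cell (observed vs imputed vs masked) is carried
    over onto the quant cell so downstream analysis can tell measured
    detections from boundary-rescued ones.
    """
    for p in boundaries.precursors:
        if p not in tt:
            raise ValidationError(f"boundary row {p} has no transitions")
    run_ids = boundaries.runs
    missing_runs = [r for r in run_ids if r not in runs]
    if missing_runs:
        raise ValidationError(f"no spectrum source for runs {missing_runs}")
    vals = np.full(boundaries.shape, np.nan)
    prov = boundaries.provenance.to_numpy().copy()
    precs = boundaries.precursors
    s = boundaries.starts.to_numpy()
    e = boundaries.ends.to_numpy()
    from .matrices import PROV_BOUNDARY, PROV_IMPUTED

    for cj, run in enumerate(run_ids):
        source = runs[run]
        for ri, p in enumerate(precs):
            if np.isnan(s[ri, cj]):
                continue
            total = 0.0
            for tr in tt.transitions_for(p):
                xic = source.xic(tr, ppm_tol)
                total += integrate_peak(xic, s[ri, cj], e[ri, cj]).net_area
            vals[ri, cj] = total
            if prov[ri, cj] == PROV_IMPUTED:
                prov[ri, cj] = PROV_BOUNDARY
    return QuantMatrix(
        pd.DataFrame(vals, index=boundaries.starts.index, columns=boundaries.starts.columns),
        pd.DataFrame(prov, index=boundaries.starts.index, columns=boundaries.starts.columns),
    )


def equalize_medians(q: QuantMatrix) -> QuantMatrix:
    """Scale each run so the medians of log2 abundances agree.

    The reference is the mean of per-run medians of log2 of the positive
    observed values; run r is multiplied by ``2**(reference - median_r)``.
    Every run must contain at least one positive observed value.
    """
    vals = q.values.to_numpy().copy()
    medians = []
    for c in range(vals.shape[1]):
        col = vals[:, c]
        pos = col[~np.isnan(col) & (col > 0)]
        if pos.size == 0:
            raise ValidationError(
                f"run {q.runs[c]!r} has no positive observed values"
            )
        medians.append(float(np.median(np.log2(pos))))
    reference = float(np.mean(medians))
    for c, m in enumerate(medians):
        vals[:, c] *= 2.0 ** (reference - m)
    return QuantMatrix(
        pd.DataFrame(vals, index=q.values.index, columns=q.values.columns),
        q.provenance.copy(),
    )
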