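"""Synthetic multi-run DIA experiments with known ground truth.

The simulator emulates the statistical structure of a DIA peptide
quantitation experiment well enough to exercise every other module without
any raw-data download:

* each peptide elutes as a Gaussian chromatographic peak at a random
  position in the gradient, with a peptide-specific width;
* each run applies a mild affine time warp (slope and offset) plus
  per-peptide apex jitter, mimicking un-aligned LC drift between runs;
* peptide abundances are log-normal, optionally scaled by a per-run
  dilution fraction (matrix-matched calibration mode) and a small run
  effect, with multiplicative measurement noise;
* transitions of a peptide share boundaries and split the abundance by
  fixed per-peptide ratios; a low additive baseline is always present;
* the "library search" observes a cell with a probability that decreases
  logistically with log2 abundance (missing not at random) on top of an
  independent completely-at-random dropout — low-abundance peptides are
  the ones most likely to be missing.

Runs can stay in memory (chromatograms synthesized on demand; the fast
path) or be written out as real mzML files sampled on a DIA isolation
window cycle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chrom import Chromatogram, Spectrum, Transition, TransitionTable
from .errors import ConfigError
from .matrices import PrecursorKey, QuantMatrix, RTBoundaryMatrix, key_index
from .mzml import write_mzml

__all__ = ["SimConfig", "SyntheticTruth", "SimulatedRun", "SimExperiment",
           "simulate_experiment", "apply_missingness", "mmcc_design"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
# global minimum spacing between product m/z values; > 2x the 20 ppm
# extraction window at m/z 1200, so synthetic transitions never cross-talk
_MIN_PRODUCT_SPACING = 0.06


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Times are minutes, m/z in Th. ``mnar_tau`` is the log2 abundance at
    which the detection probability crosses 50% and ``mnar_steepness`` the
    logistic scale; ``mnar_tau=None`` disables intensity-dependent
    missingness. ``dilutions`` maps run ids to dilution fractions for
    calibration-curve mode (runs default to 1.0, undiluted).

    ``biological_log2_sd`` is the per-(peptide, run) between-sample
    variability of biological experiments; in dilution mode the runs are
    technical replicates of the same mixed sample, so it is not applied and
    only the run effect, the dilution fraction and the measurement noise
    separate runs.
    """

    n_runs: int = 10
    n_peptides: int = 50
    transitions_per_peptide: int = 3
    gradient_window: tuple[float, float] = (5.0, 95.0)
    sigma_range: tuple[float, float] = (0.05, 0.15)
    warp_slope_sd: float = 0.01
    warp_offset_sd: float = 0.1
    apex_jitter_sd: float = 0.02
    log2_abundance_mean: float = 20.0
    log2_abundance_sd: float = 2.0
    run_effect_log2_sd: float = 0.2
    biological_log2_sd: float = 0.5
    noise_cv: float = 0.10
    baseline_level: float = 1000.0
    mnar_tau: float | None = 19.0
    mnar_steepness: float = 1.0
    mcar_rate: float = 0.05
    dilutions: Mapping[str, float] | None = None
    precursor_mz_range: tuple[float, float] = (400.0, 1000.0)
    product_mz_range: tuple[float, float] = (200.0, 1200.0)
    n_isolation_windows: int = 4
    dwell_time_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gradient_window
        if hi <= lo:
            raise ConfigError("gradient window must have positive length")
        if 4.0 * self.sigma_range[1] >= hi - lo:
            raise ConfigError("peaks are wider than the gradient window")
        for name in ("warp_slope_sd", "warp_offset_sd", "apex_jitter_sd",
                     "log2_abundance_sd", "run_effect_log2_sd",
                     "biological_log2_sd", "noise_cv", "baseline_level"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.mcar_rate <= 1.0):
            raise ConfigError("mcar_rate must be in [0, 1]")
        if self.mnar_tau is not None and self.mnar_steepness <= 0:
            raise ConfigError("mnar_steepness must be > 0")

    @property
    def cycle_time_min(self) -> float:
        """Revisit interval of one isolation window (full DIA cycle)."""
        return self.n_isolation_windows * self.dwell_time_s / 60.0


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment: complete boundary and
    abundance matrices, the detection mask, and per-peptide peak shape."""

    boundaries: RTBoundaryMatrix
    abundances: QuantMatrix
    detected: pd.DataFrame
    apex: pd.DataFrame              # per (peptide, run) apex minutes
    sigma: pd.Series                # per-peptide peak width
    transition_ratios: pd.DataFrame  # peptide x transition index fractions


class SimulatedRun:
    """In-memory spectrum source for one run.

    XICs are synthesized deterministically on demand from the stored peak
    parameters: Gaussian peaks on the run's isolation-window time grid plus
    a gamma-distributed baseline. ``to_spectra``/``to_mzml`` assemble the
    very same traces into DIA spectra for the file-based path.
    """

    def __init__(
        self,
        run_id: str,
        run_index: int,
        cfg: SimConfig,
        window_edges: np.ndarray,
        peaks: dict[tuple[PrecursorKey, float], tuple[float, float, float, float, int]],
    ) -> None:
        # peaks: (precursor, product_mz) -> (apex, sigma, area, precursor_mz, tindex)
        self.run_id = run_id
        self._index = run_index
        self._cfg = cfg
        self._edges = window_edges
        self._peaks = peaks

    def _window_of(self, precursor_mz: float) -> int:
        w = int(np.searchsorted(self._edges, precursor_mz, side="right")) - 1
        return min(max(w, 0), len(self._edges) - 2)

    def _grid(self, window: int) -> np.ndarray:
        cfg = self._cfg
        lo, hi = cfg.gradient_window
        offset = window * cfg.dwell_time_s / 60.0
        return np.arange(lo + offset, hi, cfg.cycle_time_min)

    def _trace(self, key: tuple[PrecursorKey, float]) -> Chromatogram:
        apex, sigma, area, precursor_mz, tindex = self._peaks[key]
        t = self._grid(self._window_of(precursor_mz))
        y = area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
            -0.5 * ((t - apex) / sigma) ** 2
        )
        if self._cfg.baseline_level > 0:
            rng = np.random.default_rng(
                (self._cfg.seed, 7919, self._index, tindex)
            )
            y = y + self._cfg.baseline_level * rng.gamma(4.0, 0.25, size=t.size)
        return Chromatogram(t, y)

    def xic(self, transition: Transition, ppm_tol: float) -> Chromatogram:
        key = (transition.precursor, transition.product_mz)
        if key not in self._peaks:
            return Chromatogram(np.array([]), np.array([]))
        return self._trace(key)

    def to_spectra(self) -> list[Spectrum]:
        """Assemble DIA MS2 spectra equivalent to the on-demand XICs."""
        cfg = self._cfg
        by_window: dict[int, list[tuple[float, Chromatogram]]] = {}
        for (prec, product_mz), (_, _, _, pmz, _) in self._peaks.items():
            w = self._window_of(pmz)
            by_window.setdefault(w, []).append(
                (product_mz, self._trace((prec, product_mz)))
            )
        spectra: list[Spectrum] = []
        for w in range(len(self._edges) - 1):
            traces = by_window.get(w)
            lo_mz, hi_mz = self._edges[w], self._edges[w + 1]
            target = 0.5 * (lo_mz + hi_mz)
            grid = self._grid(w)
            if not traces:
                continue
            products = np.array(sorted(t[0] for t in traces))
            trace_by_mz = dict(traces)
            for i, t in enumerate(grid):
                inten = np.array(
                    [trace_by_mz[mz].intensities[i] for mz in products]
                )
                spectra.append(
                    Spectrum(
                        time_min=float(t),
                        ms_level=2,
                        mz=products,
                        intensity=inten,
                        isolation_lower=float(lo_mz),
                        isolation_upper=float(hi_mz),
                        isolation_target=float(target),
                    )
                )
        spectra.sort(key=lambda s: s.time_min)
        return spectra

    def to_mzml(self, path: str | Path) -> None:
        write_mzml(self.to_spectra(), path, run_id=self.run_id)


@dataclass
class SimExperiment:
    """Everything :func:`simulate_experiment` produces."""

    runs: dict[str, SimulatedRun]
    library: RTBoundaryMatrix
    truth: SyntheticTruth
    transitions: TransitionTable
    config: SimConfig

    def write_mzml_dir(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for run_id, run in self.runs.items():
            p = directory / f"{run_id}.mzML"
            run.to_mzml(p)
            paths[run_id] = p
        return paths


def _random_sequences(rng: np.random.Generator, n: int) -> list[str]:
    seqs: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(8, 15))
        seqs.add("".join(rng.choice(list(_AA), size=length)) + "K")
    return sorted(seqs)[:n]


def _spaced_mz(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Draw n m/z values, all at least _MIN_PRODUCT_SPACING apart."""
    vals: list[float] = []
    for _ in range(200 * n):
        v = float(rng.uniform(lo, hi))
        if all(abs(v - u) >= _MIN_PRODUCT_SPACING for u in vals):
            vals.append(v)
            if len(vals) == n:
                return np.array(vals)
    raise ConfigError("could not place product m/z values without overlap")


def mmcc_design(
    levels: tuple[float, ...] = (1.0, 0.3, 0.1, 0.07, 0.05, 0.01),
    replicates: int = 3,
) -> dict[str, float]:
    """A serial-dilution run layout: ``replicates`` runs per level, the 1.0
    level being the undiluted reference."""
    design = {}
    i = 0
    for d in levels:
        for _ in range(replicates):
            design[f"run{i:03d}"] = d
            i += 1
    return design


def apply_missingness(
    log2_abundance: pd.DataFrame,
    tau: float | None,
    s: float,
    mcar: float,
    seed: int,
) -> pd.DataFrame:
    """Detection mask for a grid of log2 abundances.

    A cell is missing with probability ``logistic((tau - log2A) / s)``
    (low-abundance cells miss more often), plus an independent MCAR dropout
    at rate ``mcar``. Returns a boolean DataFrame, True = detected.
    """
    if tau is not None and s <= 0:
        raise ConfigError("mnar steepness must be > 0")
    if not (0.0 <= mcar <= 1.0):
        raise ConfigError("mcar rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    a = log2_abundance.to_numpy(dtype=float)
    if tau is None:
        p_mnar = np.zeros_like(a)
    else:
        p_mnar = 1.0 / (1.0 + np.exp(-(tau - a) / s))
    miss = rng.random(a.shape) < p_mnar
    miss |= rng.random(a.shape) < mcar
    return pd.DataFrame(~miss, index=log2_abundance.index, columns=log2_abundance.columns)


def simulate_experiment(cfg: SimConfig) -> SimExperiment:
    """Generate a complete synthetic experiment.

    Identical configurations (including the seed) produce byte-identical
    outputs. With ``n_peptides == 0`` all matrices are empty.
    """
    rng = np.random.default_rng(cfg.seed)
    run_ids = (
        list(cfg.dilutions)
        if cfg.dilutions is not None
        else [f"run{i:03d}" for i in range(cfg.n_runs)]
    )
    n_runs = len(run_ids)
    dilution = np.array(
        [cfg.dilutions[r] if cfg.dilutions else 1.0 for r in run_ids]
    )

    lo, hi = cfg.gradient_window
    sequences = _random_sequences(rng, cfg.n_peptides)
    charges = rng.choice([2, 3], size=cfg.n_peptides)
    keys = [PrecursorKey(s, int(z)) for s, z in zip(sequences, charges)]
    precursor_mz = rng.uniform(*cfg.precursor_mz_range, size=cfg.n_peptides)
    n_trans = cfg.transitions_per_peptide
    product_mz = _spaced_mz(
        rng, cfg.n_peptides * n_trans, *cfg.product_mz_range
    ).reshape(cfg.n_peptides, n_trans) if cfg.n_peptides else np.empty((0, n_trans))

    sigma = rng.uniform(*cfg.sigma_range, size=cfg.n_peptides)
    margin = 2.0 * cfg.sigma_range[1] + 1.0
    mu = rng.uniform(lo + margin, hi - margin, size=cfg.n_peptides)
    ratios = rng.dirichlet(np.full(n_trans, 2.0), size=cfg.n_peptides) \
        if cfg.n_peptides else np.empty((0, n_trans))

    slope = rng.normal(1.0, cfg.warp_slope_sd, size=n_runs)
    offset = rng.normal(0.0, cfg.warp_offset_sd, size=n_runs)
    jitter = rng.normal(0.0, cfg.apex_jitter_sd, size=(cfg.n_peptides, n_runs))
    apex = slope[None, :] * mu[:, None] + offset[None, :] + jitter
    apex = np.clip(apex, lo + 2.0 * cfg.sigma_range[1], hi - 2.0 * cfg.sigma_range[1])
    starts = apex - 2.0 * sigma[:, None]
    ends = apex + 2.0 * sigma[:, None]

    base_log2 = rng.normal(
        cfg.log2_abundance_mean, cfg.log2_abundance_sd, size=cfg.n_peptides
    )
    run_effect = 2.0 ** rng.normal(0.0, cfg.run_effect_log2_sd, size=n_runs)
    # between-sample biological variability; dilution-series runs are
    # technical replicates of one mixed sample, so it only applies outside
    # dilution mode
    if cfg.dilutions is None and cfg.biological_log2_sd > 0:
        biology = 2.0 ** rng.normal(
            0.0, cfg.biological_log2_sd, size=(cfg.n_peptides, n_runs)
        )
    else:
        biology = np.ones((cfg.n_peptides, n_runs))
    # mean-one lognormal multiplicative noise at the requested CV
    sig_ln = math.sqrt(math.log(1.0 + cfg.noise_cv**2))
    noise = np.exp(
        rng.normal(-0.5 * sig_ln**2, sig_ln, size=(cfg.n_peptides, n_runs))
    )
    abundance = (
        2.0 ** base_log2[:, None]
        * run_effect[None, :]
        * dilution[None, :]
        * biology
        * noise
    )

    idx = key_index(keys)
    cols = pd.Index(run_ids, name="run")
    abund_df = pd.DataFrame(abundance, index=idx, columns=cols)
    with np.errstate(divide="ignore"):
        log2_abund = pd.DataFrame(
            np.log2(np.maximum(abundance, 1e-300)), index=idx, columns=cols
        )
    detected = apply_missingness(
        log2_abund,
        cfg.mnar_tau,
        cfg.mnar_steepness,
        cfg.mcar_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    truth_bounds = RTBoundaryMatrix(
        pd.DataFrame(starts, index=idx, columns=cols),
        pd.DataFrame(ends, index=idx, columns=cols),
    )
    lib_starts = pd.DataFrame(
        np.where(detected.to_numpy(), starts, np.nan), index=idx, columns=cols
    )
    lib_ends = pd.DataFrame(
        np.where(detected.to_numpy(), ends, np.nan), index=idx, columns=cols
    )
    library = RTBoundaryMatrix(lib_starts, lib_ends)

    transitions = TransitionTable(
        Transition(
            precursor=keys[p],
            precursor_mz=float(precursor_mz[p]),
            product_mz=float(product_mz[p, t]),
            label=f"t{t}",
        )
        for p in range(cfg.n_peptides)
        for t in range(n_trans)
    )

    edges = np.linspace(*cfg.precursor_mz_range, cfg.n_isolation_windows + 1)
    runs: dict[str, SimulatedRun] = {}
    for ri, run_id in enumerate(run_ids):
        peaks = {}
        for p, t in itertools.product(range(cfg.n_peptides), range(n_trans)):
            peaks[(keys[p], float(product_mz[p, t]))] = (
                float(apex[p, ri]),
                float(sigma[p]),
                float(abundance[p, ri] * ratios[p, t]),
                float(precursor_mz[p]),
                p * n_trans + t,
            )
        runs[run_id] = SimulatedRun(run_id, ri, cfg, edges, peaks)

    truth = SyntheticTruth(
        boundaries=truth_bounds,
        abundances=QuantMatrix(abund_df),
        detected=detected,
        apex=pd.DataFrame(apex, index=idx, columns=cols),
        sigma=pd.Series(sigma, index=idx),
        transition_ratios=pd.DataFrame(
            ratios, index=idx, columns=[f"t{t}" for t in range(n_trans)]
        ),
    )
    return SimExperiment(
        runs=runs, library=library, truth=truth, transitions=transitions, config=cfg
    )
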