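"""Imputation of RT boundaries and of quantitation matrices.

The method at the heart of the package is distance-weighted k-nearest-
neighbour imputation of retention-time boundaries across MS runs
(:func:`knn_impute_rt`): runs are the samples, every precursor contributes a
start feature and an end feature, and a missing boundary is filled with the
inverse-distance-weighted mean of the runs that observed it. Because a peak
boundary is a *time*, the filled value can then be turned into a real
measured quantity by integrating the extracted ion chromatogram inside the
imputed window (see :mod:`rtimpute.chrom`) — unlike the plug-in baselines
below, which insert statistical estimates directly into the quant matrix.

Plug-in baselines implemented for benchmarking:

* :func:`low_value_impute` — each missing quant receives its peptide's
  minimum observed value anywhere in the experiment;
* :func:`knn_impute_quants` — mean of the peptide's values in the k most
  similar runs;
* :func:`missforest_impute` — iterative per-run random-forest regression.

:func:`mask_boundary_pairs` removes a random fraction of observed boundary
pairs to set up hold-out benchmarks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ConfigError, NoSharedFeaturesError
from .matrices import (
    PROV_IMPUTED,
    PROV_MASKED,
    PROV_MISSING,
    PROV_PLUGIN,
    PrecursorKey,
    QuantMatrix,
    RTBoundaryMatrix,
    canonicalize_boundaries,
)

__all__ = [
    "ImputeConfig",
    "HoldoutMask",
    "ImputeResult",
    "nan_euclidean_distance",
    "knn_impute_rt",
    "mask_boundary_pairs",
    "low_value_impute",
    "knn_impute_quants",
    "missforest_impute",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputeConfig:
    """kNN settings: ``k`` donors (default 8) and the weighting scheme.

    ``distance`` weights donors by 1/d; ``uniform`` averages them equally.
    ``k`` must be smaller than the number of runs.
    """

    k: int = 8
    weighting: str = "distance"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if self.weighting not in ("distance", "uniform"):
            raise ConfigError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class HoldoutMask:
    """Cells removed for a hold-out experiment, with the fraction and seed
    that produced them (same seed, same mask)."""

    cells: frozenset[tuple[PrecursorKey, str]]
    fraction: float
    seed: int

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class ImputeResult:
    """Outcome of boundary imputation: the completed matrix, how many cells
    were filled, how many inverted windows were repaired, and the cells for
    which no donor run existed."""

    matrix: RTBoundaryMatrix
    n_imputed: int
    n_swapped: int
    unimputable: list[tuple[PrecursorKey, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def nan_euclidean_distance(
    x: np.ndarray, y: np.ndarray, total_features: int | None = None
) -> float:
    """Euclidean distance between vectors with missing entries.

    Only coordinates observed in *both* vectors contribute; the squared sum
    is rescaled by ``total_features / n_shared`` to compensate for the
    unshared coordinates:

        d(x, y) = sqrt( total / |S| * sum_{j in S} (x_j - y_j)^2 )

    Raises :class:`NoSharedFeaturesError` when no coordinate is shared.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    total = total_features if total_features is not None else x.size
    shared = ~(np.isnan(x) | np.isnan(y))
    n_shared = int(shared.sum())
    if n_shared == 0:
        raise NoSharedFeaturesError("vectors share no observed features")
    sq = float(np.sum((x[shared] - y[shared]) ** 2))
    return math.sqrt(total / n_shared * sq)


def _pairwise_nan_euclidean(X: np.ndarray) -> np.ndarray:
    """All pairwise rescaled distances between rows of X (NaN = missing).

    Entries with no shared features are NaN.
    """
    M = ~np.isnan(X)
    Xz = np.where(M, X, 0.0)
    cross = Xz @ Xz.T
    sq = (Xz**2) @ M.T  # sum over features observed in the *other* row
    d2 = sq + sq.T - 2.0 * cross
    counts = (M.astype(float) @ M.T.astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(counts > 0, np.maximum(d2, 0.0) * X.shape[1] / counts, np.nan)
    return np.sqrt(d2)


def _weighted_donor_mean(
    values: np.ndarray, dists: np.ndarray, weighting: str
) -> float:
    """Combine donor values given their distances to the target run.

    Inverse-distance weights are undefined at d=0; when any donor sits at
    zero distance, only zero-distance donors contribute, uniformly.
    """
    if weighting == "uniform":
        return float(values.mean())
    zero = dists == 0.0
    if zero.any():
        return float(values[zero].mean())
    w = 1.0 / dists
    return float(np.sum(w * values) / np.sum(w))


# ---------------------------------------------------------------------------
# RT-boundary kNN imputation
# ---------------------------------------------------------------------------

def knn_impute_rt(
    matrix: RTBoundaryMatrix, cfg: ImputeConfig = ImputeConfig()
) -> ImputeResult:
    """Impute missing RT boundaries from the k most similar runs.

    The working table has one row per run and two columns (start, end) per
    precursor; similarity between runs is the rescaled shared-coordinate
    Euclidean distance over that whole table. For each missing entry, the
    ``cfg.k`` nearest runs that observed the feature (fewer if fewer exist)
    contribute an inverse-distance-weighted mean; distance ties break by run
    column order. Observed entries are never modified. Starts and ends are
    imputed independently, so the result passes through
    :func:`canonicalize_boundaries` to repair any inverted windows. Cells
    for which no donor exists remain missing and are reported.
    """
    runs = matrix.runs
    n_runs = len(runs)
    if n_runs < 2:
        raise ConfigError("boundary imputation needs at least 2 runs")
    if cfg.k >= n_runs:
        raise ConfigError(f"k={cfg.k} must be < number of runs ({n_runs})")

    s = matrix.starts.to_numpy()
    e = matrix.ends.to_numpy()
    n_prec = s.shape[0]
    # runs as samples: features alternate start, end per precursor
    X = np.empty((n_runs, 2 * n_prec))
    X[:, 0::2] = s.T
    X[:, 1::2] = e.T
    D = _pairwise_nan_euclidean(X)
    observed = ~np.isnan(X)

    filled = X.copy()
    unimputable: list[tuple[PrecursorKey, str]] = []
    precursors = matrix.precursors
    n_imputed_entries = 0
    for i in range(n_runs):
        missing_feats = np.nonzero(~observed[i])[0]
        if missing_feats.size == 0:
            continue
        d_i = D[i].copy()
        d_i[i] = np.nan  # a run is not its own donor
        usable = ~np.isnan(d_i)
        for j in missing_feats:
            donors = np.nonzero(usable & observed[:, j])[0]
            if donors.size == 0:
                unimputable.append((precursors[j // 2], runs[i]))
                continue
            # stable sort on distance; ties resolved by run column order
            order = donors[np.argsort(d_i[donors], kind="stable")]
            sel = order[: cfg.k]
            filled[i, j] = _weighted_donor_mean(X[sel, j], d_i[sel], cfg.weighting)
            n_imputed_entries += 1

    new_s = filled[:, 0::2].T
    new_e = filled[:, 1::2].T
    was_missing = np.isnan(s)
    now_present = ~np.isnan(new_s) & ~np.isnan(new_e)
    # half-imputed pairs (one side had no donor) stay missing
    half = np.isnan(new_s) != np.isnan(new_e)
    new_s[half] = np.nan
    new_e[half] = np.nan
    prov = matrix.provenance.to_numpy().copy()
    prov[was_missing & now_present] = PROV_IMPUTED

    out = RTBoundaryMatrix(
        pd.DataFrame(new_s, index=matrix.starts.index, columns=matrix.starts.columns),
        pd.DataFrame(new_e, index=matrix.ends.index, columns=matrix.ends.columns),
        pd.DataFrame(prov, index=matrix.starts.index, columns=matrix.starts.columns),
    )
    out, n_swapped = canonicalize_boundaries(out)
    # de-duplicate cells reported once per half
    unimputable = sorted(set(unimputable), key=lambda c: (c[1], c[0]))
    if unimputable:
        logger.warning("%d cells had no donor run and remain missing", len(unimputable))
    return ImputeResult(
        matrix=out,
        n_imputed=int((was_missing & now_present).sum()),
        n_swapped=n_swapped,
        unimputable=unimputable,
    )


def mask_boundary_pairs(
    matrix: RTBoundaryMatrix, fraction: float, seed: int
) -> tuple[RTBoundaryMatrix, HoldoutMask]:
    """Randomly remove ``floor(fraction * n_observed)`` boundary pairs.

    Both members of each selected pair are blanked and the cell is flagged
    ``masked``. The same seed always selects the same cells.
    """
    if not (0.0 <= fraction < 1.0):
        raise ConfigError(f"mask fraction must be in [0, 1), got {fraction}")
    present = matrix.present_mask().to_numpy()
    rows, cols = np.nonzero(present)
    n_obs = rows.size
    n_mask = math.floor(fraction * n_obs)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_obs, size=n_mask, replace=False)
    s = matrix.starts.to_numpy().copy()
    e = matrix.ends.to_numpy().copy()
    prov = matrix.provenance.to_numpy().copy()
    precursors = matrix.precursors
    runs = matrix.runs
    cells = []
    for idx in chosen:
        r, c = rows[idx], cols[idx]
        s[r, c] = np.nan
        e[r, c] = np.nan
        prov[r, c] = PROV_MASKED
        cells.append((precursors[r], runs[c]))
    out = RTBoundaryMatrix(
        pd.DataFrame(s, index=matrix.starts.index, columns=matrix.starts.columns),
        pd.DataFrame(e, index=matrix.ends.index, columns=matrix.ends.columns),
        pd.DataFrame(prov, index=matrix.starts.index, columns=matrix.starts.columns),
    )
    return out, HoldoutMask(cells=frozenset(cells), fraction=fraction, seed=seed)


# ---------------------------------------------------------------------------
# Plug-in baselines on quant matrices
# ---------------------------------------------------------------------------

def low_value_impute(q: QuantMatrix) -> QuantMatrix:
    """Fill each missing quant with its peptide's minimum observed value
    anywhere in the experiment. Rows with no observation stay missing."""
    vals = q.values.to_numpy().copy()
    prov = q.provenance.to_numpy().copy()
    row_min = np.nanmin(
        np.where(np.isnan(vals), np.inf, vals), axis=1
    )
    n_empty = 0
    for r in range(vals.shape[0]):
        miss = np.isnan(vals[r])
        if not miss.any():
            continue
        if not np.isfinite(row_min[r]):
            n_empty += 1
            continue
        vals[r, miss] = row_min[r]
        prov[r, miss] = PROV_PLUGIN
    if n_empty:
        logger.warning("%d rows have no observed value and stay missing", n_empty)
    return QuantMatrix(
        pd.DataFrame(vals, index=q.values.index, columns=q.values.columns),
        pd.DataFrame(prov, index=q.values.index, columns=q.values.columns),
    )


def knn_impute_quants(q: QuantMatrix, k: int) -> QuantMatrix:
    """kNN plug-in imputation: runs as samples, peptides as features.

    Run-to-run distances are computed on log2 abundances (the scale on which
    intensities are roughly additive); each missing cell receives the
    unweighted mean, on the raw scale, of its peptide's values in the k
    nearest runs that observed it.
    """
    n_runs = len(q.runs)
    if k >= n_runs:
        raise ConfigError(f"k={k} must be < number of runs ({n_runs})")
    vals = q.values.to_numpy()
    with np.errstate(divide="ignore"):
        logs = np.where(np.isnan(vals), np.nan, np.log2(np.maximum(vals, 1e-12)))
    D = _pairwise_nan_euclidean(logs.T)
    observed = ~np.isnan(vals)
    out = vals.copy()
    prov = q.provenance.to_numpy().copy()
    for c in range(n_runs):
        d_c = D[c].copy()
        d_c[c] = np.nan
        usable = ~np.isnan(d_c)
        for r in np.nonzero(~observed[:, c])[0]:
            donors = np.nonzero(usable & observed[r])[0]
            if donors.size == 0:
                continue
            order = donors[np.argsort(d_c[donors], kind="stable")]
            out[r, c] = float(vals[r, order[:k]].mean())
            prov[r, c] = PROV_PLUGIN
    return QuantMatrix(
        pd.DataFrame(out, index=q.values.index, columns=q.values.columns),
        pd.DataFrame(prov, index=q.values.index, columns=q.values.columns),
    )


def missforest_impute(
    q: QuantMatrix,
    max_iter: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> QuantMatrix:
    """Iterative random-forest plug-in imputation.

    Missing cells start at their run's (column) mean. Runs are then revisited
    in order of increasing missingness; for each, a random forest is fit to
    predict that run's abundances from all other runs, using the peptides
    observed in the target run, and its missing peptides are predicted. The
    sweep repeats until the relative change in the imputed values increases
    (the usual stopping rule for this scheme) or ``max_iter`` is reached,
    and the answer from the sweep *before* the increase is returned.
    Observed cells are never modified; a fixed seed gives identical output.
    """
    vals = q.values.to_numpy().copy()
    obs = ~np.isnan(vals)
    n_rows, n_cols = vals.shape
    if n_rows < 2 or n_cols < 2:
        raise ConfigError("missforest needs at least 2 peptides and 2 runs")
    miss_per_col = (~obs).sum(axis=0)
    col_order = np.argsort(miss_per_col, kind="stable")

    filled = vals.copy()
    col_means = np.nanmean(np.where(obs, vals, np.nan), axis=0)
    global_mean = np.nanmean(vals)
    for c in range(n_cols):
        fill = col_means[c] if np.isfinite(col_means[c]) else global_mean
        if not np.isfinite(fill):
            fill = 0.0
            logger.warning("matrix has no observed values; imputing zeros")
        filled[~obs[:, c], c] = fill

    prev_change = np.inf
    prev_filled = filled.copy()
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        before = filled.copy()
        for c in col_order:
            miss_rows = ~obs[:, c]
            if not miss_rows.any():
                continue
            train_rows = obs[:, c]
            covs = np.delete(np.arange(n_cols), c)
            if not train_rows.any() or covs.size == 0:
                logger.warning("column %d degenerate; keeping mean fill", c)
                continue
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(filled[np.ix_(train_rows, covs)], filled[train_rows, c])
            filled[miss_rows, c] = rf.predict(filled[np.ix_(miss_rows, covs)])
        imputed_mask = ~obs
        denom = float(np.sum(filled[imputed_mask] ** 2))
        change = (
            float(np.sum((filled[imputed_mask] - before[imputed_mask]) ** 2)) / denom
            if denom > 0
            else 0.0
        )
        if change > prev_change:
            filled = prev_filled  # the previous sweep was the best one
            break
        prev_change = change
        prev_filled = filled.copy()

    filled = np.maximum(filled, 0.0)
    prov = q.provenance.to_numpy().copy()
    prov[(~obs) & (prov == PROV_MISSING)] = PROV_PLUGIN
    prov[(~obs) & (prov == PROV_MASKED)] = PROV_PLUGIN
    return QuantMatrix(
        pd.DataFrame(filled, index=q.values.index, columns=q.values.columns),
        pd.DataFrame(prov, index=q.values.index, columns=q.values.columns),
    )
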