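"""Retention-time boundary and quantitation matrices.

The central data structure of the package is the RT-boundary matrix: a grid
whose rows are precursors (a modified peptide sequence plus charge state) and
whose columns are MS runs. Each cell either holds the start and end of the
precursor's chromatographic peak in that run, in minutes, or is missing
because the library search did not detect the precursor there. The companion
:class:`QuantMatrix` holds nonnegative peptide abundances on the same grid.

Both matrices carry a per-cell provenance flag so downstream analysis can
distinguish values measured by the search from values recovered by boundary
imputation, plug-in imputation, or deliberately masked for hold-out
evaluation.

Missingness is encoded as NaN internally and as the empty string in CSV/TSV
files; zero is a legitimate measured value and never denotes missingness.
Times are minutes throughout. Run identifiers are raw-file basenames without
extension.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "PrecursorKey",
    "RTBoundaryMatrix",
    "QuantMatrix",
    "TrimConfig",
    "read_rt_matrix_csv",
    "write_rt_matrix_csv",
    "trim_extreme_rts",
    "canonicalize_boundaries",
    "PROV_OBSERVED",
    "PROV_IMPUTED",
    "PROV_MASKED",
    "PROV_MISSING",
    "PROV_PLUGIN",
    "PROV_BOUNDARY",
]

# Provenance codes shared by both matrix types.
PROV_OBSERVED = "observed"
PROV_IMPUTED = "imputed"          # RT boundaries filled in by kNN
PROV_MASKED = "masked"            # removed for a hold-out experiment
PROV_MISSING = "missing"          # never observed
PROV_PLUGIN = "plugin_imputed"    # quant filled in by a plug-in method
PROV_BOUNDARY = "boundary_imputed"  # quant integrated within imputed bounds

_SEQ_RE = re.compile(r"^[A-Z](?:[A-Z]|\[[+-]?\d+(?:\.\d+)?\])*$")

# Transitions of one precursor whose boundary annotations differ by no more
# than this (minutes) are reconciled by taking the median.
COLLAPSE_TOL_MIN = 0.01


class PrecursorKey(NamedTuple):
    """A modified peptide sequence plus precursor charge, e.g.
    ``("TQTHATLC[+57]STSAK", 2)``. The unit of identification and
    quantitation throughout the package."""

    sequence: str
    charge: int

    def validate(self) -> "PrecursorKey":
        if not self.sequence or not _SEQ_RE.match(self.sequence):
            raise ValidationError(
                f"invalid peptide sequence {self.sequence!r}: expected uppercase "
                "residues with optional bracketed mass offsets"
            )
        if int(self.charge) < 1:
            raise ValidationError(f"charge must be >= 1, got {self.charge}")
        return PrecursorKey(self.sequence, int(self.charge))


@dataclass(frozen=True)
class TrimConfig:
    """Configuration for extreme retention-time trimming.

    ``fraction`` is the proportion of pooled boundary values removed from
    *each* tail of the RT distribution (default 1%); values in the tails
    typically correspond to contaminants eluting in the wash phases.
    ``per_run`` pools and trims each run's boundaries separately instead of
    one global pool.
    """

    fraction: float = 0.01
    per_run: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction < 0.5):
            raise ValidationError(
                f"trim fraction must be in [0, 0.5), got {self.fraction}"
            )


def key_index(keys: Iterable[PrecursorKey]) -> pd.MultiIndex:
    """Build the (sequence, charge) MultiIndex used by all matrices."""
    keys = list(keys)
    if not keys:
        return pd.MultiIndex.from_arrays([[], []], names=["sequence", "charge"])
    return pd.MultiIndex.from_tuples(
        [tuple(k) for k in keys], names=["sequence", "charge"]
    )


def _as_key_index(keys: Iterable[PrecursorKey]) -> pd.MultiIndex:
    keys = [PrecursorKey(*k).validate() for k in keys]
    idx = key_index(keys)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValidationError(f"duplicate precursor {tuple(dup)}")
    return idx


class _Grid:
    """Shared row/column bookkeeping for the two matrix types."""

    @property
    def precursors(self) -> list[PrecursorKey]:
        return [PrecursorKey(*t) for t in self._index]

    @property
    def runs(self) -> list[str]:
        return list(self._columns)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self._index), len(self._columns))


class RTBoundaryMatrix(_Grid):
    """Precursor x run grid of optional (start, end) retention-time pairs.

    Parameters
    ----------
    starts, ends:
        DataFrames of minutes, indexed by (sequence, charge) with one column
        per run; NaN marks a missing cell. The two members of a pair must be
        present or absent together.
    provenance:
        Optional DataFrame of provenance codes with the same layout; present
        cells default to ``"observed"``.
    """

    def __init__(
        self,
        starts: pd.DataFrame,
        ends: pd.DataFrame,
        provenance: pd.DataFrame | None = None,
    ) -> None:
        if not starts.index.equals(ends.index) or not starts.columns.equals(ends.columns):
            raise ValidationError("starts and ends must share index and columns")
        self._index = _as_key_index(list(starts.index))
        self._columns = pd.Index([str(c) for c in starts.columns], name="run")
        if self._columns.has_duplicates:
            raise ValidationError("duplicate run identifiers")
        self.starts = pd.DataFrame(
            starts.to_numpy(dtype=float), index=self._index, columns=self._columns
        )
        self.ends = pd.DataFrame(
            ends.to_numpy(dtype=float), index=self._index, columns=self._columns
        )
        sp, ep = self.starts.notna(), self.ends.notna()
        if not sp.equals(ep):
            raise ValidationError(
                "start and end of a boundary pair must be present or absent together"
            )
        vals = np.concatenate(
            [self.starts.to_numpy().ravel(), self.ends.to_numpy().ravel()]
        )
        present = vals[~np.isnan(vals)]
        if present.size and (not np.all(np.isfinite(present)) or present.min() < 0):
            raise ValidationError("boundary times must be finite and >= 0")
        if provenance is None:
            prov = np.where(sp.to_numpy(), PROV_OBSERVED, PROV_MISSING)
            self.provenance = pd.DataFrame(
                prov, index=self._index, columns=self._columns
            )
        else:
            self.provenance = pd.DataFrame(
                provenance.to_numpy(dtype=object),
                index=self._index,
                columns=self._columns,
            )

    # -- basic queries ----------------------------------------------------

    def present_mask(self) -> pd.DataFrame:
        """Boolean DataFrame: True where a (start, end) pair is present."""
        return self.starts.notna()

    @property
    def n_present(self) -> int:
        return int(self.present_mask().to_numpy().sum())

    def copy(self) -> "RTBoundaryMatrix":
        return RTBoundaryMatrix(
            self.starts.copy(), self.ends.copy(), self.provenance.copy()
        )

    def validate_canonical(self) -> None:
        """Assert start <= end on every present cell."""
        bad = (self.starts > self.ends).to_numpy().sum()
        if bad:
            raise ValidationError(f"{bad} cells have start > end")

    def equals(self, other: "RTBoundaryMatrix", tol: float = 1e-6) -> bool:
        """Equality of keys, missingness pattern, and values to ``tol`` minutes."""
        if not (
            self.starts.index.equals(other.starts.index)
            and self.starts.columns.equals(other.starts.columns)
        ):
            return False
        for a, b in ((self.starts, other.starts), (self.ends, other.ends)):
            av, bv = a.to_numpy(), b.to_numpy()
            if not np.array_equal(np.isnan(av), np.isnan(bv)):
                return False
            m = ~np.isnan(av)
            if m.any() and np.max(np.abs(av[m] - bv[m])) > tol:
                return False
        return True

    @classmethod
    def empty(cls, precursors: Iterable[PrecursorKey], runs: Iterable[str]) -> "RTBoundaryMatrix":
        idx = _as_key_index(precursors)
        cols = pd.Index(list(runs), name="run")
        nan = pd.DataFrame(np.nan, index=idx, columns=cols)
        return cls(nan, nan.copy())


class QuantMatrix(_Grid):
    """Precursor x run grid of nonnegative peptide abundances.

    Abundance is the background-subtracted peak area summed over a peptide's
    transitions, in intensity-minutes (an arbitrary per-instrument scale).
    NaN marks a missing quantitation.
    """

    def __init__(
        self, values: pd.DataFrame, provenance: pd.DataFrame | None = None
    ) -> None:
        self._index = _as_key_index(list(values.index))
        self._columns = pd.Index([str(c) for c in values.columns], name="run")
        if self._columns.has_duplicates:
            raise ValidationError("duplicate run identifiers")
        self.values = pd.DataFrame(
            values.to_numpy(dtype=float), index=self._index, columns=self._columns
        )
        arr = self.values.to_numpy()
        present = arr[~np.isnan(arr)]
        if present.size and (not np.all(np.isfinite(present)) or present.min() < 0):
            raise ValidationError("abundances must be finite and >= 0 when present")
        if provenance is None:
            prov = np.where(self.values.notna().to_numpy(), PROV_OBSERVED, PROV_MISSING)
            self.provenance = pd.DataFrame(prov, index=self._index, columns=self._columns)
        else:
            self.provenance = pd.DataFrame(
                provenance.to_numpy(dtype=object),
                index=self._index,
                columns=self._columns,
            )

    def observed_mask(self) -> pd.DataFrame:
        return self.values.notna()

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values.copy(), self.provenance.copy())

    # -- report I/O (long form TSV: precursor, charge, run, abundance, provenance)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for (seq, z) in self.values.index:
            for run in self.values.columns:
                v = self.values.at[(seq, z), run]
                rows.append(
                    {
                        "precursor": seq,
                        "charge": z,
                        "run": run,
                        "abundance": "" if pd.isna(v) else f"{v:.6f}",
                        "provenance": self.provenance.at[(seq, z), run],
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QuantMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"precursor": str, "run": str})
        required = {"precursor", "charge", "run", "abundance"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"quant report missing columns {sorted(required - set(df.columns))}"
            )
        keys = list(dict.fromkeys(zip(df["precursor"], df["charge"])))
        runs = list(dict.fromkeys(df["run"]))
        idx = pd.MultiIndex.from_tuples(
            [(s, int(z)) for s, z in keys], names=["sequence", "charge"]
        )
        values = df.pivot(
            index=["precursor", "charge"], columns="run", values="abundance"
        )
        values.index = pd.MultiIndex.from_tuples(
            [(s, int(z)) for s, z in values.index], names=["sequence", "charge"]
        )
        values = values.reindex(index=idx, columns=runs)
        prov = None
        if "provenance" in df.columns:
            prov = df.pivot(
                index=["precursor", "charge"], columns="run", values="provenance"
            )
            prov.index = values.index.copy()
            prov = prov.reindex(index=idx, columns=runs).fillna(PROV_MISSING)
        return cls(values, prov)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _provenance_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".provenance.csv")


def _parse_header(columns: list[str]) -> list[str]:
    """Extract ordered run names from ``<run>_start`` / ``<run>_end`` columns."""
    runs: list[str] = []
    starts, ends = set(), set()
    for col in columns:
        if col.endswith("_start"):
            starts.add(col[: -len("_start")])
            runs.append(col[: -len("_start")])
        elif col.endswith("_end"):
            ends.add(col[: -len("_end")])
        else:
            raise FormatError(f"unrecognized column {col!r}")
    if starts != ends:
        odd = sorted(starts.symmetric_difference(ends))
        raise FormatError(f"unpaired start/end columns for runs: {odd}")
    return runs


def read_rt_matrix_csv(path: str | Path) -> RTBoundaryMatrix:
    """Read an RT-boundary matrix from CSV.

    The expected header is ``precursor,charge,<run>_start,<run>_end,...``;
    empty fields are missing values. Transition-level files repeat the
    precursor key on several rows; those rows are collapsed to one precursor
    row, taking the median when annotations agree within
    :data:`COLLAPSE_TOL_MIN` minutes and raising a validation error naming
    the precursor otherwise.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"precursor": str}, keep_default_na=True)
    if "precursor" not in df.columns or "charge" not in df.columns:
        raise FormatError("RT matrix CSV must begin with 'precursor,charge' columns")
    runs = _parse_header([c for c in df.columns if c not in ("precursor", "charge")])

    keys: list[PrecursorKey] = []
    seen: set[PrecursorKey] = set()
    for seq, z in zip(df["precursor"], df["charge"]):
        k = PrecursorKey(str(seq), int(z)).validate()
        if k not in seen:
            seen.add(k)
            keys.append(k)

    idx = pd.MultiIndex.from_tuples(keys, names=["sequence", "charge"])
    starts = pd.DataFrame(np.nan, index=idx, columns=runs)
    ends = pd.DataFrame(np.nan, index=idx, columns=runs)
    grouped = df.groupby(["precursor", "charge"], sort=False)
    for (seq, z), sub in grouped:
        key = (str(seq), int(z))
        for run in runs:
            s_vals = sub[f"{run}_start"].dropna().to_numpy(dtype=float)
            e_vals = sub[f"{run}_end"].dropna().to_numpy(dtype=float)
            pair = []
            for vals in (s_vals, e_vals):
                if vals.size == 0:
                    pair.append(np.nan)
                elif vals.max() - vals.min() <= COLLAPSE_TOL_MIN:
                    pair.append(float(np.median(vals)))
                else:
                    raise ValidationError(
                        f"transitions of precursor {key} disagree on boundaries in "
                        f"run {run!r} by more than {COLLAPSE_TOL_MIN} min"
                    )
            # a half-present pair after collapsing counts as missing
            if any(math.isnan(v) for v in pair):
                pair = [np.nan, np.nan]
            starts.at[key, run], ends.at[key, run] = pair

    prov = None
    sidecar = _provenance_sidecar(path)
    if sidecar.exists():
        pdf = pd.read_csv(sidecar, dtype={"precursor": str})
        pdf = pdf.set_index(["precursor", "charge"])
        pdf.index = pd.MultiIndex.from_tuples(
            [(s, int(z)) for s, z in pdf.index], names=["sequence", "charge"]
        )
        prov = pdf.reindex(index=idx, columns=runs).fillna(PROV_MISSING)
    return RTBoundaryMatrix(starts, ends, prov)


def write_rt_matrix_csv(matrix: RTBoundaryMatrix, path: str | Path) -> None:
    """Write a matrix so that :func:`read_rt_matrix_csv` reproduces it.

    Values are printed with six decimals (sub-millisecond in minutes);
    missing cells are empty fields. If any cell carries non-trivial
    provenance (imputed/masked), a ``<name>.provenance.csv`` sidecar with
    the per-cell codes is written next to the main file.
    """
    path = Path(path)
    out = pd.DataFrame(
        {
            "precursor": [k[0] for k in matrix.starts.index],
            "charge": [k[1] for k in matrix.starts.index],
        }
    )
    for run in matrix.runs:
        out[f"{run}_start"] = [
            "" if pd.isna(v) else f"{v:.6f}" for v in matrix.starts[run]
        ]
        out[f"{run}_end"] = ["" if pd.isna(v) else f"{v:.6f}" for v in matrix.ends[run]]
    out.to_csv(path, index=False)

    codes = set(matrix.provenance.to_numpy().ravel())
    if codes - {PROV_OBSERVED, PROV_MISSING}:
        prov = matrix.provenance.copy()
        prov.insert(0, "charge", [k[1] for k in prov.index])
        prov.insert(0, "precursor", [k[0] for k in prov.index])
        prov.to_csv(_provenance_sidecar(path), index=False)


# ---------------------------------------------------------------------------
# Trimming and canonicalization
# ---------------------------------------------------------------------------

def trim_extreme_rts(
    matrix: RTBoundaryMatrix, cfg: TrimConfig = TrimConfig()
) -> RTBoundaryMatrix:
    """Blank boundary pairs holding extreme retention times.

    All present starts and ends are pooled into one distribution (globally by
    default, per run with ``cfg.per_run``); the ``floor(fraction * n)``
    smallest and largest values are flagged, and every cell containing a
    flagged value loses *both* members of its pair. Extreme retention times
    mostly belong to contaminants eluting in the column wash, so the whole
    putative peak is discarded rather than one edge.
    """
    out = matrix.copy()
    s, e = out.starts.to_numpy(), out.ends.to_numpy()
    prov = out.provenance.to_numpy()

    def _trim_pool(cols: np.ndarray) -> None:
        # pool starts and ends of the selected columns together
        rows, cs = np.nonzero(~np.isnan(s[:, cols]))
        cs = cols[cs]
        vals = np.concatenate([s[rows, cs], e[rows, cs]])
        cells = np.concatenate([np.stack([rows, cs], 1)] * 2)
        n = vals.size
        c = math.floor(cfg.fraction * n)
        if c == 0:
            return
        order = np.argsort(vals, kind="stable")
        hit = np.concatenate([order[:c], order[n - c:]])
        for r, col in cells[hit]:
            s[r, col] = np.nan
            e[r, col] = np.nan
            prov[r, col] = PROV_MISSING

    if cfg.per_run:
        for j in range(s.shape[1]):
            _trim_pool(np.array([j]))
    else:
        _trim_pool(np.arange(s.shape[1]))
    return RTBoundaryMatrix(
        pd.DataFrame(s, index=out.starts.index, columns=out.starts.columns),
        pd.DataFrame(e, index=out.ends.index, columns=out.ends.columns),
        pd.DataFrame(prov, index=out.starts.index, columns=out.starts.columns),
    )


def canonicalize_boundaries(
    matrix: RTBoundaryMatrix,
) -> tuple[RTBoundaryMatrix, int]:
    """Swap any (start, end) pair with start > end; return (matrix, n_swapped).

    Needed because starts and ends are imputed as independent features, which
    can occasionally produce inverted windows.
    """
    s, e = matrix.starts.to_numpy().copy(), matrix.ends.to_numpy().copy()
    with np.errstate(invalid="ignore"):
        inverted = s > e
    n = int(inverted.sum())
    s[inverted], e[inverted] = e[inverted], s[inverted].copy()
    out = RTBoundaryMatrix(
        pd.DataFrame(s, index=matrix.starts.index, columns=matrix.starts.columns),
        pd.DataFrame(e, index=matrix.ends.index, columns=matrix.ends.columns),
        matrix.provenance.copy(),
    )
    out.validate_canonical()
    return out, n
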