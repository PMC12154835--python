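"""Shared fixtures: small boundary matrices and simulated experiments."""

import numpy as np
import pandas as pd
import pytest

from rtimpute.matrices import RTBoundaryMatrix


def make_boundary_matrix(
    n_peptides: int,
    n_runs: int,
    missing_fraction: float = 0.0,
    seed: int = 0,
    rt_range: tuple[float, float] = (10.0, 80.0),
    width_range: tuple[float, float] = (0.2, 0.6),
) -> RTBoundaryMatrix:
    """Random but valid boundary matrix with a given missingness rate."""
    rng = np.random.default_rng(seed)
    idx = pd.MultiIndex.from_tuples(
        [(_sequence(rng), int(rng.integers(2, 4))) for _ in range(n_peptides)],
        names=["sequence", "charge"],
    )
    cols = [f"run{i:02d}" for i in range(n_runs)]
    apex = rng.uniform(*rt_range, size=(n_peptides, 1)) + rng.normal(
        0, 0.1, size=(n_peptides, n_runs)
    )
    width = rng.uniform(*width_range, size=(n_peptides, 1))
    starts = apex - width / 2
    ends = apex + width / 2
    miss = rng.random((n_peptides, n_runs)) < missing_fraction
    starts[miss] = np.nan
    ends[miss] = np.nan
    return RTBoundaryMatrix(
        pd.DataFrame(starts, index=idx, columns=cols),
        pd.DataFrame(ends, index=idx, columns=cols),
    )


def _sequence(rng) -> str:
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    n = int(rng.integers(7, 13))
    return "".join(rng.choice(aas, size=n)) + "K"


@pytest.fixture(scope="session")
def small_experiment():
    """A compact simulated experiment reused by read-only tests."""
    from rtimpute.simulate import SimConfig, simulate_experiment

    cfg = SimConfig(
        n_runs=12, n_peptides=15, gradient_window=(5.0, 20.0), seed=42
    )
    return simulate_experiment(cfg)
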