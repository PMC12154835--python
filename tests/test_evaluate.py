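"""Evaluation procedures: ratios, hold-out MSE, DA statistics, LLOQ."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtimpute.errors import DesignError
from rtimpute.evaluate import (
    DilutionDesign,
    bh_adjust,
    differential_abundance,
    expected_log_ratio,
    fit_calibration_curve,
    holdout_mse,
    mmcc_deviation,
)
from rtimpute.impute import HoldoutMask
from rtimpute.matrices import PrecursorKey, QuantMatrix

nan = float("nan")


def _quant(rows, runs=None):
    arr = np.asarray(rows, dtype=float)
    idx = pd.MultiIndex.from_tuples(
        [(f"PEPTIDE{chr(65 + i)}K", 2) for i in range(arr.shape[0])],
        names=["sequence", "charge"],
    )
    cols = runs or [f"r{i}" for i in range(arr.shape[1])]
    return QuantMatrix(pd.DataFrame(arr, index=idx, columns=cols))


class TestExpectedLogRatio:
    @pytest.mark.parametrize(
        "d,expected", [(1.0, 0.0), (0.5, -1.0), (0.01, -6.643856)]
    )
    def test_log2_of_dilution(self, d, expected):
        assert expected_log_ratio(d) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("d", [0.0, -0.5, 1.5])
    def test_domain(self, d):
        with pytest.raises(ValueError):
            expected_log_ratio(d)


class TestMmccDeviation:
    def test_exact_ratios_give_zero_deviation(self):
        ref = np.array([100.0, 1000.0, 50.0])
        design = DilutionDesign({"ref": 1.0, "half": 0.5, "tenth": 0.1})
        q = _quant(
            np.column_stack([ref, 0.5 * ref, 0.1 * ref]),
            runs=["ref", "half", "tenth"],
        )
        out = mmcc_deviation(q, design)
        assert np.allclose(out["median_abs_deviation"], 0.0, atol=1e-9)
        assert np.allclose(out["iqr"], 0.0, atol=1e-9)

    def test_single_peptide_hand_arithmetic(self):
        design = DilutionDesign({"ref": 1.0, "quarter": 0.25})
        q = _quant([[100.0, 25.0]], runs=["ref", "quarter"])
        out = mmcc_deviation(q, design)
        assert out.loc[0.25, "median_log_ratio"] == pytest.approx(-2.0)
        assert out.loc[0.25, "median_abs_deviation"] == pytest.approx(0.0)

    def test_missing_reference_peptides_counted(self):
        design = DilutionDesign({"ref": 1.0, "half": 0.5})
        q = _quant([[nan, 10.0], [100.0, 50.0]], runs=["ref", "half"])
        out = mmcc_deviation(q, design)
        assert out.loc[0.5, "n_skipped_no_reference"] == 1
        assert out.loc[0.5, "n_ratios"] == 1

    def test_design_without_reference_rejected(self):
        with pytest.raises(DesignError):
            DilutionDesign({"a": 0.5, "b": 0.1})


class TestHoldoutMse:
    def _mask(self, q, cells):
        return HoldoutMask(
            cells=frozenset(
                (PrecursorKey(*q.precursors[i]), q.runs[j]) for i, j in cells
            ),
            fraction=0.2,
            seed=0,
        )

    def test_perfect_imputation_scores_zero(self):
        q = _quant([[4.0, 8.0], [16.0, 2.0]])
        mask = self._mask(q, [(0, 0), (1, 1)])
        mse, n = holdout_mse(q, q, mask)
        assert mse == 0.0 and n == 2

    def test_hand_computed_log2_example(self):
        truth = _quant([[3.0, 15.0]])
        imputed = _quant([[1.0, 7.0]])
        mask = self._mask(truth, [(0, 0), (0, 1)])
        mse, n = holdout_mse(truth, imputed, mask)
        # log2(4)-log2(2) = 1 and log2(16)-log2(8) = 1 -> mean of squares 1
        assert mse == pytest.approx(1.0)
        assert n == 2

    def test_empty_mask_rejected(self):
        q = _quant([[1.0]])
        with pytest.raises(ValueError):
            holdout_mse(q, q, HoldoutMask(frozenset(), 0.0, 0))


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_step_up_flattens_equal_spacing(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_step_up_hand_example(self):
        q = bh_adjust([0.005, 0.04, 0.9])
        assert np.allclose(q, [0.015, 0.06, 0.9])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_q_dominates_p_and_is_monotone_in_sorted_order(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDifferentialAbundance:
    GROUPS = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
    RUNS = ["a1", "a2", "a3", "b1", "b2", "b3"]

    def test_identical_groups_not_called(self):
        q = _quant([[5.0, 5.0, 5.0, 5.0, 5.0, 5.0]], runs=self.RUNS)
        res = differential_abundance(q, self.GROUPS)
        assert res.table["log2_fc"].iloc[0] == 0.0
        assert res.table["call"].iloc[0] == "none"

    def test_tenfold_change_called_up(self):
        q = _quant(
            [
                [100.0, 110.0, 90.0, 10.0, 11.0, 9.0],
                [50.0, 52.0, 49.0, 50.0, 51.0, 50.0],
            ],
            runs=self.RUNS,
        )
        res = differential_abundance(q, self.GROUPS)
        row = res.table.iloc[0]
        assert row["log2_fc"] == pytest.approx(3.32, abs=0.01)
        assert row["call"] == "up"

    def test_sub_threshold_fold_change_not_called(self):
        # highly significant but log2 fc = 0.9 < 1.0 -> no call
        base = np.array([1000.0, 1010.0, 990.0])
        q = _quant(
            [np.concatenate([base * 2**0.9, base])], runs=self.RUNS
        )
        res = differential_abundance(q, self.GROUPS)
        row = res.table.iloc[0]
        assert row["log2_fc"] == pytest.approx(0.9, abs=1e-6)
        assert row["q_value"] < 0.01
        assert row["call"] == "none"

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(7)
        vals = 2.0 ** rng.normal(10, 1, size=(12, 6))
        q = _quant(vals, runs=self.RUNS)
        res_ab = differential_abundance(q, self.GROUPS)
        swapped = {r: ("B" if g == "A" else "A") for r, g in self.GROUPS.items()}
        res_ba = differential_abundance(q, swapped)
        assert np.allclose(
            res_ab.table["log2_fc"], -res_ba.table["log2_fc"], atol=1e-12
        )
        assert np.allclose(
            res_ab.table["p_value"], res_ba.table["p_value"], atol=1e-12
        )
        flips = {"up": "down", "down": "up", "none": "none"}
        assert [
            flips[c] for c in res_ab.table["call"]
        ] == res_ba.table["call"].tolist()

    def test_underpowered_peptides_reported_unscorable(self):
        q = _quant(
            [[5.0, nan, nan, 4.0, 5.0, 6.0], [3.0, 3.0, 3.0, 2.0, 2.0, 2.0]],
            runs=self.RUNS,
        )
        res = differential_abundance(q, self.GROUPS)
        assert len(res.unscorable) == 1
        assert len(res.table) == 1

    def test_small_group_rejected(self):
        q = _quant([[1.0, 2.0, 3.0]], runs=["a1", "a2", "b1"])
        with pytest.raises(DesignError):
            differential_abundance(q, {"a1": "A", "a2": "A", "b1": "B"})


class TestCalibrationFit:
    CONCS = [1, 2, 5, 10, 20, 50]

    def test_flat_curve_not_quantifiable(self):
        fit = fit_calibration_curve(self.CONCS, [7.0] * 6, seed=0)
        assert math.isinf(fit.lloq)

    def test_noiseless_piecewise_turning_point(self):
        resp = [0.0 if c <= 5 else 2.0 * (c - 5) for c in self.CONCS]
        fit = fit_calibration_curve(self.CONCS, resp, seed=0)
        assert fit.turning_point == 5.0
        assert fit.slope == pytest.approx(2.0)
        assert fit.noise_sd == pytest.approx(0.0)

    def test_lloq_recovered_within_one_dilution_step(self):
        # replicated curve: noise floor below c=5, clean line above; with a
        # 10% response CV the first level where the replicate CV is reliably
        # < 20% is the first linear level
        rng = np.random.default_rng(21)
        conc, resp = [], []
        for c in self.CONCS:
            for _ in range(3):
                conc.append(c)
                signal = 0.0 if c <= 5 else 2.0 * (c - 5)
                resp.append(max(signal * rng.normal(1, 0.10) + rng.normal(0, 0.2), 0.0))
        fit = fit_calibration_curve(conc, resp, seed=21)
        assert fit.quantifiable
        assert fit.lloq in (10, 20)

    def test_lod_not_above_lloq(self):
        rng = np.random.default_rng(5)
        conc = np.repeat(self.CONCS, 3)
        resp = np.maximum(
            [3.0 * max(c - 2, 0) * rng.normal(1, 0.05) + rng.normal(0, 0.5) for c in conc],
            0.0,
        )
        fit = fit_calibration_curve(conc, resp, seed=5)
        if fit.quantifiable and math.isfinite(fit.lod):
            assert fit.lod <= fit.lloq

    def test_lloq_monotone_under_noise_floor_doubling(self):
        # statistical check over seeds: doubling the noise floor never
        # lowers the median LLOQ
        def lloqs(noise_sd, seeds):
            out = []
            for s in seeds:
                rng = np.random.default_rng(s)
                conc, resp = [], []
                for c in self.CONCS:
                    for _ in range(3):
                        conc.append(c)
                        sig = 1.0 * max(c - 2.0, 0.0)
                        resp.append(max(sig + rng.normal(0, noise_sd), 0.0))
                fit = fit_calibration_curve(conc, resp, seed=s)
                out.append(fit.lloq if fit.quantifiable else 1e6)
            return np.array(out)

        seeds = range(25)
        low = lloqs(0.5, seeds)
        high = lloqs(1.0, seeds)
        assert np.median(high) >= np.median(low)

    def test_too_few_levels_rejected(self):
        with pytest.raises(DesignError):
            fit_calibration_curve([1, 2, 5], [0, 1, 2], seed=0)
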