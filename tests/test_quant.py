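import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sterolpath.quant import (
    NOT_APPLICABLE,
    EffectEstimate,
    MeasurementRecord,
    QuantError,
    QuantValue,
    ddct_expression,
    dose_response_table,
    effect_estimate,
    log2fc_matrix,
    paired_t,
    quantify,
    quantify_frame,
)


def _record(peak=2.0, is_signal=1.0, is_amount=0.1, dcw=0.1, **kw):
    defaults = dict(
        sample_id="s1",
        inhibitor="none",
        conc_uM=0.0,
        time_h=48.0,
        analyte="cholesterol",
        peak_signal=peak,
        is_signal=is_signal,
        is_amount_mg=is_amount,
        dcw_g=dcw,
        replicate=1,
    )
    defaults.update(kw)
    return MeasurementRecord(**defaults)


def _qv(value, analyte="cholesterol", detected=True, **kw):
    defaults = dict(
        analyte=analyte, inhibitor="x", conc_uM=100.0, time_h=48.0,
        value_mg_per_g=value, detected=detected,
    )
    defaults.update(kw)
    return QuantValue(**defaults)


class TestQuantify:
    def test_internal_standard_ratio(self):
        q = quantify(_record(peak=2.0, is_signal=1.0, is_amount=0.1, dcw=0.1))
        assert q.value_mg_per_g == pytest.approx(2.0)
        assert q.detected

    def test_zero_peak_below_lod(self):
        q = quantify(_record(peak=0.0))
        assert q.value_mg_per_g == 0.0
        assert not q.detected

    def test_invalid_dcw_rejected(self):
        with pytest.raises(QuantError, match="dry cell weight"):
            _record(dcw=0.0)

    def test_invalid_is_signal_rejected(self):
        with pytest.raises(QuantError, match="internal-standard"):
            _record(is_signal=0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.01, 1e6))
    def test_invariant_under_joint_signal_rescaling(self, factor):
        base = quantify(_record(peak=3.7, is_signal=1.9))
        scaled = quantify(_record(peak=3.7 * factor, is_signal=1.9 * factor))
        assert scaled.value_mg_per_g == pytest.approx(base.value_mg_per_g)


class TestPairedT:
    def test_identical_vectors_degenerate_p_one(self):
        t, df, p, degenerate = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert degenerate and p == 1.0 and df == 2

    def test_constant_nonzero_difference_degenerate(self):
        t, df, p, degenerate = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert degenerate
        assert p == 0.0
        assert np.isinf(t)

    def test_agrees_with_scipy_reference(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.1, 2.4, 2.8])
        t, df, p, _ = paired_t(x, y)
        ref = stats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_agrees_with_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = x + rng.normal(scale=0.5, size=n)
            t, df, p, degenerate = paired_t(x, y)
            ref = stats.ttest_rel(x, y)
            assert not degenerate
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)
            assert df == n - 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(QuantError):
            paired_t([1.0, 2.0], [1.0])


class TestEffectEstimate:
    def test_fold_and_percent_increase(self):
        est = effect_estimate(
            [_qv(4.51), _qv(4.51), _qv(4.51)],
            [_qv(1.0), _qv(1.0), _qv(1.0)],
        )
        assert est.fold_change == pytest.approx(4.51)
        assert est.percent_change == pytest.approx(351.0)

    def test_no_change_gives_unit_fold(self):
        est = effect_estimate([_qv(2.0)], [_qv(2.0)])
        assert est.fold_change == pytest.approx(1.0)
        assert est.percent_change == pytest.approx(0.0)

    def test_percent_decrease(self):
        est = effect_estimate([_qv(35.31)], [_qv(100.0)])
        assert est.percent_change == pytest.approx(-64.69)

    def test_undetected_control_flags_not_applicable(self):
        est = effect_estimate(
            [_qv(1.0)], [_qv(0.0, detected=False)]
        )
        assert est.fold_change is None
        assert est.percent_change == NOT_APPLICABLE
        assert est.control_below_lod

    def test_reciprocal_folds_multiply_to_one(self):
        a = [_qv(v) for v in (2.0, 2.1, 1.9)]
        b = [_qv(v) for v in (0.5, 0.55, 0.45)]
        f1 = effect_estimate(a, b).fold_change
        f2 = effect_estimate(b, a).fold_change
        assert f1 * f2 == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(0.01, 1e3), st.floats(0.01, 1e3))
    def test_percent_fold_identity_holds(self, t_val, c_val):
        est = effect_estimate([_qv(t_val)], [_qv(c_val)])
        assert est.percent_change == pytest.approx((est.fold_change - 1) * 100)


class TestDdctExpression:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "gene", "ref_gene", "inhibitor", "conc_uM", "time_h",
                "ct_target", "ct_ref", "replicate",
            ],
        )

    def test_zero_ddct_gives_unit_expression(self):
        df = self._frame(
            [
                ("g", "act", "none", 0.0, 48.0, 22.0, 16.0, 1),
                ("g", "act", "drug", 50.0, 48.0, 22.0, 16.0, 1),
            ]
        )
        (res,) = ddct_expression(df)
        assert res.rel_expr == pytest.approx(1.0)
        assert res.log2_fc == pytest.approx(0.0)

    def test_two_cycle_shift_gives_fourfold(self):
        df = self._frame(
            [
                ("g", "act", "none", 0.0, 48.0, 22.0, 16.0, 1),
                ("g", "act", "drug", 50.0, 48.0, 20.0, 16.0, 1),
            ]
        )
        (res,) = ddct_expression(df)
        assert res.rel_expr == pytest.approx(4.0)
        assert res.log2_fc == pytest.approx(2.0)

    def test_condition_swap_antisymmetry(self):
        rows = [
            ("g", "act", "none", 0.0, 48.0, 21.3, 16.0, 1),
            ("g", "act", "drug", 50.0, 48.0, 19.9, 16.1, 1),
        ]
        (fwd,) = ddct_expression(self._frame(rows))
        swapped = [
            (g, r, "drug" if inh == "none" else "none",
             50.0 if inh == "none" else 0.0, t, ct, cr, rep)
            for g, r, inh, c, t, ct, cr, rep in rows
        ]
        (rev,) = ddct_expression(self._frame(swapped))
        assert fwd.rel_expr * rev.rel_expr == pytest.approx(1.0)
        assert fwd.log2_fc == pytest.approx(np.log2(fwd.rel_expr))

    def test_missing_control_rejected(self):
        df = self._frame([("g", "act", "drug", 50.0, 48.0, 20.0, 16.0, 1)])
        with pytest.raises(QuantError, match="control"):
            ddct_expression(df)


class TestDoseResponse:
    def _table(self, analyte_values: dict[str, dict[float, float]], n=3):
        rows = []
        for analyte, by_conc in analyte_values.items():
            for conc, value in by_conc.items():
                for rep in range(1, n + 1):
                    rows.append(
                        {
                            "inhibitor": "drug" if conc else "none",
                            "conc_uM": conc,
                            "time_h": 48.0,
                            "analyte": analyte,
                            "value_mg_per_g": value,
                            "detected": value > 0,
                            "replicate": rep,
                        }
                    )
        return pd.DataFrame(rows)

    def test_decreasing_series_annotated(self):
        table = self._table({"squalene": {0.0: 1.0, 20.0: 0.7, 50.0: 0.4, 100.0: 0.1}})
        eff = dose_response_table(table)
        assert list(eff.conc_uM) == [20.0, 50.0, 100.0]
        assert (eff.trend == "decreasing").all()

    def test_flat_series_has_no_significance(self):
        table = self._table({"sterol": {0.0: 1.0, 20.0: 1.0, 100.0: 1.0}})
        eff = dose_response_table(table)
        assert (eff.percent_change == 0.0).all()
        assert not eff.significant_05.any()

    def test_single_concentration_single_row(self):
        eff = dose_response_table(self._table({"x": {0.0: 1.0, 2.0: 0.5}}))
        assert len(eff) == 1
        assert eff.trend.iloc[0] == "single"

    def test_missing_control_rejected(self):
        with pytest.raises(QuantError, match="control"):
            dose_response_table(self._table({"x": {2.0: 0.5}}))


def test_quantify_frame_matches_scalar_quantify():
    df = pd.DataFrame(
        [
            {
                "sample_id": "s1", "inhibitor": "none", "conc_uM": 0.0,
                "time_h": 48.0, "analyte": "a", "peak_signal": 2.0,
                "is_signal": 1.0, "is_amount_mg": 0.1, "dcw_g": 0.1,
                "replicate": 1,
            }
        ]
    )
    out = quantify_frame(df)
    assert out.value_mg_per_g.iloc[0] == pytest.approx(2.0)


def test_log2fc_matrix_shape():
    from sterolpath.quant import ExpressionResult

    results = [
        ExpressionResult("g1", "drug", 50.0, t, ddct=-1.0, rel_expr=2.0,
                         log2_fc=1.0, n=3)
        for t in (12.0, 24.0)
    ] + [
        ExpressionResult("g2", "drug", 50.0, 12.0, ddct=2.0, rel_expr=0.25,
                         log2_fc=-2.0, n=3)
    ]
    mat = log2fc_matrix(results)
    assert mat.shape == (2, 2)
    assert mat.loc["g1", 12.0] == 1.0
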