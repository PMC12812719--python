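"""Surrogate-index formulas, undefined-value propagation, and scaling laws."""

import numpy as np
import pandas as pd
import pytest

from glycoprog import (OGTTRecord, compute_deltas, compute_indices,
                       delta_decline, disposition_index, homa_beta, homa_ir,
                       homa_is, igi60, matsuda_index, merge_model_derived,
                       percent_decline, trapezoid_mean)


def rec(g, i, hba1c=None):
    return OGTTRecord(g0=g[0], g60=g[1], g120=g[2],
                      i0=i[0], i60=i[1], i120=i[2], hba1c=hba1c)


class TestTrapezoidMean:
    @pytest.mark.parametrize("v, expected", [
        ((100, 100, 100), 100.0),
        ((80, 120, 100), 105.0),   # (80 + 2*120 + 100)/4
        ((0, 0, 0), 0.0),
    ])
    def test_values(self, v, expected):
        assert trapezoid_mean(*v) == pytest.approx(expected)

    def test_matches_numeric_quadrature(self, rng):
        for _ in range(200):
            v = rng.uniform(1, 300, size=3)
            auc = np.trapezoid(v, x=[0.0, 60.0, 120.0])
            assert trapezoid_mean(*v) == pytest.approx(auc / 120.0, rel=1e-12)

    def test_absent_value_undefined(self):
        assert trapezoid_mean(100, None, 100) is None

    def test_negative_is_error(self):
        with pytest.raises(ValueError):
            trapezoid_mean(-1, 2, 3)


class TestMatsuda:
    def test_collapsed_case(self):
        assert matsuda_index(rec((100, 100, 100), (1, 1, 1))) == pytest.approx(100.0)

    def test_worked_example(self):
        # Gbar = 105, Ibar = 22.75; 10000/sqrt(105*22.75*7*80)
        m = matsuda_index(rec((80, 120, 100), (7, 30, 24)))
        assert m == pytest.approx(10000 / np.sqrt(105 * 22.75 * 7 * 80), rel=1e-12)
        assert m == pytest.approx(8.646, abs=5e-4)

    def test_absent_input_undefined(self):
        assert matsuda_index(rec((80, 120, 100), (7, None, 24))) is None

    def test_antitone_in_every_argument(self, rng):
        for _ in range(200):
            g = rng.uniform(60, 250, size=3)
            i = rng.uniform(2, 80, size=3)
            m0 = matsuda_index(rec(g, i))
            k = rng.integers(0, 6)
            bump = rng.uniform(1, 30)
            g2, i2 = g.copy(), i.copy()
            if k < 3:
                g2[k] += bump
            else:
                i2[k - 3] += bump
            assert matsuda_index(rec(g2, i2)) < m0

    def test_scaling_all_values_by_c_scales_by_inverse_c_squared(self, rng):
        g = np.array([85.0, 140.0, 120.0])
        i = np.array([8.0, 40.0, 30.0])
        m = matsuda_index(rec(g, i))
        for c in (0.5, 2.0, 3.7):
            assert matsuda_index(rec(c * g, c * i)) == pytest.approx(m / c**2, rel=1e-10)


class TestHOMA:
    @pytest.mark.parametrize("g0,i0,expect_is", [(81, 5, 1.0), (90, 9, 0.5)])
    def test_homa_is_values(self, g0, i0, expect_is):
        assert homa_is(g0, i0) == pytest.approx(expect_is)

    def test_reciprocal_identity(self, rng):
        for _ in range(100):
            g0 = float(rng.uniform(60, 200))
            i0 = float(rng.uniform(1, 60))
            assert homa_is(g0, i0) * homa_ir(g0, i0) == pytest.approx(1.0, rel=1e-12)

    def test_absent_undefined(self):
        assert homa_is(None, 5) is None
        assert homa_ir(90, None) is None

    @pytest.mark.parametrize("g0,i0,expected", [(99, 10, 100.0), (81, 5, 100.0)])
    def test_homa_beta_values(self, g0, i0, expected):
        assert homa_beta(g0, i0) == pytest.approx(expected)

    def test_homa_beta_boundary_undefined(self):
        assert homa_beta(63, 10) is None
        assert homa_beta(50, 10) is None


class TestIGI:
    def test_worked_example(self):
        assert igi60(rec((80, 110, None), (7, 31, None))) == pytest.approx(0.8)

    def test_zero_increment(self):
        assert igi60(rec((80, 110, None), (9, 9, None))) == 0.0

    def test_flat_glucose_undefined(self):
        assert igi60(rec((90, 90, None), (7, 30, None))) is None

    def test_invariant_under_insulin_shift(self, rng):
        for _ in range(50):
            g = (80.0, float(rng.uniform(90, 200)), None)
            i0, i60 = float(rng.uniform(2, 30)), float(rng.uniform(2, 90))
            shift = float(rng.uniform(-1, 20))
            a = igi60(rec(g, (i0, i60, None)))
            b = igi60(rec(g, (i0 + shift, i60 + shift, None)))
            assert a == pytest.approx(b, rel=1e-12)


class TestDispositionAndDeltas:
    def test_product_of_worked_values(self):
        m = matsuda_index(rec((80, 120, 100), (7, 30, 24)))
        assert disposition_index(m, 0.8) == pytest.approx(6.917, abs=5e-4)

    def test_zero_and_identity(self):
        assert disposition_index(3.2, 0) == 0
        assert disposition_index(1, 2.5) == 2.5
        assert disposition_index(None, 1.0) is None

    @pytest.mark.parametrize("b,y,expected", [
        (1.39, 1.15, 0.24),    # published non-progressor mSI change
        (0.29, 0.16, 0.13),    # published T2D-progressor mBCF change
        (2.0, 2.0, 0.0),
    ])
    def test_delta_decline(self, b, y, expected):
        assert delta_decline(b, y) == pytest.approx(expected)

    @pytest.mark.parametrize("b,y,expected", [
        (1.0, 0.5, 50.0),
        (3.3, 3.3, 0.0),
        (1.28, 0.69, 100 * (1.28 - 0.69) / 1.28),  # ~46.1 from rounded means
    ])
    def test_percent_decline(self, b, y, expected):
        assert percent_decline(b, y) == pytest.approx(expected)

    def test_percent_decline_needs_positive_baseline(self):
        assert percent_decline(0.0, 1.0) is None
        assert percent_decline(-1.0, 1.0) is None

    def test_decline_measures_agree_in_sign(self, rng):
        for _ in range(100):
            b = float(rng.uniform(0.1, 5))
            y = float(rng.uniform(-1, 5))
            assert np.sign(delta_decline(b, y)) == np.sign(percent_decline(b, y))


class TestVectorizedCohortAPI:
    def test_matches_scalar_functions(self, rng):
        n = 200
        df = pd.DataFrame({
            "id": [f"P{k}" for k in range(n)], "visit_index": 0,
            "g0": rng.uniform(64, 200, n), "g60": rng.uniform(70, 300, n),
            "g120": rng.uniform(60, 280, n), "i0": rng.uniform(1, 50, n),
            "i60": rng.uniform(2, 120, n), "i120": rng.uniform(2, 100, n),
        })
        out = compute_indices(df)
        for k in rng.integers(0, n, size=20):
            r = rec((df.g0[k], df.g60[k], df.g120[k]),
                    (df.i0[k], df.i60[k], df.i120[k]))
            assert out.matsuda[k] == pytest.approx(matsuda_index(r), rel=1e-12)
            assert out.igi60[k] == pytest.approx(igi60(r), rel=1e-12)
            assert out.homa_beta[k] == pytest.approx(homa_beta(df.g0[k], df.i0[k]), rel=1e-12)

    def test_nan_propagation(self):
        df = pd.DataFrame({"id": ["A"], "visit_index": [0], "g0": [90.0],
                           "g60": [np.nan], "g120": [110.0], "i0": [7.0],
                           "i60": [25.0], "i120": [20.0]})
        out = compute_indices(df)
        assert np.isnan(out.matsuda[0]) and np.isnan(out.igi60[0])
        assert np.isfinite(out.homa_is[0])

    def test_deltas_and_external_measures(self):
        df = pd.DataFrame({
            "id": ["A", "A", "B", "B"], "visit_index": [0, 5, 0, 5],
            "g0": [80.0, 90, 85, 95], "g60": [120.0, 150, 130, 160],
            "g120": [100.0, 130, 110, 138], "i0": [7.0, 9, 6, 8],
            "i60": [30.0, 28, 26, 25], "i120": [24.0, 23, 20, 21],
            "msi": [1.4, 1.1, 1.2, 0.8], "mbcf": [0.5, 0.45, 0.4, 0.3],
        })
        out = compute_indices(df)
        d = compute_deltas(out, measures="external")
        d = d.set_index("id")
        assert d.loc["A", "dis"] == pytest.approx(0.3)
        assert d.loc["B", "dbcf"] == pytest.approx(0.1)
        d2 = compute_deltas(out, measures="matsuda-igi").set_index("id")
        a0 = matsuda_index(rec((80, 120, 100), (7, 30, 24)))
        a5 = matsuda_index(rec((90, 150, 130), (9, 28, 23)))
        assert d2.loc["A", "dis"] == pytest.approx(a0 - a5, rel=1e-12)

    def test_merge_model_derived_recomputes_mdi(self):
        df = pd.DataFrame({"id": ["A"], "visit_index": [0], "g0": [80.0],
                           "g60": [120.0], "g120": [100.0], "i0": [7.0],
                           "i60": [30.0], "i120": [24.0]})
        ext = pd.DataFrame({"id": ["A"], "visit_index": [0],
                            "msi": [1.3], "mbcf": [0.4]})
        merged = merge_model_derived(compute_indices(df), ext)
        assert merged.mdi[0] == pytest.approx(0.52)

    def test_unknown_measure_pair_is_error(self):
        with pytest.raises(ValueError, match="unknown measure"):
            compute_deltas(pd.DataFrame({"id": [], "visit_index": []}),
                           measures="bogus")
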