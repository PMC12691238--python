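"""Unit conversion, validity domains, and equation-oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedlipid import (
    Analyte,
    LdlMethod,
    LipidPanel,
    convert_concentration,
    estimate_all,
    friedewald_ldl,
    non_hdl,
    sampson_ldl,
)


def sampson_oracle(tc, hdl, tg):
    """Independent term-by-term evaluation of the Sampson-NIH polynomial."""
    t1 = tc / 0.948
    t2 = hdl / 0.971
    t3 = tg / 8.56
    t4 = (tg * (tc - hdl)) / 2140.0
    t5 = (tg ** 2) / 16100.0
    return t1 - t2 - (t3 + t4 - t5) - 9.44


def friedewald_oracle(tc, hdl, tg):
    return tc - hdl - tg / 5.0


class TestConversion:
    @pytest.mark.parametrize(
        "value,analyte,expected",
        [
            (38.67, Analyte.CHOLESTEROL, 1.0),
            (88.57, Analyte.TRIGLYCERIDE, 1.0),
            (153.0, Analyte.CHOLESTEROL, 153.0 / 38.67),  # 3.957
        ],
    )
    def test_to_mmol(self, value, analyte, expected):
        assert convert_concentration(value, analyte, "mg/dL", "mmol/L") == pytest.approx(
            expected, abs=5e-4
        )

    @given(
        value=st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
        analyte=st.sampled_from(list(Analyte)),
    )
    @settings(derandomize=True, max_examples=100)
    def test_round_trip(self, value, analyte):
        back = convert_concentration(
            convert_concentration(value, analyte, "mg/dL", "mmol/L"),
            analyte,
            "mmol/L",
            "mg/dL",
        )
        assert back == pytest.approx(value, rel=1e-9, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            convert_concentration(-1.0, Analyte.CHOLESTEROL, "mg/dL", "mmol/L")


class TestNonHdl:
    def test_values(self):
        assert non_hdl(153, 54) == 99
        assert non_hdl(150, 1e-12) == pytest.approx(150)

    def test_hdl_at_least_tc_rejected(self):
        with pytest.raises(ValueError):
            non_hdl(50, 60)
        with pytest.raises(ValueError):
            non_hdl(50, 50)


class TestFriedewald:
    def test_worked_value(self):
        est = friedewald_ldl(153, 54, 81)
        assert est.value == pytest.approx(82.8)
        assert est.valid and est.method is LdlMethod.FRIEDEWALD

    def test_zero_tg_limit_is_non_hdl(self):
        # TG -> 0 reduces the formula to non-HDL cholesterol
        assert friedewald_ldl(160, 50, 1e-9).value == pytest.approx(110.0)

    def test_tg_domain(self):
        est = friedewald_ldl(160, 50, 401)
        assert not est.valid and est.reason == "TG>400"
        assert est.value == pytest.approx(160 - 50 - 401 / 5)
        assert friedewald_ldl(160, 50, 400).valid  # boundary itself is valid

    def test_nonpositive_flagged_unclipped(self):
        est = friedewald_ldl(100, 60, 250)
        assert est.value == pytest.approx(-10.0)
        assert not est.valid and est.reason == "nonpositive"

    def test_nonpositive_inputs_rejected(self):
        for bad in [(0, 50, 80), (160, 0, 80), (160, 50, 0)]:
            with pytest.raises(ValueError):
                friedewald_ldl(*bad)

    def test_monotonicity_grid(self):
        tcs = np.linspace(100, 250, 7)
        hdls = np.linspace(30, 80, 6)
        tgs = np.linspace(40, 390, 8)
        for hdl in hdls:
            for tg in tgs:
                vals = [friedewald_ldl(tc, hdl, tg).value for tc in tcs]
                assert all(a < b for a, b in zip(vals, vals[1:])), "increasing in TC"
        for tc in tcs:
            for tg in tgs:
                vals = [friedewald_ldl(tc, hdl, tg).value for hdl in hdls]
                assert all(a > b for a, b in zip(vals, vals[1:])), "decreasing in HDL"
            for hdl in hdls:
                vals = [friedewald_ldl(tc, hdl, tg).value for tg in tgs]
                assert all(a > b for a, b in zip(vals, vals[1:])), "decreasing in TG"

    def test_unit_system_consistency(self, rng):
        # computing in mmol/L with the conventional 2.2 divisor, then converting
        # back, agrees within 1 mg/dL (2.2 is a rounded 88.57/38.67 * 5)
        for _ in range(200):
            tc = rng.uniform(90, 260)
            hdl = rng.uniform(25, min(85, tc - 30))
            # keep the calculated value positive so both unit systems apply
            tg = rng.uniform(30, min(400, 5 * (tc - hdl - 5)))
            mgdl = friedewald_ldl(tc, hdl, tg).value
            tc_m = convert_concentration(tc, Analyte.CHOLESTEROL, "mg/dL", "mmol/L")
            hdl_m = convert_concentration(hdl, Analyte.CHOLESTEROL, "mg/dL", "mmol/L")
            tg_m = convert_concentration(tg, Analyte.TRIGLYCERIDE, "mg/dL", "mmol/L")
            via_mmol = convert_concentration(
                tc_m - hdl_m - tg_m / 2.2, Analyte.CHOLESTEROL, "mmol/L", "mg/dL"
            )
            assert abs(via_mmol - mgdl) < 1.0


class TestSampson:
    def test_worked_value(self):
        assert sampson_ldl(153, 54, 81).value == pytest.approx(83.54, abs=5e-3)

    def test_constant_term_only(self):
        # degenerate all-zero inputs isolate the constant: evaluate the raw
        # polynomial (the public function rejects non-positive inputs)
        assert sampson_oracle(0.0, 0.0, 0.0) == pytest.approx(-9.44)

    def test_tg_domain(self):
        est = sampson_ldl(160, 50, 801)
        assert not est.valid and est.reason == "TG>800"
        assert sampson_ldl(160, 50, 800).valid
        assert sampson_ldl(160, 50, 500).valid  # Friedewald-invalid, Sampson-valid

    def test_oracle_equivalence_random_panels(self, rng):
        for _ in range(1000):
            tc = rng.uniform(80, 300)
            hdl = rng.uniform(20, min(100, tc - 26))
            tg = rng.uniform(20, 800)
            assert sampson_ldl(tc, hdl, tg).value == pytest.approx(
                sampson_oracle(tc, hdl, tg), abs=1e-9
            )
            assert friedewald_ldl(tc, hdl, tg).value == pytest.approx(
                friedewald_oracle(tc, hdl, tg), abs=1e-9
            )

    def test_close_to_friedewald_at_median_panel(self):
        f = friedewald_ldl(153, 54, 81).value
        s = sampson_ldl(153, 54, 81).value
        assert abs(s - f) < 2.0


class TestEstimateAll:
    def test_three_methods_with_direct(self, median_panel):
        ests = {e.method: e for e in estimate_all(median_panel)}
        assert set(ests) == {LdlMethod.DIRECT, LdlMethod.FRIEDEWALD, LdlMethod.SAMPSON}
        assert ests[LdlMethod.DIRECT].value == 95.0 and ests[LdlMethod.DIRECT].valid
        assert ests[LdlMethod.FRIEDEWALD].value == pytest.approx(82.8)
        assert ests[LdlMethod.SAMPSON].value == pytest.approx(83.54, abs=5e-3)

    def test_direct_omitted_when_missing(self, caplog):
        panel = LipidPanel("x", "boy", 10, tc=160, hdl=50, tg=500)
        ests = estimate_all(panel)
        assert len(ests) == 2
        by_method = {e.method: e for e in ests}
        assert not by_method[LdlMethod.FRIEDEWALD].valid  # 400 < 500
        assert by_method[LdlMethod.SAMPSON].valid  # 500 < 800


class TestLipidPanel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LipidPanel("a", "girl", 5, tc=100, hdl=100, tg=50)
        with pytest.raises(ValueError):
            LipidPanel("a", "girl", -1, tc=100, hdl=50, tg=50)
        with pytest.raises(ValueError):
            LipidPanel("a", "girl", 5, tc=100, hdl=50, tg=0)
        with pytest.raises(ValueError):
            LipidPanel("a", "girl", 5, tc=100, hdl=50, tg=50, ldl_direct=0)

    def test_non_hdl_property(self, median_panel):
        assert median_panel.non_hdl == 99.0
        assert math.isclose(median_panel.non_hdl, non_hdl(median_panel.tc, median_panel.hdl))
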