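"""Degradation pharmacology: % inhibition, 4PL, ratiometric, V/D window."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpdscreen.dose_response import (
    dual_reporter_ratio,
    fit_4pl,
    fit_flow_table,
    percent_inhibition,
    ratiometric_degradation,
    vd_score,
    viability_from_gate,
)
from tpdscreen.exceptions import FitError, ValidationError
from tpdscreen.synthetic_screen import (
    four_pl,
    simulate_dose_response,
    simulate_flow_ratiometric,
)

DOSES = np.array([0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0])


class TestPercentInhibition:
    def test_anchor_points(self):
        assert percent_inhibition(100.0, 100.0, 0.0) == 0.0
        assert percent_inhibition(0.0, 100.0, 0.0) == 100.0
        assert percent_inhibition(25.0, 100.0, 0.0) == 75.0
        # out-of-range samples are not clipped
        assert percent_inhibition(-10.0, 100.0, 0.0) == pytest.approx(110.0)
        with pytest.raises(ValidationError):
            percent_inhibition(1.0, 5.0, 5.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-50, max_value=50),
        s=st.floats(min_value=-1, max_value=2),
    )
    def test_affine_invariance(self, a, b, s):
        high, low = 100.0, 10.0
        sample = low + s * (high - low)
        base = percent_inhibition(sample, high, low)
        moved = percent_inhibition(a * sample + b, a * high + b, a * low + b)
        assert moved == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestFit4PL:
    def test_exact_data_round_trip(self):
        y = four_pl(DOSES, 0.1, 1.0, 0.09, 1.0)
        fit = fit_4pl(DOSES, y)
        assert fit.bottom == pytest.approx(0.1, rel=1e-6)
        assert fit.top == pytest.approx(1.0, rel=1e-6)
        assert fit.ec50 == pytest.approx(0.09, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.dmax == pytest.approx(0.9, rel=1e-6)
        # inflection identity on the fitted curve
        assert fit.predict(fit.ec50) == pytest.approx(
            (fit.top + fit.bottom) / 2, rel=1e-9)

    def test_abs_dc50_crosses_half_of_control(self):
        y = four_pl(DOSES, 0.1, 1.0, 0.09, 1.0)
        fit = fit_4pl(DOSES, y)
        assert fit.abs_dc50 is not None
        assert fit.predict(fit.abs_dc50) == pytest.approx(0.5, abs=1e-9)
        assert fit.bottom < 0.5 < fit.top
        # curve that never reaches 50% of control: abs DC50 absent
        shallow = four_pl(DOSES, 0.7, 1.0, 0.09, 1.0)
        assert fit_4pl(DOSES, shallow).abs_dc50 is None

    def test_ascending_data_canonicalized(self):
        y = four_pl(DOSES, 0.0, 1.0, 0.05, -1.2)  # rises with dose
        fit = fit_4pl(DOSES, y)
        assert fit.bottom <= fit.top
        assert fit.hill == pytest.approx(-1.2, rel=1e-5)
        assert fit.ec50 == pytest.approx(0.05, rel=1e-5)

    def test_input_validation(self):
        with pytest.raises(FitError):
            fit_4pl([1.0, 2.0, 3.0], [1.0, 0.5, 0.1])
        with pytest.raises(ValidationError):
            fit_4pl([0.0, 1.0, 2.0, 3.0], [1, 1, 1, 1])

    def test_noisy_recovery_is_mostly_within_ten_percent(self):
        ok = 0
        for seed in range(50):
            tab = simulate_dose_response(0.1, 1.0, 0.09, 2.0, DOSES,
                                         cv=0.05, n_rep=3, seed=seed)
            fit = fit_4pl(tab.dose.to_numpy(), tab.response.to_numpy())
            ok += abs(fit.ec50 - 0.09) / 0.09 <= 0.10
        assert ok >= 45  # full 200-seed study runs in the acceptance suite


class TestRatiometric:
    def test_dmso_equals_no_degradation(self):
        assert ratiometric_degradation(1100.0, 2150.0, 100.0, 150.0,
                                       dmso_ratio=0.5) == pytest.approx(0.0)

    def test_background_only_gfp_is_full_degradation(self):
        assert ratiometric_degradation(100.0, 2150.0, 100.0, 150.0,
                                       dmso_ratio=0.5) == pytest.approx(1.0)

    def test_medians_before_ratio(self):
        gfp = [1100.0, 1150.0, 900.0]
        mch = [2150.0, 2100.0, 2300.0]
        expected = 1 - ((np.median(gfp) - 100) / (np.median(mch) - 150)) / 0.5
        assert ratiometric_degradation(gfp, mch, 100.0, 150.0, 0.5) == (
            pytest.approx(expected))

    def test_mcherry_below_background_flagged_nan(self):
        assert np.isnan(
            ratiometric_degradation(500.0, 100.0, 100.0, 150.0, 0.5))

    def test_generator_consistency_at_dc50(self):
        doses = np.sort(np.append(np.geomspace(1e-3, 30, 10), 0.09))
        tab = simulate_flow_ratiometric(0.09, 1.20, doses, dmax=0.95,
                                        cv=0, seed=0)
        row = tab.loc[tab.dose == 0.09].iloc[0]
        dmso = tab.iloc[0]
        dmso_ratio = (dmso.median_gfp - 100) / (dmso.median_mch - 150)
        deg = ratiometric_degradation(row.median_gfp, row.median_mch,
                                      100.0, 150.0, dmso_ratio)
        # the DMSO anchor at the lowest dose is itself slightly degraded,
        # hence the loose tolerance
        assert deg == pytest.approx(0.95 / 2, rel=0.05)


class TestViabilityGate:
    def test_relative_viability_and_floor(self):
        rel, ok = viability_from_gate(450, 1000, dmso_fraction=0.45)
        assert rel == pytest.approx(1.0) and ok
        rel, ok = viability_from_gate(90, 1000, dmso_fraction=0.45)
        assert rel == pytest.approx(0.2) and not ok  # below the 25% floor
        with pytest.raises(ValidationError):
            viability_from_gate(10, 0, 0.45)

    def test_monotone_toxicity_excludes_a_suffix(self):
        doses = np.geomspace(0.01, 30, 10)
        viable = four_pl(doses, 0.02, 0.9, 1.0, 1.0)
        flags = [viability_from_gate(v * 1000, 1000, 0.9)[1] for v in viable]
        # once a dose fails the floor, all higher doses fail too
        first_fail = flags.index(False)
        assert not any(flags[first_fail:])


class TestVDWindow:
    def test_paper_style_arithmetic(self):
        win = vd_score(1.20, 0.09, top_dose=25.0)
        assert win.vd_score == pytest.approx(1.20 / 0.09)  # = 13.3
        assert not win.gi50_fallback_used and not win.dc50_fallback_used

    def test_top_dose_fallbacks(self):
        win = vd_score(None, 0.01, top_dose=25.0)
        assert win.vd_score == pytest.approx(2500.0)
        assert win.gi50_fallback_used
        # inhibitor: toxicity without degradation gives a window < 1
        win = vd_score(7.5, None, top_dose=25.0)
        assert win.vd_score == pytest.approx(0.3)
        assert win.dc50_fallback_used
        both = vd_score(None, None, top_dose=25.0)
        assert both.vd_score == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        base = vd_score(1.20, 0.09, 25.0).vd_score
        scaled = vd_score(1.20 * c, 0.09 * c, 25.0 * c).vd_score
        assert scaled == pytest.approx(base, rel=1e-12)


class TestDualReporter:
    def test_identities(self):
        assert dual_reporter_ratio(100, 200, 100, 200) == 1.0
        assert dual_reporter_ratio(50, 200, 100, 200) == 0.5
        with pytest.raises(ValidationError):
            dual_reporter_ratio(0, 200, 100, 200)


def test_flow_workflow_recovers_window():
    doses = np.geomspace(3e-4, 25, 11)
    tab = simulate_flow_ratiometric(0.09, 1.20, doses, cv=0.05, seed=11)
    deg_fit, viab_fit, window = fit_flow_table(tab, bg_gfp=100.0, bg_mch=150.0)
    assert deg_fit.rel_dc50 == pytest.approx(0.09, rel=0.25)
    assert window.vd_score == pytest.approx(1.20 / 0.09, rel=0.15)
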