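"""Firefly QC gate, plate polynomial normalization, robust z."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpdscreen.exceptions import ConfigError, FitError, ValidationError
from tpdscreen.qc_normalize import (
    MIN_LOG10_RATIO,
    NormalizedWell,
    firefly_qc,
    fit_plate_polynomial,
    normalize_screen,
    normalize_wells,
    robust_zscore,
)
from tpdscreen.screen_io import PlateWell
from tpdscreen.synthetic_screen import ScreenSimConfig, simulate_screen


def lib_well(well_id, firefly, hibit=100.0, gene="G1"):
    return PlateWell("P1", "R1", well_id, gene, ["sg1"], "library", hibit, firefly)


def ctrl_well(well_id, firefly):
    return PlateWell("P1", "R1", well_id, "", [], "media_ctrl", 5.0, firefly)


class TestFireflyQC:
    def test_threshold_is_ratio_to_control_median(self):
        # reference 1000: 1200 RLU (ratio log10 1.2 = 0.0792) fails the
        # log10(1.25) = 0.0969 gate, 1300 RLU (0.1139) passes
        wells = [
            ctrl_well("A01", 1000.0),
            lib_well("B01", 1200.0, gene="G1"),
            lib_well("B02", 1300.0, gene="G2"),
            lib_well("B03", 1000.0, gene="G3"),
        ]
        out = {w.well_id: w for w in firefly_qc(wells)}
        assert out["B01"].firefly_log10_ratio == pytest.approx(
            math.log10(1.2))
        assert not out["B01"].qc_pass
        assert out["B02"].firefly_log10_ratio == pytest.approx(
            math.log10(1.3))
        assert out["B02"].qc_pass
        # firefly equal to the reference: log10(1) = 0 < threshold
        assert not out["B03"].qc_pass

    def test_plate_without_controls_errors(self):
        with pytest.raises(ConfigError):
            firefly_qc([lib_well("A01", 500.0)])

    def test_qc_monotone_in_threshold(self):
        wells = [ctrl_well("A01", 1000.0)] + [
            lib_well(f"B{i:02d}", f, gene=f"G{i}")
            for i, f in enumerate([1100, 1300, 2000, 5000], start=1)
        ]
        passing = []
        for thr in [MIN_LOG10_RATIO, 0.2, 0.5]:
            out = firefly_qc(wells, min_log10_ratio=thr)
            passing.append({w.well_id for w in out if w.qc_pass})
        assert passing[0] >= passing[1] >= passing[2]


class TestPlatePolynomial:
    def test_exact_cubic_recovered(self):
        # wells lying exactly on y = 2x^3 + x
        xs = np.linspace(1.0, 10.0, 25)
        wells = [
            NormalizedWell("P1", "R1", f"A{i + 1:02d}" if i < 24 else "B01",
                           f"G{i}", "library", float(2 * x**3 + x), float(x),
                           qc_pass=True)
            for i, x in enumerate(xs)
        ]
        poly = fit_plate_polynomial(wells, robustify=False)
        assert np.allclose(poly.coefficients, (0.0, 1.0, 0.0, 2.0),
                           rtol=1e-10, atol=1e-8)
        assert poly.fit_domain == (1.0, 10.0)

    def test_robust_refit_resists_displaced_wells(self):
        rng = np.random.default_rng(0)
        xs = rng.uniform(1.0, 10.0, 200)
        ys = 5.0 + 3.0 * xs + 0.1 * xs**3
        ys = ys * (1 + rng.normal(0, 0.02, xs.size))
        shifted = rng.choice(xs.size, size=10, replace=False)
        ys[shifted] *= 10.0  # 5% of wells displaced upward tenfold
        wells = [
            NormalizedWell("P1", "R1", "A01", f"G{i}", "library",
                           float(y), float(x), qc_pass=True)
            for i, (x, y) in enumerate(zip(xs, ys))
        ]
        clean = np.delete(np.arange(xs.size), shifted)
        robust = fit_plate_polynomial(wells, robustify=True)
        plain = fit_plate_polynomial(wells, robustify=False)

        def med_abs_resid(poly):
            pred = np.array([poly.predict(x)[0] for x in xs[clean]])
            return np.median(np.abs(ys[clean] - pred))

        assert med_abs_resid(robust) < med_abs_resid(plain)

    def test_degenerate_designs_error(self):
        wells = [
            NormalizedWell("P1", "R1", "A01", f"G{i}", "library", 10.0, 5.0,
                           qc_pass=True)
            for i in range(10)
        ]
        with pytest.raises(FitError, match="singular|equal"):
            fit_plate_polynomial(wells)
        with pytest.raises(FitError):
            fit_plate_polynomial(wells[:3])


class TestNormalizeWells:
    def test_rel_change_is_observed_over_predicted(self):
        xs = np.linspace(1, 30, 30)
        wells = [
            NormalizedWell("P1", "R1", "A01", f"G{i}", "library",
                           float(10 * x), float(x), qc_pass=True)
            for i, x in enumerate(xs)
        ]
        poly = fit_plate_polynomial(wells, robustify=False)
        target = NormalizedWell("P1", "R1", "B01", "GX", "library",
                                500.0, 15.0, qc_pass=True)
        normalize_wells([target], {("P1", "R1"): poly})
        assert target.predicted_hibit == pytest.approx(150.0)
        assert target.rel_change == pytest.approx(500.0 / 150.0)
        same = NormalizedWell("P1", "R1", "B02", "GY", "library",
                              150.0, 15.0, qc_pass=True)
        normalize_wells([same], {("P1", "R1"): poly})
        assert same.rel_change == pytest.approx(1.0)

    def test_noise_free_simulation_normalizes_exactly(self):
        # cubic generator + cubic normalizer: rel_change is constant across
        # non-hit wells to machine precision
        cfg = ScreenSimConfig(
            n_genes=80, seed=3, measurement_cv=0.0,
            cellnum_lognormal_sigma=0.3, plate_effect_sigma=0.0,
            infection_failure_rate=0.0, hit_genes={"G0010": 1.0},
        )
        wells, _, _ = simulate_screen(cfg)
        normed, _ = normalize_screen(wells)
        rc = np.array([
            w.rel_change for w in normed
            if w.well_class == "library" and w.qc_pass and w.gene_id != "G0010"
        ])
        assert np.ptp(rc) / rc.mean() < 1e-6
        hit = [w.rel_change for w in normed if w.gene_id == "G0010"]
        assert np.allclose(hit, 1.0 / (1.0 - cfg.degradation_factor), rtol=1e-6)

    def test_noisy_simulation_tracks_ground_truth(self):
        # hit genes with rescue fractions spanning the whole range, so the
        # true per-well effect varies and a rank correlation is informative
        # rescuers must stay rare for the plate baseline to hold (~10% here)
        rng = np.random.default_rng(4)
        hits = {f"G{i:04d}": float(r)
                for i, r in zip(range(1, 31), rng.uniform(0.05, 1.0, 30))}
        cfg = ScreenSimConfig(n_genes=300, seed=21, infection_failure_rate=0.0,
                              hit_genes=hits)
        wells, truth, _ = simulate_screen(cfg)
        normed, _ = normalize_screen(wells)
        lib = [w for w in normed
               if w.well_class == "library" and w.qc_pass
               and w.gene_id in hits]
        est = np.array([w.rel_change for w in lib])
        true = np.array([truth.true_rel_change[w.well_key] for w in lib])
        from scipy.stats import spearmanr

        assert spearmanr(est, true).statistic >= 0.9
        nonhit = np.array([
            w.rel_change for w in normed
            if w.well_class == "library" and w.qc_pass
            and w.gene_id not in hits
        ])
        assert np.median(nonhit) == pytest.approx(1.0, abs=0.05)


class TestRobustZ:
    def test_definition_on_small_sample(self):
        z = robust_zscore([0, 1, 2, 3, 4])
        # median 2, MAD 1: z(4) = 2 / 1.4826
        assert z[-1] == pytest.approx(2 / 1.4826, rel=1e-6)
        assert z[2] == 0.0

    def test_degenerate_fallbacks(self):
        assert np.all(robust_zscore([5.0] * 6) == 0.0)
        # MAD 0 but SD > 0: falls back to SD scaling
        vals = [1.0, 1.0, 1.0, 1.0, 1.0, 10.0]
        z = robust_zscore(vals)
        assert z[-1] == pytest.approx((10.0 - 1.0) / np.std(vals))
        with pytest.raises(ValidationError):
            robust_zscore([1.0, 2.0, 3.0])

    def test_large_sample_calibration(self):
        x = np.random.default_rng(0).normal(size=100_000)
        z = robust_zscore(x)
        assert abs(np.median(z)) < 0.02
        mad_scaled = 1.4826 * np.median(np.abs(z - np.median(z)))
        assert mad_scaled == pytest.approx(1.0, abs=0.02)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(min_value=-50, max_value=50).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, -1.2, 4.5, 2.2, -0.7, 1.1, 9.0])
        z = robust_zscore(x)
        za = robust_zscore(a * x + b)
        assert np.allclose(za, np.sign(a) * z, rtol=1e-9, atol=1e-9)
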