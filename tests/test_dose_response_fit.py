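import numpy as np
import pandas as pd
import pytest

from clskinetics.dose_response_fit import (
    PARAM_NAMES,
    ParamPlotDataset,
    WesternCalibration,
    eq1_activity,
    extract_signature,
    fit_all_params,
    fit_dose_response,
    fit_grid,
    fit_param_vs_cofactor,
    normalize_grid,
    western_linearize,
)
from clskinetics.kinetic_core import LinearFractional
from clskinetics.synthetic_data import (
    AssayDesign,
    NoiseModel,
    generate_assay,
    tif2_like_truth,
)


# ---------------------------------------------------------------------------
# Eq-1 dose-response fitting
# ---------------------------------------------------------------------------


class TestFitDoseResponse:
    def test_noiseless_recovery(self):
        # oracle: Eq 1 evaluated at the printed doses
        S = np.array([0.0, 10.0, 100.0, 1000.0])
        A = eq1_activity(S, 100.0, 20.0, 50.0)
        np.testing.assert_allclose(
            A, [100.0, 86.6666667, 46.6666667, 23.8095238], rtol=1e-7
        )
        est = fit_dose_response(S, A)
        assert est.amax == pytest.approx(100.0, rel=1e-6)
        assert est.amin == pytest.approx(20.0, rel=1e-6)
        assert est.ic50 == pytest.approx(50.0, rel=1e-6)
        assert est.r_squared == pytest.approx(1.0, abs=1e-10)
        assert est.ratio == pytest.approx(100.0 * 50.0 / 20.0, rel=1e-6)

    def test_midpoint_identity(self):
        amax, amin, ic50 = 80.0, 10.0, 25.0
        assert eq1_activity(ic50, amax, amin, ic50) == pytest.approx(
            (amax + amin) / 2
        )

    def test_flat_curve_flagged(self):
        S = np.array([0.0, 10.0, 100.0, 1000.0])
        est = fit_dose_response(S, np.full(4, 7.0))
        assert est.amax == est.amin == pytest.approx(7.0)
        assert np.isnan(est.ic50)
        assert any("flat" in f for f in est.flags)

    def test_increasing_activity_flagged_wrong_mode(self):
        S = np.array([0.0, 10.0, 100.0, 1000.0])
        A = np.array([10.0, 30.0, 60.0, 90.0])
        est = fit_dose_response(S, A)
        assert any("wrong mode" in f for f in est.flags)

    def test_shallow_repression_leaves_ic50_undefined(self):
        S = np.array([0.0, 10.0, 100.0, 1000.0])
        A = eq1_activity(S, 100.0, 97.0, 50.0)
        est = fit_dose_response(S, A)
        assert np.isnan(est.ic50)
        assert any("unidentifiable" in f for f in est.flags)

    def test_joint_fit_matches_two_stage_on_noiseless(self):
        S = np.array([0.0, 5.0, 20.0, 80.0, 320.0])
        A = eq1_activity(S, 60.0, 12.0, 30.0)
        two = fit_dose_response(S, A)
        joint = fit_dose_response(S, A, joint=True)
        assert joint.amax == pytest.approx(two.amax, rel=1e-4)
        assert joint.ic50 == pytest.approx(two.ic50, rel=1e-4)

    def test_requires_zero_dose(self):
        with pytest.raises(ValueError, match="zero"):
            fit_dose_response([1.0, 10, 100, 1000], [9, 8, 5, 3])

    def test_requires_three_positive_doses(self):
        with pytest.raises(ValueError):
            fit_dose_response([0.0, 10.0], [10.0, 5.0])

    def test_roundtrip_property(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            amax = 10 ** rng.uniform(0, 3)
            amin = amax * rng.uniform(0.01, 0.6)
            ic50 = 10 ** rng.uniform(0, 2.2)
            S = np.array([0.0, 3.0, 30.0, 300.0])
            est = fit_dose_response(S, eq1_activity(S, amax, amin, ic50))
            assert est.amax == pytest.approx(amax, rel=1e-6)
            assert est.amin == pytest.approx(amin, rel=1e-5)
            assert est.ic50 == pytest.approx(ic50, rel=1e-5)

    def test_ic50_recovery_under_noise(self):
        # 4-dose design, triplicates, 5% CV: median error within 15%
        rng = np.random.default_rng(123)
        amax, amin, ic50 = 100.0, 15.0, 20.0
        S = np.repeat([0.0, 3.0, 30.0, 300.0], 3)
        errs = []
        for _ in range(200):
            A = eq1_activity(S, amax, amin, ic50) * rng.lognormal(
                -0.5 * np.log(1.0025), np.sqrt(np.log(1.0025)), size=S.size
            )
            est = fit_dose_response(S, A)
            errs.append(abs(est.ic50 - ic50) / ic50)
        assert np.median(errs) <= 0.15


# ---------------------------------------------------------------------------
# grid normalization
# ---------------------------------------------------------------------------


def _small_table(seed=0, n_exp=2, noise=NoiseModel(0.0, 0.0)):
    truth = tif2_like_truth()
    return truth, generate_assay(
        truth, AssayDesign(n_experiments=n_exp), noise, seed=seed
    )


class TestNormalizeGrid:
    def test_global_anchor_is_one(self):
        # restrict to one reporter level so the aggregated first point IS
        # the anchor cell
        _, table = _small_table(n_exp=1)
        table = table[table.reporter_dose == table.reporter_dose.min()]
        ds = normalize_grid(table, anchor="global")
        for p in PARAM_NAMES:
            assert ds.series[p][0][0] == pytest.approx(1.0)

    def test_identical_experiments_zero_sem(self):
        truth, t1 = _small_table(n_exp=1)
        t1 = t1[t1.reporter_dose == t1.reporter_dose.min()]
        t2 = t1.copy()
        t2["experiment"] = 1
        both = pd.concat([t1, t2], ignore_index=True)
        ds = normalize_grid(both, anchor="global")
        for p in PARAM_NAMES:
            sem = ds.series[p][1]
            assert np.all(sem[np.isfinite(sem)] == pytest.approx(0.0, abs=1e-9))

    def test_noiseless_grid_matches_forward_model(self):
        truth, table = _small_table(n_exp=1)
        ds = normalize_grid(table, anchor="global", endogenous=truth.endogenous)
        from clskinetics.synthetic_data import activity_fn

        A = activity_fn(truth)
        lo_r = min(AssayDesign().reporter_doses)
        x0 = min(AssayDesign().cofactor_doses) + truth.endogenous
        expected = []
        for x in ds.x:
            vals = []
            for r in AssayDesign().reporter_doses:
                vals.append(A(x, 0.0, r) / A(x0, 0.0, lo_r))
            expected.append(np.mean(vals))
        np.testing.assert_allclose(ds.series["amax"][0], expected, rtol=1e-6)

    def test_scale_invariance_of_global_normalization(self):
        _, table = _small_table(n_exp=1)
        scaled = table.copy()
        scaled["activity"] *= 37.5
        ds1 = normalize_grid(table, anchor="global")
        ds2 = normalize_grid(scaled, anchor="global")
        for p in ("amax", "amin"):
            np.testing.assert_allclose(ds1.series[p][0], ds2.series[p][0], rtol=1e-9)

    def test_missing_anchor_cell_raises(self):
        _, table = _small_table(n_exp=1)
        lo_r = table["reporter_dose"].min()
        lo_c = table["cofactor_dose"].min()
        broken = table[
            ~((table.reporter_dose == lo_r) & (table.cofactor_dose == lo_c))
        ]
        with pytest.raises(ValueError, match="anchor"):
            normalize_grid(broken, anchor="global")

    def test_trace_mode_keeps_dose_axis_params_raw(self):
        truth, table = _small_table(n_exp=1)
        ds = normalize_grid(table, anchor="trace")
        cells = fit_grid(table)
        raw_mean = cells.groupby("cofactor_dose")["ic50"].mean().to_numpy()
        np.testing.assert_allclose(ds.series["ic50"][0], raw_mean, rtol=1e-9)

    def test_x_axis_offset_by_endogenous(self):
        _, table = _small_table(n_exp=1)
        ds = normalize_grid(table, endogenous=2.7)
        assert ds.x[0] == pytest.approx(2.7)


# ---------------------------------------------------------------------------
# Western linearization
# ---------------------------------------------------------------------------


class TestWestern:
    def test_noiseless_recovery(self):
        p = np.array([10.0, 25.0, 50.0, 100.0, 200.0])
        od = 10.0 * p / (50.0 + p)
        np.testing.assert_allclose(
            od, [1.6666667, 3.3333333, 5.0, 6.6666667, 8.0], rtol=1e-6
        )
        cal, corrected = western_linearize(od, p)
        assert cal.m1 == pytest.approx(10.0, rel=1e-6)
        assert cal.m2 == pytest.approx(50.0, rel=1e-6)
        assert corrected[2] == pytest.approx(25.0, rel=1e-6)  # p = m2 halves

    def test_zero_plasmid_zero_corrected(self):
        cal = WesternCalibration(10.0, 50.0)
        assert cal.linearize(0.0) == 0.0

    def test_linear_regime_identity(self):
        cal = WesternCalibration(10.0, 5000.0)
        p = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(cal.linearize(p), p, rtol=1e-3)

    def test_no_curvature_warns_identity(self):
        p = np.array([1.0, 2.0, 3.0, 4.0])
        od = 0.01 * p  # perfectly linear: m2 unidentifiable
        with pytest.warns(UserWarning):
            cal, corrected = western_linearize(od, p)
        np.testing.assert_allclose(corrected, p)


# ---------------------------------------------------------------------------
# parameter-plot fits
# ---------------------------------------------------------------------------


class TestFitParamVsCofactor:
    def test_linear_preferred_over_mm_on_linear_data(self):
        x = np.array([2.7, 12.7, 32.7, 102.7])
        y = 0.03 * x
        fit = fit_param_vs_cofactor(x, y, sem=np.full(4, 0.01))
        assert fit.bic["linear"] < fit.bic["mm"]
        assert fit.best_shape == "linear"

    def test_lf_recovery_under_noise(self):
        rng = np.random.default_rng(42)
        a, b, d = 2.0, 0.5, 0.02
        x = np.array([1.0, 5.0, 15.0, 40.0, 100.0, 250.0])
        truth = (a + b * x) / (1 + d * x)
        y = truth * (1 + 0.01 * rng.standard_normal(x.size))
        fit = fit_param_vs_cofactor(x, y, sem=0.01 * truth)
        assert fit.lf.a == pytest.approx(a, rel=0.05)
        assert fit.lf.b == pytest.approx(b, rel=0.05)
        assert fit.lf.d == pytest.approx(d, rel=0.05)

    def test_x_intercept_reported(self):
        x = np.array([2.7, 12.7, 32.7, 102.7])
        y = (5.0 + 0.5 * x) / (1 + 0.001 * x)
        fit = fit_param_vs_cofactor(x, y, sem=np.full(4, 0.05))
        assert fit.x_intercept == pytest.approx(-10.0, rel=0.1)
        assert np.isfinite(fit.x_intercept_se)

    def test_direction_matches_finite_differences(self):
        rng = np.random.default_rng(9)
        from clskinetics.config_formulas import lf_shape

        for _ in range(30):
            a, b, d = 10 ** rng.uniform(-1, 1, 3)
            x = np.linspace(1, 100, 6)
            y = (a + b * x) / (1 + d * x)
            fit = fit_param_vs_cofactor(x, y, sem=np.full(6, 1e-3))
            sh = lf_shape(fit.lf, x_range=(1.0, 100.0), const_tol=1e-6)
            fd = np.diff(fit.lf(x))
            if sh.direction == "inc":
                assert np.all(fd >= -1e-12)
            elif sh.direction == "dec":
                assert np.all(fd <= 1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_param_vs_cofactor([1.0], [2.0])


# ---------------------------------------------------------------------------
# signature extraction
# ---------------------------------------------------------------------------


class TestExtractSignature:
    def _fits_for(self, truth, seed=1, n_exp=6, mode="cofactor"):
        table = generate_assay(
            truth, AssayDesign(n_experiments=n_exp), NoiseModel(0.05, 0.10),
            seed=seed,
        )
        ds = normalize_grid(table, mode=mode, endogenous=truth.endogenous)
        return fit_all_params(ds), ds

    def test_tif2_like_signature(self):
        truth = tif2_like_truth()
        fits, ds = self._fits_for(truth)
        sig = extract_signature(fits, x_range=(ds.x.min(), ds.x.max()))
        assert sig.directions["amax"] == "inc"
        assert sig.directions["amin"] == "dec"
        assert sig.directions["ic50"] == "dec"
        assert sig.amax_gt_amin

    def test_reporter_axis_signature(self):
        truth = tif2_like_truth()
        fits, ds = self._fits_for(truth, mode="reporter")
        sig = extract_signature(fits, x_range=(ds.x.min(), ds.x.max()))
        # the reporter is the CLS accelerator: A_max linear through the
        # origin and IC50 independent of reporter dose
        assert sig.directions["amax"] == "inc"
        assert sig.shapes["amax_linear_origin"]
        assert sig.directions["ic50"] == "const"

    def test_all_flat_series_all_const(self):
        x = np.array([1.0, 10.0, 30.0, 100.0])
        flat = {
            p: fit_param_vs_cofactor(x, np.full(4, 2.0), sem=np.full(4, 0.1))
            for p in PARAM_NAMES
        }
        sig = extract_signature(flat, x_range=(1.0, 100.0))
        assert all(d == "const" for d in sig.directions.values())

    def test_missing_fit_key_raises(self):
        with pytest.raises(ValueError, match="missing"):
            extract_signature({"amax": None})

    def test_none_fit_is_noninformative(self):
        x = np.array([1.0, 10.0, 30.0, 100.0])
        some = fit_param_vs_cofactor(x, np.full(4, 2.0), sem=np.full(4, 0.1))
        sig = extract_signature(
            {"amax": some, "amin": None, "ic50": None, "ratio": None},
            x_range=(1.0, 100.0),
        )
        assert sig.directions["amin"] is None
        assert sig.h_amin_vs_amax == "unknown"
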