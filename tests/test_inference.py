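"""Inference stages: exact-fit identities, flags, model selection, recovery."""

import numpy as np
import pandas as pd
import pytest

import slowbind as sb

from conftest import KI_COMPOUND_2, KI_COMPOUND_8


def _noiseless_progress(params: sb.SlowBindingCurveParams, t_end=1200.0, n=121):
    t = np.linspace(0.0, t_end, n)
    return t, np.asarray(sb.progress_value(t, params))


def _competitive_grid(ki, vmax=1.0, km=100.0, noise=0.0, seed=0,
                      S=(50.0, 100.0, 200.0, 400.0), I=(0.0, 12.5, 25.0, 50.0), reps=1):
    mech = sb.MechanismSpec(
        mm=sb.MichaelisMentenParams(vmax, km), inh=sb.InhibitionModel("competitive", ki)
    )
    design = sb.AssayDesign(
        inhibitor_concs=I, substrate_concs=S, replicates=reps, noise_sd=noise, seed=seed
    )
    return sb.simulate_steady_state(design, mech)


class TestProgressCurveFit:
    def test_exact_recovery_on_noiseless_curve(self):
        truth = sb.SlowBindingCurveParams(vi=1.0, vs=0.5, kobs=0.01)
        t, y = _noiseless_progress(truth, t_end=600.0)
        fit = sb.fit_progress_curve(t, y)
        assert fit.converged and not fit.flags
        for name, true in [("vi", 1.0), ("vs", 0.5), ("kobs", 0.01)]:
            assert fit.params[name] == pytest.approx(true, rel=1e-6)

    def test_linear_curve_flags_kobs_unidentifiable(self):
        t = np.linspace(0.0, 1200.0, 121)
        fit = sb.fit_progress_curve(t, 0.0003 * t)
        assert "kobs_unidentifiable" in fit.flags

    def test_activation_pattern_flagged(self):
        # signal accelerating over time: vs > vi is activation, not inhibition
        truth = sb.SlowBindingCurveParams(vi=0.2, vs=1.0, kobs=0.01)
        t, y = _noiseless_progress(truth, t_end=600.0)
        fit = sb.fit_progress_curve(t, y)
        assert "activation" in fit.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            sb.fit_progress_curve([0, 1, 2, 3], [0, 1, 2, 3])

    def test_monte_carlo_median_kobs_within_5pct(self):
        truth = sb.SlowBindingCurveParams(vi=1.0, vs=0.3, kobs=0.004)
        t = np.linspace(0.0, 1200.0, 121)
        clean = np.asarray(sb.progress_value(t, truth))
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(100):
            y = clean + rng.normal(0.0, 0.01 * clean.max(), size=t.size)
            estimates.append(sb.fit_progress_curve(t, y).params["kobs"])
        assert np.median(estimates) == pytest.approx(truth.kobs, rel=0.05)


class TestKobsHyperbolaFit:
    def test_exact_recovery(self, two_step_truth):
        I = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0])
        series = pd.DataFrame(
            {"inhibitor_um": I, "kobs_per_s": sb.kobs_of_I(I, two_step_truth), "kobs_se": np.nan}
        )
        fit = sb.fit_kobs_hyperbola(series)
        assert fit.converged and not fit.flags
        assert fit.params["k3"] == pytest.approx(two_step_truth.k3, rel=1e-6)
        assert fit.params["k4"] == pytest.approx(two_step_truth.k4, rel=1e-6)
        assert fit.params["Kiapp"] == pytest.approx(two_step_truth.Kiapp, rel=1e-6)
        assert fit.extra["overall_ki_star_um"] == pytest.approx(
            sb.overall_ki_star(two_step_truth), rel=1e-6
        )

    def test_constant_series_flagged_poorly_constrained(self):
        series = pd.DataFrame(
            {"inhibitor_um": [5.0, 10.0, 20.0, 40.0], "kobs_per_s": [2e-3] * 4}
        )
        fit = sb.fit_kobs_hyperbola(series)
        assert "poorly_constrained" in fit.flags

    def test_needs_four_concentrations(self, two_step_truth):
        I = np.array([5.0, 10.0, 20.0])
        series = pd.DataFrame({"inhibitor_um": I, "kobs_per_s": sb.kobs_of_I(I, two_step_truth)})
        with pytest.raises(ValueError, match="4 distinct"):
            sb.fit_kobs_hyperbola(series)


class TestMechanismClassification:
    def test_hyperbolic_series_is_two_step(self, two_step_truth):
        I = np.array([6.25, 12.5, 25.0, 50.0, 100.0])
        series = pd.DataFrame({"inhibitor_um": I, "kobs_per_s": sb.kobs_of_I(I, two_step_truth)})
        assert sb.classify_mechanism(series) == "two_step"

    def test_linear_series_is_one_step(self):
        I = np.array([6.25, 12.5, 25.0, 50.0, 100.0])
        series = pd.DataFrame({"inhibitor_um": I, "kobs_per_s": 4e-4 + 2e-5 * I})
        assert sb.classify_mechanism(series) == "one_step"

    def test_low_concentration_arc_reads_as_one_step(self, two_step_truth):
        # far below Kiapp the hyperbola is locally linear; at realistic kobs
        # noise the extra parameter is not justified
        I = np.array([0.5, 1.0, 1.5, 2.0, 3.0])
        rng = np.random.default_rng(7)
        kobs = np.asarray(sb.kobs_of_I(I, two_step_truth)) * (1 + rng.normal(0, 0.01, I.size))
        series = pd.DataFrame({"inhibitor_um": I, "kobs_per_s": kobs})
        assert sb.classify_mechanism(series) == "one_step"

    def test_two_stage_consistency_on_closed_form_data(self, slow_binding_mechanism, two_step_truth):
        # per-curve fits then hyperbola fit reproduce the generating law
        design = sb.AssayDesign(replicates=1, noise_sd=0.0, seed=0)
        params = {
            float(I): sb.closed_form_params(slow_binding_mechanism, 375.0, float(I))
            for I in design.inhibitor_concs
        }
        curves = sb.simulate_progress_closed_form(design, params)
        series = sb.extract_kobs_series(curves)
        for _, row in series.iterrows():
            assert row.kobs_per_s == pytest.approx(
                params[row.inhibitor_um].kobs, rel=1e-6
            )
        assert sb.classify_mechanism(series) == "two_step"


class TestModeClassification:
    def test_noiseless_competitive_grid(self):
        call = sb.classify_mode(_competitive_grid(KI_COMPOUND_2))
        assert call.mode == "competitive"
        assert call.ki_um == pytest.approx(KI_COMPOUND_2, rel=1e-6)

    def test_noiseless_noncompetitive_grid(self, mm_unit):
        mech = sb.MechanismSpec(mm=mm_unit, inh=sb.InhibitionModel("noncompetitive", 20.0))
        design = sb.AssayDesign(
            inhibitor_concs=[0.0, 10.0, 20.0, 40.0],
            substrate_concs=[50.0, 100.0, 200.0, 400.0],
            replicates=1,
            noise_sd=0.0,
            seed=1,
        )
        call = sb.classify_mode(sb.simulate_steady_state(design, mech))
        assert call.mode == "noncompetitive"
        assert call.ki_um == pytest.approx(20.0, rel=1e-6)

    def test_singular_design_rejected(self):
        # one substrate level: the mode cannot be identified
        grid = pd.DataFrame(
            {
                "substrate_um": [100.0] * 4,
                "inhibitor_um": [0.0, 10.0, 20.0, 40.0],
                "v_au_per_s": [0.5, 0.3, 0.2, 0.15],
                "replicate": [1] * 4,
            }
        )
        with pytest.raises(ValueError, match="singular"):
            sb.classify_mode(grid)

    def test_label_invariant_under_rescaling(self):
        grid = _competitive_grid(KI_COMPOUND_2, noise=0.02, seed=31)
        base = sb.classify_mode(grid)
        scaled = grid.assign(v_au_per_s=grid.v_au_per_s * 1e3)  # velocity units
        units = grid.assign(
            substrate_um=grid.substrate_um * 1e3, inhibitor_um=grid.inhibitor_um * 1e3
        )  # nM-style concentration rescale
        assert sb.classify_mode(scaled).mode == base.mode
        call_units = sb.classify_mode(units)
        assert call_units.mode == base.mode
        assert call_units.ki_um == pytest.approx(base.ki_um * 1e3, rel=1e-6)

    def test_competitive_chosen_in_at_least_90pct_of_noisy_grids(self):
        wins = 0
        for i, seed in enumerate(np.random.SeedSequence(123).generate_state(100) % 2**31):
            call = sb.classify_mode(_competitive_grid(KI_COMPOUND_2, noise=0.02, seed=int(seed), reps=3))
            wins += call.mode == "competitive"
        assert wins >= 90

    def test_lineweaver_burk_common_intercept_diagnostic(self):
        call = sb.classify_mode(_competitive_grid(KI_COMPOUND_2, noise=0.02, seed=8, reps=3))
        assert call.lb_intercept_p > 1e-4  # competitive: intercepts consistent


class TestDixon:
    def test_noiseless_intersections_at_minus_ki(self):
        for ki in (KI_COMPOUND_2, KI_COMPOUND_8):
            res = sb.dixon_ki(_competitive_grid(ki))
            assert res.ki_um == pytest.approx(ki, rel=1e-9)
            np.testing.assert_allclose(res.intersections_um, -ki, rtol=1e-9)

    def test_scale_invariance_in_vmax(self):
        a = sb.dixon_ki(_competitive_grid(KI_COMPOUND_2, vmax=1.0))
        b = sb.dixon_ki(_competitive_grid(KI_COMPOUND_2, vmax=250.0))
        assert a.ki_um == pytest.approx(b.ki_um, rel=1e-9)

    def test_agrees_with_global_fit_on_noiseless_data(self):
        grid = _competitive_grid(KI_COMPOUND_8)
        assert sb.dixon_ki(grid).ki_um == pytest.approx(
            sb.classify_mode(grid).ki_um, rel=1e-6
        )

    def test_uncompetitive_pattern_has_no_intersection(self, mm_unit):
        mech = sb.MechanismSpec(mm=mm_unit, inh=sb.InhibitionModel("uncompetitive", 20.0))
        design = sb.AssayDesign(
            inhibitor_concs=[0.0, 10.0, 20.0, 40.0],
            substrate_concs=[50.0, 100.0, 200.0, 400.0],
            replicates=1,
            noise_sd=0.0,
            seed=1,
        )
        with pytest.raises(ValueError, match="parallel"):
            sb.dixon_ki(sb.simulate_steady_state(design, mech))


class TestIC50Fit:
    def test_exact_recovery(self):
        design = sb.AssayDesign(inhibitor_concs=[6.25, 12.5, 25.0, 50.0, 100.0], replicates=1)
        table = sb.simulate_dose_response(design, sb.DoseResponseParams(39.7), noise_pct_sd=0.0)
        fit = sb.fit_ic50(table)
        assert fit.converged
        assert fit.params["ic50"] == pytest.approx(39.7, rel=1e-6)
        assert fit.params["hill"] == pytest.approx(1.0, rel=1e-6)

    def test_weak_inhibition_withholds_estimate(self):
        design = sb.AssayDesign(inhibitor_concs=[6.25, 12.5, 25.0, 50.0, 100.0], replicates=1)
        table = sb.simulate_dose_response(design, sb.DoseResponseParams(5000.0), noise_pct_sd=0.0)
        fit = sb.fit_ic50(table)
        assert not fit.converged
        assert "ic50_above_max_tested" in fit.flags
        assert "ic50" not in fit.params
        assert fit.params["ic50_lower_bound_um"] == 100.0


class TestCharacterizeCompound:
    def test_slow_binding_competitive_compound_end_to_end(self, slow_binding_mechanism):
        progress = sb.simulate_progress_mechanistic(
            sb.AssayDesign(
                inhibitor_concs=(0.0, 3.125, 6.25, 12.5, 25.0, 37.5, 50.0, 75.0, 100.0),
                replicates=3,
                noise_sd=0.01,
                seed=1,
            ),
            slow_binding_mechanism,
        )
        grid = _competitive_grid(KI_COMPOUND_2, noise=0.02, seed=1, reps=3)
        dose_design = sb.AssayDesign(
            inhibitor_concs=[6.25, 12.5, 25.0, 50.0, 100.0], replicates=3, seed=2
        )
        dose = sb.simulate_dose_response(dose_design, sb.DoseResponseParams(39.7))
        dose_pre = sb.simulate_dose_response(
            sb.AssayDesign(inhibitor_concs=[6.25, 12.5, 25.0, 50.0, 100.0], replicates=3, seed=3),
            sb.DoseResponseParams(13.2),
        )
        result = sb.characterize_compound(
            "slow-binder", progress=progress, steady_state=grid,
            dose=dose, dose_preincubated=dose_pre,
        )
        assert result.mode.mode == "competitive"
        assert result.mechanism_class == "two_step"
        assert result.two_step is not None
        assert result.ic50.params["ic50"] == pytest.approx(39.7, rel=0.25)
        assert result.ic50_preincubated.params["ic50"] == pytest.approx(13.2, rel=0.25)
        report = result.to_dict()
        assert report["mode"]["mode"] == "competitive"
        assert "k3_per_s" in report["two_step"]

    def test_fast_equilibrating_compound_has_no_time_dependence(self, mm_unit):
        # competitive but not slow-binding: progress curves are straight lines
        mech = sb.MechanismSpec(mm=mm_unit, inh=sb.InhibitionModel("competitive", 44.2))
        design = sb.AssayDesign(replicates=2, noise_sd=0.01, seed=4)
        params = {
            float(I): sb.closed_form_params(mech, 375.0, float(I))
            for I in design.inhibitor_concs
        }
        progress = sb.simulate_progress_closed_form(design, params)
        result = sb.characterize_compound("fast-binder", progress=progress)
        assert result.mechanism_class == "no_time_dependence"
        assert result.two_step is None

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            sb.characterize_compound("nothing")
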