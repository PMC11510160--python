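"""Trial orchestration: population runs, DDI protocols, calibration, sensitivity."""

import pandas as pd
import pytest

from oxypbpk import (
    DoseRegimen,
    InteractionSpec,
    Perpetrator,
    PerpetratorPK,
    TrialDesign,
    analytic_steady_state,
    calibrate_fm_cyp3a,
    ddi_protocol,
    make_template,
    recovery_fixture,
    run_trial_set,
    sensitivity_scan,
)
from oxypbpk.population import AbundanceDist
from oxypbpk.trials import _recalibrated_parent, perpetrator_average_fold


def _degenerate_design(seed=0, **kw):
    template = make_template("caucasian_healthy", prop_female=0.0)
    zero_cv = {k: AbundanceDist(mean=v.mean, cv=0.0) for k, v in template.abundances.items()}
    template = template.model_copy(
        update=dict(
            weight_cv=0.0,
            liver_weight_cv=0.0,
            mppgl_cv=0.0,
            q_h_cv=0.0,
            hematocrit_cv=0.0,
            abundances=zero_cv,
            cyp3a5_phenotype_freqs={"EM": 0.0, "IM": 0.0, "PM": 1.0},
            cyp3a5_abundance_by_phenotype={"EM": 103.0, "IM": 51.5, "PM": 1.0},
        )
    )
    kw.setdefault("n_trials", 1)
    kw.setdefault("n_subjects_per_trial", 1)
    return TrialDesign(template=template, seed=seed, **kw)


def _saturating_inducer(start_day=700.0, ind_max=16.0):
    # enormous unbound exposure -> fold pinned at ind_max
    return Perpetrator(
        name="strong-inducer",
        pk=PerpetratorPK(ka=1.0, v_f=50.0, cl_f=1.0, fu=1.0, kp_liver=1.0, molecular_weight=300.0),
        regimen=DoseRegimen(
            compound="strong-inducer",
            route="oral",
            dose=1e6,
            interval=24.0,
            start_day=start_day,
            duration_days=30.0,
        ),
        interaction=InteractionSpec(mechanism="induction", ind_max=ind_max, ind_c50=0.32),
    )


class TestRunTrialSet:
    def test_degenerate_design_matches_deterministic_subject(self, config):
        design = _degenerate_design()
        summary = run_trial_set(design, config)
        phys = config.physiology
        ss = analytic_steady_state(
            config.compounds["cholesterol"],
            config.compounds["4b-hydroxycholesterol"],
            phys,
            1.73 * design.template.weight_mean / 24.0,
        )
        assert summary.mean_css_metabolite_ng_ml == pytest.approx(
            ss.css_metabolite_ng_ml, rel=1e-9
        )

    def test_same_seed_reproduces_summary(self, config):
        design = TrialDesign(
            template=make_template("caucasian_healthy"), n_trials=3, n_subjects_per_trial=5, seed=12
        )
        a = run_trial_set(design, config)
        b = run_trial_set(design, config)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        assert a.mean_css_metabolite_ng_ml == b.mean_css_metabolite_ng_ml

    def test_different_seeds_differ(self, config):
        template = make_template("caucasian_healthy")
        a = run_trial_set(TrialDesign(template=template, n_trials=2, n_subjects_per_trial=5, seed=1), config)
        b = run_trial_set(TrialDesign(template=template, n_trials=2, n_subjects_per_trial=5, seed=2), config)
        assert a.mean_css_metabolite_ng_ml != b.mean_css_metabolite_ng_ml

    def test_percentiles_bracket_mean(self, config):
        design = TrialDesign(
            template=make_template("caucasian_healthy"), n_trials=4, n_subjects_per_trial=25, seed=8
        )
        s = run_trial_set(design, config)
        assert s.p5_css_metabolite_ng_ml < s.mean_css_metabolite_ng_ml < s.p95_css_metabolite_ng_ml

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            _degenerate_design(n_trials=0)


class TestDdiProtocol:
    def test_null_perpetrator_gives_unit_ratios(self, config):
        perp = _saturating_inducer()
        null = perp.model_copy(
            update={
                "interaction": InteractionSpec(mechanism="induction", ind_max=1.0, ind_c50=0.32)
            }
        )
        summary = ddi_protocol(_degenerate_design(n_subjects_per_trial=3), null, config)
        assert summary.subjects["ddi_ratio"].tolist() == pytest.approx([1.0] * 3)

    def test_saturating_inducer_approaches_indmax(self, config):
        """Metabolite formation is ~purely CYP3A, so the saturated DDI ratio
        approaches the Ind_max cap."""
        summary = ddi_protocol(_degenerate_design(), _saturating_inducer(), config)
        assert summary.mean_ddi_ratio == pytest.approx(16.0, rel=0.01)

    def test_strong_inhibitor_kills_formation(self, config):
        perp = _saturating_inducer().model_copy(
            update={"interaction": InteractionSpec(mechanism="competitive_inhibition", ki=1e-9)}
        )
        summary = ddi_protocol(_degenerate_design(), perp, config)
        assert summary.mean_ddi_ratio < 1e-3

    def test_overlap_with_baseline_rejected(self, config):
        with pytest.raises(ValueError, match="baseline"):
            ddi_protocol(_degenerate_design(), _saturating_inducer(start_day=100.0), config)

    def test_paired_ratio_insensitive_to_abundance_scale(self, config):
        """Under a saturated fold the per-subject ratio does not depend on the
        subject's absolute abundances: ratio variance << Css variance."""
        design = TrialDesign(
            template=make_template("caucasian_healthy"), n_trials=2, n_subjects_per_trial=20, seed=4
        )
        summary = ddi_protocol(design, _saturating_inducer(), config)
        cv_ratio = summary.subjects["ddi_ratio"].std() / summary.subjects["ddi_ratio"].mean()
        cv_css = (
            summary.subjects["css_baseline_ng_ml"].std()
            / summary.subjects["css_baseline_ng_ml"].mean()
        )
        assert cv_ratio < 0.02 * cv_css

    def test_ode_route_agrees_with_analytic(self, config):
        design = _degenerate_design(perpetrator_days=30.0)
        perp = config.perpetrators["rifampicin"]
        analytic = ddi_protocol(design, perp, config, method="analytic")
        ode = ddi_protocol(design, perp, config, method="ode")
        # oral-dosing dynamics fluctuate within the day; agreement to a few %
        assert ode.mean_ddi_ratio == pytest.approx(analytic.mean_ddi_ratio, rel=0.05)


class TestCalibration:
    def test_fixed_point(self, config):
        phys = config.physiology
        current = analytic_steady_state(
            config.compounds["cholesterol"],
            config.compounds["4b-hydroxycholesterol"],
            phys,
            1.73 * phys.body_weight / 24.0,
        ).css_metabolite_ng_ml
        result = calibrate_fm_cyp3a(current, config)
        assert result.clint_cyp3a4 == pytest.approx(4.17e-7, rel=1e-3)

    def test_zero_target_rejected(self, config):
        with pytest.raises(ValueError, match="unreachable|> 0"):
            calibrate_fm_cyp3a(0.0, config)

    def test_unbracketed_target_reports_diagnostics(self, config):
        with pytest.raises(ValueError, match="no sign change"):
            calibrate_fm_cyp3a(1e6, config)

    def test_monotone_in_clint(self, config):
        phys = config.physiology
        metabolite = config.compounds["4b-hydroxycholesterol"]
        from oxypbpk.params import scaled_liver_clint

        clmet_ref = sum(
            scaled_liver_clint(p, phys) for p in config.compounds["cholesterol"].pathways
        )
        css = []
        for clint in (1e-7, 4e-7, 8e-7):
            parent = _recalibrated_parent(config, clint, 5.6, 2.8, clmet_ref)
            css.append(
                analytic_steady_state(
                    parent, metabolite, phys, 1.73 * phys.body_weight / 24.0
                ).css_metabolite_ng_ml
            )
        assert css[0] < css[1] < css[2]

    def test_recovery_from_noisy_fixture(self, config):
        fixture = recovery_fixture(4.17e-7, config, seed=5)
        result = calibrate_fm_cyp3a(fixture.observed_baseline_css_ng_ml, config, ddi_fold=10.0)
        assert result.clint_cyp3a4 == pytest.approx(fixture.truth["clint_cyp3a4"], rel=0.10)
        assert result.achieved_ddi_ratio == pytest.approx(10.0, rel=0.01)

    def test_zero_noise_recovery_is_exact(self, config):
        fixture = recovery_fixture(4.17e-7, config, seed=5, noise_cv=0.0)
        result = calibrate_fm_cyp3a(fixture.observed_baseline_css_ng_ml, config)
        assert result.clint_cyp3a4 == pytest.approx(4.17e-7, rel=1e-6)

    def test_hlm_rebalance_preserves_total_clearance(self, config):
        from oxypbpk.params import scaled_liver_clint

        phys = config.physiology
        clmet_ref = sum(
            scaled_liver_clint(p, phys) for p in config.compounds["cholesterol"].pathways
        )
        parent = _recalibrated_parent(config, 8e-7, 5.6, 2.8, clmet_ref)
        total = sum(scaled_liver_clint(p, phys) for p in parent.pathways)
        assert total == pytest.approx(clmet_ref, rel=1e-12)


class TestSensitivity:
    def test_cyp27a1_scan_reproduces_reported_folds(self, config):
        table = sensitivity_scan(config, "physiology.abundances.CYP27A1", [40.0, 20.0])
        parent_fold = table.css_parent_mg_ml[1] / table.css_parent_mg_ml[0]
        met_fold = table.css_metabolite_ng_ml[1] / table.css_metabolite_ng_ml[0]
        assert parent_fold == pytest.approx(1.16, rel=0.03)
        assert met_fold == pytest.approx(1.56, rel=0.03)

    def test_dose_scan_is_linear(self, config):
        table = sensitivity_scan(config, "dosing.cholesterol_infusion.dose", [1.0, 3.0])
        assert table.css_parent_mg_ml[1] == pytest.approx(3 * table.css_parent_mg_ml[0], rel=1e-9)
        assert table.css_metabolite_ng_ml[1] == pytest.approx(
            3 * table.css_metabolite_ng_ml[0], rel=1e-9
        )

    def test_empty_values_gives_empty_table(self, config):
        table = sensitivity_scan(config, "physiology.abundances.CYP27A1", [])
        assert len(table) == 0
        assert list(table.columns) == ["value", "css_parent_mg_ml", "css_metabolite_ng_ml"]

    def test_unresolvable_path_rejected(self, config):
        with pytest.raises(KeyError, match="resolve"):
            sensitivity_scan(config, "physiology.abundances.CYP99", [1.0])


class TestPerpetratorAverageFold:
    def test_flat_profile_limit_equals_fold_at_average_concentration(self, config):
        """With negligible elimination over the dosing interval the profile is
        flat, so the cycle-mean fold equals the Emax fold at C_avg."""
        perp = config.perpetrators["rifampicin"]
        slow = perp.model_copy(
            update={
                "pk": perp.pk.model_copy(update={"cl_f": 1e-4}),
            }
        )
        c_avg = 600.0 / (24.0 * 1e-4)
        c_u = 0.15 * c_avg / 822.94 * 1000.0
        from oxypbpk import induction_fold

        assert perpetrator_average_fold(slow) == pytest.approx(
            induction_fold(c_u, 16.0, 0.32), rel=1e-3
        )

    def test_fluctuating_profile_averages_below_fold_at_cavg(self, config):
        """Jensen: averaging a concave Emax fold over a fluctuating profile
        gives less induction than the fold at the average concentration."""
        perp = config.perpetrators["rifampicin"]
        c_avg = 600.0 / (24.0 * 7.0)
        c_u = 0.15 * c_avg / 822.94 * 1000.0
        from oxypbpk import induction_fold

        at_cavg = induction_fold(c_u, 16.0, 0.32)
        avg = perpetrator_average_fold(perp)
        assert 1.0 < avg < at_cavg
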