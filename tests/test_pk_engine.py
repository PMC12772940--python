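"""Covariate algebra, BSV sampling, closed-form solver vs ODE, steady state."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from retrodose import (
    DoseEvent,
    Patient,
    PopPKModelSpec,
    Regimen,
    apply_covariates,
    concentration,
    concentration_many,
    generate_fixture_spec,
    ode_concentration,
    sample_individuals,
    steady_state_history,
    terminal_half_life,
)
from retrodose.model import CovariateRelation


def _spec(covariates=(), omega=None, **params):
    defaults = {"CL_F": 5.0, "V_F": 50.0, "Ka": 1.0}
    defaults.update(params)
    return PopPKModelSpec(
        drug_name="t",
        structure="one_cpt_oral",
        typical_params=defaults,
        covariates=list(covariates),
        omega=omega or {},
    )


ADULT = Patient(age=40, weight=70, height=180)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


class TestCovariates:
    def test_power_at_reference_is_identity(self):
        rel = CovariateRelation(
            target_param="CL_F", covariate="weight", form="power", theta=0.75, ref_value=70
        )
        assert apply_covariates(_spec([rel]), ADULT)["CL_F"] == pytest.approx(5.0)

    def test_power_egfr_half(self):
        rel = CovariateRelation(
            target_param="CL_F", covariate="eGFR", form="power", theta=0.5, ref_value=90
        )
        patient = ADULT.model_copy(update={"eGFR": 45.0})
        out = apply_covariates(_spec([rel]), patient)
        assert out["CL_F"] == pytest.approx(5.0 * math.sqrt(0.5), rel=1e-12)

    def test_comedication_flag_semantics(self):
        rel = CovariateRelation(
            target_param="CL_F", covariate="inducer", form="proportional", theta=0.5
        )
        with_tag = ADULT.model_copy(update={"comedications": {"inducer"}})
        assert apply_covariates(_spec([rel]), with_tag)["CL_F"] == pytest.approx(7.5)
        assert apply_covariates(_spec([rel]), ADULT)["CL_F"] == pytest.approx(5.0)

    def test_factors_compose_multiplicatively_in_order(self):
        rels = [
            CovariateRelation(target_param="CL_F", covariate="weight", form="power", theta=1.0, ref_value=70),
            CovariateRelation(target_param="CL_F", covariate="flag", form="proportional", theta=1.0),
        ]
        patient = ADULT.model_copy(update={"weight": 35.0, "comedications": {"flag"}})
        assert apply_covariates(_spec(rels), patient)["CL_F"] == pytest.approx(5.0 * 0.5 * 2.0)

    def test_power_on_absent_pregnancy_is_domain_error(self):
        rel = CovariateRelation(
            target_param="CL_F", covariate="pregnancy_week", form="power", theta=1.0, ref_value=30
        )
        with pytest.raises(ValueError, match="pregnancy_week"):
            apply_covariates(_spec([rel]), ADULT)


# ---------------------------------------------------------------------------
# Between-subject sampling
# ---------------------------------------------------------------------------


class TestSampling:
    def test_zero_omega_gives_typical_values(self):
        sample = sample_individuals(_spec(), ADULT, 50, seed=1)
        assert np.all(sample.arrays["CL_F"] == 5.0)
        assert np.all(sample.arrays["Ka"] == 1.0)

    def test_lognormal_location_recovered(self):
        spec = _spec(omega={"CL_F": 0.3})
        sample = sample_individuals(spec, ADULT, 10_000, seed=2)
        logs = np.log(sample.arrays["CL_F"])
        se = 0.3 / math.sqrt(len(logs))
        assert abs(logs.mean() - math.log(5.0)) < 3 * se
        assert logs.std() == pytest.approx(0.3, rel=0.05)

    def test_same_seed_bit_identical(self):
        spec = _spec(omega={"CL_F": 0.3, "V_F": 0.2})
        a = sample_individuals(spec, ADULT, 1000, seed=7)
        b = sample_individuals(spec, ADULT, 1000, seed=7)
        assert np.array_equal(a.arrays["CL_F"], b.arrays["CL_F"])
        assert np.array_equal(a.eta, b.eta)

    def test_correlated_etas(self):
        spec = PopPKModelSpec(
            drug_name="t",
            structure="one_cpt_oral",
            typical_params={"CL_F": 5.0, "V_F": 50.0, "Ka": 1.0},
            omega={"CL_F": 0.3, "V_F": 0.2},
            omega_corr=[[1.0, 0.5], [0.5, 1.0]],
        )
        sample = sample_individuals(spec, ADULT, 20_000, seed=3)
        rho = np.corrcoef(sample.eta.T)[0, 1]
        assert rho == pytest.approx(0.5, abs=0.03)

    def test_individual_view(self):
        sample = sample_individuals(_spec(omega={"CL_F": 0.2}), ADULT, 10, seed=4)
        ind = sample[3]
        assert ind["CL_F"] == sample.arrays["CL_F"][3]
        assert len(list(sample)) == 10


# ---------------------------------------------------------------------------
# Closed-form concentration
# ---------------------------------------------------------------------------


class TestClosedForm:
    def test_zero_before_and_at_oral_dose(self):
        ind = {"CL_F": 5.0, "V_F": 50.0, "Ka": 1.0}
        doses = [DoseEvent(10.0, 300.0)]
        assert concentration(ind, doses, 5.0, "one_cpt_oral") == 0.0
        assert concentration(ind, doses, 10.0, "one_cpt_oral") == 0.0
        assert concentration(ind, doses, 11.0, "one_cpt_oral") > 0.0

    def test_missed_dose_contributes_nothing(self):
        ind = {"CL_F": 5.0, "V_F": 50.0, "Ka": 1.0}
        taken = [DoseEvent(0.0, 300.0)]
        with_missed = [DoseEvent(0.0, 300.0), DoseEvent(12.0, 0.0)]
        assert concentration(ind, with_missed, 20.0, "one_cpt_oral") == pytest.approx(
            concentration(ind, taken, 20.0, "one_cpt_oral"), rel=1e-14
        )

    def test_superposition(self):
        ind = {"CL_F": 5.0, "V_F": 50.0, "Ka": 1.0}
        a = [DoseEvent(0.0, 300.0)]
        b = [DoseEvent(12.0, 150.0)]
        both = a + b
        t = 20.0
        assert concentration(ind, both, t, "one_cpt_oral") == pytest.approx(
            concentration(ind, a, t, "one_cpt_oral") + concentration(ind, b, t, "one_cpt_oral"),
            rel=1e-12,
        )

    def test_dose_scale_equivariance_exact(self):
        ind = {"CL_F": 5.0, "V_F": 50.0, "Ka": 1.0}
        doses = [DoseEvent(12.0 * i, 300.0) for i in range(5)]
        scaled = [DoseEvent(d.time, 2.5 * d.amount) for d in doses]
        t = 55.0
        assert concentration(ind, scaled, t, "one_cpt_oral") == pytest.approx(
            2.5 * concentration(ind, doses, t, "one_cpt_oral"), rel=1e-12
        )

    @given(drop=st.integers(min_value=0, max_value=4))
    def test_removing_any_dose_strictly_lowers_concentration(self, drop):
        ind = {"CL_F": 3.5, "V_F": 45.0, "Ka": 1.0}
        doses = [DoseEvent(12.0 * i, 300.0) for i in range(5)]
        edited = [DoseEvent(d.time, 0.0 if i == drop else d.amount) for i, d in enumerate(doses)]
        t = doses[drop].time + 6.0
        full = concentration(ind, doses, t, "one_cpt_oral")
        assert concentration(ind, edited, t, "one_cpt_oral") < full

    def test_tlag_shifts_response(self):
        ind = {"CL_F": 5.0, "V_F": 50.0, "Ka": 1.0, "tlag": 1.5}
        ref = {"CL_F": 5.0, "V_F": 50.0, "Ka": 1.0}
        doses = [DoseEvent(0.0, 300.0)]
        assert concentration(ind, doses, 1.0, "one_cpt_oral") == 0.0
        assert concentration(ind, doses, 6.5, "one_cpt_oral") == pytest.approx(
            concentration(ref, doses, 5.0, "one_cpt_oral"), rel=1e-12
        )

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(5)
        params = {
            "CL_F": 3.5 * np.exp(rng.normal(0, 0.2, 8)),
            "V_F": 45.0 * np.exp(rng.normal(0, 0.2, 8)),
            "Ka": np.full(8, 1.0),
        }
        doses = [DoseEvent(0.0, 300.0), DoseEvent(12.0, 300.0)]
        many = concentration_many(params, doses, 20.0, "one_cpt_oral")
        for i in range(8):
            ind = {k: float(v[i]) for k, v in params.items()}
            assert many[i] == pytest.approx(concentration(ind, doses, 20.0, "one_cpt_oral"), rel=1e-12)

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError, match="structur"):
            concentration({"CL_F": 5.0, "V_F": 50.0}, [DoseEvent(0.0, 100.0)], 1.0, "three_cpt")


def _random_params(rng, structure):
    p = {
        "CL_F": float(rng.uniform(0.5, 15.0)),
        "V_F": float(rng.uniform(20.0, 80.0)),
    }
    if structure != "one_cpt_bolus":
        p["Ka"] = float(rng.uniform(0.4, 3.0))
    if structure == "two_cpt_oral":
        p["Q_F"] = float(rng.uniform(1.0, 10.0))
        p["Vp_F"] = float(rng.uniform(30.0, 120.0))
    if rng.random() < 0.3:
        p["tlag"] = float(rng.uniform(0.0, 1.0)) if structure != "one_cpt_bolus" else 0.0
    if rng.random() < 0.3:
        p["F_rel"] = float(rng.uniform(0.5, 1.0))
    return p


@pytest.mark.parametrize("structure", ["one_cpt_oral", "one_cpt_bolus", "two_cpt_oral"])
def test_closed_form_matches_ode_oracle(structure):
    """Superposition solver vs independent numeric integration, 1e-6 relative."""
    rng = np.random.default_rng(2024)
    doses = [DoseEvent(0.0, 300.0), DoseEvent(12.0, 300.0), DoseEvent(24.0, 0.0), DoseEvent(36.0, 300.0)]
    for _ in range(12):
        p = _random_params(rng, structure)
        t = float(rng.uniform(38.0, 60.0))
        closed = concentration(p, doses, t, structure)
        numeric = ode_concentration(p, doses, t, structure)
        assert closed == pytest.approx(numeric, rel=1e-6)


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------


def _analytic_ss_trough(D, F, Ka, V, k, tau):
    """Closed-form steady-state trough for first-order oral absorption."""
    ek, eka = math.exp(-k * tau), math.exp(-Ka * tau)
    return F * D * Ka / (V * (Ka - k)) * (ek / (1 - ek) - eka / (1 - eka))


class TestSteadyState:
    def test_runin_trough_matches_analytic(self, adult):
        spec = _spec(CL_F=3.5, V_F=45.0, Ka=1.0)
        reg = Regimen(300.0, 12.0)
        hist = steady_state_history(spec, adult, reg, 1)
        trough = concentration(spec.typical_params, hist.events, hist.sampling_time, "one_cpt_oral")
        expected = _analytic_ss_trough(300.0, 1.0, 1.0, 45.0, 3.5 / 45.0, 12.0)
        assert trough == pytest.approx(expected, rel=1e-3)

    def test_consecutive_troughs_converged(self, adult):
        # t1/2 = 10 h with q12h dosing: the stated stopping rule
        spec = _spec(CL_F=math.log(2) / 10.0 * 50.0, V_F=50.0, Ka=1.0)
        hist = steady_state_history(spec, adult, Regimen(300.0, 12.0), 1)
        t_last = hist.sampling_time
        trough = concentration(spec.typical_params, hist.events, t_last, "one_cpt_oral")
        prev = concentration(spec.typical_params, hist.events[:-1], t_last - 12.0, "one_cpt_oral")
        assert abs(trough - prev) / trough < 1e-4

    def test_doubling_runin_changes_little(self, adult):
        spec = _spec(CL_F=3.5, V_F=45.0, Ka=1.0)
        reg = Regimen(300.0, 12.0)
        h1 = steady_state_history(spec, adult, reg, 1)
        h2 = steady_state_history(spec, adult, reg, 1, runin_half_lives=40.0)
        c1 = concentration(spec.typical_params, h1.events, h1.sampling_time, "one_cpt_oral")
        c2 = concentration(spec.typical_params, h2.events, h2.sampling_time, "one_cpt_oral")
        assert abs(c1 - c2) / c2 < 1e-4

    def test_sampling_time_one_interval_after_last_slot(self, adult):
        hist = steady_state_history(_spec(), adult, Regimen(100.0, 8.0), 3)
        assert hist.sampling_time == pytest.approx(hist.events[-1].time + 8.0)
        assert len(hist.editable_slots()) == 3

    def test_invalid_regimen(self):
        with pytest.raises(ValueError):
            Regimen(0.0, 12.0)
        with pytest.raises(ValueError):
            Regimen(100.0, -1.0)


def test_terminal_half_life_two_compartment_is_beta_phase():
    spec = generate_fixture_spec("two_cpt", 1)
    thalf = terminal_half_life(spec.typical_params, "two_cpt_oral")
    # beta must be slower than the one-compartment collapse of the same CL/V
    assert thalf > math.log(2) / (spec.typical_params["CL_F"] / spec.typical_params["V_F"])
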