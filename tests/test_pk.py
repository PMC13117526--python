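"""Two-compartment infusion model: closed forms, derived values, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from pigtrial import pk
from pigtrial.pk import (
    REFERENCE_PARAMS,
    DoseRegimen,
    PKParams,
    concentration,
    derived_params,
    disposition_rates,
    fit_population,
    macro_from_micro,
    micro_constants,
    study_regimen,
)
from pigtrial.synthetic import PK_VALIDATION_TIMES, generate_pk_population


def ode_concentration(times, regimen, params):
    """Independent oracle: numerically integrate the compartment ODEs."""
    k10, k12, k21 = micro_constants(params)

    def infusion_rate(t):
        return sum(
            dose / dur for start, dur, dose in regimen.events if start < t <= start + dur
        )

    def rhs(t, y):
        a1, a2 = y  # amounts (mg)
        da1 = infusion_rate(t) - (k10 + k12) * a1 + k21 * a2
        da2 = k12 * a1 - k21 * a2
        return [da1, da2]

    t_events = sorted({e[0] for e in regimen.events} | {e[0] + e[1] for e in regimen.events})
    sol = solve_ivp(
        rhs, (0.0, max(times)), [0.0, 0.0], t_eval=np.asarray(times),
        rtol=1e-10, atol=1e-12, max_step=0.25, method="LSODA",
    )
    return sol.y[0] / params.V1


class TestMicroConstants:
    def test_one_compartment_degenerate(self):
        k10, k12, k21 = micro_constants(PKParams(CL=3, V1=10, Q=0))
        assert (k10, k12, k21) == (0.3, 0.0, 0.0)

    def test_arithmetic(self):
        k10, k12, k21 = micro_constants(PKParams(CL=3.25, V1=4, Q=2, V2=60))
        assert k10 == pytest.approx(0.8125)
        assert k12 == pytest.approx(0.5)
        assert k21 == pytest.approx(1 / 30, abs=1e-5)

    def test_inconsistent_peripheral(self):
        with pytest.raises(ValueError):
            micro_constants(PKParams(CL=3, V1=10, Q=2, V2=0))

    def test_round_trip_micro_macro(self):
        p = PKParams(CL=3.25, V1=4, Q=2, V2=60)
        k10, k12, k21 = micro_constants(p)
        q = macro_from_micro(k10, k12, k21, p.V1)
        for name in ("CL", "V1", "Q", "V2"):
            assert getattr(q, name) == pytest.approx(getattr(p, name), rel=1e-12)


class TestDispositionRates:
    def test_degenerate_limit(self):
        alpha, beta = disposition_rates(0.3, 0.0, 0.0)
        assert alpha == pytest.approx(0.3)
        assert beta == 0.0

    @pytest.mark.parametrize(
        "k10,k12,k21", [(0.8, 0.5, 0.03), (0.1, 0.9, 0.5), (1.5, 0.01, 0.01)]
    )
    def test_matches_eigenvalues(self, k10, k12, k21):
        alpha, beta = disposition_rates(k10, k12, k21)
        A = np.array([[-(k10 + k12), k21], [k12, -k21]])
        eig = np.sort(np.abs(np.linalg.eigvals(A)))[::-1]
        assert alpha == pytest.approx(eig[0], rel=1e-10)
        assert beta == pytest.approx(eig[1], rel=1e-10)
        # Vieta identities
        assert alpha * beta == pytest.approx(k10 * k21, rel=1e-10)
        assert alpha + beta == pytest.approx(k10 + k12 + k21, rel=1e-10)
        assert alpha >= beta > 0


class TestConcentration:
    def test_zero_before_first_dose(self):
        reg = study_regimen()
        assert concentration(0.5, reg, REFERENCE_PARAMS) == 0.0
        assert concentration(1.0, reg, REFERENCE_PARAMS) == 0.0

    def test_negative_time_errors(self):
        with pytest.raises(ValueError):
            concentration(-1.0, study_regimen(), REFERENCE_PARAMS)

    def test_one_compartment_end_of_infusion_closed_form(self):
        # C(T) = (R0/CL)(1 - exp(-CL T / V1)) for a T-hour infusion at rate R0
        p = PKParams(CL=2.0, V1=5.0, Q=0.0)
        reg = DoseRegimen(events=((0.0, 2.0, 30.0),))
        r0 = 15.0
        expected = (r0 / p.CL) * (1 - np.exp(-p.CL * 2.0 / p.V1))
        assert concentration(2.0, reg, p) == pytest.approx(expected, rel=1e-12)

    def test_superposition_of_three_doses(self):
        reg = study_regimen()
        t = np.linspace(0, 72, 200)
        total = concentration(t, reg, REFERENCE_PARAMS)
        parts = sum(
            concentration(t, DoseRegimen(events=(e,)), REFERENCE_PARAMS)
            for e in reg.events
        )
        np.testing.assert_allclose(total, parts, atol=1e-10)

    def test_dose_proportionality(self):
        reg = study_regimen()
        reg2 = DoseRegimen(events=tuple((s, d, 2 * m) for s, d, m in reg.events))
        t = np.linspace(0, 72, 100)
        np.testing.assert_allclose(
            concentration(t, reg2, REFERENCE_PARAMS),
            2 * concentration(t, reg, REFERENCE_PARAMS),
            rtol=1e-12,
        )

    def test_agrees_with_ode_oracle(self):
        reg = study_regimen()
        t = np.linspace(0.25, 72, 120)
        closed = concentration(t, reg, REFERENCE_PARAMS)
        numeric = ode_concentration(t, reg, REFERENCE_PARAMS)
        rel = np.abs(closed - numeric) / np.maximum(np.abs(numeric), 1e-9)
        assert rel.max() < 1e-6


class TestDerivedParams:
    def test_reference_course_reproduces_study_values(self):
        # 2 kg piglet, single 40 mg dose: terminal half-life ~33 h, AUC ~12.3
        reg = DoseRegimen(events=((1.0, 1.0, 40.0),), weight_kg=2.0)
        d = derived_params(REFERENCE_PARAMS, reg)
        assert d.t_half_beta == pytest.approx(33.0, abs=0.1)
        assert d.auc_inf == pytest.approx(12.3, abs=0.01)

    def test_one_compartment_half_life(self):
        p = PKParams(CL=2.0, V1=10.0)
        d = derived_params(p, DoseRegimen(events=((0.0, 1.0, 20.0),)))
        assert d.t_half_beta == pytest.approx(np.log(2) * p.V1 / p.CL, rel=1e-12)

    def test_auc_matches_quadrature(self):
        reg = study_regimen()
        d = derived_params(REFERENCE_PARAMS, reg)
        from scipy.integrate import quad

        auc_num, _ = quad(
            lambda t: concentration(t, reg, REFERENCE_PARAMS), 0, 2000,
            limit=500, epsabs=1e-10, epsrel=1e-10,
        )
        assert d.auc_inf == pytest.approx(auc_num, rel=1e-3)

    def test_mass_balance_exact(self):
        reg = study_regimen()
        d = derived_params(REFERENCE_PARAMS, reg)
        assert d.auc_inf * REFERENCE_PARAMS.CL == pytest.approx(
            reg.total_dose, rel=1e-12
        )

    def test_auc_monotone_decreasing_in_cl(self):
        reg = study_regimen()
        aucs = [
            derived_params(
                PKParams(CL=cl, V1=20.0, Q=2.0, V2=55.8), reg
            ).auc_inf
            for cl in (1.0, 2.0, 4.0)
        ]
        assert aucs[0] > aucs[1] > aucs[2]

    def test_cmax_at_end_of_an_infusion(self):
        reg = study_regimen()
        d = derived_params(REFERENCE_PARAMS, reg)
        ends = [s + dur for s, dur, _ in reg.events]
        assert min(abs(d.t_cmax - e) for e in ends) < 0.02


class TestFitPopulation:
    def _dataset(self, params, seed, n=6, cv=0.0, times=PK_VALIDATION_TIMES):
        return generate_pk_population(
            pk.PKParams(
                CL=params.CL, V1=params.V1, Q=params.Q, V2=params.V2, cv_prop=cv
            ),
            study_regimen(),
            times,
            n,
            np.random.default_rng(seed),
        )

    def test_noise_free_exact_recovery(self):
        truth = PKParams(CL=3.25, V1=20.0, Q=2.0, V2=55.8)
        df = self._dataset(truth, seed=1, cv=0.0)
        fit = fit_population(
            df, study_regimen(),
            init=PKParams(CL=2.0, V1=10.0, Q=1.0, V2=30.0, cv_prop=0.1),
        )
        for name in ("CL", "V1", "Q", "V2"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-3
            )

    def test_two_compartment_beats_one_on_aic(self):
        truth = PKParams(CL=3.25, V1=20.0, Q=2.0, V2=55.8)
        wins = 0
        for s in range(3):
            df = self._dataset(truth, seed=50 + s, cv=0.15)
            f2 = fit_population(
                df, study_regimen(),
                init=PKParams(CL=2.0, V1=10.0, Q=1.0, V2=30.0, cv_prop=0.1),
            )
            f1 = fit_population(
                df, study_regimen(),
                init=PKParams(CL=2.0, V1=10.0, cv_prop=0.1),
                n_compartments=1,
            )
            wins += f2.aic < f1.aic
        assert wins >= 2

    def test_laplace_mode_recovers_population_cl(self):
        truth = PKParams(CL=3.25, V1=20.0, Q=2.0, V2=55.8, cv_prop=0.2, omega={"CL": 0.3})
        df = generate_pk_population(
            truth, study_regimen(), PK_VALIDATION_TIMES, 12, np.random.default_rng(42)
        )
        fit = fit_population(
            df, study_regimen(),
            init=PKParams(CL=2.0, V1=10.0, Q=1.0, V2=30.0, cv_prop=0.1, omega={"CL": 0.2}),
            method="laplace",
        )
        assert fit.params.CL == pytest.approx(truth.CL, rel=0.2)
        assert 0.05 < fit.params.omega["CL"] < 0.6

    def test_input_validation(self):
        reg = study_regimen()
        df = pd.DataFrame(
            {"subject_id": ["a", "a"], "time_h": [2.0, 25.0], "conc_mg_per_L": [1.0, 1.2]}
        )
        with pytest.raises(ValueError):
            fit_population(df, reg)  # single subject
        with pytest.raises(ValueError):
            fit_population(df.drop(columns="time_h"), reg)


class TestRegimen:
    def test_sorted_and_positive(self):
        with pytest.raises(ValueError):
            DoseRegimen(events=((24.0, 1.0, 40.0), (1.0, 1.0, 40.0)))
        with pytest.raises(ValueError):
            DoseRegimen(events=((0.0, 0.0, 40.0),))
        with pytest.raises(ValueError):
            DoseRegimen(events=())

    def test_study_default(self):
        reg = study_regimen(weight_kg=2.0)
        assert reg.total_dose == pytest.approx(120.0)
        assert [e[0] for e in reg.events] == [1.0, 24.0, 48.0]
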