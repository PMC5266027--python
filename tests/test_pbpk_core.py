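import copy

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

from bolusim import (
    BodyParameters,
    ConstructionError,
    InjectionProtocol,
    PatientProfile,
    ValidationError,
    build_model,
    compute_body_parameters,
    injection_input,
    simulate,
    total_mass_in_system,
)

# --- reference regression constants (first pinned run of the frozen topology)
REFERENCE_PEAK_TIME_S = 27.2
REFERENCE_PEAK_CONC = 7.6707  # mg I/mL at the cerebral arterial tap


class TestInjectionInput:
    def test_plateau_value_during_bolus(self, protocol):
        assert injection_input(protocol, 5.0) == pytest.approx(4 * 370)

    def test_zero_after_bolus_end(self, protocol):
        assert injection_input(protocol, 45 / 4) == 0.0
        assert injection_input(protocol, 60.0) == 0.0

    def test_integral_equals_injected_mass(self, protocol):
        total, err = quad(
            lambda t: injection_input(protocol, t), 0, 100, points=[protocol.duration_s]
        )
        assert total == pytest.approx(45 * 370, rel=1e-9)

    def test_negative_time_rejected(self, protocol):
        with pytest.raises(ValidationError):
            injection_input(protocol, -1.0)

    def test_protocol_invariants(self):
        with pytest.raises(ValidationError, match="rate_ml_s"):
            InjectionProtocol(rate_ml_s=0)
        with pytest.raises(ValidationError, match="volume_ml"):
            InjectionProtocol(volume_ml=-1)


class TestBuildModel:
    def test_state_dimension_matches_documented_counts(self, config, reference_profile):
        body = compute_body_parameters(reference_profile, config)
        assert build_model(body, config, recirculation=True).n_states == 44
        # single-pass default appends an absorbing sink state
        assert build_model(body, config, recirculation=False).n_states == 45

    def test_single_pass_graph_is_acyclic_and_ends_in_sink(self, reference_model):
        assert reference_model.state_names[-1] == "sink"
        assert not reference_model.recirculation

    def test_cycle_with_recirculation_off_is_construction_error(
        self, config, reference_profile
    ):
        cfg = copy.deepcopy(config)
        for edge in cfg["topology"]["edges"]:
            edge.pop("returns", None)  # keep the loop closed in single-pass mode
        body = compute_body_parameters(reference_profile, cfg)
        with pytest.raises(ConstructionError, match="cycle"):
            build_model(body, cfg, recirculation=False)

    def test_unbalanced_flow_names_offending_node(self, config, reference_profile):
        cfg = copy.deepcopy(config)
        edge = next(
            e for e in cfg["topology"]["edges"]
            if (e["source"], e["target"]) == ("carotid_artery", "cerebral_artery")
        )
        edge["flow_fraction"] *= 1.5
        body = compute_body_parameters(reference_profile, cfg)
        with pytest.raises(ConstructionError, match="carotid_artery|cerebral_artery"):
            build_model(body, cfg, recirculation=False)


class TestSimulate:
    def test_zero_dose_gives_identically_zero_curve(self, reference_model):
        proto = InjectionProtocol(volume_ml=0.0)
        curve = simulate(reference_model, proto, t_end_s=60.0)
        assert np.all(curve.concentration["cerebral_artery"] == 0.0)
        assert np.all(curve.states == 0.0)

    def test_dose_linearity(self, reference_model, protocol, reference_curve):
        doubled = InjectionProtocol(
            volume_ml=protocol.volume_ml,
            rate_ml_s=protocol.rate_ml_s,
            iodine_mg_ml=2 * protocol.iodine_mg_ml,
        )
        c2 = simulate(reference_model, doubled, t_end_s=90.0)
        a = reference_curve.concentration["cerebral_artery"]
        b = c2.concentration["cerebral_artery"]
        scale = a.max()
        assert np.allclose(b, 2 * a, atol=2e-6 * scale, rtol=1e-6)

    def test_cerebral_curve_shape_and_peak_window(self, reference_curve):
        """Single dominant peak within the clinically observed first-pass window."""
        c = reference_curve.concentration["cerebral_artery"]
        t = reference_curve.time_s
        i = int(np.argmax(c))
        assert c[0] == 0.0
        assert 10.0 <= t[i] <= 35.0
        assert t[i] == pytest.approx(REFERENCE_PEAK_TIME_S, abs=0.2)
        assert c[i] == pytest.approx(REFERENCE_PEAK_CONC, rel=1e-3)
        # unimodal at the grid level: rises to the peak, decays after
        tol = 1e-9 * c.max()
        assert np.all(np.diff(c[: i + 1]) >= -tol)
        assert np.all(np.diff(c[i:]) <= tol)

    def test_mass_conservation_and_non_negativity(self, reference_curve, protocol):
        assert reference_curve.mass_balance_error() <= 1e-6
        assert reference_curve.states.min() >= 0.0

    def test_total_mass_helper_matches_cumulative_input(
        self, reference_model, reference_curve, protocol
    ):
        k = 300  # t = 30 s, injection finished
        total = total_mass_in_system(reference_model, reference_curve.states[k])
        assert total == pytest.approx(protocol.total_mass_mg, rel=1e-6)
        assert total_mass_in_system(
            reference_model, np.zeros(reference_model.n_states)
        ) == 0.0

    def test_sink_absorbs_entire_dose_asymptotically(self, reference_model, protocol):
        curve = simulate(reference_model, protocol, t_end_s=3000.0, dt_out_s=5.0)
        sink = curve.states[-1, -1]
        assert sink / protocol.total_mass_mg > 0.99

    def test_dt_out_only_resamples(self, reference_model, protocol, reference_curve):
        fine = simulate(reference_model, protocol, t_end_s=90.0, dt_out_s=0.05)
        coarse = reference_curve.concentration["cerebral_artery"]
        assert np.allclose(
            fine.concentration["cerebral_artery"][::2], coarse, rtol=1e-9, atol=1e-12
        )

    def test_solver_convergence_on_refinement(self, reference_model, protocol, reference_curve):
        tight = simulate(reference_model, protocol, t_end_s=90.0, rtol=5e-9, atol=5e-11)
        a = reference_curve.concentration["cerebral_artery"]
        b = tight.concentration["cerebral_artery"]
        assert abs(b.max() - a.max()) / a.max() < 1e-3
        t = reference_curve.time_s
        assert abs(t[np.argmax(b)] - t[np.argmax(a)]) <= 0.1

    def test_ps_zero_organ_has_empty_extracellular_space(self, reference_model, reference_curve):
        # brain PS = 0 in the default table (intact blood-brain barrier)
        idx = reference_model.state_index("brain_ec")
        assert np.all(reference_curve.states[:, idx] == 0.0)

    def test_short_window_rejected(self, reference_model, protocol):
        with pytest.raises(ValidationError, match="scan window"):
            simulate(reference_model, protocol, t_end_s=30.0)

    def test_overlong_injection_warns_but_runs(self, config, reference_profile):
        body = compute_body_parameters(reference_profile, config)
        model = build_model(body, config)
        proto = InjectionProtocol(volume_ml=400.0, rate_ml_s=4.0, scan_delay_s=5.0,
                                  scan_duration_s=50.0)
        with pytest.warns(UserWarning, match="outlasts"):
            simulate(model, proto, t_end_s=60.0)


class TestWeightDependence:
    def test_peak_enhancement_strictly_decreasing_in_weight(self, config, protocol):
        """Heavier patients dilute the bolus: ME(50) > ME(75) > ME(100)."""
        peaks = []
        for w in (50.0, 75.0, 100.0):
            p = PatientProfile(sex="male", height_cm=170.0, weight_kg=w)
            body = compute_body_parameters(p, config)
            model = build_model(body, config)
            curve = simulate(model, protocol, t_end_s=90.0)
            peaks.append(curve.concentration["cerebral_artery"].max())
        assert peaks[0] > peaks[1] > peaks[2]


def _two_tank_model(v1: float, v2: float, q: float):
    """Toy cascade A -> B -> sink used against the closed-form washout."""
    body = BodyParameters(
        total_blood_volume=v1 + v2,
        cardiac_output=q,
        regional_flow={"A": q, "B": q},
        regional_blood_volume={"A": v1, "B": v2},
    )
    cfg = {
        "compartments": [
            {"name": "A", "kind": "vascular", "flow_fraction": 1.0,
             "blood_volume_fraction": v1 / (v1 + v2)},
            {"name": "B", "kind": "vascular", "flow_fraction": 1.0,
             "blood_volume_fraction": v2 / (v1 + v2)},
        ],
        "topology": {
            "injection_site": "A",
            "output_taps": ["B"],
            "edges": [
                {"source": "A", "target": "B", "flow_fraction": 1.0},
                {"source": "B", "target": "A", "flow_fraction": 1.0, "returns": True},
            ],
        },
    }
    return build_model(body, cfg, recirculation=False)


class TestWashoutOracle:
    def test_integrator_matches_two_tank_closed_form(self):
        """a1 = m0 e^{-k1 t}; a2 = m0 k1/(k2-k1) (e^{-k1 t} - e^{-k2 t})."""
        v1, v2, q, m0 = 40.0, 25.0, 5.0, 1000.0
        model = _two_tank_model(v1, v2, q)
        proto = InjectionProtocol(volume_ml=0.0, scan_delay_s=1.0, scan_duration_s=1.0)
        curve = simulate(
            model, proto, t_end_s=60.0, dt_out_s=0.1,
            initial_state=np.array([m0, 0.0, 0.0]),
        )
        t = curve.time_s
        k1, k2 = q / v1, q / v2
        a1 = m0 * np.exp(-k1 * t)
        a2 = m0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
        assert np.max(np.abs(curve.states[:, 0] - a1)) / m0 < 1e-6
        assert np.max(np.abs(curve.states[:, 1] - a2)) / m0 < 1e-6
        # sink holds exactly the mass the tanks have released
        assert curve.states[-1, 2] == pytest.approx(m0 - a1[-1] - a2[-1], abs=1e-3)

    def test_integrator_matches_matrix_exponential_on_default_model(
        self, reference_model, protocol, reference_curve
    ):
        """Piecewise-exact LTI solution as an independent numerical oracle."""
        A = reference_model.matrix
        n = reference_model.n_states
        u = np.zeros(n)
        u[reference_model.state_index("antecubital_vein")] = (
            protocol.rate_ml_s * protocol.iodine_mg_ml
        )
        t_inj = protocol.duration_s

        def forced_response(t):
            # augmented exponential handles the singular (absorbing) A:
            # expm([[A, u], [0, 0]] t) top-right block = int_0^t expm(A s) u ds
            M = np.zeros((n + 1, n + 1))
            M[:n, :n] = A
            M[:n, n] = u
            return expm(M * t)[:n, n]

        for t_check in (5.0, 11.2, 30.0, 60.0):  # output-grid times
            if t_check <= t_inj:
                a = forced_response(t_check)
            else:
                a = expm(A * (t_check - t_inj)) @ forced_response(t_inj)
            k = int(round(t_check / 0.1))
            sim = reference_curve.states[k]
            assert np.allclose(sim, a, rtol=1e-6, atol=1e-6 * protocol.total_mass_mg)
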