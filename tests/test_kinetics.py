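"""Hill regulation, cell classification and reaction terms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eyedisc import (
    FieldState,
    ModelParameters,
    classify_cells,
    hh_boundary_flux,
    hill_activation,
    hill_inhibition,
    initial_state,
    reaction_rates,
)
from eyedisc.errors import (
    ConfigurationRejected,
    InvalidArgument,
    InvalidState,
    ShapeIncompatible,
)

HOUR = 3600.0


class TestHill:
    @pytest.mark.parametrize(
        "c, K, n, expected",
        [
            (2.0, 2.0, 1.0, 0.5),      # half-max at c = K for any n
            (2.0, 2.0, 4.0, 0.5),
            (0.0, 1.0, 2.0, 0.0),
            (3.0, 1.0, 2.0, 9.0 / 10.0),  # c = 3K, n = 2
        ],
    )
    def test_activation_values(self, c, K, n, expected):
        assert hill_activation(c, K, n) == pytest.approx(expected, rel=1e-12)

    def test_inhibition_values(self):
        assert hill_inhibition(0.0, 1.0, 2.0) == 1.0
        assert hill_inhibition(1.0, 1.0, 2.0) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=100)
    @given(
        c=st.floats(0.0, 1e6),
        K=st.floats(1e-6, 1e3),
        n=st.floats(1.0, 8.0),
    )
    def test_complement_identity_and_range(self, c, K, n):
        sig = hill_activation(c, K, n)
        sigbar = hill_inhibition(c, K, n)
        assert 0.0 <= sig <= 1.0
        assert sig + sigbar == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        K=st.floats(1e-3, 10.0),
        n=st.floats(1.0, 6.0),
        c1=st.floats(0.0, 100.0),
        c2=st.floats(0.0, 100.0),
    )
    def test_monotonicity(self, K, n, c1, c2):
        lo, hi = sorted((c1, c2))
        assert hill_activation(lo, K, n) <= hill_activation(hi, K, n) + 1e-15

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgument):
            hill_activation(-1.0, 1.0, 2.0)
        with pytest.raises(InvalidArgument):
            hill_activation(1.0, 0.0, 2.0)
        with pytest.raises(InvalidArgument):
            hill_activation(1.0, 1.0, 0.0)


class TestClassification:
    def test_three_states(self):
        p = ModelParameters()
        hth = np.array([p.theta_Hth * 2, p.theta_Hth / 2, p.theta_Hth / 2])
        hh = np.array([p.theta_Hh * 5, p.theta_Hh / 2, p.theta_Hh * 5])
        Pi, Theta, Phi = classify_cells(hth, hh, p)
        # progenitor regardless of Hh; furrow; differentiated
        assert Pi.tolist() == [1, 0, 0]
        assert Theta.tolist() == [0, 1, 0]
        assert Phi.tolist() == [0, 0, 1]

    def test_boundary_is_closed_below(self):
        """H(x) = 0 at x = 0: a cell exactly at threshold is not progenitor."""
        p = ModelParameters()
        Pi, Theta, Phi = classify_cells(
            np.array([p.theta_Hth]), np.array([p.theta_Hh]), p
        )
        assert (Pi[0], Theta[0], Phi[0]) == (0.0, 1.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        hth=st.lists(st.floats(0, 2), min_size=1, max_size=20),
        hh=st.floats(0, 1),
    )
    def test_partition_of_unity(self, hth, hh):
        p = ModelParameters()
        arr = np.array(hth)
        Pi, Theta, Phi = classify_cells(arr, np.full_like(arr, hh), p)
        np.testing.assert_allclose(Pi + Theta + Phi, 1.0, atol=1e-14)

    def test_smoothed_partition_within_tolerance(self):
        p = ModelParameters()
        hth = np.linspace(0, 1, 101)
        hh = np.linspace(0, 0.1, 101)
        Pi, Theta, Phi = classify_cells(hth, hh, p, smooth=True)
        np.testing.assert_allclose(Pi + Theta + Phi, 1.0, atol=1e-12)

    def test_mesh_mismatch_rejected(self):
        with pytest.raises(ShapeIncompatible):
            classify_cells(np.zeros(3), np.zeros(4), ModelParameters())


class TestReactionRates:
    def _state(self, p, **over):
        n = 4
        fields = {k: np.zeros(n) for k in ("c_Hh", "c_Dpp", "c_pMad", "c_Eya", "c_Hth")}
        fields.update(over)
        st = FieldState(**fields)
        st.Pi, st.Theta, st.Phi = classify_cells(st.c_Hth, st.c_Hh, p)
        return st

    def test_hh_production_in_differentiated_region(self):
        p = ModelParameters()
        st = self._state(p, c_Hh=np.full(4, p.theta_Hh * 10))
        # c_Hth = 0 < theta, c_Hh high -> Phi = 1 everywhere
        rates = reaction_rates(st, p)
        expected = p.p_Hh - p.delta_Hh * p.theta_Hh * 10
        np.testing.assert_allclose(rates["Hh"], expected)

    def test_hth_steady_state_is_stationary(self):
        p = ModelParameters()
        st = self._state(p, c_Hth=np.full(4, p.p_Hth / p.delta_Hth))
        np.testing.assert_allclose(reaction_rates(st, p)["Hth"], 0.0, atol=1e-18)

    def test_dpp_decay_only_without_furrow(self):
        p = ModelParameters()
        st = self._state(
            p,
            c_Hth=np.full(4, 2 * p.theta_Hth),  # all progenitor: Theta = 0
            c_Dpp=np.full(4, 0.5),
            c_Hh=np.full(4, 0.01),
        )
        np.testing.assert_allclose(
            reaction_rates(st, p)["Dpp"], -p.delta_Dpp * 0.5
        )

    def test_production_scales_with_indicator(self):
        """R_Hh production term is exactly linear in Phi."""
        p = ModelParameters()
        st = self._state(p, c_Hh=np.full(4, p.theta_Hh * 10))
        r1 = reaction_rates(st, p)["Hh"] + p.delta_Hh * st.c_Hh
        st.Phi = st.Phi * 0.5
        r2 = reaction_rates(st, p)["Hh"] + p.delta_Hh * st.c_Hh
        np.testing.assert_allclose(r2, 0.5 * r1)

    def test_negative_concentration_rejected(self):
        p = ModelParameters()
        st = self._state(p)
        st.c_Dpp[0] = -1e-9
        with pytest.raises(InvalidState):
            reaction_rates(st, p)


class TestInitialState:
    def test_progenitor_steady_state(self):
        p = ModelParameters()
        st = initial_state(p, 10)
        np.testing.assert_allclose(st.c_Hth, p.p_Hth / p.delta_Hth)
        np.testing.assert_allclose(st.Pi, 1.0)
        assert st.c_Hh.sum() == 0.0  # no Hh mass initially

    def test_relaxation_to_steady_state_matches_closed_form(self):
        """With repression absent the Hth ODE relaxes as an exponential."""
        p = ModelParameters()
        c0, target = 0.2, p.p_Hth / p.delta_Hth
        t = np.linspace(0, 10 * HOUR, 2000)
        # fine explicit integration of dc/dt = p - delta c
        c = np.empty_like(t)
        c[0] = c0
        dt = t[1] - t[0]
        for i in range(1, len(t)):
            c[i] = c[i - 1] + dt * (p.p_Hth - p.delta_Hth * c[i - 1])
        exact = target + (c0 - target) * np.exp(-p.delta_Hth * t)
        np.testing.assert_allclose(c, exact, rtol=1e-3)
        # analytic limit
        assert abs(exact[-1] - target) / target < np.exp(-p.delta_Hth * t[-1]) + 1e-10

    def test_subthreshold_configuration_rejected(self):
        with pytest.raises(ConfigurationRejected):
            ModelParameters(theta_Hth=1.5)


class TestBoundaryFlux:
    def test_margin_and_ramp(self):
        p = ModelParameters()
        L = 100.0
        assert hh_boundary_flux(0.1 * L, 5 * HOUR, L, p) == pytest.approx(p.eta)
        assert hh_boundary_flux(0.5 * L, 5 * HOUR, L, p) == 0.0
        # midpoint of the shutdown ramp
        t_mid = 0.5 * (p.t_on + p.t_off)
        assert hh_boundary_flux(0.0, p.t_off, L, p) == pytest.approx(0.5 * p.eta)
        assert hh_boundary_flux(0.0, 10.25 * HOUR, L, p) == pytest.approx(0.75 * p.eta)
        assert hh_boundary_flux(0.0, 11 * HOUR, L, p) == 0.0

    def test_invalid_arguments(self):
        p = ModelParameters()
        with pytest.raises(InvalidArgument):
            hh_boundary_flux(0.0, -1.0, 100.0, p)
        with pytest.raises(InvalidArgument):
            hh_boundary_flux(0.0, 0.0, 0.0, p)


class TestParameters:
    def test_yaml_roundtrip(self, tmp_path):
        p = ModelParameters(eta=1.23e-4)
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        assert ModelParameters.from_yaml(path) == p

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigurationRejected):
            ModelParameters.from_dict({"not_a_parameter": 1.0})

    def test_hill_override(self):
        p = ModelParameters(hill_overrides={"K_Hh_hth": 0.123})
        assert p.hill("Hh", "hth") == (0.123, p.n_Hh)
        assert p.hill("Hh", "eya") == (p.K_Hh, p.n_Hh)
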