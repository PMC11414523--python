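"""Transfer functions, closed-form voltages/delta-T, and the numerical line
integral, checked against direct arithmetic and quadrature oracles."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from rflead import (
    ConstantField,
    HeatingCurve,
    ModelKind,
    SingularDenominatorError,
    TransferModel,
    Wavenumber,
    closed_form_voltage_sem,
    closed_form_voltage_tlm,
    delta_T_sem,
    delta_T_tlm,
    heating_curve,
    numerical_voltage,
    sem_transfer,
    straight_path,
    tlm_transfer,
)

wavenumbers = st.builds(
    Wavenumber,
    kR=st.floats(0.5, 40.0),
    kI=st.floats(-20.0, 0.0),
)


def _quadrature_voltage(E: complex, transfer, d: float) -> complex:
    re, _ = quad(lambda l: (transfer(l) * E).real, 0, d, limit=200)
    im, _ = quad(lambda l: (transfer(l) * E).imag, 0, d, limit=200)
    return complex(re, im)


class TestTransferFunctions:
    def test_sem_boundary_and_half_wavelength(self, king30):
        assert sem_transfer(king30, 0.0) == 1.0
        k = Wavenumber(10.0, 0.0)
        assert sem_transfer(k, math.pi / 10.0) == pytest.approx(-1.0)

    def test_sem_direct_arithmetic(self, king30):
        l = 0.1
        expected = cmath.exp(-1j * complex(king30.kR, king30.kI) * l)
        assert sem_transfer(king30, l) == pytest.approx(expected, rel=1e-14)

    def test_sem_negative_length_rejected(self, king30):
        with pytest.raises(ValueError):
            sem_transfer(king30, -0.01)

    def test_sem_magnitude_never_grows(self, king30):
        l = np.linspace(0, 1.0, 200)
        mags = np.abs(sem_transfer(king30, l))
        assert mags[0] == pytest.approx(1.0)
        assert np.all(np.diff(mags) <= 1e-15)

    def test_tlm_boundary_condition(self, king15):
        for gamma in (0.0, 0.3, 1.0):
            assert tlm_transfer(king15, gamma, 0.0, 0.4) == pytest.approx(1.0)

    def test_tlm_reduces_to_sem_at_zero_gamma(self, king15):
        l = np.linspace(0, 0.4, 9)
        np.testing.assert_allclose(
            tlm_transfer(king15, 0.0, l, 0.4), sem_transfer(king15, l), rtol=1e-12
        )

    def test_tlm_direct_arithmetic(self, king15):
        k, gamma, d, l = complex(king15.kR, king15.kI), 1.0, 0.4, 0.2
        expected = (
            cmath.exp(-1j * k * l)
            * (1 - gamma * cmath.exp(-2j * k * (d - l)))
            / (1 - gamma * cmath.exp(-2j * k * d))
        )
        assert tlm_transfer(king15, gamma, l, d) == pytest.approx(expected, rel=1e-14)

    def test_tlm_singular_pole(self):
        k = Wavenumber(10.0, 0.0)  # lossless
        d = math.pi / 10.0  # 2*k*d = 2*pi: exp term = 1, gamma = 1 -> pole
        with pytest.raises(SingularDenominatorError):
            tlm_transfer(k, 1.0, 0.1, d)

    def test_out_of_range_l_rejected(self, king15):
        with pytest.raises(ValueError):
            tlm_transfer(king15, 0.5, 0.5, 0.4)


class TestClosedFormVoltage:
    def test_zero_length_gives_zero(self, king30):
        assert closed_form_voltage_sem(100.0, king30, 0.0) == 0
        assert closed_form_voltage_tlm(100.0, king30, 0.5, 0.0) == pytest.approx(0.0)

    def test_full_wavelength_real_k_gives_zero(self):
        k = Wavenumber(10.0, 0.0)
        assert abs(closed_form_voltage_sem(1.0, k, 2 * math.pi / 10.0)) < 1e-13

    def test_k_zero_limit_is_length_times_field(self):
        k = Wavenumber(0.0, 0.0)
        assert closed_form_voltage_sem(3.0, k, 0.25) == pytest.approx(0.75)
        assert closed_form_voltage_tlm(3.0, k, 0.5, 0.25) == pytest.approx(0.75)

    @pytest.mark.parametrize("d", [0.05, 0.25, 0.6])
    def test_sem_matches_quadrature(self, king30, d):
        E = 80.0 - 35.0j
        v = closed_form_voltage_sem(E, king30, d)
        ref = _quadrature_voltage(E, lambda l: sem_transfer(king30, l), d)
        assert v == pytest.approx(ref, rel=1e-6)

    @pytest.mark.parametrize("gamma", [0.0, 0.5, 1.0])
    def test_tlm_matches_quadrature(self, king30, gamma):
        E, d = 100.0, 0.25
        v = closed_form_voltage_tlm(E, king30, gamma, d)
        ref = _quadrature_voltage(E, lambda l: tlm_transfer(king30, gamma, l, d), d)
        assert v == pytest.approx(ref, rel=1e-6)

    def test_tlm_gamma_zero_is_sem(self, king15):
        for d in (0.1, 0.44, 0.7):
            assert closed_form_voltage_tlm(1.0, king15, 0.0, d) == pytest.approx(
                closed_form_voltage_sem(1.0, king15, d), rel=1e-12
            )


class TestDeltaT:
    def test_nonnegative_everywhere(self, king15):
        d = np.linspace(0.0, 1.0, 400)
        assert np.all(np.asarray(delta_T_sem(1.0, king15, d)) >= 0)
        assert np.all(np.asarray(delta_T_tlm(1.0, king15, 0.7, d)) >= 0)

    def test_sem_equals_voltage_magnitude_squared(self, king30):
        for d in (0.02, 0.2275, 0.5):
            assert delta_T_sem(2.5, king30, d) == pytest.approx(
                abs(closed_form_voltage_sem(2.5, king30, d)) ** 2, rel=1e-12
            )

    @given(
        k=wavenumbers,
        gamma=st.floats(0.0, 0.999),
        d=st.floats(1e-3, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_tlm_closed_form_is_voltage_squared(self, k, gamma, d):
        """The trig/hyperbolic delta-T expression is algebraically identical
        to |V|^2 for real reflection coefficients.  Restricted to k*d away
        from zero: for k*d -> 0 both sides cancel catastrophically in
        floating point and no fixed tolerance is meaningful."""
        assume(k.magnitude * d >= 0.05)
        expected = abs(closed_form_voltage_tlm(1.0, k, gamma, d)) ** 2
        assert delta_T_tlm(1.0, k, gamma, d) == pytest.approx(expected, rel=1e-6, abs=1e-30)

    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.7, 1.0])
    def test_tlm_closed_form_tight_agreement_at_moderate_length(self, king15, gamma):
        for d in (0.1, 0.3, 0.46):
            expected = abs(closed_form_voltage_tlm(1.0, king15, gamma, d)) ** 2
            assert delta_T_tlm(1.0, king15, gamma, d) == pytest.approx(expected, rel=1e-10)

    def test_complex_gamma_routes_through_voltage(self, king15):
        gamma = 0.3 + 0.2j
        d = 0.3
        assert delta_T_tlm(1.0, king15, gamma, d) == pytest.approx(
            abs(closed_form_voltage_tlm(1.0, king15, gamma, d)) ** 2, rel=1e-12
        )

    def test_reduction_chain_at_zero_gamma(self, king30):
        """TLM -> SEM at gamma = 0 holds for h, V, and delta_T together."""
        d = 0.31
        l = np.linspace(0, d, 7)
        np.testing.assert_allclose(
            tlm_transfer(king30, 0.0, l, d), sem_transfer(king30, l), rtol=1e-12
        )
        assert closed_form_voltage_tlm(1.0, king30, 0.0, d) == pytest.approx(
            closed_form_voltage_sem(1.0, king30, d), rel=1e-12
        )
        assert delta_T_tlm(1.0, king30, 0.0, d) == pytest.approx(
            delta_T_sem(1.0, king30, d), rel=1e-12
        )

    def test_short_wire_quadratic_sem(self, king30):
        """For kd << 1 the rise is quadratic in length: delta_T ~ E^2 d^2."""
        d = 1e-3 / king30.magnitude
        ratio = delta_T_sem(1.0, king30, d) / d**2
        assert 0.99 <= ratio <= 1.01

    def test_short_wire_quarter_for_open_end(self, king30):
        """With full reflection the short-wire rise is reduced fourfold."""
        d = 1e-3 / king30.magnitude
        ratio = delta_T_tlm(1.0, king30, 1.0, d) / d**2
        assert 0.99 / 4 <= ratio <= 1.01 / 4


class TestHeatingCurve:
    def test_validation(self):
        with pytest.raises(ValueError):
            HeatingCurve(np.array([0.1, 0.1]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            HeatingCurve(np.array([0.1, 0.2]), np.array([1.0, -2.0]))

    def test_csv_round_trip(self, king30, tmp_path):
        hc = heating_curve(TransferModel(ModelKind.SEM, king30), np.linspace(0.01, 0.5, 50))
        p = tmp_path / "curve.csv"
        hc.to_csv(p)
        back = HeatingCurve.from_csv(p)
        np.testing.assert_allclose(back.lengths, hc.lengths)
        np.testing.assert_allclose(back.relative_delta_T, hc.relative_delta_T)


class TestNumericalVoltage:
    def test_zero_field_gives_zero(self, king30):
        path = straight_path([0, 0, 0], [0, 0, 1], 0.2, 0.002)
        v = numerical_voltage(ConstantField([0, 0, 0]), path, TransferModel(ModelKind.SEM, king30))
        assert v == 0

    def test_constant_field_matches_closed_form(self, king30):
        d = 0.3
        path = straight_path([0, 0, 0], [0, 0, 1], d, 0.001)
        v = numerical_voltage(
            ConstantField([0, 0, 100.0]), path, TransferModel(ModelKind.SEM, king30)
        )
        assert v == pytest.approx(closed_form_voltage_sem(100.0, king30, d), rel=1e-4)

    def test_first_order_convergence(self, king30):
        """Halving the step at least halves the error against the closed form."""
        d, E = 0.3, 100.0
        exact = closed_form_voltage_sem(E, king30, d)
        errors = []
        for step in (4e-3, 2e-3, 1e-3):
            path = straight_path([0, 0, 0], [0, 0, 1], d, step)
            v = numerical_voltage(
                ConstantField([0, 0, E]), path, TransferModel(ModelKind.SEM, king30)
            )
            errors.append(abs(v - exact))
        assert errors[0] / errors[1] >= 2.0
        assert errors[1] / errors[2] >= 2.0

    def test_tlm_constant_field_matches_closed_form(self, king30):
        d = 0.25
        path = straight_path([0, 0, 0], [0, 0, 1], d, 0.0005)
        model = TransferModel(ModelKind.TLM, king30, 0.5, d)
        v = numerical_voltage(ConstantField([0, 0, 1.0]), path, model)
        assert v == pytest.approx(closed_form_voltage_tlm(1.0, king30, 0.5, d), rel=1e-5)

    def test_tip_and_proximal_forms_agree_for_symmetric_field(self, king15):
        """A constant (hence symmetric) field gives the same |V| whether the
        transfer function is parameterized from the tip or the capped end."""
        d = 0.4
        path = straight_path([0, 0, -d / 2], [0, 0, 1], d, 0.001)
        model = TransferModel(ModelKind.TLM, king15, 0.6, d)
        field = ConstantField([0, 0, 50.0 - 20.0j])
        v_tip = numerical_voltage(field, path, model)
        v_prox = numerical_voltage(field, path, model, proximal_form=True)
        assert abs(v_tip) == pytest.approx(abs(v_prox), rel=1e-9)

    def test_out_of_domain_point_named(self, king30):
        from rflead import EFieldGrid

        ax = np.linspace(-0.1, 0.1, 5)
        grid = EFieldGrid(ax, ax, ax, np.zeros((5, 5, 5, 3), dtype=complex))
        path = straight_path([0, 0, 0], [0, 0, 1], 0.5, 0.01)  # exits the grid
        with pytest.raises(ValueError, match="outside"):
            numerical_voltage(grid, path, TransferModel(ModelKind.SEM, king30))
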