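"""Spectral-density forms: evaluation, normalization, asymptotics, assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

import sdtails as st
from sdtails.spectral_density import SINGLE_PEAK_FORMS, TWO_PEAK_FORMS


def make_peak(form, omega=1500.0, lam=20.0, gamma=10.0):
    if form == "drude_lorentz":
        return st.PeakSpec(form, 0.0, lam, gamma)
    if form in TWO_PEAK_FORMS:
        return st.PeakSpec(form, omega, lam, gamma, omega2=0.8 * omega, gamma2=2 * gamma)
    return st.PeakSpec(form, omega, lam, gamma)


class TestEvaluation:
    def test_displaced_drude_peak_height(self):
        # closed form lambda*omega/(pi*gamma) plus the mirror-Lorentzian tail
        pk = st.PeakSpec("displaced_drude", 1500.0, 20.0, 10.0)
        assert st.evaluate_sd(pk, 1500.0) == pytest.approx(954.94, abs=0.5)

    def test_solvent_value_at_electronic_gap(self):
        # independent closed form 2*lam*gamma*w/(pi*(w^2+gamma^2))
        pk = st.PeakSpec("drude_lorentz", 0.0, 715.7, 54.5)
        expected = 2 * 715.7 * 54.5 * 35650.0 / (math.pi * (35650.0**2 + 54.5**2))
        assert st.evaluate_sd(pk, 35650.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.6965, abs=2e-4)

    @pytest.mark.parametrize("form", st.FORMS)
    def test_zero_at_origin_and_odd(self, form):
        pk = make_peak(form)
        assert st.evaluate_sd(pk, 0.0) == 0.0
        w = np.array([3.0, 77.7, 1500.0, 40000.0])
        np.testing.assert_allclose(
            st.evaluate_sd(pk, -w), -st.evaluate_sd(pk, w), rtol=1e-12
        )

    @pytest.mark.parametrize("form", st.FORMS)
    def test_positive_on_positive_axis(self, form):
        pk = make_peak(form)
        w = np.geomspace(0.1, 1e5, 400)
        assert np.all(st.evaluate_sd(pk, w) > 0)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            st.PeakSpec("lorentz_exp", 1500.0, 20.0, 10.0)

    def test_drude_lorentz_requires_zero_center(self):
        with pytest.raises(ValueError, match="omega = 0"):
            st.PeakSpec("drude_lorentz", 100.0, 20.0, 10.0)


class TestNormalization:
    @settings(max_examples=25, deadline=None)
    @given(
        form=hs.sampled_from(st.FORMS),
        omega=hs.floats(300.0, 4000.0),
        lam=hs.floats(1.0, 500.0),
        gamma=hs.floats(2.0, 60.0),
        ratio=hs.floats(0.5, 0.95),
    )
    def test_reorganization_energy_matches_lambda(self, form, omega, lam, gamma, ratio):
        """lambda = int J/omega for every form and random valid parameters."""
        if form == "drude_lorentz":
            pk = st.PeakSpec(form, 0.0, lam, gamma)
        elif form in TWO_PEAK_FORMS:
            pk = st.PeakSpec(form, omega, lam, gamma, omega2=ratio * omega, gamma2=1.7 * gamma)
        else:
            pk = st.PeakSpec(form, omega, lam, gamma)
        assert st.reorganization_energy(pk) == pytest.approx(lam, rel=1e-9)
        assert st.reorganization_energy(pk, method="quad") == pytest.approx(lam, rel=1e-6)

    def test_solvent_row_reorganization(self):
        pk = st.PeakSpec("drude_lorentz", 0.0, 715.7, 54.5)
        assert st.reorganization_energy(pk) == pytest.approx(715.7, rel=1e-10)

    def test_composite_total_is_column_sum(self, table1):
        model = st.assemble_from_table(table1, "displaced_drude")
        assert st.reorganization_energy(model) == pytest.approx(1569.5, rel=1e-9)

    @pytest.mark.parametrize("form", TWO_PEAK_FORMS)
    def test_two_peak_pair_intensity(self, form, table1):
        model = st.assemble_from_table(table1, form)
        assert st.reorganization_energy(model, method="quad") == pytest.approx(
            1569.5, rel=1e-6
        )


class TestAsymptotics:
    @pytest.mark.parametrize(
        "form, low, high",
        [
            ("drude_lorentz", 1, -1),
            ("displaced_drude", 1, -1),
            ("ubo", 1, -3),
            ("rlc", 3, -1),
            ("ohmic_2pk", 1, -7),
            ("superohmic_2pk", 3, -5),
        ],
    )
    def test_power_laws(self, form, low, high):
        a = st.asymptotics(make_peak(form))
        assert a.low_exponent == low
        assert a.high_exponent == high
        assert a.low_exponent_numeric == pytest.approx(low, rel=0.01)
        assert a.high_exponent_numeric == pytest.approx(high, rel=0.01)

    def test_rlc_tail_prefactor_doubles_drude(self):
        dd = st.asymptotics(st.PeakSpec("displaced_drude", 1500.0, 20.0, 10.0))
        rlc = st.asymptotics(st.PeakSpec("rlc", 1500.0, 20.0, 10.0))
        assert rlc.high_prefactor / dd.high_prefactor == pytest.approx(2.0, rel=1e-12)

    def test_tail_ordering_at_gap(self, table1):
        """J_rlc > J_drude > J_ubo at the electronic transition frequency."""
        at_gap = {
            f: st.evaluate_sd(st.assemble_from_table(table1, f), 35650.0)
            for f in SINGLE_PEAK_FORMS[1:]
        }
        assert at_gap["rlc"] > at_gap["displaced_drude"] > at_gap["ubo"]


class TestAssembly:
    def test_table1_single_peak_form(self, table1):
        model = st.assemble_from_table(table1, "displaced_drude")
        assert len(model) == 9
        assert model.peaks[0].form == "drude_lorentz"
        assert all(p.form == "displaced_drude" for p in model.peaks[1:])

    def test_two_peak_pairing_order(self, table1):
        model = st.assemble_from_table(table1, "ohmic_2pk")
        pairs = [(p.omega, p.omega2) for p in model.peaks[1:]]
        assert pairs == [(1663, 1243), (1416, 784), (1376, 1193), (665, 442)]
        assert len(model) == 5

    def test_solvent_only_degenerate_input(self, table1):
        solvent = table1[table1["omega_cm1"] == 0]
        model = st.assemble_from_table(solvent, "ubo")
        assert len(model) == 1 and model.peaks[0].form == "drude_lorentz"

    def test_odd_vibrational_rows_rejected_for_two_peak(self, table1):
        df = table1.iloc[:4]  # solvent + 3 vibrational rows
        with pytest.raises(ValueError, match="even number"):
            st.assemble_from_table(df, "ohmic_2pk")

    def test_negative_parameters_rejected(self, table1):
        df = table1.copy()
        df.loc[1, "lambda_cm1"] = -5.0
        with pytest.raises(ValueError, match="negative"):
            st.assemble_from_table(df, "displaced_drude")

    def test_csv_roundtrip(self, table1, tmp_path):
        path = tmp_path / "peaks.csv"
        table1.to_csv(path, index=False)
        model = st.assemble_from_table(str(path), "ubo")
        assert len(model) == 9


class TestDegenerateTwoPeakConvention:
    """Single-peak presentation of the 2-peak forms: equal centers, doubled widths."""

    @pytest.mark.parametrize("form", TWO_PEAK_FORMS)
    def test_peak_height_matches_single_forms(self, form):
        pk = st.PeakSpec(form, 1500.0, 20.0, 20.0, omega2=1500.0, gamma2=20.0)
        w = np.linspace(1400.0, 1600.0, 4001)
        height = st.evaluate_sd(pk, w).max()
        assert height == pytest.approx(20.0 * 1500.0 / (math.pi * 10.0), rel=0.01)

    def test_degenerate_poles_rejected_by_expansion(self):
        pk = st.PeakSpec("ohmic_2pk", 1500.0, 20.0, 20.0, omega2=1500.0, gamma2=20.0)
        with pytest.raises(ValueError, match="simple poles"):
            st.bcf_expansion(st.SpectralDensityModel([pk]), 300.0)
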