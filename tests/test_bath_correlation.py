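"""BCF expansion vs quadrature oracle, Pade decomposition, term structure."""

import numpy as np
import pytest

import sdtails as st
from sdtails.bath_correlation import pade_coth
from sdtails.units import KB_CM1_PER_K, beta_cm

T300 = 300.0


class TestPade:
    def test_zero_terms_is_classical_kernel(self):
        xi, eta = st.pade_decomposition(0)
        assert xi.size == 0 and eta.size == 0

    def test_production_setting_has_eight_poles(self):
        xi, eta = st.pade_decomposition(8)
        assert xi.size == 8 and eta.size == 8
        assert np.all(np.diff(xi) > 0) and np.all(eta > 0)

    def test_low_poles_approach_matsubara(self):
        xi, _ = st.pade_decomposition(8)
        matsubara = 2 * np.pi * np.arange(1, 9)
        # the first poles coincide with Matsubara, the last ones overshoot
        assert xi[0] == pytest.approx(matsubara[0], rel=1e-6)
        assert xi[-1] > matsubara[-1]

    @pytest.mark.parametrize("y", [0.5, 1.0, 2.0, 5.0])
    def test_error_decreases_with_order(self, y):
        exact = 1.0 / np.tanh(y)
        err = [abs(complex(pade_coth(y, n)) - exact) for n in (2, 8)]
        assert err[1] < err[0] or err[1] < 1e-14

    def test_taylor_match_order_one(self):
        # [0/1] Pade: xi^2 = 60 and eta = 5/2 reproduce the x and x^3
        # Taylor coefficients of 1/(e^x-1) - 1/x + 1/2
        xi, eta = st.pade_decomposition(1)
        assert xi[0] ** 2 == pytest.approx(60.0, rel=1e-12)
        assert eta[0] == pytest.approx(2.5, rel=1e-12)


class TestTermStructure:
    def test_term_counts_per_feature(self):
        dl = st.SpectralDensityModel([st.PeakSpec("drude_lorentz", 0, 715.7, 54.5)])
        dd = st.SpectralDensityModel([st.PeakSpec("displaced_drude", 1500, 20, 10)])
        two = st.SpectralDensityModel(
            [st.PeakSpec("ohmic_2pk", 1663, 490, 10, omega2=1243, gamma2=36.55)]
        )
        for model, n_peak in [(dl, 1), (dd, 2), (two, 4)]:
            exp = st.bcf_expansion(model, T300, n_pade=8)
            kinds = [t.origin for t in exp.terms]
            assert kinds.count("peak_pole") == n_peak
            assert kinds.count("pade_pole") == 8

    def test_table1_composite_has_25_terms(self, table1):
        model = st.assemble_from_table(table1, "ubo")
        exp = st.bcf_expansion(model, T300, n_pade=8)
        assert len(exp) == 25  # 1 solvent + 2*8 vibrational + 8 Pade

    def test_displaced_drude_oscillates_at_center(self):
        pk = st.PeakSpec("displaced_drude", 1500.0, 20.0, 10.0)
        exp = st.bcf_expansion(st.SpectralDensityModel([pk]), T300)
        peak_terms = [t for t in exp.terms if t.origin == "peak_pole"]
        assert sorted(t.omega for t in peak_terms) == [-1500.0, 1500.0]
        assert all(t.gamma == pytest.approx(10.0) for t in peak_terms)

    def test_drude_lorentz_is_pure_decay(self):
        pk = st.PeakSpec("drude_lorentz", 0.0, 715.7, 54.5)
        exp = st.bcf_expansion(st.SpectralDensityModel([pk]), T300)
        (term,) = [t for t in exp.terms if t.origin == "peak_pole"]
        assert term.omega == 0.0 and term.gamma == pytest.approx(54.5)

    def test_identical_poles_different_coefficients_across_forms(self):
        """The three single-peak forms share Omega_j exactly; only c_j differ."""
        exps = {
            f: st.bcf_expansion(
                st.SpectralDensityModel([st.PeakSpec(f, 1500.0, 20.0, 10.0)]), T300
            )
            for f in ("displaced_drude", "ubo", "rlc")
        }
        mus = {
            f: sorted(
                (t.omega, t.gamma) for t in e.terms if t.origin == "peak_pole"
            )
            for f, e in exps.items()
        }
        assert mus["displaced_drude"] == mus["ubo"] == mus["rlc"]
        cs = {
            f: sorted(
                (round(t.c.real, 6), round(t.c.imag, 6))
                for t in e.terms
                if t.origin == "peak_pole"
            )
            for f, e in exps.items()
        }
        assert cs["displaced_drude"] != cs["ubo"] != cs["rlc"]

    def test_conjugate_closure(self, table1):
        exp = st.bcf_expansion(st.assemble_from_table(table1, "rlc"), T300)
        cbar = exp.conjugate_coefficients()
        # C*(t) reconstructed from cbar must equal conj(C(t))
        t = np.array([3.0, 17.0, 120.0])
        from sdtails.units import CM1_TO_RAD_PER_FS

        mus = np.array([term.mu for term in exp.terms])
        cstar = np.array(
            [np.sum(cbar * np.exp(-mus * CM1_TO_RAD_PER_FS * tt)) for tt in t]
        )
        np.testing.assert_allclose(cstar, np.conj(exp.evaluate(t)), rtol=1e-10)


class TestOracle:
    def test_imaginary_part_vanishes_at_t0(self):
        model = st.SpectralDensityModel([st.PeakSpec("ubo", 1500.0, 20.0, 10.0)])
        c0 = st.bcf_quadrature(model, T300, 0.0)
        assert abs(c0.imag) < 1e-10 * abs(c0.real)

    def test_time_reversal_symmetry(self):
        model = st.SpectralDensityModel([st.PeakSpec("ubo", 1500.0, 20.0, 10.0)])
        cp = st.bcf_quadrature(model, T300, [4.0, 21.0])
        cm = st.bcf_quadrature(model, T300, [-4.0, -21.0])
        np.testing.assert_allclose(cm, np.conj(cp), rtol=1e-6)

    def test_solvent_expansion_matches_quadrature(self):
        model = st.SpectralDensityModel([st.PeakSpec("drude_lorentz", 0, 715.7, 54.5)])
        t = np.array([1.0, 5.0, 20.0, 80.0, 200.0, 500.0])
        ce = st.bcf_expansion(model, T300, 8).evaluate(t)
        cq = st.bcf_quadrature(model, T300, t)
        assert np.abs(ce - cq).max() / np.abs(cq).max() < 1e-3

    @pytest.mark.parametrize("form", ["displaced_drude", "ohmic_2pk"])
    def test_composite_expansion_matches_quadrature(self, form, table1):
        model = st.assemble_from_table(table1, form)
        t = np.array([1.0, 7.0, 33.0, 150.0, 500.0])
        ce = st.bcf_expansion(model, T300, 8).evaluate(t)
        cq = st.bcf_quadrature(model, T300, t)
        assert np.abs(ce - cq).max() / np.abs(cq).max() < 1e-3

    def test_pade_contribution_fades_at_high_temperature(self):
        model = st.SpectralDensityModel([st.PeakSpec("ubo", 1500.0, 20.0, 10.0)])

        def pade_weight(temp):
            exp = st.bcf_expansion(model, temp, 8)
            w = {"peak_pole": 0.0, "pade_pole": 0.0}
            for term in exp.terms:
                w[term.origin] += abs(term.c)
            return w["pade_pole"] / w["peak_pole"]

        assert pade_weight(3000.0) < 0.1 * pade_weight(300.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            beta_cm(0.0)
        assert beta_cm(300.0) == pytest.approx(1.0 / (KB_CM1_PER_K * 300.0))
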