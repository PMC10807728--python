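"""Signal assembly: algebraic identities between the printed forms, and the
cross-check of the composed modulation against exact propagation."""

import numpy as np
import pytest

from siftersim import dipolar_model as dm
from siftersim import quantum_core as qc
from siftersim import relaxation_models as rm
from siftersim import signal_composition as sc


def relax(tau_d=3.5, beta=1.4, xi=2.4):
    comps = (rm.StretchedExpParams(1.0, tau_d, beta),)
    return comps, rm.SidreSurfaceParams(comps, xi)


class TestTransferFactor:
    def test_vanishes_at_trace_ends(self):
        assert sc.transfer_factor(0.5, 0.0, 2.0) == 0.0
        assert sc.transfer_factor(0.5, 2.0, 0.0) == 0.0

    def test_maximum_at_symmetric_point(self):
        D, tau0 = 0.3, 2.0
        t = np.linspace(-tau0, tau0, 101)
        vals = sc.transfer_factor(D, (tau0 + t) / 2, (tau0 - t) / 2)
        assert vals[50] == pytest.approx(D * tau0**2 / 4)
        np.testing.assert_allclose(vals, vals[::-1], atol=1e-15)


class TestMonoradical:
    def test_zero_transfer_reduces_to_sidre_surface(self):
        bt, bs = relax()
        tau0 = 2.5
        t = np.linspace(-tau0, tau0, 41)
        tr = sc.compose_monoradical(bt, bs, 0.0, tau0, t)
        tau1, tau2 = (tau0 + t) / 2, (tau0 - t) / 2
        np.testing.assert_allclose(tr.amplitude, rm.evaluate_bs(bs, tau1, tau2),
                                   atol=1e-15)

    def test_trace_ends_equal_hahn_decay_at_tau0(self):
        bt, bs = relax()
        tau0 = 2.0
        tr = sc.compose_monoradical(bt, bs, 0.1, tau0, np.array([-tau0, 0.0, tau0]))
        want = rm.evaluate_bt(bt, tau0)
        assert tr.amplitude[0] == pytest.approx(want, abs=1e-14)
        assert tr.amplitude[2] == pytest.approx(want, abs=1e-14)

    def test_divided_form_is_one_plus_weighted_parabola(self):
        bt, bs = relax()
        D, tau0 = 0.08, 2.5
        t = np.linspace(-tau0, tau0, 81)
        tr = sc.compose_monoradical(bt, bs, D, tau0, t)
        out = sc.divide_by_sidre(tr, bs)
        tau1, tau2 = (tau0 + t) / 2, (tau0 - t) / 2
        btbt = rm.evaluate_bt(bt, tau1) * rm.evaluate_bt(bt, tau2)
        want = 1.0 + D * tau1 * tau2 * btbt / rm.evaluate_bs(bs, tau1, tau2)
        np.testing.assert_allclose(out.amplitude, want, rtol=1e-12)

    def test_divided_no_filtering_is_pure_parabola(self):
        bt, bs = relax(xi=1.4)  # xi = beta: Bt.Bt == BS
        D, tau0 = 0.08, 2.0
        t = np.linspace(-tau0, tau0, 41)
        out = sc.divide_by_sidre(sc.compose_monoradical(bt, bs, D, tau0, t), bs)
        np.testing.assert_allclose(out.amplitude,
                                   1.0 + D * (tau0**2 - t**2) / 4, rtol=1e-12)


class TestArtefactTerm:
    def test_reduces_to_transfer_factor_for_unit_form_factor(self):
        assert sc.artefact_term(1.0, 1.0, 0.4, 1.0, 1.5) == pytest.approx(0.6)

    def test_vanishes_at_ends(self):
        assert sc.artefact_term(0.3, 1.0, 0.4, 2.0, 0.0) == 0.0


class TestBiradical:
    def test_zero_depth_equals_monoradical(self):
        bt, bs = relax()
        d = dm.DistanceDistribution.gaussian(3.0, 0.2)
        params = sc.CompositionParams(lam=0.0, D=0.05, tau0=2.5)
        t = np.linspace(-2.5, 2.5, 51)
        tr = sc.compose_biradical(d, bt, bs, params, t)
        mono = sc.compose_monoradical(bt, bs, 0.05, 2.5, t)
        np.testing.assert_allclose(tr.amplitude, mono.amplitude, atol=1e-14)

    def test_full_depth_no_relaxation_gives_form_factor(self):
        # lambda -> 1, D = 0, relaxation off: V -> F(t), K terms cancel
        d = dm.DistanceDistribution.gaussian(3.0, 0.2)
        t = np.linspace(-2.5, 2.5, 51)
        lam = 1.0 - 1e-9
        params = sc.CompositionParams(lam=lam, D=0.0, tau0=2.5)
        tr = sc.compose_biradical(d, None, None, params, t)
        np.testing.assert_allclose(tr.amplitude, dm.powder_form_factor(d, t),
                                   atol=1e-7)

    def test_equivalence_with_direct_pathway_sum(self, rng):
        # (1-lam) V_nm + lam V_mod  ==  F BS + Fs (BtBt - BS) + A BtBt,
        # assembled here independently from the primitive kernels
        for _ in range(25):
            lam = rng.uniform(0.0, 0.9)
            D = rng.uniform(0.0, 0.3)
            tau0 = rng.uniform(1.0, 4.0)
            bt, bs = relax(tau_d=rng.uniform(1.5, 8.0), beta=rng.uniform(0.6, 1.8),
                           xi=rng.uniform(1.9, 3.5))
            d = dm.DistanceDistribution.gaussian(rng.uniform(2.2, 4.5),
                                                 rng.uniform(0.05, 0.5))
            t = np.linspace(-tau0, tau0, 31)
            tr, bd = sc.compose_biradical(d, bt, bs, sc.CompositionParams(lam, D, tau0),
                                          t, return_breakdown=True)
            tau1, tau2 = (tau0 + t) / 2, (tau0 - t) / 2
            f = dm.powder_form_factor(d, t)
            fs = dm.sine_product_term(d, tau1, tau2)
            btbt = rm.evaluate_bt(bt, tau1) * rm.evaluate_bt(bt, tau2)
            bs_v = rm.evaluate_bs(bs, tau1, tau2)
            art = dm.powder_form_factor(d, tau1) * dm.powder_form_factor(d, tau2) \
                * D * tau1 * tau2
            direct = (1 - lam) * (bs_v + D * tau1 * tau2 * btbt) \
                + lam * (f * bs_v + fs * (btbt - bs_v) + art * btbt)
            np.testing.assert_allclose(tr.amplitude, direct, atol=1e-10)

    def test_modulated_part_separable_from_breakdown(self):
        bt, bs = relax()
        d = dm.DistanceDistribution.gaussian(3.0, 0.2)
        lam, D, tau0 = 0.3, 0.02, 2.5
        t = np.linspace(-tau0, tau0, 101)
        tr, bd = sc.compose_biradical(d, bt, bs, sc.CompositionParams(lam, D, tau0),
                                      t, return_breakdown=True)
        main_bg = 0.5 * (bd["bs"] + bd["btbt"])
        recovered = (tr.amplitude - bd["v_nm_scaled"]) / lam - bd["artefact"]
        np.testing.assert_allclose(recovered / main_bg, bd["f"], atol=1e-12)

    def test_symmetry_in_t(self):
        bt, bs = relax()
        d = dm.DistanceDistribution.gaussian(2.6, 0.3)
        t = np.linspace(-2.0, 2.0, 41)
        tr = sc.compose_biradical(d, bt, bs, sc.CompositionParams(0.4, 0.1, 2.0), t)
        np.testing.assert_allclose(tr.amplitude, tr.amplitude[::-1], atol=1e-12)

    def test_depth_one_rejected(self):
        with pytest.raises(ValueError):
            sc.CompositionParams(lam=1.0, D=0.0, tau0=2.0)

    def test_matches_exact_two_spin_propagation(self):
        # powder-average the exact pair propagator over the orientation
        # quadrature and compare with the composed modulated signal
        r = 3.0
        tau0 = 1.2
        t = np.linspace(-tau0, tau0, 13)
        n_theta = 21
        x, w = np.polynomial.legendre.leggauss(n_theta)
        u, wu = 0.5 * (x + 1), 0.5 * w
        omega_perp = dm.dipolar_frequency(r, np.pi / 2)
        avg = np.zeros_like(t)
        for ui, wi in zip(u, wu):
            omega = omega_perp * (1 - 3 * ui**2)
            system = qc.SpinSystem(2, ((0, 1, omega),))
            tr = qc.sifter_trace_exact(system, tau0, t, detect_spins=(0, 1))
            avg += wi * tr.amplitude
        d = dm.DistanceDistribution.delta(r)
        params = sc.CompositionParams(lam=1.0 - 1e-12, D=0.0, tau0=tau0)
        composed = sc.compose_biradical(d, None, None, params, t, n_theta=n_theta)
        np.testing.assert_allclose(composed.amplitude, avg, atol=1e-10)


class TestDivideAndMainTerm:
    def test_dividing_bs_by_itself_is_unity(self):
        bt, bs = relax()
        tau0 = 2.0
        t = np.linspace(-tau0, tau0, 21)
        tr = rm.sidre_trace(bs, tau0, t)
        out = sc.divide_by_sidre(tr, bs)
        np.testing.assert_allclose(out.amplitude, 1.0, atol=1e-12)
        assert out.metadata["n_masked"] == 0

    def test_masking_counts_subfloor_points(self):
        bt, bs = relax(tau_d=0.05, beta=1.0, xi=1.5)  # decays to < 1e-6 fast
        tau0 = 3.0
        t = np.linspace(-tau0, tau0, 61)
        tr = sc.compose_monoradical(bt, bs, 0.0, tau0, t)
        out = sc.divide_by_sidre(tr, bs)
        assert out.metadata["n_masked"] > 0
        assert np.isnan(out.amplitude).sum() == out.metadata["n_masked"]

    def test_main_term_between_product_and_surface(self):
        bt, bs = relax()
        tau0 = 3.0
        t = np.linspace(-tau0, tau0, 61)
        tau1, tau2 = (tau0 + t) / 2, (tau0 - t) / 2
        btbt = rm.evaluate_bt(bt, tau1) * rm.evaluate_bt(bt, tau2)
        bs_v = rm.evaluate_bs(bs, tau1, tau2)
        main = sc.main_term_background(bt, bs, tau0, t)
        assert np.all(main >= btbt - 1e-15)
        assert np.all(main <= bs_v + 1e-15)
        assert main[0] == pytest.approx(rm.evaluate_bt(bt, tau0), abs=1e-14)

    def test_main_term_equals_bs_without_filtering(self):
        bt, bs = relax(xi=1.4)
        tau0 = 2.0
        t = np.linspace(-tau0, tau0, 21)
        np.testing.assert_allclose(sc.main_term_background(bt, bs, tau0, t),
                                   rm.evaluate_bs(bs, (tau0 + t) / 2, (tau0 - t) / 2),
                                   rtol=1e-12)
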