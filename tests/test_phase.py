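"""Asymptotic phase, PRCs (continuation vs direct), the iPRC with its
adjoint oracle, isochron linearization/globalization, and the slow-field
offset theory."""

import dataclasses

import numpy as np
import pytest

import slowphase as sp
from slowphase import phase as ph
from slowphase.exceptions import BasinError, DomainError
from slowphase.models import MODEL_DEFAULTS, PlanarSlowFastSystem


class TestAsymptoticPhase:
    def test_on_cycle_points(self, phenomenor, phenomenor_lc):
        for th in (0.0, 0.3, 0.77):
            got = sp.asymptotic_phase(phenomenor_lc, phenomenor,
                                      phenomenor_lc.point(th))
            assert abs(ph.wrap_phase(got - th)) < 1e-8

    def test_phase_advances_with_flow(self, phenomenor, phenomenor_lc):
        """phi_{0.2 T}(gamma(0.3)) has phase 0.5: theta = t/T."""
        from slowphase.dynamics import integrate

        z = integrate(phenomenor, phenomenor_lc.point(0.3),
                      0.2 * phenomenor_lc.period, tol=1e-12).end
        got = sp.asymptotic_phase(phenomenor_lc, phenomenor, z)
        assert abs(ph.wrap_phase(got - 0.5)) < 1e-8

    def test_point_outside_basin_raises(self, phenomenor, phenomenor_lc):
        # a state pinned far away never produces the reference crossing
        with pytest.raises(BasinError):
            sp.asymptotic_phase(phenomenor_lc, phenomenor, (-30.0, -900.0),
                                n_periods=1)


class TestPRC:
    def test_zero_amplitude_is_identically_zero(self, phenomenor,
                                                phenomenor_lc):
        prc = sp.prc_continuation(phenomenor_lc, phenomenor, 0.0, n_theta=8)
        assert np.allclose(prc.delta_theta, 0.0, atol=1e-9)
        assert sp.prc_direct(phenomenor_lc, phenomenor, 0.0, 0.3) == \
            pytest.approx(0.0, abs=1e-8)

    def test_small_amplitude_prc_flat_on_branches(self, phenomenor,
                                                  phenomenor_lc):
        """Below the branch-to-nullcline gap (A < 0.1) the PRC is close to
        zero away from the folds: isochrons there are nearly vertical."""
        prc = sp.prc_continuation(phenomenor_lc, phenomenor, 0.05, n_theta=32,
                                  delta_A=0.05 / 4, int_tol=1e-11)
        mask, _ = sp.dynamics.lower_branch_mask(phenomenor, phenomenor_lc)
        grid_mask = mask[::phenomenor_lc.n_samples // 32]
        # drop the two samples nearest the fold at each end of the branch
        idx = np.nonzero(grid_mask)[0][2:-2]
        assert np.max(np.abs(prc.delta_theta[idx])) < 2e-3

    def test_positive_pulse_on_lower_branch_delays(self, phenomenor,
                                                   phenomenor_lc,
                                                   pheno_prc_025):
        """Kicks that stay below the repelling branch delay the oscillator."""
        prc = pheno_prc_025
        assert prc.theta_star is not None
        mask, _ = sp.dynamics.lower_branch_mask(phenomenor, phenomenor_lc)
        n = phenomenor_lc.n_samples
        on_branch = np.array([mask[int(np.floor(t * n)) % n]
                              for t in prc.theta_grid])
        sel = on_branch & ~prc.crossing_mask
        assert sel.sum() > 10
        assert np.all(prc.delta_theta[sel] <= 1e-12)

    def test_discontinuity_lands_on_repelling_branch(self, phenomenor,
                                                     phenomenor_lc,
                                                     pheno_prc_025):
        """gamma(theta*) + A e_v sits on the middle (repelling) branch."""
        z = phenomenor_lc.point(pheno_prc_025.theta_star)
        zk = z + 0.25 * np.array([1.0, 0.0])
        assert abs(phenomenor.fast_rhs(*zk)) < 1e-5
        h = 1e-6
        dfdx = (phenomenor.fast_rhs(zk[0] + h, zk[1])
                - phenomenor.fast_rhs(zk[0] - h, zk[1])) / (2 * h)
        assert dfdx > 0

    def test_delta_theta_is_periodic_interpolant(self, pheno_prc_025):
        prc = pheno_prc_025
        assert prc(0.25) == pytest.approx(prc(1.25), abs=1e-12)
        j = 17
        assert prc(prc.theta_grid[j]) == pytest.approx(prc.delta_theta[j],
                                                       abs=1e-12)


class TestIPRC:
    def test_normalization_and_adjoint_oracle(self, fixture_osc, fixture_lc):
        """<grad Theta, Z> T = 1 along the cycle, and the finite-amplitude
        gradient matches an independent backward-adjoint solve."""
        ipr = sp.compute_iprc(fixture_lc, fixture_osc, n_theta=16)
        adj = sp.iprc_adjoint(fixture_lc, fixture_osc, n_theta=16)
        Z = np.array([fixture_osc.rhs(0.0, fixture_lc.point(t))
                      for t in ipr.theta_grid])
        norm = np.einsum("ij,ij->i", ipr.gradients, Z) * fixture_lc.period
        assert np.max(np.abs(norm - 1.0)) < 1e-6
        rel = (np.linalg.norm(ipr.gradients - adj.gradients, axis=1)
               / np.linalg.norm(adj.gradients, axis=1))
        assert rel.max() < 1e-5

    def test_adjoint_oracle_epileptor(self, epileptor_p0, epileptor_p0_lc):
        adj = sp.iprc_adjoint(epileptor_p0_lc, epileptor_p0, n_theta=12)
        Z = np.array([epileptor_p0.rhs(0.0, epileptor_p0_lc.point(t))
                      for t in adj.theta_grid])
        norm = np.einsum("ij,ij->i", adj.gradients, Z) * epileptor_p0_lc.period
        assert np.max(np.abs(norm - 1.0)) < 1e-8

    def test_observed_first_order_convergence(self, fixture_osc, fixture_lc):
        """PRC(A, .)/A approaches the gradient at first order as A halves."""
        th = 0.3
        e = np.array([1.0, 0.0])
        quotients = []
        for A in (4e-3, 2e-3, 1e-3):
            d = sp.prc_direct(fixture_lc, fixture_osc, A, th)
            quotients.append(d / A)
        # successive differences shrink by about half
        d1 = abs(quotients[1] - quotients[0])
        d2 = abs(quotients[2] - quotients[1])
        assert d2 < 0.75 * d1

    def test_iprc_antisymmetric_under_half_period(self, fixture_osc,
                                                  fixture_lc):
        """The fixture's (x,y) -> (-x,-y) symmetry maps theta to
        theta + 1/2 and negates the gradient."""
        ipr = sp.compute_iprc(fixture_lc, fixture_osc, n_theta=16)
        g = ipr.gradients
        assert np.max(np.abs(g[8:] + g[:8])) < 1e-6


class TestIsochrons:
    @pytest.fixture(scope="class")
    def pheno_N(self, phenomenor, phenomenor_lc, pheno_iprc):
        return sp.isochron_linearization(pheno_iprc, phenomenor_lc, phenomenor)

    def test_tangent_in_gradient_kernel(self, pheno_iprc, pheno_N):
        dots = np.einsum("ij,ij->i", pheno_iprc.gradients, pheno_N)
        assert np.max(np.abs(dots)) < 1e-12
        assert np.allclose(np.linalg.norm(pheno_N, axis=1), 1.0)

    def test_linearization_reconstructs_gradient(self, epileptor_p0,
                                                 epileptor_p0_lc):
        """grad = N_perp / (T <N_perp, Z>) reproduces the adjoint-exact
        gradient to 1e-8."""
        adj = sp.iprc_adjoint(epileptor_p0_lc, epileptor_p0, n_theta=12)
        N = sp.isochron_linearization(adj, epileptor_p0_lc, epileptor_p0)
        T = epileptor_p0_lc.period
        for j, th in enumerate(adj.theta_grid):
            Z = epileptor_p0.rhs(0.0, epileptor_p0_lc.point(th))
            npe = np.array([-N[j][1], N[j][0]])
            rec = npe / (T * (npe @ Z))
            err = np.linalg.norm(rec - adj.gradients[j]) / np.linalg.norm(
                adj.gradients[j])
            assert err < 1e-8

    def test_isochrons_run_along_pulse_direction_on_branch(self, phenomenor,
                                                           phenomenor_lc,
                                                           pheno_iprc,
                                                           pheno_N):
        """Between the branch and the slow nullcline a kick in v barely
        moves the phase, so the isochron tangent is dominated by the fast
        component (curves of nearly constant slow value)."""
        mask, _ = sp.dynamics.lower_branch_mask(phenomenor, phenomenor_lc)
        grid_mask = mask[::phenomenor_lc.n_samples // len(pheno_N)]
        idx = np.nonzero(grid_mask)[0][2:-2]
        assert np.all(np.abs(pheno_N[idx, 0]) > 20 * np.abs(pheno_N[idx, 1]))

    def test_globalized_points_pass_membership(self, phenomenor,
                                               phenomenor_lc, pheno_N):
        theta = 0.25
        curve = sp.globalize_isochron(phenomenor_lc, phenomenor, theta,
                                      pheno_N)
        assert len(curve.points) > 10
        for p in curve.points[:: max(1, len(curve.points) // 8)]:
            got = sp.asymptotic_phase(phenomenor_lc, phenomenor, p,
                                      n_periods=3)
            assert abs(ph.wrap_phase(got - theta)) < 1e-4

    def test_cycle_point_is_its_own_isochron_seed(self, phenomenor_lc,
                                                  pheno_N):
        curve = sp.globalize_isochron(phenomenor_lc, phenomenor_lc.system,
                                      0.4, pheno_N)
        d = np.linalg.norm(curve.points - phenomenor_lc.point(0.4), axis=1)
        assert d.min() < 1e-10  # the base point itself is on the curve

    def test_lower_branch_isochrons_bend_above_nullcline(self, phenomenor,
                                                         phenomenor_lc,
                                                         pheno_N):
        """Above the slow nullcline the lower-branch isochrons bend toward
        earlier phases: the curve tilts instead of continuing at constant
        excitability."""
        theta = 0.6  # a lower-branch phase
        curve = sp.globalize_isochron(phenomenor_lc, phenomenor, theta,
                                      pheno_N)
        base = phenomenor_lc.point(theta)
        assert base[0] < -2.0 / 3.0
        # nullcline fast coordinate at the base's slow value
        vn = 1.6 * base[1] - 0.86 - np.arctanh(0.5) / 1000.0
        above = curve.points[curve.points[:, 0] > vn + 0.05]
        below = curve.points[(curve.points[:, 0] > base[0] + 1e-3)
                             & (curve.points[:, 0] < vn - 0.01)]
        assert len(above) > 3 and len(below) > 3
        # below the nullcline: nearly constant slow value (vertical isochron)
        assert np.max(np.abs(below[:, 1] - base[1])) < 5e-4
        # above: a systematic slow offset appears (the bend)
        assert np.max(np.abs(above[:, 1] - base[1])) > 5 * np.max(
            np.abs(below[:, 1] - base[1]))


class TestOffsetTheory:
    def test_offset_vanishes_for_x_independent_slow_field(self, fixture_osc,
                                                          fixture_lc):
        """With g = g(y) the cycle and layer integrands coincide, so the
        predicted isochron offset collapses to zero."""
        const_g = PlanarSlowFastSystem(
            fast_rhs=fixture_osc.fast_rhs,
            slow_rhs=lambda x, y: 1.0,
            epsilon=fixture_osc.epsilon,
            params={},
            epsilon_absorbed=False,
        )
        z_bar = np.array([-1.9, 0.1])
        off = sp.predict_isochron_offset(const_g, fixture_lc, z_bar)
        assert off == pytest.approx(0.0, abs=1e-12)
        assert sp.isochron_slope_sign(const_g, z_bar, fixture_lc) == 0

    def test_offset_scales_linearly_with_epsilon(self):
        """Halving the timescale ratio roughly halves the offset."""
        d = MODEL_DEFAULTS["fixture"]
        offs = []
        for mu in (20.0, 40.0):
            system = sp.make_fixture_oscillator(mu)
            lc = sp.find_limit_cycle(
                system, sp.PoincareSection(*d["section"]), d["guess"]
            )
            offs.append(sp.predict_isochron_offset(system, lc, (-1.9, 0.1)))
        ratio = offs[0] / offs[1]
        assert 2.0 * 0.8 < ratio < 2.0 * 1.2

    def test_offset_sign_matches_measured_tilt_epileptor_minus(self):
        """For the P- epileptor the predicted slow offset and a globalized
        isochron's measured tilt agree in sign."""
        d = MODEL_DEFAULTS["epileptor"]
        system = sp.get_model("epileptor", "P-")
        lc = sp.find_limit_cycle(system, sp.PoincareSection(*d["section"]),
                                 d["guess"])
        adj = sp.iprc_adjoint(lc, system, n_theta=32)
        N = sp.isochron_linearization(adj, lc, system)
        theta = 0.3
        curve = sp.globalize_isochron(lc, system, theta, N)
        base = lc.point(theta)
        outward = curve.points[curve.points[:, 0] > base[0] + 0.2]
        assert len(outward) > 0
        # probe mid-way out: the far tip approaches the repelling branch,
        # where the layer-flow prediction is not defined
        probe = outward[np.argmin(np.abs(outward[:, 0] - (base[0] + 0.3)))]
        measured = probe[1] - base[1]
        predicted = sp.predict_isochron_offset(system, lc, probe)
        assert np.sign(measured) == np.sign(predicted)
        # and the monotonicity rule gives the same constant sign
        assert sp.isochron_slope_sign(system, probe, lc) == -1

    def test_slope_sign_constant_along_epileptor_branches(self,
                                                          epileptor_p0,
                                                          epileptor_p0_lc):
        """g is monotone increasing in v for the epileptor variants, so the
        predicted isochron slope sign is constant (negative)."""
        mask, _ = sp.dynamics.lower_branch_mask(epileptor_p0,
                                                epileptor_p0_lc)
        pts = epileptor_p0_lc.samples[mask][::300] + np.array([0.3, 0.0])
        signs = {sp.isochron_slope_sign(epileptor_p0, p, epileptor_p0_lc)
                 for p in pts}
        assert signs == {-1}

    def test_repelling_start_raises(self, phenomenor, phenomenor_lc):
        from slowphase.dynamics import _fast_roots

        mid = sorted(_fast_roots(phenomenor, 0.05, (-4, 4)))[1]
        with pytest.raises(DomainError):
            sp.predict_isochron_offset(phenomenor, phenomenor_lc,
                                       (mid, 0.05))
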