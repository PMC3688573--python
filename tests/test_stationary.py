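"""Exact stationary solution: closed-form limits, boundary identities,
conservation and monotonicity of the total adult population."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habitat_split import (
    ModelParams,
    critical_recruitment,
    decay_lengths,
    evaluate_profile,
    recruitment_flux,
    solve_stationary,
    total_adults,
    validate_params,
)


def params_strategy(p_choices=(0.0, 1.0, math.inf)):
    """Random valid parameter sets spanning closed/partial/absorbing edges."""
    pos = st.floats(0.3, 3.0)
    return st.builds(
        ModelParams,
        D_J=pos,
        D_A=pos,
        sigma_J=pos,
        sigma_A=st.floats(0.05, 1.0),
        R=st.floats(0.0, 3.0),
        g=st.floats(0.5, 2.0),
        tau=st.just(0.0),
        p=st.sampled_from(p_choices),
        h=st.floats(0.0, 2.5),
        L=st.floats(3.0, 9.0),
    ).filter(lambda q: q.h < q.L - 0.3)


class TestCriticalRecruitment:
    def test_zero_split_closed_edge_equals_adult_mortality(self):
        # recruitment must exactly replace adult mortality when the fragment
        # touches the river and nothing leaks through the outer edge
        p = ModelParams(h=0.0, L=5.0, sigma_A=0.1)
        assert critical_recruitment(p) == pytest.approx(0.1, abs=1e-15)

    def test_closed_edge_closed_form(self):
        # R_c = sigma_A cosh(alpha h) for p = 0
        h = 2.0 * math.acosh(2.0)
        p = ModelParams(D_J=1.0, sigma_J=0.25, sigma_A=1.0, h=h, L=h + 5.0)
        assert critical_recruitment(p) == pytest.approx(2.0, rel=1e-12)

    def test_independent_of_fragment_size_for_closed_edge(self, defaults):
        r1 = critical_recruitment(defaults.with_(L=defaults.h + 2.0))
        r2 = critical_recruitment(defaults.with_(L=defaults.h + 50.0))
        assert r1 == pytest.approx(r2, rel=1e-14)

    def test_permeable_edge_raises_threshold(self, defaults):
        r0 = critical_recruitment(defaults)
        r1 = critical_recruitment(defaults.with_(p=1.0))
        rinf = critical_recruitment(defaults.with_(p=math.inf))
        assert r0 < r1 < rinf


class TestSolveStationary:
    def test_below_threshold_returns_null_solution(self, defaults):
        sol = solve_stationary(defaults.with_(h=5.0, L=10.0))  # R_c >> R
        assert not sol.exists
        assert sol.N_T == 0.0
        assert sol.C == sol.E == sol.F == 0.0

    def test_no_split_closed_form_total(self):
        # N_T = g (1/sigma_A - 1/R) when the fragment touches the river
        p = ModelParams(h=0.0, L=5.0, sigma_A=0.1, R=0.5, g=1.0)
        assert solve_stationary(p).N_T == pytest.approx(8.0, rel=1e-12)

    def test_saturation_ceiling_at_large_recruitment(self):
        # total deaths balance the maximum juvenile production g
        p = ModelParams(h=0.0, L=5.0, sigma_A=0.1, R=1e12, g=1.0)
        assert solve_stationary(p).N_T == pytest.approx(10.0, rel=1e-9)

    def test_generic_amplitude_solver_matches_closed_form(self, defaults):
        # passing the Monod law explicitly exercises the bracketing solver
        ref = solve_stationary(defaults)
        gen = solve_stationary(defaults, flux=recruitment_flux)
        assert gen.N_T == pytest.approx(ref.N_T, rel=1e-10)
        assert gen.phi_river == pytest.approx(ref.phi_river, rel=1e-10)


class TestBoundaryIdentities:
    """The returned profile satisfies every boundary condition exactly."""

    @pytest.mark.parametrize("p_edge", [0.0, 1.0, math.inf])
    def test_all_boundaries(self, defaults, p_edge):
        p = defaults.with_(p=p_edge, R=1.0)
        sol = solve_stationary(p)
        assert sol.exists
        # metamorphosis boundary
        assert sol.juvenile_density(p.h) == pytest.approx(0.0, abs=1e-300)
        # flux matching at h: adult influx equals juvenile efflux
        influx = -p.D_A * float(sol.adult_density_derivative(p.h))
        efflux = float(sol.juvenile_flux(p.h))
        assert influx == pytest.approx(efflux, rel=1e-10)
        # Robin (or Dirichlet) condition at L
        if math.isinf(p_edge):
            assert float(sol.adult_density(p.L)) == pytest.approx(0.0, abs=1e-14)
        else:
            robin = p.D_A * float(sol.adult_density_derivative(p.L)) + p_edge * float(
                sol.adult_density(p.L)
            )
            assert abs(robin) <= 1e-10 * float(sol.adult_density(p.h))
        # stationary saturating river-flux condition
        assert float(sol.juvenile_flux(0.0)) == pytest.approx(
            recruitment_flux(sol.N_T, p), rel=1e-10
        )

    def test_stationary_ode_residuals(self, defaults):
        # central second differences of the closed-form profile must satisfy
        # D f'' - sigma f = 0 to 1e-8 of the profile scale
        p = defaults.with_(R=1.0)
        sol = solve_stationary(p)
        dd = 1e-3

        def d2(f, x):  # fourth-order five-point second derivative
            return (
                -f(x + 2 * dd) + 16 * f(x + dd) - 30 * f(x) + 16 * f(x - dd) - f(x - 2 * dd)
            ) / (12 * dd**2)

        xj = np.linspace(2 * dd, p.h - 2 * dd, 400)
        res_j = p.D_J * d2(sol.juvenile_density, xj) - p.sigma_J * sol.juvenile_density(xj)
        assert np.max(np.abs(res_j)) <= 1e-8 * float(np.max(np.abs(sol.juvenile_density(xj))))
        xa = np.linspace(p.h + 2 * dd, p.L - 2 * dd, 400)
        res_a = p.D_A * d2(sol.adult_density, xa) - p.sigma_A * sol.adult_density(xa)
        assert np.max(np.abs(res_a)) <= 1e-8 * float(np.max(np.abs(sol.adult_density(xa))))


class TestTotalAdults:
    def test_extinct_solution_has_zero_total(self, defaults):
        assert total_adults(solve_stationary(defaults.with_(R=0.01))) == 0.0

    def test_closed_edge_balance_with_juvenile_efflux(self, rng):
        # with a closed outer edge all adult deaths are paid by the influx at h
        for _ in range(20):
            p = ModelParams(
                sigma_J=float(rng.uniform(0.3, 2.0)),
                sigma_A=float(rng.uniform(0.05, 0.5)),
                R=float(rng.uniform(0.5, 3.0)),
                h=float(rng.uniform(0.1, 1.5)),
                L=float(rng.uniform(3.0, 8.0)),
            )
            sol = solve_stationary(p)
            if not sol.exists:
                continue
            efflux = float(sol.juvenile_flux(p.h))
            assert p.sigma_A * sol.N_T == pytest.approx(efflux, rel=1e-10)

    def test_closed_form_matches_trapezoid_quadrature(self, defaults):
        sol = solve_stationary(defaults.with_(R=1.0, p=0.7))
        x = np.linspace(defaults.h, defaults.L, 10_000)
        quad = float(np.trapezoid(sol.adult_density(x), x))
        assert quad == pytest.approx(sol.N_T, rel=1e-8)


class TestEvaluateProfile:
    def test_juvenile_vanishes_at_metamorphosis_point(self, defaults):
        prof = evaluate_profile(solve_stationary(defaults), [0.0, defaults.h, 3.0])
        assert prof.J[-1] == 0.0
        assert prof.x_juvenile[-1] == prof.x_adult[0] == defaults.h

    def test_juvenile_profile_strictly_decreasing(self, defaults):
        sol = solve_stationary(defaults)
        x = np.linspace(0.0, defaults.h, 300)
        assert np.all(np.diff(sol.juvenile_density(x)) < 0)

    def test_adult_profile_peaks_at_edge_for_closed_boundary(self, defaults):
        sol = solve_stationary(defaults)
        x = np.linspace(defaults.h, defaults.L, 300)
        assert np.all(sol.adult_density_derivative(x) <= 0)
        a = sol.adult_density(x)
        assert a[0] == np.max(a)

    def test_positions_outside_domain_rejected(self, defaults):
        sol = solve_stationary(defaults)
        with pytest.raises(ValueError, match=r"\[0, L\]"):
            evaluate_profile(sol, [defaults.L + 1.0])


class TestThresholdBehaviour:
    def test_transcritical_continuity(self, defaults):
        # N_T -> 0 continuously as R decreases to R_c; exactly 0 at and below
        rc = critical_recruitment(defaults)
        for eps in (1e-3, 1e-6, 1e-9):
            nt = solve_stationary(defaults.with_(R=rc * (1 + eps))).N_T
            assert 0.0 < nt < 20.0 * eps * defaults.g / rc
        assert solve_stationary(defaults.with_(R=rc)).N_T == 0.0
        assert solve_stationary(defaults.with_(R=rc * 0.999)).N_T == 0.0

    def test_monotone_in_split_distance_and_rates(self, defaults):
        base = defaults.with_(R=1.0)
        nts_h = [
            solve_stationary(base.with_(h=h, L=h + 5.0)).N_T for h in (0.2, 0.7, 1.4)
        ]
        assert nts_h[0] > nts_h[1] > nts_h[2] > 0
        nts_sj = [solve_stationary(base.with_(sigma_J=s)).N_T for s in (0.5, 1.0, 1.8)]
        assert nts_sj[0] > nts_sj[1] > nts_sj[2] > 0
        nts_r = [solve_stationary(base.with_(R=r)).N_T for r in (0.5, 1.0, 2.0)]
        assert nts_r[0] < nts_r[1] < nts_r[2]
        nts_g = [solve_stationary(base.with_(g=g)).N_T for g in (0.5, 1.0, 2.0)]
        assert nts_g[0] < nts_g[1] < nts_g[2]

    def test_large_patch_equivalence(self, defaults):
        # with beta*s = 40 a permeable edge is indistinguishable from p = 0
        _, beta = decay_lengths(defaults)
        L = defaults.h + 40.0 / beta
        nt_perm = solve_stationary(defaults.with_(p=2.0, L=L, R=1.0)).N_T
        nt_closed = solve_stationary(defaults.with_(p=0.0, L=L, R=1.0)).N_T
        assert nt_perm == pytest.approx(nt_closed, rel=1e-6)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(params=params_strategy())
def test_existence_criterion_and_positivity(params):
    """exists iff R > R_c; positive profiles and exact boundary fluxes."""
    params = validate_params(params)
    sol = solve_stationary(params)
    rc = critical_recruitment(params)
    assert sol.exists == (params.R > rc)
    assert sol.N_T >= 0.0
    if not sol.exists:
        assert sol.N_T == 0.0
        return
    assert sol.N_T > 0.0
    x = np.linspace(params.h, params.L, 64)
    a = sol.adult_density(x)
    interior = a[:-1] if params.absorbing_edge else a
    assert np.all(interior > 0)
    if params.h > 0:
        xj = np.linspace(0.0, params.h * (1 - 1e-9), 64)
        assert np.all(sol.juvenile_density(xj) > 0)
    # river flux condition closes the loop
    assert float(sol.juvenile_flux(0.0)) == pytest.approx(
        recruitment_flux(sol.N_T, params), rel=1e-9
    )
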