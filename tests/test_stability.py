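import numpy as np
import pytest

from carrgodex import (
    ModelParameters,
    autonomous_coexistence_eigenvalues,
    bifurcation_diagram,
    coexistence_eigenvalues,
    coexistence_jacobian,
    dex_concentration,
    effective_rates,
    equilibria,
    hopf_times,
    oscillation_test,
    rhs_nonautonomous,
)
from conftest import random_table_params


class TestEquilibria:
    def test_three_fixed_points(self, coexistence_params):
        death, prolif, coex = equilibria(coexistence_params, 0.0)
        assert (death.x_star, death.y_star) == (0.0, 0.0)
        assert (prolif.x_star, prolif.y_star) == (1.0, 0.0)
        assert (coex.x_star, coex.y_star) == pytest.approx((0.5, 0.5))

    def test_coexistence_tumor_coordinate_is_death_to_proliferation_ratio(self):
        p = ModelParameters(rho=1.0, K=2.0, kappa1=1.0, kappa2=1.0, theta=0.4)
        _, _, coex = equilibria(p, 0.0)
        assert coex.x_star == pytest.approx(0.4)

    def test_zero_death_rate_gives_tumor_free_coexistence(self):
        p = ModelParameters(rho=1.5, K=2.0, kappa1=3.0, kappa2=1.0, theta=0.0)
        _, _, coex = equilibria(p, 0.0)
        assert (coex.x_star, coex.y_star) == pytest.approx((0.0, 0.5))

    def test_rhs_vanishes_at_every_equilibrium(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = random_table_params(rng)
            t = rng.uniform(0, 2)
            for eq in equilibria(p, t):
                dx, dy = rhs_nonautonomous(p, t, eq.x_star, eq.y_star)
                scale = max(1.0, abs(eq.x_star), abs(eq.y_star))
                assert abs(dx) < 1e-9 * scale and abs(dy) < 1e-9 * scale

    def test_zero_kappa_rejected(self):
        p = ModelParameters(rho=1, K=1, kappa1=0.0, kappa2=1, theta=0.5)
        with pytest.raises(ValueError):
            equilibria(p, 0.0)

    def test_out_of_quadrant_flagged(self):
        # theta(0) < 0 pushes the coexistence tumor coordinate negative
        p = ModelParameters(rho=1, K=2, kappa1=1, kappa2=1, theta=0.2, c3=-1.0, D0=0.1)
        _, _, coex = equilibria(p, 0.0)
        assert coex.x_star < 0 and not coex.in_quadrant


class TestCoexistenceEigenvalues:
    def test_worked_example_stable_spiral(self, coexistence_params):
        pair = coexistence_eigenvalues(coexistence_params, 0.0)
        assert pair.discriminant == pytest.approx(-3.0)
        expected = complex(-0.25, 0.25 * np.sqrt(3))
        assert pair.lambda_plus == pytest.approx(expected)
        assert pair.lambda_minus == pytest.approx(expected.conjugate())

    def test_time_independent_without_drug_effect(self):
        p = ModelParameters(rho=2, K=3, kappa1=4, kappa2=0.5, theta=0.6)
        pairs = [coexistence_eigenvalues(p, t) for t in (0.0, 0.5, 3.0)]
        for pair in pairs[1:]:
            assert pair.lambda_plus == pairs[0].lambda_plus
            assert pair.lambda_minus == pairs[0].lambda_minus

    def test_matches_numeric_jacobian(self):
        """Closed form vs dense eigen-decomposition of the analytic 2x2."""
        rng = np.random.default_rng(23)
        for _ in range(500):
            p = random_table_params(rng)
            t = rng.uniform(0, 2)
            if abs(effective_rates(p, t).theta_t) < 1e-8:
                continue
            pair = coexistence_eigenvalues(p, t)
            vals = sorted(np.linalg.eigvals(coexistence_jacobian(p, t)),
                          key=lambda v: (-v.real, -v.imag))
            scale = max(1.0, abs(vals[0]), abs(vals[1]))
            assert abs(pair.lambda_plus - vals[0]) < 1e-10 * scale
            assert abs(pair.lambda_minus - vals[1]) < 1e-10 * scale

    def test_trace_and_determinant_identities(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            p = random_table_params(rng)
            t = rng.uniform(0, 2)
            r = effective_rates(p, t)
            if abs(r.theta_t) < 1e-8:
                continue
            pair = coexistence_eigenvalues(p, t)
            trace = -r.rho_t * r.theta_t / (p.kappa2 * r.K_t)
            det = r.theta_t * r.rho_t * (r.K_t * p.kappa2 - r.theta_t) / (r.K_t * p.kappa2)
            assert pair.lambda_plus + pair.lambda_minus == pytest.approx(trace, rel=1e-8, abs=1e-10)
            assert pair.lambda_plus * pair.lambda_minus == pytest.approx(det, rel=1e-8, abs=1e-10)

    def test_killing_rate_does_not_enter_spectrum(self):
        base = ModelParameters(rho=2, K=4, kappa1=1.0, kappa2=0.6, theta=0.5, c0=1, c3=-1, D0=0.5)
        pair1 = coexistence_eigenvalues(base, 0.3)
        pair2 = coexistence_eigenvalues(base.with_updates(kappa1=50.0), 0.3)
        assert pair1.lambda_plus == pytest.approx(pair2.lambda_plus)
        assert pair1.lambda_minus == pytest.approx(pair2.lambda_minus)

    def test_singular_death_rate_falls_back_to_numeric(self):
        # theta(t) == 0 at t=0 when c3 == -theta
        p = ModelParameters(rho=1, K=2, kappa1=1, kappa2=1, theta=0.5, c3=-0.5, D0=0.1)
        pair = coexistence_eigenvalues(p, 0.0)
        assert np.isfinite(pair.lambda_plus.real) and np.isfinite(pair.lambda_minus.real)
        # the 2x2 Jacobian is nilpotent there: both eigenvalues vanish
        assert abs(pair.lambda_plus) < 1e-12 and abs(pair.lambda_minus) < 1e-12

    def test_stable_whenever_oscillatory_with_positive_death_rate(self):
        rng = np.random.default_rng(43)
        count = 0
        while count < 200:
            p = random_table_params(rng)
            t = rng.uniform(0, 3)
            r = effective_rates(p, t)
            if r.theta_t <= 1e-8:
                continue
            pair = coexistence_eigenvalues(p, t)
            if pair.discriminant < 0:
                assert pair.max_real < 0
                count += 1


class TestOscillationTest:
    def test_matches_imaginary_part_condition(self):
        rng = np.random.default_rng(59)
        for _ in range(500):
            p = random_table_params(rng)
            t = rng.uniform(0, 2)
            if abs(effective_rates(p, t).theta_t) < 1e-8:
                continue
            pair = coexistence_eigenvalues(p, t)
            assert oscillation_test(p, t) == (pair.lambda_plus.imag != 0)

    def test_large_death_rate_suppresses_oscillation(self):
        # theta(t) >= kappa2 K(t) makes the radicand >= 1
        p = ModelParameters(rho=1, K=2, kappa1=1, kappa2=0.5, theta=2.5)
        assert not oscillation_test(p, 0.0)

    def test_small_death_rate_oscillates(self):
        p = ModelParameters(rho=1, K=2, kappa1=1, kappa2=0.5, theta=1e-6)
        assert oscillation_test(p, 0.0)


class TestHopfDetection:
    def test_no_drug_effect_gives_no_crossings(self):
        p = ModelParameters(rho=1, K=2, kappa1=1, kappa2=1, theta=0.5)
        assert hopf_times(p, 6.0) == []

    def test_pro_proliferative_drug_destabilizes_then_restabilizes(self, dex_params):
        """c3 < -theta: unstable until the drug clears, then one Hopf."""
        pair0 = coexistence_eigenvalues(dex_params, 0.0)
        assert pair0.max_real > 0  # at least one positive eigenvalue at t=0
        crossings = hopf_times(dex_params, 6.0)
        assert len(crossings) == 1
        # the leading real part changes sign where theta(t) crosses zero
        expected = np.log(-dex_params.c3 / dex_params.theta) / dex_params.sigma
        assert crossings[0] == pytest.approx(expected, abs=1e-5)

    def test_crossing_near_two_half_lives_for_default_regime(self, dex_params):
        [t_hopf] = hopf_times(dex_params, 6.0)
        two_half_lives = 2 * np.log(2) / dex_params.sigma
        assert t_hopf * 24 == pytest.approx(7.0, abs=0.1)  # hours
        assert t_hopf == pytest.approx(two_half_lives, rel=0.06)


class TestBifurcationDiagram:
    def test_labels_flip_once_across_hopf_time(self, dex_params):
        t_grid = np.linspace(0.0, 2.0, 400)
        diagram = bifurcation_diagram(dex_params, t_grid)
        labels = np.array(diagram.labels)
        unstable = np.isin(labels, ("unstable", "unstable_spiral"))
        flips = np.nonzero(unstable[:-1] != unstable[1:])[0]
        assert len(flips) == 1
        assert len(diagram.hopf_times) == 1
        t_flip = t_grid[flips[0]]
        assert abs(t_flip - diagram.hopf_times[0]) < (t_grid[1] - t_grid[0]) * 2

    def test_late_time_oscillatory_state_is_stable(self, dex_params):
        # > 5 half-lives after treatment the drug has cleared
        t_grid = np.linspace(1.0, 6.0, 50)
        diagram = bifurcation_diagram(dex_params, t_grid)
        assert all(lbl == "stable_spiral" for lbl in diagram.labels)

    def test_constant_labels_without_drug(self):
        p = ModelParameters(rho=1, K=2, kappa1=1, kappa2=1, theta=0.5)
        diagram = bifurcation_diagram(p, np.linspace(0, 3, 30))
        assert len(set(diagram.labels)) == 1
        assert diagram.hopf_times == []

    def test_csv_export_schema(self, tmp_path, dex_params):
        diagram = bifurcation_diagram(dex_params, np.linspace(0, 2, 20))
        path = tmp_path / "bif.csv"
        diagram.to_csv(path)
        header = path.read_text().splitlines()[0].split(",")
        assert header == ["time_hr", "re_lambda_plus", "im_lambda_plus",
                          "re_lambda_minus", "im_lambda_minus", "label",
                          "x_star", "y_star"]


class TestAutonomousSpectrum:
    def test_drug_free_limit_appends_clearance_eigenvalue(self, coexistence_params):
        vals = autonomous_coexistence_eigenvalues(coexistence_params, 0.0)
        pair = coexistence_eigenvalues(coexistence_params, 0.0)
        assert sorted(vals.real)[0] == pytest.approx(-coexistence_params.sigma)
        two = sorted(vals, key=lambda v: -v.real)[:2]
        assert two[0] == pytest.approx(pair.lambda_plus)
        assert two[1] == pytest.approx(pair.lambda_minus)

    def test_third_eigenvalue_is_minus_five_per_day(self):
        p = ModelParameters(rho=1, K=1, kappa1=1, kappa2=1, theta=0.5, sigma=5.0)
        vals = autonomous_coexistence_eigenvalues(p, 0.0)
        assert min(vals.real) == pytest.approx(-5.0)

    def test_agrees_with_nonautonomous_pair_along_clearance_curve(self):
        rng = np.random.default_rng(71)
        for _ in range(50):
            p = random_table_params(rng)
            t = rng.uniform(0.0, 1.5)
            D = dex_concentration(p, t)
            vals = autonomous_coexistence_eigenvalues(p, D)
            if abs(effective_rates(p, t).theta_t) < 1e-8:
                continue
            pair = coexistence_eigenvalues(p, t)
            got = sorted(vals, key=lambda v: (-v.real, -v.imag))
            want = sorted([pair.lambda_plus, pair.lambda_minus, complex(-p.sigma)],
                          key=lambda v: (-v.real, -v.imag))
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-8, abs=1e-9)


def test_boundary_equilibria_never_stable_when_coexistence_admissible():
    """With an interior coexistence point and positive effective growth,
    neither the extinction point nor the tumor-only point is stable."""
    rng = np.random.default_rng(83)
    for _ in range(100):
        p = random_table_params(rng, interior=True)
        t = rng.uniform(0, 3)
        r = effective_rates(p, t)
        if r.rho_t <= 0 or r.theta_t >= p.kappa2 * r.K_t:
            continue
        # extinction point: J = diag(rho(t), -theta(t))
        assert r.rho_t > 0
        # tumor-only point: eigenvalues -rho(t) and kappa2 K(t) - theta(t)
        assert p.kappa2 * r.K_t - r.theta_t > 0
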