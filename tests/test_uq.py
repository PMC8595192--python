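import numpy as np
import pytest

from morphoscar import ParameterSet, NumericsConfig, simulate
from morphoscar.observables import summarize_trajectory
from morphoscar import uq
from morphoscar.params import InvalidParameterError

TINY_CFG = NumericsConfig(n_elements=40, dt=0.5, dt_early=0.5, t_early=0.0,
                          t_end=2.0, grading=1.5)


class TestKLExpansion:
    def test_zero_at_origin_every_draw(self):
        spec = uq.KLSpec(n_terms=30, domain_length=10.0)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            u = uq.kl_realization(spec, np.array([-3.0, 0.0]), rng)
            assert u[-1] == 0.0
            assert u[0] != 0.0

    def test_zero_mean_unit_domain_variance(self):
        spec = uq.KLSpec(n_terms=60, domain_length=10.0)
        X = np.linspace(-10.0, 0.0, 101)
        rng = np.random.default_rng(12345)
        n_draws = 10_000
        draws = np.empty((n_draws, X.size))
        for k in range(n_draws):
            draws[k] = uq.kl_realization(spec, X, rng)
        se = 1.0 / np.sqrt(n_draws)
        assert np.abs(draws.mean(axis=0)).max() < 4 * se
        # pointwise variance averaged over the interior of the domain -> 1
        var = draws.var(axis=0)[:-1]
        assert var.mean() == pytest.approx(1.0, abs=3 * np.sqrt(2) * se)

    def test_variance_profile_matches_quadrature_oracle(self):
        spec = uq.KLSpec(n_terms=7, domain_length=10.0)
        X = np.linspace(-10.0, 0.0, 401)
        j = np.arange(1, 8)
        analytic = (2.0 / 7) * np.sin(
            np.outer(X, (2 * j - 1) * np.pi / 20.0)) ** 2 @ np.ones(7)
        # integrate the analytic pointwise variance over the domain
        assert np.trapezoid(analytic, X) / 10.0 == pytest.approx(1.0, rel=1e-3)


class TestLognormal:
    def test_degenerate_sd(self):
        M, S = uq.lognormal_moments(350.0, 0.0)
        assert (M, S) == (pytest.approx(np.log(350.0)), 0.0)

    def test_unit_case_closed_form(self):
        M, S = uq.lognormal_moments(1.0, 1.0)
        assert M == pytest.approx(np.log(1.0 / np.sqrt(2.0)))
        assert S == pytest.approx(np.sqrt(np.log(2.0)))

    def test_monte_carlo_round_trip(self):
        M, S = uq.lognormal_moments(350.0, 35.0)
        z = np.random.default_rng(7).standard_normal(10 ** 6)
        samp = np.exp(M + S * z)
        assert samp.mean() == pytest.approx(350.0, rel=5e-3)
        assert samp.std() == pytest.approx(35.0, rel=2e-2)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidParameterError):
            uq.lognormal_moments(-1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            uq.lognormal_moments(1.0, -1.0)

    def test_heterogeneous_field_properties(self):
        u_hat = np.array([-1.0, 0.0, 2.0])
        f = uq.heterogeneous_field(350.0, 0.0, u_hat)
        assert np.allclose(f, 350.0)
        f = uq.heterogeneous_field(350.0, 35.0, u_hat)
        assert np.all(f > 0)
        M, _ = uq.lognormal_moments(350.0, 35.0)
        assert f[1] == pytest.approx(np.exp(M))


class TestAgeGroups:
    def test_group2_means_are_adult_defaults(self):
        groups = uq.load_age_groups()
        g2 = groups[2].means
        base = ParameterSet()
        for name in ("N_bar", "rho_bar", "delta_N", "E", "mu", "k_c"):
            assert getattr(g2, name) == pytest.approx(getattr(base, name))

    def test_groups_valid_and_aging_directions(self):
        groups = uq.load_age_groups()
        from morphoscar import validate_parameters
        rho = []
        for gid in (1, 2, 3, 4):
            g = groups[gid]
            assert validate_parameters(g.means).ok
            rho.append(g.means.rho_bar)
        assert rho[0] > rho[1] > rho[2] > rho[3]   # collagen declines
        assert groups[1].means.N_bar > groups[4].means.N_bar
        assert groups[4].means.E > groups[2].means.E

    def test_monotone_contraction_with_age(self):
        """Deterministic group-mean runs: from the adult group on, a higher
        age group contracts more (smaller minimum relative surface area)."""
        groups = uq.load_age_groups()
        cfg = NumericsConfig(n_elements=100, dt=0.5, dt_early=0.1)
        mins = {}
        for gid in (2, 3, 4):
            s = summarize_trajectory(simulate(groups[gid].means, cfg))
            mins[gid] = s.RSA_min
        assert mins[2] >= mins[3] >= mins[4]


class TestPatientSampling:
    def test_same_seed_same_patient(self):
        groups = uq.load_age_groups()
        x = np.linspace(-10, 0, 51)
        kl = uq.KLSpec(n_terms=20, domain_length=10.0)
        p1 = uq.sample_patient(groups[2], kl, (42, 2, 0), x=x)
        p2 = uq.sample_patient(groups[2], kl, (42, 2, 0), x=x)
        for name in groups[2].heterogeneous:
            np.testing.assert_array_equal(np.asarray(getattr(p1, name)),
                                          np.asarray(getattr(p2, name)))

    def test_zero_sd_reduces_to_group_means(self):
        groups = uq.load_age_groups()
        g = groups[2]
        g0 = uq.AgeGroupSpec(group_id=2, age_range=g.age_range,
                             means=g.means,
                             sd={k: 0.0 for k in g.heterogeneous},
                             heterogeneous=g.heterogeneous)
        p = uq.sample_patient(g0, uq.KLSpec(n_terms=10), (1, 2, 3),
                              x=np.linspace(-10, 0, 21))
        assert np.ndim(p.E) == 0 and p.E == g.means.E

    def test_fields_positive_and_valid(self):
        from morphoscar import validate_parameters
        groups = uq.load_age_groups()
        x = np.linspace(-10, 0, 51)
        p = uq.sample_patient(groups[2], uq.KLSpec(n_terms=30), 99, x=x)
        for name in groups[2].heterogeneous:
            assert np.all(np.asarray(getattr(p, name)) > 0)
        assert validate_parameters(p).ok


class TestCohorts:
    def test_worker_count_invariance(self):
        groups = uq.load_age_groups()
        r1 = uq.run_cohort(groups[2], n_b=4, base_seed=17,
                           numerics=TINY_CFG, n_jobs=1)
        r4 = uq.run_cohort(groups[2], n_b=4, base_seed=17,
                          numerics=TINY_CFG, n_jobs=4)
        assert r1.summaries.equals(r4.summaries)
        assert r1.failures == 0

    def test_zero_sd_cohort_is_constant(self):
        groups = uq.load_age_groups()
        g = groups[2]
        g0 = uq.AgeGroupSpec(group_id=2, age_range=g.age_range,
                             means=g.means,
                             sd={k: 0.0 for k in g.heterogeneous},
                             heterogeneous=g.heterogeneous)
        r = uq.run_cohort(g0, n_b=3, base_seed=5, numerics=TINY_CFG)
        assert r.summaries["RSA_min"].nunique() == 1

    def test_heterogeneous_simulation_runs(self):
        groups = uq.load_age_groups()
        r = uq.run_cohort(groups[2], n_b=2, base_seed=23, numerics=TINY_CFG)
        assert r.failures == 0
        assert len(r.summaries) == 2
        # heterogeneity genuinely perturbs the outcome
        assert r.summaries["SED_max"].nunique() == 2


class TestStatistics:
    def test_critical_value_large_cohort(self):
        res = uq.group_t_test(np.zeros(1950), np.zeros(1950), alpha=0.001)
        assert res.critical == pytest.approx(3.293, abs=5e-4)
        assert res.df == 3898

    def test_identical_groups_not_rejected(self):
        a = np.random.default_rng(0).normal(size=100)
        res = uq.group_t_test(a, a.copy())
        assert res.t == 0.0 and not res.reject

    def test_two_point_hand_case(self):
        a = np.array([0.0, 1e-6])
        b = np.array([1.0, 1.0 + 1e-6])
        res = uq.group_t_test(a, b, alpha=0.001)
        # s_p = sqrt((s_a^2+s_b^2)/2) = 1e-6/sqrt... hand: var=5e-13 each
        sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert res.t == pytest.approx((a.mean() - b.mean()) / sp)
        assert res.reject

    def test_unequal_sizes_rejected(self):
        with pytest.raises(ValueError):
            uq.group_t_test(np.zeros(3), np.zeros(4))

    def test_confidence_interval_properties(self):
        lo, hi = uq.confidence_interval(np.full(10, 3.3))
        assert lo == hi == pytest.approx(3.3)
        rng = np.random.default_rng(2)
        s = rng.standard_normal(400)
        lo1, hi1 = uq.confidence_interval(s[:100])
        lo2, hi2 = uq.confidence_interval(s)
        assert (hi2 - lo2) < (hi1 - lo1)    # width shrinks with n

    def test_confidence_interval_coverage(self):
        rng = np.random.default_rng(31)
        hits = 0
        reps = 300
        for _ in range(reps):
            lo, hi = uq.confidence_interval(rng.standard_normal(50))
            hits += lo <= 0.0 <= hi
        assert 0.90 <= hits / reps <= 0.99

    def test_kde_and_ecdf(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal(10_000)
        out = uq.kde_and_ecdf(s)
        assert out["ecdf_y"][-1] == 1.0
        assert np.all(np.diff(out["ecdf_y"]) >= 0)
        mass = np.trapezoid(out["pdf"], out["grid"])
        assert mass == pytest.approx(1.0, abs=0.02)
        mode = out["grid"][np.argmax(out["pdf"])]
        assert abs(mode) < 0.25

    def test_degenerate_sample_gets_ecdf_only(self):
        out = uq.kde_and_ecdf(np.full(5, 2.0))
        assert out["pdf"] is None
        assert out["ecdf_y"][-1] == 1.0
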