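import numpy as np
import pytest

import exmort as em


def _stub_data(p_init, p_obs, n, launch_ages, target_ages):
    """Data whose forward model is pure transport: i ≡ 0 and m ≡ 0."""
    initial = em.PrevalenceCrossSection(2009.0, launch_ages, p_init)
    target = em.PrevalenceCrossSection(2015.0, target_ages, p_obs, n)
    zero = lambda t, a: 0.0
    return em.BayesData(initial, target, incidence=zero, general_mortality=zero)


class TestLogPrior:
    def test_uniform_box(self):
        prior = em.PriorSpec.uniform()
        assert em.log_prior(prior, 5.0, 1.5) == 0.0
        assert em.log_prior(prior, 1.5, 1.5) == -np.inf
        assert em.log_prior(prior, 5.0, 2.5) == -np.inf

    def test_normal_mode_at_mean(self):
        prior = em.PriorSpec.bivariate_normal()
        g50, g90 = np.meshgrid(np.linspace(2, 9, 71), np.linspace(1, 2, 51), indexing="ij")
        lp = em.log_prior(prior, g50, g90)
        k = np.unravel_index(np.argmax(lp), lp.shape)
        assert g50[k] == pytest.approx(5.5, abs=0.06)
        assert g90[k] == pytest.approx(1.5, abs=0.02)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            em.PriorSpec(kind="jeffreys")


class TestLogLikelihood:
    def test_hand_evaluated_quadratic_form(self):
        # p_obs=(0.10, 0.20), p_mod=(0.12, 0.19), n=1000:
        # -0.5 * (0.0004/9e-5 + 0.0001/1.6e-4) = -2.53472
        data = _stub_data(
            p_init=[0.12, 0.19],
            p_obs=[0.10, 0.20],
            n=[1000.0, 1000.0],
            launch_ages=np.array([54.0, 64.0]),
            target_ages=np.array([60.0, 70.0]),
        )
        ll = em.log_likelihood(data, 1.0, 1.0)
        assert ll == pytest.approx(-2.53472, abs=1e-4)

    def test_perfect_fit_is_maximum(self):
        data = _stub_data(
            p_init=[0.10, 0.20],
            p_obs=[0.10, 0.20],
            n=[1000.0, 1000.0],
            launch_ages=np.array([54.0, 64.0]),
            target_ages=np.array([60.0, 70.0]),
        )
        assert em.log_likelihood(data, 1.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_group_sizes(self):
        kwargs = dict(
            p_init=[0.12, 0.19],
            p_obs=[0.10, 0.20],
            launch_ages=np.array([54.0, 64.0]),
            target_ages=np.array([60.0, 70.0]),
        )
        ll1 = em.log_likelihood(_stub_data(n=[1000.0, 1000.0], **kwargs), 1.0, 1.0)
        ll2 = em.log_likelihood(_stub_data(n=[2000.0, 2000.0], **kwargs), 1.0, 1.0)
        assert ll2 == pytest.approx(2.0 * ll1, rel=1e-12)

    def test_degenerate_observed_prevalence_names_age(self):
        data = _stub_data(
            p_init=[0.12, 0.19],
            p_obs=[0.0, 0.20],
            n=[1000.0, 1000.0],
            launch_ages=np.array([54.0, 64.0]),
            target_ages=np.array([60.0, 70.0]),
        )
        with pytest.raises(ValueError, match="age 60"):
            em.log_likelihood(data, 1.0, 1.0)


class TestModeledPrevalence:
    def test_pure_transport_identity(self):
        # R ≡ 1 and i ≡ 0: initial prevalence rides the characteristic unchanged
        launch = np.arange(50.0, 86.0, 1.0)
        p_init = np.linspace(0.05, 0.30, launch.size)
        target_ages = launch + 6.0
        data = em.BayesData(
            initial_cs=em.PrevalenceCrossSection(2009.0, launch, p_init),
            target_cs=em.PrevalenceCrossSection(
                2015.0, target_ages, np.full(launch.size, 0.1), np.full(launch.size, 100.0)
            ),
            incidence=lambda t, a: 0.0,
            general_mortality=lambda t, a: 0.02,
        )
        ages, p_mod, _ = em.modeled_prevalence(data, 1.0, 1.0)
        keep = ages <= 90.0
        expect = np.interp(ages - 6.0, launch, p_init)
        assert np.max(np.abs(p_mod[keep] - expect[keep])) < 1e-12

    def test_matches_forward_solution_at_truth(self, diabetes_data):
        ages, p_mod, _ = em.modeled_prevalence(diabetes_data, 4.5, 1.4)
        idx = np.searchsorted(diabetes_data.target_cs.ages, ages)
        p_obs = diabetes_data.target_cs.prevalence[idx]
        assert np.max(np.abs(p_mod - p_obs)) < 1e-6

    def test_monotone_decreasing_in_r50(self, diabetes_data):
        r50s = np.array([3.0, 4.5, 6.0])
        _, p_mod, _ = em.modeled_prevalence(diabetes_data, r50s, np.full(3, 1.4))
        assert np.all(np.diff(p_mod, axis=1) <= 1e-15)

    def test_nonpositive_parameters_rejected(self, diabetes_data):
        with pytest.raises(ValueError):
            em.modeled_prevalence(diabetes_data, -1.0, 1.4)

    def test_launch_off_grid_excluded_and_reported(self, diabetes_data):
        ages, _, excluded = em.modeled_prevalence(diabetes_data, 4.5, 1.4)
        assert ages[0] == 56.0  # launches below age 50 have no initial value
        assert {a for a, _ in excluded} == {50.0, 51.0, 52.0, 53.0, 54.0, 55.0}


class TestBayesDataValidation:
    def test_time_order(self):
        cs1 = em.PrevalenceCrossSection(2009.0, [50.0, 90.0], [0.1, 0.2])
        cs2 = em.PrevalenceCrossSection(2015.0, [50.0, 90.0], [0.1, 0.2], [10.0, 10.0])
        with pytest.raises(ValueError):
            em.BayesData(cs2.with_group_sizes(10), cs1, lambda t, a: 0.0, lambda t, a: 0.0)

    def test_group_sizes_required(self):
        cs1 = em.PrevalenceCrossSection(2009.0, [50.0, 90.0], [0.1, 0.2])
        cs2 = em.PrevalenceCrossSection(2015.0, [50.0, 90.0], [0.1, 0.2])
        with pytest.raises(ValueError, match="group sizes"):
            em.BayesData(cs1, cs2, lambda t, a: 0.0, lambda t, a: 0.0)


class TestPosteriorGrid:
    def test_prior_only_uniform_quantiles(self):
        res = em.fit_posterior(None, em.PriorSpec.uniform())
        assert sum(res.posterior.ravel()) == pytest.approx(1.0, abs=1e-12)
        assert res.ci_r50 == pytest.approx((2.175, 8.825), abs=1e-9)
        assert res.ci_r90 == pytest.approx((1.025, 1.975), abs=1e-9)

    def test_no_overlap_raises(self):
        grid = em.GridSpec(r50=np.linspace(9.5, 10.0, 11), r90=np.linspace(1.0, 2.0, 11))
        with pytest.raises(ValueError, match="do not overlap"):
            em.fit_posterior(None, em.PriorSpec.uniform(), grid)

    def test_recovery_of_generating_parameters(self, diabetes_data):
        grid = em.GridSpec.from_ranges((2.0, 9.0), (1.0, 2.0), 71, 51)
        res = em.MortalityRatioModel(diabetes_data).fit(grid)
        assert res.map_point[0] == pytest.approx(4.5, abs=0.1)
        assert res.map_point[1] == pytest.approx(1.4, abs=0.1)
        assert res.ci_r50[0] <= 4.5 <= res.ci_r50[1]
        assert res.ci_r90[0] <= 1.4 <= res.ci_r90[1]
        # structural invariants of the grid summary
        assert res.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        k = np.unravel_index(np.argmax(res.log_posterior), res.log_posterior.shape)
        assert res.map_lattice == (res.r50_grid[k[0]], res.r90_grid[k[1]])
        assert res.r50_grid[0] <= res.ci_r50[0] <= res.ci_r50[1] <= res.r50_grid[-1]
        assert res.ci_r50[0] <= res.map_point[0] <= res.ci_r50[1]
        assert res.ci_r90[0] <= res.map_point[1] <= res.ci_r90[1]

    def test_prior_robustness_at_large_n(self, diabetes_data):
        grid = em.GridSpec.from_ranges((2.0, 9.0), (1.0, 2.0), 71, 51)
        flat = em.MortalityRatioModel(diabetes_data, prior=em.PriorSpec.uniform()).fit(grid)
        normal = em.MortalityRatioModel(
            diabetes_data, prior=em.PriorSpec.bivariate_normal()
        ).fit(grid)
        for j in (0, 1):
            shift = abs(normal.map_point[j] - flat.map_point[j]) / flat.map_point[j]
            assert shift < 0.02

    def test_grid_refinement_stability(self, diabetes_data):
        coarse = em.MortalityRatioModel(diabetes_data).fit(
            em.GridSpec.from_ranges((3.5, 5.5), (1.2, 1.6), 21, 21)
        )
        fine = em.MortalityRatioModel(diabetes_data).fit(
            em.GridSpec.from_ranges((3.5, 5.5), (1.2, 1.6), 41, 41)
        )
        cell50 = 2.0 / 20
        cell90 = 0.4 / 20
        assert abs(fine.map_point[0] - coarse.map_point[0]) < cell50
        assert abs(fine.map_point[1] - coarse.map_point[1]) < cell90

    def test_interval_width_shrinks_as_sqrt_n(self, diabetes_world):
        scen, initial, target, gm = diabetes_world
        widths = {}
        for n, span50, span90 in [(1e4, 0.7, 0.07), (1e6, 0.07, 0.007), (1e8, 0.007, 0.0007)]:
            data = em.BayesData(
                initial, target.with_group_sizes(n), scen.incidence, gm
            )
            grid = em.GridSpec.from_ranges(
                (4.5 - span50, 4.5 + span50), (1.4 - span90, 1.4 + span90), 81, 81
            )
            res = em.fit_posterior(data, em.PriorSpec.uniform(), grid)
            widths[n] = (
                res.ci_r50[1] - res.ci_r50[0],
                res.ci_r90[1] - res.ci_r90[0],
            )
        for j in (0, 1):
            for n_lo, n_hi in [(1e4, 1e6), (1e6, 1e8)]:
                ratio = widths[n_lo][j] / widths[n_hi][j]
                assert 10.0 / 1.5 < ratio < 10.0 * 1.5

    def test_summary_and_frame(self, diabetes_data):
        res = em.MortalityRatioModel(diabetes_data).fit(
            em.GridSpec.from_ranges((3.5, 5.5), (1.2, 1.6), 21, 21)
        )
        text = res.summary()
        assert "R(50) MAP" in text and "95% CI" in text
        frame = res.to_frame()
        assert set(frame.columns) == {"r50", "r90", "log_posterior"}
        assert len(frame) == 21 * 21
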