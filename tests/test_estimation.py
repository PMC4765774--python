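import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protdeg import (
    GrowthTimeCourse,
    InsufficientDataError,
    compare_conditions,
    compute_interval_estimates,
    estimate_beta,
    estimate_net_rate,
    generate_balanced_growth,
    per_cell_signal,
    zero_order_validity_check,
)
from protdeg.estimation import cumulative_od

from conftest import recover_beta


def make_tc(times, od, activity, dilution=None, condition="WT", replicate="r1"):
    return GrowthTimeCourse(condition=condition, replicate=replicate,
                            times=np.asarray(times, float),
                            od=np.asarray(od, float),
                            activity=np.asarray(activity, float),
                            dilution_factor=None if dilution is None
                            else np.asarray(dilution, float))


class TestPerCellSignal:
    def test_constant_per_cell_level(self):
        tc = make_tc([0, 1], [0.5, 1.0], [1000, 2000])
        np.testing.assert_allclose(per_cell_signal(tc), [2000, 2000])

    def test_dilution_leaves_per_cell_unchanged(self):
        # a 10x dilution drops OD 1.0 -> 0.1 but P (intensive) is untouched
        p = 2000.0
        od = np.array([0.25, 0.5, 1.0, 0.2, 0.4])
        dil = np.array([1, 1, 1, 10, 1], float)
        tc = make_tc([0, 1, 2, 3, 4], od, p * od, dilution=dil)
        np.testing.assert_allclose(per_cell_signal(tc), p)
        # cumulative biomass keeps growing exponentially through the event
        np.testing.assert_allclose(cumulative_od(tc),
                                   0.25 * 2.0 ** np.arange(5), rtol=1e-12)

    def test_noiseless_generator_round_trip(self, balanced_design_factory):
        design = balanced_design_factory(noise_cv=0.0, replicates=1)
        tc = [t for t in generate_balanced_growth(design) if t.condition == "WT"][0]
        # generator holds P at the zero-order steady state (alpha-beta)/mu
        np.testing.assert_allclose(per_cell_signal(tc), 25000.0, rtol=1e-12)

    def test_nonpositive_od_rejected(self):
        with pytest.raises(ValueError):
            make_tc([0, 1], [0.5, 0.0], [1, 1])


class TestIntervalEstimates:
    def test_doubling_culture_constant_protein(self):
        c = 5000.0
        od = np.array([0.1, 0.2, 0.4, 0.8])
        tc = make_tc([0, 1, 2, 3], od, c * od)
        ivs = compute_interval_estimates(tc)
        for iv in ivs:
            assert iv.mu == pytest.approx(np.log(2), rel=1e-12)
            assert iv.dpdt == pytest.approx(0.0, abs=1e-9)
            assert iv.net_rate == pytest.approx(np.log(2) * c, rel=1e-12)

    def test_everything_flat_gives_zero_rates(self):
        tc = make_tc([0, 1, 2, 3], [0.3] * 4, [600.0] * 4)
        for iv in compute_interval_estimates(tc):
            assert iv.mu == 0 and iv.dpdt == 0 and iv.net_rate == 0

    def test_net_rate_identity_holds_exactly(self):
        rng = np.random.default_rng(7)
        tc = make_tc(np.arange(5.0), rng.uniform(0.1, 1, 5), rng.uniform(10, 100, 5))
        for iv in compute_interval_estimates(tc):
            assert iv.net_rate == iv.dpdt + iv.mu * iv.p_avg

    def test_generator_growth_rate_recovered(self, balanced_design_factory):
        design = balanced_design_factory(mu=1.1, noise_cv=0.0, replicates=1)
        for tc in generate_balanced_growth(design):
            for iv in compute_interval_estimates(tc):
                assert iv.mu == pytest.approx(1.1, abs=1e-9)


class TestEstimateNetRate:
    def test_noiseless_round_trip(self, balanced_design_factory):
        design = balanced_design_factory(noise_cv=0.0, replicates=1)
        tc = [t for t in generate_balanced_growth(design) if t.condition == "WT"][0]
        # alpha - beta = 40000 - 15000
        assert estimate_net_rate(tc) == pytest.approx(25000.0, rel=1e-6)

    def test_flat_data_gives_zero(self):
        tc = make_tc([0, 1, 2, 3], [0.3] * 4, [600.0] * 4)
        assert estimate_net_rate(tc) == 0.0

    def test_single_interval_errors(self):
        tc = make_tc([0, 1], [0.1, 0.2], [10, 20])
        with pytest.raises(InsufficientDataError):
            estimate_net_rate(tc)

    def test_window_capped_at_five_time_points(self):
        # 9 points; the first five (4 intervals) carry mu=ln2, the rest a
        # very different growth rate, so the earliest consistent window wins
        t = np.arange(9.0)
        od = np.concatenate([0.01 * 2.0 ** np.arange(5),
                             0.16 * 8.0 ** np.arange(1, 5)])
        c = 1000.0
        tc = make_tc(t, od, c * od)
        assert estimate_net_rate(tc) == pytest.approx(np.log(2) * c, rel=1e-9)


class TestEstimateBeta:
    def test_self_subtraction_is_zero(self):
        res = estimate_beta([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.beta == 0.0

    @given(st.lists(st.floats(-1e5, 1e5), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_self_subtraction_property(self, rates):
        assert estimate_beta(rates, rates).beta == pytest.approx(0.0, abs=1e-9)

    def test_zero_noise_recovery_exact(self, balanced_design_factory):
        tcs = generate_balanced_growth(balanced_design_factory(noise_cv=0.0))
        res = recover_beta(tcs)
        assert res.beta == pytest.approx(15000.0, rel=1e-9)
        assert res.sem == pytest.approx(0.0, abs=1e-6)
        assert res.n == 4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            estimate_beta([], [1.0])

    def test_sem_propagation_in_quadrature(self):
        cond = np.array([1.0, 2.0, 3.0])
        ctrl = np.array([10.0, 14.0])
        res = estimate_beta(cond, ctrl)
        sem_c = cond.std(ddof=1) / np.sqrt(3)
        sem_k = ctrl.std(ddof=1) / np.sqrt(2)
        assert res.sem == pytest.approx(np.hypot(sem_c, sem_k), rel=1e-12)
        only = estimate_beta(cond, ctrl, sem_mode="condition_only")
        assert only.sem == pytest.approx(sem_c, rel=1e-12)

    def test_negative_beta_not_clamped(self):
        res = estimate_beta([10.0, 11.0], [1.0, 2.0])
        assert res.beta < 0


class TestExactRecoveryGrid:
    @pytest.mark.parametrize("alpha", [1e4, 4e4])
    @pytest.mark.parametrize("mu", [0.3, 1.0, 1.1])
    @pytest.mark.parametrize("beta_frac", [0.0, 0.25, 0.5])
    def test_noiseless_beta_recovery(self, balanced_design_factory, alpha, mu,
                                     beta_frac):
        beta = beta_frac * alpha
        tcs = generate_balanced_growth(
            balanced_design_factory(alpha=alpha, mu=mu, vmax=beta, noise_cv=0.0)
        )
        res = recover_beta(tcs)
        assert res.beta == pytest.approx(beta, rel=1e-6, abs=1e-6 * alpha)


class TestDilutionInvariance:
    def test_dilution_event_does_not_move_beta(self, balanced_design_factory):
        # low threshold forces a dilution event mid-course; high threshold none
        base = balanced_design_factory(noise_cv=0.0, dilution_threshold=1e9)
        diluted = balanced_design_factory(noise_cv=0.0, dilution_threshold=0.5)
        b0 = recover_beta(generate_balanced_growth(base)).beta
        b1 = recover_beta(generate_balanced_growth(diluted)).beta
        assert abs(b1 - b0) < 1e-9 * max(abs(b0), 1.0)


class TestCompareConditions:
    def test_identical_groups(self):
        assert compare_conditions([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_near_complete_separation(self):
        p = compare_conditions([0, 0, 0, 0.0], [10, 10, 10, 10.0001])
        assert p < 1e-3

    def test_matches_hand_computed_welch(self):
        # textbook Welch statistic and Welch-Satterthwaite df, computed
        # independently from first principles
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        tstat = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        from scipy.stats import t as tdist

        expected = 2 * tdist.sf(abs(tstat), df)
        assert compare_conditions(a, b) == pytest.approx(expected, rel=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [1.0, 2.0])


class TestZeroOrderValidity:
    @pytest.mark.parametrize(
        "p_values, km, flagged",
        [
            ([10000.0, 12000.0], 600.0, False),  # typical balanced growth
            ([600.0], 600.0, True),              # at Km: clearly first order
            ([6000.0], 600.0, False),            # exactly 10*Km: strict inequality
            ([5999.9], 600.0, True),
        ],
    )
    def test_threshold(self, p_values, km, flagged):
        assert zero_order_validity_check(p_values, km) is flagged
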