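import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aridiv.shiftfit as sf
from aridiv.bd_sim import (
    SimulationSpec,
    prune_random_tips,
    simulate_piecewise,
    simulate_yule,
    yule_branching_times,
)
from aridiv.shiftfit import (
    FitResult,
    ShiftModel,
    bd_shift_loglik,
    fit_constant,
    fit_k_shifts,
    lrt,
)
from aridiv.treeio import BranchingTimes, branching_times, parse_newick


def _bt(times_desc, n=None):
    times = np.asarray(times_desc, dtype=float)
    return BranchingTimes(times, n or len(times) + 1)


def yule_loglik_closed_form(times_desc, lam):
    """Independent closed form for the pure-birth complete-sampling density,
    conditioned on the crown age and survival (trivial for pure birth):

        sum_{i>=2} (ln lam - lam x_i) - 2 lam x1

    derived directly from the exponential waiting times of the reconstructed
    pure-birth process (each age-a event contributes rate factor lam and
    survival factor e^{-lam a}; the two crown lineages each contribute
    e^{-lam x1}).
    """
    x = np.asarray(times_desc, dtype=float)
    return float(np.sum(np.log(lam) - lam * x[1:]) - 2 * lam * x[0])


def euler_reconstructed_density(x1, x2, lam, mu, rho, h=2e-5):
    """First-principles numerical oracle for the 3-tip density: Euler
    integration of the backward extinction / one-sampled-lineage equations

        p0' = mu - (lam + mu) p0 + lam p0^2,   p0(0) = 1 - rho
        p1' = -(lam + mu) p1 + 2 lam p0 p1,    p1(0) = rho

    assembled as  lam p1(x2) * p1(x1)^2 / (1 - p0(x1))^2.
    """
    steps = int(np.ceil(x1 / h))
    p0, p1 = 1.0 - rho, rho
    t = 0.0
    vals = {}
    targets = sorted({x2, x1})
    ti = 0
    for _ in range(steps + 1):
        while ti < len(targets) and targets[ti] <= t + 1e-15:
            vals[targets[ti]] = (p0, p1)
            ti += 1
        p0, p1 = (
            p0 + h * (mu - (lam + mu) * p0 + lam * p0 * p0),
            p1 + h * (-(lam + mu) * p1 + 2 * lam * p0 * p1),
        )
        t += h
    while ti < len(targets):
        vals[targets[ti]] = (p0, p1)
        ti += 1
    p0_1, p1_1 = vals[x1]
    _, p1_2 = vals[x2]
    return lam * p1_2 * p1_1**2 / (1.0 - p0_1) ** 2


class TestShiftModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            ShiftModel((0.2,), (0.0, 0.1), (), 1.0)
        with pytest.raises(ValueError):
            ShiftModel((0.2, 0.3), (0.0, 0.0), (5.0, 3.0), 1.0)  # not ascending
        with pytest.raises(ValueError):
            ShiftModel((0.2,), (0.0,), (), 0.0)


class TestLoglik:
    @pytest.mark.parametrize("seed", range(50))
    def test_yule_limit_matches_symbolic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        lam_true = float(rng.uniform(0.05, 1.0))
        times = np.sort(yule_branching_times(n, lam_true, 1, rng)[0])[::-1]
        bt = _bt(times, n)
        lam = float(rng.uniform(0.05, 1.0))
        model = ShiftModel((lam,), (0.0,), (), 1.0)
        assert bd_shift_loglik(bt, model) == pytest.approx(
            yule_loglik_closed_form(times, lam), abs=1e-8
        )

    def test_two_identical_epochs_equal_one(self):
        bt = _bt([12.0, 7.5, 6.1, 3.3, 0.9])
        one = ShiftModel((0.3,), (0.1,), (), 0.7)
        for shift in (2.0, 6.5, 11.0):
            two = ShiftModel((0.3, 0.3), (0.1, 0.1), (shift,), 0.7)
            assert bd_shift_loglik(bt, two) == pytest.approx(
                bd_shift_loglik(bt, one), abs=1e-10
            )

    @pytest.mark.parametrize(
        "lam,mu,rho", [(0.3, 0.12, 1.0), (0.25, 0.1, 0.6), (0.4, 0.25, 0.45)]
    )
    def test_three_tip_first_principles_oracle(self, lam, mu, rho):
        x1, x2 = 6.0, 2.5
        bt = _bt([x1, x2])
        mine = math.exp(bd_shift_loglik(bt, ShiftModel((lam,), (mu,), (), rho)))
        oracle = euler_reconstructed_density(x1, x2, lam, mu, rho)
        assert mine == pytest.approx(oracle, rel=1e-3)  # 3 significant figures

    def test_epoch_dependence(self):
        # a shift placed between branching events changes the density
        bt = _bt([12.0, 7.5, 6.1, 3.3, 0.9])
        a = bd_shift_loglik(bt, ShiftModel((0.1, 0.4), (0, 0), (5.0,), 1.0))
        b = bd_shift_loglik(bt, ShiftModel((0.4, 0.1), (0, 0), (5.0,), 1.0))
        assert a != pytest.approx(b)


class TestFitConstant:
    def test_consistency_yule(self):
        # median lambda-hat over 200 replicates of n=200 at lam=0.2
        rng = np.random.default_rng(77)
        bts = yule_branching_times(200, 0.2, 200, rng)
        ests = []
        for row in bts:
            fit = fit_constant(_bt(np.sort(row)[::-1], 200))
            ests.append(fit.model.lambdas[0])
        assert 0.18 <= float(np.median(ests)) <= 0.22

    def test_relabeling_invariance(self):
        a = parse_newick("((a:4,b:4):6,(c:8,d:8):2);")
        b = parse_newick("((d:4,c:4):6,(b:8,a:8):2);")
        fa = fit_constant(branching_times(a))
        fb = fit_constant(branching_times(b))
        assert fa.loglik == pytest.approx(fb.loglik)

    def test_free_param_counts(self, yule_factory):
        bt = branching_times(yule_factory(12))
        assert fit_constant(bt, process="yule").n_free_params == 1
        assert fit_constant(bt, process="birthdeath").n_free_params == 2

    def test_closed_form_matches_numeric(self, yule_factory):
        bt = branching_times(yule_factory(20))
        cf = fit_constant(bt, 1.0, "yule")
        model, ll, _ = sf._optimize_rates(bt, 1.0, (), "yule")
        assert cf.loglik == pytest.approx(ll, abs=1e-6)
        assert cf.model.lambdas[0] == pytest.approx(model.lambdas[0], rel=1e-4)

    def test_rho_sanity_lambda_increases(self):
        # incomplete sampling masks early divergences: lambda-hat at rho<1
        # is at least the complete-sampling estimate on the same data
        for seed in range(10):
            bt = branching_times(simulate_yule(30, 0.2, seed))
            l_full = fit_constant(bt, 1.0).model.lambdas[0]
            l_part = fit_constant(bt, 0.45).model.lambdas[0]
            assert l_part >= l_full - 1e-9


class TestFitKShifts:
    def test_nested_never_worse(self):
        for seed in range(8):
            bt = branching_times(simulate_yule(25, 0.3, seed))
            f0 = fit_constant(bt)
            f1 = fit_k_shifts(bt, k=1, grid_step=0.2)
            assert f1.loglik >= f0.loglik - 1e-9

    def test_nested_never_worse_numeric_path(self):
        bt = branching_times(simulate_yule(18, 0.3, seed=5))
        f0 = fit_constant(bt, rho=0.5)
        f1 = fit_k_shifts(bt, rho=0.5, k=1, grid_step=2.0)
        assert f1.loglik >= f0.loglik - 1e-6

    def test_recovery_small(self):
        # reduced version of the acceptance recovery study
        spec = SimulationSpec(200, (0.03, 0.32), (0.0, 0.0), (10.0,))
        ests = []
        for s in np.random.SeedSequence(5).spawn(20):
            tree = simulate_piecewise(spec, seed=np.random.default_rng(s))
            fit = fit_k_shifts(branching_times(tree), k=1, grid_step=0.1)
            ests.append(fit.model.shift_times[0])
        assert abs(float(np.median(ests)) - 10.0) <= 1.0

    def test_tie_break_prefers_oldest(self, yule_factory, monkeypatch):
        # force an exact tie at every grid point: the oldest must win
        bt = branching_times(yule_factory(15))
        monkeypatch.setattr(
            sf, "_yule_segment_loglik", lambda B, A: np.zeros_like(np.asarray(B, float))
        )
        grid = sf.shift_time_grid(bt, 0.5)
        model, _ = sf._fit_shifts_yule_complete(bt, grid, 1)
        assert model.shift_times[0] == pytest.approx(float(grid[-1]))

    def test_grid_margin(self, yule_factory):
        bt = branching_times(yule_factory(15))
        grid = sf.shift_time_grid(bt, 0.1)
        t_asc = np.sort(bt.times)
        assert grid.min() > t_asc[1]
        assert grid.max() < t_asc[-2]

    def test_no_admissible_grid(self):
        bt = _bt([10.0, 9.0, 1.0])
        with pytest.raises(ValueError):
            fit_k_shifts(bt, k=1, grid_step=20.0)

    def test_k2_runs(self, yule_factory):
        bt = branching_times(yule_factory(20, lam=0.4, seed=9))
        f1 = fit_k_shifts(bt, k=1, grid_step=1.0)
        f2 = fit_k_shifts(bt, k=2, grid_step=1.0)
        assert f2.loglik >= f1.loglik - 1e-9
        assert f2.n_free_params == 5
        assert len(f2.model.shift_times) == 2

    def test_power_directional_rho045(self):
        # 51 tips pruned to 23, rho = 0.45: rejections under the shifted
        # scenario exceed rejections under matched constant-rate nulls
        shifted = SimulationSpec(51, (0.03, 0.32), (0.0, 0.0), (10.0,))
        null = SimulationSpec(51, (0.166,), (0.0,), ())

        def rejections(spec, root_seed, reps=15):
            rej = 0
            for s in np.random.SeedSequence(root_seed).spawn(reps):
                rng = np.random.default_rng(s)
                tree = prune_random_tips(simulate_piecewise(spec, rng), 28, rng)
                bt = branching_times(tree)
                f0 = fit_constant(bt, 0.45)
                f1 = fit_k_shifts(bt, 0.45, 1, grid_step=2.0)
                rej += lrt(f0, f1).p_value < 0.05
            return rej

        assert rejections(shifted, 21) > rejections(null, 22)


class TestLRT:
    def _fit(self, ll, k):
        model = ShiftModel(
            (0.2,) * (k + 1), (0.0,) * (k + 1), tuple(range(1, k + 1)), 1.0
        )
        return FitResult(model, ll, sf._n_free(k + 1, "yule"), True)

    def test_paper_like_pair(self):
        res = lrt(self._fit(-100.0, 0), self._fit(-97.3, 1))
        assert res.chi2 == pytest.approx(5.4)
        assert res.df == 2
        assert res.p_value == pytest.approx(math.exp(-2.7), rel=1e-6)
        assert res.p_value == pytest.approx(0.067, abs=5e-4)

    def test_identical_fits(self):
        res = lrt(self._fit(-50.0, 0), self._fit(-50.0, 1))
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    @given(
        c1=st.floats(min_value=0, max_value=40),
        c2=st.floats(min_value=0, max_value=40),
    )
    @settings(max_examples=50, deadline=None)
    def test_p_decreasing_in_chi2(self, c1, c2):
        lo, hi = sorted((c1, c2))
        p_lo = lrt(self._fit(-50.0, 0), self._fit(-50.0 + lo / 2, 1)).p_value
        p_hi = lrt(self._fit(-50.0, 0), self._fit(-50.0 + hi / 2, 1)).p_value
        if hi > lo + 1e-9:
            assert p_hi < p_lo

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._fit(-50.0, 1), self._fit(-49.0, 0))

    def test_worse_alternative_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._fit(-50.0, 0), self._fit(-51.0, 1))
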