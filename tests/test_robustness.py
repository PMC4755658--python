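"""Rank-correlation curves and through-origin robustness slopes."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fdrobust as fr
from fdrobust.errors import DegenerateInputError


def brute_spearman(x, y):
    """Average-rank oracle: Pearson correlation of hand-built rank vectors."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def permutation_with_rank_distance(n: int, target_sum_d2: float):
    """Permutation of 0..n-1 whose squared rank displacement sum approximates
    ``target_sum_d2`` (greedy disjoint swaps; a swap at offset o adds 2 o^2).

    Returns (permutation, achieved sum of squared displacements).
    """
    perm = list(range(n))
    used = [False] * n
    remaining = target_sum_d2
    for i in range(n):
        if used[i] or remaining < 2:
            continue
        o = int(math.floor(math.sqrt(remaining / 2)))
        while o >= 1:
            j = i + o
            if j < n and not used[j]:
                perm[i], perm[j] = perm[j], perm[i]
                used[i] = used[j] = True
                remaining -= 2 * o * o
                break
            o -= 1
    return perm, target_sum_d2 - remaining


class TestSpearman:
    def test_identical_and_reversed_orderings(self):
        x = [3.0, 1.0, 7.0, 5.0]
        assert fr.spearman(x, x) == pytest.approx(1.0)
        assert fr.spearman(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        assert fr.spearman(x, y) == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            x = rng.integers(0, 6, n).astype(float)  # many ties
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert fr.spearman(x, y) == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.raises(DegenerateInputError):
            fr.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRobustnessCurve:
    def make_inputs(self, n_plots=10, n_steps=5):
        full = pd.Series(np.arange(n_plots, dtype=float),
                         index=[f"p{i}" for i in range(n_plots)])
        stepped = pd.DataFrame([full.to_numpy()] * (n_steps + 1),
                               columns=full.index)
        remaining = 1.0 - 0.05 * np.arange(n_steps + 1)
        return full, stepped, remaining

    def test_identical_values_give_unit_correlations(self):
        full, stepped, remaining = self.make_inputs()
        curve = fr.robustness_curve(full, stepped, remaining)
        np.testing.assert_allclose(curve.rho, 1.0)
        assert curve.remaining[0] == 1.0

    def test_single_adjacent_transposition_hand_value(self):
        full, stepped, remaining = self.make_inputs(n_plots=10)
        swapped = stepped.iloc[2].copy()
        swapped[["p0", "p1"]] = swapped[["p1", "p0"]].to_numpy()
        stepped.iloc[2] = swapped
        curve = fr.robustness_curve(full, stepped, remaining)
        # one adjacent swap among 10: rho = 1 - 6*2 / (10*99)
        assert curve.rho[2] == pytest.approx(1.0 - 12.0 / 990.0, abs=1e-12)

    def test_not_computable_plot_excluded_pairwise(self):
        full, stepped, remaining = self.make_inputs(n_plots=6)
        stepped.iloc[3, stepped.columns.get_loc("p2")] = np.nan
        curve = fr.robustness_curve(full, stepped, remaining)
        assert curve.n_plots[3] == 5
        assert curve.rho[3] == pytest.approx(1.0)

    def test_below_min_plots_leaves_step_undefined(self):
        full, stepped, remaining = self.make_inputs(n_plots=4)
        stepped.iloc[1, :2] = np.nan
        curve = fr.robustness_curve(full, stepped, remaining)
        assert np.isnan(curve.rho[1]) and curve.n_plots[1] == 2

    def test_unusable_everywhere_raises(self):
        full, stepped, remaining = self.make_inputs(n_plots=4)
        stepped.iloc[:, :2] = np.nan
        with pytest.raises(DegenerateInputError, match="unusable"):
            fr.robustness_curve(full, stepped, remaining)


class TestFitSlope:
    def curve(self, remaining, rho, label="c"):
        return fr.RobustnessCurve(label, np.asarray(remaining, float),
                                  np.asarray(rho, float),
                                  np.full(len(remaining), 10))

    def test_perfect_correlations_give_zero_slope(self):
        a = np.linspace(1.0, 0.5, 11)
        slope = fr.fit_slope(self.curve(a, np.ones_like(a)))
        assert slope.slope == pytest.approx(0.0, abs=1e-15)

    def test_exact_exponential_recovered_exactly(self):
        a = np.linspace(1.0, 0.5, 11)
        rho = np.exp(-2.0 * (1.0 - a))
        slope = fr.fit_slope(self.curve(a, rho))
        assert slope.slope == pytest.approx(2.0, abs=1e-12)

    def test_nonpositive_rho_excluded_and_counted(self):
        a = np.array([1.0, 0.9, 0.8, 0.7])
        rho = np.array([1.0, 0.8, -0.1, 0.6])
        slope = fr.fit_slope(self.curve(a, rho))
        assert slope.n_excluded_nonpositive == 1
        assert slope.n_steps == 3

    def test_step_density_invariance_on_exact_curve(self):
        beta = 1.7
        coarse = np.linspace(1.0, 0.5, 6)
        fine = np.linspace(1.0, 0.5, 51)
        s1 = fr.fit_slope(self.curve(coarse, np.exp(-beta * (1 - coarse))))
        s2 = fr.fit_slope(self.curve(fine, np.exp(-beta * (1 - fine))))
        assert s1.slope == pytest.approx(s2.slope, abs=1e-12)

    def test_known_decay_rates_recovered_and_ordered(self):
        a = np.linspace(1.0, 0.5, 21)
        s_slow = fr.fit_slope(self.curve(a, np.exp(-0.5 * (1 - a))))
        s_fast = fr.fit_slope(self.curve(a, np.exp(-3.0 * (1 - a))))
        assert s_slow.slope == pytest.approx(0.5, abs=1e-12)
        assert s_fast.slope == pytest.approx(3.0, abs=1e-12)
        assert s_fast.slope > s_slow.slope  # larger rate = faster rank loss

    def test_too_few_usable_steps_raises(self):
        with pytest.raises(DegenerateInputError):
            fr.fit_slope(self.curve([1.0], [1.0]))


class TestEndToEndRateRecovery:
    def test_constructed_rank_decay_rate_recovered(self):
        """Index rankings built to lose rank agreement at a known exponential
        rate must yield that rate back from curve + slope fitting."""
        rate = 2.0
        n = 200
        steps = np.arange(0, 11)
        remaining = 1.0 - 0.05 * steps
        full = pd.Series(np.arange(n, dtype=float),
                         index=[f"p{i}" for i in range(n)])
        rows = [full.to_numpy()]
        max_d2 = n * (n * n - 1) / 6.0
        for a in remaining[1:]:
            target_rho = math.exp(-rate * (1.0 - a))
            perm, achieved = permutation_with_rank_distance(
                n, (1.0 - target_rho) * max_d2
            )
            assert abs(achieved - (1.0 - target_rho) * max_d2) < 4
            rows.append(np.array(perm, dtype=float))
        stepped = pd.DataFrame(rows, columns=full.index)
        curve = fr.robustness_curve(full, stepped, remaining)
        slope = fr.fit_slope(curve)
        assert slope.slope == pytest.approx(rate, rel=0.05)

    def test_two_decay_rates_order_correctly_through_the_pipeline(self):
        n = 150
        remaining = 1.0 - 0.1 * np.arange(0, 6)
        full = pd.Series(np.arange(n, dtype=float),
                         index=[f"p{i}" for i in range(n)])
        max_d2 = n * (n * n - 1) / 6.0
        slopes = []
        for rate in (0.5, 3.0):
            rows = [full.to_numpy()]
            for a in remaining[1:]:
                rho = math.exp(-rate * (1 - a))
                perm, _ = permutation_with_rank_distance(n, (1 - rho) * max_d2)
                rows.append(np.array(perm, dtype=float))
            stepped = pd.DataFrame(rows, columns=full.index)
            slopes.append(fr.fit_slope(fr.robustness_curve(full, stepped, remaining)).slope)
        assert slopes[0] < slopes[1]  # fitted rates preserve the true ordering


def test_spearman_agrees_with_scipy_on_clean_data():
    rng = np.random.default_rng(99)
    x, y = rng.random(30), rng.random(30)
    assert fr.spearman(x, y) == pytest.approx(stats.spearmanr(x, y).statistic)
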