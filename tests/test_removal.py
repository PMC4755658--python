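"""Rarest-first fractional removal schedules, plot-wise and pool-wise."""

import numpy as np
import pandas as pd
import pytest

import fdrobust as fr


def make_cm(rows, plots=None, species=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    plots = plots or [f"p{i+1}" for i in range(rows.shape[0])]
    species = species or [f"s{i+1:02d}" for i in range(rows.shape[1])]
    return fr.CommunityMatrix(pd.DataFrame(rows, index=plots, columns=species))


class TestWorkedExample:
    """Ten-species walkthrough with two-decimal relative abundances, 5% steps."""

    @pytest.fixture
    def schedule(self, worked_cm):
        return fr.removal_schedule_plotwise(worked_cm, step_size=0.05, floor=0.5,
                                            round_digits=2)

    def test_first_step_removes_three_rarest_plus_a_hundredth_of_the_fourth(self, schedule):
        amounts = schedule.removed_amount(1)[0]
        assert schedule.n_fully_removed(1)[0] == 3
        assert amounts[3] == pytest.approx(0.01, abs=1e-12)
        assert amounts[:3].sum() == pytest.approx(0.04, abs=1e-12)
        assert amounts[4:].sum() == 0.0

    def test_second_step_finishes_fourth_takes_fifth_and_part_of_sixth(self, schedule):
        delta = schedule.removed_amount(2)[0] - schedule.removed_amount(1)[0]
        assert delta[3] == pytest.approx(0.01, abs=1e-12)  # rest of the 4th
        assert delta[4] == pytest.approx(0.02, abs=1e-12)  # whole 5th
        assert delta[5] == pytest.approx(0.02, abs=1e-12)  # part of the 6th
        assert schedule.fractions[2, 0, 3] == pytest.approx(1.0)
        assert schedule.fractions[2, 0, 5] == pytest.approx(0.5)

    def test_dominant_relative_abundance(self, worked_abundances):
        p = fr.round_relative(fr.relative_abundances(worked_abundances))
        assert p[-1] == pytest.approx(0.54)


class TestPlotwiseContract:
    def test_ten_steps_to_the_half_abundance_floor(self, worked_cm):
        schedule = fr.removal_schedule_plotwise(worked_cm, step_size=0.05, floor=0.5)
        assert schedule.n_steps == 10
        assert schedule.remaining_share(10)[0] == pytest.approx(0.5, abs=1e-12)

    def test_conservation_and_monotone_decline(self):
        rng = np.random.default_rng(4)
        cm = make_cm(rng.lognormal(1, 1.5, (3, 25)))
        schedule = fr.removal_schedule_plotwise(cm, step_size=0.05, floor=0.5)
        for s in range(schedule.n_steps + 1):
            removed = schedule.removed_amount(s).sum(axis=1)
            remaining = schedule.remaining_total(s)
            np.testing.assert_allclose(removed + remaining,
                                       schedule.relative.sum(axis=1), atol=1e-12)
            if s >= 1:
                expected = 1.0 - min(s * 0.05, 0.5)
                np.testing.assert_allclose(schedule.remaining_share(s), expected,
                                           atol=1e-12)

    def test_cumulative_fractions_never_decrease(self):
        rng = np.random.default_rng(8)
        cm = make_cm(rng.lognormal(0, 2, (2, 30)))
        schedule = fr.removal_schedule_plotwise(cm)
        diffs = np.diff(schedule.fractions, axis=0)
        assert (diffs >= -1e-12).all()

    def test_strictly_rarer_species_removed_first(self):
        rng = np.random.default_rng(15)
        cm = make_cm(rng.lognormal(0, 1.5, (1, 20)))
        schedule = fr.removal_schedule_plotwise(cm, step_size=0.02)
        p = schedule.relative[0]
        for s in range(1, schedule.n_steps + 1):
            f = schedule.fractions[s, 0]
            for i in range(20):
                if 0 < f[i] < 1:  # a species under way: all strictly rarer done
                    strictly_rarer = (p < p[i]) & (p > 0)
                    assert np.allclose(f[strictly_rarer], 1.0)

    def test_abundance_ties_broken_by_species_id(self):
        cm = make_cm([[2.0, 2.0, 6.0]], species=["b", "a", "c"])
        schedule = fr.removal_schedule_plotwise(cm, step_size=0.2, floor=0.5)
        # 'a' (p = 0.2) must be consumed before 'b' despite the tie
        assert schedule.fractions[1, 0, 1] == pytest.approx(1.0)
        assert schedule.fractions[1, 0, 0] == pytest.approx(0.0)


class TestPoolwise:
    def test_single_plot_equals_plotwise_exactly(self, worked_cm):
        plot = fr.removal_schedule_plotwise(worked_cm, step_size=0.05, floor=0.5)
        pool = fr.removal_schedule_poolwise(worked_cm, step_size=0.05, floor=0.5)
        assert np.array_equal(plot.fractions, pool.fractions)
        assert np.array_equal(plot.relative, pool.relative)

    def test_plot_without_the_removed_species_is_unaffected(self):
        # pool ranking removes s1 (pool abundance 1) first; plot p2 lacks s1
        cm = make_cm([[1.0, 9.0, 90.0], [0.0, 10.0, 90.0]])
        schedule = fr.removal_schedule_poolwise(cm, step_size=0.005, floor=0.5)
        assert schedule.remaining_share(1)[1] == pytest.approx(1.0)
        assert schedule.remaining_share(1)[0] < 1.0

    def test_disjoint_plots_decline_only_on_their_own_species(self):
        cm = make_cm([[1.0, 5.0, 0.0, 0.0], [0.0, 0.0, 2.0, 10.0]])
        schedule = fr.removal_schedule_poolwise(cm, step_size=0.05, floor=0.5)
        share = np.array([schedule.remaining_share(s) for s in range(schedule.n_steps + 1)])
        # pool order: s1 (1/18), s3 (2/18), s2 (5/18), s4 (10/18)
        # while s1 is being consumed only plot 1 declines
        assert share[1, 1] == pytest.approx(1.0)
        assert share[1, 0] < 1.0
        # once removal reaches s3, plot 2 starts declining
        declining = np.nonzero(share[:, 1] < 1.0)[0]
        assert len(declining) > 0


class TestApplyStep:
    def test_step_zero_is_the_full_plot(self, worked_cm):
        schedule = fr.removal_schedule_plotwise(worked_cm, step_size=0.05)
        ids, weights = fr.apply_step(schedule, 0, "plot1")
        assert ids == worked_cm.species_ids
        np.testing.assert_allclose(weights, schedule.relative[0], atol=1e-12)

    def test_partial_species_weighted_or_dropped(self, worked_cm):
        schedule = fr.removal_schedule_plotwise(worked_cm, step_size=0.05,
                                                round_digits=2)
        ids_w, w = fr.apply_step(schedule, 1, "plot1", partial="weight")
        assert "s04" in ids_w  # half-removed species retained at reduced weight
        i = ids_w.index("s04")
        # s04 keeps 0.01 of 0.02; rounded proportions sum to 0.99, so the
        # surviving total after one 0.05 step is 0.94
        assert w[i] == pytest.approx(0.01 / 0.94, abs=1e-9)
        ids_d, _ = fr.apply_step(schedule, 1, "plot1", partial="drop")
        assert "s04" not in ids_d
        assert set(ids_d) == {"s05", "s06", "s07", "s08", "s09", "s10"}

    def test_weights_renormalised(self, worked_cm):
        schedule = fr.removal_schedule_plotwise(worked_cm, step_size=0.05)
        for s in range(schedule.n_steps + 1):
            _, w = fr.apply_step(schedule, s, "plot1")
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_fully_removed_species_no_longer_affect_gower_ranges(self, worked_cm):
        # after removal, distances must equal those of an independently built
        # dataset containing only the survivors
        traits = fr.TraitTable(
            pd.DataFrame({"h": np.arange(10, dtype=float) ** 2},
                         index=worked_cm.species_ids),
            {"h": "continuous"},
        )
        schedule = fr.removal_schedule_plotwise(worked_cm, step_size=0.05,
                                                round_digits=2)
        ids, _ = fr.apply_step(schedule, 3, "plot1", partial="drop")
        d_reduced = fr.gower(traits, species=ids)
        independent = fr.TraitTable(traits.data.loc[ids].copy(), dict(traits.types))
        d_independent = fr.gower(independent)
        np.testing.assert_allclose(d_reduced.values, d_independent.values, atol=1e-12)


class TestTransformedSchedules:
    def test_log_transform_removes_fewer_species_on_skewed_data(self):
        rng = np.random.default_rng(33)
        cm = make_cm(rng.lognormal(0.0, 2.0, (1, 120)))
        raw = fr.removal_schedule_plotwise(cm, step_size=0.005, floor=0.5)
        logged = fr.removal_schedule_plotwise(
            cm, step_size=0.005, floor=0.5, abundance_transform="log_plus_one"
        )
        step_at_80 = round(0.2 / 0.005)
        assert (logged.n_fully_removed(step_at_80)[0]
                < raw.n_fully_removed(step_at_80)[0])

    def test_ranking_follows_transformed_abundances(self):
        # the transform is monotone, so the removal order itself is unchanged;
        # what changes is how much of each step a rare species consumes
        cm = make_cm([[1.0, 10.0, 100.0]])
        raw = fr.removal_schedule_plotwise(cm, step_size=0.05, floor=0.5)
        logged = fr.removal_schedule_plotwise(cm, step_size=0.05, floor=0.5,
                                              abundance_transform="log_plus_one")
        assert logged.relative[0, 0] > raw.relative[0, 0]
        assert logged.fractions[1, 0, 0] < raw.fractions[1, 0, 0]


def test_schedule_long_export_round_trips(tmp_path, worked_cm):
    schedule = fr.removal_schedule_plotwise(worked_cm, step_size=0.05)
    frame = schedule.to_frame()
    assert set(frame.columns) == {"step", "plot", "species",
                                  "cumulative_removed_fraction", "remaining_total"}
    assert frame.step.max() == schedule.n_steps
    frame.to_csv(tmp_path / "schedule.csv", index=False)
    back = pd.read_csv(tmp_path / "schedule.csv")
    assert len(back) == len(frame)
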