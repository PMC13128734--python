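import numpy as np
import pandas as pd
import pytest

from centroidlex.evaluation import (
    SweepConfig,
    individual_first_m_curve,
    loess_fit,
    participant_rank_summary,
    remove_count_outliers,
    response_count_curve,
    run_sweep,
)
from centroidlex.responses import aggregate
from centroidlex.synthetic import SyntheticConfig, make_world


class TestRemoveCountOutliers:
    def test_matches_direct_z_computation(self):
        # oracle on {10,11,12,13,1000}: mean 209.2, sample SD 442.07, so
        # z(1000)=1.789 -- below 4 SD nothing is removed; at 1.5 SD it is
        counts = np.array([10.0, 11.0, 12.0, 13.0, 1000.0])
        vals = np.arange(5.0)
        z = (counts - counts.mean()) / counts.std(ddof=1)
        assert np.abs(z).max() == pytest.approx(1.7888, abs=1e-3)
        c4, _, keep4 = remove_count_outliers(counts, vals, threshold_sd=4.0)
        assert keep4.all() and len(c4) == 5
        c15, v15, _ = remove_count_outliers(counts, vals, threshold_sd=1.5)
        assert list(c15) == [10, 11, 12, 13] and list(v15) == [0, 1, 2, 3]

    def test_planted_extreme_outlier_removed_at_4sd(self):
        # 40 tight points + one extreme: |z| of the outlier exceeds 4
        counts = np.concatenate([np.linspace(10, 12, 40), [10000.0]])
        vals = np.zeros(41)
        kept, _, keep = remove_count_outliers(counts, vals, threshold_sd=4.0)
        assert keep.sum() == 40 and 10000.0 not in kept

    def test_zero_sd_and_tiny_input_unchanged(self):
        c, v, keep = remove_count_outliers([5.0, 5.0, 5.0], [1, 2, 3])
        assert keep.all()
        c, v, keep = remove_count_outliers([5.0], [1])
        assert keep.all()

    def test_below_threshold_untouched(self):
        rng = np.random.default_rng(3)
        counts = rng.normal(100, 10, size=50)  # max |z| ~ 3 for n=50
        _, _, keep = remove_count_outliers(counts, np.zeros(50), threshold_sd=4.0)
        z = (counts - counts.mean()) / counts.std(ddof=1)
        assert (keep == (np.abs(z) < 4.0)).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        counts = np.concatenate([rng.normal(10, 1, 30), [500.0]])
        vals = np.arange(31.0)
        perm = rng.permutation(31)
        c1, v1, _ = remove_count_outliers(counts, vals, threshold_sd=4.0)
        c2, v2, _ = remove_count_outliers(counts[perm], vals[perm], threshold_sd=4.0)
        assert sorted(zip(c1, v1)) == sorted(zip(c2, v2))


class TestLoess:
    def test_reproduces_line_exactly_both_families(self):
        x = np.linspace(0, 10, 60)
        y = 2 * x + 1
        for family in ("gaussian", "symmetric"):
            fit = loess_fit(x, y, family=family)
            np.testing.assert_allclose(fit["y_fit"], 2 * fit["x"] + 1, atol=1e-6)

    def test_constant_y_gives_constant_fit(self):
        x = np.linspace(0, 5, 30)
        fit = loess_fit(x, np.full(30, 7.0))
        np.testing.assert_allclose(fit["y_fit"], 7.0, atol=1e-9)

    def test_symmetric_family_resists_gross_outlier(self):
        x = np.linspace(0, 10, 50)
        y = 2 * x + 1
        y_out = y.copy()
        y_out[-1] += 500.0  # gross y-outlier at the far end
        robust = loess_fit(x, y_out, family="symmetric")
        naive = loess_fit(x, y_out, family="gaussian")
        true_end = 2 * robust["x"].iloc[-5] + 1
        assert abs(robust["y_fit"].iloc[-5] - true_end) < 0.05
        assert abs(naive["y_fit"].iloc[-5] - true_end) > 1.0  # visibly displaced

    def test_cross_check_against_statsmodels_lowess(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 10, 80))
        y = np.sin(x) + rng.normal(0, 0.05, 80)
        ours = loess_fit(x, y, span=0.4, family="gaussian", grid=x)
        ref = lowess(y, x, frac=0.4, it=0, return_sorted=True)
        np.testing.assert_allclose(ours["y_fit"], ref[:, 1], atol=0.05)

    def test_insufficient_points_error(self):
        with pytest.raises(ValueError):
            loess_fit([1.0, 2.0], [1.0, 2.0])

    def test_degenerate_window_local_mean(self):
        x = np.array([1.0, 1.0, 1.0, 5.0, 5.0, 5.0])
        y = np.array([2.0, 4.0, 3.0, 10.0, 10.0, 10.0])
        fit = loess_fit(x, y, span=0.5, family="gaussian", grid=np.array([1.0]))
        assert fit["y_fit"].iloc[0] == pytest.approx(3.0)


class TestResponseCountCurve:
    def _table(self, counts, ranks):
        return pd.DataFrame(
            {"n_unique": counts, "n_total": counts * 3, "rank": ranks}
        )

    def test_plateau_near_closed_form_crossing(self):
        counts = np.arange(5, 100, dtype=float)
        ranks = np.maximum(1.0, 50.0 - counts)  # crosses rank 3 at count 47
        # a span local enough to resolve the kink (wide windows average the
        # descending and flat arms and shift the apparent crossing right)
        curve, plateaus = response_count_curve(
            self._table(counts, ranks), "unique", thresholds=(3,), span=0.3
        )
        step = plateaus["grid_step"]
        assert plateaus["thresholds"]["3"] == pytest.approx(47.0, abs=2 * step)

    def test_plateau_counts_monotone_in_threshold(self):
        counts = np.arange(5, 100, dtype=float)
        ranks = np.maximum(1.0, 50.0 - counts)
        _, plateaus = response_count_curve(
            self._table(counts, ranks), "unique", thresholds=(3, 5, 18), span=0.3
        )
        t = plateaus["thresholds"]
        assert t["18"] <= t["5"] <= t["3"]  # smaller threshold needs more data

    def test_no_crossing_reports_not_reached(self):
        counts = np.arange(5, 50, dtype=float)
        ranks = np.full_like(counts, 100.0)
        _, plateaus = response_count_curve(
            self._table(counts, ranks), "unique", thresholds=(3,)
        )
        assert plateaus["thresholds"]["3"] is None


class TestParticipantRankSummary:
    def test_worked_example(self):
        table = pd.DataFrame(
            {"participant": ["p1"] * 3, "rank": [1, 2, 3]}
        )
        per, summary = participant_rank_summary(table)
        assert per["mean_rank"].iloc[0] == 2 and per["median_rank"].iloc[0] == 2
        assert (summary["mean_rank"] == 2).all()

    def test_matches_naive_groupby_oracle(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {
                "participant": [f"p{i % 7}" for i in range(200)],
                "rank": rng.integers(1, 1000, size=200),
            }
        )
        per, _ = participant_rank_summary(table)
        for p in per["participant"]:
            vals = [
                r for pp, r in zip(table["participant"], table["rank"]) if pp == p
            ]
            row = per[per["participant"] == p].iloc[0]
            assert row["mean_rank"] == pytest.approx(float(np.mean(vals)))
            assert row["median_rank"] == pytest.approx(float(np.median(vals)))

    def test_group_level_table_rejected(self):
        with pytest.raises(ValueError):
            participant_rank_summary(pd.DataFrame({"rank": [1, 2]}))


class TestRunSweep:
    @pytest.fixture
    def world_and_sets(self):
        world = make_world(SyntheticConfig(vocab_size=300, dim=16, n_targets=30, seed=13))
        return world, aggregate(world.records, "group")

    def test_shape_and_determinism(self, world_and_sets):
        world, sets = world_and_sets
        cfg = SweepConfig(
            spaces={"synth": (world.space, "exact")},
            weightings=("token",),
            lexicon_sizes=(100, 300),
            k_max=20,
        )
        df1, tables1 = run_sweep(sets, cfg)
        df2, _ = run_sweep(sets, cfg)
        assert len(df1) == 2 * 20  # N x k rows for one space x weighting
        assert df1.to_csv() == df2.to_csv()

    def test_hit_cells_consistent_with_rank_tables(self, world_and_sets):
        world, sets = world_and_sets
        cfg = SweepConfig(
            spaces={"synth": (world.space, "exact")},
            weightings=("type", "token"),
            lexicon_sizes=(100, 300),
        )
        df, tables = run_sweep(sets, cfg)
        for row in df.sample(20, random_state=0).itertuples():
            ranks = tables[f"{row.space}_{row.weighting}"]
            sub = ranks[ranks["N"] == row.N]["rank"]
            assert row.hit_at_k == pytest.approx((sub <= row.k).mean())

    def test_invalid_lexicon_size_rejected(self, world_and_sets):
        world, _ = world_and_sets
        with pytest.raises(ValueError):
            SweepConfig(spaces={"s": (world.space, "exact")}, lexicon_sizes=(10**6,))


class TestIndividualFirstM:
    @pytest.fixture
    def world(self):
        return make_world(
            SyntheticConfig(
                vocab_size=400, dim=30, n_targets=15, responses_per_target=6,
                n_participants=15, noise_sd=0.2, seed=17,
            ),
            level="individual",
        )

    def test_m1_equals_single_response_centroid_ranks(self, world):
        df = individual_first_m_curve(
            world.records, world.space, m_max=2, k_max=5, lexicon_size=400
        )
        from centroidlex.centroid import centroid_batch
        from centroidlex.embeddings import make_vectorizer
        from centroidlex.ranking import hit_curve, rank_batch

        first = [r for r in world.records if r.position <= 1]
        sets = aggregate(first, "individual")
        cents = centroid_batch(sets, make_vectorizer(world.space), "token")
        excl = {(s.target, s.participant): set(s.items) for s in sets}
        table = rank_batch(cents, world.space, [400], excl)
        expected = hit_curve(table["rank"].to_numpy(), 5)
        got = df[df["m"] == 1].set_index("k")["hit_at_k"]
        for k in range(1, 6):
            assert got.loc[k] == pytest.approx(expected.fractions[k])

    def test_low_noise_hit1_improves_with_m(self):
        world = make_world(
            SyntheticConfig(
                vocab_size=500, dim=40, n_targets=15, responses_per_target=8,
                n_participants=15, noise_sd=0.05, seed=19,
            ),
            level="individual",
        )
        df = individual_first_m_curve(
            world.records, world.space, m_max=8, lexicon_size=500, k_max=1
        )
        hit1 = df[df["k"] == 1].sort_values("m")["hit_at_k"].to_numpy()
        assert df[df["k"] == 1]["n_pairs"].iloc[0] >= 200
        # non-decreasing up to sampling error: allow dips <= 2 percentage points
        assert (np.diff(hit1) >= -0.02).all()

    def test_m_caps_at_available_responses(self, world):
        df = individual_first_m_curve(
            world.records, world.space, m_max=10, lexicon_size=400, k_max=1
        )
        n6 = df[(df["m"] == 6) & (df["k"] == 1)]["hit_at_k"].item()
        n10 = df[(df["m"] == 10) & (df["k"] == 1)]["hit_at_k"].item()
        assert n6 == n10  # only 6 responses exist per pair
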