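"""Combination typology, date matching, feature assembly and the grid."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from spectransfer import (
    CombinationSpec,
    DateMode,
    ExperimentParams,
    TransferExperiment,
    assemble_features,
    enumerate_combinations,
    match_dates,
    run_combination,
)
from spectransfer.transfer import classify_combination, identity_plan

from conftest import make_dates

SIX_TRIALS = ["HZ_20", "MR_20", "HZ_21", "MR_21", "HZ_22", "MR_22"]


class TestEnumeration:
    def test_six_trials_give_36_typed_combinations(self):
        specs = enumerate_combinations(SIX_TRIALS)
        assert len(specs) == 36
        counts = Counter(s.comb_type for s in specs)
        assert counts == {"WYWL": 6, "WYAL": 6, "AYWL": 12, "AYAL": 12}

    def test_two_trials_same_year(self):
        specs = enumerate_combinations(["HZ_20", "MR_20"])
        counts = Counter(s.comb_type for s in specs)
        assert counts == {"WYWL": 2, "WYAL": 2}

    def test_single_trial(self):
        specs = enumerate_combinations(["HZ_20"])
        assert len(specs) == 1 and specs[0].comb_type == "WYWL"

    @pytest.mark.parametrize(
        "a,b,expected",
        [("HZ_20", "HZ_20", "WYWL"), ("HZ_20", "MR_20", "WYAL"),
         ("HZ_20", "HZ_21", "AYWL"), ("HZ_20", "MR_21", "AYAL")],
    )
    def test_classification(self, a, b, expected):
        assert classify_combination(a, b) == expected

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_combinations(["HZ_20", "HZ_20"])


class TestDateMatching:
    def test_nearest_doy_example(self):
        # MR_20 early dates (1 Apr, 23 Apr) vs HZ_20 (26 Mar, 9 Apr):
        # DOY 92 is closer to 86 (delta 6) than to 100 (delta 8)
        plan = match_dates(make_dates([92, 114]), make_dates([86, 100]))
        assert [(p.train_date.doy, p.test_date.doy, p.delta_doy) for p in plan.pairs] \
            == [(92, 86, 6), (114, 100, 14)]

    def test_identity_matching(self):
        dates = make_dates([80, 100, 120], stages=[30, 65, 80])
        plan = match_dates(dates, dates)
        assert all(p.delta_doy == 0 for p in plan.pairs)
        assert plan.stage_labels() == ["30_30", "65_65", "80_80"]

    def test_contested_test_date_goes_to_closest_claimant(self):
        plan = match_dates(make_dates([100, 101]), make_dates([100]))
        assert len(plan) == 1
        assert plan.pairs[0].train_date.doy == 100

    def test_tie_goes_to_earlier_test_date(self):
        plan = match_dates(make_dates([100]), make_dates([98, 102]))
        assert plan.pairs[0].test_date.doy == 98

    def test_input_order_invariance(self):
        train = make_dates([130, 92, 114])
        test = make_dates([100, 86, 140])
        p1 = match_dates(train, test)
        p2 = match_dates(list(reversed(train)), list(reversed(test)))
        assert [(p.train_date.doy, p.test_date.doy) for p in p1.pairs] == \
               [(p.train_date.doy, p.test_date.doy) for p in p2.pairs]

    @pytest.mark.parametrize("seed", range(5))
    def test_nearest_neighbor_optimality_oracle(self, seed):
        rng = np.random.default_rng(seed)
        train = make_dates(sorted(rng.choice(np.arange(60, 220), 7, replace=False)))
        test = make_dates(sorted(rng.choice(np.arange(60, 220), 5, replace=False)))
        plan = match_dates(train, test)
        test_doys = [d.doy for d in test]
        used = [p.test_index for p in plan.pairs]
        assert len(used) == len(set(used))  # each test date at most once
        for p in plan.pairs:
            best = min(abs(p.train_date.doy - d) for d in test_doys)
            assert p.delta_doy == best

    def test_stage_label_na_for_missing_stage(self):
        plan = match_dates(make_dates([100], stages=[65]), make_dates([99]))
        assert plan.pairs[0].stage_label == "65_NA"

    def test_validation(self):
        with pytest.raises(ValueError, match="non-empty"):
            match_dates([], make_dates([100]))
        with pytest.raises(ValueError, match="duplicate"):
            match_dates(make_dates([100]) + make_dates([100]), make_dates([90]))


class TestFeatureAssembly:
    def test_column_counts_per_mode(self, small_campaign):
        a, b = small_campaign.values()
        plan = match_dates(a.dates, b.dates)
        assert len(plan) == 3
        for mode, expected in [
            (DateMode.individual(1), 23),
            (DateMode.increment(1), 46),
            (DateMode.all_times(), 69),
        ]:
            tr, te = assemble_features(a, b, plan, mode)
            assert tr.X.shape[1] == expected
            assert list(tr.X.columns) == list(te.X.columns)

    def test_increments_nest(self, small_campaign):
        a, b = small_campaign.values()
        plan = match_dates(a.dates, b.dates)
        tr1, _ = assemble_features(a, b, plan, DateMode.increment(1))
        tr_all, _ = assemble_features(a, b, plan, DateMode.all_times())
        assert set(tr1.X.columns) < set(tr_all.X.columns)

    def test_only_harvested_plots_kept(self, small_campaign):
        a, b = small_campaign.values()
        plan = identity_plan(a.dates)
        tr, _ = assemble_features(a, a, plan, DateMode.all_times())
        yt = a.yield_table.set_index("plot_id")
        assert yt.loc[tr.X.index, "harvested"].all()
        assert not tr.y.isna().any()

    def test_bad_mode_index(self, small_campaign):
        a, b = small_campaign.values()
        plan = match_dates(a.dates, b.dates)
        with pytest.raises(ValueError, match="out of range"):
            assemble_features(a, b, plan, DateMode.individual(7))
        with pytest.raises(ValueError, match="increment"):
            assemble_features(a, b, plan, DateMode.increment(2))


class TestRunCombination:
    def test_deterministic(self, small_campaign, relaxed_params):
        (a_id, _) = small_campaign.keys()
        spec = CombinationSpec(a_id, a_id, "WYWL", DateMode.all_times())
        r1 = run_combination(spec, small_campaign, relaxed_params)
        r2 = run_combination(spec, small_campaign, relaxed_params)
        assert r1 == r2

    def test_within_trial_split_sizes(self, small_campaign, relaxed_params):
        (a_id, _) = small_campaign.keys()
        spec = CombinationSpec(a_id, a_id, "WYWL", DateMode.individual(1))
        row = run_combination(spec, small_campaign, relaxed_params)
        n_harvested = int(small_campaign[a_id].yield_table["harvested"].sum())
        assert row["n_test"] == round(0.2 * n_harvested)
        assert row["n_train"] <= n_harvested - row["n_test"]

    def test_across_trial_uses_all_test_plots(self, small_campaign, relaxed_params):
        a_id, b_id = small_campaign.keys()
        spec = CombinationSpec(a_id, b_id, "WYAL", DateMode.all_times())
        row = run_combination(spec, small_campaign, relaxed_params)
        n_harvested_b = int(small_campaign[b_id].yield_table["harvested"].sum())
        assert row["n_test"] == n_harvested_b
        assert row["comb_type"] == "WYAL"

    def test_min_train_plots_enforced(self, small_campaign):
        (a_id, _) = small_campaign.keys()
        spec = CombinationSpec(a_id, a_id, "WYWL", DateMode.individual(0))
        with pytest.raises(ValueError, match="min_train_plots"):
            run_combination(spec, small_campaign, ExperimentParams(min_train_plots=5000))


@pytest.fixture(scope="module")
def results(small_campaign):
    params = ExperimentParams(min_train_plots=20)
    return TransferExperiment(small_campaign, params).run()


class TestExperimentGrid:
    def test_row_count(self, results):
        # 2 trials -> 4 combinations; 3 matched dates each ->
        # 3 individual + 1 increment + 1 all_times = 5 modes
        assert len(results.table) == 4 * 5
        assert results.table.groupby(["train_trial", "test_trial"]).ngroups == 4

    def test_result_schema(self, results):
        expected = {"train_trial", "test_trial", "comb_type", "date_mode",
                    "date_label", "stage_label", "n_train", "n_test", "n_latent",
                    "r2", "rmse", "rrmse_mean", "mae", "bias", "offset"}
        assert expected <= set(results.table.columns)
        assert set(results.table["date_mode"]) == {"individual", "increment",
                                                   "all_times"}

    def test_rerun_identical(self, small_campaign, results):
        params = ExperimentParams(min_train_plots=20)
        again = TransferExperiment(small_campaign, params).run()
        pd.testing.assert_frame_equal(results.table, again.table)

    def test_signal_peak_date_has_best_individual_r2(self, results):
        # generator signal peaks on the second of three dates; checked on the
        # across-trial cells whose test sets are large enough to be stable
        sub = results.table[(results.table["date_mode"] == "individual")
                            & (results.table["comb_type"] == "WYAL")]
        for (_, _), grp in sub.groupby(["train_trial", "test_trial"]):
            assert grp["r2"].to_numpy().argmax() == 1

    def test_all_times_close_to_best_individual(self, results):
        # pooling all dates should not lose accuracy vs. the best single date
        for (_, _), grp in results.table.groupby(["train_trial", "test_trial"]):
            best_ind = grp.loc[grp["date_mode"] == "individual", "r2"].max()
            all_times = grp.loc[grp["date_mode"] == "all_times", "r2"].iloc[0]
            assert all_times >= best_ind - 0.1

    def test_summary_text(self, results):
        text = results.summary()
        assert "models evaluated: 20" in text
        assert "WYWL" in text and "WYAL" in text

    def test_best_model_table_shape(self, results):
        best = results.best_model_table()
        assert len(best) == 4
        assert {"best_individual_r2", "best_multidate_r2", "r2_difference"} <= \
            set(best.columns)

    def test_csv_roundtrip(self, results, tmp_path):
        path = tmp_path / "results.csv"
        results.to_csv(path)
        back = pd.read_csv(path)
        assert len(back) == len(results.table)
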