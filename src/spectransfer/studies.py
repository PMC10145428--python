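"""Ground-truth validation studies on synthetic campaigns.

Because the pipeline's inputs are simulated with known structure, every
stage can be checked against the generating parameters: the seasonal
signal curve should reappear as the seasonal profile of individual-date
model R^2; an additive NDRE1 level shift between trials should leave the
rank-based R^2 untouched while inflating bias; combining dates with
independent noise should beat any single date; and with no signal at all,
test-set R^2 should collapse to sampling noise.  Each function here runs
one such study end to end and returns the measured quantities.

All randomness is derived from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .evaluate import compare_types
from .synthdata import TrialConfig, generate_trial
from .transfer import (
    CombinationSpec,
    DateMode,
    ExperimentParams,
    TransferExperiment,
    run_combination,
)

#: Seven-date seasonal signal with a unique mid-season peak.
PEAKED_SIGNAL = [0.20, 0.35, 0.50, 0.85, 0.50, 0.35, 0.20]
PEAK_INDEX = 3


def _seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence((int(seed), k)).generate_state(1, np.uint32)[0] % (2**31))


def _recovery_config(seed: int, n_rows: int, n_plots_per_row: int, **kw) -> TrialConfig:
    base = dict(
        location_code="HZ",
        year=2020,
        n_rows=n_rows,
        n_plots_per_row=n_plots_per_row,
        date_doys=[80, 95, 110, 125, 140, 155, 170],
        stage_by_date=[22, 27, 33, 65, 75, 80, 85],
        signal_curve=list(PEAKED_SIGNAL),
        seed=seed,
    )
    base.update(kw)
    return TrialConfig(**base)


def parameter_recovery_study(
    seed: int = 1, n_rows: int = 25, n_plots_per_row: int = 40
) -> dict:
    """Within-trial individual-date models on a peaked signal curve.

    One 1000-plot trial with rho_d peaking at 0.85 on the fourth of seven
    dates; each date's WYWL model (80/20 split) is fitted and evaluated.
    The R^2 profile should peak at the peak-signal date with a value close
    to rho_peak^2.
    """
    trial = generate_trial(_recovery_config(_seed(seed, 0), n_rows, n_plots_per_row))
    campaign = {trial.trial_id: trial}
    params = ExperimentParams(split_seed=seed, cv_seed=seed)
    r2 = []
    for k in range(len(trial.dates)):
        spec = CombinationSpec(
            trial.trial_id, trial.trial_id, "WYWL", DateMode.individual(k)
        )
        r2.append(run_combination(spec, campaign, params)["r2"])
    r2 = np.asarray(r2)
    return {
        "r2_by_date": r2,
        "peak_index": int(np.argmax(r2)),
        "expected_peak_index": PEAK_INDEX,
        "peak_r2": float(r2[PEAK_INDEX]),
        "rho_peak_sq": float(max(PEAKED_SIGNAL) ** 2),
        "n_plots": n_rows * n_plots_per_row,
    }


def offset_robustness_study(
    seed: int = 1,
    ndre_offset: float = 0.08,
    n_rows: int = 25,
    n_plots_per_row: int = 40,
) -> dict:
    """Across-trial transfer with and without an NDRE1 level shift.

    Two trials share all generating parameters (including the yield level)
    but differ in seed; the test trial is generated twice, once with an
    additive NDRE1 offset.  Since PLS predictions are linear in the
    predictors, the offset shifts predictions by a constant: the
    correlation-based R^2 should be nearly unchanged while |bias| grows.
    """
    train = generate_trial(_recovery_config(_seed(seed, 1), n_rows, n_plots_per_row))
    test_cfg = _recovery_config(
        _seed(seed, 2), n_rows, n_plots_per_row, location_code="MR"
    )
    params = ExperimentParams(split_seed=seed, cv_seed=seed)
    out = {}
    for label, offset in (("no_offset", 0.0), ("offset", ndre_offset)):
        test = generate_trial(replace(test_cfg, ndre_level_offset=offset))
        campaign = {train.trial_id: train, test.trial_id: test}
        spec = CombinationSpec(
            train.trial_id, test.trial_id, "WYAL", DateMode.all_times()
        )
        row = run_combination(spec, campaign, params)
        out[f"r2_{label}"] = row["r2"]
        out[f"bias_{label}"] = row["bias"]
    out["r2_shift"] = abs(out["r2_offset"] - out["r2_no_offset"])
    out["bias_ratio"] = abs(out["bias_offset"]) / max(abs(out["bias_no_offset"]), 1e-12)
    return out


def multidate_gain_study(
    seed: int = 1, n_rows: int = 25, n_plots_per_row: int = 40
) -> dict:
    """All-times vs. individual-date models when two dates carry signal.

    Yield correlates at rho = 0.6 with each of two dates' NDRE1, with
    independent date-specific noise, so pooling both dates recovers more
    yield variance than either alone (population R^2 2 rho^2 / (1 + rho^2)
    vs. rho^2).
    """
    cfg = TrialConfig(
        location_code="HZ",
        year=2020,
        n_rows=n_rows,
        n_plots_per_row=n_plots_per_row,
        date_doys=[120, 140],
        stage_by_date=[45, 70],
        signal_curve=[0.6, 0.6],
        seed=_seed(seed, 3),
    )
    trial = generate_trial(cfg)
    campaign = {trial.trial_id: trial}
    params = ExperimentParams(split_seed=seed, cv_seed=seed)
    r2_ind = [
        run_combination(
            CombinationSpec(trial.trial_id, trial.trial_id, "WYWL", DateMode.individual(k)),
            campaign, params,
        )["r2"]
        for k in range(2)
    ]
    r2_all = run_combination(
        CombinationSpec(trial.trial_id, trial.trial_id, "WYWL", DateMode.all_times()),
        campaign, params,
    )["r2"]
    return {
        "r2_individual": np.asarray(r2_ind),
        "r2_all_times": float(r2_all),
        "gain": float(r2_all - max(r2_ind)),
    }


def null_calibration_study(
    seed: int = 1,
    n_rows: int = 50,
    n_plots_per_row: int = 50,
    n_permutations: int = 100,
    pixels_per_plot: int = 32,
) -> dict:
    """Full transfer grid on a six-trial campaign with zero signal.

    With rho_d = 0 everywhere no model should predict: every test-set R^2
    is sampling noise (test sets hold 500 plots).  The 36 full-model R^2
    values are then used to check the type-I behaviour of the Tukey-HSD
    type comparison: under label permutation the four combination types
    are exchangeable, so all four should share a letter in nearly every
    permutation replicate.
    """
    doy_sets = [[85, 105, 125, 145], [88, 108, 128, 148], [82, 102, 122, 142]]
    configs = []
    for yi, year in enumerate((2020, 2021, 2022)):
        for li, loc in enumerate(("HZ", "MR")):
            configs.append(
                TrialConfig(
                    location_code=loc,
                    year=year,
                    n_rows=n_rows,
                    n_plots_per_row=n_plots_per_row,
                    date_doys=[d + li for d in doy_sets[yi]],
                    stage_by_date=[30, 45, 65, 80],
                    signal_curve=[0.0, 0.0, 0.0, 0.0],
                    pixels_per_plot=pixels_per_plot,
                    seed=_seed(seed, 10 + 2 * yi + li),
                )
            )
    campaign = [generate_trial(c) for c in configs]
    params = ExperimentParams(split_seed=seed, cv_seed=seed)
    table = TransferExperiment(campaign, params).run().table

    full = table[table["date_mode"] == "all_times"].reset_index(drop=True)
    rng = np.random.default_rng(_seed(seed, 99))
    shared = 0
    values = full["r2"].to_numpy()
    labels = full["comb_type"].to_numpy()
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        cmp = compare_types(pd.DataFrame({"comb_type": labels[perm], "r2": values}))
        letters = list(cmp.table["letters"])
        if set.intersection(*[set(l) for l in letters]):
            shared += 1
    return {
        "n_models": int(len(table)),
        "max_r2": float(table["r2"].max()),
        "min_n_test": int(table["n_test"].min()),
        "shared_letter_frac": shared / n_permutations,
        "table": table,
    }


def outlier_recovery_study(
    seed: int = 1, n_rows: int = 20, n_plots_per_row: int = 20, n_planted: int = 5
) -> dict:
    """Planted gross outliers in the 23-statistic feature space.

    Five plots are shifted by +10 column SDs in every predictor; the LOF
    filter should remove all of them while touching at most a sliver of
    the clean plots.
    """
    from .qc import filter_outliers

    cfg = _recovery_config(_seed(seed, 4), n_rows, n_plots_per_row)
    trial = generate_trial(cfg)
    X = trial.stats_wide(PEAK_INDEX).copy()
    planted = X.index[:n_planted]
    X.loc[planted] = X.loc[planted] + 10 * X.std(ddof=1)
    X_f, _, report = filter_outliers(X)
    removed_ids = X.index[report.removed]
    n_planted_removed = int(sum(pid in removed_ids for pid in planted))
    n_clean_removed = report.n_removed - n_planted_removed
    return {
        "n_planted": n_planted,
        "n_planted_removed": n_planted_removed,
        "clean_removed_frac": n_clean_removed / (len(X) - n_planted),
    }


def pls_ols_agreement(seed: int = 1, n: int = 20, p: int = 5) -> dict:
    """Full-rank PLS1 vs. an independent least-squares solve."""
    from .plsr import fit_pls

    rng = np.random.default_rng(_seed(seed, 5))
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + 0.1 * rng.normal(size=n)
    model = fit_pls(X, y, n_latent=p)
    beta = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
    ols_pred = beta[0] + X @ beta[1:]
    return {"max_abs_diff": float(np.abs(model.predict(X) - ols_pred).max())}


def date_matching_optimality() -> dict:
    """Nearest-DOY optimality of date matching over the study date tables.

    For every ordered pair of the six study trials, each kept pair must
    have no strictly closer test date (checked exhaustively), and each
    test date must be used at most once.
    """
    import datetime as _dt

    from .synthdata import STUDY_TRIALS
    from .spectral import MeasurementDate
    from .transfer import match_dates

    dates_by_trial = {
        tid: [MeasurementDate.from_iso(d, s) for d, s in spec["dates"]]
        for tid, spec in STUDY_TRIALS.items()
    }
    violations = 0
    reused = 0
    n_pairs = 0
    for a in dates_by_trial:
        for b in dates_by_trial:
            if a == b:
                continue
            plan = match_dates(dates_by_trial[a], dates_by_trial[b])
            n_pairs += len(plan)
            seen = set()
            for pair in plan.pairs:
                best = min(abs(pair.train_date.doy - t.doy) for t in dates_by_trial[b])
                if pair.delta_doy > best:
                    violations += 1
                if pair.test_index in seen:
                    reused += 1
                seen.add(pair.test_index)
    return {"n_pairs": n_pairs, "suboptimal_pairs": violations, "reused_test_dates": reused}
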