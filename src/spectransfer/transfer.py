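"""Train x test trial transfer grid.

Every ordered pair of trials (including train = test) is one model
combination, classified by whether train and test share the year and/or
the location: WYWL (same trial, evaluated on a held-out 20% random plot
split), WYAL, AYWL and AYAL (trained on all usable plots of the train
trial, evaluated on all harvested plots of the test trial).

Measurement dates are matched between trials by least day-of-year (DOY)
difference; a test date claimed by several train dates is kept only for
the closest claimant.  Predictor sets are assembled per matched date pair
(23 NDRE1 statistics each) for three date modes: individual dates, date
increments (first i + 1 pairs, i = 1 .. n - 2) and the full-season
"all times" model.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluate import EvalResult, compute_metrics
from .plsr import CVPlan, PLSYieldModel
from .qc import filter_outliers
from .spectral import MeasurementDate
from .synthdata import TrialDataset

logger = logging.getLogger(__name__)

COMBINATION_TYPES = ("WYWL", "WYAL", "AYWL", "AYAL")


# ---------------------------------------------------------------------------
# Combination typology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DateMode:
    """Which matched date pairs feed the predictor matrix."""

    kind: str  # "individual" | "increment" | "all_times"
    index: int | None = None

    @classmethod
    def individual(cls, k: int) -> "DateMode":
        return cls("individual", k)

    @classmethod
    def increment(cls, i: int) -> "DateMode":
        if i < 1:
            raise ValueError("increment index starts at 1")
        return cls("increment", i)

    @classmethod
    def all_times(cls) -> "DateMode":
        return cls("all_times", None)

    def pair_slice(self, n_pairs: int) -> list[int]:
        if self.kind == "individual":
            if not 0 <= self.index < n_pairs:
                raise ValueError(f"individual date index {self.index} out of range")
            return [self.index]
        if self.kind == "increment":
            if self.index > n_pairs - 2:
                raise ValueError(
                    f"increment {self.index} exceeds n_matched_dates - 2 = {n_pairs - 2}"
                )
            return list(range(self.index + 1))
        return list(range(n_pairs))

    def label(self) -> str:
        if self.kind == "individual":
            return f"date_{self.index}"
        if self.kind == "increment":
            return f"increment_{self.index}"
        return "all_times"


def _trial_key(trial) -> tuple[str, int | str]:
    """(location, year) from a TrialDataset or a 'LOC_YY' label."""
    if isinstance(trial, TrialDataset):
        return trial.location_code, trial.year
    loc, _, yr = str(trial).rpartition("_")
    return loc, yr


def classify_combination(train, test) -> str:
    tl, ty = _trial_key(train)
    sl, sy = _trial_key(test)
    same_year, same_loc = ty == sy, tl == sl
    if same_year and same_loc:
        return "WYWL"
    if same_year:
        return "WYAL"
    if same_loc:
        return "AYWL"
    return "AYAL"


@dataclass(frozen=True)
class CombinationSpec:
    """One train x test cell of the transfer grid."""

    train_trial: str
    test_trial: str
    comb_type: str
    date_mode: DateMode | None = None


def enumerate_combinations(trials) -> list[CombinationSpec]:
    """Full Cartesian train x test grid over trial ids, typed.

    ``trials`` may be TrialDatasets or 'LOC_YY' labels.
    """
    ids = [t.trial_id if isinstance(t, TrialDataset) else str(t) for t in trials]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trial ids")
    specs = []
    for tr, tr_id in zip(trials, ids):
        for te, te_id in zip(trials, ids):
            specs.append(
                CombinationSpec(tr_id, te_id, classify_combination(tr, te))
            )
    return specs


# ---------------------------------------------------------------------------
# Date matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchedPair:
    train_index: int
    test_index: int
    train_date: MeasurementDate
    test_date: MeasurementDate
    delta_doy: int

    @property
    def stage_label(self) -> str:
        a = self.train_date.zadoks_stage
        b = self.test_date.zadoks_stage
        return f"{'NA' if a is None else a}_{'NA' if b is None else b}"


@dataclass
class DateMatchPlan:
    """Ordered train -> test date pairing by least DOY difference."""

    pairs: list[MatchedPair]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_increments(self) -> int:
        return max(0, len(self.pairs) - 2)

    def stage_labels(self) -> list[str]:
        return [p.stage_label for p in self.pairs]


def match_dates(
    train_dates: list[MeasurementDate], test_dates: list[MeasurementDate]
) -> DateMatchPlan:
    """Pair each train date with the nearest test date by |delta DOY|.

    Calendar years are ignored: matching is pure DOY arithmetic.  DOY ties
    go to the earlier test date.  If several train dates claim the same
    test date only the closest claimant keeps it (ties: earlier train
    date); the rest are dropped and logged.
    """
    if not train_dates or not test_dates:
        raise ValueError("both date lists must be non-empty")
    for lst, name in ((train_dates, "train"), (test_dates, "test")):
        doys = [d.doy for d in lst]
        if len(set(doys)) != len(doys):
            raise ValueError(f"duplicate DOYs in {name} dates")
    train_sorted = sorted(enumerate(train_dates), key=lambda t: t[1].doy)
    test_sorted = sorted(enumerate(test_dates), key=lambda t: t[1].doy)

    claims: list[MatchedPair] = []
    for ti, td in train_sorted:
        best = min(test_sorted, key=lambda t: (abs(td.doy - t[1].doy), t[1].doy))
        claims.append(
            MatchedPair(ti, best[0], td, best[1], abs(td.doy - best[1].doy))
        )
    kept: dict[int, MatchedPair] = {}
    for pair in claims:  # claims are in train-DOY order: earlier wins ties
        cur = kept.get(pair.test_index)
        if cur is None or pair.delta_doy < cur.delta_doy:
            if cur is not None:
                logger.info(
                    "dropping matched pair %s->%s (delta %d): test date claimed "
                    "closer by another train date",
                    cur.train_date.date, cur.test_date.date, cur.delta_doy,
                )
            kept[pair.test_index] = pair
        else:
            logger.info(
                "dropping matched pair %s->%s (delta %d): test date already "
                "claimed at delta %d",
                pair.train_date.date, pair.test_date.date, pair.delta_doy,
                cur.delta_doy,
            )
    pairs = sorted(kept.values(), key=lambda p: p.train_date.doy)
    if not pairs:
        raise ValueError("no matched date pairs remain after de-duplication")
    return DateMatchPlan(pairs)


def identity_plan(dates: list[MeasurementDate]) -> DateMatchPlan:
    """Self-matching plan for within-trial (WYWL) models."""
    pairs = [
        MatchedPair(i, i, d, d, 0)
        for i, d in sorted(enumerate(dates), key=lambda t: t[1].doy)
    ]
    return DateMatchPlan(pairs)


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Predictor matrix with the aligned harvested-plot yield vector."""

    trial_id: str
    X: pd.DataFrame  # index: plot_id; columns: d{pair}_{stat}
    y: pd.Series     # gy_dt_ha, aligned to X rows


class _StatsCache:
    """Per-(trial, date) memo of the 23-statistics wide tables."""

    def __init__(self, **extract_kw):
        self._memo: dict[tuple[str, int], pd.DataFrame] = {}
        self.extract_kw = extract_kw

    def get(self, trial: TrialDataset, date_index: int) -> pd.DataFrame:
        key = (trial.trial_id, date_index)
        if key not in self._memo:
            self._memo[key] = trial.stats_wide(date_index, **self.extract_kw)
        return self._memo[key]


def _trial_features(
    trial: TrialDataset, date_indices: list[int],
    pair_ids: list[int], cache: _StatsCache,
) -> FeatureMatrix:
    blocks = []
    for j, di in zip(pair_ids, date_indices):
        stats = cache.get(trial, di)
        if stats.empty:
            d = trial.dates[di].date
            raise ValueError(f"no spectral records for trial {trial.trial_id} date {d}")
        blocks.append(stats.add_prefix(f"d{j:02d}_"))
    X = pd.concat(blocks, axis=1, join="inner").dropna()
    yt = trial.yield_table.set_index("plot_id")
    harvested = yt.index[yt["harvested"]]
    X = X.loc[X.index.intersection(harvested)]
    y = yt.loc[X.index, "gy_dt_ha"]
    return FeatureMatrix(trial.trial_id, X, y)


def assemble_features(
    train: TrialDataset,
    test: TrialDataset,
    plan: DateMatchPlan,
    mode: DateMode,
    cache: _StatsCache | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Positionally aligned train/test predictor matrices for one date mode.

    Column ``d{j}_{stat}`` of the test matrix holds the test-trial date
    matched to pair ``j``'s train-trial date, so columns correspond across
    matrices even when the calendar dates differ.  Unharvested plots and
    plots missing any included date are dropped.
    """
    cache = cache or _StatsCache()
    pair_ids = mode.pair_slice(len(plan))
    train_fm = _trial_features(
        train, [plan.pairs[j].train_index for j in pair_ids], pair_ids, cache
    )
    test_fm = _trial_features(
        test, [plan.pairs[j].test_index for j in pair_ids], pair_ids, cache
    )
    return train_fm, test_fm


# ---------------------------------------------------------------------------
# Running the grid
# ---------------------------------------------------------------------------

@dataclass
class ExperimentParams:
    """Knobs of the transfer experiment (defaults are the study settings)."""

    test_fraction: float = 0.20       # WYWL held-out share
    split_seed: int = 1
    cv_folds: int = 10
    cv_seed: int = 1
    max_latent: int | None = None
    min_train_plots: int = 50
    apply_outlier_filter: bool = True
    k_neighbors: int | None = None
    max_removal_frac: float = 0.10
    buffer_m: float = 0.20            # raster-extraction settings
    min_pixels: int = 10


def _holdout_ids(trial: TrialDataset, params: ExperimentParams) -> set[str]:
    """Seeded 20% random plot split, fixed per trial so every date mode of a
    WYWL combination is evaluated on the same held-out plots."""
    yt = trial.yield_table
    ids = yt.loc[yt["harvested"], "plot_id"].to_numpy()
    seed = np.random.SeedSequence(
        (int(params.split_seed), zlib.crc32(trial.trial_id.encode()))
    )
    rng = np.random.default_rng(seed)
    n_test = int(round(params.test_fraction * ids.size))
    return set(rng.choice(ids, size=n_test, replace=False))


def run_combination(
    spec: CombinationSpec,
    campaign: dict[str, TrialDataset],
    params: ExperimentParams | None = None,
    cache: _StatsCache | None = None,
    plan: DateMatchPlan | None = None,
) -> dict:
    """Fit and evaluate one train x test x date-mode cell.

    Returns a tidy result row (dict) with metadata and all six metrics.
    """
    params = params or ExperimentParams()
    if spec.date_mode is None:
        raise ValueError("spec.date_mode must be set for run_combination")
    train = campaign[spec.train_trial]
    test = campaign[spec.test_trial]
    if plan is None:
        plan = (
            identity_plan(train.dates)
            if spec.train_trial == spec.test_trial
            else match_dates(train.dates, test.dates)
        )
    cache = cache or _StatsCache(buffer_m=params.buffer_m, min_pixels=params.min_pixels)
    train_fm, test_fm = assemble_features(train, test, plan, spec.date_mode, cache)

    if spec.comb_type == "WYWL":
        hold = _holdout_ids(train, params)
        test_rows = train_fm.X.index.isin(hold)
        X_test = train_fm.X.loc[test_rows]
        y_test = train_fm.y.loc[test_rows]
        X_train = train_fm.X.loc[~test_rows]
        y_train = train_fm.y.loc[~test_rows]
        # test columns carry the train-trial names already (identity plan)
    else:
        X_train, y_train = train_fm.X, train_fm.y
        X_test, y_test = test_fm.X, test_fm.y

    if params.apply_outlier_filter:
        X_train, y_train, report = filter_outliers(
            X_train, y_train,
            k_neighbors=params.k_neighbors,
            max_removal_frac=params.max_removal_frac,
        )
    else:
        report = None
    if len(X_train) < params.min_train_plots:
        raise ValueError(
            f"{len(X_train)} training plots < min_train_plots={params.min_train_plots} "
            f"for {spec.train_trial}->{spec.test_trial} {spec.date_mode.label()}"
        )

    results = PLSYieldModel(y_train, X_train).fit_cv(
        max_latent=params.max_latent,
        cv=CVPlan(params.cv_folds, seed=params.cv_seed),
    )
    pred = results.predict(X_test)
    metrics = compute_metrics(y_test.to_numpy(), pred)

    pair_ids = spec.date_mode.pair_slice(len(plan))
    last = plan.pairs[pair_ids[-1]]
    row = {
        "train_trial": spec.train_trial,
        "test_trial": spec.test_trial,
        "comb_type": spec.comb_type,
        "date_mode": spec.date_mode.kind,
        "date_label": (
            last.train_date.date.isoformat()
            if spec.date_mode.kind == "individual"
            else spec.date_mode.label()
        ),
        "stage_label": last.stage_label,
        "n_train": int(len(X_train)),
        "n_test": metrics.n_test,
        "n_latent": results.n_latent,
        "n_outliers_removed": None if report is None else report.n_removed,
    }
    row.update(metrics.as_dict())
    return row


def run_experiment(
    campaign: list[TrialDataset] | dict[str, TrialDataset],
    params: ExperimentParams | None = None,
) -> pd.DataFrame:
    """EvalResult rows for every combination x every date mode."""
    return TransferExperiment(campaign, params).run().table


class TransferExperiment:
    """The full transfer study on one campaign.

    ``run()`` evaluates every train x test combination under every date
    mode (each individual matched date, each date increment, all times)
    and returns a :class:`TransferResults` holding the tidy result table.
    Individual cell failures are logged and skipped, not fatal.
    """

    def __init__(
        self,
        campaign: list[TrialDataset] | dict[str, TrialDataset],
        params: ExperimentParams | None = None,
    ):
        if isinstance(campaign, dict):
            self.campaign = dict(campaign)
        else:
            self.campaign = {t.trial_id: t for t in campaign}
            if len(self.campaign) != len(campaign):
                raise ValueError("duplicate trial ids in campaign")
        self.params = params or ExperimentParams()

    def run(self) -> "TransferResults":
        params = self.params
        cache = _StatsCache(buffer_m=params.buffer_m, min_pixels=params.min_pixels)
        rows = []
        for spec in enumerate_combinations(list(self.campaign.values())):
            train = self.campaign[spec.train_trial]
            test = self.campaign[spec.test_trial]
            try:
                plan = (
                    identity_plan(train.dates)
                    if spec.train_trial == spec.test_trial
                    else match_dates(train.dates, test.dates)
                )
            except ValueError as err:
                logger.warning("skipping %s->%s: %s", spec.train_trial, spec.test_trial, err)
                continue
            modes = [DateMode.individual(k) for k in range(len(plan))]
            modes += [DateMode.increment(i) for i in range(1, plan.n_increments + 1)]
            modes.append(DateMode.all_times())
            for mode in modes:
                cell = replace(spec, date_mode=mode)
                try:
                    rows.append(run_combination(cell, self.campaign, params, cache, plan))
                except (ValueError, np.linalg.LinAlgError) as err:
                    logger.warning(
                        "skipping %s->%s %s: %s",
                        spec.train_trial, spec.test_trial, mode.label(), err,
                    )
        return TransferResults(pd.DataFrame(rows), self.params)


class TransferResults:
    """Tidy result table of the transfer grid plus summary views."""

    #: column order of the results table / CSV
    COLUMNS = [
        "train_trial", "test_trial", "comb_type", "date_mode", "date_label",
        "stage_label", "n_train", "n_test", "n_latent", "r2", "rmse",
        "rrmse_mean", "mae", "bias", "offset", "n_outliers_removed",
    ]

    def __init__(self, table: pd.DataFrame, params: ExperimentParams | None = None):
        if len(table):
            table = table[[c for c in self.COLUMNS if c in table.columns]]
        self.table = table.reset_index(drop=True)
        self.params = params

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def best_model_table(self) -> pd.DataFrame:
        from .evaluate import best_model_table

        return best_model_table(self.table)

    def compare_types(self, metric: str = "r2", which: str = "all_times", alpha: float = 0.05):
        """Tukey-HSD grouping of ``metric`` across combination types.

        ``which``: 'all_times' (full models), 'individual', or 'multi'
        (increments + all_times).
        """
        from .evaluate import compare_types

        t = self.table
        if which == "multi":
            sub = t[t["date_mode"].isin(["increment", "all_times"])]
        else:
            sub = t[t["date_mode"] == which]
        return compare_types(sub[["comb_type", metric]], alpha=alpha)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Transfer experiment results",
            "=" * 48,
            f"models evaluated: {len(t)}",
            f"train x test combinations: {t.groupby(['train_trial', 'test_trial']).ngroups}",
        ]
        full = t[t["date_mode"] == "all_times"]
        if len(full):
            lines.append("full ('all times') models, mean R^2 by type:")
            for typ, grp in full.groupby("comb_type"):
                lines.append(
                    f"  {typ}: R^2 = {grp['r2'].mean():.3f} "
                    f"(n = {len(grp)}, RMSE = {grp['rmse'].mean():.2f} dt/ha)"
                )
        return "\n".join(lines)
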