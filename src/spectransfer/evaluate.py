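"""Evaluation metrics for predicted vs. measured grain yield.

R^2 is the squared Pearson correlation of observed and predicted yield —
not 1 - SSres/SStot — because plot-level phenotyping needs relative
discrimination of genotypes and can tolerate a level shift; the systematic
components are reported separately as bias (mean of predicted - observed)
and offset (intercept of the least-squares regression of observed on
predicted).  Model types are compared by one-way ANOVA with Tukey's HSD
post-hoc test and a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

#: Sign conventions, echoed into results metadata with every output file.
METRIC_CONVENTIONS = {
    "r2": "squared Pearson correlation of observed and predicted",
    "bias": "mean(predicted - observed); positive = overprediction",
    "offset": "intercept of least-squares regression observed ~ predicted",
    "rrmse_mean": "100 * rmse / mean(observed), percent",
}


@dataclass
class EvalResult:
    """Metrics for one train x test x date-mode model evaluation."""

    r2: float
    rmse: float
    rrmse_mean: float
    mae: float
    bias: float
    offset: float
    n_test: int

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "rrmse_mean": self.rrmse_mean,
            "mae": self.mae,
            "bias": self.bias,
            "offset": self.offset,
            "n_test": self.n_test,
        }


def compute_metrics(observed, predicted) -> EvalResult:
    """All six evaluation metrics for one prediction vector."""
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size:
        raise ValueError("observed and predicted lengths differ")
    if o.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(o) == 0:
        raise ValueError("observed yield has zero variance")
    resid = p - o
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    bias = float(np.mean(resid))
    o_mean = float(np.mean(o))
    rrmse = 100.0 * rmse / o_mean if o_mean != 0 else np.nan
    if np.std(p) == 0:
        warnings.warn("predictions have zero variance; R^2 and offset undefined",
                      stacklevel=2)
        r2 = np.nan
        offset = np.nan
    else:
        r2 = float(np.corrcoef(o, p)[0, 1] ** 2)
        slope = float(np.cov(o, p, ddof=1)[0, 1] / np.var(p, ddof=1))
        offset = o_mean - slope * float(np.mean(p))
    return EvalResult(
        r2=r2, rmse=rmse, rrmse_mean=rrmse, mae=mae, bias=bias,
        offset=offset, n_test=int(o.size),
    )


@dataclass
class GroupComparison:
    """Tukey-HSD grouping of a metric across model types."""

    table: pd.DataFrame        # group, mean, n, letters
    pairwise: pd.DataFrame     # group1, group2, meandiff, p_adj, reject
    alpha: float

    def letters(self) -> dict[str, str]:
        return dict(zip(self.table["group"], self.table["letters"]))


def _compact_letter_display(groups: list[str], nonsig: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; groups in the
    input order get letters in alphabet order.
    """
    letter_sets: list[set[str]] = []  # groups covered by each letter
    for g in groups:
        placed = False
        for s in letter_sets:
            if g in s:
                placed = True
                continue
            if all(frozenset((g, other)) in nonsig for other in s):
                s.add(g)
                placed = True
        if not placed:
            # new letter: g plus every earlier group non-different from g
            # and mutually compatible with the members already inside
            new = {g}
            for other in groups:
                if other == g or frozenset((g, other)) not in nonsig:
                    continue
                if all(frozenset((other, m)) in nonsig for m in new):
                    new.add(other)
            letter_sets.append(new)
    # absorb duplicates and redundant (subset) letters
    unique: list[set[str]] = []
    for s in letter_sets:
        if s not in unique:
            unique.append(s)
    letter_sets = [
        s for i, s in enumerate(unique)
        if not any(s < t for j, t in enumerate(unique) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def compare_types(results, alpha: float = 0.05) -> GroupComparison:
    """Tukey-HSD comparison of a metric across combination types.

    ``results`` is an iterable of ``(comb_type, value)`` pairs (or a
    DataFrame with those two columns, in that order).  Each train x test
    combination's metric counts as one observation.
    """
    if isinstance(results, pd.DataFrame):
        df = results.iloc[:, :2].copy()
        df.columns = ["group", "value"]
    else:
        df = pd.DataFrame(results, columns=["group", "value"])
    df = df.dropna()
    counts = df.groupby("group")["value"].agg(["mean", "count"])
    if len(counts) < 2 or (counts["count"] < 2).any():
        raise ValueError("need >= 2 groups with >= 2 values each")
    degenerate = df.groupby("group")["value"].std(ddof=1).eq(0)
    if degenerate.any():
        warnings.warn(
            f"zero within-group variance in {list(degenerate[degenerate].index)}",
            stacklevel=2,
        )
    tk = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy(), alpha=alpha)
    from itertools import combinations

    pairs = list(combinations([str(g) for g in tk.groupsunique], 2))
    pw = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": np.asarray(tk.meandiffs, dtype=float),
            "p_adj": np.asarray(tk.pvalues, dtype=float),
            "reject": np.asarray(tk.reject, dtype=bool),
        }
    )
    nonsig = {
        frozenset((a, b))
        for a, b, rej in zip(pw["group1"], pw["group2"], pw["reject"])
        if not rej
    }
    groups = list(counts.index)
    letters = _compact_letter_display(groups, nonsig)
    table = pd.DataFrame(
        {
            "group": groups,
            "mean": counts["mean"].to_numpy(),
            "n": counts["count"].to_numpy(),
            "letters": [letters[g] for g in groups],
        }
    )
    return GroupComparison(table=table, pairwise=pw, alpha=alpha)


def best_model_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per train x test pair: best individual-date vs. best multi-date R^2.

    Multi-date pools the date increments and the all-times model.  Missing
    date modes yield missing cells, not errors.
    """
    rows = []
    for (train, test), grp in results.groupby(["train_trial", "test_trial"], sort=False):
        indiv = grp.loc[grp["date_mode"] == "individual", "r2"]
        multi = grp.loc[grp["date_mode"].isin(["increment", "all_times"]), "r2"]
        best_i = float(indiv.max()) if indiv.notna().any() else np.nan
        best_m = float(multi.max()) if multi.notna().any() else np.nan
        rows.append(
            {
                "train_trial": train,
                "test_trial": test,
                "comb_type": grp["comb_type"].iloc[0],
                "best_individual_r2": best_i,
                "best_multidate_r2": best_m,
                "r2_difference": best_m - best_i,
            }
        )
    return pd.DataFrame(rows)
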