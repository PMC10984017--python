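"""Tube-test dominance ranking and lick-microstructure analysis.

Social rank is scored from a round-robin tube-dominance tournament: each
mouse's *percent wins* is 100 x (trials won) / (trials participated in),
pooled over all testing days, and cage ranks (1 = dominant) follow percent
wins with a deterministic tie-break.  Drinking behavior is decomposed into
lick *bouts*: runs of consecutive licks whose inter-lick intervals stay at
or below a threshold, discarding runs shorter than a minimum lick count.
Condition contrasts (e.g. pre- vs during-isolation by rank, stimulated vs
unstimulated trials) use a two-factor ANOVA with Type III sums of squares
plus a rank-vs-licks Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TournamentRecord",
    "LickStream",
    "BoutTable",
    "TrialTable",
    "percent_wins",
    "assign_ranks",
    "segment_bouts",
    "microstructure_summary",
    "condition_contrast",
    "trials_from_cues",
]

SPOUTS = ("alcohol", "water", "sucrose")
CONDITIONS = ("pre_SI", "SI")


@dataclass
class TournamentRecord:
    """Pairwise tube-test outcomes for one cage.

    ``trials`` has columns ``day`` (1-based), ``mouse_a``, ``mouse_b``,
    ``winner``; the winner must be one of the two contestants.
    """

    trials: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"day", "mouse_a", "mouse_b", "winner"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"tournament trials missing columns: {sorted(missing)}")
        t = self.trials
        ok = (t["winner"] == t["mouse_a"]) | (t["winner"] == t["mouse_b"])
        if not bool(ok.all()):
            raise ValueError("every winner must be one of the two contestants")

    @property
    def mice(self) -> list:
        return sorted(set(self.trials["mouse_a"]) | set(self.trials["mouse_b"]))


@dataclass
class LickStream:
    """Timestamped licks on one spout in one session."""

    lick_times_s: np.ndarray
    spout: str
    mouse: str = ""
    condition: str = "pre_SI"
    stimulated: bool | None = None

    def __post_init__(self) -> None:
        if self.spout not in SPOUTS:
            raise ValueError(f"spout must be one of {SPOUTS}, got {self.spout!r}")
        t = np.asarray(self.lick_times_s, dtype=float)
        if t.ndim != 1:
            raise ValueError("lick times must be a 1-D array")
        if t.size and t[0] < 0:
            raise ValueError("lick times must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("lick times must be strictly sorted ascending")
        self.lick_times_s = t

    @property
    def n_licks(self) -> int:
        return int(self.lick_times_s.size)


@dataclass
class BoutTable:
    """Non-overlapping lick bouts: start_s, end_s, n_licks, spout."""

    bouts: pd.DataFrame
    spout: str
    min_licks: int
    ili_threshold_s: float
    n_discarded_licks: int = 0

    def __post_init__(self) -> None:
        b = self.bouts
        if len(b):
            if not (np.diff(b["start_s"].to_numpy()) > 0).all():
                raise ValueError("bouts must be ordered by start time")
            if (b["end_s"].to_numpy()[:-1] >= b["start_s"].to_numpy()[1:]).any():
                raise ValueError("bouts must not overlap")
            if (b["n_licks"] < self.min_licks).any():
                raise ValueError("every bout must have n_licks >= min_licks")

    def __len__(self) -> int:
        return len(self.bouts)


@dataclass
class TrialTable:
    """Cued-access trials: cue_onset_s, access_start_s, access_end_s, stimulated."""

    trials: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.trials
        if len(t):
            if (t["access_end_s"] <= t["access_start_s"]).any():
                raise ValueError("access durations must be positive")
            ends = t["access_end_s"].to_numpy()[:-1]
            starts = t["access_start_s"].to_numpy()[1:]
            if (ends > starts).any():
                raise ValueError("access windows must not overlap")

    def __len__(self) -> int:
        return len(self.trials)


def percent_wins(record: TournamentRecord, mouse) -> float:
    """Percent of tube-test trials won by ``mouse``, pooled across days."""
    t = record.trials
    played = (t["mouse_a"] == mouse) | (t["mouse_b"] == mouse)
    n = int(played.sum())
    if n == 0:
        raise KeyError(f"mouse {mouse!r} appears in no trial")
    wins = int((t.loc[played, "winner"] == mouse).sum())
    return 100.0 * wins / n


def _head_to_head_wins(record: TournamentRecord, a, b) -> int:
    t = record.trials
    direct = ((t["mouse_a"] == a) & (t["mouse_b"] == b)) | (
        (t["mouse_a"] == b) & (t["mouse_b"] == a)
    )
    return int((t.loc[direct, "winner"] == a).sum())


def assign_ranks(record: TournamentRecord) -> pd.DataFrame:
    """Rank cage mates by percent wins (rank 1 = dominant).

    Ties are broken by head-to-head wins against the tied opponent, then by
    lexicographic mouse id, so the ranking is deterministic and auditable.
    Returns a DataFrame with columns ``mouse``, ``percent_wins``, ``rank``.
    """
    mice = record.mice
    if len(mice) < 2:
        raise ValueError("ranking requires at least two mice")
    pw = {m: percent_wins(record, m) for m in mice}

    import functools

    def cmp(a, b) -> int:
        if pw[a] != pw[b]:
            return -1 if pw[a] > pw[b] else 1
        h2h_a = _head_to_head_wins(record, a, b)
        h2h_b = _head_to_head_wins(record, b, a)
        if h2h_a != h2h_b:
            return -1 if h2h_a > h2h_b else 1
        return -1 if str(a) < str(b) else 1

    order = sorted(mice, key=functools.cmp_to_key(cmp))
    out = pd.DataFrame(
        {
            "mouse": order,
            "percent_wins": [pw[m] for m in order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return out


def segment_bouts(
    stream: LickStream,
    ili_threshold_s: float = 1.0,
    min_licks: int = 3,
) -> BoutTable:
    """Segment a lick stream into bouts.

    Consecutive licks with inter-lick interval <= ``ili_threshold_s`` belong
    to the same bout; runs with fewer than ``min_licks`` licks are discarded
    (their licks are counted in ``n_discarded_licks`` so lick totals are
    conserved).
    """
    if ili_threshold_s <= 0:
        raise ValueError("ili_threshold_s must be positive")
    if min_licks < 1:
        raise ValueError("min_licks must be >= 1")
    t = stream.lick_times_s
    if t.size == 0:
        empty = pd.DataFrame(columns=["start_s", "end_s", "n_licks", "spout"])
        return BoutTable(empty, stream.spout, min_licks, ili_threshold_s, 0)

    # split at gaps exceeding the threshold
    gaps = np.diff(t) > ili_threshold_s
    run_starts = np.concatenate([[0], np.flatnonzero(gaps) + 1])
    run_ends = np.concatenate([np.flatnonzero(gaps), [t.size - 1]])
    counts = run_ends - run_starts + 1
    keep = counts >= min_licks
    discarded = int(counts[~keep].sum())
    bouts = pd.DataFrame(
        {
            "start_s": t[run_starts[keep]],
            "end_s": t[run_ends[keep]],
            "n_licks": counts[keep].astype(int),
            "spout": stream.spout,
        }
    )
    return BoutTable(bouts, stream.spout, min_licks, ili_threshold_s, discarded)


def microstructure_summary(bouts: BoutTable, stream: LickStream) -> dict:
    """Summarize lick microstructure: total licks, bout count, licks per bout.

    ``mean_licks_per_bout`` is NaN when there are no bouts.
    """
    if bouts.spout != stream.spout:
        raise ValueError(
            f"bout table is for spout {bouts.spout!r}, stream for {stream.spout!r}"
        )
    n_bouts = len(bouts)
    bout_licks = int(bouts.bouts["n_licks"].sum()) if n_bouts else 0
    total = stream.n_licks
    if bout_licks + bouts.n_discarded_licks != total:
        raise ValueError("bout table does not account for all licks in the stream")
    return {
        "total_licks": total,
        "n_bouts": n_bouts,
        "mean_licks_per_bout": (bout_licks / n_bouts) if n_bouts else float("nan"),
    }


def _condition_order(levels) -> list:
    """Baseline condition (pre_SI / unstimulated) first, then lexicographic."""
    known = {c: i for i, c in enumerate(CONDITIONS)}
    return sorted(levels, key=lambda c: (known.get(c, len(known)), str(c)))


def _anova_two_way(df: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Type III two-way ANOVA with sum-coded factors (statsmodels OLS)."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    formula = (
        f"{value} ~ C({factor_a}, Sum) + C({factor_b}, Sum) "
        f"+ C({factor_a}, Sum):C({factor_b}, Sum)"
    )
    model = smf.ols(formula, data=df).fit()
    table = anova_lm(model, typ=3)
    table = table.rename(
        index={
            f"C({factor_a}, Sum)": factor_a,
            f"C({factor_b}, Sum)": factor_b,
            f"C({factor_a}, Sum):C({factor_b}, Sum)": f"{factor_a}:{factor_b}",
        }
    )
    return table


def condition_contrast(
    summaries: pd.DataFrame,
    value: str = "total_licks",
    condition_col: str = "condition",
    rank_col: str = "rank",
    posthoc_method: str = "holm",
    rank_regressor: str = "rank",
) -> dict:
    """Two-factor contrast of a microstructure metric across condition x rank.

    Emits per-cell means +/- SEM, a Type III two-way ANOVA table
    (condition x rank), Holm-corrected pairwise condition contrasts within
    each rank, and the rank-vs-metric Pearson correlation (r, r^2, p) using
    integer rank (or percent_wins) as the regressor.
    """
    from statsmodels.stats.multitest import multipletests

    df = summaries.copy()
    cells = df.groupby([condition_col, rank_col], observed=True)[value]
    counts = cells.size()
    if (counts < 2).any():
        bad = counts[counts < 2]
        raise ValueError(
            "need >= 2 observations per condition x rank cell for SEM/ANOVA; "
            f"short cells: {list(bad.index)}"
        )
    cell_stats = cells.agg(["mean", "sem", "size"]).reset_index()

    n_ranks = df[rank_col].nunique()
    n_conds = df[condition_col].nunique()
    if n_ranks >= 2 and n_conds >= 2:
        anova = _anova_two_way(df, value, condition_col, rank_col)
        anova_records = {
            str(k): {
                "F": float(anova.loc[k, "F"]),
                "p": float(anova.loc[k, "PR(>F)"]),
                "df": float(anova.loc[k, "df"]),
            }
            for k in anova.index
            if k not in ("Intercept", "Residual")
        }
    elif n_conds >= 2:
        # single-factor collapse: paired-by-mouse comparison if possible, else Welch
        conds = _condition_order(df[condition_col].unique())
        a = df[df[condition_col] == conds[0]].sort_values("mouse")[value].to_numpy()
        b = df[df[condition_col] == conds[1]].sort_values("mouse")[value].to_numpy()
        if a.size == b.size:
            tstat, p = stats.ttest_rel(b, a)
        else:
            tstat, p = stats.ttest_ind(b, a, equal_var=False)
        anova_records = {
            condition_col: {"t": float(tstat), "p": float(p), "df": float(a.size - 1)}
        }
    else:
        raise ValueError("contrast requires >= 2 condition levels")

    # post hoc: condition contrast within each rank level
    posthoc = []
    if n_conds == 2:
        conds = _condition_order(df[condition_col].unique())
        pvals, rows = [], []
        for r, sub in df.groupby(rank_col, observed=True):
            a = sub[sub[condition_col] == conds[0]][value].to_numpy()
            b = sub[sub[condition_col] == conds[1]][value].to_numpy()
            tstat, p = stats.ttest_ind(b, a, equal_var=False)
            rows.append({"rank": r, "contrast": f"{conds[1]} - {conds[0]}",
                         "t": float(tstat), "p_raw": float(p)})
            pvals.append(p)
        if rows:
            adj = multipletests(pvals, method=posthoc_method)[1]
            for row, p_adj in zip(rows, adj):
                row["p_adj"] = float(p_adj)
            posthoc = rows

    # rank-vs-metric correlation (pooled within each condition)
    regressor = rank_col if rank_regressor == "rank" else rank_regressor
    correlations = {}
    for c, sub in df.groupby(condition_col, observed=True):
        x = sub[regressor].to_numpy(dtype=float)
        y = sub[value].to_numpy(dtype=float)
        if np.ptp(x) > 0 and x.size >= 3:
            r, p = stats.pearsonr(x, y)
            correlations[str(c)] = {"r": float(r), "r2": float(r * r), "p": float(p)}
    return {
        "value": value,
        "cells": cell_stats.to_dict("records"),
        "anova": anova_records,
        "posthoc": posthoc,
        "posthoc_correction": posthoc_method,
        "rank_correlation": correlations,
        "rank_regressor": rank_regressor,
        "anova_sum_of_squares": "type III, sum coding",
    }


def trials_from_cues(
    cue_onsets_s: Sequence[float],
    access_duration_s: float,
    stimulated_flags: Sequence[bool] | None = None,
) -> TrialTable:
    """Build the trial table of a cued two-bottle-choice session.

    A cue light at each onset signals bottle availability for
    ``access_duration_s`` seconds, after which bottles retract; on a
    stimulation session a flagged subset of trials (typically 50%) carries
    optogenetic stimulation.
    """
    onsets = np.asarray(cue_onsets_s, dtype=float)
    if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
        raise ValueError("cue onsets must be strictly sorted")
    if access_duration_s <= 0:
        raise ValueError("access duration must be positive")
    if onsets.size > 1 and access_duration_s >= np.min(np.diff(onsets)):
        raise ValueError("access windows overlap the next cue onset")
    if stimulated_flags is None:
        stimulated = np.zeros(onsets.size, dtype=bool)
    else:
        stimulated = np.asarray(stimulated_flags, dtype=bool)
        if stimulated.size != onsets.size:
            raise ValueError("one stimulation flag per cue onset required")
    return TrialTable(
        pd.DataFrame(
            {
                "cue_onset_s": onsets,
                "access_start_s": onsets,
                "access_end_s": onsets + access_duration_s,
                "stimulated": stimulated,
            }
        )
    )


def assign_licks_to_trials(stream: LickStream, trials: TrialTable) -> np.ndarray:
    """Map each lick to a trial index, or -1 for the intertrial period."""
    t = stream.lick_times_s
    out = np.full(t.size, -1, dtype=int)
    for i, row in trials.trials.iterrows():
        inside = (t >= row["access_start_s"]) & (t < row["access_end_s"])
        out[inside] = i
    return out
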