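"""Cross-session ensemble bookkeeping and overlap analysis.

Imaged neurons are matched across sessions by an identity map (global id,
session, within-session local id) produced upstream by cell registration.
This module computes the co-registration rate, the overlap between
event-responsive ensembles of two sessions/conditions (restricted to
neurons co-registered across both), and a 2x2 chi-square comparing overlap
proportions between two condition pairs — e.g. whether stimulation recruits
more of the isolation ensemble than of the pre-isolation ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapRow",
    "validate_identity_map",
    "coregistration_rate",
    "ensemble_overlap",
    "overlap_chi2",
]


@dataclass
class OverlapRow:
    """Overlap of responsive ensembles between two sessions.

    ``n_common`` neurons responsive in both, ``n_a``/``n_b`` responsive in
    each, out of ``n_coregistered`` neurons tracked across both sessions.
    """

    n_common: int
    n_a: int
    n_b: int
    n_coregistered: int
    direction: str = "excited"
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.n_common <= min(self.n_a, self.n_b) <= self.n_coregistered):
            raise ValueError(
                "overlap counts must satisfy n_common <= min(n_a, n_b) "
                "<= n_coregistered"
            )


def validate_identity_map(idmap: pd.DataFrame) -> pd.DataFrame:
    """Check identity-map invariants; returns the validated frame.

    (session, local_id) pairs are unique and a global id appears at most
    once per session.
    """
    required = {"global_id", "session", "local_id"}
    if not required <= set(idmap.columns):
        raise ValueError(f"identity map needs columns {sorted(required)}")
    if idmap.duplicated(["session", "local_id"]).any():
        raise ValueError("(session, local_id) pairs must be unique")
    if idmap.duplicated(["global_id", "session"]).any():
        raise ValueError("a global id may appear at most once per session")
    return idmap


def coregistration_rate(idmap: pd.DataFrame, sessions: list | None = None) -> dict:
    """Fraction of neurons tracked across every listed session.

    The numerator counts global ids present in all listed sessions; the
    denominator is the mean per-session neuron count over those sessions
    (the convention for "X% of neurons were co-registered").
    """
    idmap = validate_identity_map(idmap)
    all_sessions = sorted(idmap["session"].unique())
    if sessions is None:
        sessions = all_sessions
    if not sessions:
        raise ValueError("session subset must be non-empty")
    unknown = set(sessions) - set(all_sessions)
    if unknown:
        raise KeyError(f"unknown sessions: {sorted(unknown)}")
    sub = idmap[idmap["session"].isin(sessions)]
    spanned = sub.groupby("global_id")["session"].nunique()
    n_full = int((spanned == len(sessions)).sum())
    mean_count = float(sub.groupby("session")["global_id"].size().mean())
    return {
        "rate": n_full / mean_count if mean_count else 0.0,
        "n_coregistered": n_full,
        "mean_neurons_per_session": mean_count,
        "sessions": list(sessions),
        "definition": "global ids present in every listed session / "
                      "mean per-session neuron count",
    }


def _responsive_globals(
    labels: pd.DataFrame, idmap: pd.DataFrame, session, direction: str
) -> tuple[set, set]:
    """(responsive global ids, all labeled global ids) for one session."""
    sess_map = idmap[idmap["session"] == session].set_index("local_id")["global_id"]
    missing = set(labels["neuron_id"]) - set(sess_map.index)
    if missing:
        raise ValueError(
            f"neurons {sorted(missing)[:5]}... labeled but absent from the "
            f"identity map for session {session!r}"
        )
    gids = labels["neuron_id"].map(sess_map)
    resp = set(gids[labels["label"] == direction])
    return resp, set(gids)


def ensemble_overlap(
    labels_a: pd.DataFrame,
    labels_b: pd.DataFrame,
    idmap: pd.DataFrame,
    session_a,
    session_b,
    direction: str = "excited",
    label: str = "",
) -> OverlapRow:
    """Overlap of the responsive ensembles of two sessions.

    ``labels_*`` are classification tables (``neuron_id`` = within-session
    local id, ``label``); only neurons co-registered across both sessions
    enter the counts.  ``direction`` selects excited or inhibited
    ensembles (the two are analyzed separately).
    """
    idmap = validate_identity_map(idmap)
    resp_a, all_a = _responsive_globals(labels_a, idmap, session_a, direction)
    resp_b, all_b = _responsive_globals(labels_b, idmap, session_b, direction)
    coreg = all_a & all_b
    A = resp_a & coreg
    B = resp_b & coreg
    return OverlapRow(
        n_common=len(A & B),
        n_a=len(A),
        n_b=len(B),
        n_coregistered=len(coreg),
        direction=direction,
        label=label,
    )


def overlap_chi2(row_1: OverlapRow, row_2: OverlapRow, correction: bool = False) -> dict:
    """2x2 chi-square comparing overlap proportions of two condition pairs.

    Each row contributes (overlapping, non-overlapping) counts out of its
    reference ensemble ``n_b`` (the ensemble whose recruitment is being
    compared, e.g. the stimulation ensemble).  Yates continuity correction
    is off by default; the setting is recorded in the output.
    """
    table = np.array(
        [
            [row_1.n_common, row_1.n_b - row_1.n_common],
            [row_2.n_common, row_2.n_b - row_2.n_common],
        ]
    )
    if (table.sum(axis=1) == 0).any():
        raise ValueError("both rows need a non-zero reference ensemble")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=correction)
    return {
        "chi2": float(chi2),
        "p": float(p),
        "dof": int(dof),
        "table": table,
        "expected": expected,
        "continuity_correction": correction,
        "proportions": [
            row_1.n_common / row_1.n_b,
            row_2.n_common / row_2.n_b,
        ],
    }
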