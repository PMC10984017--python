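"""Synthetic cohort generation with planted ground truth.

Every downstream stage of the pipeline (rank scoring, bout segmentation,
contact detection, peri-event classification, decoding, ensemble overlap)
is exercised on data from these generators, which plant a known truth:
latent tube-test skill ordered by intended rank, bout-structured lick
streams with recorded bout compositions, pose sessions with scripted
interaction episodes, calcium traces with event-locked excited / inhibited
neurons, and cross-session identity maps with a set co-registration rate.

Design notes
------------
* Determinism: every generator takes a seed and draws from its own
  ``numpy.random.Generator``; no global state.
* Bout gap floor: between-bout gaps are guaranteed >= a declared floor
  (default 2 s = 2x the default segmentation threshold), so the planted
  bout decomposition is the unique answer the segmenter can return.
* Pose episodes are constructed with geometric margins wide enough that
  keypoint jitter cannot move a planted frame across the 60 px / 135 deg
  rule, and non-episode frames keep the intruder >= 74 px away so the
  distance criterion is always violated outside episodes.
* Calcium transients are a single-exponential decay kernel (tau default
  1.0 s) scaled in units of the noise SD, on a white Gaussian noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import LickStream, TournamentRecord
from .pose import PoseSession

__all__ = [
    "CohortConfig",
    "gen_tournament",
    "gen_lick_stream",
    "gen_pose_session",
    "gen_calcium_population",
    "gen_identity_map",
    "gen_cohort",
]


@dataclass
class CohortConfig:
    """Planted effect structure for a synthetic drinking cohort.

    ``rank_effect_alcohol`` is the licks-per-rank-step slope on integer
    ranks (1 = dominant), so a positive value reproduces the observed
    pattern of subordinates drinking more alcohol.  ``isolation_effect``
    is the added alcohol licks under social isolation common to all ranks,
    and ``rank_x_isolation`` the extra isolation escalation per rank step
    (subordinates escalate more).  Subordinate ranks realize their
    isolation escalation through licks per bout, dominant ranks through
    bout number.
    """

    n_cages: int = 4
    mice_per_cage: int = 4
    base_licks_alcohol: float = 250.0
    base_licks_water: float = 150.0
    rank_effect_alcohol: float = 50.0
    isolation_effect: float = 100.0
    rank_x_isolation: float = 50.0
    session_s: float = 3600.0
    bout_rate_per_min: float = 0.35
    within_bout_ili_s: float = 0.15
    min_bout_licks: int = 3
    gap_floor_s: float = 2.0
    tournament_days: int = 3
    meetings_per_day: int = 1
    skill_spread: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cages < 1 or self.mice_per_cage < 1:
            raise ValueError("counts must be >= 1")

    @property
    def n_mice(self) -> int:
        return self.n_cages * self.mice_per_cage

    def expected_licks(self, rank: int, isolated: bool) -> float:
        """Planted mean alcohol licks for a mouse of this rank/condition."""
        si = 1.0 if isolated else 0.0
        return (
            self.base_licks_alcohol
            + self.rank_effect_alcohol * (rank - 1)
            + self.isolation_effect * si
            + self.rank_x_isolation * (rank - 1) * si
        )

    def licks_sd(self, rank: int = 1, isolated: bool = False) -> float:
        """Analytic SD of session total licks (compound Poisson).

        Bout count N ~ Poisson(lam); licks per bout l = m + Poisson(L - m)
        with m = min_bout_licks, so Var(total) = lam*Var(l) + lam*E[l]^2.
        """
        lam = self.bout_rate_per_min * self.session_s / 60.0
        L = self.expected_licks(rank, isolated) / lam
        m = self.min_bout_licks
        var_l = max(L - m, 0.0)
        return float(np.sqrt(lam * var_l + lam * L**2))


def gen_tournament(
    mice: list,
    skills: np.ndarray | dict | None = None,
    days: int = 3,
    meetings_per_day: int = 1,
    skill_spread: float = 3.0,
    seed: int = 0,
) -> TournamentRecord:
    """Simulate a round-robin tube-test tournament from latent skill.

    Every ordered pair meets ``meetings_per_day`` times per day for
    ``days`` days; mouse a beats mouse b with logistic probability
    sigmoid(skill_a - skill_b).  ``skills`` defaults to a descending
    ladder spaced by ``skill_spread`` (first mouse most dominant);
    ``skill_spread=0`` gives coin-flip outcomes, ``np.inf`` deterministic
    wins in skill order.
    """
    if len(mice) < 2:
        raise ValueError("a tournament needs at least two mice")
    if days < 1 or meetings_per_day < 1:
        raise ValueError("days and meetings_per_day must be >= 1")
    deterministic = skills is None and np.isinf(skill_spread)
    if skills is None:
        spread = 1.0 if deterministic else skill_spread
        skills = {m: -spread * i for i, m in enumerate(mice)}
    elif not isinstance(skills, dict):
        skills = dict(zip(mice, np.asarray(skills, dtype=float)))
    rng = np.random.default_rng(seed)
    rows = []
    for day in range(1, days + 1):
        for a in mice:
            for b in mice:
                if a == b:
                    continue
                for _ in range(meetings_per_day):
                    ds = skills[a] - skills[b]
                    if deterministic or np.isposinf(ds):
                        p = 1.0 if ds > 0 else 0.0
                    elif np.isneginf(ds):
                        p = 0.0
                    else:
                        p = 1.0 / (1.0 + np.exp(-ds))
                    winner = a if rng.random() < p else b
                    rows.append(
                        {"day": day, "mouse_a": a, "mouse_b": b, "winner": winner}
                    )
    return TournamentRecord(pd.DataFrame(rows))


def gen_lick_stream(
    session_s: float,
    bout_rate_per_min: float,
    licks_per_bout_mean: float,
    within_bout_ili_s: float = 0.15,
    min_bout_licks: int = 3,
    gap_floor_s: float = 2.0,
    ili_jitter: float = 0.2,
    spout: str = "alcohol",
    seed: int = 0,
    n_bouts: int | None = None,
    **stream_kwargs,
) -> tuple[LickStream, pd.DataFrame]:
    """Generate a bout-structured lick stream plus its ground-truth bouts.

    Bout count is Poisson(rate x duration) unless ``n_bouts`` pins it;
    licks per bout are ``min_bout_licks + Poisson(mean - min)``; within-bout
    inter-lick intervals are ``within_bout_ili_s`` with multiplicative
    jitter, and bouts are separated by gaps >= ``gap_floor_s`` (free time
    is spread over the gaps by a Dirichlet draw).  Ground truth has one row
    per bout: start_s, end_s, n_licks.

    Raises a configuration error when the requested bouts cannot fit in the
    session with the declared gap floor, or when the within-bout interval
    does not stay strictly below the gap floor.
    """
    # the gap floor is 2x the intended segmentation threshold, so within-bout
    # intervals must stay at or below gap_floor/2 even after jitter
    if within_bout_ili_s * (1 + 3 * ili_jitter) >= 0.5 * gap_floor_s:
        raise ValueError(
            "within-bout inter-lick interval (with jitter) must stay below "
            "half the between-bout gap floor"
        )
    if licks_per_bout_mean < min_bout_licks:
        raise ValueError("licks_per_bout_mean must be >= min_bout_licks")
    rng = np.random.default_rng(seed)
    if n_bouts is None:
        n_bouts = int(rng.poisson(bout_rate_per_min * session_s / 60.0))
    if n_bouts == 0:
        stream = LickStream(np.array([]), spout, **stream_kwargs)
        gt = pd.DataFrame(columns=["start_s", "end_s", "n_licks"])
        return stream, gt

    extra = licks_per_bout_mean - min_bout_licks
    counts = min_bout_licks + (
        rng.poisson(extra, size=n_bouts) if extra > 0 else np.zeros(n_bouts, int)
    )
    # within-bout ILIs, jittered but capped below the gap floor
    ilis = [
        np.clip(
            within_bout_ili_s * (1 + ili_jitter * rng.standard_normal(c - 1)),
            0.25 * within_bout_ili_s,
            0.5 * gap_floor_s,
        )
        for c in counts
    ]
    durations = np.array([x.sum() for x in ilis])
    required = durations.sum() + gap_floor_s * (n_bouts - 1)
    free = session_s - required
    if free <= 0:
        raise ValueError(
            f"{n_bouts} bouts with gap floor {gap_floor_s}s do not fit in "
            f"{session_s}s"
        )
    slack = free * rng.dirichlet(np.ones(n_bouts + 1))
    starts = np.empty(n_bouts)
    t = slack[0]
    rows = []
    times = []
    for i in range(n_bouts):
        starts[i] = t
        lick_t = t + np.concatenate([[0.0], np.cumsum(ilis[i])])
        times.append(lick_t)
        rows.append(
            {"start_s": lick_t[0], "end_s": lick_t[-1], "n_licks": int(counts[i])}
        )
        t = lick_t[-1] + gap_floor_s + slack[i + 1]
    stream = LickStream(np.concatenate(times), spout, **stream_kwargs)
    return stream, pd.DataFrame(rows)


def gen_pose_session(
    duration_s: float,
    fps: float,
    episodes: list[tuple[float, float]],
    arena_px: tuple[float, float] = (400.0, 400.0),
    jitter_px: float = 1.0,
    seed: int = 0,
) -> tuple[PoseSession, pd.DataFrame]:
    """Generate a resident-intruder pose session with scripted contact.

    During each planted episode the intruder body sits 20-45 px from the
    resident head within an 80 deg cone of the heading; outside episodes it
    stays >= 80 px away, violating the distance criterion.  Keypoint jitter
    is Gaussian truncated at +/-3 px and keypoints are clipped to the
    arena.  Ground truth lists the episode intervals and their frame
    spans.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    eps = sorted(episodes)
    for (s0, e0) in eps:
        if not (0 <= s0 < e0 <= duration_s):
            raise ValueError(f"episode ({s0}, {e0}) outside session")
    for (_, e0), (s1, _) in zip(eps, eps[1:]):
        if s1 < e0:
            raise ValueError("episodes must not overlap")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    w, h = arena_px
    if min(w, h) < 260:
        raise ValueError("arena must be at least 260 px on each side")
    margin = 110.0  # keeps episode-frame intruder placements inside the arena

    # resident: smooth random walk reflected inside the arena interior,
    # heading vector 20 px long
    body = np.empty((n, 2))
    body[0] = (w / 2, h / 2)
    steps = rng.normal(0, 2.0, size=(n - 1, 2))
    body[1:] = body[0] + np.cumsum(steps, axis=0)
    body[:, 0] = margin + np.abs((body[:, 0] - margin) % (2 * (w - 2 * margin))
                                 - (w - 2 * margin))
    body[:, 1] = margin + np.abs((body[:, 1] - margin) % (2 * (h - 2 * margin))
                                 - (h - 2 * margin))
    theta = np.cumsum(rng.normal(0, 0.2, size=n))  # heading direction
    heading = np.column_stack([np.cos(theta), np.sin(theta)])
    head = body + 20.0 * heading

    in_episode = np.zeros(n, dtype=bool)
    gt_rows = []
    for (s0, e0) in eps:
        f0, f1 = int(round(s0 * fps)), int(round(e0 * fps))
        in_episode[f0:f1] = True
        gt_rows.append(
            {"start_s": s0, "end_s": e0, "start_frame": f0, "end_frame": f1}
        )

    # episode frames: intruder 20-45 px from the head, within an 80 deg cone
    # of the heading — margins absorb the (truncated) keypoint jitter
    dist = rng.uniform(20, 45, n)
    ang = rng.uniform(-np.pi * 80 / 180, np.pi * 80 / 180, n)
    direction = theta + ang
    intruder = head + dist[:, None] * np.column_stack(
        [np.cos(direction), np.sin(direction)]
    )
    # non-episode frames: uniform over the arena, resampled until >= 74 px
    # from the head so the distance criterion is violated even after jitter
    far = ~in_episode
    while far.any():
        idx = np.flatnonzero(far)
        cand = rng.uniform([0, 0], [w, h], size=(idx.size, 2))
        ok = np.linalg.norm(cand - head[idx], axis=1) >= 74.0
        intruder[idx[ok]] = cand[ok]
        far[idx[ok]] = False

    def jitter(points: np.ndarray) -> np.ndarray:
        j = np.clip(rng.normal(0, jitter_px, points.shape), -3.0, 3.0)
        out = points + j
        out[:, 0] = np.clip(out[:, 0], 0, w)
        out[:, 1] = np.clip(out[:, 1], 0, h)
        return out

    session = PoseSession(fps, jitter(head), jitter(body), jitter(intruder))
    gt = pd.DataFrame(gt_rows, columns=["start_s", "end_s", "start_frame", "end_frame"])
    return session, gt


def gen_calcium_population(
    n_neurons: int,
    event_times_s: dict[str, np.ndarray] | np.ndarray,
    duration_s: float,
    frac_excited: float = 0.2,
    frac_inhibited: float = 0.1,
    amplitude_z: float = 3.0,
    kernel_tau_s: float = 1.0,
    noise_sd: float = 1.0,
    fps: float = 20.0,
    disjoint_ensembles: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate an imaged population with event-locked responses.

    Excited neurons add ``+amplitude_z`` (in noise-SD units) times an
    exponential decay kernel at each of their class's events; inhibited
    neurons the negative; the rest are pure noise.  With
    ``disjoint_ensembles`` each event class recruits its own
    non-overlapping neuron sets.  Returns (traces [neurons x frames],
    frame_times_s, ground truth with neuron_id / event_class / response /
    amplitude_z).
    """
    if not isinstance(event_times_s, dict):
        event_times_s = {"event": np.asarray(event_times_s, dtype=float)}
    if frac_excited < 0 or frac_inhibited < 0 or frac_excited + frac_inhibited > 1:
        raise ValueError("response fractions must be >= 0 and sum to <= 1")
    if fps <= 0:
        raise ValueError("fps must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fps))
    ft = np.arange(n_frames) / fps
    traces = noise_sd * rng.standard_normal((n_neurons, n_frames))

    kernel_len = int(round(10 * kernel_tau_s * fps)) + 1
    kernel = np.exp(-np.arange(kernel_len) / (kernel_tau_s * fps))

    classes = list(event_times_s)
    n_exc = int(round(frac_excited * n_neurons))
    n_inh = int(round(frac_inhibited * n_neurons))
    pool = rng.permutation(n_neurons)
    gt_rows = []
    cursor = 0
    for ci, cls in enumerate(classes):
        if disjoint_ensembles:
            take = pool[cursor: cursor + n_exc + n_inh]
            cursor += n_exc + n_inh
            if take.size < n_exc + n_inh:
                raise ValueError("not enough neurons for disjoint class ensembles")
        else:
            take = rng.permutation(n_neurons)[: n_exc + n_inh]
        exc, inh = take[:n_exc], take[n_exc: n_exc + n_inh]
        impulse = np.zeros(n_frames)
        idx = np.clip(np.round(np.asarray(event_times_s[cls]) * fps).astype(int),
                      0, n_frames - 1)
        impulse[idx] = 1.0
        transient = np.convolve(impulse, kernel)[:n_frames]
        traces[exc] += amplitude_z * transient
        traces[inh] -= amplitude_z * transient
        resp = np.full(n_neurons, "none", dtype=object)
        resp[exc], resp[inh] = "excited", "inhibited"
        amp = np.zeros(n_neurons)
        amp[exc], amp[inh] = amplitude_z, -amplitude_z
        for i in range(n_neurons):
            gt_rows.append(
                {"neuron_id": i, "event_class": cls,
                 "response": resp[i], "amplitude_z": amp[i]}
            )
    return traces, ft, pd.DataFrame(gt_rows)


def gen_identity_map(
    n_sessions: int,
    n_neurons_per_session: int,
    coregistration_rate: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate cross-session cell registration with a set tracking rate.

    Each of ``n_neurons_per_session`` global cells is co-registered across
    all sessions with probability ``coregistration_rate``; otherwise it
    appears in a strict, non-empty subset of sessions.  Returns rows
    (global_id, session, local_id); local ids are per-session indices.
    """
    if not 0 <= coregistration_rate <= 1:
        raise ValueError("coregistration_rate must be in [0, 1]")
    if n_sessions < 1 or n_neurons_per_session < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_sessions, dtype=int)
    target = n_neurons_per_session
    rows = []
    # fully tracked cells: Binomial(per-session count, rate) of the quota
    if n_sessions == 1:
        n_full = target
    else:
        n_full = int(rng.binomial(target, coregistration_rate))
    for gid in range(n_full):
        for s in range(n_sessions):
            rows.append({"global_id": gid, "session": s, "local_id": int(counts[s])})
            counts[s] += 1
    # partial cells fill each session's remaining quota over strict subsets
    gid = n_full
    while (counts < target).any():
        open_sessions = np.flatnonzero(counts < target)
        k_max = min(n_sessions - 1, open_sessions.size)
        k = int(rng.integers(1, k_max + 1))
        sess = np.sort(rng.choice(open_sessions, size=k, replace=False))
        for s in sess:
            rows.append(
                {"global_id": gid, "session": int(s), "local_id": int(counts[s])}
            )
            counts[s] += 1
        gid += 1
    return pd.DataFrame(rows)


def gen_cohort(config: CohortConfig) -> dict:
    """Generate a full drinking cohort: tournaments, ranks, lick streams.

    Returns a dict with ``tournaments`` (per cage), ``mice`` (DataFrame of
    mouse, cage, true rank), and ``streams``: one (LickStream, ground-truth
    bouts) per mouse x condition x spout, with alcohol totals following the
    planted rank / isolation / interaction structure.  Subordinate ranks
    (upper half) escalate under isolation via licks per bout at a fixed
    bout count; dominant ranks via bout number at fixed licks per bout.
    """
    rng = np.random.default_rng(config.seed)
    lam = config.bout_rate_per_min * config.session_s / 60.0
    tournaments = {}
    mice_rows = []
    streams = {}
    for cage in range(config.n_cages):
        mice = [f"c{cage}m{i}" for i in range(config.mice_per_cage)]
        tournaments[cage] = gen_tournament(
            mice,
            days=config.tournament_days,
            meetings_per_day=config.meetings_per_day,
            skill_spread=config.skill_spread,
            seed=int(rng.integers(2**31)),
        )
        for i, m in enumerate(mice):
            rank = i + 1
            mice_rows.append({"mouse": m, "cage": cage, "rank": rank})
            subordinate = rank > config.mice_per_cage / 2
            for condition in ("pre_SI", "SI"):
                iso = condition == "SI"
                for spout in ("alcohol", "water"):
                    if spout == "alcohol":
                        target = config.expected_licks(rank, iso)
                    else:
                        target = config.base_licks_water
                    target = max(target, config.min_bout_licks + 1.0)
                    if spout == "water" or not iso or subordinate:
                        # fixed bout count; licks-per-bout carries the effect
                        n_b = max(int(rng.poisson(lam)), 1)
                        lpb = max(target / lam, float(config.min_bout_licks))
                        pinned = n_b
                    else:
                        # dominant escalation: bout number carries the effect
                        lpb = max(
                            config.expected_licks(rank, False) / lam,
                            float(config.min_bout_licks),
                        )
                        n_b = max(int(rng.poisson(target / lpb)), 1)
                        pinned = n_b
                    streams[(m, condition, spout)] = gen_lick_stream(
                        config.session_s,
                        config.bout_rate_per_min,
                        licks_per_bout_mean=lpb,
                        within_bout_ili_s=config.within_bout_ili_s,
                        min_bout_licks=config.min_bout_licks,
                        gap_floor_s=config.gap_floor_s,
                        spout=spout,
                        seed=int(rng.integers(2**31)),
                        n_bouts=pinned,
                        mouse=m,
                        condition=condition,
                    )
    return {
        "tournaments": tournaments,
        "mice": pd.DataFrame(mice_rows),
        "streams": streams,
        "config": config,
    }
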