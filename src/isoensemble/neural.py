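"""Peri-event calcium analysis: alignment, Z-scoring, classification, clustering.

Activity traces are excerpted around behavioral events (bout onsets, cue
lights, interaction onsets) into a neurons x trials x time-bin tensor,
baseline-normalized per neuron.  Neurons are classified excited / inhibited
/ non-responsive by a Wilcoxon signed-rank test on per-trial response-minus-
baseline differences combined with a +/-1.98 criterion on the standardized
mean response.  Trial-averaged time courses are grouped by agglomerative
(Ward) clustering, and cluster composition is compared between neuron
groups (e.g. non-specific vs projection-specific) with size-normalized
proportions and a chi-square contingency test.

Note on the +/-1.98 rule: 1.98 is the ~95% two-sided critical value of a
standard normal / large-df t, so the magnitude criterion is applied to the
*standardized* mean response (mean per-trial response-minus-baseline
difference divided by its standard error across trials), which is ~N(0,1)
for an unmodulated neuron.  Applied to a raw pooled-sample mean Z the rule
would have essentially zero power and zero false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "PeriEventTensor",
    "FunctionalClustering",
    "align_events",
    "zscore_baseline",
    "classify_responses",
    "population_mean_response",
    "cluster_functional",
    "cluster_enrichment",
]

DEGENERACY_EPS = 1e-6


@dataclass
class PeriEventTensor:
    """Neurons x trials x time-bin activity around an event class.

    ``bin_edges_s`` are relative to the event; ``baseline_window`` must
    precede the event and be disjoint from ``response_window``.
    ``normalized`` records whether values are baseline Z units.
    """

    values: np.ndarray
    bin_edges_s: np.ndarray
    event_class: str
    neuron_ids: np.ndarray
    baseline_window: tuple[float, float]
    response_window: tuple[float, float]
    normalized: bool = False
    n_dropped_trials: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be neurons x trials x bins")
        self.bin_edges_s = np.asarray(self.bin_edges_s, dtype=float)
        if self.bin_edges_s.size != self.values.shape[2] + 1:
            raise ValueError("bin edge count must be n_bins + 1")
        self.neuron_ids = np.asarray(self.neuron_ids)
        if self.neuron_ids.size != self.values.shape[0]:
            raise ValueError("one neuron id per tensor row required")
        if np.unique(self.neuron_ids).size != self.neuron_ids.size:
            raise ValueError("neuron ids must be unique")
        b0, b1 = self.baseline_window
        r0, r1 = self.response_window
        if not (b0 < b1 <= 0):
            raise ValueError("baseline window must precede the event")
        if not (b1 <= r0 < r1):
            raise ValueError("baseline and response windows must be disjoint")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])

    def _window_cols(self, window: tuple[float, float]) -> np.ndarray:
        c = self.bin_centers_s
        return (c >= window[0]) & (c < window[1])

    @property
    def baseline_cols(self) -> np.ndarray:
        return self._window_cols(self.baseline_window)

    @property
    def response_cols(self) -> np.ndarray:
        return self._window_cols(self.response_window)


@dataclass
class FunctionalClustering:
    """Agglomerative clustering of trial-averaged neuron time courses."""

    cluster_ids: np.ndarray  # per neuron, 1..k, relabeled by descending peak
    linkage_tree: np.ndarray
    cluster_means: pd.DataFrame  # cluster x time-bin mean time course
    neuron_ids: np.ndarray

    @property
    def k(self) -> int:
        return int(self.cluster_ids.max())


def align_events(
    traces: np.ndarray,
    frame_times_s: np.ndarray,
    event_times_s: np.ndarray,
    event_class: str = "event",
    baseline_window: tuple[float, float] = (-5.0, 0.0),
    response_window: tuple[float, float] = (0.0, 5.0),
    bin_s: float = 0.25,
    neuron_ids: np.ndarray | None = None,
) -> PeriEventTensor:
    """Excerpt per-neuron activity around events into fixed time bins.

    Each trial's samples are averaged within ``bin_s``-wide bins spanning
    the baseline and response windows.  Events whose window is not fully
    covered by the recording are dropped (counted in ``n_dropped_trials``).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    ft = np.asarray(frame_times_s, dtype=float)
    if traces.shape[1] != ft.size:
        raise ValueError("traces and frame_times must have equal length")
    if not np.all(np.diff(ft) > 0):
        raise ValueError("frame times must be strictly increasing")
    t0, t1 = baseline_window[0], response_window[1]
    edges = np.arange(t0, t1 + bin_s / 2, bin_s)
    n_bins = edges.size - 1

    events = np.asarray(event_times_s, dtype=float)
    usable = (events + t0 >= ft[0]) & (events + t1 <= ft[-1])
    dropped = int((~usable).sum())
    events = events[usable]
    if events.size == 0:
        raise ValueError("no event window fully covered by the recording")

    n_neurons = traces.shape[0]
    out = np.empty((n_neurons, events.size, n_bins))
    for j, ev in enumerate(events):
        rel = ft - ev
        idx = np.searchsorted(edges, rel, side="right") - 1
        inside = (idx >= 0) & (idx < n_bins)
        cols = idx[inside]
        counts = np.bincount(cols, minlength=n_bins)
        if (counts == 0).any():
            raise ValueError("bin width too small for the sampling rate")
        sums = np.zeros((n_neurons, n_bins))
        np.add.at(sums.T, cols, traces[:, inside].T)
        out[:, j, :] = sums / counts
    if neuron_ids is None:
        neuron_ids = np.arange(n_neurons)
    return PeriEventTensor(
        out, edges, event_class, np.asarray(neuron_ids),
        baseline_window, response_window,
        normalized=False, n_dropped_trials=dropped,
    )


def zscore_baseline(tensor: PeriEventTensor) -> PeriEventTensor:
    """Baseline-normalize a tensor to Z units, per neuron.

    mu and sigma are pooled over all baseline bins across trials (sample
    SD, ddof=1).  Neurons with sigma below the degeneracy guard are
    excluded from the output.
    """
    base = tensor.values[:, :, tensor.baseline_cols]
    if base.shape[2] == 0:
        raise ValueError("no baseline bins present")
    mu = base.reshape(tensor.n_neurons, -1).mean(axis=1)
    sd = base.reshape(tensor.n_neurons, -1).std(axis=1, ddof=1)
    keep = sd > DEGENERACY_EPS
    if not keep.any():
        raise ValueError("all neurons have degenerate (constant) baselines")
    z = (tensor.values[keep] - mu[keep, None, None]) / sd[keep, None, None]
    return replace(
        tensor, values=z, neuron_ids=tensor.neuron_ids[keep], normalized=True
    )


def response_statistics(tensor: PeriEventTensor) -> pd.DataFrame:
    """Per-neuron per-trial response-minus-baseline summary statistics.

    Returns mean_diff (Z), its standard error over trials, the standardized
    mean response ``z_score`` = mean_diff / SE, and the Wilcoxon signed-rank
    p-value over per-trial differences.
    """
    resp = tensor.values[:, :, tensor.response_cols].mean(axis=2)
    base = tensor.values[:, :, tensor.baseline_cols].mean(axis=2)
    diffs = resp - base  # neurons x trials
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    se = diffs.std(axis=1, ddof=1) / np.sqrt(n)
    rows = []
    for i in range(diffs.shape[0]):
        d = diffs[i]
        if np.allclose(d, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(d).pvalue)
        z = mean[i] / se[i] if se[i] > 0 else 0.0
        rows.append(
            {
                "neuron_id": tensor.neuron_ids[i],
                "mean_diff_z": float(mean[i]),
                "z_score": float(z),
                "p_value": p,
                "n_trials": n,
            }
        )
    return pd.DataFrame(rows)


def classify_responses(
    tensor: PeriEventTensor,
    alpha: float = 0.05,
    z_thresh: float = 1.98,
    min_trials: int = 5,
) -> pd.DataFrame:
    """Label each neuron excited / inhibited / none for this event class.

    excited:   Wilcoxon p <= alpha AND standardized mean response >= +z_thresh
    inhibited: Wilcoxon p <= alpha AND standardized mean response <= -z_thresh
    none otherwise.  With fewer than ``min_trials`` trials every neuron is
    labeled none (reason recorded in the ``note`` column).
    """
    if tensor.n_trials < min_trials:
        return pd.DataFrame(
            {
                "neuron_id": tensor.neuron_ids,
                "event_class": tensor.event_class,
                "label": "none",
                "z_score": np.nan,
                "p_value": np.nan,
                "note": f"fewer than {min_trials} trials",
            }
        )
    st = response_statistics(tensor)
    label = np.full(len(st), "none", dtype=object)
    sig = st["p_value"] <= alpha
    label[sig & (st["z_score"] >= z_thresh)] = "excited"
    label[sig & (st["z_score"] <= -z_thresh)] = "inhibited"
    st = st.assign(event_class=tensor.event_class, label=label, note="")
    return st[["neuron_id", "event_class", "label", "z_score", "p_value",
               "mean_diff_z", "n_trials", "note"]]


def population_mean_response(
    tensor_a: PeriEventTensor,
    tensor_b: PeriEventTensor | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> dict:
    """Neuron-averaged time course(s) with SEM, plus a condition x time ANOVA.

    With two tensors (same binning), fits a two-way ANOVA of per-neuron
    per-bin values on condition x time bin — the population-level contrast
    used for isolation or stimulation effects on event responses.
    """
    def timecourse(t: PeriEventTensor) -> pd.DataFrame:
        per_neuron = t.values.mean(axis=1)  # neurons x bins
        return pd.DataFrame(
            {
                "time_s": t.bin_centers_s,
                "mean": per_neuron.mean(axis=0),
                "sem": per_neuron.std(axis=0, ddof=1) / np.sqrt(t.n_neurons),
            }
        )

    out = {"timecourse": {labels[0]: timecourse(tensor_a)}}
    if tensor_b is None:
        return out
    if not np.allclose(tensor_a.bin_edges_s, tensor_b.bin_edges_s):
        raise ValueError("tensors must share binning for a population contrast")
    out["timecourse"][labels[1]] = timecourse(tensor_b)

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    frames = []
    for lab, t in zip(labels, (tensor_a, tensor_b)):
        per_neuron = t.values.mean(axis=1)
        n, b = per_neuron.shape
        frames.append(
            pd.DataFrame(
                {
                    "value": per_neuron.ravel(),
                    "time_bin": np.tile(np.arange(b), n),
                    "condition": lab,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    model = smf.ols("value ~ C(condition) * C(time_bin)", data=df).fit()
    table = anova_lm(model, typ=2)
    out["anova"] = {
        "condition": {
            "F": float(table.loc["C(condition)", "F"]),
            "p": float(table.loc["C(condition)", "PR(>F)"]),
        },
        "time": {
            "F": float(table.loc["C(time_bin)", "F"]),
            "p": float(table.loc["C(time_bin)", "PR(>F)"]),
        },
        "interaction": {
            "F": float(table.loc["C(condition):C(time_bin)", "F"]),
            "p": float(table.loc["C(condition):C(time_bin)", "PR(>F)"]),
        },
    }
    return out


def cluster_functional(
    timecourses: np.ndarray,
    k: int = 9,
    neuron_ids: np.ndarray | None = None,
) -> FunctionalClustering:
    """Hierarchically cluster trial-averaged time courses into k clusters.

    Each time course is standardized (zero mean, unit SD) so that squared
    Euclidean distance is a monotone transform of correlation distance,
    then Ward linkage is cut at k clusters.  Cluster ids are relabeled by
    descending cluster-mean peak, so cluster 1 has the strongest
    activation motif.  Deterministic and neuron-order invariant for
    distinct inputs.
    """
    X = np.atleast_2d(np.asarray(timecourses, dtype=float))
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < k:
        raise ValueError("need at least k neurons to form k clusters")
    if neuron_ids is None:
        neuron_ids = np.arange(X.shape[0])
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] <= DEGENERACY_EPS
    Xs = np.where(flat[:, None], 0.0, (X - mu) / np.where(sd == 0, 1.0, sd))
    tree = linkage(Xs, method="ward")
    raw = fcluster(tree, t=k, criterion="maxclust")
    # relabel clusters by descending peak of the raw (unstandardized) mean
    peaks = {c: X[raw == c].mean(axis=0).max() for c in np.unique(raw)}
    order = sorted(peaks, key=lambda c: (-peaks[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    ids = np.array([remap[c] for c in raw])
    means = pd.DataFrame(
        [X[ids == c].mean(axis=0) for c in range(1, len(order) + 1)],
        index=pd.Index(range(1, len(order) + 1), name="cluster"),
    )
    return FunctionalClustering(ids, tree, means, np.asarray(neuron_ids))


def cluster_enrichment(
    clustering: FunctionalClustering, group_labels: np.ndarray
) -> dict:
    """Group composition of each functional cluster, normalized by group size.

    For cluster c and group g the normalized proportion is
    (n_cg / N_g) / sum_g' (n_cg' / N_g'), which is 1/n_groups for all
    groups when composition simply reflects sampling.  A chi-square test of
    the cluster x group contingency table (expected counts proportional to
    group sizes) tests for enrichment.
    """
    groups = np.asarray(group_labels)
    if groups.size != clustering.cluster_ids.size:
        raise ValueError("one group label per neuron required")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("enrichment needs >= 2 groups")
    n_g = {g: int((groups == g).sum()) for g in uniq}
    if min(n_g.values()) == 0:
        raise ValueError("empty group")
    rows = []
    table = []
    for c in range(1, clustering.k + 1):
        in_c = clustering.cluster_ids == c
        counts = {g: int((groups[in_c] == g).sum()) for g in uniq}
        rates = {g: counts[g] / n_g[g] for g in uniq}
        denom = sum(rates.values())
        props = {g: (rates[g] / denom if denom > 0 else np.nan) for g in uniq}
        rows.append({"cluster": c, **{f"n_{g}": counts[g] for g in uniq},
                     **{f"prop_{g}": props[g] for g in uniq}})
        table.append([counts[g] for g in uniq])
    table = np.array(table)
    keep = table.sum(axis=1) > 0
    chi2, p, dof, _ = stats.chi2_contingency(table[keep], correction=False)
    return {
        "proportions": pd.DataFrame(rows),
        "chi2": float(chi2),
        "p": float(p),
        "dof": int(dof),
        "groups": list(uniq),
    }
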