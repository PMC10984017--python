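"""Pseudo-simultaneous population decoding with a linear SVM.

Neurons recorded in different animals/sessions are combined into a
pseudo-simultaneous population: per resample, every neuron independently
contributes ``n_trials_per_class`` trials drawn with replacement from its
own trials of each class, and the resulting pseudo-trial x neuron feature
matrix (mean baseline-Z in a feature window) is decoded with a linear SVM
under stratified cross-validation.  Chance level is established by
within-resample label shuffles, and group decoding accuracies (e.g. all
BLA vs non-specific vs projection-specific, or pre- vs during-isolation)
are compared with Kruskal-Wallis / rank-sum tests.

Pseudo-trials are artificial conjunctions — trial-to-trial noise
correlations between neurons from different animals are destroyed by
construction, which typically inflates decodable information relative to
truly simultaneous populations.

Leakage control: pseudo-trials are built *within cross-validation folds* of
each neuron's real trials.  Naive resampling lets the same real trial feed
both training and held-out pseudo-trials, which decodes class-independent
features well above chance (finite-sample class-mean differences become
learnable); partitioning real trials into folds first restores an unbiased
chance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import PredefinedSplit, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .neural import PeriEventTensor

__all__ = [
    "PseudoPopulationDataset",
    "build_pseudopopulation",
    "decode",
    "shuffle_control",
    "compare_decoders",
]


@dataclass
class PseudoPopulationDataset:
    """Resampled pseudo-simultaneous feature matrices with class labels.

    ``resamples`` is a list of (X, y): X is pseudo-trials x neurons, y the
    class labels (balanced by construction).  ``fold_ids`` assigns each
    pseudo-trial of each resample to a cross-validation fold: the
    pseudo-trials of fold f were drawn only from each neuron's real trials
    in fold f, so held-out folds never share real trials with training
    folds.  ``provenance`` records each neuron's animal index and group
    label.
    """

    resamples: list[tuple[np.ndarray, np.ndarray]]
    fold_ids: list[np.ndarray]
    provenance: pd.DataFrame
    classes: tuple[str, str]
    n_trials_per_class: int
    cv_folds: int
    seed: int
    n_excluded_neurons: int = 0

    def __post_init__(self) -> None:
        for X, y in self.resamples:
            if not np.isfinite(X).all():
                raise ValueError("features must be finite")
            _, counts = np.unique(y, return_counts=True)
            if counts.size != 2 or counts[0] != counts[1]:
                raise ValueError("classes must be balanced within each resample")

    @property
    def n_neurons(self) -> int:
        return len(self.provenance)


def _trial_features(tensor: PeriEventTensor, window: tuple[float, float]) -> np.ndarray:
    """Per-neuron per-trial mean activity in the feature window."""
    c = tensor.bin_centers_s
    cols = (c >= window[0]) & (c < window[1])
    if not cols.any():
        raise ValueError("feature window contains no bins")
    return tensor.values[:, :, cols].mean(axis=2)  # neurons x trials


def build_pseudopopulation(
    animal_tensors: list[dict[str, PeriEventTensor]],
    classes: tuple[str, str],
    feature_window: tuple[float, float] = (0.0, 5.0),
    n_trials_per_class: int = 20,
    n_resamples: int = 100,
    min_trials: int = 5,
    cv_folds: int = 5,
    groups: list[str] | None = None,
    seed: int = 0,
) -> PseudoPopulationDataset:
    """Assemble pseudo-simultaneous populations from per-animal tensors.

    ``animal_tensors`` maps each animal to one tensor per event class;
    neurons with fewer than ``min_trials`` trials for either class are
    excluded (count recorded).  Per resample, each neuron's real trials
    are first partitioned into ``cv_folds`` groups, then each fold's
    pseudo-trials are sampled with replacement from that group only —
    independently per class and per neuron, never crossing animals.
    """
    if classes[0] == classes[1]:
        raise ValueError("need two distinct classes")
    if n_trials_per_class < cv_folds:
        raise ValueError("n_trials_per_class must be >= cv_folds")
    min_trials = max(min_trials, cv_folds)
    rng = np.random.default_rng(seed)
    feats: list[tuple[np.ndarray, np.ndarray]] = []  # per neuron: class-0/1 trials
    prov_rows = []
    n_excluded = 0
    for ai, tensors in enumerate(animal_tensors):
        f0 = _trial_features(tensors[classes[0]], feature_window)
        f1 = _trial_features(tensors[classes[1]], feature_window)
        ids0 = tensors[classes[0]].neuron_ids
        ids1 = tensors[classes[1]].neuron_ids
        common, i0, i1 = np.intersect1d(ids0, ids1, return_indices=True)
        n_excluded += (ids0.size - common.size) + (ids1.size - common.size)
        if f0.shape[1] < min_trials or f1.shape[1] < min_trials:
            n_excluded += common.size
            continue
        for ci, (r0, r1) in enumerate(zip(f0[i0], f1[i1])):
            feats.append((r0, r1))
            prov_rows.append(
                {
                    "animal": ai,
                    "neuron_id": common[ci],
                    "group": groups[ai] if groups is not None else "all",
                }
            )
    if not feats:
        raise ValueError("no eligible neurons for pseudo-population")

    n = n_trials_per_class
    labels = np.array([classes[0]] * n + [classes[1]] * n)
    # pseudo-trial slot -> fold, identical for both classes (balanced folds)
    slot_folds = np.arange(n) * cv_folds // n
    fold_vec = np.concatenate([slot_folds, slot_folds])
    resamples = []
    fold_ids = []
    for _ in range(n_resamples):
        X = np.empty((2 * n, len(feats)))
        for j, (r0, r1) in enumerate(feats):
            for cls_offset, r in ((0, r0), (n, r1)):
                groups_f = np.array_split(rng.permutation(r.size), cv_folds)
                for f in range(cv_folds):
                    slots = cls_offset + np.flatnonzero(slot_folds == f)
                    pool = r[groups_f[f]]
                    X[slots, j] = rng.choice(pool, size=slots.size, replace=True)
        resamples.append((X, labels.copy()))
        fold_ids.append(fold_vec.copy())
    return PseudoPopulationDataset(
        resamples,
        fold_ids,
        pd.DataFrame(prov_rows),
        tuple(classes),
        n,
        cv_folds,
        seed,
        n_excluded_neurons=n_excluded,
    )


def _cv_accuracy(X: np.ndarray, y: np.ndarray, fold_vec: np.ndarray, C: float) -> float:
    clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
    cv = PredefinedSplit(fold_vec)
    return float(cross_val_score(clf, X, y, cv=cv).mean())


def decode(
    dataset: PseudoPopulationDataset,
    folds: int = 5,
    C: float = 1.0,
    group: str = "all",
) -> pd.DataFrame:
    """Cross-validated linear-SVM accuracy for each resample.

    Cross-validation follows the real-trial fold partition fixed at
    construction time (``folds`` must match the dataset's ``cv_folds``);
    features are standardized inside each training fold only (pipeline), so
    no test-set statistics leak into training.  Returns one row per
    resample with the mean held-out accuracy.  Deterministic given the
    dataset.
    """
    if dataset.n_trials_per_class < folds:
        raise ValueError("need at least `folds` trials per class")
    if folds != dataset.cv_folds:
        raise ValueError(
            f"folds={folds} does not match the dataset's real-trial "
            f"partition (cv_folds={dataset.cv_folds})"
        )
    rows = []
    for i, (X, y) in enumerate(dataset.resamples):
        acc = _cv_accuracy(X, y, dataset.fold_ids[i], C)
        rows.append({"resample": i, "group": group, "accuracy": acc})
    return pd.DataFrame(rows)


def shuffle_control(
    dataset: PseudoPopulationDataset,
    n_shuffles: int = 100,
    folds: int = 5,
    C: float = 1.0,
    observed: pd.DataFrame | None = None,
    seed: int = 0,
) -> dict:
    """Label-shuffle null distribution for decoding accuracy.

    Class labels are permuted within each resample before cross-validation.
    Returns the null accuracies and, when ``observed`` is given, the
    empirical p-value (1 + #null >= observed mean) / (1 + n_null).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    null = []
    for k in range(n_shuffles):
        i = int(rng.integers(len(dataset.resamples)))
        X, y = dataset.resamples[i]
        y_perm = rng.permutation(y)
        null.append(_cv_accuracy(X, y_perm, dataset.fold_ids[i], C))
    null = np.asarray(null)
    out = {"null_accuracies": null, "null_mean": float(null.mean())}
    if observed is not None:
        obs = float(observed["accuracy"].mean())
        out["observed_mean"] = obs
        out["p_empirical"] = float((1 + (null >= obs).sum()) / (1 + null.size))
    return out


def compare_decoders(results: dict[str, pd.DataFrame], correction: str = "holm") -> dict:
    """Compare resample accuracy distributions across decoder groups.

    Kruskal-Wallis omnibus across >= 2 groups; with exactly two groups the
    pairwise Mann-Whitney rank-sum test is the reported contrast.  Pairwise
    post hoc p-values carry the named multiplicity correction.
    """
    from statsmodels.stats.multitest import multipletests

    if len(results) < 2:
        raise ValueError("need >= 2 groups to compare")
    names = list(results)  # caller's ordering defines contrast direction
    samples = [results[g]["accuracy"].to_numpy() for g in names]
    H, p = stats.kruskal(*samples)
    pairs, praw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            U, pu = stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            pairs.append({"a": names[i], "b": names[j], "U": float(U), "p_raw": float(pu)})
            praw.append(pu)
    adj = multipletests(praw, method=correction)[1]
    for row, pa in zip(pairs, adj):
        row["p_adj"] = float(pa)
    return {
        "groups": names,
        "means": {g: float(np.mean(s)) for g, s in zip(names, samples)},
        "omnibus": {"H": float(H), "p": float(p)},
        "pairwise": pairs,
        "correction": correction,
    }
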