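"""Peri-event alignment, Z-scoring, response classification, clustering."""

import numpy as np
import pandas as pd
import pytest

from isoensemble.neural import (
    PeriEventTensor,
    align_events,
    classify_responses,
    cluster_enrichment,
    cluster_functional,
    population_mean_response,
    zscore_baseline,
)
from isoensemble.synth import gen_calcium_population


def direct_alignment_oracle(trace, ft, event, edges):
    """Average raw samples into peri-event bins by explicit looping."""
    out = np.empty(edges.size - 1)
    for b in range(edges.size - 1):
        lo, hi = event + edges[b], event + edges[b + 1]
        sel = (ft >= lo) & (ft < hi)
        out[b] = trace[sel].mean()
    return out


class TestAlignment:
    def test_constant_trace_gives_constant_bins(self):
        ft = np.arange(0, 100, 0.05)
        traces = np.full((1, ft.size), 7.0)
        t = align_events(traces, ft, [50.0])
        assert np.allclose(t.values, 7.0)

    def test_planted_transient_peaks_just_after_event(self):
        ev = np.array([40.0])
        traces, ft, _ = gen_calcium_population(
            5, ev, duration_s=80.0, frac_excited=1.0, frac_inhibited=0.0,
            amplitude_z=5.0, noise_sd=0.1, seed=0
        )
        t = align_events(traces, ft, ev)
        peak_bin = t.values.mean(axis=(0, 1)).argmax()
        assert t.bin_centers_s[peak_bin] == pytest.approx(0.125, abs=0.26)

    def test_matches_direct_indexing_oracle(self, rng):
        ft = np.arange(0, 60, 1 / 20)
        traces = rng.standard_normal((3, ft.size))
        events = [10.0, 25.3, 47.8]
        t = align_events(traces, ft, events)
        for n in range(3):
            for j, ev in enumerate(events):
                oracle = direct_alignment_oracle(traces[n], ft, ev, t.bin_edges_s)
                assert np.allclose(t.values[n, j], oracle)

    def test_edge_trials_dropped_and_counted(self):
        ft = np.arange(0, 60, 0.05)
        traces = np.zeros((1, ft.size))
        t = align_events(traces, ft, [2.0, 30.0, 59.0])
        assert t.n_trials == 1 and t.n_dropped_trials == 2
        with pytest.raises(ValueError):
            align_events(traces, ft, [1.0])


class TestZscore:
    def _tensor(self, values):
        return PeriEventTensor(
            np.asarray(values, float),
            bin_edges_s=np.array([-1.0, -0.5, 0.0, 0.5]),
            event_class="e",
            neuron_ids=np.arange(np.asarray(values).shape[0]),
            baseline_window=(-1.0, 0.0),
            response_window=(0.0, 0.5),
        )

    def test_hand_computed_example(self):
        # baseline samples {1, 3}: mu=2, sample SD=sqrt(2); response 4 -> ~1.414
        z = zscore_baseline(self._tensor([[[1.0, 3.0, 4.0]]]))
        assert z.values[0, 0, 2] == pytest.approx(2.0 / np.sqrt(2.0))

    def test_null_response_mean_zero(self, rng):
        vals = rng.standard_normal((4, 30, 3))
        z = zscore_baseline(self._tensor(vals))
        assert np.allclose(z.values[:, :, :2].mean(axis=(1, 2)), 0.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        ft = np.arange(0, 120, 0.05)
        traces = rng.standard_normal((3, ft.size))
        events = [20.0, 60.0, 100.0]
        z1 = zscore_baseline(align_events(traces, ft, events))
        z2 = zscore_baseline(align_events(3.7 * traces - 11.0, ft, events))
        assert np.allclose(z1.values, z2.values, atol=1e-9)

    def test_degenerate_neurons_excluded(self):
        vals = np.stack([np.zeros((5, 3)), np.random.default_rng(0).normal(size=(5, 3))])
        z = zscore_baseline(self._tensor(vals))
        assert z.n_neurons == 1 and z.neuron_ids[0] == 1
        with pytest.raises(ValueError):
            zscore_baseline(self._tensor(np.zeros((2, 5, 3))))


class TestClassification:
    def test_planted_responses_recovered(self, small_population):
        tensor = small_population["tensors"]["alcohol"]
        gt = small_population["ground_truth"]
        gt = gt[gt["event_class"] == "alcohol"].set_index("neuron_id")
        labels = classify_responses(tensor).set_index("neuron_id")
        planted_exc = gt[gt["response"] == "excited"].index
        planted_inh = gt[gt["response"] == "inhibited"].index
        assert (labels.loc[planted_exc, "label"] == "excited").mean() >= 0.9
        assert (labels.loc[planted_inh, "label"] == "inhibited").mean() >= 0.9

    def test_consistent_but_weak_response_labeled_none(self):
        # all-positive per-trial differences (tiny Wilcoxon p) whose
        # standardized mean stays below 1.98 -> magnitude criterion fails
        diffs = np.array([0.01] * 19 + [5.0])
        vals = np.zeros((1, 20, 3))
        vals[0, :, 2] = diffs
        vals[0, :, 0] = 1e-4 * np.arange(20)  # non-degenerate baseline
        t = PeriEventTensor(vals, np.array([-1.0, -0.5, 0.0, 0.5]), "e",
                            np.array([0]), (-1.0, 0.0), (0.0, 0.5), normalized=True)
        out = classify_responses(t)
        assert out.loc[0, "p_value"] < 0.05
        assert 0 < out.loc[0, "z_score"] < 1.98
        assert out.loc[0, "label"] == "none"

    def test_too_few_trials_labeled_none_with_reason(self):
        vals = np.random.default_rng(0).normal(size=(2, 3, 4))
        t = PeriEventTensor(vals, np.array([-1.0, -0.5, 0.0, 0.5, 1.0]), "e",
                            np.array([0, 1]), (-1.0, 0.0), (0.0, 1.0))
        out = classify_responses(t, min_trials=5)
        assert (out["label"] == "none").all()
        assert out["note"].str.contains("fewer than 5").all()


class TestPopulationMean:
    def test_identical_tensors_zero_condition_f(self, small_population):
        t = small_population["tensors"]["alcohol"]
        out = population_mean_response(t, t)
        assert out["anova"]["condition"]["F"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_tensor_flat_line(self):
        t = PeriEventTensor(np.zeros((3, 4, 8)),
                            np.linspace(-1, 1, 9), "e", np.arange(3),
                            (-1.0, 0.0), (0.0, 1.0))
        tc = population_mean_response(t)["timecourse"]["A"]
        assert (tc["mean"] == 0).all()

    def test_planted_condition_offset_detected(self, rng):
        shape = (200, 10, 40)
        edges = np.linspace(-5, 5, 41)
        a = PeriEventTensor(rng.standard_normal(shape), edges, "e",
                            np.arange(200), (-5.0, 0.0), (0.0, 5.0))
        b = PeriEventTensor(rng.standard_normal(shape) + 1.0, edges, "e",
                            np.arange(200), (-5.0, 0.0), (0.0, 5.0))
        out = population_mean_response(a, b)
        assert out["anova"]["condition"]["p"] < 1e-6

    def test_bin_mismatch_rejected(self, small_population):
        t = small_population["tensors"]["alcohol"]
        other = PeriEventTensor(np.zeros((2, 3, 4)), np.linspace(-1, 1, 5), "e",
                                np.arange(2), (-1.0, 0.0), (0.0, 1.0))
        with pytest.raises(ValueError):
            population_mean_response(t, other)


class TestClustering:
    def _two_motifs(self, rng, n=60, bins=40):
        early = np.exp(-np.arange(bins) / 4.0)
        dip = -np.concatenate([np.zeros(bins // 2), np.ones(bins - bins // 2)])
        X = np.empty((n, bins))
        truth = np.arange(n) % 2
        X[truth == 0] = early + 0.1 * rng.standard_normal((int((truth == 0).sum()), bins))
        X[truth == 1] = dip + 0.1 * rng.standard_normal((int((truth == 1).sum()), bins))
        return X, truth

    def test_recovers_planted_motifs(self, rng):
        X, truth = self._two_motifs(rng)
        fc = cluster_functional(X, k=2)
        # cluster 1 is relabeled to the strongest activation = early-peak motif
        agreement = ((fc.cluster_ids == 1) == (truth == 0)).mean()
        assert agreement >= 0.95

    def test_identical_timecourses_zero_within_variance(self):
        X = np.tile(np.sin(np.linspace(0, 3, 20)), (10, 1))
        fc = cluster_functional(X, k=3)
        for c in np.unique(fc.cluster_ids):
            assert np.allclose(np.var(X[fc.cluster_ids == c], axis=0), 0.0)

    def test_permutation_invariant_partition(self, rng):
        X, _ = self._two_motifs(rng, n=40)
        fc1 = cluster_functional(X, k=2)
        perm = rng.permutation(40)
        fc2 = cluster_functional(X[perm], k=2, neuron_ids=perm)
        restored = np.empty(40, dtype=int)
        restored[perm] = fc2.cluster_ids
        assert (restored == fc1.cluster_ids).all()

    def test_k_guard(self, rng):
        with pytest.raises(ValueError):
            cluster_functional(rng.standard_normal((10, 5)), k=1)
        with pytest.raises(ValueError):
            cluster_functional(rng.standard_normal((3, 5)), k=4)


class TestEnrichment:
    def _clustering(self, cluster_ids):
        ids = np.asarray(cluster_ids)
        k = ids.max()
        means = pd.DataFrame(np.zeros((k, 4)),
                             index=pd.Index(range(1, k + 1), name="cluster"))
        from isoensemble.neural import FunctionalClustering
        return FunctionalClustering(ids, np.empty((0, 4)), means, np.arange(ids.size))

    def test_identical_distribution_gives_half(self):
        fc = self._clustering([1, 1, 2, 2, 1, 1, 2, 2])
        out = cluster_enrichment(fc, np.array(["A"] * 4 + ["B"] * 4))
        props = out["proportions"]
        assert np.allclose(props[["prop_A", "prop_B"]], 0.5)

    def test_exclusive_cluster(self):
        fc = self._clustering([1, 1, 2, 2])
        out = cluster_enrichment(fc, np.array(["A", "A", "B", "B"]))
        row = out["proportions"].set_index("cluster")
        assert row.loc[1, "prop_A"] == 1.0 and row.loc[1, "prop_B"] == 0.0

    def test_chi2_matches_textbook_formula(self, rng):
        ids = rng.integers(1, 5, size=200)
        groups = np.where(rng.random(200) < 0.4, "A", "B")
        out = cluster_enrichment(self._clustering(ids), groups)
        table = np.array([
            [((ids == c) & (groups == g)).sum() for g in ("A", "B")]
            for c in range(1, 5)
        ])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert out["chi2"] == pytest.approx(chi2, abs=1e-9)

    def test_single_group_rejected(self):
        fc = self._clustering([1, 2, 1, 2])
        with pytest.raises(ValueError):
            cluster_enrichment(fc, np.array(["A"] * 4))
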