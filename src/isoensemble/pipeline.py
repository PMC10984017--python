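"""End-to-end analysis chain on a synthetic cohort.

``run_pipeline`` wires every stage together — simulate a cohort, score
ranks, segment licks into bouts, contrast conditions, detect social
contact from pose, align and classify calcium responses, decode event
class from pseudo-populations, and compute cross-session ensemble overlap
— writing each artifact to disk.  Identical config + seed reruns produce
byte-identical output files; this is the reproducibility contract the
tests pin down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, ensembles, io, neural, pose, synth

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Scale knobs for the full synthetic-cohort run."""

    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    # pose stage
    pose_duration_s: float = 300.0
    pose_fps: float = 30.0
    pose_episodes: tuple = ((30.0, 40.0), (120.0, 128.0), (200.0, 215.0))
    # neural stage
    n_neurons: int = 60
    n_events_per_class: int = 20
    recording_fps: float = 20.0
    amplitude_z: float = 3.0
    # decoding stage
    n_resamples: int = 20
    n_trials_per_class: int = 20
    n_shuffles: int = 20
    # ensembles stage
    n_sessions: int = 4
    coregistration_rate: float = 0.3


def _event_schedule(n_events: int, spacing_s: float, offset_s: float) -> np.ndarray:
    return offset_s + spacing_s * np.arange(n_events)


def run_pipeline(config: PipelineConfig, outdir, seed: int = 0) -> dict:
    """Run the full chain and write artifacts into ``outdir``.

    Returns a dict of the in-memory results keyed by stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    results: dict = {}

    # --- behavior: cohort, ranks, bouts, contrast -------------------------
    cohort_cfg = synth.CohortConfig(
        **{**config.cohort.__dict__, "seed": int(rng.integers(2**31))}
    )
    cohort = synth.gen_cohort(cohort_cfg)
    ranks = []
    for cage, record in cohort["tournaments"].items():
        io.write_tournament(record, out / f"tournament_cage{cage}.csv")
        ranks.append(behavior.assign_ranks(record).assign(cage=cage))
    rank_table = pd.concat(ranks, ignore_index=True)
    rank_table.to_csv(out / "ranks.csv", index=False)

    streams = [s for s, _ in cohort["streams"].values()]
    io.write_lick_streams(streams, out / "licks.csv")
    summaries = []
    bout_frames = []
    for (mouse, condition, spout), (stream, _gt) in cohort["streams"].items():
        bouts = behavior.segment_bouts(stream)
        bout_frames.append(
            bouts.bouts.assign(mouse=mouse, condition=condition)
        )
        s = behavior.microstructure_summary(bouts, stream)
        rank = int(cohort["mice"].set_index("mouse").loc[mouse, "rank"])
        summaries.append(
            {"mouse": mouse, "condition": condition, "spout": spout, "rank": rank, **s}
        )
    pd.concat(bout_frames, ignore_index=True).to_csv(out / "bouts.csv", index=False)
    summary_df = pd.DataFrame(summaries)
    summary_df.to_csv(out / "microstructure.csv", index=False)
    contrast = behavior.condition_contrast(summary_df[summary_df["spout"] == "alcohol"])
    io.write_json(contrast, out / "contrast.json")
    results["ranks"] = rank_table
    results["microstructure"] = summary_df
    results["contrast"] = contrast

    # --- pose: social-contact detection ----------------------------------
    session, pose_gt = synth.gen_pose_session(
        config.pose_duration_s,
        config.pose_fps,
        list(config.pose_episodes),
        seed=int(rng.integers(2**31)),
    )
    events = pose.detect_interaction(
        pose.head_body_distance(session),
        pose.approach_angle(session),
        session.fps,
    )
    io.write_event_series(events, out / "interaction_events.csv")
    io.write_json(
        {"interaction_time_s": pose.interaction_time(events), "n_bouts": len(events)},
        out / "interaction_summary.json",
    )
    results["interaction"] = events

    # --- neural: peri-event classification --------------------------------
    spacing = 25.0
    duration = spacing * (2 * config.n_events_per_class + 1)
    ev = {
        "alcohol": _event_schedule(config.n_events_per_class, 2 * spacing, spacing),
        "water": _event_schedule(config.n_events_per_class, 2 * spacing, 2 * spacing),
    }
    traces, ft, gt = synth.gen_calcium_population(
        config.n_neurons,
        ev,
        duration_s=duration,
        amplitude_z=config.amplitude_z,
        fps=config.recording_fps,
        seed=int(rng.integers(2**31)),
    )
    io.write_population_h5(out / "population.h5", traces, ft, ev)
    labels = []
    tensors = {}
    for cls, times in ev.items():
        tensor = neural.zscore_baseline(
            neural.align_events(traces, ft, times, event_class=cls)
        )
        tensors[cls] = tensor
        labels.append(neural.classify_responses(tensor))
    label_df = pd.concat(labels, ignore_index=True)
    label_df.to_csv(out / "response_labels.csv", index=False)
    timecourses = tensors["alcohol"].values.mean(axis=1)
    clustering = neural.cluster_functional(
        timecourses, k=min(9, config.n_neurons - 1)
    )
    pd.DataFrame(
        {"neuron_id": clustering.neuron_ids, "cluster": clustering.cluster_ids}
    ).to_csv(out / "clusters.csv", index=False)
    results["labels"] = label_df
    results["clustering"] = clustering

    # --- decoding: alcohol vs water ---------------------------------------
    dataset = decoding.build_pseudopopulation(
        [tensors],
        classes=("alcohol", "water"),
        n_trials_per_class=config.n_trials_per_class,
        n_resamples=config.n_resamples,
        seed=int(rng.integers(2**31)),
    )
    acc = decoding.decode(dataset)
    null = decoding.shuffle_control(
        dataset,
        n_shuffles=config.n_shuffles,
        observed=acc,
        seed=int(rng.integers(2**31)),
    )
    acc.to_csv(out / "decoding.csv", index=False)
    io.write_json(
        {
            "mean_accuracy": float(acc["accuracy"].mean()),
            "null_mean": null["null_mean"],
            "p_empirical": null["p_empirical"],
        },
        out / "decoding_summary.json",
    )
    results["decoding"] = acc

    # --- ensembles: co-registration and overlap ---------------------------
    idmap = synth.gen_identity_map(
        config.n_sessions,
        config.n_neurons,
        config.coregistration_rate,
        seed=int(rng.integers(2**31)),
    )
    io.write_identity_map(idmap, out / "identity_map.csv")
    rate = ensembles.coregistration_rate(idmap)
    # overlap of alcohol- vs water-excited ensembles across two sessions,
    # using the same local neuron indexing as the tensors
    labels_by_class = {
        cls: df.rename(columns={"neuron_id": "local"}).assign(
            neuron_id=lambda d: d["local"]
        )
        for cls, df in ((c, l) for c, l in zip(ev, labels))
    }
    local_ids = {
        s: set(idmap[idmap["session"] == s]["local_id"]) for s in (0, 1)
    }
    lab_a = labels_by_class["alcohol"]
    lab_b = labels_by_class["water"]
    lab_a = lab_a[lab_a["neuron_id"].isin(local_ids[0])]
    lab_b = lab_b[lab_b["neuron_id"].isin(local_ids[1])]
    row_ab = ensembles.ensemble_overlap(lab_a, lab_b, idmap, 0, 1, label="alc-wat")
    row_aa = ensembles.ensemble_overlap(lab_a, lab_a, idmap, 0, 0, label="alc-alc")
    chi = (
        ensembles.overlap_chi2(row_aa, row_ab)
        if row_aa.n_b and row_ab.n_b
        else {"chi2": float("nan"), "p": float("nan")}
    )
    io.write_json(
        {
            "coregistration": rate,
            "overlap": [row_aa.__dict__, row_ab.__dict__],
            "chi2": {k: chi[k] for k in ("chi2", "p")},
        },
        out / "overlap.json",
    )
    results["coregistration"] = rate
    results["overlap"] = (row_aa, row_ab)
    return results
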