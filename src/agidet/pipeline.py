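"""End-to-end orchestration: simulate → features → models → events.

Functions here are pure given their seed arguments, so two runs with the
same configuration produce identical reports (the reproducibility contract
exercised by the CLI and the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from . import physio_features, physio_models, pose_features, sequence_models
from .data_model import FeatureWindow, label_windows
from .event_engine import (
    WindowDecision,
    assemble_episodes,
    attach_buffers,
    compute_lead_times,
)
from .synthetic import (
    ParticipantBundle,
    PhysioSimConfig,
    PoseSimConfig,
    generate_cohort,
    generate_physio,
)

logger = logging.getLogger(__name__)

#: physio generator sized so that episodes + leads fit comfortably in 1 h
DEFAULT_PHYSIO = PhysioSimConfig(
    duration_s=3600.0,
    n_episodes=2,
    episode_duration_range_s=(480.0, 780.0),
)
DEFAULT_POSE = PoseSimConfig(duration_s=420.0, fps=5.0, n_episodes=1,
                             episode_duration_range_s=(120.0, 180.0))


def labelled_features(bundle: ParticipantBundle, preagitation: str = "exclude",
                      config: physio_features.FeatureConfig | None = None) -> pd.DataFrame:
    """Wristband feature matrix for one participant, labelled by episode overlap."""
    windows = physio_features.extract_feature_matrix(bundle.stream, config)
    labelled = label_windows(windows, bundle.physio_labels, preagitation=preagitation)
    df = physio_features.windows_to_frame(labelled)
    df.insert(0, "participant_id", bundle.participant_id)
    return df


def cohort_features(bundles: list[ParticipantBundle], preagitation: str = "exclude",
                    config: physio_features.FeatureConfig | None = None) -> dict[str, pd.DataFrame]:
    return {b.participant_id: labelled_features(b, preagitation, config) for b in bundles}


def wristband_tables(
    features_by_pid: dict[str, pd.DataFrame],
    algos=physio_models.ALGOS,
    seed: int = 0,
    model_config: physio_models.ModelConfig | None = None,
):
    """Personalized + general protocol reports and the statistical comparison."""
    personal = physio_models.run_personalized_protocol(
        features_by_pid, algos, seed=seed, config=model_config)
    general = physio_models.run_general_protocol(
        features_by_pid, algos, seed=seed, config=model_config)
    comparison = None
    pids = {r.participant_id for r in personal}
    if len(pids) >= 3 and "extra_trees" in algos:
        comparison = physio_models.compare_models(personal, reference="extra_trees")
    return personal, general, comparison


def pose_table(
    bundle: ParticipantBundle,
    spec_template: sequence_models.SequenceModelSpec | None = None,
    threshold: float = 0.8,
    window_s: float = 30.0,
    stride_s: float = 1.0,
):
    """The video-channel comparison grid for one participant's pose stream."""
    frames_df = pose_features.frames_to_features(bundle.pose_frames)
    windows = pose_features.build_windows(frames_df, bundle.pose_labels,
                                          fps=bundle.pose_config.fps,
                                          window_s=window_s, stride_s=stride_s)
    names = list(pose_features.FEATURE_NAMES)
    train_mask = np.ones(len(windows), dtype=bool)  # reduction fits on training data
    mat = pd.DataFrame(
        np.vstack([w.frames for i, w in enumerate(windows) if train_mask[i]]),
        columns=names,
    )
    reduced = pose_features.reduce_features(mat, threshold=threshold)
    table = sequence_models.compare_sequence_models(
        windows, names, reduced, spec_template=spec_template)
    return table, windows, reduced


def wristband_decision_stream(
    model,
    eval_windows: list[FeatureWindow],
    feature_names: list[str],
    threshold: float = 0.5,
) -> list[WindowDecision]:
    """Classify every evaluation window into a streaming decision list."""
    df = physio_features.windows_to_frame(eval_windows)
    X = (
        df[feature_names]
        .fillna(df[feature_names].median(numeric_only=True))
        .to_numpy(dtype=float)
    )
    proba = model.predict_proba(X)[:, 1]
    return [
        WindowDecision(w.window_start, w.window_end, float(p), bool(p >= threshold))
        for w, p in zip(eval_windows, proba)
    ]


def leadtime_protocol(
    n_participants: int = 5,
    seed: int = 0,
    physio_template: PhysioSimConfig | None = None,
    algo: str = "extra_trees",
    model_config: physio_models.ModelConfig | None = None,
    min_consecutive: int = 2,
):
    """Train per-participant models with pre-agitation merged into the
    positive class on one session, stream a second session through the
    event engine, and score alert lead times against ground truth."""
    template = physio_template or DEFAULT_PHYSIO
    records = []
    for i in range(n_participants):
        rng = np.random.default_rng([seed, 7000 + i])
        base = replace(
            template,
            participant_id=f"p{i + 1:02d}",
            dominant_channel=("eda", "acc", "temp")[i % 3],
            baseline_pulse_offset=float(rng.uniform(-8.0, 8.0)),
        )
        s_train, s_eval = (int(v) for v in rng.integers(0, 2**31 - 1, size=2))
        train_stream, _, train_labels = generate_physio(replace(base, seed=s_train))
        eval_stream, _, eval_labels = generate_physio(replace(base, seed=s_eval))

        train_windows = physio_features.extract_feature_matrix(train_stream)
        train_labelled = label_windows(train_windows, train_labels, preagitation="merge")
        df = physio_features.windows_to_frame(train_labelled)
        X, y, names = physio_models.frame_to_xy(df)
        X_bal, y_bal = physio_models.upsample(X, y, seed=s_train)
        model = physio_models.train_classifier(X_bal, y_bal, algo, seed=s_train,
                                               config=model_config)

        eval_windows = physio_features.extract_feature_matrix(eval_stream)
        decisions = wristband_decision_stream(model, eval_windows, names)
        events = assemble_episodes(decisions, min_consecutive=min_consecutive,
                                   participant_id=base.participant_id)
        for e in events:
            attach_buffers(e, eval_stream.t0, eval_stream.t1)
        records.extend(compute_lead_times(events, eval_labels))
    return records


def run_full(
    outdir,
    seed: int = 0,
    n_participants: int = 5,
    physio_template: PhysioSimConfig | None = None,
    pose_template: PoseSimConfig | None = None,
    model_config: physio_models.ModelConfig | None = None,
    sequence_spec: sequence_models.SequenceModelSpec | None = None,
    algos=physio_models.ALGOS,
    leadtime_participants: int = 3,
):
    """The whole pipeline on a fresh synthetic cohort; writes report CSVs."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    physio_template = physio_template or DEFAULT_PHYSIO
    pose_template = pose_template or DEFAULT_POSE

    bundles = generate_cohort(n_participants, physio_template, pose_template,
                              seed=seed, include_pose=True)
    feats = cohort_features(bundles)
    personal, general, comparison = wristband_tables(feats, algos, seed=seed,
                                                     model_config=model_config)
    table4 = physio_models.reports_to_frame(personal + general)
    table4.to_csv(outdir / "wristband_metrics.csv", index=False, float_format="%.10g")
    if comparison is not None:
        comparison.to_frame().to_csv(outdir / "wristband_comparison.csv", index=False,
                                     float_format="%.10g")

    seq_spec = sequence_spec or sequence_models.SequenceModelSpec(
        epochs=20, hidden_dim=24, time_subsample=5, seed=seed)
    video_table, _, reduced = pose_table(bundles[0], spec_template=seq_spec)
    video_out = video_table.drop(columns=["latency_median_s"])  # wall clock is not reproducible
    video_out.to_csv(outdir / "video_metrics.csv", index=False, float_format="%.10g")

    lead = leadtime_protocol(leadtime_participants, seed=seed,
                             physio_template=physio_template, model_config=model_config)
    lead_df = pd.DataFrame([
        {"participant_id": r.participant_id, "truth_onset": r.truth_onset,
         "truth_end": r.truth_end, "first_alert": r.first_alert, "lead_s": r.lead_s}
        for r in lead
    ])
    lead_df.to_csv(outdir / "leadtimes.csv", index=False, float_format="%.10g")
    return {
        "wristband": table4,
        "comparison": comparison.to_frame() if comparison is not None else None,
        "video": video_out,
        "leadtimes": lead_df,
        "reduced_features": reduced,
    }
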