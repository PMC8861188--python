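"""End-to-end orchestration: audio -> frames -> segments -> features -> models.

Two entry points:

* :func:`analyze_cohort` runs the whole analysis on an in-memory synthetic
  cohort (used by tests and the reproduction script);
* :func:`run_pipeline` is the disk-based variant driven by a
  :class:`PipelineConfig`, writing every stage artifact (feature CSVs,
  segment CSVs, threshold JSON, partition JSON, report JSON/CSV) plus a run
  log with checksums so re-runs are verifiable.

Threshold calibration uses labelled exemplar recordings: by default the
first ``n_exemplars`` recordings of the cohort with their ground-truth
interval labels, mirroring the practice of hand-labelling a handful of
recordings to place the thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dsp, segmentation as seg
from .cohort import Cohort, GenerativeParams, generate_cohort, load_recording_wav
from .dataset import (
    balanced_partition,
    build_labelled_dataset,
    feature_fev1_correlations,
    random_partition,
)
from .models import compare_feature_subsets, reports_table, run_task_suite

log = logging.getLogger("voicelung")


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run; every field is echoed to the
    run log."""

    out_dir: str = "runs/run0"
    audio_dir: str | None = None  # None -> synthesise a cohort
    manifest: str | None = None
    labels_dir: str | None = None
    n_subjects: int = 26
    n_recordings: int = 323
    seed: int = 0
    # frame grid
    sample_rate: int = 22050
    frame_length: int = 2048
    hop_length: int = 512
    window: str = "hann"
    # segmentation
    min_votes: int = 3
    median_width: int = 5
    min_gap_s: float = 0.10
    min_seg_s: float = 0.15
    n_exemplars: int = 5
    threshold_file: str | None = None
    # partitioning
    partition_mode: str = "balanced"  # "balanced" | "random"
    bin_width: float = 5.0
    train_fraction: float = 0.7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.min_votes > len(seg.DISCRIMINATIVE_FEATURES):
            raise ValueError(
                f"min_votes={self.min_votes} exceeds the "
                f"{len(seg.DISCRIMINATIVE_FEATURES)} available rules"
            )
        if self.partition_mode not in ("balanced", "random"):
            raise ValueError("partition_mode must be 'balanced' or 'random'")

    def grid(self) -> dsp.FrameGrid:
        return dsp.FrameGrid(
            sample_rate=self.sample_rate,
            frame_length=self.frame_length,
            hop_length=self.hop_length,
            window=self.window,
        )


@dataclass
class CohortAnalysis:
    """Everything the pipeline computes for one cohort."""

    dataset: pd.DataFrame  # features + fev1 + labels, indexed by recording_id
    partition: object
    reports: list
    rules: list
    segments: dict[str, seg.SegmentSet]
    frame_accuracy: float | None = None
    segment_recall: dict[str, float] | None = None
    subset_comparison: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None


def calibrate_from_cohort(
    cohort: Cohort, grid: dsp.FrameGrid, n_exemplars: int = 5
) -> list[seg.ThresholdRule]:
    """Calibrate threshold rules from the first ``n_exemplars`` recordings
    using their ground-truth interval labels."""
    frames_list = []
    for rec in cohort.recordings[:n_exemplars]:
        f = dsp.compute_frame_features(rec.waveform, grid)
        f["kind"] = seg.frame_ground_truth(f["time_s"].to_numpy(), rec.labels)
        frames_list.append(f)
    exemplar = pd.concat(frames_list, ignore_index=True)
    return seg.calibrate_thresholds(exemplar)


def segment_recall(
    truth: list, predicted: seg.SegmentSet, kind: str, min_coverage: float = 0.5
) -> float:
    """Fraction of ground-truth segments of ``kind`` covered >= 50% by
    predicted segments of the same kind."""
    gt = [(l.start_s, l.end_s) for l in truth if l.kind == kind]
    pred = predicted.of_kind(kind)
    if not gt:
        return float("nan")
    hits = 0
    for s, e in gt:
        cover = sum(max(0.0, min(e, pe) - max(s, ps)) for ps, pe in pred)
        if cover >= min_coverage * (e - s):
            hits += 1
    return hits / len(gt)


def analyze_cohort(
    cohort: Cohort,
    grid: dsp.FrameGrid | None = None,
    seed: int = 0,
    min_votes: int = 3,
    n_exemplars: int = 5,
    partition_mode: str = "balanced",
    run_cv: bool = True,
    score_segmentation: bool = True,
    compare_subsets: bool = True,
    rules: list | None = None,
) -> CohortAnalysis:
    """Run the full analysis on an in-memory cohort.

    Threshold rules are calibrated from the first ``n_exemplars`` recordings
    unless pre-calibrated ``rules`` are given.  Segmentation quality (frame
    accuracy, per-kind segment recall) is scored against the cohort's
    ground-truth labels when requested.
    """
    grid = grid or dsp.FrameGrid(sample_rate=cohort.params.sample_rate)
    if rules is None:
        exemplars = cohort.recordings[:n_exemplars]
        if any(not r.labels for r in exemplars):
            raise ValueError(
                "exemplar recordings lack interval labels; supply pre-calibrated "
                "rules or a labelled exemplar set"
            )
        rules = calibrate_from_cohort(cohort, grid, n_exemplars=n_exemplars)

    rows, fev1s, subj_ids = {}, [], []
    segments: dict[str, seg.SegmentSet] = {}
    correct = total = 0
    recalls = {"breath": [], "speech": []}
    from .dataset import aggregate_recording_features, attach_biological

    for rec in cohort.recordings:
        frames = dsp.compute_frame_features(rec.waveform, grid)
        kinds = seg.classify_frames(frames, rules, min_votes=min_votes)
        segs = seg.frames_to_segments(
            kinds, grid, duration_s=rec.duration_s
        )
        segments[rec.recording_id] = segs
        if score_segmentation:
            gt = seg.frame_ground_truth(frames["time_s"].to_numpy(), rec.labels)
            correct += int((kinds == gt).sum())
            total += len(gt)
            for kind in ("breath", "speech"):
                r = segment_recall(rec.labels, segs, kind)
                if np.isfinite(r):
                    recalls[kind].append(r)
        vec = aggregate_recording_features(frames, segs)
        vec = attach_biological(vec, rec.subject)
        rows[rec.recording_id] = vec
        fev1s.append(rec.fev1_pct)
        subj_ids.append(rec.subject.subject_id)

    feature_rows = pd.DataFrame(rows).T
    dataset = build_labelled_dataset(feature_rows, np.array(fev1s), subj_ids)

    part_fn = balanced_partition if partition_mode == "balanced" else random_partition
    partition = part_fn(
        dataset["fev1_pct"].to_numpy(), ids=list(dataset.index), seed=seed
    )
    reports = run_task_suite(dataset, partition, seed=seed, run_cv=run_cv)

    analysis = CohortAnalysis(
        dataset=dataset,
        partition=partition,
        reports=reports,
        rules=rules,
        segments=segments,
    )
    if score_segmentation and total:
        analysis.frame_accuracy = correct / total
        analysis.segment_recall = {
            k: float(np.mean(v)) if v else float("nan") for k, v in recalls.items()
        }
    if compare_subsets:
        analysis.subset_comparison = compare_feature_subsets(
            dataset, partition, seed=seed
        )
    from .dataset import ACOUSTIC_FEATURES

    acoustic = dataset[ACOUSTIC_FEATURES].dropna(axis=0)
    analysis.correlations = feature_fev1_correlations(
        acoustic, dataset.loc[acoustic.index, "fev1_pct"].to_numpy()
    )
    return analysis


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Disk-based pipeline run; returns the run directory.

    Missing or unreadable WAVs are skipped with a log line; if every
    recording fails the run aborts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    grid = config.grid()

    if config.audio_dir is None:
        params = GenerativeParams(sample_rate=config.sample_rate, seed=config.seed)
        cohort = generate_cohort(
            params, n_subjects=config.n_subjects, n_recordings=config.n_recordings
        )
    else:
        cohort = _load_disk_cohort(config)
    if not cohort.recordings:
        raise RuntimeError("no readable recordings")

    rules = (
        seg.load_rules(config.threshold_file) if config.threshold_file else None
    )
    analysis = analyze_cohort(
        cohort,
        grid=grid,
        seed=config.seed,
        min_votes=config.min_votes,
        n_exemplars=config.n_exemplars,
        partition_mode=config.partition_mode,
        score_segmentation=config.audio_dir is None,
        rules=rules,
    )

    # stage artifacts
    seg_dir = out / "segments"
    seg_dir.mkdir(exist_ok=True)
    for rid, segs in analysis.segments.items():
        segs.to_frame().to_csv(seg_dir / f"{rid}.csv", index=False)
    seg.save_rules(analysis.rules, out / "thresholds.json")
    analysis.dataset.to_csv(out / "features.csv")
    analysis.partition.to_json(out / "partition.json")
    analysis.correlations.to_csv(out / "correlations.csv")
    if analysis.subset_comparison is not None:
        analysis.subset_comparison.to_csv(out / "subset_comparison.csv", index=False)
    table = reports_table(analysis.reports)
    table.to_csv(out / "reports.csv", index=False)
    (out / "reports.json").write_text(
        json.dumps([r.to_dict() for r in analysis.reports], indent=2)
    )

    checksums = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))
        if p.name != "run_log.json"
    }
    run_log = {
        "config": dataclasses.asdict(config),
        "elapsed_s": round(time.time() - t0, 2),
        "n_recordings": len(cohort.recordings),
        "frame_accuracy": analysis.frame_accuracy,
        "segment_recall": analysis.segment_recall,
        "checksums": checksums,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return out


def _load_disk_cohort(config: PipelineConfig) -> Cohort:
    """Build a Cohort from on-disk WAVs + manifest (no ground-truth labels).

    Recordings that fail to read are skipped and logged.
    """
    from .cohort import Recording, SubjectProfile

    manifest = pd.read_csv(config.manifest)
    audio_root = Path(config.audio_dir)
    subjects: dict[str, SubjectProfile] = {}
    recordings = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        if sid not in subjects:
            subjects[sid] = SubjectProfile(
                subject_id=sid,
                sex=int(row["sex"]),
                height_cm=float(row["height_cm"]),
                weight_kg=float(row["weight_kg"]),
                baseline_fev1=float(row["fev1_pct"]),
            )
        wav_path = audio_root / Path(str(row["wav_path"])).name
        try:
            y, sr = load_recording_wav(wav_path)
        except (OSError, ValueError) as exc:
            log.warning("skipping %s: %s", wav_path, exc)
            continue
        labels = []
        if config.labels_dir:
            lab_path = Path(config.labels_dir) / f"{row['recording_id']}.csv"
            if lab_path.exists():
                from .cohort import GroundTruthLabel

                labels = [
                    GroundTruthLabel(r.start_s, r.end_s, r.kind)
                    for r in pd.read_csv(lab_path).itertuples()
                ]
        recordings.append(
            Recording(
                recording_id=str(row["recording_id"]),
                subject=subjects[sid],
                fev1_pct=float(row["fev1_pct"]),
                waveform=y,
                sample_rate=sr,
                labels=labels,
            )
        )
    params = GenerativeParams(sample_rate=config.sample_rate, seed=config.seed)
    return Cohort(params=params, subjects=list(subjects.values()), recordings=recordings)
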