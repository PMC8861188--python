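"""Threshold-based separation of breath and speech.

Five frame-level features discriminate breathing from speech in voice
recordings: spectral contrast, roll-off at 95%, RMS energy, spectral
bandwidth and mean amplitude.  For each feature a threshold is calibrated as
the midpoint of the breath and speech class medians on labelled exemplar
frames; a frame is called breath when at least ``min_votes`` of the rules
place it on the breath side.  Frame labels are then median-filtered and
run-length encoded into contiguous segments, with short gaps absorbed and
sub-minimum runs merged away.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .dsp import FrameGrid

#: the five features that discriminate breath from speech frames
DISCRIMINATIVE_FEATURES = ["contrast", "rolloff95", "rms", "bandwidth", "mean_amp"]

BREATH, SPEECH = "breath", "speech"


@dataclass(frozen=True)
class ThresholdRule:
    """Decision rule for one feature: breath lies on ``breath_side`` of
    ``threshold``."""

    feature_name: str
    threshold: float
    breath_side: str  # "below" | "above"

    def __post_init__(self) -> None:
        if self.feature_name not in DISCRIMINATIVE_FEATURES:
            raise ValueError(f"unknown discriminative feature {self.feature_name!r}")
        if self.breath_side not in ("below", "above"):
            raise ValueError("breath_side must be 'below' or 'above'")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def breath_votes(self, values: np.ndarray) -> np.ndarray:
        if self.breath_side == "below":
            return np.asarray(values) < self.threshold
        return np.asarray(values) > self.threshold


@dataclass
class SegmentSet:
    """Ordered, non-overlapping typed intervals covering one recording."""

    segments: list[tuple[float, float, str]]
    recording_id: str = ""

    def __post_init__(self) -> None:
        prev_end = 0.0
        for start, end, kind in self.segments:
            if kind not in (BREATH, SPEECH):
                raise ValueError(f"bad segment kind {kind!r}")
            if start < prev_end - 1e-9 or end <= start:
                raise ValueError("segments must be ordered and non-overlapping")
            prev_end = end

    def of_kind(self, kind: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, k in self.segments if k == kind]

    def total_duration(self, kind: str | None = None) -> float:
        return sum(e - s for s, e, k in self.segments if kind is None or k == kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.segments, columns=["start_s", "end_s", "kind"])


class CalibrationError(RuntimeError):
    """Raised when too few usable threshold rules can be derived."""


def calibrate_thresholds(
    exemplar_frames: pd.DataFrame,
    label_column: str = "kind",
    min_rules: int = 3,
) -> list[ThresholdRule]:
    """Derive one rule per discriminative feature from labelled frames.

    For each feature the threshold is the midpoint of the breath and speech
    class medians and the breath side is the side the breath median falls
    on.  A feature whose class medians coincide is excluded with a warning;
    fewer than ``min_rules`` usable rules is a calibration failure.
    """
    labels = exemplar_frames[label_column]
    breath = exemplar_frames.loc[labels == BREATH]
    speech = exemplar_frames.loc[labels == SPEECH]
    if len(breath) < 3 or len(speech) < 3:
        raise CalibrationError("need >= 3 labelled frames of each kind")
    rules: list[ThresholdRule] = []
    for feat in DISCRIMINATIVE_FEATURES:
        mb = float(breath[feat].median())
        ms = float(speech[feat].median())
        if mb == ms:
            warnings.warn(
                f"feature {feat!r} has identical class medians; rule excluded",
                stacklevel=2,
            )
            continue
        rules.append(
            ThresholdRule(
                feature_name=feat,
                threshold=(mb + ms) / 2.0,
                breath_side="below" if mb < ms else "above",
            )
        )
    if len(rules) < min_rules:
        raise CalibrationError(
            f"only {len(rules)} usable rules (< {min_rules}); calibration failed"
        )
    return rules


def classify_frames(
    frames: pd.DataFrame,
    rules: list[ThresholdRule],
    min_votes: int = 3,
) -> np.ndarray:
    """Label each frame breath/speech by majority vote over the rules."""
    if len(frames) == 0:
        raise ValueError("empty frame matrix")
    if min_votes > len(rules):
        raise ValueError(f"min_votes={min_votes} exceeds {len(rules)} rules")
    votes = np.zeros(len(frames), dtype=int)
    for rule in rules:
        votes += rule.breath_votes(frames[rule.feature_name].to_numpy())
    return np.where(votes >= min_votes, BREATH, SPEECH)


def frames_to_segments(
    frame_kinds: np.ndarray,
    grid: FrameGrid,
    median_width: int = 5,
    min_gap_s: float = 0.10,
    min_seg_s: float = 0.15,
    duration_s: float | None = None,
) -> SegmentSet:
    """Turn per-frame labels into contiguous typed intervals.

    Labels are median-filtered (width ``median_width`` frames), run-length
    encoded, then gaps shorter than ``min_gap_s`` are absorbed into the
    flanking kind and remaining runs shorter than ``min_seg_s`` merged into
    their longer neighbour.  Segment boundaries fall on frame-centre times;
    the last segment is extended to ``duration_s`` when given.
    """
    kinds = np.asarray(frame_kinds)
    if kinds.size == 0:
        raise ValueError("no frame labels")
    is_breath = (kinds == BREATH).astype(int)
    if median_width > 1:
        is_breath = median_filter(is_breath, size=median_width, mode="nearest")

    hop_s = grid.hop_length / grid.sample_rate
    runs = _run_lengths(is_breath)  # list of (value, n_frames)
    runs = _absorb_short_runs(runs, min_frames=max(1, int(round(min_gap_s / hop_s))))
    runs = _absorb_short_runs(runs, min_frames=max(1, int(round(min_seg_s / hop_s))))

    segments: list[tuple[float, float, str]] = []
    pos = 0
    for value, n in runs:
        start = pos * hop_s
        end = (pos + n) * hop_s
        segments.append((start, end, BREATH if value else SPEECH))
        pos += n
    if duration_s is not None and segments:
        s, e, k = segments[-1]
        # pin the cover to the true recording duration
        segments[-1] = (s, duration_s if duration_s > s else e, k)
    return SegmentSet(segments=segments)


def _run_lengths(values: np.ndarray) -> list[list]:
    runs: list[list] = []
    for v in values:
        if runs and runs[-1][0] == v:
            runs[-1][1] += 1
        else:
            runs.append([v, 1])
    return runs


def _absorb_short_runs(runs: list[list], min_frames: int) -> list[list]:
    """Repeatedly flip the shortest sub-minimum run into its neighbours'
    kind (interior runs only; edge runs merge inward)."""
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        lengths = [n for _, n in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_frames:
            break
        value, n = runs.pop(shortest)
        if shortest > 0:
            runs[shortest - 1][1] += n
        else:
            runs[0][1] += n
        # merge now-adjacent runs of equal kind
        merged: list[list] = []
        for v, m in runs:
            if merged and merged[-1][0] == v:
                merged[-1][1] += m
            else:
                merged.append([v, m])
        runs = merged
    return runs


def breath_cycle_stats(segments: SegmentSet) -> dict[str, float]:
    """Breath-count and cycle statistics of a segmented recording.

    The mean breath cycle duration is the mean interval between onsets of
    successive breath segments; with fewer than two breath segments it is
    NaN.
    """
    onsets = [s for s, _ in segments.of_kind(BREATH)]
    mean_cycle = float(np.mean(np.diff(onsets))) if len(onsets) >= 2 else float("nan")
    return {
        "breath_count": float(len(onsets)),
        "speech_count": float(len(segments.of_kind(SPEECH))),
        "breath_total_s": segments.total_duration(BREATH),
        "speech_total_s": segments.total_duration(SPEECH),
        "mean_breath_cycle_s": mean_cycle,
    }


def save_rules(rules: list[ThresholdRule], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(r) for r in rules], indent=2))


def load_rules(path: str | Path) -> list[ThresholdRule]:
    return [ThresholdRule(**d) for d in json.loads(Path(path).read_text())]


def frame_ground_truth(
    times_s: np.ndarray, labels: "pd.DataFrame | list"
) -> np.ndarray:
    """Assign each frame centre the kind of the ground-truth interval it
    falls in (frames past the last interval take its kind)."""
    if not isinstance(labels, pd.DataFrame):
        labels = pd.DataFrame(
            [{"start_s": l.start_s, "end_s": l.end_s, "kind": l.kind} for l in labels]
        )
    out = np.full(len(times_s), SPEECH, dtype=object)
    for _, row in labels.iterrows():
        m = (times_s >= row.start_s) & (times_s < row.end_s)
        out[m] = row.kind
    last = labels.iloc[-1]
    out[times_s >= last.end_s] = last.kind
    return out
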