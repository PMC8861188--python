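"""Synthetic voice-recording cohorts with a known FEV1% -> acoustics link.

The generator emulates the shape of a bronchoprovocation study cohort:
subjects with clinically stable mild asthma read aloud for ~30 s after each
challenge dose while their lung function (FEV1% predicted) is measured.  A
recording alternates speech spans (harmonic source with a slow amplitude
envelope) and breath spans (broadband noise).  Lung function is planted in
the acoustics through two monotone mechanisms, both motivated by the
clinical picture of airway obstruction (louder breath sounds, higher
respiratory rate):

* breath intensity: breath RMS grows linearly as FEV1% falls
  (``breath_gain_slope`` per percentage point);
* respiratory rate: the interval between breath onsets shrinks linearly as
  FEV1% falls (``cycle_slope`` seconds per point), and breath spans lengthen
  slightly (``breath_dur_slope``).

The acoustics of each recording are driven by the measured FEV1% plus
Gaussian noise (``noise_sd``, in FEV1% points), so the best achievable
reconstruction error from acoustics alone is ~``noise_sd``.

Every recording ships with ground-truth breath/speech interval labels so the
downstream threshold segmentation can be scored exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "SubjectProfile",
    "GroundTruthLabel",
    "GenerativeParams",
    "Recording",
    "Cohort",
    "synth_speech_segment",
    "synth_breath_segment",
    "assemble_recording",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Biological covariates of one participant."""

    subject_id: str
    sex: int  # coded 0/1
    height_cm: float
    weight_kg: float
    baseline_fev1: float  # percent predicted

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError("sex must be coded 0/1")
        if not 140 <= self.height_cm <= 200:
            raise ValueError("height_cm out of [140, 200]")
        if not 40 <= self.weight_kg <= 120:
            raise ValueError("weight_kg out of [40, 120]")
        if not 50 < self.baseline_fev1 <= 125:
            raise ValueError("baseline_fev1 out of (50, 125]")


@dataclass(frozen=True)
class GroundTruthLabel:
    """One labelled time interval of a recording."""

    start_s: float
    end_s: float
    kind: str  # "breath" | "speech"

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError("require 0 <= start_s < end_s")
        if self.kind not in ("breath", "speech"):
            raise ValueError("kind must be 'breath' or 'speech'")


@dataclass(frozen=True)
class GenerativeParams:
    """Knobs of the synthetic cohort generator.

    ``fev1_mean``/``fev1_sd`` parametrise the truncated-normal marginal of
    FEV1% on (50, 125]; the defaults were chosen so the generated cohort
    matches the reference dataset shape: modal 5% bin near 100, no sample at
    or below 50, and roughly 72% of recordings above the 80% normality cut.
    """

    sample_rate: int = 22050
    recording_s: float = 30.0
    speech_dur_range: tuple[float, float] = (2.0, 5.0)
    breath_dur_range: tuple[float, float] = (0.3, 1.2)
    f0_range: tuple[float, float] = (110.0, 220.0)
    breath_gain_slope: float = 0.01  # relative RMS change per FEV1% point
    cycle_slope: float = 0.02  # seconds of breath-onset interval per point
    breath_dur_slope: float = 0.004  # relative breath-span change per point
    noise_sd: float = 2.0  # FEV1% points of acoustic-link noise
    seed: int = 0
    # acoustic levels (linear amplitude)
    breath_base_rms: float = 0.03
    speech_rms: float = 0.2
    speech_fmax: float = 4000.0
    # subject baseline FEV1%: truncated normal, support (fev1_lo, fev1_hi]
    fev1_mean: float = 102.0
    fev1_sd: float = 5.0
    fev1_lo: float = 50.0
    fev1_hi: float = 125.0
    # half the maximum challenge-induced FEV1% drop (depth ~ U(0, 2*this))
    within_subject_sd: float = 34.0

    def __post_init__(self) -> None:
        for name in ("speech_dur_range", "breath_dur_range", "f0_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be positive and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.recording_s <= 0 or self.sample_rate <= 0:
            raise ValueError("recording_s and sample_rate must be positive")


@dataclass
class Recording:
    """One synthetic recording with its ground truth."""

    recording_id: str
    subject: SubjectProfile
    fev1_pct: float
    waveform: np.ndarray
    sample_rate: int
    labels: list[GroundTruthLabel]

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.sample_rate


@dataclass
class Cohort:
    """A generated cohort: recordings plus a tidy manifest."""

    params: GenerativeParams
    subjects: list[SubjectProfile]
    recordings: list[Recording]

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "recording_id": r.recording_id,
                "subject_id": r.subject.subject_id,
                "sex": r.subject.sex,
                "height_cm": r.subject.height_cm,
                "weight_kg": r.subject.weight_kg,
                "fev1_pct": r.fev1_pct,
                "wav_path": f"audio/{r.recording_id}.wav",
            }
            for r in self.recordings
        ]
        return pd.DataFrame(rows)


def _breath_target_rms(fev1: float, params: GenerativeParams) -> float:
    gain = 1.0 + params.breath_gain_slope * (100.0 - fev1)
    return max(params.breath_base_rms * gain, 1e-4)


def synth_breath_segment(
    duration: float,
    fev1: float,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Broadband breath noise whose RMS falls as FEV1% rises.

    The segment is white Gaussian noise rescaled to the exact target RMS, so
    for a fixed random stream the RMS is monotonically non-increasing in
    ``fev1``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0 < fev1 <= 150:
        raise ValueError("fev1 out of (0, 150]")
    n = int(round(duration * params.sample_rate))
    y = rng.standard_normal(n)
    y *= _breath_target_rms(fev1, params) / np.sqrt(np.mean(y**2))
    return np.clip(y, -1.0, 1.0)


def synth_speech_segment(
    duration: float,
    f0: float,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Harmonic speech surrogate: stacked partials with 1/k roll-off and a
    slow amplitude envelope, normalised to ``params.speech_rms``."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    lo, hi = params.f0_range
    if not lo <= f0 <= hi:
        raise ValueError(f"f0 must lie within {params.f0_range}")
    n = int(round(duration * params.sample_rate))
    t = (np.arange(n) / params.sample_rate).astype(np.float32)
    n_harm = max(1, int(params.speech_fmax // f0))
    k = np.arange(1, n_harm + 1, dtype=np.float32)
    phases = rng.uniform(0, 2 * np.pi, size=n_harm).astype(np.float32)
    # float32 additive synthesis: partials x samples within one span
    y = np.sin(np.float32(2 * np.pi * f0) * np.outer(k, t) + phases[:, None])
    y = (y / k[:, None]).sum(axis=0).astype(np.float64)
    t64 = np.arange(n) / params.sample_rate
    env_f = rng.uniform(1.5, 3.5)
    env_phase = rng.uniform(0, 2 * np.pi)
    y *= 0.8 + 0.2 * np.sin(2 * np.pi * env_f * t64 + env_phase)
    y *= params.speech_rms / np.sqrt(np.mean(y**2))
    peak = np.max(np.abs(y))
    if peak > 0.99:
        y *= 0.99 / peak
    return y


def assemble_recording(
    fev1: float,
    subject: SubjectProfile,
    params: GenerativeParams,
    rng: np.random.Generator,
    recording_id: str = "rec",
) -> Recording:
    """Alternate speech and breath spans (starting with speech) until the
    target duration is reached; returns waveform plus ground-truth labels.

    ``fev1`` is perturbed by ``noise_sd`` before driving the acoustics, so
    the generated sound reflects the measured lung function only up to that
    noise.
    """
    if not 50 < fev1 <= 125:
        raise ValueError("fev1 out of (50, 125]")
    fev1_eff = fev1 + rng.normal(0.0, params.noise_sd)
    fev1_eff = float(np.clip(fev1_eff, 40.0, 135.0))

    # subject-specific voice pitch with small per-span jitter
    f0_lo, f0_hi = params.f0_range
    span = f0_hi - f0_lo
    frac = 0.15 + 0.45 * hash_fraction(subject.subject_id) + 0.3 * subject.sex
    base_f0 = float(np.clip(f0_lo + span * frac, f0_lo, f0_hi))

    pieces: list[np.ndarray] = []
    labels: list[GroundTruthLabel] = []
    t = 0.0
    kind = "speech"
    s_lo, s_hi = params.speech_dur_range
    b_lo, b_hi = params.breath_dur_range
    while t < params.recording_s:
        if kind == "speech":
            dur = rng.uniform(s_lo, s_hi)
            # respiratory-rate link: shorter phonation spans at low FEV1%
            dur = max(dur + params.cycle_slope * (fev1_eff - 100.0), 0.8)
            f0 = float(np.clip(base_f0 * rng.uniform(0.95, 1.05), f0_lo, f0_hi))
            piece = synth_speech_segment(dur, f0, params, rng)
        else:
            dur = rng.uniform(b_lo, b_hi)
            dur = max(dur * (1.0 + params.breath_dur_slope * (100.0 - fev1_eff)), 0.15)
            piece = synth_breath_segment(dur, fev1_eff, params, rng)
        actual = len(piece) / params.sample_rate
        labels.append(GroundTruthLabel(t, t + actual, kind))
        pieces.append(piece)
        t += actual
        kind = "breath" if kind == "speech" else "speech"
    waveform = np.concatenate(pieces)
    return Recording(
        recording_id=recording_id,
        subject=subject,
        fev1_pct=float(fev1),
        waveform=waveform,
        sample_rate=params.sample_rate,
        labels=labels,
    )


def hash_fraction(key: str) -> float:
    """Deterministic [0, 1) value from a string key (seed-independent)."""
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled normal restricted to (lo, hi]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[(draw > lo) & (draw <= hi)]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def _subject_fev1_series(
    baseline: float, n: int, params: GenerativeParams, rng: np.random.Generator
) -> np.ndarray:
    """Repeated FEV1% measurements for one subject.

    Emulates a progressive challenge: lung function falls away from baseline
    along a convex dose ramp (most visits stay near baseline, the last doses
    bite), reaching a subject-specific maximal drop, then partially
    recovering.  Values stay inside the cohort support (50, 125].
    """
    # maximal dose-response drop for this subject, in FEV1% points; uniform
    # over [0, 2*within_subject_sd] so the cohort spans non-responders to
    # strong responders
    depth = rng.uniform(0.0, 2.0 * params.within_subject_sd)
    peak_at = max(2, int(round(n * rng.uniform(0.5, 0.85))))
    profile = np.empty(n)
    for j in range(n):
        if j <= peak_at:
            profile[j] = (j / peak_at) ** 2
        else:
            profile[j] = max(0.0, 1.0 - 0.6 * (j - peak_at) / max(1, n - peak_at))
    values = baseline - depth * profile + rng.normal(0.0, 2.0, size=n)
    return np.clip(values, params.fev1_lo + 0.5, params.fev1_hi)


def sample_cohort_design(
    params: GenerativeParams,
    n_subjects: int,
    n_recordings: int,
    rng: np.random.Generator,
) -> tuple[list[SubjectProfile], list[np.ndarray]]:
    """Draw subjects and their per-visit FEV1% series (no audio)."""
    baselines = _truncated_normal(
        rng, params.fev1_mean, params.fev1_sd, params.fev1_lo + 5.0, params.fev1_hi, n_subjects
    )
    subjects = [
        SubjectProfile(
            subject_id=f"S{i + 1:03d}",
            sex=int(rng.integers(0, 2)),
            height_cm=float(np.round(rng.uniform(150, 190), 1)),
            weight_kg=float(np.round(rng.uniform(50, 100), 1)),
            baseline_fev1=float(baselines[i]),
        )
        for i in range(n_subjects)
    ]
    # distribute recordings as evenly as possible across subjects
    per = np.full(n_subjects, n_recordings // n_subjects)
    per[: n_recordings % n_subjects] += 1
    series = [
        _subject_fev1_series(s.baseline_fev1, int(m), params, rng)
        for s, m in zip(subjects, per)
    ]
    return subjects, series


def generate_cohort(
    params: GenerativeParams,
    n_subjects: int = 26,
    n_recordings: int = 323,
) -> Cohort:
    """Generate a full cohort: subjects, FEV1% series and audio.

    Fully deterministic for a fixed ``params`` (including ``params.seed``).
    """
    if n_subjects < 1 or n_recordings < n_subjects:
        raise ValueError("require n_subjects >= 1 and n_recordings >= n_subjects")
    rng = np.random.default_rng(params.seed)
    subjects, series_list = sample_cohort_design(params, n_subjects, n_recordings, rng)

    recordings: list[Recording] = []
    idx = 0
    for subject, series in zip(subjects, series_list):
        for fev1 in series:
            idx += 1
            rec = assemble_recording(
                float(fev1),
                subject,
                params,
                rng,
                recording_id=f"R{idx:04d}",
            )
            recordings.append(rec)
    return Cohort(params=params, subjects=subjects, recordings=recordings)


def labels_frame(labels: Sequence[GroundTruthLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"start_s": l.start_s, "end_s": l.end_s, "kind": l.kind} for l in labels]
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write WAVs (PCM16 mono), manifest CSV and ground-truth label CSVs."""
    out = Path(out_dir)
    (out / "audio").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        pcm = np.clip(rec.waveform, -1.0, 1.0)
        wavfile.write(
            out / "audio" / f"{rec.recording_id}.wav",
            rec.sample_rate,
            np.round(pcm * 32767).astype(np.int16),
        )
        labels_frame(rec.labels).to_csv(
            out / "labels" / f"{rec.recording_id}.csv", index=False
        )
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    return out


def load_recording_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV into float64 in [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    return data, int(sr)


def load_cohort(root: str | Path) -> tuple[pd.DataFrame, Path]:
    """Load a written cohort's manifest; audio/labels are read lazily."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    return manifest, root
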