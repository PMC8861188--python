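"""Per-recording feature vectors, labels and train/test partitioning.

A recording is summarised by 23 acoustic features: the mean of each of the
nine frame descriptors over breath frames and over speech frames (18), plus
breath count, speech count, total breath and speech duration, and the mean
breath cycle duration.  Optionally the subject's sex, height and weight are
appended (26 features).  Lung function labels follow the American Thoracic
Society convention: normal means FEV1% predicted > 80, and severity grades
are half-open FEV1% bands.

Balanced partitioning stratifies the 70:30 train/test split over 5-point
FEV1% bins — (50, 55], (55, 60], ... , (120, 125] — so both splits share the
(skewed) target distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import SubjectProfile
from .dsp import FRAME_FEATURE_COLUMNS
from .segmentation import BREATH, SPEECH, SegmentSet, breath_cycle_stats

#: canonical ordering of the 23 acoustic features
ACOUSTIC_FEATURES: list[str] = (
    [f"breath_{c}" for c in FRAME_FEATURE_COLUMNS]
    + [f"speech_{c}" for c in FRAME_FEATURE_COLUMNS]
    + [
        "breath_count",
        "speech_count",
        "breath_total_s",
        "speech_total_s",
        "mean_breath_cycle_s",
    ]
)

#: biological covariates appended for the _P model variants
BIOLOGICAL_FEATURES = ["sex", "height_cm", "weight_kg"]

#: default ATS-style severity bands: half-open on the left, normal is > 80
DEFAULT_ATS_BOUNDARIES: list[tuple[float, str]] = [
    (35.0, "very_severe"),  # fev1 < 35
    (50.0, "severe"),  # 35 <= fev1 < 50
    (60.0, "moderately_severe"),  # 50 <= fev1 < 60
    (70.0, "moderate"),  # 60 <= fev1 < 70
    (80.0, "mild"),  # 70 <= fev1 <= 80  (normal strictly above 80)
]

NORMAL_CUT = 80.0


def aggregate_recording_features(
    frames: pd.DataFrame, segments: SegmentSet
) -> pd.Series:
    """Collapse a frame feature matrix into the 23-entry recording vector.

    Per-kind means are taken over frames whose centre time falls inside a
    segment of that kind; a kind with no frames yields NaN entries (imputed
    downstream from training medians).
    """
    times = frames["time_s"].to_numpy()
    kind = np.full(len(frames), "", dtype=object)
    for start, end, k in segments.segments:
        kind[(times >= start) & (times < end)] = k
    out: dict[str, float] = {}
    for k, prefix in ((BREATH, "breath"), (SPEECH, "speech")):
        sel = frames.loc[kind == k, FRAME_FEATURE_COLUMNS]
        for c in FRAME_FEATURE_COLUMNS:
            out[f"{prefix}_{c}"] = float(sel[c].mean()) if len(sel) else float("nan")
    out.update(breath_cycle_stats(segments))
    return pd.Series(out, index=ACOUSTIC_FEATURES, dtype=float)


def attach_biological(vector: pd.Series, subject: SubjectProfile) -> pd.Series:
    """Append sex (0/1), height and weight to a 23-entry acoustic vector."""
    extra = pd.Series(
        {
            "sex": float(subject.sex),
            "height_cm": subject.height_cm,
            "weight_kg": subject.weight_kg,
        }
    )
    return pd.concat([vector, extra])


class MinMaxNormalizer:
    """Min-max scaling fitted on training rows only.

    Test values are intentionally not clipped, so they may fall outside
    [0, 1].  A constant training column maps to 0 everywhere.
    """

    def __init__(self) -> None:
        self.min_: pd.Series | None = None
        self.range_: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "MinMaxNormalizer":
        if len(train) == 0:
            raise ValueError("empty training set")
        self.min_ = train.min()
        self.range_ = train.max() - self.min_
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if self.min_ is None:
            raise RuntimeError("fit before transform")
        rng = self.range_.replace(0.0, 1.0)  # constant column -> 0 everywhere
        return (matrix - self.min_) / rng

    def inverse_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if self.min_ is None:
            raise RuntimeError("fit before inverse_transform")
        rng = self.range_.replace(0.0, 1.0)
        return matrix * rng + self.min_


def label_binary(fev1_pct: float) -> str:
    """ATS normality: normal iff FEV1% predicted is strictly above 80."""
    if not np.isfinite(fev1_pct) or fev1_pct <= 0:
        raise ValueError("fev1_pct must be finite and positive")
    return "normal" if fev1_pct > NORMAL_CUT else "abnormal"


def label_ats_grade(
    fev1_pct: float,
    boundaries: list[tuple[float, str]] | None = None,
) -> str:
    """Ordinal severity grade from the configured FEV1% boundary table."""
    if not np.isfinite(fev1_pct) or fev1_pct <= 0:
        raise ValueError("fev1_pct must be finite and positive")
    table = boundaries if boundaries is not None else DEFAULT_ATS_BOUNDARIES
    if fev1_pct > NORMAL_CUT:
        return "normal"
    for upper, name in table:
        if fev1_pct < upper:
            return name
    return table[-1][1]  # the band touching the normality cut (<= 80)


def feature_fev1_correlations(
    matrix: pd.DataFrame, fev1: np.ndarray
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of every feature against FEV1%.

    Constant features (or fewer than 3 complete pairs) report NaN.
    """
    fev1 = np.asarray(fev1, dtype=float)
    rows = []
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(fev1)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 complete pairs for {col!r}")
        if np.ptp(x[ok]) == 0:
            rows.append({"feature": col, "r": np.nan, "p": np.nan})
            continue
        r, p = sps.pearsonr(x[ok], fev1[ok])
        rows.append({"feature": col, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class PartitionSpec:
    """A train/test split with its provenance."""

    mode: str  # "balanced" | "random"
    seed: int
    train_fraction: float = 0.7
    bin_width: float = 5.0
    bin_lo: float = 50.0
    bin_hi: float = 125.0
    train_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mode": self.mode,
                    "seed": self.seed,
                    "train_fraction": self.train_fraction,
                    "bin_width": self.bin_width,
                    "bin_edges": list(
                        np.arange(self.bin_lo, self.bin_hi + self.bin_width, self.bin_width)
                    ),
                    "train_ids": [str(i) for i in self.train_ids],
                    "test_ids": [str(i) for i in self.test_ids],
                },
                indent=2,
            )
        )


def fev1_bin_index(
    fev1: np.ndarray, bin_width: float = 5.0, lo: float = 50.0, hi: float = 125.0
) -> np.ndarray:
    """Index of the half-open bin (lo, lo+w], (lo+w, lo+2w], ... per value.

    Values at or below ``lo`` (or above ``hi``) extend the edge bins, with a
    warning.
    """
    fev1 = np.asarray(fev1, dtype=float)
    n_bins = int(round((hi - lo) / bin_width))
    if np.any(fev1 <= lo) or np.any(fev1 > hi):
        warnings.warn("FEV1% values outside the bin range; edge bins extended")
    idx = np.ceil((fev1 - lo) / bin_width).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def _n_train(n: int, fraction: float) -> int:
    """Training count per bin: round(fraction*n) with ties toward train."""
    return int(np.floor(fraction * n + 0.5))


def balanced_partition(
    fev1: np.ndarray,
    ids: list | None = None,
    seed: int = 0,
    train_fraction: float = 0.7,
    bin_width: float = 5.0,
    bin_lo: float = 50.0,
    bin_hi: float = 125.0,
) -> PartitionSpec:
    """70:30 split stratified over 5-point FEV1% bins.

    Within each bin rows are shuffled (seeded) and the first
    round(train_fraction * n) go to train; singleton bins go entirely to
    train.
    """
    fev1 = np.asarray(fev1, dtype=float)
    if fev1.size == 0:
        raise ValueError("empty dataset")
    if ids is None:
        ids = list(range(len(fev1)))
    ids = np.asarray(ids, dtype=object)
    rng = np.random.default_rng(seed)
    bins = fev1_bin_index(fev1, bin_width, bin_lo, bin_hi)
    train_ids: list = []
    test_ids: list = []
    for b in np.unique(bins):
        members = ids[bins == b]
        order = rng.permutation(len(members))
        k = _n_train(len(members), train_fraction)
        train_ids.extend(members[order[:k]])
        test_ids.extend(members[order[k:]])
    return PartitionSpec(
        mode="balanced",
        seed=seed,
        train_fraction=train_fraction,
        bin_width=bin_width,
        bin_lo=bin_lo,
        bin_hi=bin_hi,
        train_ids=train_ids,
        test_ids=test_ids,
    )


def random_partition(
    fev1: np.ndarray,
    ids: list | None = None,
    seed: int = 0,
    train_fraction: float = 0.7,
) -> PartitionSpec:
    """Unstratified seeded 70:30 split."""
    fev1 = np.asarray(fev1, dtype=float)
    if fev1.size == 0:
        raise ValueError("empty dataset")
    if ids is None:
        ids = list(range(len(fev1)))
    ids = np.asarray(ids, dtype=object)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    k = _n_train(len(ids), train_fraction)
    return PartitionSpec(
        mode="random",
        seed=seed,
        train_fraction=train_fraction,
        train_ids=list(ids[order[:k]]),
        test_ids=list(ids[order[k:]]),
    )


def build_labelled_dataset(
    feature_rows: pd.DataFrame,
    fev1: np.ndarray,
    subject_ids: list[str] | None = None,
    boundaries: list[tuple[float, str]] | None = None,
) -> pd.DataFrame:
    """Assemble features + FEV1% + derived labels into one tidy table."""
    df = feature_rows.copy()
    df["fev1_pct"] = np.asarray(fev1, dtype=float)
    df["binary_label"] = [label_binary(v) for v in df["fev1_pct"]]
    df["ats_grade"] = [label_ats_grade(v, boundaries) for v in df["fev1_pct"]]
    if subject_ids is not None:
        df["subject_id"] = list(subject_ids)
    return df


def impute_from_train(
    matrix: pd.DataFrame, train_index: pd.Index
) -> tuple[pd.DataFrame, list[str]]:
    """Median-impute missing entries using training rows only.

    Returns the imputed matrix and the list of columns that needed
    imputation (flagged in run reports).
    """
    out = matrix.copy()
    flagged = []
    medians = out.loc[train_index].median()
    for col in out.columns:
        if out[col].isna().any():
            fill = medians[col]
            if np.isnan(fill):
                fill = 0.0
            out[col] = out[col].fillna(fill)
            flagged.append(col)
    return out, flagged
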