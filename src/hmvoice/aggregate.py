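"""Frame → segment → activity → subject feature aggregation.

Every frame-level measure is summarized with five distribution statistics
(mean, median, sample variance, min, max), separately for voiced and
unvoiced frames; a segment additionally carries a seven-value duration block
(run counts, total and mean run durations, voiced fraction).  Segment
vectors are summarized with the same five statistics into activity vectors,
and the four conversational-activity vectors are concatenated in a fixed
order into the subject vector, so every subject shares one stable dimension
naming.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .framing import ACTIVITIES

__all__ = [
    "FeatureVector",
    "summarize_distribution",
    "segment_features",
    "activity_features",
    "subject_vector",
    "subjects_to_matrix",
    "impute_missing",
    "feature_group_of",
    "write_feature_matrix",
    "read_feature_matrix",
]

STAT_NAMES = ("mean", "median", "var", "min", "max")

VOICED_FEATURES = ("f0_hz", "jitter_pct", "shimmer_pct", "hnr_db")
SHARED_FEATURES = (
    ("loudness",)
    + tuple(f"mfcc_{i:02d}" for i in range(13))
    + tuple(f"mfcc_{i:02d}_d" for i in range(13))
    + tuple(f"mfcc_{i:02d}_dd" for i in range(13))
    + ("spectral_entropy",)
)
DURATION_NAMES = (
    "dur.n_voiced_runs",
    "dur.n_unvoiced_runs",
    "dur.voiced_total_s",
    "dur.voiced_mean_run_s",
    "dur.unvoiced_total_s",
    "dur.unvoiced_mean_run_s",
    "dur.voiced_fraction",
)


@dataclass
class FeatureVector:
    """Fixed-dimension numeric summary at segment, activity, or subject level."""

    level: str  # segment | activity | subject
    values: np.ndarray
    names: list[str]
    subject_id: str = ""
    activity: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")


def summarize_distribution(values) -> tuple[float, float, float, float, float]:
    """(mean, median, sample variance, min, max); NaNs dropped, empty → NaNs.

    A singleton has variance 0 by convention.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        return (np.nan,) * 5
    var = float(np.var(x, ddof=1)) if len(x) > 1 else 0.0
    return (
        float(np.mean(x)),
        float(np.median(x)),
        var,
        float(np.min(x)),
        float(np.max(x)),
    )


def _runs(flags: np.ndarray) -> list[int]:
    """Lengths of maximal constant runs of True in a boolean sequence."""
    lengths, count = [], 0
    for f in flags:
        if f:
            count += 1
        elif count:
            lengths.append(count)
            count = 0
    if count:
        lengths.append(count)
    return lengths


def segment_features(
    frame_table: pd.DataFrame,
    hop_s: float = 0.010,
    subject_id: str = "",
    activity: str = "",
) -> FeatureVector:
    """Summarize one segment's frame table into the segment-level vector.

    Voiced-stratum statistics cover all features (including pitch, jitter,
    shimmer, HNR); the unvoiced stratum covers loudness, cepstra and spectral
    entropy only.  If a stratum has no frames its block is all-NaN (resolved
    later by cross-subject imputation).
    """
    voiced_mask = frame_table["voiced"].to_numpy(dtype=bool) if len(frame_table) else np.empty(0, bool)
    values: list[float] = []
    names: list[str] = []

    for feat in VOICED_FEATURES + SHARED_FEATURES:
        col = (
            frame_table.loc[voiced_mask, feat].to_numpy()
            if len(frame_table)
            else np.empty(0)
        )
        for stat, v in zip(STAT_NAMES, summarize_distribution(col)):
            values.append(v)
            names.append(f"voiced.{feat}.{stat}")
    for feat in SHARED_FEATURES:
        col = (
            frame_table.loc[~voiced_mask, feat].to_numpy()
            if len(frame_table)
            else np.empty(0)
        )
        for stat, v in zip(STAT_NAMES, summarize_distribution(col)):
            values.append(v)
            names.append(f"unvoiced.{feat}.{stat}")

    v_runs = _runs(voiced_mask)
    u_runs = _runs(~voiced_mask) if len(voiced_mask) else []
    n_v, n_u = int(voiced_mask.sum()), int((~voiced_mask).sum()) if len(voiced_mask) else 0
    dur = [
        float(len(v_runs)),
        float(len(u_runs)),
        n_v * hop_s,
        np.mean(v_runs) * hop_s if v_runs else 0.0,
        n_u * hop_s,
        np.mean(u_runs) * hop_s if u_runs else 0.0,
        n_v / (n_v + n_u) if (n_v + n_u) else np.nan,
    ]
    values.extend(dur)
    names.extend(DURATION_NAMES)
    return FeatureVector(
        level="segment",
        values=np.asarray(values),
        names=names,
        subject_id=subject_id,
        activity=activity,
    )


def activity_features(segment_vectors: list[FeatureVector]) -> FeatureVector:
    """Five statistics across a subject's segments of one activity."""
    if not segment_vectors:
        raise ValueError("need at least one segment vector")
    names0 = segment_vectors[0].names
    for sv in segment_vectors[1:]:
        if sv.names != names0:
            raise ValueError("segment vectors have mismatched dimensions")
    M = np.vstack([sv.values for sv in segment_vectors])
    values: list[float] = []
    names: list[str] = []
    for j, base in enumerate(names0):
        for stat, v in zip(STAT_NAMES, summarize_distribution(M[:, j])):
            values.append(v)
            names.append(f"{stat}.{base}")
    return FeatureVector(
        level="activity",
        values=np.asarray(values),
        names=names,
        subject_id=segment_vectors[0].subject_id,
        activity=segment_vectors[0].activity,
    )


def subject_vector(
    activity_vectors: dict[str, FeatureVector],
    activity_subset: tuple[str, ...] = ACTIVITIES,
) -> FeatureVector:
    """Concatenate activity vectors in fixed order into the subject vector.

    A missing activity contributes an all-NaN block with the shared dimension
    names (imputed across subjects at analysis time).
    """
    for act in activity_vectors:
        if act not in ACTIVITIES:
            raise ValueError(
                f"unknown activity {act!r}; valid: {', '.join(ACTIVITIES)}"
            )
    for act in activity_subset:
        if act not in ACTIVITIES:
            raise ValueError(
                f"unknown activity {act!r}; valid: {', '.join(ACTIVITIES)}"
            )
    present = [a for a in activity_subset if a in activity_vectors]
    if not present:
        raise ValueError("no activity vectors present for the requested subset")
    template = activity_vectors[present[0]]
    values: list[float] = []
    names: list[str] = []
    subject_id = template.subject_id
    for act in ACTIVITIES:
        if act not in activity_subset:
            continue
        if act in activity_vectors:
            av = activity_vectors[act]
            values.extend(av.values)
            names.extend(f"{act}.{n}" for n in av.names)
        else:
            values.extend([np.nan] * len(template.names))
            names.extend(f"{act}.{n}" for n in template.names)
    return FeatureVector(
        level="subject", values=np.asarray(values), names=names,
        subject_id=subject_id,
    )


def subjects_to_matrix(subject_vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack subject vectors into one table (rows: subjects)."""
    if not subject_vectors:
        raise ValueError("no subject vectors")
    names0 = subject_vectors[0].names
    for sv in subject_vectors[1:]:
        if sv.names != names0:
            raise ValueError("subject vectors have mismatched dimension names")
    df = pd.DataFrame(
        np.vstack([sv.values for sv in subject_vectors]),
        columns=names0,
        index=[sv.subject_id for sv in subject_vectors],
    )
    df.index.name = "subject_id"
    return df


def impute_missing(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cross-subject median imputation of missing dimensions.

    Returns the imputed matrix and a per-subject count of imputed cells.
    Columns that are entirely missing are filled with 0.
    """
    report = {
        str(idx): int(row.isna().sum())
        for idx, row in matrix.iterrows()
        if row.isna().any()
    }
    medians = matrix.median(axis=0)
    out = matrix.fillna(medians).fillna(0.0)
    return out, report


def feature_group_of(name: str) -> str:
    """Map a dimension name to its feature group.

    Prosodic: pitch, jitter, shimmer, HNR and loudness.  Articulation:
    cepstral coefficients and spectral entropy.  Duration-block dimensions
    form their own group.
    """
    if ".dur." in name or name.startswith("dur."):
        return "duration"
    for token in ("f0_hz", "jitter", "shimmer", "hnr", "loudness"):
        if token in name:
            return "prosodic"
    for token in ("mfcc", "entropy"):
        if token in name:
            return "articulation"
    return "other"


def write_feature_matrix(
    matrix: pd.DataFrame, labels: np.ndarray, path: str | Path
) -> None:
    """Write the subject matrix as CSV with subject_id and label first."""
    out = matrix.copy()
    out.insert(0, "label", np.asarray(labels, dtype=int))
    out.to_csv(path, index=True)


def read_feature_matrix(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path, index_col="subject_id")
    labels = df.pop("label").to_numpy(dtype=int)
    return df, labels
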