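"""Audio I/O, segment annotations, short-term framing and silence flagging.

Speech segments are sliced into 25 ms frames at a 10 ms hop (100 frames per
second).  Silence is flagged per frame with a relative energy rule: a frame
is silent when its RMS level falls more than a threshold (default 40 dB)
below the segment's 95th-percentile frame RMS, which makes the decision
invariant to global gain and robust to isolated clicks.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioSegment",
    "FrameSequence",
    "read_wav",
    "read_annotations",
    "cut_segment",
    "slice_frames",
    "detect_silence",
]

DEFAULT_FRAME_LEN_S = 0.025
DEFAULT_HOP_S = 0.010
DEFAULT_SILENCE_THRESHOLD_DB = 40.0

ACTIVITIES = ("FMC", "EC", "SDAC", "LC")


@dataclass
class AudioSegment:
    """A mono waveform cut from a recording, with its annotation metadata."""

    samples: np.ndarray
    sample_rate_hz: float
    subject_id: str = ""
    activity: str = ""
    start_s: float = 0.0
    end_s: float | None = None

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment samples must be 1-D (mono)")
        if self.end_s is None:
            self.end_s = self.start_s + len(self.samples) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass
class FrameSequence:
    """Frames (rows) cut at a fixed hop from one segment."""

    frame_matrix: np.ndarray  # (n_frames, samples_per_frame)
    frame_times: np.ndarray  # center time of each frame, seconds
    sample_rate_hz: float
    frame_len_s: float = DEFAULT_FRAME_LEN_S
    hop_s: float = DEFAULT_HOP_S
    silence_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.silence_flags is None:
            self.silence_flags = np.zeros(len(self.frame_matrix), dtype=bool)
        if len(self.silence_flags) != len(self.frame_matrix):
            raise ValueError("silence_flags length must equal frame count")

    def __len__(self) -> int:
        return len(self.frame_matrix)


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file to float samples in [-1, 1]; stereo is averaged."""
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo input averaged to mono")
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, float(rate)


def read_annotations(path: str | Path) -> list[dict]:
    """Read segment annotations from CSV or JSON.

    Expected fields: ``subject_id``, ``activity``, ``start_s``, ``end_s`` and
    optionally ``audio_path``.  Malformed rows raise with their line number.
    """
    path = Path(path)
    rows: list[dict] = []
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        iterator = enumerate(raw, start=1)
    else:
        with open(path, newline="") as fh:
            raw = list(csv.DictReader(fh))
        iterator = enumerate(raw, start=2)  # header is line 1
    for lineno, row in iterator:
        try:
            rec = {
                "subject_id": str(row["subject_id"]),
                "activity": str(row["activity"]),
                "start_s": float(row["start_s"]),
                "end_s": float(row["end_s"]),
            }
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed annotation row: {exc}") from exc
        if rec["end_s"] <= rec["start_s"]:
            raise ValueError(f"{path}:{lineno}: end_s must exceed start_s")
        if "audio_path" in row:
            rec["audio_path"] = str(row["audio_path"])
        rows.append(rec)
    return rows


def cut_segment(
    samples: np.ndarray,
    sample_rate_hz: float,
    annotation: dict,
) -> AudioSegment:
    """Cut one annotated segment out of a full recording."""
    i0 = int(round(annotation["start_s"] * sample_rate_hz))
    i1 = int(round(annotation["end_s"] * sample_rate_hz))
    if i0 < 0 or i1 > len(samples):
        raise ValueError(
            f"segment [{annotation['start_s']}, {annotation['end_s']}] s is "
            f"outside the recording ({len(samples) / sample_rate_hz:.2f} s)"
        )
    return AudioSegment(
        samples=samples[i0:i1],
        sample_rate_hz=sample_rate_hz,
        subject_id=annotation.get("subject_id", ""),
        activity=annotation.get("activity", ""),
        start_s=annotation["start_s"],
        end_s=annotation["end_s"],
    )


def slice_frames(
    segment: AudioSegment,
    frame_len_s: float = DEFAULT_FRAME_LEN_S,
    hop_s: float = DEFAULT_HOP_S,
) -> FrameSequence:
    """Slice a segment into overlapping fixed-length frames.

    Frame count is ``floor((N - L) / hop) + 1``; a trailing partial frame is
    dropped.  Frame time is the frame center relative to the recording start.
    """
    fs = segment.sample_rate_hz
    L = int(round(frame_len_s * fs))
    hop = int(round(hop_s * fs))
    x = segment.samples
    if len(x) < L:
        warnings.warn(
            f"segment of {len(x)} samples is shorter than one frame ({L}); "
            "returning an empty frame sequence"
        )
        return FrameSequence(
            frame_matrix=np.empty((0, L)),
            frame_times=np.empty(0),
            sample_rate_hz=fs,
            frame_len_s=frame_len_s,
            hop_s=hop_s,
        )
    n_frames = (len(x) - L) // hop + 1
    idx = np.arange(L)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    times = segment.start_s + (hop * np.arange(n_frames) + L / 2.0) / fs
    return FrameSequence(
        frame_matrix=frames,
        frame_times=times,
        sample_rate_hz=fs,
        frame_len_s=frame_len_s,
        hop_s=hop_s,
    )


def detect_silence(
    frames: FrameSequence,
    threshold_db_below_peak: float = DEFAULT_SILENCE_THRESHOLD_DB,
) -> FrameSequence:
    """Flag silent frames relative to the segment's own level.

    The reference level is the 95th percentile of frame RMS in dB; frames more
    than ``threshold_db_below_peak`` dB below it are silent.  An all-zero
    segment is entirely silent.
    """
    if len(frames) == 0:
        return frames
    rms = np.sqrt(np.mean(frames.frame_matrix**2, axis=1))
    if np.all(rms == 0):
        frames.silence_flags = np.ones(len(frames), dtype=bool)
        return frames
    with np.errstate(divide="ignore"):
        rms_db = 20.0 * np.log10(rms)
    ref_db = np.percentile(rms_db[np.isfinite(rms_db)], 95)
    frames.silence_flags = ~(rms_db > ref_db - threshold_db_below_peak)
    return frames
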