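"""End-to-end extraction and experiment pipeline.

``analyze_segment`` runs the full short-term analysis on one speech segment
(framing, silence flagging, pitch-candidate scoring, Viterbi decoding,
voicing, jitter/shimmer/HNR from the time-varying harmonic fit, loudness,
cepstra and spectral entropy); ``run_extract`` cascades segment → activity →
subject aggregation over an annotated corpus, and ``run_experiment`` applies
the repeated undersampled CV protocol to a subject-level feature matrix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate, features, framing, harmonic_model, pitch
from .evalstats import ProtocolConfig, balanced_repeated_cv
from .framing import ACTIVITIES, AudioSegment

__all__ = ["PipelineConfig", "analyze_segment", "run_extract", "run_experiment"]


@dataclass
class PipelineConfig:
    """Full resolved configuration of the extraction/evaluation pipeline."""

    frame_len_s: float = framing.DEFAULT_FRAME_LEN_S
    hop_s: float = framing.DEFAULT_HOP_S
    silence_threshold_db: float = framing.DEFAULT_SILENCE_THRESHOLD_DB
    fmin_hz: float = pitch.DEFAULT_FMIN_HZ
    fmax_hz: float = pitch.DEFAULT_FMAX_HZ
    bins_per_octave: int = pitch.DEFAULT_BINS_PER_OCTAVE
    smooth_width: int = pitch.DEFAULT_SMOOTH_WIDTH
    transition_sigma_log2: float = pitch.DEFAULT_TRANSITION_SIGMA_LOG2
    h_max: int = harmonic_model.DEFAULT_H_MAX
    scoring_h_max: int | None = None  # uncapped harmonic series when scoring pitch
    hnr_threshold_db: float = 0.0
    basis_order: int = harmonic_model.DEFAULT_BASIS_ORDER
    cepstrum: str = "mel"
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    version: str = "1"
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["protocol"] = ProtocolConfig(**d.get("protocol", {}))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the global seed (stable hash rule)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _voiced_runs(active: np.ndarray, voiced: np.ndarray) -> list[list[int]]:
    """Maximal runs of consecutive voiced frame indices."""
    runs: list[list[int]] = []
    current: list[int] = []
    for t in active:
        if voiced[t] and current and t == current[-1] + 1:
            current.append(int(t))
        elif voiced[t]:
            if current:
                runs.append(current)
            current = [int(t)]
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def analyze_segment(
    segment: AudioSegment, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Full frame-level analysis of one segment; one row per non-silent frame."""
    config = config or PipelineConfig()
    frames = framing.slice_frames(segment, config.frame_len_s, config.hop_s)
    frames = framing.detect_silence(frames, config.silence_threshold_db)
    n = len(frames)
    fs = segment.sample_rate_hz

    pitch_hz = np.full(n, np.nan)
    jitter = np.full(n, np.nan)
    shimmer = np.full(n, np.nan)
    hnr = np.full(n, np.nan)
    voiced = np.zeros(n, dtype=bool)

    active = np.where(~frames.silence_flags)[0]
    if len(active):
        grid = pitch.candidate_grid(
            config.fmin_hz, config.fmax_hz, config.bins_per_octave
        )
        lattice = pitch.build_lattice(
            frames.frame_matrix[active], fs, grid,
            smooth_width=config.smooth_width, h_max=config.scoring_h_max,
        )
        contour = pitch.viterbi_track(lattice, config.transition_sigma_log2)
        refined = pitch.refine_contour(
            contour, frames.frame_matrix[active], fs, grid, h_max=config.h_max
        )
        for j, t in enumerate(active):
            f0 = refined[j]
            H = harmonic_model.n_harmonics_for(f0, fs, config.h_max)
            fit = harmonic_model.fit_harmonic_map(
                frames.frame_matrix[t], f0, H, fs
            )
            hnr[t] = harmonic_model.hnr_db(fit)
        voiced[active] = harmonic_model.classify_voicing(
            hnr[active], config.hnr_threshold_db
        )
        pitch_hz[active[voiced[active]]] = refined[voiced[active]]

        # Jitter/shimmer: cycle marks are extracted once per voiced run (the
        # denoised-waveform marks are far better conditioned than per-frame
        # fits) and each frame summarizes the cycles its window covers.
        hop = int(round(config.hop_s * fs))
        L = frames.frame_matrix.shape[1]
        for run in _voiced_runs(active, voiced):
            f0_run = float(np.median([pitch_hz[t] for t in run]))
            s0 = run[0] * hop
            s1 = run[-1] * hop + L
            marks, periods, amps = harmonic_model.segment_cycle_marks(
                segment.samples[s0:s1], fs, f0_run, h_max=config.h_max
            )
            if len(periods) == 0:
                continue
            marks = marks + s0 / fs
            for t in run:
                lo, hi = t * hop / fs, (t * hop + L) / fs
                inside = (marks >= lo) & (marks <= hi)
                jitter[t] = harmonic_model.estimate_jitter(
                    periods[inside[:-1] & inside[1:]]
                )
                shimmer[t] = harmonic_model.estimate_shimmer(
                    amps[inside & ~np.isnan(amps)]
                )

    loud = np.array([features.loudness_rms(f) for f in frames.frame_matrix])
    ceps = (
        np.vstack(
            [
                features.cepstral_coeffs(f, fs, cepstrum=config.cepstrum)
                for f in frames.frame_matrix
            ]
        )
        if n
        else np.empty((0, features.N_CEPSTRA))
    )
    d1 = features.delta_coeffs(ceps) if n else ceps
    d2 = features.delta_coeffs(d1) if n else ceps
    entropy = np.array([features.spectral_entropy(f) for f in frames.frame_matrix])

    return features.assemble_frame_features(
        frames.frame_times, frames.silence_flags, voiced,
        pitch_hz, jitter, shimmer, hnr, loud, ceps, d1, d2, entropy,
    )


def run_extract(
    annotations: list[dict],
    audio_loader,
    config: PipelineConfig | None = None,
    error_log: list | None = None,
) -> pd.DataFrame:
    """Extract the subject-level feature matrix from an annotated corpus.

    ``audio_loader(annotation) -> AudioSegment`` resolves each annotation row
    to its waveform (file-based or synthetic).  Per-segment failures are
    collected in ``error_log`` and the run continues.
    """
    config = config or PipelineConfig()
    seg_vectors: dict[tuple[str, str], list] = {}
    for ann in annotations:
        try:
            segment = audio_loader(ann)
            table = analyze_segment(segment, config)
            sv = aggregate.segment_features(
                table, config.hop_s,
                subject_id=ann["subject_id"], activity=ann["activity"],
            )
        except Exception as exc:  # noqa: BLE001 - per-file errors must not kill the run
            if error_log is not None:
                error_log.append({"annotation": ann, "error": str(exc)})
            continue
        seg_vectors.setdefault((ann["subject_id"], ann["activity"]), []).append(sv)

    by_subject: dict[str, dict] = {}
    for (subject_id, activity), svs in seg_vectors.items():
        by_subject.setdefault(subject_id, {})[activity] = aggregate.activity_features(svs)

    subject_vectors = [
        aggregate.subject_vector(acts) for _, acts in sorted(by_subject.items())
    ]
    return aggregate.subjects_to_matrix(subject_vectors)


def _select_columns(
    matrix: pd.DataFrame, feature_group: str, activities: tuple[str, ...]
) -> pd.DataFrame:
    groups = {"prosodic", "articulation"} if feature_group == "both" else {feature_group}
    if feature_group == "all":
        groups = {"prosodic", "articulation", "duration", "other"}
    cols = [
        c
        for c in matrix.columns
        if aggregate.feature_group_of(c) in groups
        and (not c.split(".")[0] in ACTIVITIES or c.split(".")[0] in activities)
    ]
    return matrix[cols]


def run_experiment(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    config: PipelineConfig | None = None,
    model: str = "svm",
    feature_groups: tuple[str, ...] = ("prosodic",),
    activities: tuple[str, ...] = ACTIVITIES,
) -> dict:
    """Run the balanced repeated CV protocol per requested feature group.

    Returns a JSON-serializable dict keyed by feature group with the
    performance summary, the resolved activity subset, and the config hash.
    """
    config = config or PipelineConfig()
    for g in feature_groups:
        if g not in ("prosodic", "articulation", "both", "all"):
            raise ValueError(
                f"unknown feature group {g!r}; valid: prosodic, articulation, both, all"
            )
    for a in activities:
        if a not in ACTIVITIES:
            raise ValueError(f"unknown activity {a!r}; valid: {', '.join(ACTIVITIES)}")

    results: dict = {"config_hash": config.config_hash(), "activities": list(activities)}
    for group in feature_groups:
        sub = _select_columns(matrix, group, activities)
        if sub.shape[1] == 0:
            sub = matrix  # unstructured column names: use everything
        imputed, _ = aggregate.impute_missing(sub)
        summary = balanced_repeated_cv(
            imputed.to_numpy(), labels, config.protocol, model=model
        )
        results[group] = summary.to_jsonable()
    return results
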