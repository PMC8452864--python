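import numpy as np
import pytest

from hmvoice import synthvoice as sv

FS = 16000.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


@pytest.fixture(scope="session")
def clean_tone():
    """Pure 200 Hz unit sinusoid, 1 s."""
    spec = sv.VoicedSpec(
        duration_s=1.0, sample_rate_hz=FS, f0_contour=200.0,
        n_harmonics=1, harmonic_amplitudes=[1.0],
    )
    return sv.synth_voiced(spec)


@pytest.fixture(scope="session")
def rich_voiced():
    """Harmonic-rich 200 Hz voiced signal with mild noise, 1 s."""
    spec = sv.VoicedSpec(
        duration_s=1.0, sample_rate_hz=FS, f0_contour=200.0,
        n_harmonics=5, hnr_db=20.0, seed=11,
    )
    return sv.synth_voiced(spec)


@pytest.fixture(scope="session")
def mixed_utterance():
    """Voiced / unvoiced / silence utterance with ground-truth intervals."""
    plan = sv.UtterancePlan(
        parts=[
            sv.UtterancePart(
                "voiced", 0.6,
                spec=sv.VoicedSpec(
                    duration_s=0.6, f0_contour=220.0, n_harmonics=5,
                    jitter_pct=1.0, shimmer_pct=1.0, hnr_db=20.0, seed=1,
                ),
            ),
            sv.UtterancePart("unvoiced", 0.4, noise_level=0.2),
            sv.UtterancePart("silence", 0.3),
        ],
        sample_rate_hz=FS,
    )
    return sv.synth_utterance(plan, seed=5)


@pytest.fixture(scope="session")
def null_cohort():
    """118-subject feature table with no class signal (90 cases, 28 controls)."""
    spec = sv.CohortSpec(
        n_case=90, n_control=28, pitch_shift=0.0, loudness_shift=0.0,
        loudness_var_ratio=1.0, seed=42,
    )
    return sv.synth_cohort(spec)


@pytest.fixture(scope="session")
def separable_cohort():
    """Cohort with >=3 pooled-SD group shifts on the informative dimensions."""
    spec = sv.CohortSpec(
        n_case=90, n_control=28, pitch_shift=3.0, loudness_shift=3.0,
        loudness_var_ratio=1.0, seed=7,
    )
    return sv.synth_cohort(spec)
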