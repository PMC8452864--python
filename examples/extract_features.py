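"""Extract a subject-level feature matrix from a tiny synthetic corpus.

Synthesizes two subjects whose voices differ in pitch and loudness, runs the
full short-term -> segment -> activity -> subject cascade, and prints the
pitch and loudness dimensions that separate them.
"""

import numpy as np

from hmvoice import VoicedSpec, run_extract, synth_voiced
from hmvoice.framing import AudioSegment

FS = 16000.0

waves = {}
for subject, f0, gain in (("low_loud", 190.0, 1.5), ("high_quiet", 250.0, 1.0)):
    spec = VoicedSpec(duration_s=1.2, f0_contour=f0, n_harmonics=5,
                      jitter_pct=1.0, shimmer_pct=1.0, hnr_db=20.0, seed=3)
    wave, _ = synth_voiced(spec)
    waves[subject] = gain * wave

annotations = [
    {"subject_id": s, "activity": "FMC", "start_s": 0.0, "end_s": 1.2}
    for s in waves
]


def loader(ann):
    return AudioSegment(samples=waves[ann["subject_id"]], sample_rate_hz=FS,
                        subject_id=ann["subject_id"], activity=ann["activity"])


matrix = run_extract(annotations, loader)
print(f"subjects: {list(matrix.index)}")
print(f"feature dimensions per subject: {matrix.shape[1]}")
for col in ("FMC.mean.voiced.f0_hz.mean", "FMC.mean.voiced.loudness.mean",
            "FMC.mean.voiced.jitter_pct.mean", "FMC.mean.voiced.hnr_db.mean"):
    print(f"{col}:")
    for s in matrix.index:
        print(f"  {s:>11}: {matrix.loc[s, col]:.3f}")
# The mean-pitch dimension recovers the planted 190 vs 250 Hz difference and
# the loudness dimension the 1.5x gain difference; every other dimension is
# computed the same way for every subject, giving a fixed-width matrix ready
# for classification.
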