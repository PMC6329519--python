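"""ERP difference waves, FDR mask and divergence onset.

Generates an epoched EEG study in which an animal vs non-animal effect
exists only in the HIGH-complexity condition and only from 220 ms
(a feedback-stage effect), then runs the full ERP chain: electrode
pooling, subject difference waves, point-wise t-tests, one
Benjamini-Hochberg correction over the whole family, and onset
detection.
"""

from scenecomplex.neurostats import (
    difference_waves,
    divergence_onset,
    fdr_mask,
    pointwise_tests,
    pool_electrodes,
)
from scenecomplex.synthetic import GeneratorTruth, StudyDesign, gen_subject_eeg

truth = GeneratorTruth()
epochs, _ = gen_subject_eeg(truth, StudyDesign(), seed=11, simulate_behavior=False)
print(f"{epochs.n_trials} epochs, channels: {', '.join(epochs.channels)}")

pooled = pool_electrodes(epochs)
waves = difference_waves(pooled)
mask = fdr_mask(pointwise_tests(waves), alpha=0.01, times=pooled.times)
print(f"FDR-corrected p threshold (alpha = 0.01): q = {mask.q_threshold:.5f}")

for instr in ("speed", "accurate"):
    for cond in ("LOW", "MED", "HIGH"):
        m = mask.for_contrast(instr, cond)
        onset = divergence_onset(m, mask.times)
        onset_txt = f"{onset:6.1f} ms" if onset is not None else "  none"
        print(f"  {instr:8s} {cond:4s}: onset {onset_txt}, "
              f"{int(m.sum()):3d} significant samples")
print(
    "\nOnly the HIGH condition diverges, and only after the generated "
    "220 ms onset — the signature of feedback rather than feed-forward "
    "processing."
)
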