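"""Trial-level ERP amplitude as a drift-rate regressor.

Generates a jointly coherent study — each trial's measured 220-325 ms
window amplitude modulates that trial's drift before the RT is
simulated, with a strong negative weight for HIGH complexity — and
recovers the weights with the hierarchical regression model.
"""

import numpy as np

from scenecomplex.ddm import MCMCConfig, fit_regression, posterior_prob_tests
from scenecomplex.synthetic import GeneratorTruth, StudyDesign, gen_subject_eeg

truth = GeneratorTruth()  # w = -0.03 (LOW, MED), -0.10 (HIGH)
design = StudyDesign()  # 20 subjects x 160 trials per condition x instruction
_, trials = gen_subject_eeg(truth, design, seed=23)
print(f"{len(trials)} coupled trials from {design.n_subjects} subjects")

# takes a couple of minutes at this scale
trace = fit_regression(trials, mcmc=MCMCConfig(chains=3, draws=800, burn=400, seed=4))
print(f"max R-hat: {trace.max_rhat():.3f}")
for cond in ("LOW", "MED", "HIGH"):
    w = trace[f"w_{cond}"]
    p = posterior_prob_tests(trace, f"w_{cond}", 0.0)
    print(f"  w_{cond:4s}: mean {np.mean(w):+.4f}  (true {truth.w[cond]:+.3f})  "
          f"p vs 0 = {p:.4f}")
print(f"P(w_HIGH < w_LOW) = {np.mean(trace['w_HIGH'] < trace['w_LOW']):.3f}")
print(
    "\nNegative weights: trials with a stronger feedback-window response "
    "accumulate evidence more slowly, most clearly for high-complexity scenes."
)
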