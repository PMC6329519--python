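"""Hierarchical DDM recovery: condition-dependent drift, instruction-
dependent boundary.

Generates behavior for 10 subjects from known group parameters
(v slowest for HIGH complexity; boundary larger under accuracy
instructions), fits the hierarchical model by MCMC, and prints the
group posteriors and the posterior-mass hypothesis tests.
"""

import numpy as np

from scenecomplex.ddm import MCMCConfig, ModelSpec, fit_hierarchical
from scenecomplex.synthetic import GeneratorTruth, gen_subject_behavior

truth = GeneratorTruth()  # v = 1.4 / 1.3 / 0.8, a = 1.0 (speed) / 1.8 (accurate)
trials = gen_subject_behavior(truth, n_subjects=10, trials_per_cell=40, seed=5)
print(f"{len(trials)} trials from 10 subjects")

trace = fit_hierarchical(
    trials,
    ModelSpec(boundary_factors=("instruction",)),
    MCMCConfig(chains=3, draws=1000, burn=400, seed=9),
)
cols = ["parameter", "mean", "sd", "q2.5", "q97.5", "rhat"]
summary = trace.summary()
print(summary[~summary.parameter.str.startswith("sigma")][cols].round(3).to_string(index=False))
print(f"\nmax R-hat: {trace.max_rhat():.3f} (<= 1.1 means the chains converged)")
print(f"P(v_HIGH < v_MED)      = {np.mean(trace['v_HIGH'] < trace['v_MED']):.3f}")
print(f"P(a_accurate > a_speed) = {np.mean(trace['a_accurate'] > trace['a_speed']):.3f}")
print(
    "\nEvidence accumulates most slowly for high-complexity scenes, while "
    "only the instruction moves the decision boundary."
)
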