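import numpy as np
import pandas as pd
import pytest

from scenecomplex.synthetic import GeneratorTruth, StudyDesign, gen_subject_eeg


@pytest.fixture(scope="session")
def small_coupled_study():
    """A small but complete EEG+behavior study with known ground truth."""
    truth = GeneratorTruth()
    design = StudyDesign(n_subjects=6, trials_per_cell=16)
    epochs, trials = gen_subject_eeg(truth, design, seed=2024)
    return truth, design, epochs, trials


@pytest.fixture(scope="session")
def single_cell_trials():
    """Accuracy-coded trials from one known DDM cell (v=1, a=1.6, t_er=0.3)."""
    from scenecomplex.ddm import DDMParams, simulate_trials

    sim = simulate_trials(DDMParams(v=1.0, a=1.6, t_er=0.3), n=10_000, seed=77)
    return pd.DataFrame(
        {"rt": sim["rt"], "correct": (sim["response"] == "upper").to_numpy()}
    )
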