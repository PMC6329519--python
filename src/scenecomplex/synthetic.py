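"""Synthetic study generator with known ground truth.

Builds every input the analysis chain consumes without any downloads:

* dead-leaves-style textures whose fragment count drives contrast
  energy and spatial coherence monotonically, emulating an image bank
  spanning the sparse-to-cluttered complexity continuum;
* per-subject two-choice behavior simulated from a drift-diffusion
  process with condition-dependent drift and instruction-dependent
  boundary;
* epoched EEG in which an animal vs non-animal effect is injected only
  from a configurable onset (~220 ms) in configured conditions, with
  the trial's realized feedback-window amplitude coupled to that
  trial's drift before RTs are simulated — so behavior and EEG are
  jointly coherent and the ERP-on-drift regression is a genuine
  recovery problem.

Every stochastic output is traceable to a recorded seed and the ground
truth is serialised beside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse

from .ddm.simulate import euler_paths, simulate_trials
from .ddm.wfpt import DDMParams
from .scenestats import SceneStatsConfig, scene_statistics

__all__ = [
    "GeneratorTruth",
    "StudyDesign",
    "gen_texture",
    "gen_stimulus_bank",
    "gen_subject_behavior",
    "gen_subject_eeg",
    "gen_study",
]

CONDITIONS = ("LOW", "MED", "HIGH")
INSTRUCTIONS = ("speed", "accurate")
CATEGORIES = ("animal", "non-animal")


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth parameters behind one synthetic study.

    Drift rates are per condition; boundaries per instruction;
    regression weights (on the per-subject z-scored feedback-window
    amplitude) per condition.  The ERP effect template is active for
    animal trials of ``erp_effect_conditions`` only, rising as a
    half-Gaussian from ``erp_onset_ms`` to full amplitude at
    ``erp_peak_ms`` and sustained thereafter.
    """

    v: Mapping[str, float] = field(
        default_factory=lambda: {"LOW": 1.4, "MED": 1.3, "HIGH": 0.8}
    )
    a: Mapping[str, float] = field(
        default_factory=lambda: {"speed": 1.0, "accurate": 1.8}
    )
    t_er: float = 0.3
    w: Mapping[str, float] = field(
        default_factory=lambda: {"LOW": -0.03, "MED": -0.03, "HIGH": -0.10}
    )
    between_subject_sd: Mapping[str, float] = field(
        default_factory=lambda: {"v": 0.15, "a": 0.10, "t_er": 0.03, "w": 0.02}
    )
    erp_effect_conditions: tuple[str, ...] = ("HIGH",)
    erp_onset_ms: float = 220.0
    erp_peak_ms: float = 325.0
    erp_amplitude: float = 2.0       # uV
    erp_trial_gain_sd: float = 0.3   # trial-to-trial gain of the effect
    erp_noise_sd: float = 4.5        # per-trial pooled-signal noise, uV
    channel_noise_sd: float = 3.0    # independent per-channel noise, uV

    def to_json(self) -> str:
        d = asdict(self)
        d["erp_effect_conditions"] = list(self.erp_effect_conditions)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorTruth":
        d = json.loads(text)
        d["erp_effect_conditions"] = tuple(d["erp_effect_conditions"])
        return cls(**d)


@dataclass(frozen=True)
class StudyDesign:
    """Sizes and timing of the synthetic study (EEG-experiment layout)."""

    n_subjects: int = 20
    trials_per_cell: int = 80   # per condition x instruction x category
    sfreq: float = 256.0
    epoch_start_ms: float = -100.0
    epoch_end_ms: float = 500.0
    channels: tuple[str, ...] = ("Oz", "POz", "O1", "O2", "PO3", "PO4", "PO7", "PO8")


# --------------------------------------------------------------------------
# images


def gen_texture(
    complexity: int,
    size: tuple[int, int] = (128, 128),
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Dead-leaves-style texture with ``complexity`` overlapping ellipses.

    A flat mid-grey background is covered by ``complexity`` random
    ellipses of random luminance; later leaves occlude earlier ones.
    One leaf gives a sparse, easily segmented scene; hundreds give a
    cluttered, fragmented one.  Optional white noise can be added via
    ``noise_sd``; the default is noise-free so flat regions carry
    exactly zero local contrast (discarded, and counted, by the Weibull
    fit).  Returns a float image in [0, 1]; deterministic given the
    seed.
    """
    if complexity < 1:
        raise ValueError("complexity (fragment count) must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = size
    img = np.full((h, w), 0.5)
    for _ in range(complexity):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(4, h / 8), rng.uniform(4, w / 8)
        rot = rng.uniform(0, np.pi)
        lum = rng.uniform(0.05, 0.95)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
        img[rr, cc] = lum
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal((h, w))
    return np.clip(img, 0.0, 1.0)


def gen_stimulus_bank(
    n_images: int = 1000,
    seed: int = 0,
    size: tuple[int, int] = (128, 128),
    max_complexity: int = 500,
    stats_config: SceneStatsConfig | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Image bank spanning the complexity continuum, with labels and truth.

    Fragment counts are drawn log-uniformly in [1, max_complexity];
    animal / non-animal category labels are assigned independently of
    complexity so that both categories populate every complexity level
    (matching is then feasible).  Returns the images and a frame with
    image_id, category, complexity (ground truth), ce, sc.
    """
    if n_images < 200:
        raise ValueError("bank needs >= 200 images")
    rng = np.random.default_rng(seed)
    cfg = stats_config or SceneStatsConfig()
    ks = np.exp(rng.uniform(0.0, np.log(max_complexity), n_images)).astype(int)
    ks = np.clip(ks, 1, max_complexity)
    cats = np.where(np.arange(n_images) % 2 == 0, "animal", "non-animal")
    rng.shuffle(cats)
    images, rows = [], []
    for i, (k, cat) in enumerate(zip(ks, cats)):
        img = gen_texture(int(k), size=size, seed=rng)
        st = scene_statistics(img, cfg, image_id=f"img{i:05d}")
        images.append(img)
        rows.append(
            {
                "image_id": st.image_id,
                "category": cat,
                "complexity": int(k),
                "ce": st.ce,
                "sc": st.sc,
            }
        )
    return images, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# behavior


def _draw_subject_params(truth: GeneratorTruth, rng: np.random.Generator):
    sd = truth.between_subject_sd
    v = {c: truth.v[c] + sd["v"] * rng.standard_normal() for c in truth.v}
    a = {
        i: max(0.3, truth.a[i] + sd["a"] * rng.standard_normal()) for i in truth.a
    }
    t_er = float(np.clip(truth.t_er + sd["t_er"] * rng.standard_normal(), 0.1, 0.6))
    w = {c: truth.w[c] + sd["w"] * rng.standard_normal() for c in truth.w}
    return v, a, t_er, w


def _simulate_cell(v_signed, a, t_er, n, rng) -> pd.DataFrame:
    out = simulate_trials(
        DDMParams(v=v_signed, a=a, t_er=t_er), n=n, dt=1e-3, seed=rng
    )
    # re-simulate censored paths so cells stay balanced
    while len(out) < n:
        extra = simulate_trials(
            DDMParams(v=v_signed, a=a, t_er=t_er), n=n - len(out), dt=1e-3, seed=rng
        )
        out = pd.concat([out, extra], ignore_index=True)
    return out


def gen_subject_behavior(
    truth: GeneratorTruth,
    n_subjects: int = 20,
    trials_per_cell: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate balanced response-coded behavior for every subject.

    Cells are condition x instruction x category with ``trials_per_cell``
    trials each.  Animal stimuli drift toward the upper ("target")
    boundary at +v, non-animal stimuli at -v; subject-level parameters
    are drawn around the group truth.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for j in range(n_subjects):
        v_j, a_j, t_j, _ = _draw_subject_params(truth, rng)
        for cond in truth.v:
            for instr in truth.a:
                for cat in CATEGORIES:
                    sgn = 1.0 if cat == "animal" else -1.0
                    sim = _simulate_cell(
                        sgn * v_j[cond], a_j[instr], t_j, trials_per_cell, rng
                    )
                    parts.append(
                        pd.DataFrame(
                            {
                                "subject": f"s{j:02d}",
                                "condition": cond,
                                "instruction": instr,
                                "category": cat,
                                "choice": np.where(
                                    sim["response"] == "upper", "target", "non-target"
                                ),
                                "rt": sim["rt"].to_numpy(),
                            }
                        )
                    )
    df = pd.concat(parts, ignore_index=True)
    df["correct"] = (df["category"] == "animal") == (df["choice"] == "target")
    return df


# --------------------------------------------------------------------------
# EEG


def _erp_templates(times_ms: np.ndarray, truth: GeneratorTruth):
    """Condition baselines and the category-effect template (uV)."""
    base = {}
    for cond, scale in zip(CONDITIONS, (1.0, 1.1, 1.2)):
        p1 = 3.0 * scale * np.exp(-0.5 * ((times_ms - 100.0) / 20.0) ** 2)
        n1 = -2.0 * np.exp(-0.5 * ((times_ms - 170.0) / 25.0) ** 2)
        base[cond] = np.where(times_ms >= 0, p1 + n1, 0.0)
    rise_sd = (truth.erp_peak_ms - truth.erp_onset_ms) / 3.0
    effect = np.zeros_like(times_ms)
    rising = (times_ms >= truth.erp_onset_ms) & (times_ms < truth.erp_peak_ms)
    effect[rising] = np.exp(
        -0.5 * ((times_ms[rising] - truth.erp_peak_ms) / rise_sd) ** 2
    )
    effect[times_ms >= truth.erp_peak_ms] = 1.0
    return base, truth.erp_amplitude * effect


def gen_subject_eeg(
    truth: GeneratorTruth,
    design: StudyDesign | None = None,
    seed: int = 0,
    simulate_behavior: bool = True,
):
    """Jointly coherent epoched EEG and behavior.

    For every trial an epoch is built as condition baseline + (category
    effect template, active only for animal trials of the configured
    conditions, times a trial-specific gain) + trial noise shared
    across channels + independent channel noise.  The trial's realized
    window amplitude (mean pooled voltage in the onset-to-peak window)
    is z-scored within subject and fed into that trial's drift,
    v_i = v_cond + w_cond * z_i, before the RT is simulated — evidence
    accumulation slows on trials with a stronger feedback response when
    w is negative.

    Returns ``(epochs, trials)`` where ``trials`` carries the simulated
    behavior plus the measured ``erp_amp`` per trial.  With
    ``simulate_behavior=False`` the diffusion step is skipped (epochs
    and labels only), which is much cheaper when only the ERP side is
    needed.
    """
    from .neurostats import EpochArray  # avoid import cycle at module load

    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / design.sfreq
    times = np.arange(design.epoch_start_ms, design.epoch_end_ms + dt_ms / 2, dt_ms)
    base, effect = _erp_templates(times, truth)
    win = (times >= truth.erp_onset_ms) & (times <= truth.erp_peak_ms)
    n_ch = len(design.channels)

    all_epochs, all_rows = [], []
    for j in range(design.n_subjects):
        v_j, a_j, t_j, w_j = _draw_subject_params(truth, rng)
        cells = [
            (cond, instr, cat)
            for cond in CONDITIONS
            for instr in INSTRUCTIONS
            for cat in CATEGORIES
        ]
        sig_list, row_list = [], []
        for cond, instr, cat in cells:
            n = design.trials_per_cell
            gain = (
                1.0 + truth.erp_trial_gain_sd * rng.standard_normal(n)
                if (cat == "animal" and cond in truth.erp_effect_conditions)
                else np.zeros(n)
            )
            signal = base[cond][None, :] + gain[:, None] * effect[None, :]
            signal = signal + truth.erp_noise_sd * rng.standard_normal((n, len(times)))
            sig_list.append(signal)
            for _ in range(n):
                row_list.append({"condition": cond, "instruction": instr, "category": cat})
        signal = np.concatenate(sig_list)  # trials x time, pooled-level signal
        rows = pd.DataFrame(row_list)
        epochs_j = (
            signal[:, None, :]
            + truth.channel_noise_sd
            * rng.standard_normal((len(rows), n_ch, len(times)))
        )

        # measured feedback-window amplitude, exactly what the analysis computes
        amp = epochs_j.mean(axis=1)[:, win].mean(axis=1)
        rows.insert(0, "subject", f"s{j:02d}")
        rows["erp_amp"] = amp
        if simulate_behavior:
            z = (amp - amp.mean()) / amp.std()
            # coupled behavior: drift modulated by the trial's feedback response
            sgn = np.where(rows["category"] == "animal", 1.0, -1.0)
            v_cond = rows["condition"].map(v_j).to_numpy()
            w_cond = rows["condition"].map(w_j).to_numpy()
            drift = sgn * np.maximum(0.05, v_cond + w_cond * z)
            a_tr = rows["instruction"].map(a_j).to_numpy()
            dtimes, hit_upper = euler_paths(
                drift, a_tr, 0.5 * a_tr, dt=1e-3, rng=rng
            )
            # re-simulate the rare censored paths until all are absorbed
            while np.isnan(dtimes).any():
                redo = np.flatnonzero(np.isnan(dtimes))
                dtimes[redo], hit_upper[redo] = euler_paths(
                    drift[redo], a_tr[redo], 0.5 * a_tr[redo], dt=1e-3, rng=rng
                )
            rows["choice"] = np.where(hit_upper, "target", "non-target")
            rows["rt"] = dtimes + t_j
            rows["correct"] = (rows["category"] == "animal") == (rows["choice"] == "target")
        all_epochs.append(epochs_j)
        all_rows.append(rows)

    labels = pd.concat(all_rows, ignore_index=True)
    epochs = EpochArray(
        voltages=np.concatenate(all_epochs),
        times=times,
        channels=list(design.channels),
        sfreq=design.sfreq,
        labels=labels,
        units="uV",
    )
    return epochs, labels.copy()


# --------------------------------------------------------------------------
# full study


def gen_study(
    out_dir: str | Path,
    seed: int = 0,
    truth: GeneratorTruth | None = None,
    design: StudyDesign | None = None,
    n_images: int = 1000,
    image_size: tuple[int, int] = (128, 128),
) -> dict:
    """Generate and write a complete synthetic study to ``out_dir``.

    Products: images/ (PNG), stats.csv, trials.csv, epochs.npz + .json,
    truth.json.  Returns a manifest of the written paths.  Identical
    seeds give identical datasets.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = truth or GeneratorTruth()
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))

    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    images, bank = gen_stimulus_bank(n_images=n_images, seed=sub(), size=image_size)
    for img, image_id in zip(images, bank["image_id"]):
        Image.fromarray((img * 255).astype(np.uint8)).save(img_dir / f"{image_id}.png")
    bank.to_csv(out / "stats.csv", index=False)

    epochs, trials = gen_subject_eeg(truth, design, seed=sub())
    trials.to_csv(out / "trials.csv", index=False)
    epochs.save(out / "epochs")
    (out / "truth.json").write_text(truth.to_json())

    manifest = {
        "seed": seed,
        "images": str(img_dir),
        "stats": str(out / "stats.csv"),
        "trials": str(out / "trials.csv"),
        "epochs": str(out / "epochs.npz"),
        "truth": str(out / "truth.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
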