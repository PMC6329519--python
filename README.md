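# scenecomplex

From scene statistics to decision dynamics and feedback ERPs.

`scenecomplex` implements, as a tested and reusable Python library, the
computational chain used to study how the **complexity of a natural
scene** governs the amount of **recurrent (feedback) processing** the
visual system invests in detecting an object:

1. **Scene statistics** (`scenecomplex.scenestats`) — local contrast is
   measured with Gaussian-derivative filters (a linear model of
   contrast-sensitive receptive fields) and its distribution summarised
   by two numbers: **contrast energy** `CE` (spatial mean of contrast
   magnitude, approximating the scale β of a Weibull fit to the
   contrast histogram) and **spatial coherence** `SC` (divisively
   normalised pooling, mean/sd, approximating the Weibull shape γ).
   Sparse, easily segmented scenes sit at low CE/SC; cluttered,
   fragmented scenes at high CE/SC.
2. **Matched stimulus sampling** (`scenecomplex.sampling`) — images are
   binned into LOW / MED / HIGH complexity by the lower 25%, central
   35% and upper 25% percentiles of a joint CE/SC score, and equal
   numbers of target (animal) and non-target images are selected per
   condition so the categories are indistinguishable in CE and SC
   (two-sample *t* and Wilcoxon rank-sum diagnostics).
3. **Drift-diffusion modelling** (`scenecomplex.ddm`) — the Wiener
   first-passage-time density (dual small/large-time series), a
   bridge-corrected Euler simulator, EZ closed forms, and a
   hierarchical Bayesian sampler (Metropolis-within-Gibbs) in which the
   drift rate *v* varies over complexity conditions, the boundary *a*
   over speed/accuracy instructions, and — in the regression variant —
   each trial's drift is a linear function of its single-trial ERP
   amplitude: `v_i = v_cond + w_cond · erp_i`.
4. **ERP statistics** (`scenecomplex.neurostats`) — RT filtering,
   repeated-measures ANOVA with partial η², Šidák post-hocs, electrode
   pooling, animal-minus-non-animal difference waves, point-wise
   *t*-tests, one Benjamini–Hochberg FDR correction over the whole
   family (instructions × contrasts × timepoints), divergence-onset
   detection and 220–325 ms window amplitudes.
5. **Synthetic data** (`scenecomplex.synthetic`) — dead-leaves image
   banks spanning the CE/SC continuum and jointly coherent
   behavior + EEG studies with known ground truth, so every inferential
   step is testable as a recovery problem.
6. **Workflow** (`scenecomplex.workflow` and the `scenecomplex` CLI) —
   one configuration object runs all stages in order and writes CSVs
   plus a Markdown report, with a config hash stamped on every output.

The library is aimed at researchers in visual perception and
decision modelling who want a transparent, dependency-light version of
this analysis chain to adapt, or a reference implementation to test
against.

## Worked example

`examples/` holds one short script per capability. For instance, the
ERP chain on a synthetic study whose animal/non-animal effect exists
only in the HIGH condition and only from 220 ms:

```bash
$ python examples/erp_analysis.py
19200 epochs, channels: Oz, POz, O1, O2, PO3, PO4, PO7, PO8
FDR-corrected p threshold (alpha = 0.01): q = 0.00193
  speed    LOW : onset   none,   1 significant samples
  speed    MED : onset   none,   0 significant samples
  speed    HIGH: onset  278.9 ms,  62 significant samples
  accurate LOW : onset   none,   0 significant samples
  accurate MED : onset   none,   1 significant samples
  accurate HIGH: onset  271.1 ms,  63 significant samples
```

Only the HIGH condition shows a sustained difference wave, and its
detected onset falls after the generated 220 ms — the statistical
signature of a feedback-stage effect.  The hierarchical DDM recovery
(`examples/hierarchical_fit.py`) prints the complementary behavioral
result:

```
 parameter  mean    sd  q2.5  q97.5  rhat
a_accurate 1.818 0.052 1.716  1.925 1.000
   a_speed 0.984 0.041 0.909  1.074 0.999
      t_er 0.303 0.021 0.261  0.344 1.000
    v_HIGH 0.885 0.049 0.788  0.981 1.019
     v_LOW 1.431 0.055 1.323  1.537 1.008
     v_MED 1.364 0.059 1.248  1.481 1.014
P(v_HIGH < v_MED)      = 1.000
P(a_accurate > a_speed) = 1.000
```

Drift is slowest for high-complexity scenes (generating values 1.4 /
1.3 / 0.8) while only the task instruction moves the boundary
(1.0 vs 1.8) — both recovered within a few percent with R̂ ≈ 1.

A complete study can be generated and analysed from the shell:

```bash
scenecomplex simulate --out data --seed 42
scenecomplex all --data data --out results --seed 42
```

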