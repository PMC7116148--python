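# infermap

Analysis toolkit for multi-day **sensory-preconditioning (inference)
experiments** with chronic hippocampal unit recordings.  In this paradigm an
auditory cue `Xn` predicts a visual cue `Yn` (observational learning), the
visual cue later predicts a rewarding (set 1) or neutral (set 2) outcome `Zn`
(conditioning), and finally the auditory cues are played alone (inference
test): reward-seeking to `X1` but not `X2` indicates the animal inferred the
unobserved `X1 -> Z1` relationship.  The package implements the neural and
behavioral computations such a study needs, end to end:

* **Behavior** — decision-point filtering (the latest moment with speed
  < 5 cm/s before the animal enters the outcome area; neural data after it
  are censored to control for place and approach confounds), reward-seeking
  bias measures, and DABEST-style effect sizes with bias-corrected-and-
  accelerated (BCa) bootstrap confidence intervals.
* **Cue ensembles** — per-neuron firing rates in 100 ms bins, Z-scored and
  regressed on cue indicators plus trial speed; a unit joins the ensemble of
  cue *c* when its weight `w_c` satisfies `w_c > mean(w_c) + 2·SD(w_c)`
  (across units) and `w_c > 0`.  A time-resolved companion regression relates
  firing to inference performance (correct vs incorrect) per peristimulus bin.
* **Representational similarity** — non-symmetric cross-stage RSMs
  (test-condition × training-condition Pearson correlations between
  population vectors), the within-minus-between association statistic,
  model-RSM multiple regression, one-sided Wilcoxon signed-rank tests across
  days and permutation nulls that shuffle auditory-cue identities.
* **Spike timing** — cross-correlograms with joint-probability change
  relative to a 50 ms pre-trigger baseline, Z-scored spike-triggered
  averages in a ±100 ms window at 1 ms resolution (pairs with < 20 target
  spikes excluded), and the after-minus-before asymmetry with bootstrap
  estimation.
* **Sharp-wave/ripples** — detection on the band-passed (135–250 Hz),
  reference-subtracted LFP at 7 SD above the immobility background, and the
  coactivation statistics: for a unit tuple, the normalized joint-firing
  probability

  ```
  p̂ = (n / N) / f̄
  ```

  (`n` SWRs where all members fired, `N` total SWRs in the epoch, `f̄` the
  members' mean firing rate), contrasted early (days 1–4) vs late (days 5–8)
  with bootstrap estimation, a set × day ANOVA with Tukey post hoc tests,
  X-shuffle permutation controls, SWR co-firing correlations and
  first-spike-order binomial tests.
* **Synthetic sessions** — a generator that emulates the task (cue-tuned
  Poisson units, speed coupling, planted decision points, planted spike
  lags, scheduled ripple coactivation) with full ground truth, so every
  stage is validated by parameter recovery and null calibration.

## Worked example

```python
import infermap as im

cfg = im.make_demo_config(seed=2)            # 8-day synthetic session
session, truth = im.generate_session(cfg)

res = im.CueEnsembleModel(session).fit()     # cue GLM + 2-SD ensembles
print(res.summary().head(3).to_string(index=False))
```

```
cue  threshold  n_members members
 X1   0.540635          2    0,27
 X2   0.530573          2   10,19
 Y1   0.550799          1      12
```

Each row is one cue-specific ensemble: the 2-SD weight threshold for that
cue and the units exceeding it (here exactly the generator's planted
X1-tuned units 0 and 27, and so on).

```python
rep = im.run_pipeline(dict(seed=2, n_perm=1000, n_boot=2000))
print(rep["rsa"]["correct"])
print(rep["swr"]["triplets"]["interaction_F"])
```

```
{'n_days': 8, 'within_minus_between': 0.3827800925462289,
 'wilcoxon_p': 0.00390625, 'permutation_p': 0.003996003996003996}
206.9675861312637
```

On correctly inferred trials the population pattern evoked by each auditory
cue resembles its associated visual cue (within-minus-between r = +0.38,
significant by both Wilcoxon and permutation test), and ripple coactivation
of set-1 triplets grows from early to late days while set 2 stays flat
(set × day interaction F ≈ 207) — the planted prospective-code and
"join-the-dots" patterns, recovered by the analysis chain.

The same stages are available from a shell:

```bash
infermap simulate --seed 2 --out session_dir --with-lfp
infermap ensembles session_dir
infermap rsa session_dir --n-perm 1000
infermap all --seed 2 --out results_dir
```

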