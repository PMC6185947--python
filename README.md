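# contrastpop

Population analysis of perceptual learning in a two-alternative
forced-choice (2-AFC) contrast-discrimination task, for multi-channel
spiking data recorded chronically across training days.

A subject compares a test grating (one of 14 contrasts between 10% and
60%) against a fixed 30% sample grating presented earlier in the same
trial and reports "higher" or "lower".  Each recording channel (a small
multi-unit cluster) is contrast-tuned, and the scientific questions are
how that tuning, the channel's stimulus discriminability, its relation to
the upcoming choice, the inter-channel correlation structure, and the
linearly decodable population information all change as the subject
learns.  The package implements the complete analysis chain plus a
synthetic-data generator that emulates the experiment's trial and
population structure, so every estimator can be validated against known
ground truth without any recording on hand.

## What it computes

* **Contrast response functions** — Naka–Rushton fits
  `R(C) = Rmax·Cⁿ/(Cⁿ + C50ⁿ) + M` per channel/day, their tangent slope
  at the 30% boundary, and Spearman trend tests of channel-averaged
  parameters against training day (`contrastpop.tuning`).
* **Discriminability** — tie-corrected AUROC between sample- and
  test-evoked count distributions; COBE, a count-based paired estimator
  of P(test > sample) computed within trials so that slow shared gain
  fluctuations cancel; four-parameter Weibull neurometric fits
  `y(x) = 1 − δ − γ·exp(−(x/α)^β)` and the point of neuronal equality
  (PNE, where the fitted curve crosses 0.5); test–test AUROC on correct
  and error trials (`contrastpop.discriminability`).
* **Choice probability** — AUROC between choice-conditioned activity
  distributions at fixed test contrast, plus the sample-subtracted
  variant on within-trial (test − sample) differences
  (`contrastpop.choice`).
* **Correlations** — stimulus-conditioned pairwise noise correlations
  (Fisher z-averaged), signal correlations of tuning curves, the OLS
  slope of noise-z on signal-z by signal sign × information tercile, and
  a 1000-resample permutation test for early-vs-late slope changes
  (`contrastpop.correlations`).
* **Linear Fisher information** — the bias-corrected estimator
  `Î = [Δμ̂ᵀ Σ̂⁻¹ Δμ̂ · (2N−T−3)/(2N−2) − 2T/N] / δs²` with contrast
  differences mapped to radians by δs = (π/50)·ΔC; trial equalization
  across days, per-channel trial shuffling, rank-ordered population
  curves, exponential rank fits `c + b·(1 − e^{λ·rank})`, and
  proportional information gain (`contrastpop.information`).
* **Preprocessing** — per-channel SNR screening (daily SNR ≥ 1 on ≥ 80%
  of days), a baseline-matching threshold staircase (spontaneous rate
  within 1% of target), and empirical analysis-window selection
  (`contrastpop.preprocess`).

## Worked example

Run the full pipeline on the default synthetic training course
(24 channels, 22 daily sessions, 60 trials per contrast per day, learning
enabled):

```python
from contrastpop.pipeline import RunConfig, run
from contrastpop.synthetic_data import GeneratorConfig

summary = run(RunConfig(generator=GeneratorConfig(seed=1), outdir="run_out"))
print(summary["trends"]["slope30"])        # {'rho': 0.980802, 'p': 0.0}
print(summary["trends"]["pne_distance"])   # {'rho': -0.681536, 'p': 0.000478}
print(summary["hard_auroc_difference"])
# {'mean_early': 0.072247, 'mean_late': 0.114713, 'p': 7e-06}
print(summary["noise_correlation"])
# {'mean_early': 0.114651, 'mean_late': 0.064991}
print(summary["information"])
# {'pair': '29-31', 'population_early': 54.053236, 'population_late': 209.05589}
```

Reading the output: the channel-averaged CRF slope at 30% rises steadily
across sessions (Spearman ρ = 0.98), and the PNE's distance from the 30%
boundary shrinks (ρ = −0.68) — tuning sharpens exactly at the
categorization boundary.  The AUROC separation between mirrored hard
contrast pairs (27/33, 28/32, 29/31%) grows from 0.072 to 0.115
(Wilcoxon p = 7e-6), mean noise correlations drop from 0.115 to 0.065,
and the bias-corrected Fisher information of the full 24-channel
population for the hardest discrimination (29% vs 31%) roughly
quadruples from 54 to 209 rad⁻².  Per-contrast choice probabilities also
shift away from 0.5 (e.g. at 33% contrast: 0.534 early → 0.623 late,
one-sided paired t, p < 1e-6), i.e. activity becomes more predictive of
the upcoming choice.  `run_out/` additionally holds every stage table
(CRF, neurometric, discriminability, CP, pair-correlation and information
tables) as delimited text plus `summary.json` with a provenance block.

The same pipeline is scriptable from the shell:

```bash
contrastpop run-all --out run_out
contrastpop report --out run_out
```

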