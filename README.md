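# gazecone

Simulation and analysis pipeline for **gaze-cone measurement**: do the
method of constant stimuli, the method of adjustment, and a triadic
gaze-direction task agree on how wide the zone of perceived direct gaze is?

The *gaze cone* is the wedge of gaze directions an observer judges as
directed at themself; its half-width is the *threshold of direct gaze* T,
and the full cone width is 2T. The three classical measurements are:

- **Method of constant stimuli** (dyadic): fixed gaze directions θ judged
  yes/no. One-sided data are fitted with a cumulative Gaussian on the
  proportion of *averted* judgments, `P(averted|θ) = (1−λ)·Φ((θ−T)/σ) + λ/2`,
  whose 50% point is T; two-sided data with a Gaussian bell
  `P(direct|θ) = a·exp(−(θ−c)²/2w²)`, whose SD w is the threshold.
- **Method of adjustment**: the observer steers the looker's gaze to the
  point of just (not) being looked at, in ascending and descending series;
  T is the unweighted mean of the (series × side) cell means, which cancels
  symmetric hysteresis.
- **Triadic task**: the observer reports *where* the looker is looking on a
  centimetre scale. Regressing perceived on true direction gives the
  overestimation factor (slope > 1 = overestimation); a four-piece
  regression with breakpoints at the measured directions captures the
  low-gain-near-zero, high-gain-peripheral shape. A dyadic threshold is then
  *corrected* through the section containing it:
  `T* = slope_k · T + intercept_k`, with estimation bias T*/T.

Because no trial-level data are public for this paradigm, the package ships
a generative observer simulator (`gazecone.simulate`) and validates the
pipeline by parameter recovery; see `docs/methods.md` for the model and its
calibration.

## Worked example

```python
import gazecone as gz

# simulate a live-looker-style cohort: 18 observers, 125 yes/no trials,
# 12 adjustment trials and 125 triadic reports each
data = gz.simulate_cohort(gz.exp1_cohort_config(18, master_seed=0))

# constant stimuli: cumulative-Gaussian threshold per observer
fits = [
    gz.fit_cumulative_gaussian(gz.DyadicProportions.from_trials(grp))
    for _, grp in data.dyadic.groupby("observer_id")
]
print(sum(f.threshold_deg for f in fits) / 18)    # 3.01 (deg)

# adjustment: series means -> overall threshold
summ = gz.summarize_cohort(data.adjustment, sides="one")
print(summ.overall_threshold.mean())              # 5.61 (deg)
```

The simulated cohort was generated with a mean dyadic criterion of 2.90°
(drawn from N(3.3°, 1.0°)) and a mean adjustment criterion of 5.60°; the
pipeline recovers 3.01° and 5.61° — the adjustment method measures a wider
cone than constant stimuli (ratio 1.86 for this draw), which is exactly the
between-method disagreement the package exists to quantify. Correcting both
thresholds with each observer's own piece-wise triadic regression widens the
cone further (3.95° and 8.45° for this cohort) without removing the
difference.

The same analysis, as a narrated pipeline writing tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py     --seed 0   # trial CSVs + truth
python analysis/02_fit_constant_stimuli.py --seed 0   # psychometric fits
python analysis/03_fit_adjustment.py       --seed 0   # thresholds + hysteresis
python analysis/04_fit_triadic.py          --seed 0   # linear + 4-piece fits, rm-ANOVA
python analysis/05_compare_methods.py      --seed 0   # method comparison report
```

Cohort configurations can also be given as YAML (`gazecone.config.
load_cohort_config`); trial tables are plain RFC-4180 CSVs with validated
schemas (`gazecone.io.read_trials`).

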