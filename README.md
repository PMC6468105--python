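# ssralpha

Dual spectral decomposition of rhythmically driven EEG: **ongoing power**,
**evoked power** and **intertrial phase coherence**, with cluster-based
permutation statistics and Bayes-factor inference.

## The scientific problem

When a flickering stimulus drives a steady-state response (SSR) inside the
alpha band (8–13 Hz), two standard analyses of the *same* epoched EEG give
apparently contradictory answers about spatial attention:

* **Ongoing power** — the average of per-trial power spectra,

  `onPOW(f) = (1/n) Σᵢ |Zᵢ(f)|²`,

  keeps all activity regardless of its phase across trials.  Band-mean
  alpha onPOW *decreases* over the hemisphere contralateral to the attended
  hemifield (retinotopic alpha suppression).

* **Evoked power** — the power of the trial-averaged spectrum,

  `evoPOW(f) = |(1/n) Σᵢ Zᵢ(f)|²`,

  cancels non-phase-locked activity and so isolates the weak,
  stimulus-locked SSR (10–100× weaker than ongoing alpha).  Evoked SSR
  power *increases* when its driving stimulus is attended.

* **Intertrial phase coherence** —

  `ITC(f) = |(1/n) Σᵢ Zᵢ(f)/|Zᵢ(f)||  ∈ [0, 1]`,

  the resultant length of per-trial unit phase vectors, a pure measure of
  phase locking (reported as the trial-count-debiased `ITCz = n·ITC²`).
  It also *increases* with attention to the driving stimulus.

The same per-trial Fourier coefficients therefore carry attention effects
of **opposite sign** depending on which aggregate is computed — the
"attentional-modulation conundrum".  This package implements the full
analysis chain and a synthetic-data generator whose ground truth lets the
dissociation be demonstrated and the statistics validated end to end:

1. scalp current density (SCD) transform — reference-free spherical-spline
   surface Laplacian (regularization λ = 10⁻⁴);
2. detrend + Tukey taper + zero-padded FFT to a 0.25 Hz grid;
3. onPOW / evoPOW / ITC / ITCz per condition, dB scaling for power;
4. cluster-based permutation tests across sensor neighbourhoods
   (N = 5000 sign-flip permutations, summed-t cluster mass);
5. JZS Bayes-factor t tests (Cauchy prior, r = 0.5) and Bayesian Kendall
   τ_b rank correlations (stretched-beta prior, width 0.75);
6. subject-level single-trial covariation: jackknife (leave-one-out)
   estimates, all pairwise between-condition differences, z-scoring,
   per-sensor robust (bisquare) regression, and group tests on the slopes.

Intended users: EEG/MEG researchers analysing frequency-tagging or
steady-state paradigms, and methodologists studying evoked/induced
decompositions.

## Worked example

```python
from ssralpha import AnalysisConfig, run_full, recovered_signs

cfg = AnalysisConfig(seed=1, run_trialreg=False)   # 17 synthetic subjects
report = run_full(cfg)

alpha = report.sections["alpha"]
print("alpha suppression (ignored - attended), left cluster: "
      f"{-alpha['effects']['left'].mean():.2f} dB, "
      f"BF10 = {alpha['bayes']['left'].bf10:.2e}")
ssr10 = report.sections["ssr"]["evopow"][10.0]
print(f"10 Hz evoked-power gain (attended - ignored): "
      f"{ssr10['gains'].mean():.2f} dB, BF10 = {ssr10['bayes'].bf10:.1f}")
print("recovered effect signs:", recovered_signs(report))
```

prints (seed 1):

```
alpha suppression (ignored - attended), left cluster: 1.85 dB, BF10 = 3.01e+10
10 Hz evoked-power gain (attended - ignored): 3.26 dB, BF10 = 472147.9
recovered effect signs: {'onpow_alpha': -1, 'evopow_ssr': 1, 'itcz_ssr': 1}
```

Alpha power is *lower* with attention contralateral to the cluster
(suppression 1.85 dB, decisively supported by the Bayes factor), while the
10 Hz SSR's evoked power is *higher* when its stimulus is attended
(+3.26 dB) — the opposite-sign dissociation on one dataset.  A command-line
interface offers the same functionality
(`ssralpha simulate|run --config cfg.yaml --seed N --out DIR`).

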