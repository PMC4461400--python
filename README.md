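# burstkit

Burst-kinetics inference and expression-noise analysis for clonal
single-cell expression data.

## The scientific problem

In a clonal population carrying a single reporter integration, per-cell mRNA
and protein levels vary widely even though the cells are genetically
identical. The standard kinetic explanation is the **two-state (telegraph)
model**: the promoter switches stochastically between a silent *Off* state
(rate k_on to leave it) and a productive *On* state (rate k_off to fall
back), transcribes at rate k_m while On, and transcripts decay first-order
at rate δ. Its stationary mRNA copy-number law is the Peccoud–Ycart
(beta-Poisson) distribution

    p(n) = ∫₀¹ Poisson(n; λx) · Beta(x; α, β) dx,
    α = k_on/δ,  β = k_off/δ,  λ = k_m/δ,

with the biologically meaningful reparameterization

* **burst size** b = k_m/k_off — mean transcripts per On episode,
* **burst frequency** f = k_on/δ — On-transition rate in units of the mRNA
  lifetime.

In the bursty regime, b controls mean expression (⟨n⟩ ≈ f·b) while f
controls the noise (CV² ≈ (1/f)(1 + 1/b)), so a cohort of integration-site
clones in which b and f vary *independently* shows mean and CV uncorrelated —
the orthogonal-control signature this package is built to detect, quantify,
and trace to promoter chromatin accessibility.

`burstkit` provides, for people analyzing smFISH count tables,
flow-cytometry event tables, and DNase-qPCR panels from such clone cohorts:

* the exact stationary law, moments, sampling, and a Gillespie simulation
  oracle (`burstkit.telegraph`);
* a seeded synthetic-cohort generator reproducing the study's statistical
  structure — orthogonal (b, f) dispersions, a buffered GFP readout,
  accessibility coupled to burst frequency, qPCR noise
  (`burstkit.cohort`);
* scatter density-mode gating, clone clustering, matched-mean noise-pair
  selection, Poisson MOI (`burstkit.flow`);
* bootstrap moment summaries and the log-log scaling regressions that
  separate Poisson from bursty transcription (`burstkit.moments`);
* per-clone maximum-likelihood (b̂, f̂) with 1.92-unit profile-likelihood
  95% CIs, plus RNA half-life estimation from inhibition time courses
  (`burstkit.fitting`);
* ΔCt-based chromatin inaccessibility, noise-pair ratios, kinetics–
  accessibility regressions and PCA (`burstkit.chromatin`).

## Worked example

```python
import numpy as np
import burstkit as bk

# a bursty clone: 8 transcripts per burst, one burst per 2 mRNA lifetimes
params = bk.TelegraphParams.from_bursts(burst_size=8, burst_freq=0.5, lam=1000)
print(bk.analytic_moments(params))
# Moments(mean=3.98..., variance=35.35..., cv=1.49..., fano=8.87...)

counts = bk.sample_stationary(params, n_cells=600, seed=2, clone_id="demo")
fit = bk.fit_clone(counts, delta=1.0, lam=1000.0, compute_ci=True)
print(round(fit.burst_size, 2), [round(v, 2) for v in fit.burst_size_ci])
print(round(fit.burst_freq, 2), [round(v, 2) for v in fit.burst_freq_ci])
# 7.6 [6.38, 9.15]
# 0.55 [0.48, 0.64]
```

The fitted burst size (7.6, 95% CI 6.4–9.2) and burst frequency (0.55, CI
0.48–0.64) recover the generating values (8, 0.5) within their
profile-likelihood intervals; a burst size well above 1 marks the clone as
non-Poissonian.

Cohort level:

```python
cohort = bk.generate_cohort(bk.CohortConfig(seed=1))   # 200 clones x 600 cells
means = np.array([c.counts.mean() for c in cohort.counts])
varis = np.array([c.counts.var(ddof=1) for c in cohort.counts])
print(round(bk.loglog_regression(means, varis).slope, 2))
# 1.56  — between Poisson scaling (1) and pure burst-size modulation (2)
```

A command-line interface mirrors the library
(`burstkit simulate | gate | cluster | pairs | moi | moments | scaling |
fit | chromatin`); see `burstkit --help`.

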