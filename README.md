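# bernshrink

Semi-parametric **shrinkage density estimation** for univariate data on a
bounded support, combining a Bernstein-polynomial estimator with a finite
Gaussian mixture model.

## The problem

Kernel density estimators are badly biased near the edges of a compactly
supported density: part of every kernel placed near a boundary spills its
mass outside the support, so the estimate is too low at the edges and does
not even integrate to one over the support.  Two families of estimators
avoid this:

* the **Vitale (Bernstein) estimator**, a nonparametric smoother of the
  empirical CDF F_n,

  f̃₁,ₙ,ₘ(x) = m · Σ_{k=0}^{m−1} [F_n((k+1)/m) − F_n(k/m)] · b_k(m−1, x),

  where b_k(m, x) = C(m,k) xᵏ(1−x)^{m−k} is the Bernstein basis — a true
  density on [0, 1] for every degree m;
* a **Gaussian mixture** f̃₂,ₙ(x) = Σ_k π̂_k N(μ̂_k, σ̂_k)(x) fitted by EM,
  a parametric model with no edge trouble at all.

`bernshrink` implements the convex **shrinkage combination** of the two,

  f̂ₙ,ₘ(x) = λ̂ · f̃₁,ₙ,ₘ(x) + (1 − λ̂) · f̃₂,ₙ(x),    λ̂ ∈ [0, 1],

where λ̂ is itself estimated by an EM algorithm that treats the component
label of each observation as hidden: E-step
τ̄ᵢ₁ = λ f̃₁(Xᵢ) / (λ f̃₁(Xᵢ) + (1−λ) f̃₂(Xᵢ)), M-step λ ← (1/n) Σᵢ τ̄ᵢ₁.
At λ̂ = 1 the estimator reduces exactly to the Bernstein estimator, at
λ̂ = 0 to the Gaussian mixture.  The number of mixture components K is
selected by the gap statistic, and data on a general support are first
mapped to [0, 1] (interval: affine; real line: y = 1/2 + arctan(x)/π;
positive half-line: y = x/(1+x)).

The package also ships the comparators used in the accompanying
simulation study — the Gaussian kernel estimator and the Bernstein
mixture fitted by EM (simplex weights over the scaled basis
B_{mi} = (m+1) b_i(m, ·)) — plus quadrature ISE/IAE/KL metrics, a
Monte-Carlo benchmark harness, and an asymptotic pointwise confidence
interval with half-width z_{1−α/2} · λ̂ · √(γ(x)/n) · m^{±1/4},
γ(x) = f(x)(4πx(1−x))^{−1/2}.

Intended users: statisticians and quantitative scientists estimating
densities of bounded or transformed data (epidemic counts, distances,
durations) who want boundary-honest estimates with a parametric fallback.

## Worked example

Draw 200 points from the bimodal beta mixture 0.5·B(3,9) + 0.5·B(9,3) and
fit the shrinkage estimator, letting the package choose the Bernstein
degree (held-out likelihood) and K (gap statistic):

```sh
$ bernshrink simulate a --n 200 --seed 42 --out beta_mix.csv
wrote 200 draws from density (a) to beta_mix.csv
$ bernshrink fit beta_mix.csv --support interval:0,1 --m auto --m-max 100 --seed 0 --out-prefix beta_fit
lambda=1.000000 m=74 K=2 unit_mass=1.000000 -> beta_fit.json, beta_fit_density.csv
```

Reading the output: the gap statistic found the two modes (K=2), but the
λ-EM put all weight on the Bernstein component (λ̂ = 1.0 — for this
clearly non-Gaussian shape the nonparametric component dominates the
likelihood), the selected degree is m = 74, and the fitted density
integrates to 1.000000 over [0, 1] — the boundary-honesty the method is
for.  A warning notes that the fitted Gaussian mixture alone would leave
1.2% of its mass outside the unit interval; with λ̂ = 1 this does not
affect the final estimate.  `beta_fit_density.csv` tabulates the density
with pointwise 95% confidence bands:

```
x,density,lower,upper
0.005,0.002076903012,-0.002229675484,0.006383481509
0.01,0.01261022968,0.003675627282,0.02154483207
...
```

The same works for unbounded data with `--support real` / `--support
positive` (the estimate then lives on the transformed unit scale), or
`--support auto` for data-driven finite bounds.

The library API mirrors the CLI:

```python
import numpy as np
from bernshrink import UnitSample, fit_shrinkage, evaluate_shrinkage

sample = UnitSample(np.loadtxt("beta_mix.csv", skiprows=1))
est = fit_shrinkage(sample, m=74, K="auto", seed=0)
est.lam, est.gmm.K          # (1.0, 2)
evaluate_shrinkage(est, 0.2)  # density value at x = 0.2
```

## The simulation benchmark

`bernshrink benchmark` reruns the Monte-Carlo comparison of the four
estimators (shrinkage, Vitale, Gaussian kernel, Bernstein mixture) over
six test densities — two beta mixtures, a two-component normal mixture, a
chi-squared(2), and two gamma mixtures — at sample sizes 50/100/200, with
per-trial oracle selection of the Bernstein degree (m ≤ 300) and kernel
bandwidth (h = i/1000, i ≤ 300), a seeded 2/3–1/3 train/test split, and
ISE/IAE/KL averaged over N trials:

```sh
bernshrink benchmark --densities a,c,f --n 200 -N 100 --seed 0 \
    --estimators shrinkage,kernel --m-max 100 --outdir benchmark_out
```

Results land in `benchmark_out/` as a tidy per-trial log (`trials.csv`,
which interrupted runs resume from), averaged tables per metric, and a
JSON summary.

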