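# Methods

## Model

Annual death proportions `y_t = deaths_t / births_t` are modelled around a
smooth secular decline with superimposed lognormal-density excess terms.
With `t = year − 1930` (so `log t` is defined for every modelled year; the
origin is fixed to keep coefficients comparable across series, but is
overridable):

* **floored logistic** (`family="logistic"`):
  `E[y] = α + (1 − α)·expit(η)`, where `α ∈ [0, 1)` is the lower limit the
  rate approaches as the linear predictor falls — mortality does not decay
  to zero. The trend part of `η` is `β₁ + β₂ t`.
* **exponential cubic** (`family="expcubic"`): `E[y] = exp(η)` with trend
  `β₁ + β₂ t + β₃ t² + β₄ t³`.

Every excess term adds `(a/t)·exp(−(log t − μ)²/(2σ²))` to `η` — the
kernel of a lognormal density: a bell on the log-time axis with location
`μ` (log of the median year offset) and width `σ` (log of the geometric
standard deviation), whose maximum in real time is `t* = exp(μ − σ²)`
(mode before median, since `σ > 0`). Terms live *inside* the linear
predictor; "excess rates" plotted or summed downstream are always the
derived difference `observed − undisturbed`, never a quantity added to the
rate directly. Width ties force `σ_k = σ_m` for a designated master `m < k`
and remove one free parameter each. Two auxiliary structures:

* a **war term** (first bell of an `expcubic` model, `war_term=True`)
  absorbs a wartime mortality surge when fitting series that start before
  a post-war analysis window; it is *kept* in the undisturbed baseline by
  default since it predates (and has negligible mass inside) the default
  1950–2000 excess window;
* **intervention dummies** — a single-year pulse and/or a level-shift step
  in `η` — absorb reporting-definition changes (the motivating case is a
  stillbirth-definition change: a one-year spike plus a permanent shift).
  They too stay in the undisturbed baseline: they encode measurement, not
  excess mortality.

## Estimation

The estimator minimises the binomial-variance weighted residual sum of
squares

    Q(θ) = Σ_t (y_t − fit_t(θ))² / var_t,   var_t = fit_t(1 − fit_t)/births_t.

Because the variance depends on the fit, weights are refreshed from the
current fitted values and the weighted problem re-solved (trust-region
reflective least squares, numerical Jacobian) until the deviance changes by
less than 1e−8 relative, with at most 25 reweighting cycles (a one-shot
mode — single weighted pass — exists as a sensitivity option).
Non-convergence is flagged and warned about, never raised. The reported
**deviance** is `Q` at the converged fit (Pearson-type), **df** is
observations minus free parameters (tied widths and externally fixed
parameters do not count), and **overdispersion** `OD = deviance/df`
summarises extra-binomial variability; national vital-statistics series
typically show OD of order 10–40.

Bounds: free widths `σ ≥ 1e−3`; `α ∈ [0, min observed rate]`; bell
locations `μ ∈ [0, log(max t) + 1]`; amplitudes unbounded (hard
non-negativity was tried and rejected — an amplitude pinned at zero makes
its own `μ`, `σ` unidentifiable and stalls the optimiser). Standard errors
come from the unscaled weighted Jacobian covariance (OD-scaled SEs are an
option); the Jacobian is column-normalised before a conditioning test, and
a numerically singular fit raises an identifiability error naming the
near-collinear parameters.

### Starting values and multimodality

The objective is multimodal when bells overlap: the main failure modes are
a merged two-bell optimum and sign-compensating bell pairs. Auto-started
fits therefore race two deterministic strategies and keep the lower
deviance, then refit the winner at full precision:

1. **stagewise build-up** — fit one bell, seed the next at the most
   prominent positive residual peaks on the predictor scale (top-3 peaks ×
   two starting widths, best kept), refit, repeat;
2. **one-shot peeling** — fit the trend alone, then seed all bells at once
   by iteratively peeling the strongest residual peak.

Both finish with a **reseeding polish**: each bell in turn is zeroed, the
residuals re-scanned, the bell reseeded at the strongest positive peak and
the model refitted, keeping any deviance improvement (at most two sweeps).
The search phases run with capped reweighting cycles and looser inner
tolerances; only the final refit uses the full tolerances. Everything is
deterministic — identical inputs give identical fits. Stepwise selection
applies the same candidate-and-polish scheme per step. Residual
multimodality remains possible on weakly informative data (small birth
cohorts, narrow bells of a few years' width); warm-starting from prior
estimates is recommended there, and simulation studies in the test suite
warm-start each replicate at the generating parameters so that interval
calibration is measured separately from optimiser multimodality.

A Poisson log-linear companion (`fit_loglinear_trend`) fits
`deaths ~ Poisson(births·exp(polynomial in t))` via a GLM with log-births
offset, optionally excluding a year window from estimation while
predicting across it — the historical window-exclusion approach to excess
estimation, kept deliberately distinct from the bell-decomposition
approach.

## Inference

* **Model comparison**: for nested fits, `OD = dev₁/df₂` from the refined
  model and `F = (dev₀ − dev₁)/df₁/OD`, referred to the upper tail of
  `F(df₁, df₂)`. The scaling makes the test a variance-ratio test that
  remains calibrated under overdispersion.
* **Profile intervals**: a parameter is fixed on a bracketing grid, all
  others re-optimised, and the bounds located (monotone bracketing plus
  root refinement, warm-started refits) where the profiled deviance
  crosses `dev_min + OD·F_level(1, df₂)`. With this scaling the interval
  reduces to the OD-scaled Wald interval when the objective is quadratic;
  the test suite verifies near-agreement in the quasi-linear large-births
  regime (the estimator's objective is never exactly quadratic, so exact
  equality is not attainable). If no crossing occurs within ±10 SE a
  warning is issued and the reached bound returned. A parametric-bootstrap
  percentile interval is available as an independent cross-check.
* **Excess deaths** over a window (default 1950–2000, inclusive, every
  year required present): `O = Σ deaths`, `E = Σ births·undisturbed_rate`
  from the *full-data* fit with bells zeroed (not a window-excluded refit —
  that alternative is exposed through the log-linear route). The interval
  for `O − E` and `O/E` refits the model with the slope `β₂` frozen at
  each end of its profile interval and recomputes `E`: the slope governs
  how fast the baseline falls, and its uncertainty dominates the excess.
* **Peak timing**: `peak_year = exp(μ − σ²) + 1930`, with a delta-method
  interval on `(μ, σ)` using their estimated covariance (a tied width uses
  the master's entries); a parametric bootstrap is the labelled
  alternative. Default level 0.95.

## Synthetic data

`simulate_series` draws annual death counts at the model's true rates:
binomially for `dispersion = 0`, or beta-binomially with intraclass
correlation `ρ` (`deaths | p ~ Binomial(births, p)`,
`p ~ Beta(rate·s, (1−rate)·s)`, `s = 1/ρ − 1`), inflating the count
variance by `1 + (births − 1)ρ` and nesting the binomial at `ρ = 0`. The
observed overdispersion of real national series has no published
generative model; the beta-binomial is this package's stand-in, chosen
because it keeps `deaths ≤ births` and has a single dial. Live births
default to a gentle log-linear decline (−0.5%/yr) with 2% lognormal
jitter from a base of 3 million — post-war magnitudes, not demographic
realism (no maternal-age structure, cohort effects, migration).
`make_reference_fixture` instead produces noise-free series at published
reference estimates with `deaths = round(rate·births)` (symmetric
rounding, realised rate within `0.5/births` of the model).

What passing tests show, and what they do not: exact recovery on
noise-free fixtures validates the optimiser and the model algebra;
binomial-simulation coverage validates interval calibration *under the
model's own noise assumptions*. Real series violate those assumptions
(serial correlation, reporting artefacts, extra-binomial noise), so
intervals on real data should be read as model-conditional.

## Numerical and design choices

* Rates are proportions in (0, 1) internally; per-1000 is presentation
  only. Standardized residuals `(obs − fit)/sqrt(var)` are scale-free.
* The deviance is *defined* as the weighted residual sum of squares — the
  only definition consistent with `OD = deviance/df` at the magnitudes
  this methodology reports.
* Upper-tail F p-values are used throughout (the refinement question is
  one-sided: did the added term reduce the deviance).
* Degenerate inputs: fitted rates at 0 or 1 make the binomial variance
  vanish and raise; duplicate years, deaths > births, and empty pools are
  rejected at construction; excluding an absent year is a no-op; gaps in a
  series are simply absent from the fit (no imputation).
* Year-window problem sizes in the tests: 69-year series (1950–2018) for
  the pooled-Europe configurations, 85 years (1934–2018) for the US ones;
  the simulation study uses 100 replicates at one million births/year.
* The denominator of a stillbirth-style series is whatever the `births`
  column holds (live births by convention); the `role` tag records the
  endpoint.

## Known limitations

* No autocorrelation-robust errors: years are treated as independent given
  the trend; real residual series show runs.
* Bells are exchangeable — a fit may return them in any order; consumers
  that care should sort by `μ` (ties permitting).
* The undisturbed baseline is counterfactual and unverifiable; excess
  estimates are relative to the assumed trend family, and the two families
  can disagree materially on `E`.
* Optimiser multimodality on weakly informative series (see above).
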