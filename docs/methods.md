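# Methods

This note documents the statistical model, the simulation design, the
numerical conventions and the design choices behind `gpdcat`.

## Item bank and calibration parameters

The bank holds 52 items: 12 GHQ-12 items (4 ordinal categories, 3
thresholds) and 40 Affectometer-2 items (5 categories, 4 thresholds).  Two
parameter sets ship with the package under `src/gpdcat/data/`:

* `factor_params.csv` — bifactor loadings and normal-ogive thresholds.
  Every item loads on the general distress factor; positively worded items
  additionally load on one of two wording factors (posGHQ, posAff).
  Negatively worded items have no specific loading.
* `irt_params.csv` — logistic-metric graded-response-model (GRM)
  parameters: discrimination α and intercept-form thresholds t.

The conversion between the two is the classical normal-ogive-to-logistic
mapping with scaling constant 1.7 (`convert_discrimination`,
`convert_thresholds`): only the general-factor loading enters the
numerator, while all of an item's loadings contribute to the uniqueness
term in the denominator (M = 1 factor for negative items, M = 2 for
positive ones).  The wording factors are treated as nuisance dimensions and
are not scored.

Both tables are transcriptions of a published calibration; the IRT table
derives from *unrounded* factor estimates.  Recomputing it from the
2-decimal loadings (`ItemBank.recomputed_irt()`) reproduces it closely but
not exactly: the propagated rounding error grows with the loading and
reaches ≈ 0.12 on the largest thresholds (λ ≈ 0.88).  The simulation
machinery therefore consumes the transcribed IRT table, which is the
operative calibration; the recomputed values exist for auditing the
conversion.

Model-based reliability of the general factor uses the standard bifactor
omega-hierarchical on the latent-response metric:
ω_H = (Σλ_gen)² / [(Σλ_gen)² + (Σ posGHQ λ_spec)² + (Σ posAff λ_spec)² +
Σ(1 − h²)].  The packaged loadings give ω_H = 0.90.  An alternative on the
summed-score metric could be swapped in; the function is deliberately
isolated.

## Graded response model

`gpdcat.grm` implements the logistic GRM in intercept form: the cumulative
boundary probability is `P*_k(θ) = expit(α θ − t_k)`, category
probabilities are adjacent differences of the `P*_k`, and item information
is Samejima's

```
I(θ) = α² Σ_k (Q_k − Q_{k+1})² / P_k ,   Q_k = P*_k (1 − P*_k),
```

with the outer boundaries contributing Q = 0.  Items with different
category counts are held in arrays padded with `+inf` thresholds; a phantom
boundary carries probability zero and drops out of every sum.  Category
probabilities below 1e-12 contribute zero information (guarded division).
Test information is the sum of item informations and the conditional
standard error of measurement is `SEM(θ) = 1/√I(θ)` (∞ where I = 0).

SEM curves default to the grid [−3.5, 3.5] in steps of 0.15.
`best_k_subset_curve` re-selects, at every grid point, the k items with the
highest information *at that point* — the locally optimal fixed form — and
is monotone improving in k.

## The administered metric

The conversion formulas produce intercept-form thresholds (`α θ − t_k`).
The R package the field uses for graded-response CAT simulation (catIrt)
parameterizes the GRM in slope–difficulty form `α(θ − b_k)`, and the
published simulation this package reproduces supplied the intercept-form
t-values in the difficulty slots.  The *operative administered bank*
therefore has boundary locations `b_k = t_k`, i.e. intercept thresholds
`α·t_k` — items are effectively more spread out along the trait continuum
than the nominal metric implies.

`ItemBank.as_administered()` returns the bank in that metric, and the
simulation study administers it.  This choice was validated empirically:
under the nominal intercept metric the simulated efficiency table is
systematically more optimistic than the published one (e.g. ≈ 10 instead of
12 items at SEM 0.32 under N(0,1) truths, GHQ mixing ≈ 27 % instead of
19.7 % at SEM 0.25), while under the administered metric the full
10-row × 5-threshold × 2-distribution design reproduces the published
means, SDs, mixing and RMSEs within Monte Carlo error and integer rounding.
Everything outside the simulation study — conversion checks, probability
and information functions, reliability — uses the nominal metric.

## Adaptive administration

A session (`run_cat_session`) proceeds:

1. Draw θ₀ ~ U(−1, 1) and select the first starter item by the configured
   rule at θ₀.
2. Select starter items 2..3 at a Bayesian-modal interim estimate under a
   standard-normal prior.  Maximum likelihood is undefined on the short,
   frequently all-extreme starting patterns, so the starting portion is
   scored by the Bayesian interim scorer for every estimator
   (`start_scoring="fixed"` instead keeps all starters at θ₀).  Because the
   interim scorer does not depend on the cell's estimator, MLE and
   uniform-prior BME sessions remain identical under shared seeds.
3. After the three starters, alternate estimate → select → respond until
   SEM ≤ threshold or all 52 items are administered.  No termination check
   occurs before the starters are complete; starter items count toward all
   administered-item totals.

Estimators and their SEMs:

* **MLE** — bounded maximization of the GRM log-likelihood on [−6, 6]
  (Brent, xatol 1e-6); SEM = 1/√I(θ̂) with expected (Fisher) information.
  All-lowest / all-highest patterns have no interior maximum and return the
  bound with `converged=False`; the session continues with that value.
* **BME, normal prior** — posterior mode (log-likelihood − θ²/2);
  SEM = 1/√(I + 1), the prior contributing unit precision.
* **BME, uniform prior** — bounded MLE on the prior support (default
  [−6, 6]); the prior adds no curvature, making it formally equivalent to
  MLE.
* **EAP** — posterior mean by fixed-grid quadrature, 61 equally spaced
  nodes on [−6, 6] with prior weights; SEM = posterior SD.  Tests verify
  agreement with a 611-node grid to 1e-3.

Selection rules: UW-FI picks the candidate maximizing Samejima information
at the current estimate; FP-KL maximizes the symmetrized Kullback–Leibler
divergence between the categorical response distributions at θ̂ ± δ with
δ = 0.1 (the two rules agree as δ → 0).  Ties break to the lowest bank
index.  A `randomesque_pool` hook exists (pool = 1, i.e. deterministic
argmax, throughout the design); item-exposure control and content
balancing are deliberately absent.

RNG contract: each session derives independent child streams for the
starting draw, the responses and (if ever needed) randomesque selection
from one seed, so changing the estimator never perturbs the response
stream.  The study derives per-simulee seeds as a stable function of
(master seed, distribution index, cell index, simulee index), making every
cell and every simulee independently re-runnable.

## Synthetic data

True latent distress values are drawn from N(0, 1) — the presumed
population distribution, used untruncated and undiscretized — or from
U(−3, 3), which removes the influence of the population distribution on
CAT performance.  Stochastic responses come from the calibrated GRM itself
via a single uniform draw against the cumulative boundary curve.  Because
simulated respondents follow the calibration model exactly, the simulation
carries no model misfit: efficiency results are an upper bound on what
recalibrated real-world administration would achieve, and passing tests
demonstrate internal consistency of the pipeline, not validity of the
calibration in new samples.

## Simulation design and outputs

The design crosses 10 estimator/selector/prior rows — MLE × {UW-FI, FP-KL}
and {BME, EAP} × {UW-FI, FP-KL} × {normal, uniform} — with the five SEM
thresholds 0.25, 0.32, 0.40, 0.45, 0.50 (50 cells), each run under both
trait distributions with 10,000 simulees per cell by default.  Cell
outputs: mean and SD of administered items, mean per-session percentage of
GHQ-12 items (a per-session mean of a ratio, then averaged), RMSE between
final estimates and truths on the logit scale, their Pearson correlation,
and per-item exposure counts.  Printed tables round item counts to
integers, percentages to 1 decimal and RMSE to 3 decimals; unrounded
values are always stored alongside.

Problem sizes used by the shipped checks: the two efficiency cells of the
test suite run at the design's full 10,000 simulees (SE of a mean item
count ≈ 0.06); accuracy and mixing cells at 2,000 (SE of an RMSE ≈ 0.004
logits); ordering properties at 400, where the differences examined are an
order of magnitude larger than the noise.

## Known limitations

* The 2-decimal rounding of the packaged loadings means three of the 208
  recomputed IRT parameters (thresholds of the two most discriminating GHQ
  items) differ from the transcribed values by slightly more than 0.09
  (up to 0.117).
* GHQ mixing percentages in short sessions (SEM thresholds 0.45–0.50) are
  sensitive to the exact starter-selection convention; uniform-prior rows
  can run several percentage points above the published values there, while
  mixing at the stringent thresholds (0.25–0.32) is reproduced closely.
* The mean item count of the shortest Bayesian cells sits at the upper
  edge of the published integer's rounding window (≈ 3.5 administered
  items where 3 is printed).
* Exposure counts are reproduced as outputs but only checked
  qualitatively (near-zero-information items are rarely selected);
  exposure profiles are highly implementation-sensitive.
* Fitting the bifactor model to raw survey responses, model-fit indices,
  and multidimensional scoring of the wording factors are out of scope.
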