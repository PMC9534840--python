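# Methods

## Model

Each ego's relationships are treated as a resource-allocation problem: a
finite budget of social effort (here, grooming) spread over `L` partners,
each relationship carrying a cost `s_i`. Maximising allocation entropy under
a mean-cost constraint gives, in the discrete case with `r` cost categories
`s_max = s_1 > ... > s_r = s_min`, Boltzmann layer probabilities
`p_k ∝ e^{-mu_hat s_k}` and cumulative circle sizes
`chi_k = (e^{k mu} - 1)/(e^{r mu} - 1)` with the rescaled multiplier
`mu = mu_hat (s_max - s_min)/(r - 1)`. Consecutive circles scale
approximately by `e^mu` for large `mu` (the classic empirical ratio ~3
corresponds to `mu ≈ 1`) and collapse into the innermost circle as
`mu -> -inf` (the "inverted" regime).

The continuum limit replaces categories by a normalised cost
`t = (s_max - s)/(s_max - s_min) ∈ [0, 1]` and a single scale parameter
`eta`: `chi(t) = (e^{eta t} - 1)/(e^eta - 1)`, the CDF of
`p(t) ∝ e^{eta t}`. Two correspondences with the discrete model are exposed:

* `eta = (r - 1)(e^mu - 1)` — obtained by matching the discrete forward
  difference `(chi_{k+1} - chi_k)/(chi_k Δt)`, `Δt = 1/(r-1)`, to the
  continuum logarithmic derivative in the normal regime. This is the
  conventional correspondence and the default; at `r = 4`, `e^mu = 3` it
  gives `eta = 6`.
* `eta = r mu` — the exact algebraic identity `chi(k/r; r mu) = chi_k`,
  which holds to machine precision for every `(k, r, mu)`.

The finite-difference matching behind the first correspondence is an
approximation: over `mu ∈ [0.5, 1.5]` it agrees with the continuum
log-derivative at `t = k/r` to within ~7% for the outer layers but up to
~19% for the innermost layer, where the continuum description is weakest.

## Estimation

For an ego with positive weights `s_1..s_L` (L ≥ 2, not all equal), the
normalised costs use the ego's **own observed extremes**, so `t = 0` and
`t = 1` are always attained. Since `p(t) ∝ e^{eta t}` is an exponential
family with natural parameter `eta` and sufficient statistic `t`, the MLE
solves the moment condition `E[t; eta] = t_bar` with
`E[t; eta] = e^eta/(e^eta - 1) - 1/eta`, strictly increasing in `eta`.

Numerics: the root is found by Brent's method on `[-50, 50]` (tolerance
1e-10), expanding the bracket geometrically when `t_bar` demands it and
clipping at `|eta| = 1e12`; `t_bar = 1/2` returns exactly 0. The removable
singularity at `eta = 0` is handled by second-order series for `|eta| <
1e-6` (`chi`, `E[t]`) and `|eta| < 1e-3` (`Var[t]`, where cancellation sets
in earlier); exponentials are factored as `e^{eta(t-1)}` forms so nothing
overflows for `|eta|` into the hundreds. Degenerate inputs (all weights
equal) yield a flagged record, never a numeric `eta`.

Confidence intervals at level `1 - 2δ` (default `δ = 0.025`, i.e. 95%) are
Wald intervals on `t_bar` using the analytic model variance
`Var(t; eta_hat)/L` — the exponential-family identity `Var(t) = dE[t]/deta`
gives `Var(t; eta) = 1/eta² - e^eta/(e^eta - 1)²` — mapped through the
strictly monotone inverse `eta(t_bar)`. This construction was chosen because
it is analytic, testable, and calibration-verifiable by simulation: measured
coverage at `eta = 4`, `L = 50` over 1000 replicates is ~94%. A percentile
bootstrap over partners (resampling and renormalising by the resample's own
extremes) is provided as a cross-check. The regime label is `normal`/
`inverted` by the sign of `eta_hat`, or `boundary` whenever the interval
straddles zero.

Two properties of this estimator matter when reading results:

* **Observed-range attenuation.** Because costs are renormalised by sample
  extremes, `eta_hat` measures the distribution's scale over the *observed*
  range. With few partners the sample minimum cost sits well inside (0, 1)
  (roughly `E[min t] ≈ 1 - ln(L)/eta` for positive `eta`), so `eta_hat` is
  systematically below the generative `eta` at small `L`. This attenuation —
  stronger in smaller groups — is precisely the mechanism by which small
  groups show lower fitted `eta` and more boundary/inverted structure.
* **Width asymmetry.** The inverse `eta(t_bar)` is convex for `eta > 0`, so
  at small `L` the propagated interval is wide and right-skewed; its mean
  width reaches the CLT `1/sqrt(L)` rate only for large `L` (the factor-2
  ratio holds to within a few percent from `L ≈ 160` upward at `eta = 6`).
  Near the regime boundary the same sampling spread can carry a genuinely
  positive ego slightly negative; such fits are always labelled `boundary`.

## Curation rules

From raw focal-follow tables (follows: id, group, focal, date, duration,
scan count; events: follow, scan index, behaviour, partner, optional
minutes), the pipeline:

1. discards follows of ≤ 5 minutes (visibility losses), with their events;
2. binarises grooming per follow — a partner groomed on any scan of a follow
   contributes 1, however many scans it spanned (default mode); the
   alternative mode sums grooming minutes, with one scored scan counting as
   one minute when no minute column is given (follows are 10 min/10 scans);
3. aggregates dyad weights over the whole study window (an optional date
   filter defaults to "all");
4. builds one directed ego-network per acting individual, rejecting
   cross-group dyads (study groups are closed);
5. excludes egos with fewer than five distinct groomed partners from fitting
   — five being the canonical innermost-circle size in primates — while
   keeping them as partners in others' networks. Under-observation of
   excluded egos (< 20% of mean follow count) is reported as a diagnostic,
   not enforced.

Duplicate (follow, scan, partner) rows are collapsed with a warning
(multi-observer entry noise); non-grooming behaviours are counted and
ignored. Repeated grooming of the same partner in different follows on one
day counts once per follow.

## Synthetic data

The generator emulates the study conditions: four groups of 26/60/11/14
individuals, ~300 retained 10-minute/10-scan follows per ego (drawn Poisson,
inflated by a 5% short-follow fraction so the discard rule is exercised),
and per-scan grooming propensity `g = 0.15` — a realistic grooming time
budget for chimpanzees. Each ego's partners receive latent costs
`t_i ~ p(t; eta_true)` via inverse-transform sampling, mapped to rates
`s_i = s_max - t_i(s_max - s_min)` with arbitrary-units extremes 10/1 (only
ratios matter after normalisation). On each scan the ego grooms partner `i`
with probability `g s_i / Σs`, or nobody; per-follow binarisation then makes
the expected dyad count analytic, `F(1 - (1 - p_i)^{10})`, which the tests
exploit. Occasional non-grooming ("proximity") rows exercise the behaviour
filter.

The "study preset" draws each ego's `eta_true` lognormally with modal value
4; the largest group gets a wider spread (`sigma_log` 0.55 vs 0.35), placing
its mean near 6 while the others stay near the mode — the qualitative
group-level pattern the method is meant to resolve. The per-scan categorical
choice (at most one groomee per scan) is a modelling stand-in: no generative
story links continuous grooming time to scan detections, and this one was
chosen because it mirrors scan sampling and keeps expectations analytic.

What the generator does **not** emulate: fission–fusion movement and
visibility bias (follows are missing at random here), observer
heterogeneity, kin/age/sex structure in partner choice, and temporal drift
in relationships. Passing recovery tests therefore show the estimator works
when its sampling assumptions hold, not that field data satisfy them.

Because of observed-range attenuation plus scan-process saturation, fitted
`eta` under the full observation model sits below `eta_true` (e.g. ~1.3
versus 2.0 at `L = 11` even before count noise); quantitative recovery
claims are therefore benchmarked in "exact" mode (fitting draws from the
model density directly), where the estimator is unbiased to Monte-Carlo
precision.

## Problem sizes used in validation

Recovery uses 200 replicates of `L = 500` exact draws per `eta`; coverage
uses 1000 replicates at `L = 50`; the end-to-end check runs the full
four-group preset (111 egos, ~35k follows) once at a fixed seed. These sizes
give Monte-Carlo errors comfortably below the asserted tolerances while the
whole suite stays fast.

## Known limitations

* `eta_hat` is a per-ego point estimate; no pooling or hierarchical
  shrinkage across egos is attempted, and group comparisons are descriptive.
* The Wald interval relies on approximate normality of `t_bar`; at the
  minimum partner count (L = 5) intervals are very wide and the regime label
  is usually `boundary`.
* The minute-weighting mode trusts recorded bout minutes; it applies no
  censoring correction for bouts extending beyond the observation window.
* Egos whose every weight is equal (common at very low observation effort)
  cannot be fitted and are only flagged.
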