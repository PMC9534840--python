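# egolayers

Layered structure of weighted ego-networks, estimated from focal-follow
grooming observations.

Primate (and human) social relationships are organised in nested "circles" of
decreasing intensity: a few intense bonds, more medium ones, many weak ones,
with consecutive circle sizes scaling by roughly 3. `egolayers` implements
the continuum maximum-entropy description of this structure for directed
grooming networks: each ego allocates a finite grooming budget over its `L`
partners, and the fraction of its relationships whose normalised cost is at
most `t` follows

```
chi(t) = (e^{eta t} - 1) / (e^eta - 1),        t in [0, 1],
```

the CDF of the truncated exponential density `p(t) ∝ e^{eta t}`. The
normalised cost of partner `i` with grooming weight `s_i` is
`t_i = (s_max - s_i) / (s_max - s_min)` using the ego's own observed
extremes, so `t = 0` is the most-groomed partner. A single scale parameter
`eta` characterises each ego: `eta > 0` is the "normal" regime (many weak
ties, circles scaling geometrically), `eta < 0` the "inverted" regime (most
ties intense, typical of small groups), `eta = 0` the uniform boundary. The
discrete r-layer model with per-layer scaling ratio `e^mu` corresponds to
`eta = (r - 1)(e^mu - 1)`; the canonical human structure (r = 4, ratio 3)
gives `eta = 6`.

The MLE of `eta` is the root of the moment condition

```
E[t; eta] = e^eta/(e^eta - 1) - 1/eta = t_bar,
```

which is strictly increasing in `eta` and solved by bracketed root finding;
confidence intervals are Wald intervals on `t_bar` with the analytic model
variance `Var(t; eta)/L`, propagated through the monotone inverse (a
bootstrap over partners is available as a cross-check).

The package is aimed at behavioural ecologists with scan-sampled focal-follow
data: it curates raw observation tables into per-ego directed grooming
networks (binarised per follow, follows of ≤ 5 min discarded, egos with
fewer than five partners excluded from fitting but kept as partners), fits
every retained ego, and reports per-group distributions of `eta`. A
simulation module generates focal-follow datasets with known `eta` for
validation and power analysis.

## Worked example

```python
from egolayers import ContinuumEgoModel

# one ego's grooming weights toward its five partners
res = ContinuumEgoModel([10, 5, 2, 2, 1], ego_id="Ada", group_id="g1").fit()
print(res.summary())
```

```
Continuum ego-network layer model
==============================================
ego:        Ada
alters (L): 5
sigma:      4.0000
t_bar:      0.6667
eta:        2.1491  (se 1.7262)
95% CI:     [-0.7315, 9.4047]
regime:     boundary
log-lik:    0.8632
```

The mean weight is `sigma = 4`, giving mean normalised cost
`t_bar = (10 - 4)/(10 - 1) = 2/3` and hence `eta = 2.149`: a mildly "normal"
allocation (more weak than strong ties). With only five partners the 95%
interval `[-0.73, 9.40]` still straddles zero, so the regime label is
`boundary` — single-ego fits at the minimum partner count are intentionally
humble. `res.predict(0.5)` returns the fitted `chi(0.5) = 0.2545`: about a
quarter of Ada's relationships sit in the stronger half of her cost range.

The same analysis runs from the shell over whole datasets:

```
egolayers simulate --seed 1 --out-dir synth/        # 4-group synthetic study
egolayers curate --follows synth/follows.csv --events synth/events.csv \
                 --out networks.csv
egolayers fit --networks networks.csv --out fits.csv
egolayers report --fits fits.csv --networks networks.csv --out-dir report/
```

`report/` then holds `fits.csv` (one row per ego: `L`, `sigma`, `t_bar`,
`eta_hat`, CI bounds, regime), `group_summary.csv` (per-group mean/mode of
`eta`, counts of retained/excluded/inverted egos), per-ego `chi(t)` plots
with their machine-readable backing tables, and GraphML exports of each
ego-network.

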