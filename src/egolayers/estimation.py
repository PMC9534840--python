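"""Per-ego maximum-likelihood estimation of the layer scale parameter eta.

Given one ego's positive grooming weights ``s_1 .. s_L`` toward its alters,
each weight is mapped to a normalised cost

    t_i = (s_max - s_i) / (s_max - s_min)

using the ego's own observed extremes, so t = 0 is the most-groomed alter and
t = 1 the least.  Under the continuum maximum-entropy model the t_i follow
the truncated-exponential density p(t) ∝ exp(eta * t) on [0, 1], for which
the MLE of eta is the moment condition

    E[t; eta] = e^eta/(e^eta - 1) - 1/eta = t_bar

solved by monotone root finding (E[t; .] is strictly increasing).  Confidence
intervals are Wald intervals on t_bar with the model variance
Var(t; eta_hat)/L — the exponential-family identity Var(t) = dE[t]/deta makes
the variance analytic — propagated through the strictly monotone inverse
eta(t_bar), at level 1 - 2*delta (delta = 0.025 gives the conventional 95%).
A nonparametric bootstrap over alters is available as a cross-check.

The fitting surface is :class:`ContinuumEgoModel` (built from raw weights or
an :class:`~egolayers.curation.EgoNetwork`) whose ``fit`` returns a
:class:`ContinuumEgoResults`; the module-level functions expose the
individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .circles import (
    continuum_cdf,
    mean_normalized_cost,
    var_normalized_cost,
)
from .curation import EgoNetwork
from .errors import DegenerateNetworkError, InsufficientDataError

__all__ = [
    "NormalizedCosts",
    "ContinuumFit",
    "ContinuumEgoModel",
    "ContinuumEgoResults",
    "normalize_costs",
    "solve_eta",
    "confidence_interval",
    "bootstrap_confidence_interval",
    "fit_ego",
    "empirical_cdf",
    "fit_band",
    "loglike",
]

#: default root bracket for eta; expanded geometrically when t_bar demands it
ETA_BRACKET = (-50.0, 50.0)
#: hard cap on bracket expansion (E[t] = 1 - 1e-12 maps to eta ~ 1e12)
ETA_LIMIT = 1e12


@dataclass
class NormalizedCosts:
    """Normalised costs t_i of one ego's relationships.

    ``sigma`` is the arithmetic mean of the raw weights (the ego's average
    cost per relationship); ``t_bar = (s_max - sigma)/(s_max - s_min)`` is
    the sufficient statistic for eta.
    """

    t_values: np.ndarray
    sigma: float
    s_max: float
    s_min: float

    @property
    def L(self) -> int:
        return self.t_values.size

    @property
    def t_bar(self) -> float:
        return float(self.t_values.mean())


def normalize_costs(network) -> NormalizedCosts:
    """Map an ego's weights to normalised costs via its observed extremes.

    Accepts an :class:`EgoNetwork` or a plain sequence of positive weights.
    Raises :class:`InsufficientDataError` for L < 2 and
    :class:`DegenerateNetworkError` when all weights are equal (the transform
    has a zero denominator).  The alters carrying s_max and s_min land at
    t = 0 and t = 1 exactly.
    """
    if isinstance(network, EgoNetwork):
        s = network.weight_array()
    else:
        s = np.sort(np.asarray(network, dtype=float))[::-1]
    if s.size < 2:
        raise InsufficientDataError(f"need at least 2 alters, got {s.size}")
    if np.any(s <= 0):
        raise ValueError("weights must be positive")
    s_max, s_min = float(s[0]), float(s[-1])
    if s_max == s_min:
        raise DegenerateNetworkError(
            f"all {s.size} weights equal ({s_max}); normalised cost undefined"
        )
    t = (s_max - s) / (s_max - s_min)
    return NormalizedCosts(t_values=t, sigma=float(s.mean()), s_max=s_max, s_min=s_min)


def solve_eta(t_bar: float, tol: float = 1e-10, bracket=ETA_BRACKET) -> float:
    """Invert the moment condition E[t; eta] = t_bar for eta.

    E[t; .] is strictly increasing, so the root is unique; it is found by
    Brent's method on ``bracket`` (default [-50, 50]), expanded geometrically
    when t_bar lies outside the bracket's image and clipped at |eta| = 1e12.
    Returns 0.0 exactly when t_bar is at the symmetry point 1/2.  Raises
    ``ValueError`` for t_bar outside (0, 1) — the boundary means infinite eta.
    """
    t_bar = float(t_bar)
    if not 0.0 < t_bar < 1.0:
        raise ValueError(f"t_bar must lie strictly in (0, 1), got {t_bar}")
    if abs(t_bar - 0.5) < 1e-14:
        return 0.0

    def f(eta):
        return mean_normalized_cost(eta) - t_bar

    lo, hi = float(bracket[0]), float(bracket[1])
    while f(hi) < 0 and hi < ETA_LIMIT:
        hi *= 2
    while f(lo) > 0 and lo > -ETA_LIMIT:
        lo *= 2
    if f(hi) < 0:  # t_bar beyond the expandable range: return the clipped bound
        return hi
    if f(lo) > 0:
        return lo
    return float(brentq(f, lo, hi, xtol=tol))


def loglike(eta: float, t_values) -> float:
    """Log-likelihood of eta under p(t) = eta e^{eta t}/(e^eta - 1) on [0, 1]."""
    t = np.asarray(t_values, dtype=float)
    eta = float(eta)
    if abs(eta) < 1e-6:
        log_c = -eta / 2.0 - eta * eta / 24.0
    elif eta > 0:
        log_c = np.log(eta) - eta - np.log1p(-np.exp(-eta))
    else:
        log_c = np.log(-eta) - np.log1p(-np.exp(eta))
    return float(t.size * log_c + eta * t.sum())


def confidence_interval(t_values, eta_hat: float, delta: float = 0.025):
    """Wald confidence bounds on eta at level 1 - 2*delta.

    The interval t_bar ± z_{1-delta} * sqrt(Var(t; eta_hat)/L) on the mean
    normalised cost is mapped through the strictly increasing inverse
    eta(t_bar); the bounds therefore always straddle eta_hat.  t-bounds
    falling outside (0, 1) are clipped just inside, which clips the eta bound
    at the solver limit.
    """
    if not 0.0 < delta < 0.5:
        raise ValueError(f"delta must lie in (0, 0.5), got {delta}")
    t = np.asarray(t_values, dtype=float)
    L = t.size
    if L < 2:
        raise InsufficientDataError("need at least 2 alters for an interval")
    if not np.isfinite(eta_hat):
        raise ValueError("eta_hat must be finite")
    z = norm.ppf(1.0 - delta)
    se = np.sqrt(var_normalized_cost(eta_hat) / L)
    eps = 1e-12
    t_lo = min(max(t.mean() - z * se, eps), 1.0 - eps)
    t_hi = min(max(t.mean() + z * se, eps), 1.0 - eps)
    lo, hi = solve_eta(t_lo), solve_eta(t_hi)
    # guard against round-off pushing a bound across the point estimate
    return min(lo, eta_hat), max(hi, eta_hat)


def bootstrap_confidence_interval(weights, delta: float = 0.025,
                                  n_boot: int = 2000, seed=None):
    """Percentile bootstrap interval for eta, resampling alters with replacement.

    Each resample is renormalised by its own extremes before refitting, so
    the whole estimation path is exercised.  Degenerate resamples (all
    weights equal) are skipped.  Cross-check for the Wald interval.
    """
    s = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    etas = []
    for _ in range(n_boot):
        resample = rng.choice(s, size=s.size, replace=True)
        if resample.max() == resample.min():
            continue
        t = (resample.max() - resample) / (resample.max() - resample.min())
        t_bar = float(t.mean())
        if not 0.0 < t_bar < 1.0:
            continue
        etas.append(solve_eta(t_bar))
    if not etas:
        raise DegenerateNetworkError("all bootstrap resamples degenerate")
    lo, hi = np.quantile(etas, [delta, 1.0 - delta])
    return float(lo), float(hi)


@dataclass
class ContinuumFit:
    """Fitted continuum model for one ego: estimate, uncertainty, regime."""

    ego_id: str
    group_id: str
    L: int
    n_follows: int
    sigma: float
    t_bar: float
    eta_hat: float
    ci_low: float
    ci_high: float
    delta: float
    regime: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _regime_label(eta_hat: float, ci_low: float, ci_high: float) -> str:
    if ci_low < 0.0 < ci_high or eta_hat == 0.0:
        return "boundary"
    return "normal" if eta_hat > 0 else "inverted"


def fit_ego(network: EgoNetwork, delta: float = 0.025,
            min_partners: int = 5) -> ContinuumFit:
    """Fit the continuum model to one retained ego-network.

    Composes ``normalize_costs`` -> ``solve_eta`` -> ``confidence_interval``.
    Networks below ``min_partners`` alters are refused
    (:class:`InsufficientDataError`): with so few relationships the fit is
    meaningless.  A degenerate network (all weights equal) yields a flagged
    record with NaN estimates rather than an exception, so batch pipelines
    can report it.
    """
    if network.L < min_partners:
        raise InsufficientDataError(
            f"ego {network.ego_id!r} groomed only {network.L} partners "
            f"(< {min_partners})"
        )
    try:
        costs = normalize_costs(network)
    except DegenerateNetworkError:
        nan = float("nan")
        return ContinuumFit(
            ego_id=network.ego_id, group_id=network.group_id, L=network.L,
            n_follows=network.n_follows, sigma=float(np.mean(list(network.weights.values()))),
            t_bar=nan, eta_hat=nan, ci_low=nan, ci_high=nan, delta=delta,
            regime="degenerate", degenerate=True,
        )
    eta_hat = solve_eta(costs.t_bar)
    ci_low, ci_high = confidence_interval(costs.t_values, eta_hat, delta)
    return ContinuumFit(
        ego_id=network.ego_id, group_id=network.group_id, L=costs.L,
        n_follows=network.n_follows, sigma=costs.sigma, t_bar=costs.t_bar,
        eta_hat=eta_hat, ci_low=ci_low, ci_high=ci_high, delta=delta,
        regime=_regime_label(eta_hat, ci_low, ci_high), degenerate=False,
    )


def empirical_cdf(costs):
    """Right-continuous empirical CDF of the normalised costs.

    Accepts a :class:`NormalizedCosts` or a plain array of t values.  Returns
    ``(t_points, fractions)`` with ties grouped at a single step; the final
    fraction is always 1.
    """
    t = costs.t_values if isinstance(costs, NormalizedCosts) else np.asarray(costs, float)
    if t.size == 0:
        raise InsufficientDataError("empty cost list")
    points, counts = np.unique(t, return_counts=True)
    fractions = np.cumsum(counts) / t.size
    return points, fractions


def fit_band(fit: ContinuumFit, t_grid):
    """Pointwise confidence envelope for chi(t) from the eta interval.

    chi(t; eta) is strictly decreasing in eta for fixed t in (0, 1), so the
    band is [chi(t; ci_high), chi(t; ci_low)].  Degenerate fits give an empty
    band.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if fit.degenerate or not (np.isfinite(fit.ci_low) and np.isfinite(fit.ci_high)):
        return np.empty(0), np.empty(0)
    lower = np.asarray(continuum_cdf(fit.ci_high, t_grid))
    upper = np.asarray(continuum_cdf(fit.ci_low, t_grid))
    return lower, upper


# ---------------------------------------------------------------------------
# model / results objects


class ContinuumEgoModel:
    """Continuum layer model for a single ego's relationship weights.

    Parameters
    ----------
    endog : array-like or EgoNetwork
        The ego's positive grooming weights toward its alters (order
        irrelevant), or a curated :class:`EgoNetwork`.
    ego_id, group_id : str, optional
        Identifiers carried into the results; taken from the network when
        one is supplied.

    Examples
    --------
    >>> model = ContinuumEgoModel([10, 5, 2, 2, 1])
    >>> res = model.fit()
    >>> round(res.eta, 4)
    2.1491
    """

    def __init__(self, endog, ego_id: str = "ego", group_id: str = ""):
        if isinstance(endog, EgoNetwork):
            self.network = endog
            self.endog = endog.weight_array()
            self.ego_id = endog.ego_id
            self.group_id = endog.group_id
        else:
            self.network = None
            self.endog = np.sort(np.asarray(endog, dtype=float))[::-1]
            self.ego_id = ego_id
            self.group_id = group_id
        if self.endog.size < 2:
            raise InsufficientDataError("need at least 2 alters to fit")

    def loglike(self, eta: float) -> float:
        costs = normalize_costs(self.endog)
        return loglike(eta, costs.t_values)

    @classmethod
    def from_network(cls, network: EgoNetwork) -> "ContinuumEgoModel":
        return cls(network)

    def fit(self, delta: float = 0.025, method: str = "wald",
            n_boot: int = 2000, seed=None) -> "ContinuumEgoResults":
        """Estimate eta and its 1 - 2*delta confidence interval.

        ``method`` selects the interval: "wald" (analytic, default) or
        "bootstrap" (percentile over alter resamples, needing ``seed`` for
        reproducibility).
        """
        costs = normalize_costs(self.endog)
        eta_hat = solve_eta(costs.t_bar)
        if method == "wald":
            ci = confidence_interval(costs.t_values, eta_hat, delta)
        elif method == "bootstrap":
            ci = bootstrap_confidence_interval(self.endog, delta, n_boot, seed)
        else:
            raise ValueError(f"unknown CI method {method!r}")
        return ContinuumEgoResults(self, costs, eta_hat, ci, delta)


class ContinuumEgoResults:
    """Results of a :class:`ContinuumEgoModel` fit.

    Attributes
    ----------
    eta : float
        The ML estimate of the scale parameter (also ``params[0]``).
    bse : float
        Asymptotic standard error 1/sqrt(L * Var(t; eta)).
    regime : str
        "normal" (eta > 0), "inverted" (eta < 0) or "boundary" when the
        confidence interval straddles zero.
    """

    def __init__(self, model, costs: NormalizedCosts, eta_hat: float,
                 ci, delta: float):
        self.model = model
        self.costs = costs
        self.eta = float(eta_hat)
        self.ci_low, self.ci_high = float(ci[0]), float(ci[1])
        self.delta = float(delta)
        self.nobs = costs.L

    @property
    def params(self) -> np.ndarray:
        return np.array([self.eta])

    @property
    def bse(self) -> float:
        return 1.0 / np.sqrt(self.nobs * var_normalized_cost(self.eta))

    @property
    def llf(self) -> float:
        return loglike(self.eta, self.costs.t_values)

    @property
    def regime(self) -> str:
        return _regime_label(self.eta, self.ci_low, self.ci_high)

    def conf_int(self):
        return np.array([[self.ci_low, self.ci_high]])

    def predict(self, t):
        """Fitted cumulative layer curve chi(t; eta_hat)."""
        return continuum_cdf(self.eta, t)

    def empirical_cdf(self):
        return empirical_cdf(self.costs)

    def fit_band(self, t_grid):
        return fit_band(self.as_record(), t_grid)

    def as_record(self) -> ContinuumFit:
        """The fit as a flat, serialisable record."""
        return ContinuumFit(
            ego_id=self.model.ego_id, group_id=self.model.group_id,
            L=self.nobs,
            n_follows=self.model.network.n_follows if self.model.network else 0,
            sigma=self.costs.sigma, t_bar=self.costs.t_bar, eta_hat=self.eta,
            ci_low=self.ci_low, ci_high=self.ci_high, delta=self.delta,
            regime=self.regime, degenerate=False,
        )

    def summary(self) -> str:
        lines = [
            "Continuum ego-network layer model",
            "=" * 46,
            f"ego:        {self.model.ego_id}",
            f"alters (L): {self.nobs}",
            f"sigma:      {self.costs.sigma:.4f}",
            f"t_bar:      {self.costs.t_bar:.4f}",
            f"eta:        {self.eta:.4f}  (se {self.bse:.4f})",
            f"{100 * (1 - 2 * self.delta):.0f}% CI:     "
            f"[{self.ci_low:.4f}, {self.ci_high:.4f}]",
            f"regime:     {self.regime}",
            f"log-lik:    {self.llf:.4f}",
        ]
        return "\n".join(lines)
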