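"""Closed-form mathematics of layered ego-network structure.

Social relationships of a single individual (the *ego*) are modelled as a
resource-allocation problem: the ego has a finite budget of social effort and
each relationship carries a cost.  Maximising the entropy of the allocation
subject to a mean-cost constraint yields, in the discrete case, a Boltzmann
distribution over ``r`` relationship categories with costs
``s_max = s_1 > s_2 > ... > s_r = s_min`` and a Lagrange multiplier ``mu_hat``.
The cumulative layer sizes ("social circles") then scale geometrically with a
ratio that approaches ``e**mu`` for large rescaled multiplier
``mu = mu_hat * (s_max - s_min) / (r - 1)``.

Taking the number of categories to a continuum replaces ``mu`` with a single
scale parameter ``eta``.  With normalised cost ``t in [0, 1]`` (``t = 0`` the
most intense relationship, ``t = 1`` the least), the fraction of relationships
of normalised cost at most ``t`` is

    chi(t) = (exp(eta*t) - 1) / (exp(eta) - 1)

which is the CDF of the truncated-exponential density ``p(t) ∝ exp(eta*t)``
on the unit interval.  ``eta > 0`` is the "normal" regime (many weak ties,
nested circles with scaling ratio ~ e**mu); ``eta < 0`` is the "inverted"
regime in which most ties sit in the innermost circle; ``eta = 0`` is the
uniform boundary.

All functions here are pure and overflow-safe for ``|eta|`` at least up to a
few hundred; the removable singularity at ``eta = 0`` (or ``mu = 0``) is
handled by series expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscreteCircleModel",
    "ContinuumModel",
    "layer_probabilities",
    "discrete_circle_sizes",
    "discrete_scaling_ratio",
    "continuum_cdf",
    "continuum_pdf",
    "continuum_log_derivative",
    "mean_normalized_cost",
    "var_normalized_cost",
    "eta_from_mu",
]

#: below this |eta| the closed forms suffer catastrophic cancellation and the
#: second-order series around the uniform limit is used instead
SMALL_ETA = 1e-6


# ---------------------------------------------------------------------------
# continuum model


def continuum_cdf(eta: float, t):
    """Fraction chi(t) of relationships with normalised cost <= t.

    chi(t) = (e^{eta t} - 1)/(e^eta - 1), with chi(0) = 0 and chi(1) = 1.
    Vectorised over ``t``.  For |eta| < SMALL_ETA the series
    t + eta*t*(t-1)/2 is used.  Raises ``ValueError`` for t outside [0, 1].
    """
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("t must lie in [0, 1]")
    eta = float(eta)
    if not np.isfinite(eta):
        raise ValueError("eta must be finite")
    if abs(eta) < SMALL_ETA:
        out = t + eta * t * (t - 1.0) / 2.0
    elif eta > 0:
        # factor e^{eta(t-1)} so nothing overflows for large positive eta
        out = np.exp(eta * (t - 1.0)) * (-np.expm1(-eta * t)) / (-np.expm1(-eta))
    else:
        # mirror symmetry chi(t; eta) = 1 - chi(1 - t; -eta)
        out = 1.0 - np.asarray(continuum_cdf(-eta, 1.0 - t))
    return out if out.ndim else float(out)


def continuum_pdf(eta: float, t):
    """Model density p(t) = eta e^{eta t}/(e^eta - 1) on [0, 1]."""
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("t must lie in [0, 1]")
    eta = float(eta)
    if abs(eta) < SMALL_ETA:
        out = np.ones_like(t) + eta * (t - 0.5)
    else:
        # eta e^{eta t}/(e^eta - 1) = eta e^{eta(t-1)}/(1 - e^{-eta}); both
        # factors stay bounded on the branch sign(eta) matches
        if eta > 0:
            out = eta * np.exp(eta * (t - 1.0)) / (-np.expm1(-eta))
        else:
            out = -eta * np.exp(eta * t) / (-np.expm1(eta))
    return out if out.ndim else float(out)


def continuum_log_derivative(eta: float, t: float) -> float:
    """Logarithmic derivative chi'(t)/chi(t) = eta e^{eta t}/(e^{eta t} - 1).

    Tends to ``eta`` as eta -> +inf and to 0 as eta -> -inf; has a pole at
    t = 0, which raises ``ValueError``.
    """
    t = float(t)
    if not 0 < t <= 1:
        raise ValueError("t must lie in (0, 1] (pole at t = 0)")
    eta = float(eta)
    x = eta * t
    if abs(x) < SMALL_ETA:
        # eta * (1/x + 1/2 + x/12 + ...) ; for eta -> 0 this is 1/t + eta/2
        return 1.0 / t + eta / 2.0 + eta * x / 12.0
    # e^x/(e^x - 1) = 1/(1 - e^{-x})
    return eta / (-np.expm1(-x))


def mean_normalized_cost(eta: float) -> float:
    """Model mean E[t] = e^eta/(e^eta - 1) - 1/eta, strictly increasing in eta.

    Equals 1/2 at eta = 0 (uniform limit; series 1/2 + eta/12 - eta^3/720 used
    for small |eta|) and obeys the mirror symmetry E[t; -eta] = 1 - E[t; eta].
    """
    eta = float(eta)
    if not np.isfinite(eta):
        raise ValueError("eta must be finite")
    if abs(eta) < SMALL_ETA:
        return 0.5 + eta / 12.0 - eta**3 / 720.0
    if eta > 0:
        return 1.0 / (-np.expm1(-eta)) - 1.0 / eta
    return 1.0 - mean_normalized_cost(-eta)


def var_normalized_cost(eta: float) -> float:
    """Model variance Var[t] = dE[t]/deta = 1/eta^2 - e^eta/(e^eta - 1)^2.

    The identity with the derivative of the mean holds because p(t) ∝ e^{eta t}
    is an exponential family with natural parameter eta.  Symmetric in eta;
    equals 1/12 at eta = 0.
    """
    a = abs(float(eta))
    if a < 1e-3:
        # 1/12 - eta^2/240 + O(eta^4); cancellation sets in well before 1e-3
        return 1.0 / 12.0 - a * a / 240.0
    e = np.exp(-a)
    return 1.0 / (a * a) - e / (-np.expm1(-a)) ** 2


# ---------------------------------------------------------------------------
# discrete model


def layer_probabilities(model: "DiscreteCircleModel") -> np.ndarray:
    """Boltzmann probabilities p_k ∝ exp(-mu_hat * s_k) over the r categories.

    Computed with a max-shift so arbitrarily large exponents never overflow;
    the result always sums to one.
    """
    s = np.asarray(model.cost_levels, dtype=float)
    x = -model.mu_hat * s
    x -= x.max()
    w = np.exp(x)
    return w / w.sum()


def discrete_circle_sizes(mu: float, r: int) -> np.ndarray:
    """Cumulative layer sizes chi_k = (e^{k mu} - 1)/(e^{r mu} - 1), k=1..r.

    chi_r = 1 always; strictly increasing in k; mu = 0 gives the exact limit
    k/r.  As mu -> -inf every chi_k -> 1 (inverted regime: all relationships
    in the innermost circle).
    """
    r = int(r)
    if r < 2:
        raise ValueError("r must be >= 2")
    mu = float(mu)
    k = np.arange(1, r + 1, dtype=float)
    if mu == 0.0:
        return k / r
    if mu > 0:
        # e^{(k-r)mu} (1 - e^{-k mu}) / (1 - e^{-r mu}): overflow-free
        return np.exp((k - r) * mu) * (-np.expm1(-k * mu)) / (-np.expm1(-r * mu))
    return np.expm1(k * mu) / np.expm1(r * mu)


def discrete_scaling_ratio(mu: float, r: int, k: int) -> float:
    """Ratio chi_{k+1}/chi_k of consecutive circle sizes.

    Tends to e^mu as mu -> +inf (geometric scaling of circles; e^mu ≈ 3
    reproduces the classic human layer ratio) and to 1 as mu -> -inf.
    """
    r = int(r)
    k = int(k)
    if not 1 <= k < r:
        raise ValueError(f"k must satisfy 1 <= k < r, got k={k}, r={r}")
    mu = float(mu)
    if mu == 0.0:
        return (k + 1) / k
    if mu > 0:
        return np.exp(mu) * (-np.expm1(-(k + 1) * mu)) / (-np.expm1(-k * mu))
    return np.expm1((k + 1) * mu) / np.expm1(k * mu)


def eta_from_mu(mu: float, r: int, method: str = "asymptotic") -> float:
    """Continuum scale parameter equivalent to a discrete (mu, r) pair.

    method="asymptotic" (default): eta = (r - 1)(e^mu - 1), obtained by
    matching the discrete finite difference (chi_{k+1} - chi_k)/(chi_k Δt)
    with Δt = 1/(r-1) to the continuum logarithmic derivative in the normal
    regime.  With the canonical r = 4 layers and scaling ratio e^mu = 3 this
    gives eta = 6.

    method="exact": eta = r * mu, under which chi(k/r; eta) reproduces every
    chi_k exactly (pure algebra).  The two differ away from mu = 0; the
    asymptotic form is the conventional correspondence.
    """
    r = int(r)
    if r < 2:
        raise ValueError("r must be >= 2")
    mu = float(mu)
    if method == "asymptotic":
        return (r - 1) * float(np.expm1(mu))
    if method == "exact":
        return r * mu
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# container classes


@dataclass
class DiscreteCircleModel:
    """Discrete maximum-entropy circle model with r cost categories.

    Parameters
    ----------
    cost_levels : sequence of float
        Strictly decreasing costs s_1 > s_2 > ... > s_r (s_1 = s_max is the
        innermost, most expensive relationship category).
    mu_hat : float
        Lagrange multiplier enforcing the mean-cost constraint.
    """

    cost_levels: np.ndarray
    mu_hat: float

    def __post_init__(self):
        self.cost_levels = np.asarray(self.cost_levels, dtype=float)
        if self.cost_levels.size < 2:
            raise ValueError("need at least 2 cost levels")
        if not np.all(np.diff(self.cost_levels) < 0):
            raise ValueError("cost_levels must be strictly decreasing")
        self.mu_hat = float(self.mu_hat)

    @property
    def r(self) -> int:
        return self.cost_levels.size

    @property
    def s_max(self) -> float:
        return float(self.cost_levels[0])

    @property
    def s_min(self) -> float:
        return float(self.cost_levels[-1])

    @property
    def mu(self) -> float:
        """Rescaled multiplier mu = mu_hat (s_max - s_min)/(r - 1)."""
        return self.mu_hat * (self.s_max - self.s_min) / (self.r - 1)

    @property
    def Z_r(self) -> float:
        """Normalisation constant of the Boltzmann weights."""
        return float(np.sum(np.exp(-self.mu_hat * self.cost_levels)))

    @property
    def sigma(self) -> float:
        """Average cognitive cost E[s_k] under the layer probabilities."""
        return float(np.dot(self.probabilities(), self.cost_levels))

    def probabilities(self) -> np.ndarray:
        return layer_probabilities(self)

    def circle_sizes(self) -> np.ndarray:
        return discrete_circle_sizes(self.mu, self.r)

    def to_continuum(self, method: str = "asymptotic") -> "ContinuumModel":
        return ContinuumModel(eta=eta_from_mu(self.mu, self.r, method=method))


@dataclass
class ContinuumModel:
    """Continuum circle model parameterised by the scale parameter eta."""

    eta: float

    def __post_init__(self):
        self.eta = float(self.eta)
        if not np.isfinite(self.eta):
            raise ValueError("eta must be finite")

    @property
    def regime(self) -> str:
        if self.eta > 0:
            return "normal"
        if self.eta < 0:
            return "inverted"
        return "boundary"

    def cdf(self, t):
        return continuum_cdf(self.eta, t)

    def pdf(self, t):
        return continuum_pdf(self.eta, t)

    def mean(self) -> float:
        return mean_normalized_cost(self.eta)

    def var(self) -> float:
        return var_normalized_cost(self.eta)

    def log_derivative(self, t: float) -> float:
        return continuum_log_derivative(self.eta, t)
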