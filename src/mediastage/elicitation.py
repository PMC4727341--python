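"""Second-order distributions for model parameters.

Every numeric parameter of the staging model carries, besides its reference
mean, a *second-order* distribution describing the analyst's uncertainty
about the parameter itself (as opposed to the first-order randomness of
patient outcomes). Four Beta recipes are provided, mirroring how evidence is
reported in the clinical literature, plus uniform and Gamma recipes and a
degenerate (point-mass) spec for quantities treated as known:

1. ``beta_from_counts`` — m events out of n observations -> Beta(m, n - m).
2. ``beta_from_mean_cv`` — only a mean is reported; a coefficient of
   variation k (default 1/5) sets the standard deviation and the method of
   moments fits the Beta. If σ = k·μ is inconsistent with a Beta of mean μ,
   k is shrunk by powers of ten until it is.
3. ``beta_from_mean_interval`` with mass 0.95 — mean plus a 95 % CI; the
   Beta with that mean whose CDF puts 95 % of the mass on the interval is
   found by bisection on α (with β = α(1-μ)/μ).
4. The same recipe with mass 0.999, for sources that report a plain range
   rather than a confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ElicitationError, FitError

BETA = "beta"
UNIFORM = "uniform"
GAMMA = "gamma"
DEGENERATE = "degenerate"

#: Absolute tolerance on the interval-mass constraint of the bisection fit.
MASS_TOL = 1e-8
#: Bracket for the bisection over the Beta α parameter.
ALPHA_BRACKET = (1e-6, 1e9)


@dataclass(frozen=True)
class SecondOrderSpec:
    """A second-order distribution.

    ``args`` by family: beta (α, β); uniform (lower, upper); gamma
    (shape, scale); degenerate (point,).
    """

    family: str
    args: tuple[float, ...]

    def __post_init__(self):
        a = tuple(float(x) for x in self.args)
        object.__setattr__(self, "args", a)
        if self.family == BETA:
            if len(a) != 2 or a[0] <= 0 or a[1] <= 0:
                raise ElicitationError(f"invalid beta parameters {a}")
        elif self.family == UNIFORM:
            if len(a) != 2 or a[0] > a[1]:
                raise ElicitationError(f"invalid uniform support {a}")
        elif self.family == GAMMA:
            if len(a) != 2 or a[0] <= 0 or a[1] <= 0:
                raise ElicitationError(f"invalid gamma parameters {a}")
        elif self.family == DEGENERATE:
            if len(a) != 1 or not math.isfinite(a[0]):
                raise ElicitationError(f"invalid point mass {a}")
        else:
            raise ElicitationError(f"unknown family {self.family!r}")

    def mean(self) -> float:
        a = self.args
        if self.family == BETA:
            return a[0] / (a[0] + a[1])
        if self.family == UNIFORM:
            return (a[0] + a[1]) / 2.0
        if self.family == GAMMA:
            return a[0] * a[1]
        return a[0]

    def sd(self) -> float:
        a = self.args
        if self.family == BETA:
            s = a[0] + a[1]
            return math.sqrt(a[0] * a[1] / (s * s * (s + 1.0)))
        if self.family == UNIFORM:
            return (a[1] - a[0]) / math.sqrt(12.0)
        if self.family == GAMMA:
            return math.sqrt(a[0]) * a[1]
        return 0.0

    def support(self) -> tuple[float, float]:
        a = self.args
        if self.family == BETA:
            return (0.0, 1.0)
        if self.family == UNIFORM:
            return (a[0], a[1])
        if self.family == GAMMA:
            return (0.0, math.inf)
        return (a[0], a[0])

    def cdf(self, x: float) -> float:
        a = self.args
        if self.family == BETA:
            return float(stats.beta.cdf(x, a[0], a[1]))
        if self.family == UNIFORM:
            return float(stats.uniform.cdf(x, loc=a[0], scale=a[1] - a[0]))
        if self.family == GAMMA:
            return float(stats.gamma.cdf(x, a[0], scale=a[1]))
        return float(x >= a[0])

    def interval(self, mass: float = 0.95) -> tuple[float, float]:
        """Central interval containing ``mass`` of the probability."""
        lo, hi = (1 - mass) / 2, 1 - (1 - mass) / 2
        a = self.args
        if self.family == BETA:
            return tuple(stats.beta.ppf([lo, hi], a[0], a[1]))
        if self.family == UNIFORM:
            w = a[1] - a[0]
            return (a[0] + lo * w, a[0] + hi * w)
        if self.family == GAMMA:
            return tuple(stats.gamma.ppf([lo, hi], a[0], scale=a[1]))
        return (a[0], a[0])

    def is_degenerate(self) -> bool:
        return self.family == DEGENERATE


def sample(spec: SecondOrderSpec, rng: np.random.Generator, size=None):
    """Draw from ``spec``; reproducible for a given generator state."""
    a = spec.args
    if spec.family == BETA:
        return rng.beta(a[0], a[1], size=size)
    if spec.family == UNIFORM:
        return rng.uniform(a[0], a[1], size=size)
    if spec.family == GAMMA:
        return rng.gamma(a[0], a[1], size=size)
    if size is None:
        return a[0]
    return np.full(size, a[0])


# -- recipes ---------------------------------------------------------------

def degenerate(value: float) -> SecondOrderSpec:
    return SecondOrderSpec(DEGENERATE, (value,))


def beta_from_counts(m: int, n: int, literal: bool = False) -> SecondOrderSpec:
    """Beta posterior for m events of interest out of n observations.

    Returns Beta(α=m, β=n-m). The ``literal`` flag switches to Beta(m, n),
    kept only for auditing: it does not reproduce the reference means and
    intervals the count-based entries were published with.
    """
    if int(m) != m or int(n) != n:
        raise ElicitationError("counts must be integers")
    m, n = int(m), int(n)
    if not 0 < m < n:
        raise ElicitationError(f"need 0 < m < n, got m={m}, n={n}")
    if literal:
        return SecondOrderSpec(BETA, (m, n))
    return SecondOrderSpec(BETA, (m, n - m))


def beta_from_mean_cv(mu: float, k: float = 0.2) -> SecondOrderSpec:
    """Method-of-moments Beta from a mean and a coefficient of variation.

    σ = k·μ; z = μ(1-μ)/σ² - 1, α = z·μ, β = z - α. If σ² >= μ(1-μ) (no
    Beta has that mean/sd combination), k is shrunk to 10^-m · k for the
    smallest natural m restoring consistency.
    """
    if not 0 < mu < 1:
        raise ElicitationError(f"mean must lie in (0, 1), got {mu}")
    if k <= 0:
        raise ElicitationError("coefficient of variation must be positive")
    var_bound = mu * (1.0 - mu)
    k_eff = k
    while (k_eff * mu) ** 2 >= var_bound:
        k_eff /= 10.0
    sigma2 = (k_eff * mu) ** 2
    z = var_bound / sigma2 - 1.0
    alpha = z * mu
    return SecondOrderSpec(BETA, (alpha, z - alpha))


def beta_from_mean_interval(mu: float, l: float, u: float,
                            mass: float = 0.95) -> SecondOrderSpec:
    """Beta with mean ``mu`` putting ``mass`` probability on [l, u].

    With β = α(1-μ)/μ the interval mass F(u) - F(l) increases monotonically
    in α (the distribution concentrates around μ ∈ (l, u)), so a bisection
    over α on an expanding bracket solves F(u) - F(l) = mass to ``MASS_TOL``.
    """
    if not (0 < l < mu < u <= 1):
        raise ElicitationError(f"need 0 < l < mu < u <= 1, got ({mu}, {l}, {u})")
    if not 0 < mass < 1:
        raise ElicitationError("mass must lie in (0, 1)")

    ratio = (1.0 - mu) / mu

    def gap(alpha: float) -> float:
        beta = alpha * ratio
        return float(stats.beta.cdf(u, alpha, beta)
                     - stats.beta.cdf(l, alpha, beta)) - mass

    lo, cap = ALPHA_BRACKET
    hi = max(1.0, lo * 2)
    while gap(hi) < 0:
        hi *= 4.0
        if hi > cap:
            raise FitError(
                f"no α in [{lo}, {cap:g}] yields interval mass {mass} "
                f"for mean {mu} on [{l}, {u}]"
            )
    if gap(lo) > 0:
        raise FitError(f"interval mass already exceeds {mass} at α={lo}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
        if abs(gap(hi)) < MASS_TOL:
            break
    alpha = hi
    if abs(gap(alpha)) >= MASS_TOL:
        raise FitError("bisection did not reach the mass tolerance")
    return SecondOrderSpec(BETA, (alpha, alpha * ratio))


def uniform_from_interval(l: float, u: float) -> SecondOrderSpec:
    """Uniform on [l, u] (the printed interval is the full support)."""
    if l >= u:
        raise ElicitationError(f"need l < u, got [{l}, {u}]")
    return SecondOrderSpec(UNIFORM, (l, u))


def gamma_from_mean_cv(mu: float, k: float = 0.2) -> SecondOrderSpec:
    """Moment-matched Gamma: shape 1/k², scale μ·k² (mean μ, sd k·μ)."""
    if mu <= 0:
        raise ElicitationError(f"mean must be positive, got {mu}")
    if k <= 0:
        raise ElicitationError("coefficient of variation must be positive")
    return SecondOrderSpec(GAMMA, (1.0 / k**2, mu * k**2))


#: Method identifiers accepted in parameter configuration files.
METHODS = ("counts", "mean_cv", "mean_ci95", "mean_range999",
           "uniform", "gamma", "degenerate")


def build_spec(method: str, mean: float, **inputs) -> SecondOrderSpec:
    """Dispatch a configuration-file record to the matching recipe.

    The fit is recomputed from the raw inputs every time; fitted shape
    parameters are never stored in configuration files.
    """
    if method == "counts":
        return beta_from_counts(inputs["m"], inputs["n"])
    if method == "mean_cv":
        return beta_from_mean_cv(mean, inputs.get("k", 0.2))
    if method == "mean_ci95":
        return beta_from_mean_interval(mean, inputs["lower"], inputs["upper"], 0.95)
    if method == "mean_range999":
        return beta_from_mean_interval(mean, inputs["lower"], inputs["upper"], 0.999)
    if method == "uniform":
        return uniform_from_interval(inputs["lower"], inputs["upper"])
    if method == "gamma":
        return gamma_from_mean_cv(mean, inputs.get("k", 0.2))
    if method == "degenerate":
        return degenerate(mean)
    raise ElicitationError(f"unknown elicitation method {method!r}")
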