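"""Imbalance scenarios and cluster-level sample-size planning.

A two-arm cluster randomized trial (CRT) with a 1:1 allocation and a binary
cluster-level covariate present in exactly half of the clusters is fully
described, at the design level, by

* ``n1`` — the common cluster size,
* ``n2`` — the total number of clusters (a multiple of 4 so that each arm can
  hold equally many covariate-positive and covariate-negative clusters),
* ``k``  — the number of covariate-positive clusters assigned to the
  intervention arm.

Under complete randomization ``k`` follows a hypergeometric distribution with
population ``n2``, ``n2/2`` successes and ``n2/2`` draws.  The degree of
covariate imbalance is expressed as a quantile ``q`` of this distribution:
``q = 0.5`` corresponds to perfect balance (``k = n2/4``), values above 0.5 to
an excess of covariate-positive clusters in the intervention arm and values
below 0.5 to a deficit.  The induced treatment–covariate correlation is
``rho_xz = 4k/n2 - 1``, and ``1/(1 - rho_xz**2)`` is the variance inflation
factor on the treatment-effect estimator of the covariate-adjusted model.

The planning formula implemented here gives the number of clusters needed for
power ``1 - beta`` against a treatment effect ``beta1`` at two-sided level
``alpha`` in a random-intercept model with unit total variance:

    n2 = 4 (sigma_e^2 + n1 sigma_u^2) / (n1 (1 - rho_xz^2))
         * ((z_{1-alpha/2} + z_{1-beta}) / beta1)^2
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PlanningSpec",
    "ImbalanceSpec",
    "TrialDesign",
    "hypergeom_pmf",
    "imbalance_quantile",
    "rho_xz_from_k",
    "required_clusters",
    "build_design",
    "CollinearDesignError",
    "DEFAULT_MIN_N2",
]

#: Smallest number of clusters a planned design may use.  The planning formula
#: can return fewer than 8 clusters for large clusters with a tiny intraclass
#: correlation, in which case extreme imbalance quantiles would make treatment
#: and covariate perfectly collinear and the adjusted model unidentifiable.
DEFAULT_MIN_N2 = 8


class CollinearDesignError(ValueError):
    """Treatment and covariate indicators are identical or opposite."""


@dataclass(frozen=True)
class PlanningSpec:
    """Inputs of an a-priori power analysis at the cluster level.

    Parameters
    ----------
    alpha
        Two-sided type-I error rate.
    power_target
        Desired power ``1 - beta``.
    beta1_target
        Detectable treatment effect, in outcome-SD units (total variance 1).
    rho_xz_assumed
        Treatment–covariate correlation assumed at the planning stage.
        Planning under the assumption of balance uses 0.
    """

    alpha: float = 0.05
    power_target: float = 0.8
    beta1_target: float = 0.5
    rho_xz_assumed: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.power_target < 1.0:
            raise ValueError(
                f"power_target must lie in (0, 1), got {self.power_target}"
            )
        if self.beta1_target == 0.0:
            raise ValueError("beta1_target must be nonzero")
        if not -1.0 < self.rho_xz_assumed < 1.0:
            raise ValueError(
                "rho_xz_assumed must lie strictly inside (-1, 1); "
                f"got {self.rho_xz_assumed}"
            )


@dataclass(frozen=True)
class ImbalanceSpec:
    """A realized degree of imbalance: quantile, count and correlation."""

    q: float
    k: int
    rho_xz: float


@dataclass(frozen=True)
class TrialDesign:
    """A fully realized CRT design.

    ``x`` and ``z`` are 0/1 vectors of length ``n2`` giving, per cluster, the
    treatment arm and the covariate value.  Intervention clusters come first
    and, within each arm, covariate-positive clusters come first; the model is
    exchangeable over clusters so the ordering is a pure bookkeeping choice.
    """

    n1: int
    n2: int
    x: np.ndarray
    z: np.ndarray
    imbalance: ImbalanceSpec

    def __post_init__(self) -> None:
        _check_n2(self.n2)
        if self.n1 < 1:
            raise ValueError(f"cluster size n1 must be >= 1, got {self.n1}")
        x = np.asarray(self.x, dtype=np.int64)
        z = np.asarray(self.z, dtype=np.int64)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        if x.shape != (self.n2,) or z.shape != (self.n2,):
            raise ValueError("x and z must have length n2")
        if int(x.sum()) != self.n2 // 2:
            raise ValueError("exactly n2/2 clusters must be in the intervention arm")
        if int(z.sum()) != self.n2 // 2:
            raise ValueError("exactly n2/2 clusters must be covariate-positive")
        if int((x * z).sum()) != self.imbalance.k:
            raise ValueError("covariate-positive intervention clusters != k")

    @property
    def n_subjects(self) -> int:
        return self.n1 * self.n2


def _check_n2(n2: int) -> None:
    if n2 <= 0 or n2 % 4 != 0:
        raise ValueError(f"n2 must be a positive multiple of 4, got {n2}")


def _check_k(n2: int, k: int) -> None:
    if not 0 <= k <= n2 // 2:
        raise ValueError(f"k must lie in [0, n2/2] = [0, {n2 // 2}], got {k}")


def hypergeom_pmf(n2: int, k: int) -> float:
    """P(K = k) for the count of covariate-positive intervention clusters.

    ``K`` is hypergeometric with population ``n2``, ``n2/2`` successes and
    ``n2/2`` draws — the distribution of the covariate-positive count in the
    intervention arm under complete 1:1 randomization.
    """
    _check_n2(n2)
    _check_k(n2, k)
    half = n2 // 2
    return float(stats.hypergeom.pmf(k, n2, half, half))


def imbalance_quantile(n2: int, q: float) -> int:
    """Smallest ``k`` whose hypergeometric CDF reaches ``q``.

    ``q = 0.5`` returns the distribution's expectation ``n2/4`` (perfect
    balance); the map is nondecreasing in ``q``.
    """
    _check_n2(n2)
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile q must lie in (0, 1), got {q}")
    half = n2 // 2
    k = int(stats.hypergeom.ppf(q, n2, half, half))
    # guard against floating-point slack in the ppf: enforce CDF(k) >= q > CDF(k-1)
    while stats.hypergeom.cdf(k, n2, half, half) < q:
        k += 1
    while k > 0 and stats.hypergeom.cdf(k - 1, n2, half, half) >= q:
        k -= 1
    return k


def rho_xz_from_k(n2: int, k: int) -> float:
    """Pearson correlation between the treatment and covariate indicators.

    With both margins fixed at ``n2/2`` the correlation of the 0/1 vectors
    reduces to ``4k/n2 - 1``.
    """
    _check_n2(n2)
    _check_k(n2, k)
    return 4.0 * k / n2 - 1.0


def required_clusters(
    n1: int,
    rho: float,
    plan: PlanningSpec,
    *,
    min_n2: int = DEFAULT_MIN_N2,
) -> tuple[float, int]:
    """Number of clusters for the target power, raw and rounded.

    The total outcome variance is fixed at 1, so ``sigma_u^2 = rho`` and
    ``sigma_e^2 = 1 - rho``.  The raw value is rounded up to the nearest
    multiple of 4 (an even number of clusters per arm, so the binary covariate
    can be perfectly balanced) and never below ``min_n2``.

    Returns
    -------
    (raw, rounded)
        The unrounded solution of the power formula and the number of
        clusters actually planned.
    """
    if n1 < 1:
        raise ValueError(f"n1 must be >= 1, got {n1}")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"ICC rho must lie in [0, 1), got {rho}")
    if min_n2 < 4 or min_n2 % 4 != 0:
        raise ValueError(f"min_n2 must be a positive multiple of 4, got {min_n2}")
    sigma_u2 = rho
    sigma_e2 = 1.0 - rho
    z_alpha = stats.norm.ppf(1.0 - plan.alpha / 2.0)
    z_beta = stats.norm.ppf(plan.power_target)
    vif = 1.0 - plan.rho_xz_assumed**2
    raw = (
        4.0
        * (sigma_e2 + n1 * sigma_u2)
        / (n1 * vif)
        * ((z_alpha + z_beta) / plan.beta1_target) ** 2
    )
    rounded = max(4 * math.ceil(raw / 4.0), min_n2)
    return raw, rounded


def build_design(
    n1: int,
    rho: float,
    q: float,
    plan: PlanningSpec | None = None,
    *,
    min_n2: int = DEFAULT_MIN_N2,
) -> TrialDesign:
    """Plan ``n2`` for balance, then impose imbalance at quantile ``q``.

    Planning deliberately assumes ``rho_xz = 0`` (a power analysis that
    ignores the possibility of imbalance); the design is then realized with
    ``k = imbalance_quantile(n2, q)`` covariate-positive clusters in the
    intervention arm.  Raises :class:`CollinearDesignError` when the realized
    ``k`` makes treatment and covariate perfectly collinear, in which case the
    adjusted model is unidentifiable.
    """
    if plan is None:
        plan = PlanningSpec()
    plan_balanced = PlanningSpec(
        alpha=plan.alpha,
        power_target=plan.power_target,
        beta1_target=plan.beta1_target,
        rho_xz_assumed=0.0,
    )
    _, n2 = required_clusters(n1, rho, plan_balanced, min_n2=min_n2)
    k = imbalance_quantile(n2, q)
    rho_xz = rho_xz_from_k(n2, k)
    if abs(rho_xz) == 1.0:
        raise CollinearDesignError(
            f"imbalance quantile q={q} with n2={n2} gives k={k}: treatment and "
            "covariate are perfectly collinear"
        )
    half = n2 // 2
    x = np.zeros(n2, dtype=np.int64)
    x[:half] = 1
    z = np.zeros(n2, dtype=np.int64)
    z[:k] = 1  # covariate-positive intervention clusters
    z[half : half + (half - k)] = 1  # covariate-positive control clusters
    return TrialDesign(
        n1=n1,
        n2=n2,
        x=x,
        z=z,
        imbalance=ImbalanceSpec(q=q, k=k, rho_xz=rho_xz),
    )
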