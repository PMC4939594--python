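"""Evaluation criteria and the closed-form theory used to cross-check them.

Three Monte-Carlo criteria summarize each simulation condition:

* percentage parameter bias, ``100 (mean(beta1_hat) - beta1) / beta1``;
* percentage standard-error bias, ``100 (mean(se) - sd(beta1_hat)) / sd``,
  comparing the average model-based standard error to the empirical standard
  deviation of the estimates;
* empirical power, the percentage of replicates rejecting ``H0: beta1 = 0``.

Closed forms provide deterministic cross-checks: the expected bias of the
unadjusted estimator under fixed imbalance, the theoretical standard error of
the adjusted estimator, and the nominal (design-stage) power implied by the
normal-approximation sample-size formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ModelSummary",
    "ConditionSummary",
    "parameter_bias_pct",
    "se_bias_pct",
    "empirical_power_pct",
    "expected_unadjusted_bias_pct",
    "theoretical_se",
    "nominal_power_pct",
    "nominal_power_pct_t",
]


def parameter_bias_pct(estimates, beta1_true: float) -> float:
    """Percentage bias of the mean treatment-effect estimate."""
    estimates = np.asarray(estimates, dtype=np.float64)
    if estimates.size == 0:
        raise ValueError("need at least one estimate")
    if beta1_true == 0.0:
        raise ValueError("percentage bias is undefined for beta1_true = 0")
    return float(100.0 * (estimates.mean() - beta1_true) / beta1_true)


def se_bias_pct(mean_se: float, sd_estimates: float) -> float:
    """Percentage bias of the mean model-based SE against the empirical SD."""
    if sd_estimates <= 0.0:
        raise ValueError("sd of estimates must be positive")
    return float(100.0 * (mean_se - sd_estimates) / sd_estimates)


def empirical_power_pct(rejections) -> float:
    """Percentage of replicates rejecting the null of no treatment effect."""
    rejections = np.asarray(rejections, dtype=bool)
    if rejections.size == 0:
        raise ValueError("need at least one replicate")
    return float(100.0 * rejections.mean())


def expected_unadjusted_bias_pct(beta1: float, beta2: float, n2: int, k: int) -> float:
    """Exact expectation of the unadjusted estimator's percentage bias.

    Under fixed imbalance the unadjusted arm-mean difference has expectation
    ``beta1 + beta2 * (zbar_I - zbar_C)`` with
    ``zbar_I - zbar_C = (2k - n2/2) / (n2/2)``.
    """
    if beta1 == 0.0:
        raise ValueError("percentage bias is undefined for beta1 = 0")
    half = n2 // 2
    delta_z = (k - (half - k)) / half
    return 100.0 * beta2 * delta_z / beta1


def theoretical_se(
    n1: int, n2: int, sigma_u2: float, sigma_e2: float, rho_xz: float = 0.0
) -> float:
    """Model-based SE of the adjusted treatment-effect estimator.

    ``sqrt(4 (sigma_e^2 + n1 sigma_u^2) / (n1 n2 (1 - rho_xz^2)))``; the
    factor ``1/(1 - rho_xz^2)`` is the variance inflation caused by
    treatment–covariate correlation.  With ``rho_xz = 0`` this is also the
    (true-variance) SE of the unadjusted estimator.
    """
    if abs(rho_xz) >= 1.0:
        raise ValueError("standard error diverges as |rho_xz| -> 1")
    return float(
        np.sqrt(4.0 * (sigma_e2 + n1 * sigma_u2) / (n1 * n2 * (1.0 - rho_xz**2)))
    )


def nominal_power_pct(
    n1: int, n2: float, rho: float, beta1: float, alpha: float = 0.05
) -> float:
    """Design-stage power by the normal approximation, assuming balance.

    Inverse of the sample-size formula: plugging the unrounded number of
    clusters back in returns the target power exactly.  Total variance 1, so
    ``sigma_u^2 = rho`` and ``sigma_e^2 = 1 - rho``.
    """
    se = np.sqrt(4.0 * (1.0 - rho + n1 * rho) / (n1 * n2))
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(100.0 * stats.norm.cdf(abs(beta1) / se - z_alpha))


def nominal_power_pct_t(
    n1: int, n2: int, rho: float, beta1: float, alpha: float = 0.05, df: int | None = None
) -> float:
    """Design-stage power from the noncentral t with ``df = n2 - 3``.

    A small-sample refinement of :func:`nominal_power_pct`; exposed for
    comparison, not used as the reported nominal line.
    """
    if df is None:
        df = n2 - 3
    se = np.sqrt(4.0 * (1.0 - rho + n1 * rho) / (n1 * n2))
    ncp = abs(beta1) / se
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        100.0 * (stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    )


@dataclass(frozen=True)
class ModelSummary:
    """Monte-Carlo summary of one fitted model at one condition."""

    model: str
    mean_beta1_hat: float
    parameter_bias_pct: float
    mean_se: float
    sd_beta1_hat: float
    se_bias_pct: float
    empirical_power_pct: float


@dataclass(frozen=True)
class ConditionSummary:
    """All evaluation criteria for one simulation condition."""

    n1: int
    rho: float
    beta2: float
    q: float
    n2: int
    k: int
    rho_xz: float
    reps: int
    failures: int
    nominal_power_pct: float
    adjusted: ModelSummary
    unadjusted: ModelSummary

    def rows(self) -> list[dict]:
        """Long-format serialization: one row per model."""
        base = {
            "n1": self.n1,
            "rho": self.rho,
            "beta2": self.beta2,
            "q": self.q,
            "n2": self.n2,
            "k": self.k,
            "rho_xz": self.rho_xz,
            "reps": self.reps,
            "failures": self.failures,
            "nominal_power_pct": self.nominal_power_pct,
        }
        out = []
        for ms in (self.adjusted, self.unadjusted):
            row = dict(base)
            row["model"] = ms.model
            row["mean_beta1_hat"] = ms.mean_beta1_hat
            row["parameter_bias_pct"] = ms.parameter_bias_pct
            row["mean_se"] = ms.mean_se
            row["sd_beta1_hat"] = ms.sd_beta1_hat
            row["se_bias_pct"] = ms.se_bias_pct
            row["empirical_power_pct"] = ms.empirical_power_pct
            out.append(row)
        return out


def summarize_model(
    model: str, beta1_hats: np.ndarray, ses: np.ndarray, rejections: np.ndarray,
    beta1_true: float,
) -> ModelSummary:
    """Collapse per-replicate fits of one model into the three criteria."""
    sd = float(np.std(beta1_hats, ddof=1))
    return ModelSummary(
        model=model,
        mean_beta1_hat=float(np.mean(beta1_hats)),
        parameter_bias_pct=parameter_bias_pct(beta1_hats, beta1_true),
        mean_se=float(np.mean(ses)),
        sd_beta1_hat=sd,
        se_bias_pct=se_bias_pct(float(np.mean(ses)), sd),
        empirical_power_pct=empirical_power_pct(rejections),
    )
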