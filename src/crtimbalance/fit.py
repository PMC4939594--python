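"""REML fitting of the adjusted and unadjusted random-intercept models.

For a balanced design (common cluster size ``n1``) whose fixed effects are all
cluster-level, the mixed model collapses to an ordinary regression of the
cluster means on the cluster-level design: the cluster means are independent
with common variance ``sigma_u^2 + sigma_e^2 / n1``, so GLS equals OLS on the
means, and REML variance components coincide with the classical ANOVA
estimators whenever the between-cluster variance estimate is interior:

    sigma_e^2_hat = within-cluster mean square
                  = sum_j sum_i (y_ij - ybar_j)^2 / (n2 (n1 - 1))
    B             = RSS of the cluster-mean OLS / (n2 - p)
    sigma_u2_hat  = B - sigma_e^2_hat / n1

with ``p`` the number of fixed effects (3 adjusted, 2 unadjusted).  The
restricted likelihood of a balanced design factorizes into a within-cluster
part and a cluster-mean part, so when the unconstrained solution would be
negative the constrained REML maximum sits on the boundary ``sigma_u^2 = 0``
with the two parts pooled:

    sigma_u2_hat = 0,
    sigma_e^2_hat = (SSW + n1 * RSS) / (n1 n2 - p),

i.e. the residual variance of the individual-level OLS fit.  Both regimes are
handled in closed form, so the fits agree with a numerically optimized REML
everywhere, not only at interior solutions.

The model-based standard error of the treatment effect uses the realized
treatment–covariate correlation ``r_xz``:

    se(beta1_hat)  = sqrt(4 (sigma_e^2_hat + n1 sigma_u2_hat)
                          / (n1 n2 (1 - r_xz^2)))          (adjusted)
    se(beta1_hat*) = sqrt(4 (sigma_e*^2_hat + n1 sigma_u*^2_hat) / (n1 n2))

which is exactly the GLS variance for 0/1 treatment coding with equal arms.
The Wald statistic ``t = beta1_hat / se`` is referred to a central t with
``n2 - 3`` (adjusted) or ``n2 - 2`` (unadjusted) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import CollinearDesignError, TrialDesign
from .simulate import TrialData

__all__ = [
    "FitResult",
    "ArmMeans",
    "arm_means",
    "reml_components",
    "fit_adjusted",
    "fit_unadjusted",
    "fit_cluster_means",
    "fits_to_frame",
]


@dataclass(frozen=True)
class FitResult:
    """One model fit on one trial."""

    model: str  # "adjusted" | "unadjusted"
    beta1_hat: float
    se_beta1: float
    sigma_u2_hat: float
    sigma_e2_hat: float
    df: int
    t_stat: float
    p_value: float
    reject: bool
    beta2_hat: float | None = None  # absent for the unadjusted model


@dataclass(frozen=True)
class ArmMeans:
    """Arm-level means of outcome and covariate."""

    ybar_I: float
    ybar_C: float
    zbar_I: float
    zbar_C: float


def arm_means(data: TrialData) -> ArmMeans:
    """Exact arithmetic means per treatment arm."""
    x = data.design.x.astype(bool)
    return ArmMeans(
        ybar_I=float(data.y[x].mean()),
        ybar_C=float(data.y[~x].mean()),
        zbar_I=float(data.design.z[x].mean()),
        zbar_C=float(data.design.z[~x].mean()),
    )


def _design_matrix(design: TrialDesign, adjusted: bool) -> np.ndarray:
    if adjusted:
        return np.column_stack(
            [np.ones(design.n2), design.x.astype(float), design.z.astype(float)]
        )
    return np.column_stack([np.ones(design.n2), design.x.astype(float)])


def _r_xz(design: TrialDesign) -> float:
    x = design.x.astype(float)
    z = design.z.astype(float)
    sx = x.std()
    sz = z.std()
    if sx == 0.0 or sz == 0.0:
        raise CollinearDesignError("degenerate design: constant x or z")
    return float(((x - x.mean()) * (z - z.mean())).mean() / (sx * sz))


def _sufficient_stats(data: TrialData) -> tuple[np.ndarray, float]:
    """Cluster means and pooled within-cluster sum of squares."""
    m = data.y.mean(axis=1)
    ssw = float(((data.y - m[:, None]) ** 2).sum())
    return m, ssw


def fit_cluster_means(
    design: TrialDesign,
    means: np.ndarray,
    ssw: np.ndarray,
    adjusted: bool,
    alpha: float = 0.05,
) -> dict[str, np.ndarray]:
    """Fit one model to a whole stack of replicates at once.

    Parameters
    ----------
    means
        ``(R, n2)`` cluster means, one row per replicate.
    ssw
        ``(R,)`` pooled within-cluster sums of squares.

    Returns arrays keyed ``beta1_hat, beta2_hat, se_beta1, sigma_u2_hat,
    sigma_e2_hat, t_stat, p_value, reject`` plus the scalar ``df``.  This is
    the workhorse behind both the per-trial API and the study runner; the two
    therefore agree exactly.
    """
    n1, n2 = design.n1, design.n2
    if n1 < 2:
        raise ValueError("within-cluster variance requires n1 >= 2")
    means = np.atleast_2d(np.asarray(means, dtype=np.float64))
    ssw = np.atleast_1d(np.asarray(ssw, dtype=np.float64))
    p = 3 if adjusted else 2
    if n2 <= p:
        raise ValueError(f"need n2 > {p} clusters for the {'adjusted' if adjusted else 'unadjusted'} model")
    if adjusted:
        r_xz = _r_xz(design)
        if abs(r_xz) >= 1.0 - 1e-12:
            raise CollinearDesignError(
                "treatment and covariate are collinear; the adjusted model "
                "is unidentifiable"
            )
        vif = 1.0 - r_xz**2
    else:
        vif = 1.0
    X = _design_matrix(design, adjusted)
    pinv = np.linalg.pinv(X)  # (p, n2)
    coefs = means @ pinv.T  # (R, p)
    resid = means - coefs @ X.T
    rss = (resid**2).sum(axis=1)

    sigma_e2 = ssw / (n2 * (n1 - 1))
    between_ms = rss / (n2 - p)
    sigma_u2 = between_ms - sigma_e2 / n1
    boundary = sigma_u2 < 0.0
    if np.any(boundary):
        # constrained REML maximum at sigma_u^2 = 0: pool within- and
        # between-cluster sums of squares into one residual variance
        pooled = (ssw + n1 * rss) / (n1 * n2 - p)
        sigma_e2 = np.where(boundary, pooled, sigma_e2)
        sigma_u2 = np.where(boundary, 0.0, sigma_u2)

    se = np.sqrt(4.0 * (sigma_e2 + n1 * sigma_u2) / (n1 * n2 * vif))
    beta1 = coefs[:, 1]
    df = n2 - p
    t = beta1 / se
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    reject = np.abs(t) > stats.t.ppf(1.0 - alpha / 2.0, df)
    out = {
        "beta1_hat": beta1,
        "se_beta1": se,
        "sigma_u2_hat": sigma_u2,
        "sigma_e2_hat": sigma_e2,
        "t_stat": t,
        "p_value": pval,
        "reject": reject,
        "df": df,
    }
    if adjusted:
        out["beta2_hat"] = coefs[:, 2]
    return out


def reml_components(data: TrialData, adjusted: bool) -> tuple[float, float]:
    """``(sigma_u2_hat, sigma_e2_hat)`` by the closed-form balanced REML."""
    m, ssw = _sufficient_stats(data)
    res = fit_cluster_means(data.design, m, np.array([ssw]), adjusted)
    return float(res["sigma_u2_hat"][0]), float(res["sigma_e2_hat"][0])


def _fit(data: TrialData, adjusted: bool, alpha: float) -> FitResult:
    m, ssw = _sufficient_stats(data)
    res = fit_cluster_means(data.design, m, np.array([ssw]), adjusted, alpha)
    return FitResult(
        model="adjusted" if adjusted else "unadjusted",
        beta1_hat=float(res["beta1_hat"][0]),
        beta2_hat=float(res["beta2_hat"][0]) if adjusted else None,
        se_beta1=float(res["se_beta1"][0]),
        sigma_u2_hat=float(res["sigma_u2_hat"][0]),
        sigma_e2_hat=float(res["sigma_e2_hat"][0]),
        df=int(res["df"]),
        t_stat=float(res["t_stat"][0]),
        p_value=float(res["p_value"][0]),
        reject=bool(res["reject"][0]),
    )


def fit_adjusted(data: TrialData, alpha: float = 0.05) -> FitResult:
    """Fit the covariate-adjusted model and test the treatment effect."""
    return _fit(data, adjusted=True, alpha=alpha)


def fits_to_frame(fits, condition: dict | None = None):
    """Long-format table of per-replicate fit results, ready for CSV export
    or for comparison with external mixed-model software."""
    import dataclasses

    import pandas as pd

    rows = []
    for rep, f in enumerate(fits):
        row = dict(condition or {})
        row["replicate"] = rep
        row.update(dataclasses.asdict(f))
        rows.append(row)
    return pd.DataFrame(rows)


def fit_unadjusted(data: TrialData, alpha: float = 0.05) -> FitResult:
    """Fit the model that ignores the covariate.

    For equal arms the treatment-effect estimate is exactly the difference of
    arm means; when the covariate truly affects the outcome and is imbalanced,
    the estimate absorbs the covariate effect and is biased by
    ``beta2 * (zbar_I - zbar_C)``.
    """
    return _fit(data, adjusted=False, alpha=alpha)
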