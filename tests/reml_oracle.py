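"""Generic numerically-optimized REML fit, independent of the package's
closed-form path.

Builds the full ``N x N`` marginal covariance ``V = sigma_u^2 ZZ' +
sigma_e^2 I`` and maximizes the restricted log-likelihood

    -2 RLL = ln|V| + ln|X' V^-1 X| + y' P y,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

over ``(log sigma_u^2, log sigma_e^2)`` with Nelder-Mead.  Deliberately slow
and matrix-based so it shares no code with the implementation under test.
"""

import numpy as np
from scipy import optimize
from scipy.linalg import block_diag


def numeric_reml_fit(y: np.ndarray, x_cluster: np.ndarray):
    """REML fit of ``y_ij = X beta + u_j + e_ij`` by brute-force optimization.

    Parameters
    ----------
    y
        ``(n2, n1)`` outcomes.
    x_cluster
        ``(n2, p)`` cluster-level fixed-effect design.

    Returns dict with ``sigma_u2, sigma_e2, beta, se`` (the model-based
    standard errors of all fixed effects).
    """
    n2, n1 = y.shape
    yi = y.ravel()
    X = np.repeat(x_cluster, n1, axis=0)
    blocks = block_diag(*[np.ones((n1, n1))] * n2)
    eye = np.eye(n1 * n2)

    def neg2rll(theta):
        su2, se2 = np.exp(theta)
        V = su2 * blocks + se2 * eye
        sign, logdet_v = np.linalg.slogdet(V)
        Vinv = np.linalg.inv(V)
        xtvx = X.T @ Vinv @ X
        _, logdet_x = np.linalg.slogdet(xtvx)
        beta = np.linalg.solve(xtvx, X.T @ Vinv @ yi)
        r = yi - X @ beta
        return logdet_v + logdet_x + r @ Vinv @ r

    # moment-based start, pushed slightly interior
    m = y.mean(axis=1)
    se2_0 = max(((y - m[:, None]) ** 2).sum() / (n2 * (n1 - 1)), 1e-3)
    su2_0 = max(np.var(m, ddof=1) - se2_0 / n1, 1e-3)
    res = optimize.minimize(
        neg2rll,
        np.log([su2_0, se2_0]),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 10_000, "maxfev": 10_000},
    )
    su2, se2 = np.exp(res.x)
    V = su2 * blocks + se2 * eye
    Vinv = np.linalg.inv(V)
    xtvx = X.T @ Vinv @ X
    cov = np.linalg.inv(xtvx)
    beta = cov @ X.T @ Vinv @ yi
    return {
        "sigma_u2": float(su2),
        "sigma_e2": float(se2),
        "beta": beta,
        "se": np.sqrt(np.diag(cov)),
        "neg2rll": float(res.fun),
    }
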