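"""Independent brute-force oracles used only by the tests.

The dense ML oracle assembles the full N x N compound-symmetry covariance
explicitly and maximizes the exact multivariate-normal likelihood over the
two variance components (slope and intercept profiled out by dense GLS).
It shares no code path with the package's profiled fitter.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def dense_negloglik(x, y, cid, var_u, var_e):
    """Exact -log L at (var_u, var_e) with (beta0, beta1) profiled by GLS."""
    n = len(y)
    Z = np.zeros((n, int(cid.max()) + 1))
    Z[np.arange(n), cid] = 1.0
    V = var_e * np.eye(n) + var_u * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    X = np.column_stack([np.ones(n), x])
    XtVi = X.T @ Vinv
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    r = y - X @ beta
    _, logdet = np.linalg.slogdet(V)
    nll = 0.5 * (logdet + r @ Vinv @ r + n * np.log(2 * np.pi))
    return nll, beta


def dense_ml_fit(x, y, cid):
    """Maximize the exact likelihood over (log var_u, log var_e).

    Returns (beta0, beta1, sd_u, sd_e, nll).  var_u is bounded below at
    e^-30, i.e. effectively 0 for comparison at 1e-4 absolute tolerance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cid = np.asarray(cid)

    def objective(params):
        params = np.clip(params, -30.0, 15.0)
        try:
            return dense_negloglik(
                x, y, cid, np.exp(params[0]), np.exp(params[1])
            )[0]
        except np.linalg.LinAlgError:
            return 1e12

    v0 = max(np.var(y), 1e-4)
    best = None
    for start in ([np.log(v0 / 2), np.log(v0 / 2)],
                  [np.log(1e-6), np.log(v0)],
                  [np.log(v0), np.log(v0 / 10)]):
        res = optimize.minimize(
            objective, start, method="L-BFGS-B",
            bounds=[(-30.0, 15.0), (-15.0, 15.0)],
        )
        res = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    var_u, var_e = np.exp(best.x)
    nll, beta = dense_negloglik(x, y, cid, var_u, var_e)
    return beta[0], beta[1], np.sqrt(var_u), np.sqrt(var_e), nll


def random_tiny_instance(rng):
    """A random balanced design of 2-5 clusters x 2-5 observations with
    genuine cluster structure in both x and y."""
    j = int(rng.integers(2, 6))
    m = int(rng.integers(2, 6))
    cid = np.repeat(np.arange(j), m)
    x = rng.normal(size=j * m) + np.repeat(rng.normal(0, rng.uniform(0, 2), j), m)
    u = np.repeat(rng.normal(0, rng.uniform(0, 1.5), j), m)
    y = 1.0 + 0.8 * x + u + rng.normal(0, rng.uniform(0.3, 1.5), j * m)
    if np.ptp(x) < 1e-6:
        x = x + rng.normal(size=j * m)
    return x, y, cid


def check_profiled_vs_dense(seed: int, n_instances: int) -> int:
    """Assert the package's profiled RI fitter agrees with the dense ML
    oracle on random tiny instances; returns the number checked."""
    from clustersim.estimators import fit_ri

    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        x, y, cid = random_tiny_instance(rng)
        ours = fit_ri((x, y, cid))
        _, b1, sd_u, sd_e, nll_oracle = dense_ml_fit(x, y, cid)
        nll_ours, _ = dense_negloglik(
            x, y, cid, max(ours.sd_u_hat, 1e-16) ** 2, ours.sd_e_hat**2
        )
        # our optimum must be at least as good as the oracle's ...
        assert nll_ours <= nll_oracle + 1e-6
        # ... and agree with it in the parameters
        assert abs(ours.beta1_hat - b1) <= 1e-6 * max(abs(b1), 1e-2)
        assert abs(ours.sd_u_hat - sd_u) <= 1e-4
        assert abs(ours.sd_e_hat - sd_e) <= 1e-4
    return n_instances


def dense_gls_slope(x, y, cid, var_u, var_e):
    """GLS slope at known variance components via direct dense inversion."""
    _, beta = dense_negloglik(x, y, cid, var_u, var_e)
    return beta[1]
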