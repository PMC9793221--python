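"""Independent numerical oracles used by the test suite.

Everything here deliberately avoids the code paths under test: dense
mixed-model equations instead of the spectral shortcut, explicit formula
evaluation instead of profiled likelihoods, and textbook estimators
written out term by term.
"""

import numpy as np


def solve_longdouble(A, b):
    """Gaussian elimination with partial pivoting in extended precision.

    Needed because near the ridge-parameter lower bound the dense system is
    too ill-conditioned for a double-precision solve to reach 1e-8.
    """
    A = np.asarray(A, dtype=np.longdouble).copy()
    b = np.asarray(b, dtype=np.longdouble).copy()
    n = len(b)
    for k in range(n):
        p = k + int(np.argmax(np.abs(A[k:, k])))
        if p != k:
            A[[k, p]] = A[[p, k]]
            b[[k, p]] = b[[p, k]]
        f = A[k + 1 :, k] / A[k, k]
        A[k + 1 :, k:] -= f[:, None] * A[k, k:]
        b[k + 1 :] -= f * b[k]
    x = np.empty(n, dtype=np.longdouble)
    for k in range(n - 1, -1, -1):
        x[k] = (b[k] - A[k, k + 1 :] @ x[k + 1 :]) / A[k, k]
    return x


def dense_mme(D, yv, lam):
    """Naive dense mixed-model equations for y = 1 mu + Z u + e at fixed lambda.

    Returns (mu, u) from the joint Henderson system, formed and solved in
    extended precision.
    """
    D = np.asarray(D, dtype=np.longdouble)
    yv = np.asarray(yv, dtype=np.longdouble)
    n, m = D.shape
    Z = D - D.mean(axis=0)
    A = np.zeros((m + 1, m + 1), dtype=np.longdouble)
    A[0, 0] = n
    A[0, 1:] = Z.sum(axis=0)
    A[1:, 0] = Z.sum(axis=0)
    A[1:, 1:] = Z.T @ Z + np.longdouble(lam) * np.eye(m)
    rhs = np.concatenate([[yv.sum()], Z.T @ yv])
    sol = solve_longdouble(A, rhs).astype(float)
    return float(sol[0]), sol[1:]


def direct_restricted_loglik(Z, yv, delta):
    """REML log-likelihood from its determinant/quadratic-form definition."""
    n = len(yv)
    X = np.ones((n, 1))
    V = Z @ Z.T + delta * np.eye(n)
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    beta = np.linalg.solve(XVX, X.T @ Vi @ yv)
    r = yv - (X @ beta).ravel()
    s2 = float(r @ Vi @ r) / (n - 1)
    _, ld_v = np.linalg.slogdet(V)
    _, ld_xvx = np.linalg.slogdet(XVX)
    _, ld_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - 1) * np.log(2 * np.pi * s2) + ld_v + ld_xvx - ld_xx + (n - 1))


def weir_cockerham_theta(d1, d2):
    """Per-locus two-population Weir & Cockerham Fst from diploid dosages."""
    r = 2
    n1, n2 = len(d1), len(d2)
    p1, p2 = d1.mean() / 2.0, d2.mean() / 2.0
    h1, h2 = np.mean(d1 == 1), np.mean(d2 == 1)
    nbar = (n1 + n2) / 2.0
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (
        s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    tot = a + b + c
    return a / tot if tot > 0 else np.nan


def descriptive_stats(x):
    """Hand-evaluated sample descriptive statistics (adjusted skew/kurtosis)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = x.sum() / n
    dev = x - mean
    s2 = (dev**2).sum() / (n - 1)
    s = np.sqrt(s2)
    m3 = (dev**3).sum() / n
    m2 = (dev**2).sum() / n
    g1 = m3 / m2**1.5
    skew = np.sqrt(n * (n - 1)) / (n - 2) * g1
    m4 = (dev**4).sum() / n
    g2 = m4 / m2**2 - 3.0
    kurt = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * g2 + 6.0)
    return {
        "min": x.min(),
        "max": x.max(),
        "mean": mean,
        "sd": s,
        "variance": s2,
        "skewness": skew,
        "kurtosis": kurt,
        "cv_percent": 100.0 * s / mean,
    }
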