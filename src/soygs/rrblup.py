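"""Ridge-regression BLUP genomic prediction.

Model: y = 1 mu + Z u + e, with Z the column-centered training dosages,
u ~ N(0, sigma2_u I) the marker effects and e ~ N(0, sigma2_e I).  This is
the GBLUP-equivalent mixed model with genetic covariance sigma2_u Z Z', so
the restricted likelihood is a one-dimensional function of the variance
ratio delta = sigma2_e / sigma2_u once Z Z' is eigendecomposed:

    V = sigma2_u (Z Z' + delta I) = sigma2_u U (D + delta I) U'.

REML profiling: for a candidate delta, the GLS intercept and the profiled
scale sigma2_u have closed forms in the rotated coordinates, and

    lR(delta) = -1/2 [ (n-p) log(2 pi s2) + sum_i log(d_i + delta)
                       + log|X' Vd^-1 X| - log|X' X| + (n-p) ]

with Vd = Z Z' + delta I, p = 1 fixed effect (the intercept) and
s2 = r' Vd^-1 r / (n-p) the profiled sigma2_u.  delta is maximized over
[1e-9, 1e9] by a coarse log-grid pass followed by bounded refinement
(tolerance 1e-8 on log delta); the whole fit is deterministic.

Marker effects at the optimum use the push-through identity

    u = (Z'Z + lambda I)^-1 Z' (y - mu 1) = Z' (Z Z' + lambda I)^-1 (y - mu 1),

with lambda = delta, so only the n x n decomposition is ever formed.
Because Z is column-centered, 1 is an eigenvector of Z Z' with eigenvalue 0
and the GLS intercept equals the training mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .datatypes import GenotypeMatrix, PhenotypeVector, check_aligned, index_of
from .errors import DataError, IntegrityError

logger = logging.getLogger("soygs")

DELTA_BOUNDS = (1e-9, 1e9)
_GRID_POINTS = 41


@dataclass
class RRBLUPFit:
    """Fitted RR-BLUP model.

    ``lambda_`` is the ridge parameter sigma2_e / sigma2_u (``inf`` when the
    markers carry no signal and sigma2_u -> 0).  ``centering`` stores the
    per-marker training dosage means, needed to center prediction inputs
    identically.  ``genomic_variance`` is sigma2_u * tr(ZZ')/n, the
    phenotypic-scale genetic variance implied by the fit.
    """

    mu: float
    u: np.ndarray
    sigma2_u: float
    sigma2_e: float
    lambda_: float
    reml_loglik: float
    marker_ids: np.ndarray
    centering: np.ndarray
    genomic_variance: float


def estimated_h2(fit: RRBLUPFit) -> float:
    """Genomic heritability implied by the variance components."""
    denom = fit.genomic_variance + fit.sigma2_e
    return fit.genomic_variance / denom if denom > 0 else 0.0


def _reml_profile(d: np.ndarray, yr: np.ndarray, xr: np.ndarray, delta: float):
    """(loglik, beta, sigma2) of the restricted likelihood at one delta.

    Rotated coordinates: d eigenvalues of ZZ', yr = U'y, xr = U'1.
    """
    n = len(d)
    w = 1.0 / (d + delta)
    xtvx = float(np.sum(xr * xr * w))
    beta = float(np.sum(xr * yr * w)) / xtvx
    r = yr - beta * xr
    sigma2 = float(np.sum(r * r * w)) / (n - 1)
    loglik = -0.5 * (
        (n - 1) * np.log(2.0 * np.pi * sigma2)
        + float(np.sum(np.log(d + delta)))
        + np.log(xtvx)
        - np.log(n)
        + (n - 1)
    )
    return loglik, beta, sigma2


def _optimize_delta(d, yr, xr) -> float:
    """Deterministic 1-D REML maximization over log(delta)."""
    lo, hi = np.log(DELTA_BOUNDS[0]), np.log(DELTA_BOUNDS[1])
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = [_reml_profile(d, yr, xr, float(np.exp(g)))[0] for g in grid]
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, _GRID_POINTS - 1)]
    res = minimize_scalar(
        lambda t: -_reml_profile(d, yr, xr, float(np.exp(t)))[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def reml_loglik_profile(
    G_train: GenotypeMatrix, y_train: PhenotypeVector, deltas
) -> np.ndarray:
    """Restricted log-likelihood at probe variance ratios (spectral path).

    Exposes the same internal profile that :func:`fit_rrblup` maximizes, for
    diagnostics and cross-checking against a direct dense evaluation.
    """
    check_aligned(G_train, y_train)
    Z = G_train.dosages - G_train.dosages.mean(axis=0)
    d, U = np.linalg.eigh(Z @ Z.T)
    d = np.clip(d, 0.0, None)
    yr = U.T @ y_train.values
    xr = U.T @ np.ones(len(d))
    return np.array([_reml_profile(d, yr, xr, float(dl))[0] for dl in deltas])


def fit_rrblup(
    G_train: GenotypeMatrix,
    y_train: PhenotypeVector,
    gram: np.ndarray | None = None,
) -> RRBLUPFit:
    """Fit the RR-BLUP model by spectral REML.

    ``gram``, if given, must be the uncentered dosage cross-product
    ``D D'`` of the training rows; it is double-centered internally into
    Z Z'.  This is purely a performance cache for evaluation designs that
    refit on many subsets of one panel -- results are identical to passing
    nothing.
    """
    check_aligned(G_train, y_train)
    if G_train.has_missing():
        raise DataError("fit_rrblup requires an imputed genotype matrix")
    n, m = G_train.dosages.shape
    if n < 10:
        raise DataError("fit_rrblup requires at least 10 training samples")
    y = y_train.values
    if np.std(y) == 0:
        raise DataError("constant phenotype; variance components unidentifiable")

    D = G_train.dosages
    centering = D.mean(axis=0)
    Z = D - centering
    if gram is None:
        K = Z @ Z.T
    else:
        if gram.shape != (n, n):
            raise IntegrityError("gram cache shape does not match training samples")
        # ZZ' = H (DD') H with H the row-centering projector
        K = gram - gram.mean(axis=0, keepdims=True)
        K = K - K.mean(axis=1, keepdims=True)
    trace_over_n = float(np.trace(K)) / n

    if trace_over_n <= 1e-12:
        # no polymorphic marker: model collapses to y = mu + e
        sigma2_e = float(np.var(y, ddof=1))
        loglik = -0.5 * (
            (n - 1) * (np.log(2.0 * np.pi * sigma2_e) + 1.0) + np.log(n)
        )
        return RRBLUPFit(
            mu=float(np.mean(y)),
            u=np.zeros(m),
            sigma2_u=0.0,
            sigma2_e=sigma2_e,
            lambda_=np.inf,
            reml_loglik=loglik,
            marker_ids=G_train.marker_ids,
            centering=centering,
            genomic_variance=0.0,
        )

    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yr = U.T @ y
    xr = U.T @ np.ones(n)
    delta = _optimize_delta(d, yr, xr)
    loglik, mu, sigma2_u = _reml_profile(d, yr, xr, delta)
    sigma2_e = delta * sigma2_u

    resid_rot = (yr - mu * xr) / (d + delta)
    u = Z.T @ (U @ resid_rot)

    return RRBLUPFit(
        mu=float(mu),
        u=u,
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        lambda_=float(delta),
        reml_loglik=float(loglik),
        marker_ids=G_train.marker_ids,
        centering=centering,
        genomic_variance=float(sigma2_u * trace_over_n),
    )


def predict_gebv(fit: RRBLUPFit, G_new: GenotypeMatrix) -> np.ndarray:
    """Genomic estimated breeding values: mu + (dosage - training mean) . u.

    Markers are matched by ID (order corrected); any marker of the fit
    missing from ``G_new`` is an error listing the missing IDs.
    """
    if G_new.has_missing():
        raise DataError("predict_gebv requires an imputed genotype matrix")
    missing = set(fit.marker_ids) - set(G_new.marker_ids)
    if missing:
        raise IntegrityError(
            f"genotypes lack {len(missing)} fitted markers, e.g. {sorted(missing)[:5]}"
        )
    cols = index_of(G_new.marker_ids, fit.marker_ids)
    D = G_new.dosages[:, cols]
    return fit.mu + (D - fit.centering) @ fit.u


def prediction_accuracy(predicted, observed) -> float:
    """Pearson correlation of predicted vs observed values.

    Returns NaN (flagged missing) when either vector is constant; negative
    correlations are reported as-is, never truncated.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise IntegrityError("predicted and observed lengths differ")
    if len(predicted) < 3:
        raise DataError("prediction_accuracy requires at least 3 pairs")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        logger.warning("prediction_accuracy: constant input, accuracy undefined")
        return float("nan")
    return float(np.corrcoef(predicted, observed)[0, 1])


def save_model(fit: RRBLUPFit, path) -> None:
    """TSV serialization: '#key value' scalar header + per-marker table."""
    with open(path, "w") as fh:
        fh.write(f"#mu\t{float(fit.mu)!r}\n#sigma2_u\t{float(fit.sigma2_u)!r}\n")
        fh.write(f"#sigma2_e\t{float(fit.sigma2_e)!r}\n#lambda\t{float(fit.lambda_)!r}\n")
        fh.write(f"#reml_loglik\t{float(fit.reml_loglik)!r}\n")
        fh.write(f"#genomic_variance\t{float(fit.genomic_variance)!r}\n")
        fh.write("marker_id\teffect\tcentering\n")
        for mid, eff, cen in zip(fit.marker_ids, fit.u, fit.centering):
            fh.write(f"{mid}\t{float(eff)!r}\t{float(cen)!r}\n")


def load_model(path) -> RRBLUPFit:
    scalars = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, val = line[1:].split("\t")
                scalars[key] = float(val)
            elif line and not line.startswith("marker_id"):
                rows.append(line.split("\t"))
    ids = np.array([r[0] for r in rows])
    return RRBLUPFit(
        mu=scalars["mu"],
        u=np.array([float(r[1]) for r in rows]),
        sigma2_u=scalars["sigma2_u"],
        sigma2_e=scalars["sigma2_e"],
        lambda_=scalars["lambda"],
        reml_loglik=scalars["reml_loglik"],
        marker_ids=ids,
        centering=np.array([float(r[2]) for r in rows]),
        genomic_variance=scalars["genomic_variance"],
    )


__all__ = [
    "DELTA_BOUNDS",
    "RRBLUPFit",
    "estimated_h2",
    "fit_rrblup",
    "load_model",
    "predict_gebv",
    "prediction_accuracy",
    "reml_loglik_profile",
    "save_model",
]
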