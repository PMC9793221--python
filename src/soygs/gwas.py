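"""Mixed-linear-model single-marker association scan.

Per-marker model: y = mu + x alpha + P beta + g + e, with P the principal
component covariates for population structure, g ~ N(0, K sigma2_g) the
polygenic background and e ~ N(0, I sigma2_e).  Variance components are
estimated once by REML on the null model (no marker) and then held fixed
for every marker test -- the P3D/EMMAX approximation that standard MLM
GWAS software uses by default.  With the kinship eigendecomposition
K = U D U' and delta = sigma2_e / sigma2_g, every marker test is an
ordinary F-test in the whitened regression

    diag(1/sqrt(d_i + delta)) U' [y | X | x],

with residual degrees of freedom n - p - 1.  Scores are -log10(P),
computed through the log survival function so extreme hits stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import GenotypeMatrix, PhenotypeVector, check_aligned
from .errors import ConfigurationError, DataError, IntegrityError
from .relatedness import KinshipMatrix, PCAResult

logger = logging.getLogger("soygs")

LOG10 = np.log(10.0)


@dataclass
class NullMLMFit:
    """Null-model REML fit plus the spectral cache for per-marker tests."""

    sample_ids: np.ndarray
    X: np.ndarray  # n x p covariates (intercept + PCs)
    U: np.ndarray  # kinship eigenvectors
    eigvals: np.ndarray
    delta: float
    sigma2_g: float
    sigma2_e: float
    reml_loglik: float
    n_pcs_used: int


@dataclass
class GWASResult:
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect: np.ndarray
    score: np.ndarray  # -log10(P); NaN = untestable marker
    n_pcs_used: int
    variance_components: tuple[float, float]

    @property
    def n_testable(self) -> int:
        return int(np.sum(~np.isnan(self.score)))


def _covariates(n: int, pcs) -> tuple[np.ndarray, int]:
    if pcs is None:
        return np.ones((n, 1)), 0
    scores = pcs.scores if isinstance(pcs, PCAResult) else np.asarray(pcs, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] != n:
        raise IntegrityError("covariate rows do not match samples")
    return np.column_stack([np.ones(n), scores]), scores.shape[1]


def _reml_profile_multi(d, yr, Xr, delta):
    """Restricted log-likelihood with a general fixed-effect design."""
    n, p = Xr.shape
    w = 1.0 / (d + delta)
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWy = (Xr * w[:, None]).T @ yr
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    sigma2 = float(np.sum(r * r * w)) / (n - p)
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    _, logdet_xx = np.linalg.slogdet(Xr.T @ Xr)
    loglik = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma2)
        + float(np.sum(np.log(d + delta)))
        + logdet_xwx
        - logdet_xx
        + (n - p)
    )
    return loglik, beta, sigma2


def fit_null_mlm(
    y: PhenotypeVector,
    pcs: PCAResult | np.ndarray | None,
    K: KinshipMatrix,
) -> NullMLMFit:
    """REML fit of y = X beta + g + e with cov(g) = K sigma2_g."""
    if not np.array_equal(y.sample_ids, K.sample_ids):
        raise IntegrityError("phenotype and kinship samples are not aligned")
    n = len(y)
    X, n_pcs = _covariates(n, pcs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [f"pc{j}" for j in range(1, X.shape[1])]
        raise DataError(f"singular covariate matrix; check columns {bad}")

    d, U = np.linalg.eigh(K.values)
    d = np.clip(d, 0.0, None)
    yr = U.T @ y.values
    Xr = U.T @ X

    # 1-D REML over delta: coarse grid then bounded refinement
    from .rrblup import DELTA_BOUNDS, _GRID_POINTS
    from scipy.optimize import minimize_scalar

    lo, hi = np.log(DELTA_BOUNDS[0]), np.log(DELTA_BOUNDS[1])
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = [_reml_profile_multi(d, yr, Xr, float(np.exp(g)))[0] for g in grid]
    i = int(np.argmax(vals))
    res = minimize_scalar(
        lambda t: -_reml_profile_multi(d, yr, Xr, float(np.exp(t)))[0],
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    loglik, _, sigma2_g = _reml_profile_multi(d, yr, Xr, delta)

    return NullMLMFit(
        sample_ids=y.sample_ids,
        X=X,
        U=U,
        eigvals=d,
        delta=delta,
        sigma2_g=float(sigma2_g),
        sigma2_e=float(delta * sigma2_g),
        reml_loglik=float(loglik),
        n_pcs_used=n_pcs,
    )


def scan_markers(
    G: GenotypeMatrix,
    null_fit: NullMLMFit,
    y: PhenotypeVector,
    pcs: PCAResult | np.ndarray | None = None,
) -> GWASResult:
    """P3D association scan with variance components fixed at the null fit.

    Markers whose dosage is constant after projecting out the covariates
    are untestable and flagged with a NaN score.
    """
    check_aligned(G, y)
    if not np.array_equal(G.sample_ids, null_fit.sample_ids):
        raise IntegrityError("genotypes and null fit samples are not aligned")
    if G.has_missing():
        raise DataError("scan_markers requires an imputed genotype matrix")
    n, m = G.dosages.shape
    p = null_fit.X.shape[1]
    if n <= p + 2:
        raise DataError("too few samples for the covariate model")

    w = 1.0 / np.sqrt(null_fit.eigvals + null_fit.delta)
    Ut = null_fit.U.T
    y_t = w * (Ut @ y.values)
    X_t = w[:, None] * (Ut @ null_fit.X)
    G_t = w[:, None] * (Ut @ G.dosages)

    Q, _ = np.linalg.qr(X_t)
    y_res = y_t - Q @ (Q.T @ y_t)
    G_res = G_t - Q @ (Q.T @ G_t)

    sxx = np.einsum("ij,ij->j", G_res, G_res)
    sxy = G_res.T @ y_res
    syy = float(y_res @ y_res)
    df = n - p - 1

    testable = sxx > max(1e-12, 1e-10 * float(sxx.max(initial=0.0)))
    effect = np.full(m, np.nan)
    score = np.full(m, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(testable, sxy / sxx, np.nan)
        ss_marker = np.where(testable, sxy**2 / sxx, np.nan)
        rss = np.maximum(syy - ss_marker, 0.0)
        F = np.where(rss > 0, ss_marker / (rss / df), np.inf)
    logp = stats.f.logsf(F[testable], 1, df)
    effect[testable] = beta[testable]
    score[testable] = -logp / LOG10
    n_untestable = int((~testable).sum())
    if n_untestable:
        logger.info("scan_markers: %d markers untestable after projection",
                    n_untestable)

    return GWASResult(
        marker_ids=G.marker_ids,
        chrom=G.chrom,
        pos=G.pos,
        effect=effect,
        score=score,
        n_pcs_used=null_fit.n_pcs_used,
        variance_components=(null_fit.sigma2_g, null_fit.sigma2_e),
    )


def select_markers_by_threshold(result: GWASResult, threshold: float) -> np.ndarray:
    """Marker IDs with score strictly above ``threshold``.

    A threshold of 0 returns every testable marker (the "all SNPs" set).
    """
    if len(result.marker_ids) == 0:
        raise DataError("empty GWAS result")
    testable = ~np.isnan(result.score)
    if threshold <= 0:
        mask = testable
    else:
        mask = testable & (result.score > threshold)
    if not mask.any():
        logger.warning("select_markers_by_threshold: empty selection at %.3g",
                       threshold)
    return result.marker_ids[mask]


def sample_random_markers(all_ids, count: int, seed: int) -> np.ndarray:
    """Uniform sample of marker IDs without replacement; seeded."""
    all_ids = np.asarray(all_ids)
    if count > len(all_ids):
        raise ConfigurationError(
            f"cannot sample {count} markers from {len(all_ids)} available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(all_ids), size=count, replace=False)
    return all_ids[idx]


def genomic_inflation(result_or_pvalues) -> float:
    """Genomic-control inflation factor lambda_GC.

    Median of the marker chi-square statistics (from p-values) divided by
    the null median of a 1-df chi-square (~0.4549).
    """
    if isinstance(result_or_pvalues, GWASResult):
        score = result_or_pvalues.score
        pvals = np.power(10.0, -score[~np.isnan(score)])
    else:
        pvals = np.asarray(result_or_pvalues, dtype=float)
        pvals = pvals[~np.isnan(pvals)]
    if pvals.size == 0:
        raise DataError("no testable p-values for inflation estimate")
    chi = stats.chi2.isf(np.clip(pvals, 1e-300, 1.0), df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


__all__ = [
    "GWASResult",
    "NullMLMFit",
    "fit_null_mlm",
    "genomic_inflation",
    "sample_random_markers",
    "scan_markers",
    "select_markers_by_threshold",
]
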