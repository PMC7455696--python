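"""Mixed-linear-model association scan and segment variance-explained.

The scan follows the single-null-fit strategy of standard MLM-GWAS tools:
variance components (Vg, Ve) are estimated once by REML under the null
model y = covariates + polygenic + residual with cov(polygenic) = Vg * K
for an additive genomic relationship matrix K, and every SNP is then
tested by a generalized-least-squares Wald test with the variance
structure held fixed.  REML uses the eigendecomposition of K, so each
likelihood evaluation is O(n) after an O(n^3) setup.

``variance_explained`` quantifies how much of the additive genetic
variance a genotyped segment accounts for, by fitting segment-class
effects (e.g. founder-origin diplotype classes) jointly with covariates
and taking the frequency-weighted variance of the fitted class effects as
a fraction of Vg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)


def grm(dosages: np.ndarray) -> np.ndarray:
    """Additive genomic relationship matrix from a dosage matrix (n x m).

    Dosages are centered at 2p and standardized by sqrt(2p(1-p)) per site,
    then K = W W' / m over polymorphic sites.  Missing dosages are mean-
    imputed (centered to zero).  Symmetric and PSD up to rounding.
    """
    g = np.asarray(dosages, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with >= 2 samples")
    p = np.nanmean(g, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("all sites are monomorphic")
    g = g[:, poly]
    p = p[poly]
    w = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    w = np.where(np.isnan(w), 0.0, w)
    return w @ w.T / w.shape[1]


@dataclass
class VarianceComponents:
    """REML variance components of the null polygenic model."""

    Vg: float
    Ve: float
    loglik: float
    converged: bool

    @property
    def heritability(self) -> float:
        tot = self.Vg + self.Ve
        return self.Vg / tot if tot > 0 else 0.0


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([X, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient (constant or collinear column)")
    return X


def fit_null(
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> VarianceComponents:
    """REML estimation of (Vg, Ve) via eigendecomposition of the GRM.

    The profile REML log-likelihood is maximized over the heritability
    ratio h = Vg/(Vg+Ve) on (0, 1) by bounded scalar optimization; the
    total variance has a closed form given h.  Raises if the optimizer
    fails to converge; boundary solutions (h ~ 0 or ~ 1) are legitimate
    fits, not failures.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X = _design(covariates, n)
    p = X.shape[1]
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)

    def neg_restricted_ll(h: float) -> float:
        w = h * d + (1.0 - h)
        wi = 1.0 / w
        XtWX = (Xt * wi[:, None]).T @ Xt
        XtWy = (Xt * wi[:, None]).T @ yt
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        rss = float(r @ (wi * r))
        sigma2 = rss / (n - p)
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * np.log(2.0 * np.pi * sigma2) + (n - p)
                     + np.sum(np.log(w)) + logdet_xwx - logdet_xx)
        return -ll

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(1e-9, 1 - 1e-9),
                                   method="bounded",
                                   options={"xatol": tol, "maxiter": max_iter})
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res.message}")
    h = float(res.x)
    w = h * d + (1.0 - h)
    wi = 1.0 / w
    XtWX = (Xt * wi[:, None]).T @ Xt
    beta = np.linalg.solve(XtWX, (Xt * wi[:, None]).T @ yt)
    r = yt - Xt @ beta
    sigma2 = float(r @ (wi * r)) / (n - p)
    if sigma2 <= 1e-12 * max(float(np.var(y)), 1e-300):
        raise RuntimeError(
            "degenerate null model: residual variance is zero "
            "(phenotype is an exact function of the covariates)")
    # snap numerical-boundary solutions to the boundary
    if h < 1e-6 and neg_restricted_ll(1e-9) <= res.fun + 1e-9:
        h = 0.0
    return VarianceComponents(Vg=h * sigma2, Ve=(1.0 - h) * sigma2,
                              loglik=-float(res.fun), converged=True)


def assoc_scan(
    gm,
    y: np.ndarray,
    covariates: np.ndarray | None,
    vc: VarianceComponents,
    K: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP Wald tests with the variance structure fixed at the null fit.

    Each SNP is tested by GLS of y on [covariates | SNP dosage] under
    V = Vg K + Ve I with (Vg, Ve) from :func:`fit_null` (single-fit
    approximation).  With K = I this reduces exactly to ordinary
    covariate-adjusted least squares.  Monomorphic SNPs are retained as
    undefined rows.  Returns a table sorted by position with columns
    chrom, pos, id, beta, se, t, p.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X = _design(covariates, n)
    if K is None:
        K = np.eye(n)
    V = vc.Vg * K + vc.Ve * np.eye(n)
    d, U = np.linalg.eigh((V + V.T) / 2.0)
    d = np.clip(d, 1e-12, None)
    T = (U / np.sqrt(d)).T          # whitening transform: T V T' = I
    yt = T @ y
    Xt = T @ X
    dos = gm.dosages()
    dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
    Gt = T @ dos
    dof = n - X.shape[1] - 1
    rows = []
    for j in range(gm.n_sites):
        gcol = dos[:, j]
        if np.ptp(gcol) == 0:
            rows.append((gm.chrom, int(gm.positions[j]) + 1, str(gm.ids[j]),
                         np.nan, np.nan, np.nan, np.nan))
            continue
        D = np.column_stack([Xt, Gt[:, j]])
        DtD = D.T @ D
        coef = np.linalg.solve(DtD, D.T @ yt)
        resid = yt - D @ coef
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(DtD)
        beta = float(coef[-1])
        se = float(np.sqrt(cov[-1, -1]))
        t = beta / se
        pval = 2.0 * stats.t.sf(abs(t), dof)
        rows.append((gm.chrom, int(gm.positions[j]) + 1, str(gm.ids[j]),
                     beta, se, t, pval))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "beta", "se", "t", "p"])


def qq_table(pvalues: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 p quantiles plus the genomic inflation
    factor lambda (median chi-square ratio), for Q-Q diagnostics."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[np.isfinite(p)]
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    chi_obs = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi_obs) / stats.chi2.isf(0.5, df=1))
    return pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(p),
        "lambda_gc": lam,
    })


def variance_explained(
    segment_classes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    vc: VarianceComponents,
    min_class_n: int = 3,
) -> float:
    """Fraction of the additive genetic variance explained by a segment.

    ``segment_classes`` labels each sample with its segment genotype class
    (e.g. founder-origin diplotype AA/AB/BB).  Class effects are fitted
    jointly with covariates by least squares; the segment variance is the
    frequency-weighted variance of the fitted class effects, and the
    returned value is segment variance / Vg.  Classes with fewer than
    ``min_class_n`` members are merged into the class with the nearest
    mean phenotype (logged).  Values above 1 are reported clipped with a
    warning.  Invariant to affine rescaling of y.
    """
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(segment_classes)
    classes, counts = np.unique(labels, return_counts=True)
    # merge sparse classes into the class with the nearest phenotype mean
    while classes.size > 1 and counts.min() < min_class_n:
        small = classes[np.argmin(counts)]
        means = {c: y[labels == c].mean() for c in classes}
        others = [c for c in classes if c != small]
        target = min(others, key=lambda c: abs(means[c] - means[small]))
        log.info("variance_explained: merging class %r (n=%d) into %r",
                 small, counts.min(), target)
        labels = np.where(labels == small, target, labels)
        classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        return 0.0
    n = y.size
    X = _design(covariates, n)
    Z = (labels[:, None] == classes[None, :]).astype(float)
    D = np.column_stack([X, Z[:, 1:]])        # first class absorbed in intercept
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    effects = np.concatenate([[0.0], coef[X.shape[1]:]])
    freqs = Z.mean(axis=0)
    mean_eff = float(freqs @ effects)
    seg_var = float(freqs @ (effects - mean_eff) ** 2)
    if vc.Vg <= 0:
        return np.nan
    frac = seg_var / vc.Vg
    if frac > 1.0:
        warnings.warn(f"segment variance exceeds Vg (fraction {frac:.2f}); reporting clipped 1.0")
        return 1.0
    return frac
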