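"""Single-marker mixed-linear-model association.

The model is y = mu + beta * dosage + g + e with a polygenic random effect
g ~ N(0, sigma_g^2 K) over a Centered-IBS kinship matrix K and residual
e ~ N(0, sigma_e^2 I).  Variance components are estimated once by REML under
the null model (P3D, "population parameters previously determined") via a
one-dimensional EMMA-style optimization over the variance ratio on the
eigendecomposition of K, then held fixed for every marker's generalized
least-squares F test (1, n-2 degrees of freedom).  With n in the hundreds the
uncompressed mixed model is tractable, so no compression clustering is
applied.  Raw p values are reported without multiplicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .genotyping import GenotypeMatrix

__all__ = [
    "VarianceComponents",
    "AssociationResult",
    "ScanResult",
    "centered_ibs_kinship",
    "fit_null_p3d",
    "marker_test",
    "association_scan",
]


def centered_ibs_kinship(matrix: GenotypeMatrix | pd.DataFrame) -> pd.DataFrame:
    """Centered-IBS genomic relationship matrix.

    Missing dosages are imputed to the site mean, each site is centered by
    its sample mean, and K = Z Z' / c with c the mean diagonal of the
    un-normalized product, so that mean(diag(K)) = 1.
    """
    dosage = matrix.dosage if isinstance(matrix, GenotypeMatrix) else matrix
    Z = dosage.to_numpy(dtype=float)
    if Z.shape[0] < 2 or Z.shape[1] < 1:
        raise ValueError("kinship needs >= 2 individuals and >= 1 site")
    col_mean = np.nanmean(Z, axis=0)
    dead = ~np.isfinite(col_mean)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} all-missing sites ignored in kinship")
        Z = Z[:, ~dead]
        col_mean = col_mean[~dead]
    inds = np.where(np.isnan(Z))
    Z[inds] = col_mean[inds[1]]
    Z = Z - Z.mean(axis=0)
    G = Z @ Z.T
    c = float(np.mean(np.diag(G)))
    if c <= 0:
        raise ValueError("all sites monomorphic: kinship undefined")
    K = G / c
    K = 0.5 * (K + K.T)
    assert abs(np.mean(np.diag(K)) - 1.0) < 1e-8
    return pd.DataFrame(K, index=dosage.index, columns=dosage.index)


@dataclass(frozen=True)
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    converged: bool = True

    @property
    def heritability(self) -> float:
        total = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / total if total > 0 else float("nan")


def _reml_neg_loglik(log_lam: float, s: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    lam = 10.0 ** log_lam
    w = lam * s + 1.0
    xtwx = np.sum(xt * xt / w)
    beta = np.sum(xt * yt / w) / xtwx
    resid = yt - xt * beta
    rss = np.sum(resid * resid / w)
    n_p = len(yt) - 1
    se2 = rss / n_p
    ll = -0.5 * (n_p * np.log(se2) + np.sum(np.log(w)) + np.log(xtwx))
    return -ll


def fit_null_p3d(
    phenotype: np.ndarray | pd.Series,
    K: pd.DataFrame | np.ndarray,
) -> VarianceComponents:
    """REML variance components of the null model y = mu + g + e.

    Uses the spectral decomposition of K and a bounded scalar search over
    log10 of the variance ratio sigma_g^2 / sigma_e^2 (exact for this
    two-component model).  Estimates are non-negative by construction.
    """
    y = np.asarray(phenotype, dtype=float)
    Km = K.to_numpy() if isinstance(K, pd.DataFrame) else np.asarray(K, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if Km.shape != (len(y), len(y)):
        raise ValueError("kinship dimension does not match phenotype length")
    if np.allclose(Km, 0.0):
        var = float(np.var(y, ddof=1))
        return VarianceComponents(0.0, var, float("nan"))
    s, U = np.linalg.eigh(Km)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones_like(y)
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(-8.0, 8.0),
        args=(s, yt, xt),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"REML optimization failed: {res.message}")
    lam = 10.0 ** res.x
    w = lam * s + 1.0
    xtwx = np.sum(xt * xt / w)
    beta = np.sum(xt * yt / w) / xtwx
    rss = np.sum((yt - xt * beta) ** 2 / w)
    se2 = float(rss / (len(y) - 1))
    sg2 = float(lam * se2)
    if lam <= 10.0 ** -7.5:  # boundary: effectively no genetic variance
        sg2 = 0.0
    return VarianceComponents(sg2, se2, float(-res.fun))


@dataclass(frozen=True)
class AssociationResult:
    site_id: str
    beta: float
    F: float
    p: float
    neg_log10_p: float
    n_used: int
    sigma_g2: float
    sigma_e2: float
    testable: bool = True


def _gls_f_test(X: np.ndarray, y: np.ndarray, L: np.ndarray) -> tuple[float, float, float]:
    """F test of the last column's coefficient after whitening by the lower
    Cholesky factor L of the (fixed) covariance structure; the overall scale
    is re-estimated from the marker-model residuals, so the test reduces to
    the ordinary regression F test when the structure is proportional to I."""
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    n, p = Xw.shape
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    s2 = float(resid @ resid) / (n - p)
    var_b = s2 * XtX_inv[-1, -1]
    F = float(beta[-1] ** 2 / var_b) if var_b > 0 else 0.0
    p_val = float(stats.f.sf(F, 1, n - p))
    return float(beta[-1]), F, p_val


def marker_test(
    dosage: np.ndarray | pd.Series,
    phenotype: np.ndarray | pd.Series,
    K: pd.DataFrame | np.ndarray,
    vc: VarianceComponents,
    site_id: str = "",
    chol: np.ndarray | None = None,
) -> AssociationResult:
    """GLS F test of one marker with V = sigma_g^2 K + sigma_e^2 I fixed.

    Individuals with missing dosage are dropped pairwise (K stays fixed for
    the remaining set).  Constant dosage gives an untestable flagged result.
    ``chol`` may carry a precomputed Cholesky factor of V for the complete
    case.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    Km = K.to_numpy() if isinstance(K, pd.DataFrame) else np.asarray(K, dtype=float)
    keep = np.isfinite(d)
    if not keep.all():
        d, y, Km = d[keep], y[keep], Km[np.ix_(keep, keep)]
        chol = None
    n = len(y)
    if n < 3 or np.ptp(d) == 0:
        return AssociationResult(
            site_id, float("nan"), float("nan"), float("nan"), float("nan"),
            n, vc.sigma_g2, vc.sigma_e2, testable=False,
        )
    if chol is None:
        V = vc.sigma_g2 * Km + vc.sigma_e2 * np.eye(n)
        chol = np.linalg.cholesky(V)
    X = np.column_stack([np.ones(n), d])
    beta, F, p = _gls_f_test(X, y, chol)
    return AssociationResult(
        site_id, beta, F, p, float(-np.log10(p)) if p > 0 else np.inf,
        n, vc.sigma_g2, vc.sigma_e2,
    )


@dataclass
class ScanResult:
    table: pd.DataFrame
    vc: VarianceComponents
    significant_05: list[str] = field(default_factory=list)
    significant_10: list[str] = field(default_factory=list)


def association_scan(
    matrix: GenotypeMatrix,
    phen: pd.DataFrame,
    trait: str = "weight_g",
    K: pd.DataFrame | None = None,
    vc: VarianceComponents | None = None,
    exact_reml_per_marker: bool = False,
) -> ScanResult:
    """Scan every site of a (filtered) genotype matrix against one trait.

    Results are returned in input site order (Manhattan plots use uniform
    spacing in that order), with the significant site sets at p < 0.05 and
    p < 0.1.  K defaults to the Centered-IBS kinship of the matrix itself and
    the variance components to a single null-model REML fit (P3D); with
    ``exact_reml_per_marker`` the null components are re-estimated on each
    marker's complete cases.
    """
    ids = [i for i in matrix.individuals if i in set(phen.individual_id)]
    phen_idx = phen.set_index("individual_id").loc[ids]
    y = phen_idx[trait].to_numpy(dtype=float)
    dosage = matrix.dosage.loc[ids]
    if K is None:
        K = centered_ibs_kinship(dosage)
    Km = K.loc[ids, ids].to_numpy()
    if vc is None:
        vc = fit_null_p3d(y, Km)
    V = vc.sigma_g2 * Km + vc.sigma_e2 * np.eye(len(ids))
    chol = np.linalg.cholesky(V)
    rows = []
    for site in matrix.site_ids:
        d = dosage[site].to_numpy(dtype=float)
        if exact_reml_per_marker:
            keep = np.isfinite(d)
            vc_site = fit_null_p3d(y[keep], Km[np.ix_(keep, keep)])
            res = marker_test(d, y, Km, vc_site, site_id=site)
        else:
            res = marker_test(d, y, Km, vc, site_id=site, chol=chol)
        rows.append(res.__dict__)
    table = pd.DataFrame(rows)
    sig05 = table.loc[table.p < 0.05, "site_id"].tolist()
    sig10 = table.loc[table.p < 0.10, "site_id"].tolist()
    return ScanResult(table=table, vc=vc, significant_05=sig05, significant_10=sig10)
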