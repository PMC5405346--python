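"""Mixed-linear-model association scan with kinship and PC covariates.

The model for a (0/1-coded) trait y is

    y = mu + PCs * beta_c + x_snp * beta + u + e,
    u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I),

with K a VanRaden genomic relationship matrix.  Variance components are
estimated once on the null (no-SNP) model by REML over the ratio
sigma_g^2 / sigma_e^2 — the P3D/EMMAX approximation — via an
eigendecomposition of K and bounded scalar optimization; every SNP is then
tested by generalized least squares at that fixed ratio with a Wald t-test.
Exact per-marker REML is available behind a flag.  Family-wise error is
controlled by Bonferroni: a SNP is significant when p < alpha / m over the
m SNPs actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_LOG_RATIO_BOUNDS = (-10.0, 10.0)


@dataclass
class KinshipMatrix:
    """Pairwise genomic relationship estimates between accessions."""

    values: np.ndarray
    accessions: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accessions)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match accessions")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def subset(self, accessions: list[str]) -> "KinshipMatrix":
        pos = {a: i for i, a in enumerate(self.accessions)}
        idx = np.array([pos[a] for a in accessions], dtype=int)
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(accessions))


def vanraden_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from allele-B dosage.

    K = Z'Z / (2 sum p_i (1 - p_i)) with Z the dosage matrix centered at
    2 p_i per locus; missing dosages are mean-imputed (zero after centering).
    Monomorphic loci carry no information and are dropped; at least two
    polymorphic loci are required.
    """
    dose = gm.calls.astype(float)
    dose[dose < 0] = np.nan
    p = np.nanmean(dose, axis=1) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic loci for kinship")
    Z = dose[poly] - 2 * p[poly, None]
    Z = np.where(np.isnan(Z), 0.0, Z)
    denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
    K = (Z.T @ Z) / denom
    return KinshipMatrix(K, list(gm.accessions))


@dataclass
class NullModelFit:
    """Variance components of the null mixed model."""

    ratio: float  # sigma_g^2 / sigma_e^2
    sigma_g2: float
    sigma_e2: float
    loglik: float
    method: str  # "reml" or "ml"
    eigenvalues: np.ndarray
    rotation: np.ndarray  # eigenvectors of K (columns)


def _gls(yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Weighted least squares in the eigenbasis; returns beta, RSS, XtWX."""
    w = 1.0 / d
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yt - Xt @ beta
    rss = float(np.sum(resid * resid * w))
    return beta, rss, XtWX


def _neg_loglik(log_ratio, yt, Xt, s, method):
    lam = np.exp(log_ratio)
    d = lam * s + 1.0
    n, p = Xt.shape
    _, rss, XtWX = _gls(yt, Xt, d)
    logdet_d = float(np.sum(np.log(d)))
    if method == "ml":
        ll = -0.5 * (n * np.log(2 * np.pi * rss / n) + n + logdet_d)
    else:  # REML
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * rss / (n - p))
            + (n - p)
            + logdet_d
            + logdet_x
        )
    return -ll


def fit_null_mlm(
    y: np.ndarray,
    X: np.ndarray,
    K: KinshipMatrix,
    method: str = "reml",
) -> NullModelFit:
    """Estimate the variance-component ratio of the null model.

    Eigendecomposes K once and optimizes the profiled (RE)ML log-likelihood
    over log(sigma_g^2 / sigma_e^2) on a bounded interval.
    """
    if method not in ("reml", "ml"):
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few observations (n={n}) for {p} fixed effects")
    s, U = np.linalg.eigh(K.values)
    s = np.clip(s, 0.0, None)
    yt, Xt = U.T @ y, U.T @ X
    res = optimize.minimize_scalar(
        _neg_loglik,
        bounds=_LOG_RATIO_BOUNDS,
        args=(yt, Xt, s, method),
        method="bounded",
        options={"xatol": 1e-8},
    )
    # compare against the no-genetic-variance boundary
    boundary_nll = _neg_loglik(-np.inf, yt, Xt, s, method)
    if boundary_nll <= res.fun:
        lam, loglik = 0.0, -boundary_nll
    else:
        lam, loglik = float(np.exp(res.x)), -float(res.fun)
    d = lam * s + 1.0
    _, rss, _ = _gls(yt, Xt, d)
    dof = n if method == "ml" else n - p
    sigma_e2 = rss / dof
    return NullModelFit(
        ratio=lam,
        sigma_g2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        loglik=loglik,
        method=method,
        eigenvalues=s,
        rotation=U,
    )


def select_pcs_bic(
    y: pd.Series,
    pcs: np.ndarray,
    K: KinshipMatrix,
    max_pcs: int | None = None,
) -> int:
    """Choose how many leading PCs the null model needs, by BIC.

    Fits the null mixed model with the first j PCs for j = 0..max_pcs and
    returns the j minimizing BIC = -2 max log L + n_params ln(n), with the
    ML likelihood (REML values are not comparable across fixed-effect sets)
    and n_params counting the fixed effects plus both variance components.
    NA phenotypes are dropped pairwise.
    """
    pcs = np.asarray(pcs, dtype=float)
    if max_pcs is None:
        max_pcs = pcs.shape[1]
    keep = y.notna().to_numpy()
    yv = y.to_numpy(dtype=float)[keep]
    acc = [a for a, k in zip(y.index, keep) if k]
    Ksub = K.subset(acc)
    pcs_sub = pcs[keep]
    n = len(yv)
    best_j, best_bic = 0, np.inf
    for j in range(max_pcs + 1):
        X = np.column_stack([np.ones(n), pcs_sub[:, :j]])
        n_params = X.shape[1] + 2
        if n <= n_params:
            raise ValueError(
                f"too few phenotyped accessions (n={n}) to fit {j} PCs"
            )
        fit = fit_null_mlm(yv, X, Ksub, method="ml")
        bic = -2.0 * fit.loglik + n_params * np.log(n)
        if bic < best_bic - 1e-12:
            best_j, best_bic = j, bic
    return best_j


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise error threshold alpha / m for m tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def mlm_scan(
    y: pd.Series,
    gm: GenotypeMatrix,
    K: KinshipMatrix | None = None,
    pcs: np.ndarray | None = None,
    alpha: float = 0.05,
    variance_ratio: float | None = None,
    per_marker_reml: bool = False,
) -> pd.DataFrame:
    """Single-marker mixed-model association scan.

    Each SNP enters as minor-allele dosage (missing calls mean-imputed) in a
    GLS test at the null model's variance ratio.  ``variance_ratio`` pins
    sigma_g^2 / sigma_e^2 (0 reduces every test to ordinary least squares);
    ``per_marker_reml`` re-estimates it per marker instead of reusing the
    null fit.  SNPs monomorphic after the NA drop are reported as NaN rows.

    Returns one row per locus: ``effect``, ``se``, ``stat``, ``p_value``,
    ``significant`` (Bonferroni at ``alpha`` over the SNPs actually tested).
    The attrs carry ``n``, ``m_tested``, ``variance_ratio`` and
    ``bonferroni`` for reporting.
    """
    keep_acc = [a for a in gm.accessions if a in y.index and pd.notna(y.loc[a])]
    if len(keep_acc) < 3:
        raise ValueError("too few phenotyped accessions")
    acc_idx = gm.accession_indices(keep_acc)
    yv = y.loc[keep_acc].to_numpy(dtype=float)
    n = len(yv)

    X0 = [np.ones(n)]
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        full_idx = {a: i for i, a in enumerate(gm.accessions)}
        X0.append(pcs[[full_idx[a] for a in keep_acc]])
    X0 = np.column_stack(X0)

    if K is not None:
        Ksub = K.subset(keep_acc)
    else:
        Ksub = KinshipMatrix(np.eye(n), keep_acc)

    if variance_ratio is not None:
        lam = float(variance_ratio)
        s, U = np.linalg.eigh(Ksub.values)
        s = np.clip(s, 0.0, None)
    else:
        null = fit_null_mlm(yv, X0, Ksub, method="reml")
        lam, s, U = null.ratio, null.eigenvalues, null.rotation

    yt = U.T @ yv
    X0t = U.T @ X0

    dose = gm.minor_dosage()[:, acc_idx].astype(float)
    dose[dose < 0] = np.nan

    rows = []
    for i, locus in enumerate(gm.loci):
        x = dose[i]
        called = np.isfinite(x)
        if not called.any() or np.nanstd(x) == 0:
            rows.append((locus, np.nan, np.nan, np.nan, np.nan))
            logger.debug("skipping monomorphic/uncalled SNP %s", locus)
            continue
        x = np.where(called, x, np.nanmean(x))
        xt = U.T @ x
        Xt = np.column_stack([X0t, xt])
        if per_marker_reml:
            res = optimize.minimize_scalar(
                _neg_loglik,
                bounds=_LOG_RATIO_BOUNDS,
                args=(yt, Xt, s, "reml"),
                method="bounded",
                options={"xatol": 1e-8},
            )
            lam_i = float(np.exp(res.x))
        else:
            lam_i = lam
        d = lam_i * s + 1.0
        try:
            beta, rss, XtWX = _gls(yt, Xt, d)
        except np.linalg.LinAlgError:
            rows.append((locus, np.nan, np.nan, np.nan, np.nan))
            logger.debug("singular design at SNP %s", locus)
            continue
        df = n - Xt.shape[1]
        if df < 1 or rss <= 0:
            rows.append((locus, np.nan, np.nan, np.nan, np.nan))
            continue
        sigma_e2 = rss / df
        cov = sigma_e2 * np.linalg.inv(XtWX)
        se = float(np.sqrt(cov[-1, -1]))
        effect = float(beta[-1])
        tstat = effect / se
        p = 2.0 * stats.t.sf(abs(tstat), df)
        rows.append((locus, effect, se, tstat, p))

    out = pd.DataFrame(
        rows, columns=["locus", "effect", "se", "stat", "p_value"]
    ).set_index("locus")
    m_tested = int(out["p_value"].notna().sum())
    thresh = bonferroni_threshold(alpha, m_tested) if m_tested else np.nan
    out["significant"] = out["p_value"] < thresh
    out.attrs.update(
        n=n, m_tested=m_tested, variance_ratio=lam, bonferroni=thresh
    )
    return out
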