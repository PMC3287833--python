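"""Variance-components linkage analysis in pedigrees.

The trait covariance among family members is modelled as

    Omega = 2 Phi sigma2_a  +  Pi sigma2_q  +  I sigma2_e,

where Phi is the pedigree kinship matrix (2 Phi the expected additive
covariance kernel), Pi the locus-specific IBD sharing matrix at the tested
position, and sigma2_a, sigma2_q, sigma2_e the polygenic, locus-specific
and residual variances.  Fixed effects (intercept plus screened covariates)
are profiled by generalized least squares inside the variance optimization;
all fits are maximum likelihood so nested log-likelihood differences are
valid test statistics.

The LOD score is (loglik_full - loglik_null)/ln(10) with the null fixing
sigma2_q = 0.  Because the tested variance component sits on the boundary
of its parameter space under the null, the pointwise p-value uses the
half-and-half chi-square mixture (1/2 chi2_0 : 1/2 chi2_1); under this
convention a LOD of 0.60 corresponds to p = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Pedigree

__all__ = [
    "VcFit",
    "LinkageResult",
    "fit_vc",
    "lod_score",
    "lod_to_pvalue",
    "screen_covariates",
    "scan_genes",
    "family_blocks",
]

_LN10 = np.log(10.0)


@dataclass
class VcFit:
    fixed_effects: np.ndarray          # intercept first, then covariates
    fixed_names: list[str]
    fixed_se: np.ndarray
    variances: dict[str, float]        # kernel label -> variance, plus "residual"
    loglik: float
    converged: bool

    def wald_pvalues(self) -> dict[str, float]:
        z = self.fixed_effects / np.where(self.fixed_se > 0, self.fixed_se, np.inf)
        return {n: float(2.0 * stats.norm.sf(abs(zi)))
                for n, zi in zip(self.fixed_names, z)}


@dataclass(frozen=True)
class LinkageResult:
    gene: str
    chrom: str
    position: int
    scope: str          # family id or "all"
    lod: float
    pvalue: float


def family_blocks(peds: Sequence[Pedigree]) -> list[slice]:
    out, start = [], 0
    for p in peds:
        out.append(slice(start, start + len(p)))
        start += len(p)
    return out


def _profile_negloglik(v: np.ndarray, block_kernels, block_Xy, n, p):
    """ML negative log-likelihood with GLS-profiled fixed effects.

    ``block_kernels[b]`` holds that family's kernel submatrices (identity
    last); ``block_Xy[b]`` the family's [X | y] matrix.
    """
    logdet = 0.0
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    for kers, Xy in zip(block_kernels, block_Xy):
        V = v[-1] * kers[-1]
        for vk, K in zip(v[:-1], kers[:-1]):
            V = V + vk * K
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        Z = np.linalg.solve(L, Xy)
        Zx, zy = Z[:, :-1], Z[:, -1]
        XtViX += Zx.T @ Zx
        XtViy += Zx.T @ zy
        ytViy += float(zy @ zy)
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    quad = ytViy - float(beta @ XtViy)
    nll = 0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
    return nll, beta, XtViX


def fit_vc(
    trait: np.ndarray,
    covariates: pd.DataFrame | None,
    kernels: Sequence[tuple[str, np.ndarray]],
    peds: Sequence[Pedigree] | None = None,
    blocks: Sequence[slice] | None = None,
) -> VcFit:
    """ML fit of the variance-components model.

    ``kernels`` lists (label, matrix) pairs, e.g. ("additive", 2*Phi) and
    ("locus", Pi); an identity residual kernel is always included.  Family
    independence is exploited through ``blocks`` (row slices per family,
    derived from ``peds`` when omitted): Omega is block-diagonal.

    Optimization is on the log-variance scale from a fixed grid of starts,
    followed by explicit boundary fits with each subset of the kernels
    removed; the best likelihood wins.  Deterministic given inputs.
    """
    y = np.asarray(trait, dtype=float)
    n = len(y)
    if covariates is not None and len(covariates.columns):
        X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
        names = ["intercept", *covariates.columns]
    else:
        X = np.ones((n, 1))
        names = ["intercept"]
    if blocks is None:
        blocks = family_blocks(peds) if peds is not None else [slice(0, n)]
    labels = [lab for lab, _ in kernels]
    mats = [np.asarray(K, dtype=float) for _, K in kernels]

    # per-block kernel submatrices (identity last) and [X|y] panels,
    # built once per fit
    block_K = [[K[sl, sl] for K in mats] + [np.eye(sl.stop - sl.start)]
               for sl in blocks]
    block_Xy = [np.column_stack([X[sl], y[sl]]) for sl in blocks]
    p = X.shape[1]

    # OLS residual variance anchors the scale of every start
    bols, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2r = max(float(np.var(y - X @ bols)), 1e-10)

    def fit_subset(active: tuple[int, ...], fracs: tuple[float, ...]):
        bk = [[kers[i] for i in active] + [kers[-1]] for kers in block_K]
        m = len(active)

        def nll_log(x):
            return _profile_negloglik(np.exp(x), bk, block_Xy, n, p)[0]

        if m == 0:
            # residual-only model: ML sigma2 has the OLS closed form
            v = np.array([max(float((y - X @ bols) @ (y - X @ bols)) / n, 1e-12)])
            val, beta, XtViX = _profile_negloglik(v, bk, block_Xy, n, p)
            return val, v, beta, XtViX, True
        best = None
        for frac in fracs:
            vk = np.full(m, frac * s2r / m)
            x0 = np.log(np.concatenate([vk, [max((1 - frac) * s2r, 1e-8)]]))
            res = optimize.minimize(nll_log, x0, method="L-BFGS-B",
                                    bounds=[(-30.0, 30.0)] * (m + 1),
                                    options={"maxiter": 200})
            if best is None or res.fun < best[0]:
                best = (float(res.fun), np.exp(res.x), bool(res.success))
        val, v, ok = best
        _, beta, XtViX = _profile_negloglik(v, bk, block_Xy, n, p)
        return val, v, beta, XtViX, ok

    # the full model plus boundary fits with each kernel (and all kernels)
    # clamped to zero, guarding against boundary misconvergence
    full_idx = tuple(range(len(mats)))
    subsets = [(full_idx, (0.3, 0.7))]
    if len(mats) >= 1:
        for i in full_idx:
            sub = tuple(j for j in full_idx if j != i)
            subsets.append((sub, (0.5,)))
        if len(mats) > 1:
            subsets.append(((), ()))

    candidates = []
    for active, fracs in subsets:
        val, v, beta, XtViX, ok = fit_subset(active, fracs)
        variances = {lab: 0.0 for lab in labels}
        for j, i in enumerate(active):
            variances[labels[i]] = float(v[j])
        variances["residual"] = float(v[-1])
        candidates.append((val, variances, beta, XtViX, ok))
    candidates.sort(key=lambda c: c[0])
    val, variances, beta, XtViX, ok = candidates[0]
    try:
        cov_beta = np.linalg.inv(XtViX)
        se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
    return VcFit(fixed_effects=np.asarray(beta), fixed_names=names, fixed_se=se,
                 variances=variances, loglik=-val, converged=ok and np.isfinite(val))


def lod_score(full: VcFit, null: VcFit) -> float:
    """(loglik_full - loglik_null) / ln(10), floored at zero."""
    return max(0.0, (full.loglik - null.loglik) / _LN10)


def lod_to_pvalue(lod: float) -> float:
    """Pointwise p for one boundary-constrained variance component.

    p = 0.5 * P(chi2_1 > 2 ln(10) LOD) for LOD > 0 and p = 1 at LOD = 0,
    the 1/2 chi2_0 : 1/2 chi2_1 mixture null.
    """
    if lod < 0:
        raise ValueError("LOD must be non-negative")
    if lod == 0:
        return 1.0
    return float(0.5 * stats.chi2.sf(2.0 * _LN10 * lod, df=1))


def screen_covariates(
    trait: np.ndarray,
    covariates: pd.DataFrame,
    peds: Sequence[Pedigree],
    phi2: np.ndarray | None = None,
    alpha: float = 0.10,
) -> list[str]:
    """Covariates kept as significant predictors at the screening level.

    Fits the polygenic-only model (2 Phi kernel + residual) with all
    covariates and retains those with Wald p below ``alpha`` (default
    0.10).  Returns retained column names in input order.
    """
    if not len(covariates.columns):
        return []
    if phi2 is None:
        phi2 = 2.0 * _kinship_blockdiag(peds)
    fit = fit_vc(trait, covariates, [("additive", phi2)], peds=peds)
    pvals = fit.wald_pvalues()
    return [c for c in covariates.columns if pvals[c] < alpha]


def _kinship_blockdiag(peds: Sequence[Pedigree]) -> np.ndarray:
    n = sum(len(p) for p in peds)
    phi = np.zeros((n, n))
    for p, sl in zip(peds, family_blocks(peds)):
        phi[sl, sl] = p.kinship_matrix()
    return phi


def scan_genes(
    study,
    trait_name: str,
    scope: str,
    retained_covariates: Sequence[str] | None = None,
    gene_map: pd.DataFrame | None = None,
) -> list[LinkageResult]:
    """Linkage scan of one trait over the gene map for one scope.

    ``scope`` is a family id or "all" (block-diagonal across families).
    Pi at each gene comes from the study's recorded descent (fully
    informative IBD); genes without descent are skipped with a warning.
    Results are ordered by chromosome and position.
    """
    import warnings

    gm = gene_map if gene_map is not None else study.gene_map
    if scope == "all":
        peds = list(study.pedigrees)
        idx = slice(0, len(study.individuals))
    else:
        peds = [study.pedigree(scope)]
        idx = study.family_slice(scope)
    y = study.traits[trait_name][idx]
    cov = study.covariates[["sex", "age", "smoking"]].iloc[idx]
    if retained_covariates is not None:
        cov = cov[list(retained_covariates)]
    phi2 = 2.0 * _kinship_blockdiag(peds)
    blocks = family_blocks(peds)
    null = fit_vc(y, cov, [("additive", phi2)], blocks=blocks)
    out = []
    for row in gm.itertuples():
        have = all(row.gene in study.descent[p.family_id] for p in peds)
        if not have:
            warnings.warn(f"gene {row.gene}: no descent recorded, skipped")
            continue
        pi = _pi_blockdiag(study, row.gene, peds)
        full = fit_vc(y, cov, [("additive", phi2), ("locus", pi)], blocks=blocks)
        lod = lod_score(full, null)
        out.append(LinkageResult(gene=row.gene, chrom=str(row.chrom),
                                 position=int(row.pos), scope=scope,
                                 lod=lod, pvalue=lod_to_pvalue(lod)))
    out.sort(key=lambda r: (r.chrom, r.position))
    return out


def _pi_blockdiag(study, gene: str, peds) -> np.ndarray:
    from .simulate import true_ibd_matrix

    n = sum(len(p) for p in peds)
    pi = np.zeros((n, n))
    for p, sl in zip(peds, family_blocks(peds)):
        pi[sl, sl] = true_ibd_matrix(study.descent[p.family_id][gene])
    return pi
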