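"""Measured-genotype association and linkage-signal attribution.

A candidate variant is tested by adding its additive-coded genotype as a
fixed covariate in the polygenic variance-components model (2 Phi kernel
plus residual), so relatedness among family members is always accounted
for; the test is a likelihood-ratio chi-square with one degree of freedom.
To attribute the linkage signal, the locus LOD is recomputed with the SNP
as a covariate: a collapse of the adjusted LOD toward zero means the
variant explains the linkage peak.  Variants are scored in the prioritized
family, in the remaining families ("others"), and in everyone ("all");
scopes in which the variant is monomorphic are reported NA.  Bonferroni
correction uses the number of candidate tests actually performed, and
pairs of candidates sharing carriers are disentangled by conditional tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import VcFit, family_blocks, fit_vc, lod_score, _kinship_blockdiag

__all__ = [
    "AssociationResult",
    "measured_genotype_test",
    "adjusted_lod",
    "variance_due_to_snp",
    "bonferroni_significant",
    "carrier_overlap",
    "conditional_test",
    "cross_family_replication",
]


@dataclass
class AssociationResult:
    variant_id: str
    scope: str                      # family id, "others", or "all"
    n_copies: int
    n_founder_entries: int
    pvalue: float | None            # None == NA (monomorphic scope)
    effect: float | None
    lod_unadjusted: float | None
    lod_adjusted: float | None
    pct_variance_snp: float | None


def _with_snp(covariates: pd.DataFrame | None, genotype: np.ndarray) -> pd.DataFrame:
    cov = covariates.copy() if covariates is not None else pd.DataFrame(
        index=range(len(genotype)))
    cov["snp"] = np.asarray(genotype, dtype=float)
    return cov


def measured_genotype_test(
    trait: np.ndarray,
    covariates: pd.DataFrame | None,
    genotype: np.ndarray,
    peds: Sequence,
    extra_covariates: pd.DataFrame | None = None,
) -> tuple[float | None, float | None]:
    """Likelihood-ratio test of the SNP fixed effect in the polygenic model.

    Returns ``(pvalue, effect)``; both ``None`` when the genotype is
    monomorphic in scope (nothing to test).  ``extra_covariates`` supports
    conditional tests (a second SNP as covariate in both models).
    """
    g = np.asarray(genotype, dtype=float)
    if np.ptp(g) == 0:
        return None, None
    phi2 = 2.0 * _kinship_blockdiag(peds)
    base_cov = covariates
    if extra_covariates is not None:
        base_cov = pd.concat(
            [c.reset_index(drop=True) for c in (covariates, extra_covariates)
             if c is not None], axis=1)
    kernels = [("additive", phi2)]
    null = fit_vc(trait, base_cov, kernels, peds=peds)
    full = fit_vc(trait, _with_snp(base_cov, g), kernels, peds=peds)
    lr = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(stats.chi2.sf(lr, df=1))
    effect = float(full.fixed_effects[full.fixed_names.index("snp")])
    return p, effect


def adjusted_lod(
    trait: np.ndarray,
    covariates: pd.DataFrame | None,
    genotype: np.ndarray,
    pi: np.ndarray,
    peds: Sequence,
) -> tuple[float, float]:
    """Linkage LOD at the gene without and with the SNP as fixed covariate."""
    g = np.asarray(genotype, dtype=float)
    phi2 = 2.0 * _kinship_blockdiag(peds)
    blocks = family_blocks(peds)

    def lod_with(cov):
        null = fit_vc(trait, cov, [("additive", phi2)], blocks=blocks)
        full = fit_vc(trait, cov, [("additive", phi2), ("locus", pi)], blocks=blocks)
        return lod_score(full, null)

    lod_un = lod_with(covariates)
    if np.ptp(g) == 0:
        return lod_un, lod_un
    return lod_un, lod_with(_with_snp(covariates, g))


def variance_due_to_snp(effect: float, genotype: np.ndarray,
                        trait: np.ndarray) -> float:
    """Percent of the in-scope trait variance explained by the fitted SNP effect.

    100 * b^2 Var(g) / Var(Y); invariant to shifting the trait.
    """
    vy = float(np.var(np.asarray(trait, dtype=float)))
    if vy <= 0:
        raise ValueError("zero trait variance")
    return float(np.clip(
        100.0 * effect ** 2 * np.var(np.asarray(genotype, dtype=float)) / vy,
        0.0, 100.0))


def bonferroni_significant(pvalues: dict[str, float | None], m: int,
                           alpha: float = 0.05) -> set[str]:
    """Variants significant after Bonferroni correction over ``m`` tests."""
    if m == 0:
        raise ValueError("m must be positive")
    tested = {k: v for k, v in pvalues.items() if v is not None}
    if m < len(tested):
        raise ValueError("m smaller than the number of tests performed")
    return {k for k, v in tested.items() if v < alpha / m}


def carrier_overlap(genotype_a: np.ndarray,
                    genotype_b: np.ndarray) -> tuple[int, int, int]:
    """(carriers of a, carriers of b, carriers of both) within a scope."""
    a = np.asarray(genotype_a) >= 1
    b = np.asarray(genotype_b) >= 1
    if len(a) != len(b):
        raise ValueError("genotype vectors not aligned")
    return int(a.sum()), int(b.sum()), int((a & b).sum())


def conditional_test(
    trait: np.ndarray,
    covariates: pd.DataFrame | None,
    genotype_a: np.ndarray,
    adjust_for: np.ndarray,
    peds: Sequence,
) -> tuple[float | None, str | None]:
    """Association p of variant a with variant b held as a fixed covariate.

    Returns ``(pvalue, flag)``; identical genotype vectors are collinear and
    yield ``(None, "collinear")``.
    """
    a = np.asarray(genotype_a, dtype=float)
    b = np.asarray(adjust_for, dtype=float)
    if np.array_equal(a, b):
        return None, "collinear"
    if np.ptp(b) == 0:
        p, _ = measured_genotype_test(trait, covariates, a, peds)
        return p, None
    extra = pd.DataFrame({"snp_b": b})
    p, _ = measured_genotype_test(trait, covariates, a, peds,
                                  extra_covariates=extra)
    return p, None


def cross_family_replication(
    variant,
    study,
    prioritized_family: str,
    trait_name: str,
    retained_covariates: Sequence[str] | None = None,
) -> list[AssociationResult]:
    """Score a candidate in the prioritized family, the others, and all.

    For each scope: copy/founder counts, the measured-genotype p-value and
    effect, the unadjusted and SNP-adjusted linkage LOD at the variant's
    gene context, and the percent of trait variance the SNP explains.
    Monomorphic scopes report NA throughout.
    """
    from .prioritization import _family_rare_coding, founder_entry_count
    from .linkage import _pi_blockdiag

    fam_ids = study.family_ids
    scopes = {
        prioritized_family: [prioritized_family],
        "others": [f for f in fam_ids if f != prioritized_family],
        "all": fam_ids,
    }
    global_g = np.asarray(variant.genotypes)
    out = []
    for scope_name, fams in scopes.items():
        peds = [study.pedigree(f) for f in fams]
        rows = np.concatenate([
            np.arange(study.family_slice(f).start, study.family_slice(f).stop)
            for f in fams])
        y = study.traits[trait_name][rows]
        cov = study.covariates[["sex", "age", "smoking"]].iloc[rows]
        if retained_covariates is not None:
            cov = cov[list(retained_covariates)]
        g = np.concatenate([
            _family_rare_coding(global_g[study.family_slice(f)], global_g)
            for f in fams])
        copies = int(g.sum())
        nf = sum(
            founder_entry_count(study.pedigree(f),
                                _family_rare_coding(global_g[study.family_slice(f)],
                                                    global_g))
            for f in fams if global_g[study.family_slice(f)].sum() > 0
        )
        if np.ptp(g) == 0:
            out.append(AssociationResult(variant.variant_id, scope_name, copies,
                                         nf, None, None, None, None, None))
            continue
        p, effect = measured_genotype_test(y, cov, g, peds)
        pi = _pi_blockdiag(study, variant.gene, peds)
        lod_un, lod_adj = adjusted_lod(y, cov, g, pi, peds)
        pct = variance_due_to_snp(effect, g, y) if effect is not None else None
        out.append(AssociationResult(variant.variant_id, scope_name, copies, nf,
                                     p, effect, lod_un, lod_adj, pct))
    return out
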