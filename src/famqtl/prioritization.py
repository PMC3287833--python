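"""Linked regions and rare candidate-variant extraction.

Once a family shows at least modest evidence of linkage at a gene (LOD at
or above the threshold, default 0.60 i.e. pointwise p = 0.05), a 1-Mbp
window centred at the gene position is searched for rare variants that
(1) entered the family through at most two founders and (2) are seen in at
least five copies among the family's members.  Those variants become the
candidates for measured-genotype association.

"Copies" are rare-allele counts (a homozygote contributes two); carrier
counts are reported alongside.  The rare allele is defined per family as
the less frequent allele among that family's members, falling back to the
global minor allele on a tie.  Variants common in the combined sample
(minor-allele frequency at or above 5% by default) are excluded — the
design targets rare variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pedigree import Pedigree
from .linkage import LinkageResult

__all__ = [
    "LinkedRegion",
    "CandidateVariant",
    "linked_regions",
    "founder_entry_count",
    "filter_candidates",
]

WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class LinkedRegion:
    gene: str
    chrom: str
    center: int
    window_start: int  # 1-based, half-open [start, end)
    window_end: int
    family: str
    lod: float


@dataclass(frozen=True)
class CandidateVariant:
    variant_id: str
    gene_context: str
    family: str
    copies_in_family: int
    n_carriers: int
    entering_founders: int
    carrier_ids: frozenset[str]


def linked_regions(results: Sequence[LinkageResult],
                   lod_threshold: float = 0.60) -> list[LinkedRegion]:
    """One 1-Mbp window per gene whose family-specific LOD meets the threshold.

    Windows are [center - 500 kb, center + 500 kb), clipped at position 1.
    ``results`` must all carry the same family scope.
    """
    out = []
    for r in results:
        if r.lod < lod_threshold:
            continue
        start = max(1, r.position - WINDOW_BP // 2)
        out.append(LinkedRegion(gene=r.gene, chrom=r.chrom, center=r.position,
                                window_start=start,
                                window_end=r.position + WINDOW_BP // 2,
                                family=r.scope, lod=r.lod))
    return out


def _family_rare_coding(fam_g: np.ndarray, global_g: np.ndarray) -> np.ndarray:
    """Recode genotypes so they count the family's rare allele.

    The rare allele is the less frequent one among the family members; on
    an exact tie the globally rarer allele is used.
    """
    fam_freq = fam_g.sum() / (2.0 * len(fam_g))
    if fam_freq > 0.5:
        return 2 - fam_g
    if fam_freq == 0.5:
        if global_g.sum() / (2.0 * len(global_g)) > 0.5:
            return 2 - fam_g
    return fam_g.copy()


def founder_entry_count(ped: Pedigree, genotypes: np.ndarray) -> int:
    """Number of founders carrying the rare allele (homozygotes count once).

    Warns when a non-founder carries the allele while no founder does —
    impossible under Mendelian inheritance without mutation, so it flags a
    data inconsistency.
    """
    g = np.asarray(genotypes)
    if len(g) != len(ped):
        raise ValueError("genotype vector not aligned to pedigree members")
    founder_rows = np.array([m.is_founder for m in ped.members])
    n_founder_carriers = int((g[founder_rows] >= 1).sum())
    if n_founder_carriers == 0 and (g[~founder_rows] >= 1).any():
        warnings.warn(
            f"family {ped.family_id}: rare allele carried by non-founders only — "
            "inconsistent with founder entry under Mendelian inheritance"
        )
    return n_founder_carriers


def filter_candidates(
    region: LinkedRegion,
    variants: Sequence,          # objects with variant_id, chrom, pos, gene, genotypes
    ped: Pedigree,
    family_slice: slice,
    max_founders: int = 2,
    min_copies: int = 5,
    maf_threshold: float = 0.05,
) -> list[CandidateVariant]:
    """Rare variants in the window passing the founder-entry and copy filters.

    Keeps variants with window_start <= pos < window_end on the region's
    chromosome, entering the family through at most ``max_founders``
    founders, with at least ``min_copies`` rare-allele copies among family
    members, and globally rare (MAF below ``maf_threshold``).
    """
    out = []
    for v in variants:
        if v.chrom != region.chrom:
            continue
        if not (region.window_start <= v.pos < region.window_end):
            continue
        global_g = np.asarray(v.genotypes)
        maf = global_g.sum() / (2.0 * len(global_g))
        maf = min(maf, 1.0 - maf)
        if maf >= maf_threshold:
            continue
        fam_g = _family_rare_coding(global_g[family_slice], global_g)
        copies = int(fam_g.sum())
        if copies < min_copies:
            continue
        nf = founder_entry_count(ped, fam_g)
        if nf > max_founders:
            continue
        carriers = frozenset(np.array(ped.ids)[fam_g >= 1])
        out.append(CandidateVariant(
            variant_id=v.variant_id, gene_context=v.gene, family=region.family,
            copies_in_family=copies, n_carriers=len(carriers),
            entering_founders=nf, carrier_ids=carriers,
        ))
    return out
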