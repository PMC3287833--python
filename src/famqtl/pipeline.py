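"""End-to-end orchestration: simulate -> segregation -> prioritize ->
linkage -> filter -> associate, with tabular report output.

The report mirrors the three summary tables of the underlying study
design: per-trait variance partitions from the joint segregation analysis
(table 1), per-family expected QTL counts with excess annotations
(table 2), and per-candidate association results with linkage attribution
(table 3).  Traits for which no family is prioritized are dropped from the
downstream stages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import linkage as lk
from . import prioritization as pz
from . import segregation as seg
from .simulate import SimConfig, SimulatedStudy, default_config, read_study, simulate_study

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "render_report",
           "load_config"]


@dataclass
class PipelineConfig:
    sim: SimConfig | None = None
    input_dir: str | None = None
    traits: list[str] | None = None          # None = all traits in the study
    seg_priors: seg.Priors = field(default_factory=seg.Priors)
    seg_settings: seg.McmcSettings = field(
        default_factory=lambda: seg.McmcSettings(burn_in=600, iterations=1800, thin=3))
    excess_threshold: float = 1.0
    lod_threshold: float = 0.60
    max_founders: int = 2
    min_copies: int = 5
    maf_threshold: float = 0.05
    screen_alpha: float = 0.10
    overlap_fraction: float = 0.5            # carrier overlap triggering conditional tests
    compute_joint_partition: bool = True
    seed: int = 0

    def __post_init__(self):
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one of sim config or input_dir must be given")
        if self.lod_threshold <= 0 or self.min_copies <= 0 or self.max_founders <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class StudyReport:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    conditional: pd.DataFrame
    prioritized: dict[str, set[str]]       # trait -> prioritized family ids
    significant: dict[str, set[str]]       # trait -> Bonferroni-significant variants
    n_tests: dict[str, int]                # trait -> candidate tests performed
    metadata: dict
    errors: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig,
                 study: SimulatedStudy | None = None) -> StudyReport:
    """Run every stage in order and assemble the study report.

    A pre-built ``study`` short-circuits the simulate/load stage (useful
    for running stages against an in-memory study).  Deterministic given
    the configuration and seed.
    """
    if study is None:
        study = (simulate_study(config.sim) if config.sim is not None
                 else read_study(config.input_dir))
    trait_names = config.traits or list(study.traits)
    cov_all = study.covariates[["sex", "age", "smoking"]]
    errors: list[str] = []

    t1_rows, t2_rows, t3_rows, cond_rows = [], [], [], []
    prioritized: dict[str, set[str]] = {}
    significant: dict[str, set[str]] = {}
    n_tests: dict[str, int] = {}

    for ti, trait in enumerate(trait_names):
        y = study.traits[trait]
        seed_t = int(np.random.SeedSequence([config.seed, 31337, ti]).generate_state(1)[0]
                     % (2 ** 31))
        try:
            if config.compute_joint_partition:
                post = seg.run_segregation(y, cov_all, study.pedigrees,
                                           priors=config.seg_priors,
                                           settings=config.seg_settings, seed=seed_t)
                part = seg.variance_partition(post)
                t1_rows.append({
                    "trait": trait,
                    **{f"{c}_pct": round(part.covariate_pct[c], 1)
                       for c in part.covariate_pct},
                    "qtl_pct": round(part.qtl_pct, 1),
                    "expected_k": round(part.expected_k, 1),
                    "residual_pct": round(part.residual_pct, 1),
                    "heritability_pct": round(part.heritability_pct, 1),
                })

            counts = seg.per_family_qtl_counts(y, cov_all, study.pedigrees,
                                               priors=config.seg_priors,
                                               settings=config.seg_settings,
                                               seed=seed_t)
            chosen = seg.prioritize_families(counts, config.excess_threshold)
            prioritized[trait] = chosen
            for fam, k in counts.items():
                t2_rows.append({
                    "trait": trait, "family": fam,
                    "family_size": len(study.pedigree(fam)),
                    "expected_k": round(k, 2),
                    "excess": round(seg.excess_qtls(counts, fam), 1),
                    "prioritized": fam in chosen,
                })
            if not chosen:
                continue  # trait not analyzed further

            candidates: dict[str, tuple] = {}
            retained_by_fam: dict[str, list[str]] = {}
            for fam in sorted(chosen):
                sl = study.family_slice(fam)
                ped = study.pedigree(fam)
                retained = lk.screen_covariates(y[sl], cov_all.iloc[sl], [ped],
                                                alpha=config.screen_alpha)
                retained_by_fam[fam] = retained
                results = lk.scan_genes(study, trait, fam,
                                        retained_covariates=retained)
                regions = pz.linked_regions(results, config.lod_threshold)
                for reg in regions:
                    for cand in pz.filter_candidates(
                            reg, study.variants, ped, sl,
                            max_founders=config.max_founders,
                            min_copies=config.min_copies,
                            maf_threshold=config.maf_threshold):
                        candidates.setdefault(cand.variant_id, (fam, cand))

            m = len(candidates)
            n_tests[trait] = m
            fam_pvals: dict[str, float | None] = {}
            for vid, (fam, cand) in sorted(candidates.items()):
                variant = study.variant(vid)
                res = assoc.cross_family_replication(
                    variant, study, fam, trait,
                    retained_covariates=retained_by_fam[fam])
                for r in res:
                    t3_rows.append({
                        "trait": trait, "variant": vid, "gene": variant.gene,
                        "scope": r.scope, "copies": r.n_copies,
                        "founders": r.n_founder_entries,
                        "pvalue": r.pvalue, "lod_unadjusted": r.lod_unadjusted,
                        "lod_adjusted": r.lod_adjusted,
                        "pct_variance_snp": r.pct_variance_snp,
                    })
                    if r.scope == fam:
                        fam_pvals[vid] = r.pvalue
            significant[trait] = (assoc.bonferroni_significant(fam_pvals, m)
                                  if m else set())

            # conditional disentangling of co-carried candidate pairs
            vids = sorted(candidates)
            for i in range(len(vids)):
                for j in range(i + 1, len(vids)):
                    fam_i = candidates[vids[i]][0]
                    if fam_i != candidates[vids[j]][0]:
                        continue
                    sl = study.family_slice(fam_i)
                    ga = np.asarray(study.variant(vids[i]).genotypes)[sl]
                    gb = np.asarray(study.variant(vids[j]).genotypes)[sl]
                    na, nb, nboth = assoc.carrier_overlap(ga, gb)
                    if min(na, nb) == 0 or nboth < config.overlap_fraction * min(na, nb):
                        continue
                    ped = study.pedigree(fam_i)
                    cov_f = cov_all.iloc[sl][retained_by_fam[fam_i]]
                    pa, fa = assoc.conditional_test(y[sl], cov_f, ga, gb, [ped])
                    pb, fb = assoc.conditional_test(y[sl], cov_f, gb, ga, [ped])
                    cond_rows.append({
                        "trait": trait, "family": fam_i,
                        "variant": vids[i], "given": vids[j],
                        "n_carriers": na, "n_both": nboth,
                        "pvalue": pa, "flag": fa,
                    })
                    cond_rows.append({
                        "trait": trait, "family": fam_i,
                        "variant": vids[j], "given": vids[i],
                        "n_carriers": nb, "n_both": nboth,
                        "pvalue": pb, "flag": fb,
                    })
        except Exception as exc:  # stage failure -> partial report
            errors.append(f"trait {trait}: {type(exc).__name__}: {exc}")
            warnings.warn(errors[-1])

    t1_cols = ["trait", "sex_pct", "age_pct", "smoking_pct", "qtl_pct",
               "expected_k", "residual_pct", "heritability_pct"]
    t3_cols = ["trait", "variant", "gene", "scope", "copies", "founders",
               "pvalue", "lod_unadjusted", "lod_adjusted", "pct_variance_snp"]
    cond_cols = ["trait", "family", "variant", "given", "n_carriers", "n_both",
                 "pvalue", "flag"]
    meta = {
        "seed": config.seed,
        "traits": trait_names,
        "excess_threshold": config.excess_threshold,
        "lod_threshold": config.lod_threshold,
        "max_founders": config.max_founders,
        "min_copies": config.min_copies,
        "maf_threshold": config.maf_threshold,
        "screen_alpha": config.screen_alpha,
        "seg_settings": vars(config.seg_settings).copy(),
        "n_tests": n_tests,
    }
    return StudyReport(
        table1=pd.DataFrame(t1_rows, columns=t1_cols if t1_rows else t1_cols),
        table2=pd.DataFrame(t2_rows, columns=["trait", "family", "family_size",
                                              "expected_k", "excess", "prioritized"]),
        table3=pd.DataFrame(t3_rows, columns=t3_cols),
        conditional=pd.DataFrame(cond_rows, columns=cond_cols),
        prioritized=prioritized, significant=significant, n_tests=n_tests,
        metadata=meta, errors=errors,
    )


def _fmt_p(p) -> str:
    if p is None or (isinstance(p, float) and not np.isfinite(p)):
        return "NA"
    return f"{p:.3g}"


def render_report(report: StudyReport, directory: str | Path) -> None:
    """Write TSV tables and a plain-text summary.

    Rounding conventions: counts and percentages to 1 decimal, p-values to
    3 significant figures, LOD scores to 2 decimals.  The table-2 analog
    annotates only prioritized families with their "(+x.x)" excess.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    report.table1.to_csv(d / "table1_variance_partition.tsv", sep="\t", index=False)

    t2 = report.table2.copy()
    if len(t2):
        t2["expected_k_annotated"] = [
            f"{row.expected_k:.1f} (+ {row.excess:.1f})" if row.prioritized
            else f"{row.expected_k:.1f}"
            for row in t2.itertuples()
        ]
    else:
        t2["expected_k_annotated"] = pd.Series(dtype=str)
    t2.to_csv(d / "table2_family_qtl_counts.tsv", sep="\t", index=False)

    t3 = report.table3.copy()
    if len(t3):
        t3["pvalue"] = [_fmt_p(p) for p in t3["pvalue"]]
        for c in ("lod_unadjusted", "lod_adjusted"):
            t3[c] = [("NA" if v is None or not np.isfinite(v) else f"{v:.2f}")
                     for v in t3[c].astype(object)]
        t3["pct_variance_snp"] = [
            ("NA" if v is None or not np.isfinite(v) else f"{v:.1f}")
            for v in t3["pct_variance_snp"].astype(object)]
    t3.to_csv(d / "table3_association.tsv", sep="\t", index=False)
    report.conditional.to_csv(d / "conditional_tests.tsv", sep="\t", index=False)

    with open(d / "run.json", "w") as fh:
        json.dump({**report.metadata,
                   "prioritized": {t: sorted(v) for t, v in report.prioritized.items()},
                   "significant": {t: sorted(v) for t, v in report.significant.items()},
                   "errors": report.errors}, fh, indent=1)

    with open(d / "summary.txt", "w") as fh:
        fh.write("famqtl pipeline summary\n=======================\n")
        for t, fams in report.prioritized.items():
            fh.write(f"trait {t}: prioritized families = "
                     f"{sorted(fams) if fams else 'none (trait not analyzed further)'}\n")
            if t in report.n_tests:
                fh.write(f"  candidate variants tested: {report.n_tests[t]}\n")
            if report.significant.get(t):
                fh.write(f"  Bonferroni-significant: {sorted(report.significant[t])}\n")
        if report.errors:
            fh.write("errors:\n" + "\n".join(report.errors) + "\n")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Recognized keys: ``simulate`` ("default", a seed mapping, or false),
    ``input_dir``, ``traits``, ``seed``, threshold settings, and a
    ``segregation`` block (burn_in, iterations, thin, n_chains).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"simulate", "input_dir", "traits", "seed", "excess_threshold",
             "lod_threshold", "max_founders", "min_copies", "maf_threshold",
             "screen_alpha", "segregation", "compute_joint_partition"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim = None
    if raw.get("simulate"):
        s = raw["simulate"]
        sim = default_config(seed=int(s.get("seed", raw.get("seed", 0)))
                             if isinstance(s, dict) else int(raw.get("seed", 0)))
    kwargs = {k: raw[k] for k in
              ("traits", "seed", "excess_threshold", "lod_threshold", "max_founders",
               "min_copies", "maf_threshold", "screen_alpha", "compute_joint_partition")
              if k in raw}
    if "segregation" in raw:
        kwargs["seg_settings"] = seg.McmcSettings(**raw["segregation"])
    return PipelineConfig(sim=sim, input_dir=raw.get("input_dir"), **kwargs)
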