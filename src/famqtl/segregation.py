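"""Oligogenic segregation analysis by reversible-jump MCMC.

The trait is modelled as

    Y = mu + X beta + sum_{i=1}^{k} Q_i alpha_i + e,

where X holds the covariates (Sex, Age, Smoking), Q_i is the design matrix
of the additive and dominance components of the i-th QTL — built from
latent, Mendelian-consistent genotypes — alpha_i = (a_i, d_i) its effects,
and e is i.i.d. normal residual.  The number of QTLs ``k`` is itself an
estimable parameter: a birth/death reversible-jump move adds or removes
whole QTLs, so the posterior over k quantifies how many trait loci a
pedigree (or a whole sample of pedigrees) is likely to harbor.

Latent genotypes are represented by a descent graph: founder alleles plus
per-meiosis segregation indicators.  Mendelian consistency is therefore
structural — any setting of the latent variables is a valid inheritance
pattern — and genotype updates are single-site Metropolis flips of founder
alleles or segregation indicators, accepted on the phenotype likelihood.

Priors (weakly informative, scale-adapted to the trait):
  k ~ Poisson(lambda=2) truncated to {0..k_max};  a_i, d_i ~ N(0, tau^2)
  with tau^2 the empirical trait variance;  q_i ~ Beta(1,1) restricted to
  (0.005, 0.995);  mu, beta flat;  sigma^2_e ~ Inv-Gamma(1/2, var(Y)/2).

Per-family analysis of the same trait yields the expected QTL count per
family; families carrying at least one QTL in excess of the average of the
other families are prioritized for sequencing follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree
from .simulate import DescentEngine

__all__ = [
    "Priors",
    "McmcSettings",
    "SegregationPosterior",
    "VariancePartition",
    "run_segregation",
    "variance_partition",
    "heritability",
    "per_family_qtl_counts",
    "excess_qtls",
    "prioritize_families",
]


@dataclass(frozen=True)
class Priors:
    """Priors of the oligogenic model, scale-adapted to the trait.

    ``k_lambda`` is the mean of the truncated-Poisson prior on the QTL
    count.  ``tau2_scale`` multiplies the empirical trait variance to give
    the N(0, tau^2) prior variance of each additive and dominance effect;
    scaling to the trait keeps the prior weakly informative on any trait
    scale, and its width sets the per-QTL Occam penalty in the marginal
    likelihood (wider = fewer spurious QTLs, but also slower detection of
    modest ones).
    """

    k_lambda: float = 2.0
    k_max: int = 8
    q_bounds: tuple[float, float] = (0.005, 0.995)
    # additive effect prior N(0, tau2_scale * var(y)); dominance prior
    # N(0, tau2_dom_scale * var(y)), same width by default — tighten it to
    # encode a mostly-additive architecture if desired;
    # residual IG(ig_shape, ig_rate_scale * var(y))
    tau2_scale: float = 1.0
    tau2_dom_scale: float = 1.0
    ig_shape: float = 0.5
    ig_rate_scale: float = 0.5


@dataclass(frozen=True)
class McmcSettings:
    burn_in: int = 2000
    iterations: int = 10000          # post burn-in
    thin: int = 5
    n_chains: int = 1                # chains run sequentially, samples pooled
    founder_flips: int | None = None  # per QTL per family per iteration (auto if None)
    seg_flips: int | None = None
    rj_moves: int = 4                # birth/death attempts per sweep


@dataclass
class SegregationPosterior:
    k_samples: np.ndarray
    share_samples: dict[str, np.ndarray]   # covariate name / "qtl" / "residual" -> shares
    acceptance_rates: dict[str, float]
    covariate_names: list[str]

    @property
    def expected_k(self) -> float:
        return float(np.mean(self.k_samples))

    def save_trace(self, path) -> None:
        """Write the retained samples (k and variance shares) as TSV."""
        cols = {"k": self.k_samples}
        cols.update({f"share_{name}": vals
                     for name, vals in self.share_samples.items()})
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


@dataclass
class VariancePartition:
    covariate_pct: dict[str, float]
    qtl_pct: float
    residual_pct: float
    expected_k: float
    heritability_pct: float


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

class _Block:
    """Per-family latent-genotype machinery and row slice."""

    def __init__(self, ped: Pedigree, start: int):
        self.engine = DescentEngine(ped)
        self.sl = slice(start, start + len(ped))
        self.n = len(ped)


class _Qtl:
    __slots__ = ("q", "a", "d", "F", "S", "lab", "g")

    def __init__(self, q, a, d, F, S, lab, g):
        self.q, self.a, self.d = q, a, d
        self.F, self.S, self.lab, self.g = F, S, lab, g  # dicts keyed by block index

    def contrib(self, bi: int) -> np.ndarray:
        g = self.g[bi].astype(float)
        return self.a * (g - 1.0) + self.d * (g == 1)


def _draw_coefficients(W, y, s2, prior_prec, rng):
    A = W.T @ W / s2 + np.diag(prior_prec)
    b = W.T @ y / s2
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
    z = rng.standard_normal(len(b))
    return mean + np.linalg.solve(L.T, z)


def _trunc_beta(a, b, lo, hi, rng):
    clo, chi = stats.beta.cdf([lo, hi], a, b)
    u = rng.uniform(clo, chi)
    return float(np.clip(stats.beta.ppf(u, a, b), lo, hi))


def run_segregation(
    trait: np.ndarray,
    covariates: pd.DataFrame,
    peds: Sequence[Pedigree],
    priors: Priors | None = None,
    settings: McmcSettings | None = None,
    seed: int = 0,
    likelihood: str = "normal",
) -> SegregationPosterior:
    """Sample the oligogenic posterior for one trait over one or more families.

    ``trait`` and the rows of ``covariates`` are aligned to the
    concatenated member order of ``peds``.  ``likelihood="constant"``
    replaces every phenotype-likelihood ratio by 1 (a diagnostic mode in
    which the chain must reproduce its priors).

    Returns the pooled posterior over ``n_chains`` seeded chains.
    """
    priors = priors or Priors()
    settings = settings or McmcSettings()
    if settings.iterations // settings.thin < 1:
        raise ValueError("no retained samples: iterations < thin")
    y = np.asarray(trait, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trait contains non-finite values")
    cov_names = list(covariates.columns)
    X = covariates.to_numpy(dtype=float)
    n = len(y)
    if sum(len(p) for p in peds) != n or len(X) != n:
        raise ValueError("trait/covariates not aligned to pedigree members")

    blocks = []
    start = 0
    for p in peds:
        blocks.append(_Block(p, start))
        start += len(p)

    const_lik = likelihood == "constant"
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("zero trait variance")
    tau2 = priors.tau2_scale * vary
    tau2_d = priors.tau2_dom_scale * vary
    ig_a, ig_b = priors.ig_shape, priors.ig_rate_scale * vary
    lam, k_max = priors.k_lambda, priors.k_max
    qlo, qhi = priors.q_bounds
    n_alleles_tot = sum(b.engine.n_alleles for b in blocks)

    all_k, all_shares = [], {name: [] for name in cov_names + ["qtl", "residual"]}
    acc = {"founder": [0, 0], "seg": [0, 0], "birth": [0, 0], "death": [0, 0]}

    for chain in range(settings.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7919, chain]))
        _run_chain(y, X, blocks, rng, settings, const_lik, vary, tau2, tau2_d,
                   ig_a, ig_b, lam, k_max, qlo, qhi, n_alleles_tot, cov_names,
                   all_k, all_shares, acc)

    rates = {m: (a / t if t else 0.0) for m, (a, t) in acc.items()}
    return SegregationPosterior(
        k_samples=np.asarray(all_k),
        share_samples={k: np.asarray(v) for k, v in all_shares.items()},
        acceptance_rates=rates,
        covariate_names=cov_names,
    )


def _run_chain(y, X, blocks, rng, settings, const_lik, vary, tau2, tau2_d,
               ig_a, ig_b, lam, k_max, qlo, qhi, n_alleles_tot, cov_names,
               all_k, all_shares, acc):
    n = len(y)
    p_cov = X.shape[1]
    qtls: list[_Qtl] = []
    mu = float(np.mean(y))
    beta = np.zeros(p_cov)
    s2 = vary
    fitted_fixed = mu + X @ beta
    r = y - fitted_fixed  # residual after fixed effects AND all QTL contribs

    def total_iters():
        return settings.burn_in + settings.iterations

    for it in range(total_iters()):
        # (a) conjugate update of mu, beta, and all QTL effects jointly
        cols = [np.ones(n), *(X[:, j] for j in range(p_cov))]
        prior_prec = [0.0] * (1 + p_cov)
        for q in qtls:
            ga = np.zeros(n)
            gd = np.zeros(n)
            for bi, b in enumerate(blocks):
                g = q.g[bi].astype(float)
                ga[b.sl] = g - 1.0
                gd[b.sl] = g == 1
            cols.extend([ga, gd])
            prior_prec.extend([1.0 / tau2, 1.0 / tau2_d])
        W = np.column_stack(cols)
        theta = _draw_coefficients(W, y, s2, np.asarray(prior_prec), rng)
        mu = float(theta[0])
        beta = theta[1:1 + p_cov]
        for qi, q in enumerate(qtls):
            q.a = float(theta[1 + p_cov + 2 * qi])
            q.d = float(theta[2 + p_cov + 2 * qi])
        r = y - W @ theta

        # (b) conjugate residual variance
        rss = float(r @ r)
        G = rng.gamma(ig_a + n / 2.0)
        s2 = (ig_b + rss / 2.0) / G

        # (c) latent genotype Metropolis updates per QTL per family block
        for q in qtls:
            for bi, b in enumerate(blocks):
                eng = b.engine
                # full sweeps by default: partial sweeps leave the latent
                # descent configuration under-mixed and bias E[k] low
                nf = settings.founder_flips or eng.n_alleles
                ns = settings.seg_flips or max(1, len(eng.nonfounder_rows))
                F, S, lab, g = q.F[bi], q.S[bi], q.lab[bi], q.g[bi]
                rr = r[b.sl]
                # founder-allele flips
                slots = rng.integers(0, eng.n_alleles, size=nf)
                for l in slots:
                    new_val = 1 - F[l]
                    sgn = 1 if new_val == 1 else -1
                    cnt = (lab == l).sum(axis=1)
                    chg = np.nonzero(cnt)[0]
                    if chg.size == 0:
                        pr = q.q / (1 - q.q) if new_val == 1 else (1 - q.q) / q.q
                        if rng.random() < min(1.0, pr):
                            F[l] = new_val
                            acc["founder"][0] += 1
                        acc["founder"][1] += 1
                        continue
                    g_new = g[chg] + sgn * cnt[chg]
                    dc = (q.a * (g_new - g[chg])
                          + q.d * ((g_new == 1).astype(float) - (g[chg] == 1)))
                    r_new = rr[chg] - dc
                    dll = 0.0 if const_lik else (
                        (rr[chg] @ rr[chg] - r_new @ r_new) / (2.0 * s2))
                    pr = q.q / (1 - q.q) if new_val == 1 else (1 - q.q) / q.q
                    if np.log(rng.random()) < min(0.0, dll + np.log(pr)):
                        F[l] = new_val
                        g[chg] = g_new
                        rr[chg] = r_new
                        acc["founder"][0] += 1
                    acc["founder"][1] += 1
                # segregation-indicator flips
                if len(eng.nonfounder_rows):
                    rows = eng.nonfounder_rows[
                        rng.integers(0, len(eng.nonfounder_rows), size=ns)]
                    sides = rng.integers(0, 2, size=ns)
                    for j, sd in zip(rows, sides):
                        S[j, sd] ^= 1
                        lab_new = eng.labels(S)
                        g_new_full = F[lab_new].sum(axis=1).astype(np.int8)
                        chg = np.nonzero(g_new_full != g)[0]
                        if chg.size == 0:
                            q.lab[bi] = lab = lab_new
                            acc["seg"][0] += 1
                            acc["seg"][1] += 1
                            continue
                        dc = (q.a * (g_new_full[chg] - g[chg]).astype(float)
                              + q.d * ((g_new_full[chg] == 1).astype(float)
                                       - (g[chg] == 1)))
                        r_new = rr[chg] - dc
                        dll = 0.0 if const_lik else (
                            (rr[chg] @ rr[chg] - r_new @ r_new) / (2.0 * s2))
                        if np.log(rng.random()) < min(0.0, dll):
                            q.lab[bi] = lab = lab_new
                            g[chg] = g_new_full[chg]
                            rr[chg] = r_new
                            acc["seg"][0] += 1
                        else:
                            S[j, sd] ^= 1
                        acc["seg"][1] += 1
                r[b.sl] = rr

        # (d) conjugate allele-frequency update per QTL
        for q in qtls:
            x = sum(int(q.F[bi].sum()) for bi in range(len(blocks)))
            q.q = _trunc_beta(1 + x, 1 + n_alleles_tot - x, qlo, qhi, rng)

        # (e) birth/death reversible-jump moves (prior-draw proposals);
        # several attempts per sweep speed up trans-dimensional mixing
        # without changing the stationary distribution
        for _rj in range(settings.rj_moves):
            r = _rj_move(qtls, blocks, r, y, s2, rng, const_lik, tau2, tau2_d,
                         lam, k_max, qlo, qhi, acc)

        # record
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            all_k.append(len(qtls))
            for j, name in enumerate(cov_names):
                all_shares[name].append(float(np.var(X[:, j] * beta[j]) / vary))
            qtl_tot = np.zeros(n)
            for q in qtls:
                for bi, b in enumerate(blocks):
                    qtl_tot[b.sl] += q.contrib(bi)
            all_shares["qtl"].append(float(np.var(qtl_tot) / vary))
            all_shares["residual"].append(float(s2 / vary))


def _rj_move(qtls, blocks, r, y, s2, rng, const_lik, tau2, tau2_d, lam, k_max,
             qlo, qhi, acc):
    """One birth/death attempt; returns the (possibly updated) residual."""
    n = len(y)
    k = len(qtls)
    if rng.random() < 0.5:
        acc["birth"][1] += 1
        if k < k_max:
            qv = rng.uniform(qlo, qhi)
            av = rng.normal(0.0, np.sqrt(tau2))
            dv = rng.normal(0.0, np.sqrt(tau2_d))
            F, S, lab, g = {}, {}, {}, {}
            contrib = np.zeros(n)
            for bi, b in enumerate(blocks):
                eng = b.engine
                F[bi] = (rng.random(eng.n_alleles) < qv).astype(np.int8)
                S[bi] = eng.random_segregation(rng)
                lab[bi] = eng.labels(S[bi])
                g[bi] = F[bi][lab[bi]].sum(axis=1).astype(np.int8)
                gf = g[bi].astype(float)
                contrib[b.sl] = av * (gf - 1.0) + dv * (gf == 1)
            r_new = r - contrib
            dll = 0.0 if const_lik else (r @ r - r_new @ r_new) / (2.0 * s2)
            # exchangeable components: birth A = LR * lambda/(k+1)
            log_A = min(700.0, dll) + np.log(lam) - np.log(k + 1)
            if np.log(rng.random()) < log_A:
                qtls.append(_Qtl(qv, av, dv, F, S, lab, g))
                r = r_new
                acc["birth"][0] += 1
    else:
        acc["death"][1] += 1
        if k > 0:
            idx = int(rng.integers(k))
            q = qtls[idx]
            contrib = np.zeros(n)
            for bi, b in enumerate(blocks):
                contrib[b.sl] = q.contrib(bi)
            r_new = r + contrib
            dll = 0.0 if const_lik else (r @ r - r_new @ r_new) / (2.0 * s2)
            # reverse of birth from k-1: death A = LR * k/lambda
            log_A = min(700.0, dll) + np.log(k) - np.log(lam)
            if np.log(rng.random()) < log_A:
                qtls.pop(idx)
                r = r_new
                acc["death"][0] += 1
    return r


# ---------------------------------------------------------------------------
# reporting operations
# ---------------------------------------------------------------------------

def variance_partition(post: SegregationPosterior) -> VariancePartition:
    """Posterior-mean variance shares (percent of total trait variance).

    Covariate shares are the empirical variances of x_j * beta_j over the
    sample, QTL share the empirical variance of the summed QTL
    contributions, and the residual share sigma^2_e — each divided by the
    empirical trait variance and averaged over posterior samples.
    """
    if len(post.k_samples) == 0:
        raise ValueError("empty posterior")
    cov = {name: 100.0 * float(np.mean(post.share_samples[name]))
           for name in post.covariate_names}
    qtl = 100.0 * float(np.mean(post.share_samples["qtl"]))
    res = 100.0 * float(np.mean(post.share_samples["residual"]))
    return VariancePartition(
        covariate_pct=cov, qtl_pct=qtl, residual_pct=res,
        expected_k=post.expected_k,
        heritability_pct=heritability(qtl, res),
    )


def heritability(qtl_pct: float, residual_pct: float) -> float:
    """Heritability as the QTL share of the variance not explained by covariates.

    h2 = 100 * qtl_pct / (qtl_pct + residual_pct), in percent.
    """
    if qtl_pct < 0 or residual_pct < 0:
        raise ValueError("variance shares must be non-negative")
    tot = qtl_pct + residual_pct
    if tot <= 0:
        raise ValueError("qtl and residual shares are both zero")
    return 100.0 * qtl_pct / tot


def per_family_qtl_counts(
    trait: np.ndarray,
    covariates: pd.DataFrame,
    peds: Sequence[Pedigree],
    priors: Priors | None = None,
    settings: McmcSettings | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Expected QTL count per family from independent per-family runs.

    Each family is analyzed separately (its members only); families of
    fewer than 3 members are excluded with a warning.  Every family's chain
    uses the same ``seed``, so families with identical structure and traits
    receive identical counts.
    """
    import warnings

    if len(peds) < 2:
        raise ValueError("need at least 2 families")
    counts: dict[str, float] = {}
    start = 0
    for ped in peds:
        sl = slice(start, start + len(ped))
        start += len(ped)
        if len(ped) < 3:
            warnings.warn(f"family {ped.family_id}: fewer than 3 members, excluded")
            continue
        post = run_segregation(trait[sl], covariates.iloc[sl], [ped],
                               priors=priors, settings=settings, seed=seed)
        counts[ped.family_id] = post.expected_k
    return counts


def excess_qtls(counts: dict[str, float], family: str) -> float:
    """Family's expected QTL count minus the mean count of the other families."""
    if family not in counts:
        raise KeyError(f"unknown family {family!r}")
    if len(counts) < 2:
        raise ValueError("need at least 2 families")
    others = [v for f, v in counts.items() if f != family]
    return counts[family] - float(np.mean(others))


def prioritize_families(counts: dict[str, float], threshold: float = 1.0) -> set[str]:
    """Families estimated to harbor at least ``threshold`` extra QTLs.

    A family is prioritized when its expected QTL count exceeds the average
    of all the other families by at least the threshold (default: one
    additional QTL).
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 families")
    return {f for f in counts if excess_qtls(counts, f) >= threshold}
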