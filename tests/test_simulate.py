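import numpy as np
import pandas as pd
import pytest

from famqtl.pedigree import Pedigree
from famqtl.simulate import (
    SimConfig,
    TraitConfig,
    default_config,
    gene_drop,
    null_config,
    read_study,
    simulate_pedigree,
    simulate_study,
    true_ibd_matrix,
    write_study,
)
from famqtl.simulate import DescentEngine


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSimulatePedigree:
    def test_trio_config(self):
        cfg = SimConfig(n_families=1, family_size_range=(3, 3), n_generations=2,
                        traits=(TraitConfig(name="Q"),))
        ped = simulate_pedigree(cfg, 0, _rng(1))
        assert len(ped) == 3 and len(ped.founder_ids) == 2

    def test_default_size_and_founder_fraction(self):
        cfg = default_config(seed=0)
        ped = simulate_pedigree(cfg, 0, _rng(7))
        assert 73 <= len(ped) <= 128
        assert 0.20 <= len(ped.founder_ids) / len(ped) <= 0.40

    def test_same_seed_identical(self):
        cfg = default_config(seed=0)
        p1 = simulate_pedigree(cfg, 0, _rng(3))
        p2 = simulate_pedigree(cfg, 0, _rng(3))
        assert p1 == p2


class TestGeneDrop:
    def test_no_entering_founders(self, three_gen):
        g, lab = gene_drop(three_gen, set(), _rng(0))
        assert (g == 0).all()

    def test_founder_allele_count_by_construction(self, three_gen):
        for nf in (1, 2):
            founders = sorted(three_gen.founder_ids)[:nf]
            g, _ = gene_drop(three_gen, set(founders), _rng(5))
            founder_rows = [three_gen.index_of(f) for f in three_gen.founder_ids]
            assert sum(g[r] for r in founder_rows) == nf

    def test_non_founder_rejected(self, trio):
        with pytest.raises(ValueError, match="not founders"):
            gene_drop(trio, {"ch"}, _rng(0))

    def test_child_transmission_frequency(self, trio):
        """Het father transmits to the child with frequency 1/2 (binomial)."""
        rng = _rng(11)
        hits = sum(int(gene_drop(trio, {"fa"}, rng)[0][trio.index_of("ch")])
                   for _ in range(10_000))
        assert abs(hits / 10_000 - 0.5) < 0.02

    def test_mendelian_consistency_all_variants(self, default_study):
        s = default_study
        for v in s.variants:
            for ped in s.pedigrees:
                g = v.genotypes[s.family_slice(ped.family_id)]
                for i in range(len(ped)):
                    f, m = ped.father_idx[i], ped.mother_idx[i]
                    if f < 0:
                        continue
                    # each parent transmits at most one copy, and a
                    # homozygous parent always transmits one
                    assert g[i] <= int(g[f] >= 1) + int(g[m] >= 1)
                    assert g[i] >= int(g[f] == 2) + int(g[m] == 2)

    def test_segregation_occurs(self, three_gen):
        """1-founder drops carry to a variable, nonzero number of members."""
        rng = _rng(2)
        founder = sorted(three_gen.founder_ids)[0]
        counts = np.array([(gene_drop(three_gen, {founder}, rng)[0] > 0).sum()
                           for _ in range(1000)])
        assert counts.mean() >= 1.0
        assert counts.var() > 0


class TestTrueIbd:
    def test_founder_pair_and_parent_offspring(self, three_gen):
        g, lab = gene_drop(three_gen, set(), _rng(0))
        pi = true_ibd_matrix(lab)
        i = three_gen.index_of
        assert pi[i("gp1"), i("gp2")] == 0.0
        assert pi[i("gp1"), i("s1")] == 0.5          # forced parent-offspring sharing
        assert pi[i("gp1"), i("gp1")] == 1.0

    def test_expected_sharing_equals_twice_kinship(self, three_gen):
        """E[Pi(i,j)] over repeated drops = 2 phi(i,j) (kinship oracle)."""
        phi = three_gen.kinship_matrix()
        eng = DescentEngine(three_gen)
        rng = _rng(8)
        acc = np.zeros((len(three_gen), len(three_gen)))
        n_drops = 10_000
        for _ in range(n_drops):
            acc += true_ibd_matrix(eng.labels(eng.random_segregation(rng)))
        np.testing.assert_allclose(acc / n_drops, 2 * phi, atol=0.02)


class TestStudy:
    def test_truth_lists_configured_functional_variants(self, default_study):
        ids = {v["variant_id"] for v in default_study.truth["functional_variants"]}
        assert ids == {"V_Q1_F7A", "V_Q1_F7B", "V_Q1_SH", "V_Q2_F7", "V_Q2_SH"}
        counts = default_study.truth["per_family_qtl_counts"]
        assert counts["Q1"]["7"] == 3
        assert all(counts["Q1"][f] == 1 for f in counts["Q1"] if f != "7")

    def test_private_variants_trace_to_recorded_founder(self, default_study):
        s = default_study
        for tv in s.truth["functional_variants"]:
            if tv["family"] is None:
                continue
            fam = tv["family"]
            g = s.variant(tv["variant_id"]).genotypes[s.family_slice(fam)]
            ped = s.pedigree(fam)
            founder_carriers = {ped.members[i].id for i in range(len(ped))
                                if g[i] > 0 and ped.members[i].is_founder}
            assert founder_carriers == set(tv["entering_founders"][fam])

    def test_determinism(self):
        s1 = simulate_study(null_config(seed=9))
        s2 = simulate_study(null_config(seed=9))
        np.testing.assert_array_equal(s1.traits["Q1"], s2.traits["Q1"])
        assert [v.variant_id for v in s1.variants] == [v.variant_id for v in s2.variants]
        np.testing.assert_array_equal(s1.variants[0].genotypes,
                                      s2.variants[0].genotypes)

    def test_trait_regression_recovers_effect(self):
        """OLS on the truth genotypes recovers a configured additive effect."""
        import statsmodels.api as sm

        cfg = default_config(seed=5)
        s = simulate_study(cfg)
        sl = s.family_slice("7")
        y = s.traits["Q1"][sl]
        X = np.column_stack([
            s.variant("V_Q1_F7A").genotypes[sl],
            s.variant("V_Q1_F7B").genotypes[sl],
            s.variant("V_Q1_SH").genotypes[sl],
            s.covariates["age"].to_numpy()[sl],
            s.covariates["smoking"].to_numpy()[sl],
        ]).astype(float)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        assert abs(fit.params[1] - 2.8) < 3 * fit.bse[1]
        assert abs(fit.params[2] - 1.6) < 3 * fit.bse[2]

    def test_null_trait_mean(self):
        cfg = null_config(seed=3)
        s = simulate_study(cfg)
        y = s.traits["Q1"]
        resid = y - y.mean()
        assert abs(resid.mean()) < 4 * y.std() / np.sqrt(len(y))

    def test_variance_decomposition_matches_configuration(self):
        """Empirical Var(sum Q a)/Var(Y) tracks the genetic share implied by
        the realized genotypes and the configured residual SD (n >= 500)."""
        cfg = default_config(seed=2)
        s = simulate_study(cfg)
        assert len(s.individuals) >= 500
        contrib = np.zeros(len(s.individuals))
        for tv in s.truth["functional_variants"]:
            if tv["trait"] != "Q1":
                continue
            g = s.variant(tv["variant_id"]).genotypes.astype(float)
            contrib += tv["additive"] * (g - 1.0)
        y = s.traits["Q1"]
        cov = s.covariates
        fixed = (0.1 * cov.sex + 0.02 * (cov.age - 50) + 0.5 * cov.smoking).to_numpy()
        expected_share = contrib.var() / (contrib.var() + fixed.var() + 1.0)
        observed_share = contrib.var() / y.var()
        assert abs(observed_share - expected_share) < 0.05


class TestRoundTrip:
    def test_write_read_preserves_genotypes_and_traits(self, tmp_path):
        s = simulate_study(null_config(seed=4))
        write_study(s, tmp_path / "study")
        back = read_study(tmp_path / "study")
        assert back.individuals == s.individuals
        assert [p.family_id for p in back.pedigrees] == [p.family_id for p in s.pedigrees]
        for v1, v2 in zip(s.variants, back.variants):
            assert v1.variant_id == v2.variant_id
            np.testing.assert_array_equal(v1.genotypes, v2.genotypes)
        np.testing.assert_allclose(back.traits["Q1"], s.traits["Q1"])
        for fam in s.family_ids:
            for gene in list(s.descent[fam])[:3]:
                np.testing.assert_array_equal(back.descent[fam][gene],
                                              s.descent[fam][gene])

    def test_vcf_allele_counts_match(self, tmp_path):
        s = simulate_study(null_config(seed=4))
        write_study(s, tmp_path / "study")
        n_alt = 0
        with open(tmp_path / "study" / "study.vcf") as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                n_alt += line.count("0/1") + 2 * line.count("1/1")
        assert n_alt == sum(int(v.genotypes.sum()) for v in s.variants)

    def test_truth_json_written(self, tmp_path):
        import json

        s = simulate_study(default_config(seed=4))
        write_study(s, tmp_path / "study")
        with open(tmp_path / "study" / "truth.json") as fh:
            truth = json.load(fh)
        assert {v["variant_id"] for v in truth["functional_variants"]} == \
            {v["variant_id"] for v in s.truth["functional_variants"]}


class TestDescentProperties:
    """Structural Mendelian properties of the descent engine."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _random_pedigree(n_extra, seed):
        from famqtl.pedigree import Individual, Pedigree

        rng = np.random.default_rng(seed)
        mem = [Individual("f0", None, None, "male", "H"),
               Individual("m0", None, None, "female", "H")]
        males, females = ["f0"], ["m0"]
        for i in range(n_extra):
            if rng.random() < 0.35:  # marry-in founder
                sex = "male" if rng.random() < 0.5 else "female"
                iid = f"x{i}"
                mem.append(Individual(iid, None, None, sex, "H"))
            else:
                fa = males[int(rng.integers(len(males)))]
                mo = females[int(rng.integers(len(females)))]
                sex = "male" if rng.random() < 0.5 else "female"
                iid = f"c{i}"
                mem.append(Individual(iid, fa, mo, sex, "H"))
            (males if mem[-1].sex == "male" else females).append(mem[-1].id)
        return Pedigree("H", mem)

    @given(st.integers(3, 25), st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_child_labels_come_from_parents(self, n_extra, seed):
        ped = self._random_pedigree(n_extra, seed)
        eng = DescentEngine(ped)
        rng = np.random.default_rng(seed + 1)
        lab = eng.labels(eng.random_segregation(rng))
        for i in range(len(ped)):
            f, m = ped.father_idx[i], ped.mother_idx[i]
            if f < 0:
                continue
            assert lab[i, 0] in lab[f]
            assert lab[i, 1] in lab[m]

    @given(st.integers(3, 20), st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_ibd_matrix_symmetric_bounded(self, n_extra, seed):
        ped = self._random_pedigree(n_extra, seed)
        eng = DescentEngine(ped)
        rng = np.random.default_rng(seed + 2)
        pi = true_ibd_matrix(eng.labels(eng.random_segregation(rng)))
        assert np.allclose(pi, pi.T)
        assert pi.min() >= 0.0 and pi.max() <= 2.0
        assert set(np.unique(pi * 2).astype(int)) <= {0, 1, 2, 3, 4}
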