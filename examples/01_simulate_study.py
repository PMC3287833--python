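"""Generate the default eight-family synthetic study and look at its truth.

The generator builds extended pedigrees (73-128 members, founders marrying
in at every generation), drops rare variants in through founders with the
descent recorded, and simulates two quantitative traits under the
oligogenic linear model Y = mu + X beta + sum_i Q_i alpha_i + e.  Family
"7" privately carries two large-effect variants for trait Q1 and one for
trait Q2.
"""

from famqtl import default_config, simulate_study

study = simulate_study(default_config(seed=1))

print(f"{len(study.pedigrees)} families, {len(study.individuals)} individuals, "
      f"{len(study.variants)} variants")
for ped in study.pedigrees:
    print(f"  family {ped.family_id}: {len(ped)} members, "
          f"{len(ped.founder_ids)} founders")

print("\nfunctional variants (truth record):")
for tv in study.truth["functional_variants"]:
    g = study.variant(tv["variant_id"]).genotypes
    where = f"private to family {tv['family']}" if tv["family"] else "shared"
    print(f"  {tv['variant_id']} ({tv['trait']}, gene {tv['gene']}): "
          f"a={tv['additive']}, {where}, {int(g.sum())} copies overall")

print("\ntrue QTL counts per family:", study.truth["per_family_qtl_counts"]["Q1"])
# The per-family counts are what the segregation analysis must recover:
# family 7 harbors 3 Q1 loci (2 private + 1 shared), every other family 1.
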