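"""Kaplan-Meier survival stratified by upregulation of a single gene.

In the synthetic cohort, carriers of the third planted gene have a 3x death
hazard.  Cases are dichotomized at z >= 2 for that gene and the two strata
compared with the log-rank test.
"""

import orscreen as ors

bundle, truth = ors.generate_cohort(ors.three_subpop_config(), seed=7)
counts, _ = ors.align_genes(bundle.counts, bundle.annotation)
expr = ors.log2_transform(ors.compute_fpkm(counts, bundle.annotation))
family = list(bundle.annotation.index[bundle.annotation["family"] == "OR"])
result = ors.run_screen(expr, bundle.cna, family)

gene = truth.hazard_gene
comp = ors.stratify_by_gene(result.zscores, gene, bundle.clinical)
up, rest = comp.curves["upregulated"], comp.curves["not_upregulated"]

print(f"stratified by {gene} (z >= 2):")
print(f"  upregulated     n={up.n:3d}  events={up.n_events:3d}  "
      f"S(120 mo)={up.probability_at(120):.2f}")
print(f"  not upregulated n={rest.n:3d}  events={rest.n_events:3d}  "
      f"S(120 mo)={rest.probability_at(120):.2f}")
print(f"  log-rank chi-square = {comp.chi_square:.2f}, p = {comp.p_value:.2e}")

# compare with a gene that carries no hazard link
control = truth.planted_genes[0]
comp0 = ors.stratify_by_gene(result.zscores, control, bundle.clinical)
c_up = comp0.curves["upregulated"]
print(f"\ncontrol gene {control}: chi-square = {comp0.chi_square:.2f}, "
      f"p = {comp0.p_value:.3f}, S(120 mo) upregulated = "
      f"{c_up.probability_at(120):.2f}")

# The hazard-linked gene's carriers sit well below the rest of the cohort.
# The control gene can still reach nominal significance in the opposite
# direction: its carriers are disjoint from the hazard carriers, so the
# "upregulated" stratum is depleted of high-risk cases — a reminder that
# single-gene survival splits inherit the cohort's carrier structure.
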