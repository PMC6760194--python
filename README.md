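# orscreen

Reference-anchored screening for ectopically over-expressed gene-family
members in tumor cohorts.

Large gene families that are silent in most healthy tissues — the olfactory
receptor (OR) family is the motivating case — are sometimes switched on in
tumors.  `orscreen` implements a complete, tested pipeline for finding the
family members that matter in a cohort: it quantifies expression (FPKM,
log2), anchors every gene to a small normal-tissue reference panel through
z-scores

```
Z_ij = (X_ij - X̄_i) / σ_i
```

(`X_ij`: log2 FPKM of gene *i* in tumor *j*; `X̄_i`, `σ_i`: mean and SD over
the reference panel), accumulates per-gene burden statistics over the
cohort of patients with any family-gene upregulation

```
sum_i      = Σ_j Z_ij          n_i = #{ j : Z_ij ≥ 2 }
weighted_i = n_i · sum_i       prevalence_i = n_i / N
```

and calls a gene **over-expressed** when its statistics exceed the family-
wide upper-tail thresholds (mean + 1.6449·SD, both selection parts) *and*
the gene carries a high-level copy-number amplification call (GISTIC 2) in
at least one tumor.  Downstream, positive cases are clustered into
sub-populations (Ward/Euclidean), compared on clinical panel genes
(Oncotype DX, PAM50; one-way ANOVA), and stratified for survival
(Kaplan-Meier + log-rank).  A synthetic-cohort generator with recorded
ground truth backs every test.

Intended users: computational biologists reproducing or extending
family-wide over-expression screens on cohort data (counts + GISTIC calls +
clinical tables, the cBioPortal/GDC export shapes).

## Worked example

```python
import orscreen as ors

bundle, truth = ors.generate_cohort(ors.three_subpop_config(), seed=7)
counts, _ = ors.align_genes(bundle.counts, bundle.annotation)
expr = ors.log2_transform(ors.compute_fpkm(counts, bundle.annotation))
family = list(bundle.annotation.index[bundle.annotation["family"] == "OR"])

result = ors.run_screen(expr, bundle.cna, family)
print(sorted(result.overexpressed_genes))   # ['ORS001', 'ORS002', 'ORS003']
```

Running `python examples/01_run_screen.py` prints:

```
screened family genes : 14 of 408 (394 lack reference variance)
thresholds            : sum 52.6, count 8.2, weighted 2904.0
part 1 (sum & weighted)  : ['ORS001', 'ORS002', 'ORS003']
part 2 (count & weighted): ['ORS001', 'ORS002', 'ORS003']
amplified (call = 2)     : 19 genes
over-expressed           : ['ORS001', 'ORS002', 'ORS003']
planted truth            : ['ORS001', 'ORS002', 'ORS003']
cases with over-expressed upregulation: 151
```

The three genes planted with a 6-SD shift in 20% of patients each (plus
matching amplification calls) are recovered exactly; the 16 decoy
amplifications on silent genes and the remaining family genes are rejected.
Most family genes "lack reference variance": they are at the detection
limit in the 4-sample normal panel and cannot be z-scored — they still
anchor the family-wide thresholds as zero-burden genes.

The other examples continue the analysis: `02_subpopulations.py` clusters
the 151 positive cases into three sub-populations, each defined by one gene
(the basal-linked one collects 67% Basal-subtype cases);
`03_panel_comparison.py` shows proliferation markers peaking in
sub-population I and invasion markers in III; `04_survival.py` finds the
hazard-linked gene's carriers at S(120 mo) = 0.25 versus 0.58 for everyone
else (log-rank p ≈ 6e-7); `05_simulate_fixtures.py` writes the canonical
fixture bundles as plain TSV.

Real data enters through the same door: `read_count_matrix`,
`read_cna_matrix`, `read_clinical`, `read_annotation`, `read_mutations`
consume tab-separated exports, and everything downstream is identical.

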