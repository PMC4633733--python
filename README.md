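# lscsig

Leukaemia stem cells (LSCs) — the engrafting fraction of an acute myeloid
leukaemia (AML) — differ from their non-engrafting blast progeny mainly
epigenetically, since the two are clonally related. `lscsig` implements the
analysis stack used to characterize that difference from 450k-style DNA
methylation arrays and expression microarrays:

- **Bump-hunting DMR calling.** Per-probe mean beta-value differences
  (group 1 − group 2) are smoothed within probe clusters (gap ≤ `maxgap`)
  and maximal runs with |smoothed difference| > 0.1 become candidate
  differentially methylated regions (DMRs) scored by their area
  A(r) = Σᵢ |smoothed diffᵢ|. Significance comes from label permutations
  with group sizes preserved:
  p(r) = (1 + #{null regions with area ≥ A(r)}) / (1 + #null regions), and a
  family-wise error rate from the per-permutation maximum null area. Small
  designs switch automatically to exhaustive enumeration.
- **Signature integration.** A DMR–gene pair enters the LSC epigenetic
  signature when the DMR has permutation p < 0.01, overlaps the ±2 kb
  promoter window of the gene's TSS, the gene moves by > 0.5 log₂ between
  groups, and methylation and expression move inversely (hypomethylated ⇒
  upregulated). Multiple DMRs per gene are numbered `GENE/DMR1`, `GENE/DMR2`
  … by coordinate.
- **Mutation association.** DMR sets from wild-type-vs-mutant comparisons
  (e.g. *NPM1*, *ASXL1* upstream regulators; *DNMT3A*, *TET2* enzymes)
  classify each signature DMR as upstream-associated, enzyme-associated,
  both, or mutation-independent, with χ² overlap-enrichment tests against a
  non-overlapping array background.
- **Cell identity.** Each reference class c (LSC/Blast, or the six normal
  progenitors HSC, MPP, L-MPP, CMP, GMP, MEP) is summarized per region d by
  (μ_dc, σ_dc) over its reference samples; a query sample x is assigned to
  argmax_c Σ_d log N(x_d; μ_dc, σ_dc). Also here: the LSC expression score
  (PC1 of signature-gene expression, median-split into high/low), classical
  MDS of the top-variance probes, and Ward clustering with a length-matched
  random-region specificity control.
- **Survival.** Kaplan–Meier curves with log-rank tests and multivariate Cox
  models (age continuous, cytogenetic risk dummy-coded intermediate/high vs
  low, mutations 0/1), via lifelines.
- **Synthetic data.** A seeded generator produces beta matrices with CpG
  island/shore/shelf/open-sea strata, planted multi-probe DMRs (~91:9
  hypo:hyper in LSC), inverse promoter methylation–expression coupling,
  mutation-driven region subsets, six-progenitor reference profiles with
  GMP-like/L-MPP-like cohort clusters, and survival times driven by a latent
  LSC score — plus ground-truth tables for scoring.

## Worked example

```python
from lscsig import (BumpHunter, build_signature, differential_expression,
                    generate_manifest, generate_two_group_study, summarize_dmrs)
from lscsig.signature import signature_frame

manifest, islands, genes = generate_manifest(n_probes=6000, seed=7)
beta, expr, samples, truth = generate_two_group_study(
    manifest, islands, genes, n_planted=60, seed=7)
lsc = samples.loc[samples.group == "LSC", "sample_id"].tolist()
blast = samples.loc[samples.group == "Blast", "sample_id"].tolist()

result = BumpHunter(beta, manifest, lsc, blast, cutoff=0.1).fit(
    n_permutations=250, seed=7)
called = result.significant(0.01)
print(summarize_dmrs(called).to_string(index=False))

signature = build_signature(called, differential_expression(expr, lsc, blast),
                            genes)
print(signature_frame(signature).head(5).to_string(index=False))
```

Output:

```
 n_dmrs  n_group1_gt  n_group2_gt  pct_hypo_group1  pct_hypo_group2  pct_island  pct_shore  pct_shelf  pct_open_sea
     48            3           45             93.8              6.2        52.1        0.0        0.0          47.9
    gene     dmr_label context  delta_beta   p_perm    log2fc  direction
GENE0018 GENE0018/DMR1  island   -0.278772 0.000529  1.069051    hypo_up
GENE0036 GENE0036/DMR1  island    0.255068 0.000529 -0.865358 hyper_down
GENE0038 GENE0038/DMR1  island   -0.232341 0.000529  0.841660    hypo_up
GENE0045 GENE0045/DMR1  island   -0.213463 0.000529  0.840882    hypo_up
GENE0052 GENE0052/DMR1  island   -0.212250 0.000529  0.833353    hypo_up
```

48 regions pass permutation p < 0.01; 93.8% are hypomethylated in the LSC
group (group 1), matching the planted hypo:hyper mix. Against the ground
truth this call set has sensitivity 0.80 at empirical FDR 0.00
(`truth.score_calls(called)`). The signature retains 17 DMR–gene pairs over
17 unique genes: promoter DMRs whose genes shifted > 0.5 log₂ in the inverse
direction.

The same flow is available from the shell:

```sh
lscsig simulate --n-probes 6000 --n-planted 60 --seed 7 --outdir demo
lscsig call-dmrs --beta demo/beta.tsv --manifest demo/manifest.tsv \
    --samples demo/samples.tsv --group-a LSC --group-b Blast \
    --perms 250 --seed 7 --outdir demo
lscsig run --seed 7 --outdir demo_full    # full pipeline + run manifest
```

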