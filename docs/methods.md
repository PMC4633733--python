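# Methods

## Region calling

Methylation is represented as beta values β ∈ [0, 1] (methylated / total
signal) in a probes × samples matrix. The caller compares two disjoint
sample groups (≥ 2 each):

1. **Per-probe difference.** d_i = mean β in group 1 − mean β in group 2.
2. **Clustering.** Probes sorted by (chromosome, position) are clustered
   greedily: a gap > `maxgap` (default 500 bp) or a chromosome change starts
   a new cluster. Clusters never span chromosomes.
3. **Smoothing.** Within each cluster of ≥ 3 probes, d is replaced by the
   running mean over probes within ± `smooth_window` (default 1,000 bp) of
   each probe; clusters of 1–2 probes pass through unsmoothed. A running
   mean cannot change the sign of a constant-sign cluster and leaves
   constants fixed.
4. **Candidate regions.** Maximal runs of consecutive probes in one cluster
   with smoothed d > +cutoff (or < −cutoff; default cutoff 0.1, i.e. a 10%
   methylation difference) form regions. A sign change splits a run. Each
   region carries value = mean smoothed d, area = Σ|smoothed d|, and a
   direction fixed by the sign of its value.
5. **Permutation inference.** The pooled sample labels are permuted B times
   (default 250) with group sizes preserved and steps 1–4 re-run per
   permutation. With N null regions pooled over permutations,
   p(r) = (1 + #{null areas ≥ area(r)}) / (1 + N), which is monotone in
   area and never exactly zero; FWER(r) = (1 + #{permutations whose maximum
   null area ≥ area(r)}) / (1 + B). When C(n, n₁) ≤ B, every label
   assignment is enumerated instead (logged); the observed assignment is
   included in the enumeration.

Downstream analyses use permutation p < 0.01; Benjamini–Hochberg adjusted
values are attached for reference (at the defaults, the p < 0.01 set
corresponds to BH-adjusted values well below 0.1). The cross-progenitor DMR
panel uses the stricter FWER < 0.1.

Two properties of the pooled-null estimator matter in practice. Its
resolution is 1/(1 + N): sparse, nearly noise-free arrays yield few null
regions and hence a coarse p-value grid. And permutations of data containing
real signal redistribute that signal into the null, so the null's upper tail
grows with the fraction of probes inside true regions. Both effects are
visible in the synthetic experiments below and shaped the default noise
level and the study designs (signal fractions of a few percent, as on real
arrays).

## Signature integration

CpG context is assigned from a merged island track: inside an island →
island; within 2 kb of an island edge → shore; 2–4 kb → shelf; otherwise
open sea. A region maps to a gene as *promoter* when it overlaps
[TSS − 2 kb, TSS + 2 kb] (symmetric, strand-ignorant — the window is wide
enough that sidedness is second-order) and as *gene body* when it overlaps
the gene span but not the promoter window; gene-body mappings are excluded
from the signature, per mapping rather than per region, so a region that is
promoter for one gene still counts for that gene. A signature entry requires
permutation p < 0.01, promoter overlap, |log₂ expression ratio| > 0.5, and
an inverse methylation–expression relation (signs of the region's value and
the gene's log₂ ratio opposite, both oriented group 1 − group 2). Region-
level β is the unweighted mean over member probes everywhere in the package.
Per-gene DMR ordinals are assigned by genomic coordinate.

## Mutation association

For each mutation, a wild-type vs mutant DMR comparison (same caller, same
defaults) yields a mutation DMR set; a signature region overlapping any
upstream-regulator set only is *upstream*, any enzyme set only is *enzyme*,
at least one of each is *both*, none is *independent*. The four counts
partition the signature. Overlap defaults to ≥ 1 shared probe
(`overlap_rule="probe"`); bp-overlap is available. Enrichment between two
region sets uses the 2×2 table {overlap, a-only, b-only, background-only}
with a Pearson χ² (df = 1, no continuity correction, upper-tail p), where
the background regions must not overlap either set; p below 2.2 × 10⁻¹⁶ is
additionally reported with the conventional "< 2.2e-16" string.

## Cell identity

Reference class profiles store, per region, the mean and the n−1 standard
deviation of region-level β across that class's reference samples (≥ 2
required), with the sd floored at `sd_floor` = 0.01 so a low-variance region
cannot dominate the score with a near-singular density. A query sample's
class score is the summed Gaussian log density across the panel; the argmax
class is assigned, ties broken by profile order with a warning. The floor
value is small relative to real between-donor variation and only binds for
degenerate references.

The LSC expression score is the first principal component of the per-gene
centred signature-gene expression; since an eigenvector's sign is arbitrary,
the score is oriented so it correlates positively with the mean expression
of the LSC-up genes, making the high/low median split stable. Ties at the
median go to "low"; the strata differ in size by at most one.

Ordination uses classical multidimensional scaling (double-centred
eigendecomposition of squared Euclidean distances, the cmdscale algorithm)
on the k = 1,000 most variable probes after removing SNP-flagged probes.
Clustering is Ward linkage on Euclidean distances of region-level β, cut to
a requested number of clusters; the specificity control rebuilds the panel
from length-matched random regions (identical per-region probe-count
multiset, drawn from probes outside the panel) and expects the cluster
structure to vanish.

## Survival

Overall survival uses product-limit estimates with two-sided log-rank tests,
and Cox proportional-hazards fits with Efron handling of ties (the lifelines
default). Covariate coding: the two-level stratum as an indicator (high = 1
vs low, or LSC-like = 1), age continuous in years, cytogenetic risk as two
dummies (intermediate vs low, high vs low), mutations present/absent. A
constant covariate is a hard error; fewer events than covariates + 5 logs a
warning. The per-gene survival association used in the expression–survival
correlation is the univariate Cox coefficient of standardized expression
(positive = higher expression, worse survival), correlated with the per-gene
log₂ expression differences by Pearson's r with a t-based p.

## Synthetic data

The generator emulates the data shapes the analysis assumes, not array
chemistry. A manifest of `n_probes` probes is organized in gene units 50 kb
apart on ≥ 2 chromosomes; each unit has a CpG island around the TSS
containing a promoter probe cluster, shore and shelf probes flanking it, an
open-sea gene-body cluster beyond 2 kb of the TSS, and isolated open-sea
probes. Cluster sizes are uniform on 3–8 probes, which is also the planted
region width: planted DMRs occupy whole clusters, since a region narrower
than its cluster would be averaged below the cutoff by the 1 kb smoother.

Noise is Gaussian on logit(β) (β clipped to [0.001, 0.999] before the
logit), which keeps β in range by construction. The default sd of 0.5
corresponds to a beta-scale sd of ≈ 0.12 at intermediate methylation —
between-patient biological variation of primary AML samples rather than
technical replicate noise. Baseline probe means are drawn per context
(islands low, open sea high); planted probes use mid-range baselines so a
± Δβ/2 shift per group stays in [0, 1]. Direction (default 91.4%
hypomethylated in LSC), mutation-driver categories (independent 0.48,
upstream 0.20, enzyme 0.19, both 0.13) and cohort cluster mix (GMP 0.77,
L-MPP 0.15, CMP 0.08) are allocated exactly by largest remainder, so counts
are deterministic given the totals. Coupled planted promoter regions shift
the mapped gene's expression by 1 log₂ (default) in the inverse direction
for the LSC group; expression noise is Gaussian on the log₂ scale (sd 0.5).

Mutation effects live in a separate cohort generated on the same manifest
(`generate_mutation_cohort`): each mutation gene gets exactly half carriers,
and regions it drives (per the truth's driver labels) differ by 0.25 β
between carriers and wild type. Keeping genotype effects out of the
two-group discovery matrices mirrors the real design — the signature comes
from an engraftment-sorted cohort, mutation contrasts from an independent
clinical cohort — and keeps the discovery permutation null clean.

The reference/cohort generator plants, per class, `markers_per_class`
marker regions shifted by ± 0.3; cohort samples are drawn from class
profiles per the cluster mix, with a latent LSC score (higher in the
L-MPP-like cluster) that drives exponential survival times through
log-hazard = log(baseline) + coefficient × score, with independent
exponential censoring, and drives signature-gene expression through random
loadings. Covariates (age, cytogenetic risk, *NPM1*/*FLT3*/*DNMT3A*
genotypes) associate with cluster membership but not directly with the
hazard. A simpler two-arm cohort (`simulate_survival_cohort`) plants an
exact hazard ratio for parameter-recovery checks, with covariates
independent of the hazard so any of them is a valid null covariate.

What the generator does **not** emulate: probe cross-hybridization, type
I/II probe chemistry, batch effects, copy-number-driven β distortion,
patient-level correlation between multiple sorted fractions, or non-
proportional hazards. Passing tests therefore demonstrate the correctness
and calibration of the algorithms under the stated statistical structure,
not robustness to those artefacts.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale designs chosen to
preserve the statistical regime of the real data: planted-recovery at
10,000 probes, 20 vs 24 samples, 200 planted regions, Δβ = 0.2, B = 250;
null calibration over 20 seeds at 3,000 probes; signature recovery at
15,000 probes with 40 planted regions (a ~1% signal fraction, comparable to
real arrays — at much higher signal fractions the permutation null's upper
tail is dominated by redistributed signal and narrow regions become
unrankable, an estimator property discussed above); classifier and survival
cohorts of 500. One global seed derives per-stage child seeds by stable
hashing (`child_seed`), so every pipeline stage is reproducible bit-for-bit
given its inputs; exhaustive-enumeration p-values are fully deterministic.

## Known limitations

- Permutation is unrestricted: when several fractions per patient are
  present, labels are not blocked by patient. Blocked permutation would
  require a patient structure the inputs do not currently carry.
- The pooled-null p-value shares granularity across regions; on arrays with
  very few null bumps the smallest attainable p may exceed 0.01.
- The χ² enrichment test treats regions as exchangeable units and ignores
  region length beyond the length-matched background construction.
- The log-density classifier assumes independent Gaussian region-level β
  given the class; correlated regions make scores overconfident, which
  affects margins but rarely argmax assignments.
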