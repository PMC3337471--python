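# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Models

### Animal model and mixed-model equations

All BLUP-family predictors fit the single-trait animal model
y = 1μ + Zu + e with var(e) = R = σ²e W⁻¹ (W a diagonal matrix of record
weights, identity unless de-regressed responses are used) and
var(u) = K σ²A, where K is A (pedigree BLUP), H (single-step), or G
(GBLUP oracle). Variance components are inputs — production estimates or
simulator truth — and are never re-estimated; this mirrors how routine
evaluations run and keeps every solver a linear solve. The mixed-model
equations are built dense and solved by Cholesky factorization; when
prediction error variances are requested the full inverse of the
coefficient matrix is formed (exactness over speed at desk scale — the
dense guard rejects pedigrees beyond ~12,000 animals). Reliability is
r² = 1 − PEV/σ²A clipped to [0, 1]; pre-clip violations are counted on the
result object rather than silently hidden.

### Relationship matrices

A uses the tabular recursion with inbreeding (a_ii = 1 + F_i,
F_i = a(s,d)/2); A⁻¹ is assembled by Henderson's rules using those F.
G = ZZ′/(2Σp(1−p)) with Z the dosage matrix centered at 2p. Base
frequencies default to the observed frequencies of the genotyped set —
the only frequencies recoverable from a distributed genotype file. The
combined inverse is H⁻¹ = A⁻¹ + [G*⁻¹ − A₂₂⁻¹] on the genotyped block
with G* = (1−w)G + wA₂₂; blending weight w defaults to 0.05, enough to
keep G* invertible when markers are fewer than animals. No further
scaling of G toward A₂₂ (mean adjustment) is applied; the switch exists
but defaults off because the evaluation it reproduces did not describe
one. The GBLUP surface is solved in the invert-free dual form
u = σ²A G V⁻¹(y − μ̂), V = GσA² + R, so it stays exact for rank-deficient
G.

### BayesB

The marker model is yᵢ = μ + Σⱼ zᵢⱼ aⱼ δⱼ + eᵢ, P(δⱼ = 0) = π, with
per-marker variance σ²ⱼ ~ scaled-inv-χ²(ν, S²) when δⱼ = 1. The sampler
is the classical Gibbs scheme with an independence Metropolis–Hastings
step for each (δⱼ, σ²ⱼ): the proposal is the prior (so the acceptance
ratio reduces to the integrated likelihood ratio, computed in O(1) per
proposal after one O(n) dot product per marker), followed by a normal
draw of aⱼ when σ²ⱼ > 0. Defaults: π = 0.95, ν = 4.2, S² chosen so the
expected genic variance (1−π)·Σ2pq·E[σ²ⱼ] matches σ²A, 10 MH cycles per
marker per iteration, chain 10,000 with 2,000 burn-in and thinning 10.
The study driver uses shorter desk-scale chains (1,500/300, thin 5),
which posterior-mean summaries at ~1,000 markers tolerate well — the
ridge-equivalence test bounds the Monte-Carlo error directly. A
common-variance mode pins all σ²ⱼ to σ²A/Σ2pq and skips the mixture
update; this is exactly Bayesian SNP-BLUP and is used as the equivalence
oracle against GBLUP and closed-form ridge, never as the implementation
under test. Residual weights enter every inner product, so de-regressed
responses use their information weights. The kernel is compiled with
numba; the chain is deterministic given its seed.

### De-regression

dEBV = pEBV/r², weight w = (1−h²)/((c + (1−r²)/r²)h²) with c = 0.5 (the
fraction of genetic variance assumed uncaptured by markers) and animals
below r² = 0.05 excluded rather than down-weighted. At r² = 1 with c = 0
the weight is unbounded and is capped at 20. Parent-average subtraction
is omitted (a documented switch-off): the simulator's pEBV are
single-trait full-data evaluations and the validation designs compare
methods, not absolute bias. The de-regression is checked by the
regression of dEBV on simulated TBV having slope 1 — the direction in
which BLUP theory makes the de-regressed record unbiased; the reverse
regression has slope r² by construction and is not a calibration check.

## Validation harness

Balanced k-fold assignment (default 6) by random permutation; every
animal validates exactly once. The per-fold, per-trait validation subset
is the top 75 by pEBV accuracy, ties broken by animal id for determinism.
Strata: P / O / PO / N by parent/offspring links into the training set
(grandparents never count; P optionally splits into 1P/2P), and bins of
the per-animal count of genomic coefficients with training animals
strictly above 0.45 (default bin edges 0, 1, 2–5, 6–10, >10). Accuracy is
the unweighted product-moment correlation of gEBV with pEBV; on synthetic
data the correlation with true breeding values and the TBV-on-gEBV slope
are reported alongside, and the trend checks in the test suite use the
TBV-based accuracy because the pEBV's own information content varies by
trait and stratum and would confound between-group comparisons. The
young-animal design holds out genotyped animals with no offspring link
anywhere in the pedigree; traits whose top-30 evaluation subset has mean
pEBV accuracy below 0.6 are flagged excluded (configurable — young
animals' EBV carry too little information to stand in for true merit
there).

## Synthetic-data generator

The simulator emulates the data a nucleus-line genomic evaluation sees:

* **Pedigree** — discrete litters with overlapping generations: each
  generation draws a small sire team (default 7) from the previous two
  generations' males, nine dams per sire, litters of six with alternating
  sex. This concentrates paternal half-sib families the way nucleus
  breeding does. Defaults give ~1,600 animals over four generations.
* **Genotypes** — gene drop of founder alleles with unlinked loci;
  founder frequencies Uniform(0.05, 0.5) (post-QC chips carry no
  near-zero-MAF markers). Dosages are masked missing at rate 0.005
  (sub-1% as in real chip data). Sex-chromosome SNP exist only as labels
  to exercise the exclusion filter.
* **Traits** — five traits with h² = (0.07, 0.16, 0.38, 0.58, 0.62) and
  additive variances (0.22, 2.11, 0.66, 4.93, 3459.09); 100 QTL per trait
  sampled among the simulated SNP, effects rescaled so var(TBV) equals
  σ²A exactly; phenotypes are TBV plus normal noise on the corrected
  scale (mean ≈ 0). All traits are simulated as own-performance records —
  the progeny-mean construction of the two low-h² traits in real
  production data is not emulated, and their pEBV accuracy distribution
  is correspondingly narrower than a progeny-test would give.
* **pEBV** — per-trait pedigree BLUP on all phenotyped animals with PEV
  from the full inverse, the production-run analogue; accuracies spread
  widely with few animals above 0.9.
* **Genotyping strategy** — animals are genotyped with role-dependent
  probabilities (sires 0.65, dams 0.45, others 0.55), reproducing the
  overlap structure in which most animals have a genotyped sire and many
  have genotyped offspring.

What the generator does **not** model: linkage and LD (the downstream
methods consume dosages only, and marker order carries no information),
selection across generations, crossbreeding, genotyping error, and real
environmental correction. Passing trend tests therefore demonstrates the
machinery and the relatedness logic under idealized inheritance, not
performance on data with LD structure or selection-induced disequilibrium.

One global seed drives named substreams per operation (pedigree,
genotypes, missingness, phenotypes, genotyping, folds, chains), so any
stage reruns identically regardless of what other stages consumed.

## Numerical and design choices

* QC inequalities are strict as specified (MAF < 0.001 and < 0.02,
  missingness > 10%, χ² > 300); drop reasons follow the precedence
  chrom > missing > maf > chi2 so each SNP reports one reason. Fractional
  dosages are rounded half-up to genotype classes for the Hardy–Weinberg
  count; monomorphic SNP get χ² = 0.
* Imputation is a single, non-iterative pass: each missing cell receives
  the sum of parental transmitted-allele probabilities (dosage/2 per
  genotyped parent, population frequency otherwise). It deliberately
  trades the accuracy of iterative peeling/phasing for a guaranteed
  complete [0, 2] dosage matrix; the masking test shows it beats
  frequency-only filling.
* Allele frequencies feeding the filters are computed on observed
  (pre-imputation) entries.
* All id joins are by token, never row position; pedigrees are
  topologically sorted on read with cycle detection.
* Study problem sizes: the replicate trend studies use ~1,600-animal
  populations (~850 genotyped), 1,000 SNP, one evaluated fold of six per
  replicate, six replicates in the test suite and the acceptance script.
  These sizes keep the full suite in the minutes range while leaving
  every stratum populated after pooling.

## Known limitations

* Dense algebra bounds the pedigree at ~12,000 animals; no sparse or
  iterative solvers.
* BayesB reports no PEV/reliability (posterior spread of gEBV is not
  accumulated); reliabilities come from the BLUP-family solvers.
* The mean relationship between N/P/PO strata and accuracy is
  reproduced, but with everyone in a small nucleus being at least
  half-sib-related the N-vs-P contrast is much weaker than in data with
  deeper population structure, and marker-based methods may show the two
  strata as statistically tied at these scales.
* Single trait only; no multi-trait models, no variance-component
  estimation, no gEBV blending into selection indexes.
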