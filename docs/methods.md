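# Methods

This note documents the statistical machinery, the defaults and the
numerical choices, in the order the pipeline runs them.

## Model and scope

All association testing is based on the fixed-effects linear model

    y = Zθ + Xβ + ε,    ε ~ N(0, σ²Iₙ),

per gene (GBST, testing H₀: β = 0 jointly over the gene's m SNPs) or per
SNP (SMA, m = 1 with a t-test on the coefficient). Covariates θ are
nuisance parameters removed by projection and never reported. There is no
kinship/mixed-model term: stratification is handled entirely by the group
indicator and within-group principal components, which is adequate for the
two-subpopulation structure the generator emulates but not for strong
family structure.

## Quality control and annotation

SNPs are kept when call rate ≥ 0.95 and MAF ≥ 0.05, both inclusive (the
conventional reading of "filtered at 95% / 5%"). Surviving missing calls
are imputed with the SNP's modal dosage — defensible only because the call
-rate filter caps missingness at 5%; a haplotype-aware imputer would be
needed for sparser data. MAF is computed on the pooled sample, not per
subgroup. SNPs map to a gene when their position lies within the gene
interval ± 5 kb (symmetric; strand is ignored); one SNP may serve several
overlapping genes, and genes with no SNP are dropped. Pathways are read
from GMT, intersected with the annotated gene universe, and kept when at
least 5 members survive.

## Stratification correction

PCA runs on the dosage matrix with each SNP column centered and scaled by
√(p̂(1−p̂)); eigenvalues are those of the sample covariance normalized by
the SNP count. The number of components that enter the model is decided by
a sequential Tracy–Widom test in the Patterson style: for the leading
remaining eigenvalue, with p eigenvalues left, compute S₁ = Σλ, S₂ = Σλ²,
the effective marker number

    n̂ = (p + 2) S₁² / (p S₂ − S₁²),

the normalized statistic ℓ = p λ₁/S₁, and compare
(ℓ − μ)/σ, with μ = (√(n̂−1) + √p)²/n̂ and
σ = (√(n̂−1) + √p)/n̂ · (1/√(n̂−1) + 1/√p)^{1/3}, against the
Tracy–Widom GOE distribution at α = 0.01; testing stops at the first
non-significant component. Two implementation details matter:

* The coefficients (p+2, p) in n̂ are the ones that make the estimator
  unbiased under the Wishart moment identities for a spectrum of p
  eigenvalues in *either* aspect-ratio regime (few samples/many markers or
  the reverse); the frequently quoted (m+1, m−1) variant presumes m counts
  samples, one more than the eigenvalues, and using it with the eigenvalue
  count inflates n̂ and the false-positive rate severalfold. Monte-Carlo
  calibration on Gaussian and genotype nulls (tests) confirms the ~1%
  level.
* TW1 tail probabilities come from Chiani's shifted-gamma approximation
  (TW1 ≈ Γ(k = 46.446, θ = 0.18605) − 9.84801), accurate to ~10⁻³ over the
  support and reproducing the standard significance points
  (0.9793 → 0.050, 2.0234 → 0.010, 3.2724 → 0.001).

The covariate matrix follows the two-group design: Z = (1, I_G1,
PC2..PCk) with component columns carrying the within-subgroup scores and
exact zeros outside the subgroup (reproduced verbatim from the design it
mirrors, including the omission of PC1 from Z); the Z* variant adds a
study-origin indicator and PC1. Component signs are fixed by making the
largest-magnitude loading positive, so outputs are reproducible.

## The SSU test and its p-value

With Q an orthonormal basis of span(Z) (rank-revealing QR; the hat matrix
is never formed explicitly), the residual r = y − QQᵗy gives
σ̂² = ‖r‖²/n (maximum likelihood, not REML — the score-test derivation
wants the H₀ MLE), U = Xᵗr/σ̂ and C = (X−QQᵗX)ᵗ(X−QQᵗX). SNP columns
whose projected variance C_ii ≤ 10⁻¹⁰ are constant given the covariates
and are dropped (count reported) before Diag(C) is inverted. Under H₀,
SSU = UᵗDiag(C)⁻¹U is asymptotically Σλᵢzᵢ² with λ the eigenvalues of
the correlation-like matrix Diag(C)^{−1/2} C Diag(C)^{−1/2} (computed with
`eigvalsh` on the symmetric matrix; round-off negatives clipped at zero).
The p-value matches the first three cumulants cₖ = Σλᵢᵏ to a shifted
scaled χ²: a = c₃/c₂, b = c₁ − c₂²/c₃, d = c₂³/c₃², p = P(χ²_d >
(SSU − b)/a), falling back to the Satterthwaite two-moment match when c₃
vanishes. Note c₁ = m (unit diagonal), a useful internal check.

σ̂ is a plug-in estimate; the cumulant match does not account for its
sampling error. The package's position: the plug-in p is primary, the
phenotype-permutation p (`ssu_permutation_pvalue`, bias-corrected
(1+#)/(1+N)) is the calibrated arbiter, and the simulation suite verifies
the plug-in's type-I error at the cohort sizes of interest (empirically
0.052 at nominal 0.05 over ~1,000 null genes with n = 244, m ≤ 25,
LD ρ up to 0.9). A residual-permutation variant exists for designs where
covariates are strongly confounded with genotype.

The SMA is computed through the partialled-out (Frisch–Waugh) regression —
residualize y and each SNP on Z, then simple regression with n − rank(Z) − 1
degrees of freedom — which is algebraically identical to refitting the
full model per SNP (verified against statsmodels OLS) and vectorizes over
the genome.

## Multiple testing

Bonferroni: α′ = α/m. BH: classic step-up on raw p — the largest k with
p₍ₖ₎ ≤ kq/m fixes the per-test threshold p₍ₖ₎; ties enter together.
Adjusted p-values are emitted for convenience but selection uses the
step-up rule directly.

## Pathway enrichment

Genes are ranked by r = −log₁₀ p (GBST p-values), ties broken by genomic
position for reproducibility; a joint mode uses −log₁₀ of the product of
several phenotypes' p-values (equivalently the sum of their metrics).
Zero p-values are capped at the smallest positive double. The weighted-KS
running sum rises by rᵢ/Σ_{g∈S}r_g at members and falls by 1/(N−N_S)
elsewhere; increments and decrements each total one, so the sum ends at
zero — asserted in tests as a conservation check. ES is the running-sum
value of maximal absolute deviation with sign preserved; only positive ES
counts as enrichment (one-sided). If every member p is 1 (Σr = 0) the
increments degrade to uniform 1/N_S. The rank-sum statistic is the sum of
members' 1-based ranks, small values indicating enrichment.

Null distributions come from phenotype permutation with the entire
gene-test → ranking → statistic pipeline recomputed per shuffle. Because
the projected genotype covariance C is phenotype-free, per-gene
eigen-cumulants are precomputed once (`GbstEngine`) and each permutation
costs one projection and one matrix product — an exact shortcut, not an
approximation. One shared permutation stream serves all pathways, which
is statistically valid (each pathway's statistic is compared with its own
null) and makes desk-scale runs of 500–10,000 permutations practical.
Both the raw #/N and the bias-corrected (1+#)/(1+N) estimates are
reported; ranking uses the corrected one, ties broken by the more extreme
observed statistic. Pathways are ranked only — no significance claims are
attached to enrichment p-values.

## Synthetic cohorts

The generator emulates the features the analysis must survive, not any
particular genome:

* **Stratification** — ancestral frequencies uniform on `maf_range`
  (default 0.05–0.5); group frequencies Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F) with a single F (default 0.05, enough for
  PC1 to separate groups cleanly at the default sizes). Default cohort:
  244 samples split 178/66, mirroring a two-breed design.
* **LD** — per gene block, haplotypes are a latent AR(1) Gaussian
  (parameter `ld_rho`, default 0.5) thresholded at each SNP's frequency
  quantile; two independent haplotypes sum to the dosage. This gives
  tunable, monotone LD decay but not realistic recombination maps.
* **Genome layout** — deterministic: genes of 5–25 SNPs at 1 kb spacing,
  50 kb between gene starts across 5 chromosomes, intergenic SNPs placed
  > 5 kb from any gene so the flank rule is exercised in both directions.
* **Phenotypes** — y = Zθ + Xβ + ε at T1/T2/T3 with a shared genetic term
  scaled by per-time multipliers (default all 1.0 — the simplest choice;
  real between-time correlation structure is unknown and not inferred),
  trait means loosely matching transition-cow metabolite summaries, noise
  SD 1.0, and effect sizes expressed in noise-SD units. Causal SNPs are
  drawn without replacement from the designated gene.
* **Pathways** — a partition of the emitted genes into `n_pathways` sets
  of ≥ 5; all causal genes are placed in the designated causal pathway.

Dosage columns are re-oriented to the realized minor allele after
simulation so that written PED/MAP files round-trip bit-exactly through
the reader (which derives minor-allele dosage from the data, ties counting
the later-sorting allele).

What passing tests on these cohorts does **not** show: robustness to
realistic LD maps, pedigree/family structure, breed-specific allele
spectra, genotyping batch effects, or non-normal phenotype error — the
generator draws exactly the model the tests assume.

## Problem sizes and determinism

Simulation-based checks use desk-scale designs chosen to keep the full
suite in the low minutes while retaining power: 1,000+ null genes at
n = 244 for type-I calibration, 15–20 replicate cohorts (n = 300, 50–100
genes) for power and end-to-end recovery, 500 permutations and 50
pathways for null uniformity, 10⁶ Monte-Carlo draws for the
quadratic-form oracle. Every stochastic component takes an explicit seed
(numpy `SeedSequence` spawning per stage), and identical config + seed
reproduces cohorts, result tables and reports byte-for-byte.

## Known limitations

* The cumulant-matched p-value ignores the sampling error of σ̂²; at very
  small n or extreme tails prefer the permutation p.
* Mode imputation biases toward the major genotype; acceptable at ≤ 5%
  missingness only.
* The Tracy–Widom test assumes independent markers; strong LD inflates
  the component count (LD pruning before PCA is out of scope).
* Enrichment is one-sided toward over-representation at the top of the
  list; depletion is not tested.
* With a single causal gene per pathway the rank-sum statistic has little
  power by construction (it gains only one rank); the weighted-KS score,
  which weights by −log₁₀ p, is the sensitive statistic in that regime.
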