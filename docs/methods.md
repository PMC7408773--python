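# Methods

## Pedigree model and cosegregation Bayes factor

Genotypes follow an autosomal-dominant two-class model: each individual is a
*carrier* (heterozygote for the pathogenic allele; the negligible homozygote
mass is folded in, so carrier × carrier transmits a carrier child with
probability 3/4) or a *non-carrier*. Founders carry with Hardy–Weinberg
probability `2q(1−q)`; `q` defaults to 1e-4 for analysis, reflecting the
rarity of pathogenic MMR alleles (the cohort's variants are absent from
population frequency databases).

Phenotypes enter through age-banded cumulative-risk tables F per
(cancer type, sex, genotype class). F is the piecewise-linear interpolant
through the band boundaries. An individual diagnosed at age *a* contributes
`F(a) − F(b)` where *b* is the largest band boundary strictly below *a*
(the incidence captured by the diagnosis liability class; the strict
inequality keeps boundary-age diagnoses from contributing zero); an
individual unaffected up to their censor age contributes `1 − F(censor)`.
Multiple primaries are treated as independent events; cancer types with no
configured table (or inapplicable to the sex, e.g. endometrial risk in
males) contribute 1. Unknown sex uses the male/female average; a missing
censor age is an error, not an imputation target.

The pedigree likelihood sums, over all genotype configurations consistent
with the fixed genotypes, founder priors × Mendelian transmission ×
phenotype liabilities. It is computed by **variable elimination** over the
binary genotype variables with a min-degree ordering and per-step
renormalization (log-scale accumulation), which is exact on arbitrary
pedigree graphs — including loops — and is verified against brute-force
enumeration (|Δ log L| < 1e-10) on random structures. Under the *neutral*
hypothesis every individual expresses the non-carrier risk, so genotypes
decouple from phenotypes and the likelihood reduces to the product of
non-carrier phenotype terms.

The cosegregation Bayes factor conditions both hypotheses on every
proband's carrier genotype and excludes proband phenotypes from the
liability product (probands were ascertained through their MMR-deficient
tumors; that evidence belongs to the tumor-characteristic LRs, not to
segregation). A family in which only the proband is genotyped contributes
LR = 1. Independent families carrying the same variant multiply.

The penetrance tables shipped in `config/penetrance_default.yaml` are
plausible dominant-MMR values on decade bands and are explicitly
replaceable configuration; the published per-family segregation LRs are
**not** reproduced numerically, because their source pedigrees exist only
as figures. Validation is by property instead: exactness against
enumeration, invariance under relabeling and inert relatives, and the
martingale E[LR] = 1 under neutral simulation (see below).

## Multifactorial likelihood classification

Posterior odds = prior odds × tumor LR product × segregation LR product;
posterior probability = odds/(1+odds); IARC classes at 0.99/0.95/0.05/0.001
with the half-open conventions stated in the code (0.984 → class 4,
0.991 → class 5). All thresholds are configurable.

Prior adjustment: priors are capped at 0.9, and priors below 0.5 in
categories with unreliable calibration (in-frame indels) are floored at
0.5; both rules are configuration.

Tumor eligibility: the index tumor of any proband (the ascertainment event)
is excluded from the LR product; additional tumors of probands and all
tumors of tested non-proband carriers count. This rule is read off the
arithmetic of the packaged evidence table (printed totals equal products
over non-index tumors only, e.g. 1.75 × 4.16 × 4.16 = 30.28) and is
explicit and configurable. The per-tumor LR lookup table is configuration,
not code: its calibration source is external. The evidence table's "Bayes"
column (2.15 / 1.85 / –) enters no printed product; it is recorded in the
fixture but not computed.

Reported values are rounded half-away-from-zero at serialization only
(2 dp odds, 3 dp probabilities). Recomputing the products from the printed
per-tumor LRs yields odds 12.10 and 870.69 where the source prints 12.07
and 870.61 — the source evidently multiplied unrounded internal LRs — but
the 3-dp posteriors (0.991, 1.000) agree either way. A double-precision
caveat: an odds → probability → odds round trip through a stored
probability loses ~|log10 odds| digits at the extremes, so internal
consistency is asserted at 1e-9 relative rather than machine epsilon.

## Variant screening and case classification

Filters keep calls meeting *all* of: Phred ≥ 30, alternative-allele ratio
≥ 0.05, depth ≥ 38, population MAF ≤ 0.01 and prior InSiGHT class ∉ {1, 2}.
The population frequency is the maximum over available databases with
missing values treated as 0 — absence of frequency evidence never removes
a variant. Filtering is stable and idempotent.

Final case classification applies priority rules: (1) MMR variant of final
class ≥ 4 or constitutional MMR epimutation → LS; (2) pathogenic variant in
a non-MMR Mendelian CRC syndrome gene (configurable map, default APC → FAP)
or biallelic MUTYH → that syndrome; (3) MMR class-3 variant → LLS (MMR VUS
carrier); (4) monoallelic pathogenic MUTYH → LLS (monoallelic MUTYH
carrier); (5) any other-gene VUS / predicted-pathogenic variant → LLS (VUS
carrier); (6) plain LLS. Cohort tallies track distinct variants by
(gene, cDNA change), separating final class ≥ 4 from the subset actually
reclassified (identified at class 3).

The packaged 115-case fixture transcribes the 49 itemized cohort cases
(variant inventories, epimutation flags, printed labels retained for
traceability); the remaining 66 cases are encoded as plain LLS with no
annotated variants, which is sufficient for every tally the pipeline
reports. One case's variant is detailed only in supplementary material and
is encoded as a single unspecified other-gene VUS.

## Allele-specific expression

Per replicate, ASE = (variant/wildtype in cDNA) / (variant/wildtype in
gDNA); 1.0 means balanced biallelic expression. Mean and n−1 SD are taken
over replicates (quadruplicates by design; fewer warns). The imbalance rule
is the package's own: *reduced expression* when mean + 2 SD < 1,
*inconclusive* when mean − 2 SD > 1, else *balanced*. The ± values in the
source are assumed to be SDs. With these defaults every reported
quadruplicate call is reproduced (0.69 ± 0.03 → reduced; 1.02 ± 0.09,
1.04 ± 0.14, 1.16 ± 0.26 → balanced); the multiplier is configurable.
Treatment conditions (untreated / puromycin) are analyzed separately.

## EMAST

A tetranucleotide marker is unstable when the tumor profile contains any
allele length absent from the paired normal profile; allele dropout
(tumor ⊂ normal) is stable — inputs are already-binned allele calls, and no
stutter modeling is attempted. A sample is EMAST-positive at ≥ 2 unstable
markers (configurable threshold) of the 6-marker panel; marker identities
are configuration.

## Methylome comparison and epimutation detection

Group comparison: per-CpG Welch two-sample t-test on β values, BH-FDR
across tested sites (≥ 3 non-missing per group), significance claimed only
when both groups exceed 10 samples (smaller comparisons carry an
`underpowered_comparison` flag). Regions aggregate member sites by mean and
combine p-values by equal-weight Stouffer; BH-FDR is then applied across
regions. A group-mean difference |Δβ| > 0.20 flags a large effect. This is
a transparent reimplementation of the standard array group-comparison
workflow, chosen for auditability; it does not claim equivalence to any
array suite's internal ranking, and no attempt is made to reproduce
genome-wide differential-methylation counts that depend on the deposited
cohort arrays.

Coordinates: site positions are 1-based (array-manifest convention),
regions are BED 0-based half-open; a site at position `pos` is in
`[start, end)` iff `start < pos ≤ end`.

Constitutional epimutation: a sample is called over a promoter DMR when its
DMR mean β lies in the hemimethylation window [0.25, 0.75] (one methylated
allele), exceeds the control mean by > 0.20 and is a > 5σ outlier against
per-sample control DMR means. The window/margin/z cut-offs are the
package's own numeric rule (the source gives none); they accept the
validated exemplar (DMR mean ≈ 0.48 against near-zero controls) and are
configurable. Fully methylated signals are flagged for review, not called.
The shipped *MLH1* DMR/C/D-region BED (GRCh37) is editable configuration.

## Synthetic data

Each generator draws from an independent stream derived from the master
seed by CRC32-labeled sub-seeding, so outputs are pure functions of
(spec, seed) and adding a generator never perturbs another.

*Pedigrees*: two/three-generation non-inbred families (founder couple,
1–4 children, spouses and grandchildren to the target size; generation age
ranges 60–85 / 35–60 / 10–35), gene-dropped under the two-class model.
The simulation allele frequency defaults to q = 0.05 so that conditioning
on a carrier proband is feasible by rejection; the neutral-calibration
property is q-consistent because both simulation and analysis use the
spec's q, and the neutral-side genotype conditional involves no penetrance.
Under the neutral hypothesis phenotypes are drawn first from non-carrier
risks, the proband is a uniformly random affected member, and genotypes are
rejection-sampled until the proband carries — making the accepted
relatives' genotypes exactly the Mendelian conditional the Bayes-factor
denominator assumes, so E[LR] = 1 holds for any analysis penetrance. Under
the pathogenic hypothesis genotypes precede phenotypes and the proband is a
random affected carrier. A configurable observation mask (default 0.6)
hides non-proband genotypes.

*Beta matrices*: bimodal background — low-methylation island sites
~Beta(1, 20) (fraction 0.3) and methylated background ~Beta(20, 2) — with
optional contiguous hemimethylated DMRs (carrier draws centered at β 0.48,
controls ~Beta(1, 30)) and optional group mean-shift spikes (truncated
normal, baseline 0.3, shift 0.4, sd 0.05). The generator emulates the
marginal site distributions of blood methylomes but **not** probe-type
effects, spatial correlation between neighboring CpGs, batch effects or
cell-composition variation — passing tests demonstrate the statistics are
implemented correctly, not that real arrays behave this ideally.

*Toy tables*: variant tables with one call violating exactly one filter
rule each; marker panels with a chosen number of unstable markers; SNuPE
replicates with lognormal peak noise (σ = 0.02) around a known true ASE.

## Numerical and experimental choices

* Elimination factors are max-normalized per step with log-scale
  accumulation; an impossible observed genotype configuration raises an
  error rather than returning an undefined ratio.
* The null-calibration experiment for the site test uses a single
  homogeneous beta distribution for both groups (the methylated-background
  compartment), n = 12 vs 12, 10,000 sites. The Welch t-test on bounded
  skewed data at n = 12 is mildly conservative (empirical raw rejection
  ≈ 0.046 at the 0.05 level); single-seed runs therefore sit one to two
  binomial SEs below nominal, and the highly skewed island compartment
  would push this further. This is a property of the test, documented
  rather than corrected.
* Problem sizes used by the validation analyses — 200 random ≤ 8-member
  pedigrees for the exactness check, 500 neutral and 200 pathogenic
  simulated families for calibration, 10,000-site matrices for the
  methylome experiments — were chosen as the smallest sizes at which the
  Monte-Carlo error bands are meaningful.

## Known limitations

* X-linked and recessive models, polygenic backgrounds and co-occurrence /
  family-history LR components are out of scope.
* Per-tumor LR calibration, penetrance tables and prior probabilities are
  consumed as configuration; the package ships plausible defaults, not
  calibrated estimates.
* Raw array preprocessing (IDAT parsing, normalization, batch correction),
  somatic calling and in-silico effect predictors are upstream of this
  package; their outputs are inputs here.
* Whether metachronous same-patient tumors should also enter segregation
  (in addition to the tumor-LR product) is not settled; only the tumor-LR
  use is implemented.
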