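# Methods

## Candidate filtering

Candidates are evaluated on their bone-marrow observation. A variant
survives when its BM VAF lies in the inclusive window [`vaf_min` = 0.02,
`vaf_max` = 0.35], it has at least `min_alt_reads` = 6 supporting reads, and
it is detected (any-tissue VAF ≥ `detect_vaf` = 0.005) in at most
`recurrence_fraction` = 0.5 of sequenced animals. The upper VAF bound
excludes suspected germline variants (a heterozygous germline variant sits
near 0.5); the lower bound is the conventional CH detection threshold; the
recurrence filter removes technical artifacts that recur across unrelated
animals, in the spirit of a panel of normals. Each rejected candidate
carries exactly one primary reason with precedence germline-VAF > low-VAF >
read-support > recurrence, so rejection tallies are unambiguous.

"Detected in most mice" has no published numeric threshold; we operationalize
*most* as a strict majority (0.5) and keep the detection threshold for
recurrence (`detect_vaf`) separate from the survivor threshold (`vaf_min`),
since cross-sample artifact detection should be more sensitive than the
biological call. Both are configurable.

## Tissue classification

With `v_bm` the BM VAF and `v_nh` the maximum VAF over the
non-hematopoietic reference tissues (`nh_reference_tissues` = tail, brain,
testis, thyroid):

| condition | label |
|---|---|
| `v_nh < detect_vaf` | CH_NONMOSAIC (blood-restricted) |
| `v_nh ≥ detect_vaf` and `v_bm / v_nh ≥ 5` | CH_MOSAIC (mosaic origin, blood expansion) |
| `v_nh ≥ detect_vaf` and `v_bm / v_nh ≤ 3` | MOSAIC_NOT_CH (embryonic mosaic) |
| otherwise | UNCLASSIFIED (reason recorded) |

The qualitative notions "similar VAFs" and "substantially expanded" are
implemented as fold-ratio thresholds (3× and 5×). The deliberate gap between
the folds yields an explicit UNCLASSIFIED band instead of silently forcing
borderline ratios into a group. Spleen, thymus, and the sorted BM fractions
(T, B, granulocyte, erythroid) count as hematopoietic. Liver and kidney,
although non-hematopoietic, filter blood and can carry hematopoietic signal,
so they are excluded from the mosaicism reference by default (configurable).

Clone sizes use the diploid heterozygous transform, fraction = 2 × VAF,
valid for autosomal heterozygous somatic mutations; VAF > 0.5 violates the
assumption and raises. The "high-VAF" sub-counts use a strict VAF > 0.1.
Group means are kept unrounded internally; display rounds to one decimal.

## Mutation spectrum

Variant typing follows the VCF anchor-base convention: equal-length
single-base alleles are SNVs; a longer `ref` with `alt` as its prefix is a
deletion of `len(ref) − len(alt)` nt; irreducible substitutions are labeled
COMPLEX and excluded from histograms (logged). Substitution classes collapse
purine references onto the pyrimidine strand (G→A reported as C→T), giving
the six standard classes. Deletion lengths are binned 1–3 / 4 / 5–31 / >31
nt; the 4-nt bin is reported explicitly (rather than merged into a
neighbor) so its emptiness in a dataset is visible and checkable.

Junction microhomology is the larger of the longest common prefix of the
deleted segment with the right flank and the longest common suffix with the
left flank — homology at either junction end counts, since an end-joining
event can resect from either side. Lengths ≥ 2 nt count as
microhomology-mediated.

Multisite events (clusters of nearby lesions produced by a single radiation
track) are detected per animal by single-linkage clustering: two variants
link when they lie on the same chromosome within `window_bp` = 100 of each
other *and* their BM VAFs agree within `vaf_tol` = 0.05 absolute (same-clone
evidence). Connected components of size ≥ 2 count as one MULTISITE event and
their members leave the SNV/deletion tallies, so per-animal counts are
post-clustering event counts. The 100 bp window follows the short-range
clustering notion used in radiation mutagenesis work; both knobs are
config-exposed and recorded in output metadata.

## Clonal architecture from colony genotypes

A colony grown from a single sorted HSC or MPP carries its founder's
heterozygous mutations at VAF ≈ 0.5. Calls require `min_depth` = 20 reads;
PRESENT needs VAF in [`het_low` = 0.3, `het_high` = 0.7], ABSENT needs
VAF < 0.3. Everything else — low depth, missing data, VAF > 0.7 (possible
loss of heterozygosity or cross-contamination) — is AMBIGUOUS, a first-class
outcome, so dropout cannot fabricate absence.

Mutations group into candidate clones when their PRESENT-colony patterns
agree (disagreement on at most `max_pattern_mismatch` colonies, default 0,
evaluated only over colonies unambiguous for both mutations; single
linkage). Mutations never observed PRESENT in any shared colony carry no
co-occurrence evidence and stay in their own groups. Relations between
groups come from their colony supports restricted to mutually unambiguous
colonies: strict non-empty containment ⇒ nested; disjoint non-empty supports
⇒ mutually exclusive; crossing supports are recorded as conflicts (they
violate the single-tree assumption rather than being forced into it). HSC
and MPP colonies are pooled for structure inference and reported per
compartment; the structure logic is compartment-agnostic.

A clone's BM fraction is 2 × (mean BM VAF over its member mutations) —
members of one clone should agree, and spreads beyond 0.05 are logged.
Consistency checks (child ≤ parent + `frac_tol`, top-level sum ≤ 1 +
`frac_tol`, default 0.1) warn rather than fail, because bulk VAFs and colony
sampling are independent measurements. The delivered fraction sums top-level
clones only (nested clones do not add); the composition report carries the
unassigned remainder. Because the published per-animal delivered fractions
could have been computed from summed doubled VAFs or from colony
proportions, the report keeps both the per-clone fractions and the colony
supports so either reading is available.

## Group statistics

**Exact rate comparison.** The between-group contrast of mutation counts is
exact Poisson regression with a single binary covariate and per-animal
exposure, which reduces to the conditional binomial: given T = y₁ + y₀ and
equal per-animal rates, y₁ ~ Binomial(T, n₁/(n₁+n₀)). We implement this
reduction directly instead of a general exact-regression sampler because the
design is exactly two groups with animal counts as offsets. The one-sided
p-value is the upper tail P(X ≥ y₁); the two-sided p-value uses the
minimum-likelihood convention (sum of all outcome probabilities no larger
than the observed one). Two-sided conventions differ between software
packages, so both p-values are always reported. Tests verify agreement with
an exact-rational enumeration oracle for all totals up to 200 and a
simulated type-I error ≤ 0.055 at nominal 0.05 (exact tests are
conservative).

**Blood indices.** Outcomes (lymphocyte %, myeloid %, RDW) are regressed on
group, age (months), and sex. Rows with missing outcomes are dropped and
logged. When no weights are supplied and a grouping vector is, a two-step
feasible WLS is used: an unweighted first pass, then weights equal to the
inverse within-group residual variance, so lower-variance observations count
more — appropriate here because irradiation inflates between-animal spread.
The fit itself is statsmodels WLS; per-term p-values use the t distribution
with n − k df. The Breusch–Pagan statistic is n × R² of the squared
residuals regressed on the design, referred to χ² with k − 1 df.

## Synthetic cohorts

The generator emulates the statistical structure of the study design: 12
irradiated / 6 control animals by default; embryonic mosaics at 0.5 per
animal with per-tissue jitter within ±20% (correlated VAFs); blood-expanded
mosaics at 0.4 per irradiated animal, with embryonic VAF drawn in
[0.006, 0.02] and BM VAF in [0.15, 0.30] so the generative label respects
the fold-ratio definitions with margin; hematopoietic-restricted clones at
Poisson(4.0) per irradiated animal (0 for controls), Dirichlet fractions
scaled to a 0.9 budget, and zero-truncated Poisson(λ=2) mutations per clone
(realized mean ≈ 2.3, so ≈ 5–6 surviving mutations per irradiated animal
after the VAF filter). The spectrum is C→T-dominant (weight 0.40), with 55%
deletions (lengths 1–3 with probability 0.35, else uniform 5–31 nt;
microhomology planted with probability 0.25) and multisite clusters with
probability 0.05. Reads are Binomial(depth, VAF + 0.001) at 30,000×
validation depth (500× discovery depth for non-carried sites), colonies
100×. A clone may be excluded from the T lineage with probability 0.5,
mirroring the observed T-cell deficit of post-irradiation clones.

What it does *not* model: hematopoiesis dynamics (no birth–death process or
neutral drift), alignment artifacts, strand bias, or contamination; colony
matrices cover only the hematopoietically expanded clones, treated as
mutually exclusive in BM. Passing recovery tests therefore show that the
algorithms invert the generative model faithfully, not that real data meet
the model's assumptions.

A separate harness builds arbitrary nested clone trees (`random_clone_tree`)
and colony draws from them. For noise-free structure-recovery tests, colony
counts are allocated proportionally to each clone's own fraction with a
guaranteed minimum of one colony per clone: with multinomial sampling a
clone can receive zero colonies, making exact recovery ill-posed rather
than informative. Multinomial allocation remains available.

## Numerical choices and degenerate inputs

- VAF is always recomputed as alt_reads / depth; zero-depth sites are
  flagged undefined rather than imputed. File readers parse floats in
  round-trip mode so write→read is exact.
- Two-sided tail summation uses a 1e-7 relative tolerance when comparing
  pmf values, guarding ties lost to floating-point rounding.
- Colony matrices with zero colonies or zero variants are valid and flow
  through genotyping, grouping, and composition (remainder 1.0).
- Equal restricted supports between two distinct groups are recorded as a
  conflict: they indicate the grouping step separated mutations that the
  relation step cannot order.
- Empty profile lists write header-only files; empty cohorts raise.

## Problem sizes in the test suite

Property suites run at sizes chosen to make the checks sharp yet quick: the
microhomology oracle on 10,000 random contexts, structure recovery on 100
random trees of 1–5 clones with 60 colonies each, the enumeration oracle on
all totals ≤ 200 (all splits for small totals, sampled splits above),
Breusch–Pagan calibration on 2,000 null replicates of n = 100, exact-test
size on 10,000 Poisson cohort draws, and the classifier false-positive rate
on 1,000 simulated control animals in 20 batches of 50.
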