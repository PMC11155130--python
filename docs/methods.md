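# Methods

This note documents the models, rules and numerical choices behind
`wsdecipher`, and what the synthetic-data generators do and do not emulate.

## Stage 1: candidate-gene prioritization

**Model.** Two independent lines of evidence are intersected. The network
line assumes that proteins directly interacting with known causative
proteins are enriched for further causative genes: set A contains every gene
adjacent to at least one seed gene in *all* k supplied PPI sources (k ≥ 2;
full intersection, not majority vote — requiring consensus trades recall for
precision against source-specific noise). One-hop neighbors only; no path
expansion. The phenotype line assumes that a gene whose knockout/variant
phenotypes overlap the disease's phenotype spectrum is a better candidate:
with P_ws the union of phenotype terms annotated to the seed genes and
P_g a gene's term set, the weight is W_g = N_g / N_ws with
N_g = |P_g ∩ P_ws|.

**Threshold semantics.** Selection into set B uses the strict inequality
W_g > 0.2. At N_ws = 70 this is exactly "shares more than 14 terms", i.e.
N_g ≥ 15; a gene at W_g = 0.2 (N_g = 14) is excluded. Both candidate sets
exclude the seed genes themselves, so a seed can never be reported as its
own candidate. All reported sets are sorted lexicographically; the pipeline
output is invariant under permutation of input rows and of source order.

**Evidence filter.** The optional high-priority step is a row-wise AND over
named boolean flags from a user-supplied evidence table (e.g. mouse-knockout
hearing impairment). Genes absent from the table are excluded and logged —
absence of evidence is treated as failure, consistent with the fail-closed
stance elsewhere.

**Parameters.** `threshold` (default 0.2, in [0,1]); `top_n` rank cutoff
(default off — the threshold alone defines set B, the rank view is only an
escape hatch); `required_flags` (default none).

## Stage 2: candidate-variant nomination

A variant must clear four stages in order; later stages are only evaluated
for variants still alive, and the per-gene stage counts are therefore
non-increasing.

1. **Consensus deleteriousness filter.** Pass iff SIFT ≤ 0.001 AND
   PolyPhen2-HVAR > 0.957 AND MutationTaster = 1 AND CADD-phred > 25 AND
   GERP++ RS > 4. Boundary semantics are exactly as stated: only SIFT admits
   equality. "MutationTaster = 1" is read as the converted score equal to 1
   within 1e-9 (the score column, not the categorical prediction); a reader
   switch (`mutationtaster_categorical`) instead maps ANNOVAR codes
   A/D → 1.0 and N/P → 0.0. A missing score yields a `missing` verdict and
   the variant fails — fail-closed avoids promoting unscored variants.
   Relaxing any cutoff can only grow the survivor set (monotonicity, tested).
   Population-frequency columns are not filtered on; no frequency cutoff is
   part of the rule set.
2. **Known-pathogenic cross-reference.** Exact variant-ID partition against
   a ClinVar/DVD-like list; |known| + |novel| = |survivors|.
3. **Conservation.** The variant's 1-based protein position i is mapped to
   the alignment column holding the i-th non-gap reference residue. The
   column is conserved iff no row is gapped there and the modal residue
   fraction ≥ `min_identity_fraction` (default 1.0 — strict identity across
   all rows; conservation is judged per residue, not per region). If the
   stated reference amino acid disagrees with the alignment's reference
   residue the verdict is *not evaluable* (None) with a warning, and the
   variant cannot become a final candidate; a position beyond the reference
   length is an error. Genes without an alignment are likewise not
   evaluable.
4. **Domain localization.** 1-based inclusive interval lookup in the
   user-supplied domain table; overlapping intervals are allowed and the
   first match by (start, end, name) wins — a deterministic tie-break, since
   nested/overlapping domain annotations are common.

Final candidate ⇔ pass ∧ novel ∧ conserved ∧ in-domain.

## Stage 3: association analysis

**Ternary phenotype coding.** Every phenotype cell is present / absent /
unrecorded; every denominator counts recorded patients only (k/n fractions
with n below the cohort size). Cells that cannot be decoded are schema
errors, never silently missing.

**Test selection.** The headline comparison of one phenotype across gene
strata builds the 2×k present/absent table over recorded patients.
The Pearson chi-square statistic Σ(O−E)²/E with df = (r−1)(c−1) and no
continuity correction is used when all expected counts are ≥ 5; otherwise
the two-sided exact test: Fisher for 2×2, Freeman–Halton for 2×3, both by
full enumeration of margin-fixed tables under the (multivariate)
hypergeometric null, summing the probability of tables no more probable
than the observed one (relative slack 1e-12 to absorb floating-point ties).
Enumeration is bounded (n ≤ 2000 for 2×2, n ≤ 500 for 2×3); larger tables
are directed to the chi-square. The expected-count < 5 rule is a declared
convention (the classic Cochran rule); it and the continuity-correction
flag are configurable. Pairwise 2×2 sub-tables use the same rule. P-values
are raw/two-sided; Bonferroni or Benjamini–Hochberg adjustment is available
but off by default. A phenotype with no contrast (uniformly present or
absent across strata) reports p = 1 rather than erroring on the degenerate
margin. Patients whose gene is outside the declared strata (default
PAX3/MITF/SOX10) are excluded from the genotype–phenotype tests.

**Phi co-occurrence.** For two phenotypes, restricted to patients with both
recorded, φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)); its p-value is the
uncorrected Pearson chi-square on the same table (χ² = n·φ² for 2×2, an
identity the tests verify on random tables). A zero margin makes φ
undefined — rendered as missing, never 0. The matrix diagonal is 1 by
convention; the significance mask is p < α (default 0.05).

**Distribution summaries.** Gene and subtype shares use the full cohort as
denominator; gene-within-subtype shares use the subtype total;
variant-class shares use patients with a *recorded* variant class (the
published class percentages are consistent with that denominator, not the
full cohort). Denominators are stated in every output table.

## Synthetic-data generators

One integer master seed drives an independent child stream per generator
(`default_rng([seed, k])`), so regenerating one input never perturbs the
others and a fixed seed gives byte-identical files.

* **PPI trio** (defaults: 3 sources; 266/167/152 one-hop partners of the
  7-gene seed panel, matching the reported source sizes; 4 planted consensus
  genes SIN3A/EP300/CHD7/KIT). Decoy partners are placed in exactly one or
  two sources (pairwise sharing rate 0.25), so the consensus recovers the
  planted set exactly; 300 background edges among non-seed genes exercise
  the one-hop restriction.
* **Annotations** (defaults: N_ws = 70 terms, planted overlaps
  SIN3A 17 / EP300 16 / CHD7 15 / KIT 15, matching the reported shared-term
  counts; 500 background genes capped at N_g ≤ 14; 10 high-weight decoys in
  set B but never in set A; 20 off-target terms per planted gene). Every
  P_ws term is annotated to at least one seed, so the union is exactly N_ws.
* **Variant bundle** (defaults: planted finals PAX3 20 / MITF 7 / SOX10 5,
  matching the reported final counts; per gene 2 known-pathogenic decoys,
  one decoy failing each single score, one non-conserved, one out-of-domain;
  50 background variants per gene with per-score pass probability 0.3 and
  5% missing cells). Background variants sit at designated non-conserved
  alignment columns, so a chance all-pass score vector cannot reach the
  final set — recovery is exact by construction, which is what the
  recovery tests certify. The 7-species MSA plants ≥ 1 divergent row (or
  gap) at every variable column and inserts reference-gap columns to
  exercise the position→column mapping. Domain layouts are synthetic
  intervals loosely shaped like the real PAX3/MITF/SOX10 architectures.
* **Cohort** (defaults: n = 443; gene mixture 138/161/124/13/4/2/1 over the
  seven genes, i.e. the reported composition; 8% independent per-cell
  missingness; 27% unrecorded sex; 45% unrecorded inheritance; de novo rate
  0.62 for SOX10 vs 0.12/0.20 for PAX3/MITF; per-gene prevalences for 13
  common phenotypes following the reported genotype–phenotype gradients).
  Phenotypes are independent Bernoulli draws per gene except designated
  pairs planted with a target φ (defaults: telecanthus–broad nasal root
  0.40, synophrys–broad nasal root 0.56) by drawing the second phenotype
  conditional on the first; a φ infeasible at the per-gene marginals is
  clamped to the Fréchet bound and logged. Missingness is masked after the
  status draw, independently per cell — the real missingness mechanism is
  unknown, so independence (MCAR) is assumed and documented.
* **exact_cohort** builds a deterministic cohort from explicit marginal
  counts (no randomness); it backs the printed-count arithmetic checks.

**What the generators do not emulate:** real HPO term semantics or ontology
structure, real allele frequencies or linkage, pedigree structure,
informative (non-random) missingness, and inter-phenotype correlation beyond
the planted pairs. Passing tests therefore certify the pipeline's logic and
statistical calibration under these idealized conditions, not performance on
real database snapshots — the original per-source partner counts, N_ws and
variant counts depend on 2023-era BioGRID/InWeb/HitPredict/HPO/gnomAD
versions and are not reproducible offline.

## Problem sizes and numerical choices

The acceptance script and tests run: an exhaustive 2×2 Fisher sweep over all
135,750 tables with n ≤ 40 against an exact-integer enumeration oracle
(agreement ≤ 1e-12); the χ² = n·φ² identity on 10,000 random tables; 1000
null cohorts of n = 300 for type-I calibration of the group test (rate
within the 95% binomial CI of 0.05); 200 cohorts of n = 400 for phi
detection (planted φ = 0.5 detected in ≥ 95% of replicates, null pairs
flagged at ≈ α); and one n = 5000 cohort with 8% missingness for prevalence
recovery. These sizes give tight Monte-Carlo error at desk scale.

Floats are serialized at 6 significant digits; all outputs are UTF-8, LF,
deterministically ordered. Gene symbols are uppercased and stripped, with an
optional alias table applied before normalization (no built-in alias
resolution — none is defined for this domain). Protein coordinates are
1-based inclusive throughout, matching p.Arg156Cys-style HGVS substitutions;
only simple substitutions are parsed, other HGVS classes pass through
untyped and are not evaluable for conservation/domain stages.

## Known limitations

* The exact tests enumerate; contingency tables beyond 2×3 fall back to the
  chi-square regardless of expected counts.
* Conservation requires the variant's gene to have an alignment whose
  reference matches the stated reference residue; disagreements yield
  not-evaluable rather than a guess.
* The familial/sporadic distinction in the cohort schema is carried by the
  inheritance column's {de novo, familial, unrecorded} vocabulary; finer
  segregation structure (families, pedigrees) is out of scope.
* No multiple-testing correction by default; with 13 phenotypes and 3
  pairwise contrasts each, users comparing many phenotypes should enable the
  `adjust` option.
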