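# Methods

## Study design being modelled

The package implements a two-phase family-genomics workflow. In the
*discovery* phase a sequenced trio — unaffected father (III-1), affected
mother (III-2), affected daughter (IV-3) — is screened for variants
consistent with autosomal-dominant, highly penetrant transmission from
mother to daughter. In the *replication* phase the surviving candidates are
genotyped in independent case/control cohorts and tested for association.
Because real trio genomes of this kind are private, the package ships a
synthetic generator that reproduces the structure both phases assume, with
recorded ground truth.

## The filtering cascade

The cascade is a conjunction of five predicates applied in a fixed order;
per alternate allele, the first failing stage is recorded in an audit trace
and later stages are not evaluated. This gives a conservation identity —
every input variant is either removed at exactly one stage or survives all
five — which the test suite asserts on every run. The kept set is
order-independent: no stage depends on input ordering (stage 4's gene-level
counts are computed over the whole stage-4 input before any removal).

Defaults (all configurable via `CascadeConfig`):

| parameter | default | units | meaning |
|---|---|---|---|
| `quality_threshold` | 20.0 | Phred | minimum carrier call quality (99 % accuracy) |
| `af_cutoff` | 0.03 | fraction | inclusive panel-frequency removal cutoff |
| `splice_max_offset` | 2 | bases | deepest intronic offset still "splice-disrupting" |
| `min_case_samples` | 2 | samples | gene-level case-carrier minimum |
| `max_control_samples` | 0 | samples | variant-level control-carrier maximum |
| `quality_group_rule` | `any_group` | — | OR over case/control groups (AND available) |

Decisions taken where the published wording leaves room:

- **Stage 1 group semantics.** "Quality ≥ 20 in cases or in controls" is an
  OR over groups, which is unusual but literal; `all_groups` switches to AND.
  A group with no quality-bearing carrier call carries no information: under
  OR it simply cannot vouch for the variant, and under AND it is ignored
  (otherwise any variant absent from controls — i.e. every dominant
  candidate — would fail). A variant with no quality-bearing carrier in
  either group is removed with reason "no qualified call". Non-carrier call
  qualities are never consulted.
- **Missing values.** A missing panel frequency never removes (stage 2); a
  missing SIFT score on a missense variant keeps it, because the criterion
  is "not predicted innocuous", and no prediction is not an innocuousness
  prediction (stage 3). The 3 % cutoff is inclusive: exactly 3.0 % is
  removed.
- **Gene-level counting, variant-level control screen (stage 4).** Case
  carriers are counted across all variants of a gene that reached stage 4,
  so two cases heterozygous at different variants of one gene (compound
  heterozygosity) both count. The control screen applies to the variant
  itself. Qualifying genotype classes are heterozygous, homozygous-alt,
  het over two alt alleles, het with one ambiguous allele, and hemizygous —
  i.e. every class carrying an alternate allele. Haploinsufficiency is a
  gene property rather than a genotype class; since every carrier class
  already qualifies, a separate haploinsufficiency flag would be redundant
  and none is implemented.
- **Multi-allelic records** are not decomposed. The cascade unit is a
  (record, alternate-allele) pair: annotations are per alternate allele,
  carrier status is per record. A record survives if any of its alternates
  does.

## Replication statistics

All tests consume a 2×3 genotype count table (cases/controls ×
hom-ref/het/hom-alt).

- **Hardy-Weinberg χ².** Allele frequency estimated from the sample,
  expectations (np̂², 2np̂q̂, nq̂²), 1 degree of freedom (one estimated
  parameter), no continuity correction. Monomorphic samples fit trivially
  and are flagged rather than erroring.
- **Exact Fisher tests.** Implemented from first principles by fixed-margin
  enumeration (a 2×K inner routine serves both the 2×3 genotype table and
  the 2×2 collapsed allele table). Two-sidedness uses the point-probability
  ("minlike") criterion — the convention of the standard genetics packages —
  with a relative tie tolerance of 1e-7 in log space; the test suite checks
  the implementation against an independent integer-arithmetic enumeration
  oracle, where tie comparison is exact, over the full space of small
  tables. All-zero columns drop out of the enumeration automatically; a
  table with a single nonzero column is determined by its margins and
  returns p = 1, flagged degenerate. Enumeration cost is O(c₁·c₂) tables
  and is negligible at cohort scale (n ≤ 250).
- **Cochran-Armitage trend.** Scores default to (0, 1, 2) (additive model;
  configurable). The asymptotic form refers the classical 1-df trend χ² to
  its χ² tail. The Monte-Carlo form resamples under the fixed-margin
  permutation null — case/control labels permuted over the pooled genotype
  vector, implemented as multivariate hypergeometric draws — and uses the
  add-one estimator p = (1 + r)/(R + 1), a valid p-value bounded below by
  1/(R+1). Because the trend statistic is symmetric in the rows and
  invariant under affine score maps, the smaller arm is resampled; this
  makes the p-value bit-for-bit invariant under swapping case/control labels
  together with score reversal at a fixed seed.
- **Discreteness caveat.** With scores (0, 1, 2) the trend statistic depends
  on the resampled row only through the integer allele count a₁ + 2a₂, so
  the permutation null is a coarse lattice. The ties-included permutation
  p therefore sits systematically *above* the continuous asymptotic tail by
  roughly the tie point mass (several hundredths at cohort scale for
  mid-range p). The Monte-Carlo p converges on the exact permutation tail —
  the suite verifies this against full enumeration of the null — and should
  not be expected to match the asymptotic p to within Monte-Carlo error.
  This is inherent to exact conditional inference on a lattice, not an
  implementation artifact.
- A principal-component-based check of Hardy-Weinberg deviation is
  sometimes mentioned alongside the χ² test in this literature without a
  concrete procedure; none is implemented here.

## Synthetic data

`simulate_trio` emulates a trio variant callset:

- Background population allele frequencies follow Beta(0.3, 3) truncated to
  (0.0005, 0.5), so the frequency filter sees both common (≥ 3 %) and rare
  variants. Panel frequencies scatter around the population value by a
  lognormal factor (σ = 0.25) with 15 % missing per panel.
- The four parental alleles are Bernoulli(af) draws (Hardy-Weinberg)
  conditioned on at least one alternate allele being present — a
  multi-sample VCF only lists sites called in someone — sampled exactly via
  the conditional binomial. The child inherits one uniformly chosen allele
  per parent, so Mendelian consistency holds by construction.
- Phred call qualities are Normal(45, 8) clipped at 0, with a 5 % fraction
  redrawn uniformly below 20 — representative of high-coverage whole-genome
  calls while exercising the confidence filter.
- Consequence classes, predictor scores and flags follow realistic
  proportions (40 % synonymous, 20 % missense with uniform SIFT scores,
  rare gain-of-function/clinical flags), so each later stage removes
  background at a plausible rate.
- The planted variant is heterozygous in mother and daughter, hom-ref in
  the father, rare or absent in every panel, protein-damaging, and in a
  disease-context gene — surviving each stage by construction. Penetrance
  defaults to 1.0; below 1.0 the unaffected father may carry the allele
  with probability 1 − penetrance, which realistically breaks the
  segregation filter.
- One global seed drives a named substream per component (trio genotypes,
  annotations, network, cohort), so changing one component's workload never
  perturbs another's draws; identical spec + seed gives byte-identical
  output files.

`simulate_cohort_table` draws controls multinomially under Hardy-Weinberg at
allele frequency p and cases from the same probabilities reweighted by
(1, γ, γ²) — the multiplicative genotype-relative-risk model, the standard
single-locus case-control generative model. Default arm sizes are 109 cases
and 111 controls, matching the larger replication cohort modelled.

What the generator does **not** emulate: linkage disequilibrium between
background variants, sequencing reads or genotyping error processes,
population stratification or admixture, relatedness beyond the trio, and
sites with more than two segregating alleles. Passing tests therefore
demonstrate the correctness of the cascade logic and the statistics under
the stated generative model, not robustness to those real-data phenomena.

## Problem sizes used in the validation suite

The packaged checks run the cascade on trios of 2 000 background variants
across 100 seeds (planted-variant recovery is 100/100 with median kept-set
size well under 5 % of background), calibrate the exact 2×3 Fisher test's
type-I error on 2 000 null cohort tables of 109/111 samples at p = 0.2
(observed rate ≈ 0.05, within the exact binomial 99 % envelope of a
conservative test), verify power is monotone in γ over {1, 1.5, 2, 3}, and
compare the Fisher implementation with the brute-force oracle over every
2×3 table of total size ≤ 12.

## Known limitations

- Only haploid and diploid genotype calls are modelled.
- The HGVS parser covers exactly the two forms the workflow needs
  (substitution, delins); everything else raises an explicit error.
- `classify_delins` reports the arithmetic consequence of a length change.
  A two-base deletion replaced by one base is a frameshift by that
  arithmetic even where an upstream annotation table describes the same
  event as a single amino-acid substitution; such contradictions in inputs
  are surfaced, never reconciled silently.
- Residue letters (e.g. K→E) are carried from annotation inputs, not
  computed: translation would require transcript sequences, which are out
  of scope.
- No covariate adjustment, meta-analysis across cohorts, or
  multiple-testing correction: raw per-table p-values are reported, flagged
  at p < 0.05 on the genotype-level exact test only.
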