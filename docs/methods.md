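# Methods

This note documents the models, estimators and numerical conventions behind
corekit, the choices made where several conventions exist, and what the
synthetic germplasm generator does and does not emulate.

## Data model

Genotypes are diploid codominant SSR calls: for each accession and locus an
unordered pair of allele labels, taken as integer fragment sizes in base
pairs.  No fragment-size binning or sizing correction is applied; calls are
used exactly as given (allele calling is an upstream concern).  A missing
genotype is written `0` on disk — the GenAlEx convention — and held as a
negative sentinel in memory.  An accession may be entirely untyped at a
locus; a half-missing call is rejected because it leaves the allele dosage
ambiguous and would corrupt frequency estimates.  Metabolite concentrations
(mg/g dry weight) must be complete and non-negative: the core-sampling
deletion rule compares totals directly, so no imputation is offered.
Accession order is preserved from the input everywhere, and every procedure
is deterministic in that order.

## SSR mining

Perfect tandem runs of 1–6 bp motifs are reported when the repeat count
reaches the per-motif-length minimum (defaults 10, 6, 5, 5, 5, 5 — the common
MISA setting for transcriptome scans).  Conventions:

* Runs are maximal and truncated to complete repeats
  (`end − start + 1 = motif length × repeats`); coordinates are 1-based
  inclusive on the given strand.
* A motif that is a repetition of a shorter unit (ATAT) is only reported at
  the shorter period, so no region is double-counted.  With the default
  thresholds this is exactly MISA's sub-pattern suppression; under unusual
  custom thresholds (a longer period with a laxer bp requirement than its
  primitive unit) the two could diverge on pathological inputs.
* Two runs separated by at most `max_interruption` bases (default 100 bp,
  MISA's default; configurable) merge into one *compound* record, which
  counts as a single locus in summaries.
* A single `N` terminates any run and runs of `N` are never SSRs; characters
  outside `{A, C, G, T, N}` are errors.  Reverse-strand scanning is
  unnecessary because canonical motif classes (lexicographic minimum over
  cyclic rotations of the motif and its reverse complement, e.g. CT → AG)
  already fold the strands.

## Diversity statistics

With allele frequencies `p_i` at a locus (copies / 2·N over the N accessions
typed there — pairwise deletion, the POPGENE default) the per-locus
statistics are Na, Ne = 1/Σp², Ho (heterozygote fraction among typed), Nei's
plug-in gene diversity H = 1 − Σp², Levene-unbiased He = 2N/(2N−1)·H,
Shannon's I = −Σ p ln p, and Botstein's PIC = 1 − Σp² − ((Σp²)² − Σp⁴).
Reporting both the plug-in H and the unbiased He reproduces the POPGENE
convention in which the two differ in the second decimal on a ~200-accession
panel.  Means across loci are unweighted (a locus with more typed accessions
gets no extra weight), and the allele retention rate of a subset is
Ra = 100 · meanNa(subset) / meanNa(full), reported to two decimals.

## Genetic structure

Codominant calls are expanded to a binary **band matrix** (accession ×
distinct allele; 1 = carries ≥ 1 copy; dosage collapsed).  A missing call
flags all of that locus's columns unknown for that accession, and unknown
columns are excluded pairwise downstream.

* **Simple matching distance** d = 1 − (matches, including shared absences)
  / (mutually known columns) — the NTSYS input for UPGMA.
* **Band squared-Euclidean distance** Σ(x−y)² over mutually known columns,
  rescaled by (total/known columns) under missingness — the GenAlEx-style
  individual distance for codominant data and the default input for PCoA,
  AMOVA and LDSS.  ("Nei's genetic distance" between individuals is not
  uniquely defined, so this explicit band distance is used instead, with
  simple matching selectable.)
* **UPGMA** merges the minimum-distance pair at height d/2 with size-weighted
  average linkage.  Ties break to the lowest (row, column) cluster index, so
  the dendrogram is deterministic; Newick branch lengths are height
  differences (ultrametric).
* **PCoA** eigendecomposes the Gower-centered matrix −½·J·D²·J.  Negative
  eigenvalues (non-Euclidean input) are reported but carry no coordinates
  and are excluded from the percent-variance denominator.
* **AMOVA** partitions SS_total = Σ_{i<j} d²_ij / n into among- and
  within-population parts; variance components come from the expected mean
  squares with the standard unequal-sample-size coefficient n₀, and
  PhiPT = σ²_among/(σ²_among + σ²_within).  Negative components are clamped
  to zero with a warning (standard practice).  The permutation p-value
  shuffles population labels with a fixed seed and compares the *unclamped*
  statistic, so that null p-values are not piled at 1 by ties at zero.
  Pairwise population PhiPT is the same analysis restricted to each pair.
  The within-individual level (Phi-IS) is out of scope; only the
  among/within-population partition is reported.

## LDSS core sampling

Least-distance stepwise sampling deletes genetic duplication one accession
at a time: locate the minimum off-diagonal distance among retained
accessions — exactly the first merge UPGMA would perform, which makes the
procedure equivalent to "repeated clustering" without rebuilding a
dendrogram — and remove the pair member with the lower total coumarin
content (unweighted sum over compounds; per-compound weights are
configurable).  Removals do not change the distances among the remaining
accessions, so the matrix is masked rather than recomputed.  Checkpoints are
recorded whenever the retained count hits a target size, which makes the
ladder nested by construction.  Tie rules, both deterministic: minimum
distance → lowest (row, column) index pair; equal coumarin totals → remove
the lexicographically larger accession id.

Target sizes default to half-up rounding of n×ratio (minimum 1).  Published
ladders occasionally mix rounding conventions (e.g. a 30% row of 63 out of
208 alongside a 40% row of 83), so an explicit `sizes=` override reproduces
any given ladder verbatim.

## Evaluation

A candidate core is compared against the original panel and the removed
complement on all seven statistics.  The significance tests on Ne, H and I
are **paired across loci**: core and original share the same loci, so the
per-locus values are coupled and an independent-samples t-test would discard
that structure.  No multiple-testing correction is applied across the three
parameters.  Degenerate inputs: zero variance of the paired differences
yields p = 1 when the mean difference is also zero, otherwise p = 0 with a
warning.  The PCoA overlay projects the full panel once and flags core
membership, rather than re-ordinating the core alone, so both sets share
axes.  A seeded uniform random-subset baseline (Ra and coumarin-mean
distributions over replicate draws) provides the reference against which
LDSS retention is judged.

The pipeline's selection rule formalizes "mainly genetic diversity,
supplemented by metabolites": among ladder collections with Ra ≥ 90%
(threshold configurable) choose the smallest, breaking ties by the higher
total-coumarin mean.

## Synthetic germplasm

The generator emulates the study design the package was built around: three
weakly differentiated wild populations of 70/69/69 accessions, 17 SSR loci
with 4–15 alleles each, and six skewed, population-structured coumarin
variables.  Per locus, ancestral frequencies are drawn from a flat symmetric
Dirichlet over the drawn allele count and population frequencies from the
Balding–Nichols Dirichlet(p·(1−F)/F), giving a single interpretable
differentiation knob with E[Fst] = F; genotypes are two independent gametes
within population (HWE, no linkage).  Allele labels form a dinucleotide
ladder of plausible fragment sizes.  Missing calls are masked completely at
random (default rate 1%).

The default F is 0.035.  The binary band encoding amplifies differentiation
relative to allele-level F, and a replicate calibration (F grid × 12–20
seeds) showed F = 0.035 realizes a mean among-population AMOVA share of
≈ 6.3% (range ≈ 5–8% across seeds, within the documented [2%, 12%] band)
with maximum pairwise PhiPT ≈ 0.07–0.09 — the weak-differentiation regime of
wild, outcrossing, gene-flow-connected populations.

Coumarins are log-normal per compound with multiplicative per-population
shifts (additive on the log scale): the first two populations are shifted up
in columbianadin and down in osthole, the third the reverse, reproducing the
qualitative geographic pattern of such panels.  Medians and spreads are set
so that columbianadin dominates (mean ≈ 2 mg/g, occasional extremes near the
18–19 mg/g seen in real panels, truncated at 20 mg/g — truncation rather
than redraw, a small documented bias), osthole averages ≈ 1.2 mg/g and
umbelliferone stays near 0.05 mg/g.

What the generator does *not* emulate: stepwise SSR mutation, linkage
between loci, genotyping artefacts (null alleles, stutter, allele dropout),
isolation-by-distance or migration structure beyond the single-F island
model, and metabolite–genotype correlation (coumarin levels are conditionally
independent of the genotype given the population).  Passing tests on
synthetic panels therefore demonstrate correctness of the estimators and the
sampling algorithm under these idealized conditions, not robustness to those
real-data features.

## Problem sizes and numerics

The test suite and the acceptance script run panels of up to 208 accessions
× 17 loci (seconds per stage), brute-force oracle comparisons on ≤ 12
accessions at 1e−10…1e−12 tolerances, and 200-replicate random baselines.
Frequencies must sum to 1 within 1e−12 per locus; distance matrices are
symmetrized and clipped at 0 to absorb floating-point noise; PCoA treats
eigenvalues below a 1e−10 relative threshold as null.  All randomness flows
through a single seeded NumPy generator per operation, so identical seeds
give bit-identical outputs end to end (the run manifest records SHA-256
digests of every artifact to make this checkable).
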