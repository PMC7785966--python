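# corekit

Construction and evaluation of **core collections** for germplasm panels from
codominant SSR (microsatellite) genotypes and per-accession metabolite
profiles.

A core collection is the smallest subset of a germplasm panel that still
represents the panel's genetic (and here also metabolic) diversity.  corekit
implements the full analysis for a medicinal-plant setting: wild accessions
genotyped at multi-allelic SSR loci, with the six root coumarins
(umbelliferone, 8-methoxypsoralen, bergapten, columbianetin acetate, osthole,
columbianadin, mg/g dry weight) quantified per accession.  The package is
aimed at researchers in plant genetic resources who need a reproducible,
scriptable version of the POPGENE / NTSYS / GenAlEx + stepwise-sampling
workflow.

## What it computes

* **SSR mining** (`corekit.ssr`) — MISA-style detection of perfect and
  compound microsatellites in transcript FASTA, with the standard minimum
  repeats (10, 6, 5, 5, 5, 5 for motif lengths 1–6), canonical motif classes
  (e.g. CT → AG/CT) and summary statistics.
* **Diversity statistics** (`corekit.diversity`) — per locus, with allele
  frequencies p and N typed accessions:
  Na; Ne = 1/Σp²; Ho; Nei's gene diversity H = 1 − Σp²;
  unbiased He = 2N/(2N−1)·H; Shannon's I = −Σ p ln p;
  Botstein's PIC = 1 − Σp² − Σ_{i<j} 2p²ᵢp²ⱼ; plus unweighted means across
  loci and the allele retention rate Ra = 100 · meanNa(subset)/meanNa(full).
* **Genetic structure** (`corekit.structure`) — binary band encoding of the
  codominant calls, simple-matching and band squared-Euclidean distances,
  UPGMA (Newick output), principal coordinates analysis, one-level AMOVA with
  Phi-PT and permutation p-values, pairwise population Phi-PT.
* **LDSS core sampling** (`corekit.ldss`) — least-distance stepwise
  sampling: repeatedly find the closest pair of retained accessions and
  delete the member with the lower total coumarin content, checkpointing
  nested subsets at a ladder of sampling ratios (40%…10% by default).
* **Evaluation** (`corekit.evaluation`) — retention percentages, t-tests on
  Ne/H/I paired across loci, removed-set comparison, coumarin means, PCoA
  overlay, and a uniform random-subset baseline.
* **Synthetic germplasm** (`corekit.synthetic`) — Balding–Nichols panels
  with a controlled differentiation parameter F and population-structured
  log-normal coumarin profiles, so the entire pipeline runs with no external
  data.

## Worked example

```python
import corekit as ck

panel = ck.generate(ck.study_like_config(), seed=1)   # 208 accessions, 3 pops, 17 loci
summary = ck.diversity_summary(panel.genotypes)
print(round(summary.means["na"], 2), summary.total_alleles)
# 9.12 155

dist = ck.genetic_distance(panel.genotypes)            # band squared-Euclidean
res = ck.amova(dist, panel.populations)
print(f"{res.percent_among:.1f}% among populations, PhiPT={res.phi_pt:.3f}")
# 8.3% among populations, PhiPT=0.083

lad = ck.ladder(panel.genotypes, panel.metabolites)    # 40%..10% LDSS ladder
print(lad.table[["name", "size", "ra", "mean_total"]].round(2).to_string(index=False))
#     name  size      ra  mean_total
# original   208  100.00        4.37
#     40CC    83   96.13        5.12
#     35CC    73   96.13        5.25
#     30CC    62   95.48        5.37
#     25CC    52   92.90        5.57
#     20CC    42   91.61        5.91
#     15CC    31   87.10        6.06
#     10CC    21   84.52        6.72
print(ck.select_core(lad.table))
# 20CC
```

The ladder shows the expected trade-off: as the sampling ratio shrinks, the
allele retention rate Ra declines while the mean total coumarin content of
the retained accessions rises (the deletion rule always removes the
lower-content member of the closest pair).  `select_core` picks the smallest
collection still retaining ≥ 90% of the original alleles, breaking ties by
coumarin content.

The same analysis is available from the shell:

```sh
corekit simulate --seed 1 --out panel/
corekit run --simulate --seed 1 --out results/
corekit mine-ssr --fasta transcripts.fa --out ssr
```

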