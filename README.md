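# twinseg

Post-twinning de novo variant, CNV and pathway analysis for quartet
families of monozygotic twins discordant for a phenotype.

## The problem

Monozygotic (MZ) twins develop from one zygote and are germline-identical,
so when one twin is affected by a congenital condition (the motivating case
is non-syndromic microtia-atresia, a malformation of the external ear) and
the co-twin is not, the genetic differences between them point at
*post-twinning* (post-zygotic) mutations. The analysis unit is the quartet:
affected twin (proband), unaffected co-twin, and both parents. A variant
that is carried by the proband but absent from the co-twin and both parents
arose after the twinning split and is a candidate cause of the discordance;
a variant shared by both twins but absent in the parents is an ordinary
germline de novo mutation and cannot explain it.

`twinseg` implements this design as a tested, reusable library:

* **segfilter** — segregation over the quartet plus three annotation
  criteria: keep protein-altering classes only (frameshift, coding indels,
  missense, stopgain, intron-exon boundary), exclude variants with minor
  allele frequency strictly above 10% in any of five population databases
  (1000 Genomes, HapMap CHB, NHLBI ESP, dbSNP, ExAC), and exclude
  synonymous/intronic classes. Every retained event carries full filter
  provenance.
* **recurrence** — variants, genes and CNV-hit genes recurring in at least
  two unrelated families.
* **cnvcall** — read-depth CNV calling against a *within-family* reference
  built from the healthy members: per-target median of normalized depths,
  log2 copy ratios with a pseudocount, greedy threshold segmentation
  (loss ≈ −1 for a one-copy deletion, gain ≈ +0.585 for a single-copy
  gain).
* **enrich** — pathway enrichment by the upper-tail hypergeometric
  probability

  P = 1 − Σᵢ₌₀^{m−1} C(M,i)·C(N−M,n−i) / C(N,n),

  with M the genes in the pathway, m the candidate genes in it, N the genes
  across all pathways and n the candidate genes within N; Benjamini-
  Hochberg q-values over the pathways hit in ≥ 2 families; significance at
  P < 0.05 and q < 0.2. The sum is evaluated with exact integer
  combinatorics.
* **twinqc** — zygosity verification by twin genotype concordance (MZ pairs
  sit near 99.9%) and coverage summaries.
* **synthdata** — a synthetic-cohort generator with a planted-mutation
  truth table, so every stage is testable without access to raw sequencing
  data.
* **vario / pipeline / cli** — VCF (via cyvcf2), annotation-table, GMT and
  pedigree I/O with normalized variant keys; cohort orchestration with a
  reproducible JSON manifest; a thin `twinseg` command with `simulate`,
  `qc`, `segregate`, `recur`, `cnv`, `enrich` and `run-all` subcommands.

## Worked example

```python
from pathlib import Path
from twinseg.synthdata import CohortScenario, generate_cohort
from twinseg.segfilter import FilterConfig, run_family

cohort = generate_cohort(
    CohortScenario(n_families=1, n_sites=500, depth_dispersion=0, seed=11),
    Path("demo_cohort"),
)
family = cohort.families[0]
events = run_family(cohort.vcf_paths[family.family_id],
                    cohort.annotation_path, family, FilterConfig())
for e in events:
    ad = e.genotypes["proband"]
    print(e.chrom, e.pos, f"{e.ref}>{e.alt}", e.gene, e.functional_class,
          f"{ad['alt_depth']}/{ad['depth']}")
```

prints

```
7 5000000 A>C DNMG001 missense 194/388
8 5000100 AT>A DNMG002 frameshift 194/388
8 5000200 A>C DNMG003 stopgain 194/388
```

— the three planted post-twinning mutations, heterozygous in the proband at
half of the 388× noise-free depth and absent from the co-twin and parents;
nothing else in the cohort survives segregation. The `examples/` directory
has one narrative script per capability (simulation, QC, segregation,
recurrence over the published six-family tables, CNV calling, enrichment,
full pipeline).

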