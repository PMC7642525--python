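# Methods

## Study design and model

The package analyses quartet families — an affected monozygotic twin
(proband), the unaffected co-twin, and both parents — to find candidate
causes of phenotypic discordance. Because MZ twins share their germline,
the only sequence variants that can explain discordance are post-zygotic
events arising after the twinning split. Operationally:

* **post-twinning de novo**: proband carries the alternate allele; co-twin
  and both parents are confidently homozygous reference. These are the
  candidates.
* **pre-twinning de novo**: both twins carry; parents are homozygous
  reference. These are ordinary germline de novo mutations, computed and
  flagged separately (`segfilter.segregate_family`) because they cannot
  explain discordance.

"Confidently homozygous reference" is genotype hom_ref *and* an alt-allele
read fraction at or below `max_carrier_alt_fraction` (default 0.05). The
read-level condition guards against allele dropout: a carrier genotyped
hom_ref but showing 10% alt reads is more plausibly an undercalled
heterozygote than a true negative. Sites with a missing genotype in any
non-proband member are excluded (conservative: a candidate must be
positively absent, not merely uncalled). Proband evidence requires
`alt_depth >= 4` and `depth >= 10` by default; none of these three
thresholds comes from the published criteria, and all are config-exposed.

## Annotation filters

The three retained criteria, applied to segregating keys with full
per-filter provenance:

1. functional class in {frameshift, nonframeshift indel, missense,
   stopgain, splice boundary} ("InDels" is read as both frameshift and
   non-frameshift coding indels; the intron-exon boundary class is its
   own vocabulary entry);
2. exclusion when the variant's frequency is *strictly* above
   `maf_threshold` (default 0.10) in at least one of the five population
   databases (1000 Genomes, HapMap CHB, ESP, dbSNP, ExAC). A frequency
   absent from a database never triggers exclusion — missing is not zero;
3. exclusion of synonymous and intronic classes.

Variant identity everywhere is `(chrom, pos, ref, alt)` after
multi-allelic splitting and minimal representation (shared suffix trimmed,
then shared prefix trimmed while advancing the position; no reference
genome required). This prevents representation differences from defeating
cross-family matching. Chromosome names are normalized by stripping a
leading `chr`.

## Recurrence

Recurrence is counted over distinct families (never the two twins of one
pair): a variant recurs when its normalized key is a candidate in >= 2
families; a gene recurs when any candidate event hits it in >= 2 families,
possibly through different variants; a gene is CNV-recurrent when called
gain/loss segments overlap its interval by >= 1 base in >= 2 families.
CNV direction is reported as `mixed` when different families disagree;
both directions count toward recurrence. HGVS labels are reporting-only
and never used for matching.

## CNV calling

A transparent stand-in for targeted-capture CNV pipelines keeping the
central design idea: the copy-number reference is built *within the
family* from the healthy members (co-twin and parents), so shared capture
and batch biases cancel.

1. Each subject's per-target depths are rescaled to a fixed mean of 100
   reads per target. Rescaling to a fixed constant (rather than to some
   input-dependent total) makes the downstream ratios exactly invariant to
   a global rescaling of all inputs, pseudocount included.
2. Reference = per-target median of the normalized healthy members; the
   median absolute deviation is recorded as spread; zero-median targets
   are masked out.
3. Ratio per target: `log2((p + c) / (r + c))` with pseudocount `c = 1`
   read on the normalized scale. A heterozygous loss sits near −1, a
   single-copy gain near +0.585; both are slightly attenuated by the
   pseudocount and by the carrier's own mean-normalization (a large event
   shifts the subject mean), which is the usual behaviour of
   mean-normalized depth ratios.
4. Segmentation is deliberately greedy threshold-plus-merge rather than
   circular binary segmentation: consecutive targets on the same side of
   `gain_threshold` (+0.3) / `loss_threshold` (−0.3) merge; gain/loss runs
   shorter than `min_targets` (3) are demoted to neutral. This is simple,
   exactly testable, and adequate for the clean planted events the
   generator produces; it has no statistical model of noise.

Sex chromosomes are processed but flagged (`sex_chrom_flag`), since
quartets mix sexes and no ploidy correction is applied.

## Pathway enrichment

For pathway gene sets read from GMT, the universe N is the union of all
pathway genes; candidate genes outside every pathway are excluded from n
(and logged) — N and n always refer to the same universe. Per family, a
pathway is "hit" when it contains at least one of that family's candidate
genes; only pathways hit in >= `min_recurrent_families` (2) families are
tested — the two-step order (recurrence first, testing second) is applied
as stated, and Benjamini-Hochberg q-values are computed over the tested
pathways only. The tested statistic uses the pooled (union) candidate set;
the published description is ambiguous between pooled and per-family
testing, so pooled was chosen and per-family upper-tail probabilities are
emitted alongside for transparency. The q-value estimator is plain BH
(the published choice of estimator is unstated) and is labelled as such.

`hypergeom_tail(M, m, N, n)` evaluates the upper tail with exact integer
combinatorics: the shorter of the two tails is summed as an integer
numerator (the complement identity `upper = 1 − lower` is applied inside
the exact arithmetic, so there is no floating-point cancellation), and the
single final big-integer division is correctly rounded. Against an
exact-rational oracle over the full grid M ≤ N ≤ 60 the relative error is
0; `m = 0` returns exactly 1.

## Synthetic cohorts

The generator emulates the *outputs* of an exome study of six discordant
MZ quartets after variant calling and annotation; it does not simulate
reads.

* Germline sites are diploid biallelic SNVs on a deterministic autosomal
  grid. Each parent is heterozygous with probability `germline_het_rate`
  (default 0.25, a plausible exome-wide average for common variant sites);
  alleles are transmitted Mendelianly and both twins inherit the same
  germline genotype.
* Somatic mosaicism: each site flips the genotype of one randomly chosen
  twin with probability `twin_discordance_rate`. Such flips are by nature
  Mendelian-inconsistent (that is what a somatic mutation is), so the
  Mendelian-consistency property is asserted at discordance 0.
* Planted post-twinning mutations are heterozygous in the proband only.
  A blueprint entry (gene, functional class, MAF profile, shared flag)
  controls the annotation each planted event receives; `shared=True`
  plants the same site in every family to create known recurrences.
* Read depth is negative-binomial with mean `depth_mean` (default 387.6
  reads, the cohort's published mean on-target coverage) and dispersion
  0.1 (variance μ + 0.1μ², a typical exome-capture overdispersion);
  heterozygous alt fractions are Binomial(depth, 0.5). Dispersion 0 is the
  noise-free mode: constant depths and exact half alt fractions, which is
  what makes exact precision/recall statements meaningful.
* A VCF record is emitted for *every* site, including all-reference sites,
  so twin concordance measured downstream is an unbiased estimator of
  1 − `twin_discordance_rate` rather than being conditioned on variant
  sites.
* CNV depth tables live on a separate 1 kb target grid (400 targets over
  two chromosomes by default) with genes of 10 consecutive targets;
  planted CNVs multiply the carrier's target depths by copy_number/2.
* Gene sets (GMT) partition the germline gene universe into blocks, with
  planted genes distributed round-robin, so enrichment runs end-to-end.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: alignment and calling artefacts, mapping bias,
multi-allelic and clustered variation, linkage disequilibrium, GC/capture
bias in depth, population stratification, and realistic annotation errors.
The generator answers "is the logic of each stage correct?", not "how does
the pipeline perform on real exomes?".

## Zygosity QC

Twin concordance compares genotype *categories* (hom_ref/het/hom_alt) at
sites where both twins are non-missing and pass `min_gq` (20) and
`min_depth` (8); there is no published formula for the ~99.9% figure, so
the genotype-level reading was chosen. The monozygosity verdict threshold
(0.99) is a conventional QC default, far below MZ expectation and far
above the dizygotic range. Concordance is symmetric in the twins and
tightening either threshold can only shrink the denominator.

## Problem sizes and numerical choices

The test and acceptance workloads use cohorts of 6 quartets with a few
hundred germline sites (and one 100,000-site single-family cohort for the
concordance calibration) — large enough for the binomial calibration
bounds to be informative and for every truth-table statement to be exact,
while keeping full runs to seconds. Acceptance checks compare the measured
concordance against the two-sided 99% binomial interval around
1 − 0.001. Floating output is written with `%.6g`; all randomness flows
from explicit integer seeds through `numpy.random.SeedSequence` spawning,
which is what makes repeated runs byte-identical.

## Known limitations

* The segmentation has no noise model; on noisy real depth data it will
  fragment events near the thresholds.
* No mosaic-fraction modelling: a post-twinning variant present in only a
  fraction of the proband's cells lowers the alt fraction and may fail the
  proband evidence thresholds.
* Recurrence carries no population background model; recurrence counts are
  descriptive, not significance statements.
* GO DAG structure, term redundancy and ontology parsing are out of scope;
  gene sets are taken as given in GMT form.
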