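# Methods

`rohvar` implements the computational chain used to isolate a fully
penetrant recessive disease variant in a small family study within a closed
population (the motivating setting is a lethal canine ciliopathy mapped in
a terrier breed): Bayesian genotype calling, case-homozygosity region
mapping, recessive-model variant filtering, splice-consequence prediction,
and cohort validation statistics. This note records the models, the
parameters that matter, and the choices made where the design was open.

## Genotype model

At a biallelic site with `r` reference and `a` alternate reads, the
likelihood of genotype H ∈ {hom-ref, het, hom-alt} is binomial with
per-read alternate probability ε, ½, 1−ε respectively, where ε is the
symmetric per-base error rate (default 0.01, a typical short-read
substitution error scale). With a prior P(H|G) over genotypes the posterior
is

    P(H | G, R) = P(H|G) · P(R|H) / P(R|G),   P(R|G) = Σ_H P(H|G) · P(R|H)

and the call is H\* = argmax_H P(H|G,R), made only when the site has at
least `min_reads` reads (default 2).

Numerical choices:

* The default prior is uniform; the reference-similarity prior that a
  production caller would use is unspecified in this setting, and a
  population prior can be passed as a parameter.
* The hom-alt likelihood is evaluated as the mirrored binomial
  `Binom(r; n, ε)` rather than `Binom(a; n, 1−ε)`. The two are identical
  analytically, but `1 − (1 − ε) ≠ ε` in floating point; the mirrored form
  makes the ref/alt symmetry bitwise exact, so genuinely symmetric evidence
  produces an exact posterior tie.
* Exact posterior ties are no-calls, never arbitrary picks: a forced pick
  would silently bias the downstream segregation filter.
* The direct product formula for the binomial pmf falls back to the
  log-space pmf when it under- or overflows (depths ≳ 1000).

## Homozygosity mapping

Candidate loci are markers that are (i) polymorphic in the cohort (both
alleles observed), (ii) fully genotyped, and (iii) homozygous in every case
for one shared allele. Identity of the homozygous allele across cases is
required by default (autozygosity around a recessive allele is identity by
descent); `allow_discordant_hom` relaxes this to any-homozygous.

Removed loci (missing data or monomorphic) are excised from the marker map
*before* candidate runs are merged, so they thin runs without breaking
them; only analyzed non-candidate loci interrupt a run. With realistic
array missingness (~0.1–1% per genotype) a break-on-missing rule would make
runs of >200 consecutive candidates statistically impossible in any cohort
of several animals, so excision is the only reading under which long runs
can exist at all. The merge operation itself remains a pure run-length
decomposition over whatever mask it is given.

Merged regions are scored by

    priority_r = 2 · MAF_r · length_r / max(length_r*)

where `length_r` is the candidate-SNP span in kb and `MAF_r` is the carrier
minor-allele frequency within the region. Regions are retained when
`priority > 0.15` and the run exceeds 200 candidate SNPs (both strict).
The score rewards regions that are long and still polymorphic among
obligate carriers — exactly the signature of a shared ancestral haplotype
that is heterozygous in carriers and homozygous in cases; its ceiling of
2 · 0.5 · 1 = 1 is reached by the longest region when carriers are
heterozygous at every SNP.

`MAF_r` aggregation is not uniquely determined by the formula as stated:
the default is the mean over the region's candidate SNPs of the per-SNP
carrier minor-allele frequency, and a pooled-allele-count variant is
available behind `pooled_maf`. The length normalisation makes priorities
invariant to any global rescaling of coordinates.

## Recessive-model variant filtering

The filter chain applies, in order:

1. **QC** — keep variants with call rate > 0.2 and MAF > 0.05 (strict
   inequalities, computed over the sequenced samples). MAF is a *keep*
   condition: within a seven-sample design of 2 cases / 2 carriers /
   3 controls the causal allele has MAF ≈ 6/14 ≈ 0.43, so the filter
   removes poorly supported and near-monomorphic calls, not the signal.
2. **Segregation** — every case homozygous-alt; every obligate carrier
   heterozygous or missing; every control hom-ref, het, or missing.
   Missing genotypes are *not* tolerated in cases: a case without a
   confirmed homozygous call cannot support the variant.
3. **ROH intersection** — keep variants inside a retained region
   (0-based half-open span).
4. **Consequence triage** — keep splice_donor, stop_gained, splice_region
   and missense classes. The classifier is a minimal single-transcript
   model: splice_donor = intronic +1/+2 past an exon 3′ end; splice_region
   = exonic last 3 nt of a junctioned exon or intronic +3..+8 / −8..−3;
   coding classes by codon substitution; precedence splice_donor >
   stop_gained > splice_region > missense > synonymous. A reference-allele
   disagreement with the supplied sequence is an error, not a silent skip.
5. **Known-variant exclusion** — exact (chrom, pos, ref, alt) matches
   against a catalogue of previously known variants are removed.

Every stage is a pure per-variant predicate (QC and segregation commute),
so survivor counts are non-increasing and are reported per stage.

## Splice-consequence model

A donor-site variant is mapped to HGVS c. notation via an exon/CDS
transcript model (strand-aware; intronic positions are donor-anchored in
the 5′ half of the intron and acceptor-anchored in the 3′ half). Cryptic
donor candidates are exonic GT dinucleotides within a window of the exon's
3′ end (default 60 nt), scored by the number of matches of the junction
9-mer (−3..+6) to the IUPAC consensus MAG|GTRAGT, ties broken toward the
smaller deletion. This is a deliberate consensus count, not a trained
position-weight matrix: in the motivating study the activated donor was
observed experimentally, so the scan is a ranking aid and the pipeline
treats the chosen offset as an input when reproducing consequence numbers.

Given a cryptic offset, the aberrant mRNA is the spliced mRNA minus the
exon's terminal `offset` nt; translation restarts from the canonical ATG
and runs to the first stop. Reported geometry:

* `frameshift` ⇔ `deleted_bp % 3 ≠ 0` (verified exhaustively in tests);
* `ptc_transcript_pos`: 1-based start of the stop codon in the aberrant
  mRNA, `None` when the canonical stop is still used;
* `aberrant_tail_aa`: both proteins are anchored at the start codon, the
  longest common prefix and the disjoint longest common suffix are removed,
  and the tail is what remains of the aberrant protein. A frameshift yields
  its full novel run (e.g. 85 aa); a clean in-frame deletion yields 0.
* an NMD heuristic flag (premature stop more than 50 nt upstream of the
  last exon junction), marked heuristic — a stop in the final exon escapes
  it, consistent with a truncated transcript remaining detectable.

Transcript alignment (used to localise the deleted block between a normal
and an aberrant transcript) is global Needleman–Wunsch with match +1,
mismatch −1, gap open −10, extend −0.5 via Biopython's PairwiseAligner.
Affine penalties are essential here: with linear gap costs, splitting a
50-bp deletion into scattered gaps costs nothing extra and any chance flank
match makes fragmentation optimal, which contradicts how the standard
pairwise-alignment web tools (whose behaviour this reproduces) report a
single contiguous gap.

## Cohort statistics

Carrier frequency is the heterozygote fraction among all genotyped animals;
the display percentage rounds half-up at one decimal (29/483 = 6.004% must
print 6.0%, which banker's rounding also gives, but half-up is the
convention for reported frequencies). The association test is a two-sided
Fisher exact test computed by hypergeometric enumeration (all tables with
the observed margins whose probability does not exceed the observed
table's), in an allelic (2×2 allele counts) and a genotypic-recessive
(hom-alt vs other) variant. The odds ratio is ∞ when only the denominator
holds a zero cell; tables with a zero row or column margin are rejected as
errors. No mode is claimed to correspond to the unidentified test behind
the motivating study's published p-value.

## Synthetic study generator

The generator emulates the study design end to end, and its defaults are
the study conditions at desk scale:

* **Pedigree** — one founder is a shared carrier ancestor; two carrier
  lineages descend from it and meet in a final carrier × carrier mating
  (default 3 generations, litter size 6). The final litter is resampled
  until it contains ≥ 2 affected homozygotes — the in-silico analogue of
  ascertainment, since families enter such studies precisely because
  affected offspring appeared. Intermediate litters are resampled until a
  carrier exists to continue the lineage. Affected individuals never
  reproduce (lethality is modelled as affection status only). Three
  unrelated founders join the last generation as sequencing controls.
* **SNP array** — 10,000 markers at 1 kb spacing over four chromosomes
  (the real array's ~170k markers scaled down ~17×), founder haplotypes
  i.i.d. Bernoulli(0.3) per marker, transmission with recombination
  probability 0.1 per marker interval, missingness 0.002. Every haplotype
  slot carrying the causal allele holds the ancestor's haplotype across the
  causal region (default 350 kb ≈ 350 markers on chromosome 2), and a
  gamete transmitting the causal allele copies its parent's causal-slot
  region segment — transmission therefore stays Mendelian marker by marker
  while cases are guaranteed homozygous and allele-identical across the
  region and carriers heterozygous for it.
* **Transcriptome** — 24 toy genes (≥3 exons, GT..AG introns, ATG-initiated
  CDS, terminal stop), six of them inside the causal region so that decoy
  variants have host genes. The designated reporter gene is a *synthetic*
  stand-in for the canine INPP5E transcript with the study geometry: ten
  exons, a 613-aa canonical protein, exon 9 ending at coding position 1572
  with a strong GTAAGT donor (the +5 G is the causal G>A target), and a
  single exonic cryptic GT 50 nt upstream of that donor. For the default
  offset the coding sequence is engineered so that cryptic-donor use yields
  a 594-aa frameshift protein whose last 85 residues are aberrant, while
  every unconstrained codon is random; the exon 9 window is kept free of
  other GT dinucleotides so the scan has a unique candidate.
* **Exome table** — 500 variants: one causal splice-region variant carrying
  the pedigree's causal genotypes; 15 decoys inside the causal region
  (8 missense, 7 splice-region) sharing the causal genotype vector — they
  ride the same autozygous haplotype, which is exactly why real studies
  find a block of co-segregating candidates there — flagged as previously
  known; and background variants with Hardy–Weinberg genotypes (allele
  frequency ~U(0.05, 0.45), a rare tranche below 0.04, a low-call-rate
  tranche). Background genotype vectors are redrawn whenever they would
  satisfy the recessive pattern, so the number of recessive-compatible
  variants is a design parameter (1 + n_decoy_recessive), not a random
  outcome.
* **Pileups** — per (sample, site): depth ~ Poisson(36) (the study's
  coverage scale; parameter-light shotgun approximation), alternate reads
  binomial with probability ε, ½, 1−ε by true genotype; a missing true
  genotype is capture dropout (depth 0).

All randomness flows from `SimConfig.seed` through per-component seed
streams; a fixed seed reproduces every output byte for byte.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium and recombination-map
realism (homozygosity-run detection depends only on run structure, not LD),
genotyping batch effects, base-quality variation, multi-allelic sites and
indels, multiple transcripts per gene, litter-size/fitness effects, and
population structure beyond the single shared ancestor.

## Problem sizes and determinism

Default validation uses 20 seeded synthetic studies (10k markers, 500
variants, 7-sample sequencing design, 7-animal array cohort); a single run
takes well under a second in memory and the full 20-seed recovery check a
few seconds. Coordinates are internally 0-based half-open everywhere;
VCF/GFF3/HGVS (1-based) and BED (0-based) conversions happen only in the
IO layer, and the genotype codes are 0/1/2 with −9 (`./.` in VCF) for
missing.

## Known limitations

* The consequence classifier is single-transcript and SNV-only; it is a
  triage device, not a VEP replacement.
* The donor scan's consensus count is coarse; it ranks exonic GTs, it does
  not predict splicing efficiency.
* The ROH caller tolerates no genotyping error inside a run (a single
  discordant call breaks it), matching the strict candidate-locus
  definition rather than sliding-window callers.
* `read_fam` recovers structure and roles but not causal genotypes
  (unknowable from a FAM file); analyses that need them use the simulated
  pedigree object.
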