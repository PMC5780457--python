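# Methods

This note documents the model behind `radmut`, the default parameters, the
numerical choices, and the deliberate simplifications. The package is
modelled on whole-genome resequencing studies of carbon-ion-irradiated
*Arabidopsis* (M2 generation, four groups of six plants), but all problem
sizes used in the examples and tests are the package's own choices.

## Biological model

**Experimental design being emulated.** M1 plants are irradiated (as dry
seeds or seedlings); induced mutations are heterozygous in M1 and
segregate 1:2:1 in single M2 descendants. Resequencing an M2 plant
therefore observes a mutation as heterozygous with probability 2/3 and
homozygous with probability 1/3 (homozygous wild type is invisible),
giving the expected het:hom ratio of 2.0. The M1 mutation frequency is 4/3
times the M2 frequency, because a segregating mutation is absent from a
given M2 plant with probability 1/4.

**Mutation categories.** Seven classes: single-base substitution (SBS),
single-base deletion (−1), deletion of ≥2 bp, single-base insertion (+1),
insertion of ≥2 bp, complex, and structural variation (SV). A deletion
accompanied by an insertion is sized by its net reference-length change
(e.g. a 10-bp deletion plus a 3-bp insertion counts as a 7-bp deletion).
Two or more SBSs and/or short indels (<50 bp each) whose footprints are
separated by fewer than 10 unmutated reference bases are merged into one
complex event; runs of ≥2 consecutive SBSs are likewise complex. Merged
events count once in all frequency statistics. SVs are carried through but
excluded from frequency and spectrum comparisons, matching the practice of
short-read studies where SV allele frequencies are unreliable.

*Merge-gap interpretation.* The merge rule is stated as "a gap of less
than 10 bases": two calls merge when ≤9 unmutated bases separate their
footprints, and stay separate at a gap of 10. Internal unmutated runs of
≥2 bases are recorded as separators on the merged event.

**Call filtering.** A call needs ≥3 mutant reads. Calls with allele
frequency (AF) ≤0.25 are excluded as unreliable (the threshold below which
validation studies found false positives). AF in (0.25, 0.80) is
heterozygous; AF ≥0.80 homozygous. A call is vetoed if any other sample
shows the same allele at AF ≥5% (cross-sample contamination), and sites
called in more than two samples are removed everywhere as shared
background artifacts (independent induced mutations essentially never
recur at one site across samples). Background carrier status itself
requires AF >5%, so sequencing traces do not inflate the carrier count.

**Context signatures.** For indels the package scores, non-exclusively:

- *homopolymer*: the edited base(s) lie in a single-base run ≥3 long,
  counting identical flanking bases (and, for insertions, the inserted
  bases themselves — the post-edit run);
- *polynucleotide repeat*: a tandem repeat (unit 2–6 bp, ≥2 exact copies,
  not period-1) overlaps the edit footprint, searched within ±12 bp;
- *junction microhomology* (Del_≥2/Ins_≥2 only): for deleted segment D
  with upstream flank U and downstream flank W, the length is
  max(longest common suffix(U, D), longest common prefix(D, W)), capped at
  10 bp and at |D|; ≥2 bp counts as present. The 2-bp minimum keeps the
  expected false-positive rate on random sequence low (a 1-bp match occurs
  at ~44% of random junctions) while retaining the short homologies that
  microhomology-mediated end joining uses.

Flags are computed on left-aligned (normalized) variants. Left-alignment
never destroys a ≥2 bp junction homology (it can convert upstream-suffix
homology into downstream-prefix homology), which was verified empirically
against a brute-force scan; the detectors are therefore alignment-stable.

**Impact prediction.** SBSs in a CDS are translated codon-wise on the
gene's strand (synonymous / nonsynonymous / stop gain / stop loss); indels
and complex events intersecting a CDS are frameshift when the net length
change is not a multiple of 3, otherwise nonsynonymous; deletions covering
a gene's whole CDS span (including symbolic SVs) count as gene loss for
every covered gene. Splice, UTR and intronic effects are all "noncoding" —
the quantity of interest is protein-coding genes with amino-acid changes.
Per sample, a gene counts once; if hit both heterozygously and
homozygously it counts under the homozygous (stronger) state.

**Statistics.** Mutation frequency (MF) = events / genome length; the
reference genome length for the real organism is 119,146,348 bp. Group
summaries report mean ± standard error (sample sd/√n). Group MFs are
compared by Welch's t-test; categorical tables (spectra, categories, size
bins) by chi-squared homogeneity tests without continuity correction,
flagging expected counts <5. The six-class strand-merged SBS spectrum
(G:C>A:T, A:T>G:C transitions; four transversions) yields Ti/Tv. Deletion
sizes are binned 1 / 2–9 / 10–49 / ≥50 bp. The phenotype-screen
calculation is per-locus MF = mutants/(plants × loci), scaled by the
genome's protein-coding gene count to give expected homozygously disrupted
genes per plant. Survival curves are fit to the single-hit multitarget
model S(D) = 1 − (1 − e^(−D/D0))^n by bounded least squares
(`scipy.optimize.curve_fit`, D0 > 0, n ≥ 1), with the quasi-threshold
dose Dq = D0·ln n; the fit requires ≥3 dose points including an
unirradiated control and a real dose response.

## Simulator

**Reference genome.** Bases are drawn i.i.d. at the requested GC fraction
(default 0.36, AT-rich like a plant genome); with homopolymer enrichment
w > 0 each base copies its predecessor with probability w/(w+10), raising
run density without biasing composition (the copy channel preserves the
stationary distribution). Gene models are embedded in place as valid ORFs
(ATG start, no internal stop, stop codon; ~30% carry one intron; both
strands), so reference-vs-annotation consistency holds by construction.

**Mutation planting.** Per-sample category counts are Poisson around
per-group expectations. The four built-in group profiles (two
dry-seed-like doses, two seedling-like doses) use per-category
expectations, deletion-size weights and context fractions chosen to
reproduce the published qualitative contrasts: ~32–38 events/plant and
43–48% deletions for dry-seed-like groups versus ~20–22 events/plant and
25–27% deletions for seedling-like groups; SBS class weights give
Ti/Tv ≈ 0.8 (within the reported 0.67–0.88 range) with G:C>A:T dominant.
Events within a sample are placed ≥60 bp apart so independent events never
merge. Zygosity is drawn 2:1 het:hom (`mendelian_m2`); complex-event
constituents share one zygosity and event id.

Context biases are honoured exactly: the configured fraction of −1/+1
events is placed inside homopolymer runs ≥3 (run start ≥ position 3 so the
anchored VCF representation exists), and the configured fraction of
Del_≥2/Ins_≥2 events carries ≥2 bp junction microhomology (insertions as
tandem duplications of the downstream flank). "None"-context placements
are rejection-sampled so that neither the planted footprint *nor its
left-aligned equivalent* carries a run, tandem repeat or microhomology —
without this, random sequence would contaminate the "none" class (a
repeat overlaps a random footprint tens of percent of the time) and the
recovered context fractions would drift above the planted ones.

**Call emission.** Depth ~ Poisson(30); mutant reads ~ Binomial(depth,
0.5) for heterozygous and Binomial(depth, 0.98) for homozygous truths
(0.98 < 1 keeps the AF ≥0.80 homozygous band meaningful). False positives
are injected per sample at AF ≤0.25 with ≥3 supporting reads — exactly the
population the AF filter must remove. Background artifacts are planted at
one site in ≥3 samples. Indel calls are emitted VCF-anchored; nothing is
pre-normalized, so the pipeline's left-alignment is genuinely exercised.

## Numerical and implementation choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; simulation, analysis and report bundles are byte-reproducible.
- Normalization trims the trailing shared base, extends left from the
  reference when an allele empties, then trims leading shared bases; it is
  idempotent and preserves net length (property-tested).
- Percentages in published-style tables are integer-rounded (`round`);
  standard errors use the sample standard deviation (ddof = 1).
- The survival fit seeds D0 from the terminal slope of the curve and
  starts n at 5, with bounds enforcing D0 > 0, n ≥ 1.
- Established libraries handle standard formats and statistics: pysam
  (VCF), Biopython (FASTA, translation), gffutils (GFF3), scipy
  (tests, fitting), pandas (tables).

## Validation

The test suite pins the detectors to independent oracles: the
microhomology detector against a brute-force suffix/prefix scan over
random deletions; the codon-effect predictor against whole-CDS
retranslation of mutated genomes; normalization against exhaustive
enumeration of equivalent variant representations; the survival fit
against noise-free synthetic curves (Dq within 1%). End-to-end, 100
replicate four-group cohorts must yield recovered category proportions
within ±0.015 of planted, zero false events (100% exclusion of injected
false positives and background sites), and ≥80% power for the planted
dry-seed vs seedling MF difference at α = 0.05.

## Limitations

- The simulator plants point-process mutations on an i.i.d.-plus-runs
  genome; it does not model real chromatin context, mutation hotspots,
  mappability, or alignment artifacts beyond the injected low-AF false
  positives and shared background sites.
- Read support is binomial per site; there is no base-quality, strand-bias
  or mapping-quality model, and SV read support is nominal (SVs pass
  through the pipeline but their frequencies are not compared, matching
  the analysis practice being emulated).
- Effect prediction ignores splice sites, UTRs, regulatory regions and
  compound heterozygosity; genes are single-transcript models.
- Complex events are planted only as SBS+indel clusters within the merge
  window; nested or templated insertions are out of scope.
- Plotting (survival curves, spectrum bars) is not included; the report
  bundle is TSV/JSON only.
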