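# Methods

## Scope and model

The package analyzes three layers of base-editing data:

1. **Amplicon reads** from transient (protoplast-style) experiments: ~250-bp
   pre-merged single-end reads covering one 20-nt protospacer + 3-nt PAM.
2. **A genome** searched for gRNA-dependent off-target candidates: every
   locus on either strand within a Hamming-distance budget of a protospacer
   and carrying a matching PAM 3′ of it (SpCas9 geometry).
3. **Per-plant variant tables** (VCF, DNA or RNA) from regenerated lines:
   on-target genotypes, background somaclonal variation, and attribution of
   SNVs to off-target candidates.

Protospacer positions are numbered 1 (PAM-distal 5′) to 20 (PAM-proximal);
the PAM occupies positions 21–23. All conversions are expressed on the
protospacer strand, so a genomic G>A inside a minus-strand site is a C>T
editing event at the complementary protospacer position.

## Read classification and quantification

Reads are aligned globally to the amplicon with affine gap scoring
(match +2, mismatch −1, gap open −6, gap extend −1; `Bio.Align`).
Length-preserving reads that already meet the identity floor are mapped
gaplessly — an exact shortcut, since a gapless map is the optimal global
alignment for equal-length, high-identity pairs under these scores — which
keeps 10⁵-read batches fast; the affine aligner handles everything else and
the two paths agree on gap-free reads (property-tested). Reads with
identity below 60% of the amplicon are discarded and counted; the floor
tolerates several percent sequencing error on 250-bp amplicons while
rejecting foreign sequence.

Outcome classes follow a fixed precedence: INDEL (any alignment gap
overlapping the protospacer + PAM footprint), then SIMULTANEOUS (≥1 C>T and
≥1 A>G on one read), C_TO_T, A_TO_G, C_TO_G, OTHER_SUB, WT. Class tallies
partition the retained reads. Denominator conventions:

* **Per-position efficiency** = edited reads / informative reads, where
  informative = retained and gap-free over the footprint. Efficiencies are
  defined only where the reference base admits the conversion.
* **Site-level efficiency** (headline) = fraction of informative reads with
  ≥1 conversion of that type anywhere in the protospacer; the maximum
  per-position efficiency is also emitted, since either convention appears
  in practice.
* **Indel frequency** = INDEL reads / all retained reads — substitutions
  and indels are reported as separate quantities, not competing outcomes.
* Simultaneous reads contribute to both the C>T and A>G per-position
  numerators (profiles stay marginal) but to only the SIMULTANEOUS class
  tally (classes stay a partition).

Allele tables count protospacer-region sequences of informative reads;
ranking is by count with lexicographic tie-break, and the reference allele
is always flagged (and appended if outranked).

## Editing-window inference

Across sites, the mean ± SEM of each (position, conversion) efficiency is
taken over *eligible* sites only — those whose reference base at that
position admits the conversion. SEM uses the sample standard deviation
(n − 1) and is undefined for n < 2. The window of a conversion is the
maximal contiguous run of positions with mean ≥ `threshold_fraction` × the
peak position mean (default 0.5, i.e. full width at half maximum); among
equal-length runs the one containing the argmax wins. Half-max is a
deliberate, documented convention — editing windows are usually described
verbally — and the fraction is a tunable. Positions with no eligible site
break contiguity rather than counting as zero.

## Off-target search and attribution

The search is mismatch-only (no DNA/RNA bulges), case-insensitive, with any
non-ACGT base counting as a mismatch. Both strands are scanned with a
vectorized sliding-window comparison; the PAM constraint (3-nt IUPAC
pattern; the relaxed "NG" PAM is written "NGN") is applied at candidate
loci. Candidates are deduplicated, sorted by (chrom, start, strand), and
0-mismatch candidates are flagged as on-target. Correctness is established
against an independently written exhaustive per-position scan on genomes
with planted sites (set-identity across budgets 0–3 and patterns NGG/NGN).

SNVs overlapping a candidate's protospacer interval are attributed with
their protospacer position and strand-resolved conversion; an attribution
is *consistent* when the conversion is one a base editor produces (C>T,
A>G, or the C>G by-product).

## Cohort profiling

* **Spectrum**: SNVs collapse onto the six pyrimidine-anchored classes
  (C>A, C>G, C>T, T>A, T>C, T>G); complementing ref/alt never changes the
  class, so DNA strand is irrelevant. RNA-mode tables reuse every operation:
  C-to-U appears as C>T, A-to-I as A>G (class T>C).
* **Zygosity** from allele frequency with strict inequalities: af > 0.7
  homozygous/biallelic, 0.3 < af ≤ 0.7 heterozygous, af ≤ 0.3 subclonal.
  Boundary values fall to the lower class. The germline-transmittable
  fraction is defined as heterozygous ∪ homozygous. AF comes from the AF
  INFO field, falling back to allele depth / total depth; records with
  neither are rejected and counted. Multi-allelic records split per ALT.
* **Genotype matrix**: a plant × site cell is `biallelic` / `edited` /
  `unedited` by the same cutoffs applied to the best consistent-conversion
  SNV inside the protospacer interval.
* **Motif context**: the genomic 3-mer centered on each mutated base,
  oriented so the mutated base reads as the deaminated C or A (purine-
  anchored C>T-class and pyrimidine-anchored A>G-class calls are
  reverse-complemented). Information content per position is R = 2 − H
  bits, H = −Σ f·log₂ f, with no small-sample correction; edge SNVs lacking
  a full flank are skipped and counted.
* **Caller intersection**: variants present in every callset keyed by
  (chrom, pos, ref, alt), AF/depth from the first callset; commutative and
  idempotent over key sets.

## Synthetic-data generator

The generator defines the conditions under which the pipeline is validated;
all randomness flows from one explicit integer seed through a single
`numpy.random.Generator` per call, and identical (parameters, seed) give
byte-identical outputs.

* **Amplicons**: 250 bp by default, one protospacer + concrete PAM placed
  uniformly, uniqueness across both strands verified (redraw on collision).
  The default window metadata is positions 4–8, the TadA-8e-style window.
* **Reads**: conversions applied only at positions carrying the source base
  (validated; a probability on the wrong base is an error). Under
  `independent`, each (read, position) converts by its own Bernoulli draw.
  Under `linked`, one uniform draw per read gates all conversions
  (position i converts iff u < p_i): a comonotone coupling that preserves
  every marginal rate exactly while making window edits co-occur on the
  same reads, reproducing the simultaneous C>T + A>G top alleles a dual
  deaminase generates; with equal rates it reduces to a single Bernoulli
  gate for the whole window. Indels: per-read rate (default at the
  sequencing-error floor, 0.5%), length uniform on 1–5 bp, insertion or
  deletion equiprobable, anchored uniformly inside the protospacer — the
  simplest model consistent with indels being reported only as an aggregate
  frequency. Sequencing error: uniform substitution at 0.3% per base, no
  quality model; FASTQ qualities are constant Q37. Truth labels record the
  applied conversions and indels (not subsequent sequencing errors), so the
  observed rate at a position with true rate p is p(1−e) + (1−p)e/3 — the
  quantity rate-recovery checks test against.
* **Genomes**: uniform-composition random chromosomes (≥1 kb). Planted
  sites are written at exact Hamming distances (mismatch positions and
  substitute bases drawn from the seed), minus-strand placements as reverse
  complements with the PAM 5′ in genome coordinates; overlap and bounds are
  rejected, and post-hoc verification re-reads every planted locus and
  re-scans the genome to confirm no unintended exact match was created.
* **Cohorts**: per plant, planted edits at specified conversions and AFs
  (first eligible window position, strand-resolved ref/alt verified against
  the genome) plus Poisson background SNVs (default mean 200/plant, the
  scale of tissue-culture somaclonal variation) drawn from a six-type
  spectrum with AFs from a subclonal/heterozygous/homozygous mixture
  (default 0.40/0.35/0.25, making the germline-transmittable share ~0.6,
  i.e. above one half) and uniform within each band (0.05–0.3 / 0.3–0.7 /
  0.7–1.0). Background indels (default mean 60/plant) are 1-bp events at a
  separate rate. Background variants avoid candidate protospacer intervals
  by default so attribution truth is exact. The default spectrum
  (C>T-dominant at 0.30, T>C 0.20, remainder spread) is a plausible
  tissue-culture-like preset; per-position editor rate magnitudes likewise
  ship as presets, labeled as such, since editor-specific true rates are a
  property of each deaminase, not of this artifact.

### What the generator does *not* model

PCR duplication and chimeras, primer and GC bias, quality-score-dependent
errors, paired-end structure (reads are pre-merged by construction),
multi-nucleotide variants, copy-number changes, and bulge-type off-targets.
Passing tests therefore demonstrate correctness of the *analysis logic*
under a clean generative model — coordinate arithmetic, strand resolution,
denominators, class precedence, statistical recovery — not robustness to
every artifact of real libraries, which upstream read QC and variant
calling are expected to handle.

## Numerical and design choices

* Alignment scores (+2/−1/−6/−1) and the 60% identity floor are package
  conventions, chosen to absorb ~3% substitution error on 250-bp amplicons
  without gapping.
* Allele-table and candidate orderings use deterministic tie-breaks
  (lexicographic; (chrom, start, strand)).
* Window inference requires a nonzero mean somewhere; an all-zero summary
  raises rather than returning a degenerate interval.
* Zygosity cutoffs are strict inequalities; `call_zygosity` rejects
  af outside (0, 1].
* Quantifying zero retained reads raises; efficiencies over zero
  informative reads are NaN, never 0.
* The pipeline derives all stage seeds from the single config seed by fixed
  offsets; manifests record SHA-256 checksums of every output so
  reproducibility is verifiable byte for byte.

## Problem sizes

Validation uses 10 sites × 10,000 reads for rate recovery (estimates within
4 binomial standard errors of generative truth), 5 sites × 5,000 reads for
window recovery (exact [4,8] for both channels of a dual editor), twenty
100-kb genomes with sites planted at 0–4 mismatches for search-oracle
equivalence, one ~600-SNV cohort for attribution (100% planted recovery,
zero background false attributions), and ~1,000-SNV cohorts for spectrum
recovery within multinomial 99% bands. These sizes give comfortable
statistical power at interactive runtimes; all scale linearly if larger
checks are wanted.

## Known limitations

* Off-target search is Hamming-only; bulge-tolerant matches are invisible.
* Site-level efficiency conventions differ across published tools; both
  emitted variants should be checked before comparing numbers across
  studies.
* The half-max window depends on the peak estimate; with few eligible sites
  per position the inferred boundary can wobble by a position, which the
  SEM columns make visible.
* RNA-mode profiling treats the variant table as given; it does not model
  RNA-editing-specific artifacts (splice proximity, hyper-edited reads).
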