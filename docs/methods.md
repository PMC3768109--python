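# Methods

## Input model

The caller consumes the 7-column extended pileup written by `samtools
mpileup -s`: chrom, 1-based position, reference base, depth, read-base
string, Phred+33 base qualities and Phred+33 per-read mapping qualities.
A per-read mapping-quality column is required because the filtering rules
act on each read's mapping quality, which the basic 6-column pileup does
not carry; this is a deliberate modernisation of older pileup layouts.
Indel observations (`+N<seq>`/`-N<seq>`) are attached to the read whose
base token they precede and inherit that read's qualities; `^X` consumes
the read-start mapping-quality character without producing a call; `*`
deletion placeholders count toward depth but never toward a base allele.
Pileup positions are 1-based, BED intervals 0-based half-open; all
internal positions are 1-based.

A fused fast path computes evidence directly from the token strings when
a line contains no indel/start/end tokens and every quality clears the
thresholds; it is property-tested for exact agreement with the general
per-read path and exists purely for throughput on 5000-deep lines.

## Caller thresholds and their senses

| parameter | default | sense |
|---|---|---|
| min base quality | 25 | strict >: a read at exactly 25 is excluded |
| min mapping quality | 15 | strict > |
| min filtered coverage | 10 | inclusive, required in both samples |
| min substitution alt reads | 20 | inclusive |
| max control alt fraction | 0.05 | strict <: exactly 5% fails |
| third-allele discard | 1/3 | inclusive: second allele at exactly one third discards |
| min indel reads (tumour) | 10 | inclusive |
| max indel reads (control) | 5 | strict <: 5 reads fail |
| min tumour:control indel ratio | 10 | inclusive; a clean control passes vacuously |
| second-indel discard | 0.40 | strict >: exactly 40% is kept |
| dominant-clone VAF | 0.20 | strict >: exactly 20% is subclonal |

Coverage and all fractions are evaluated on quality-*filtered* depth (the
reads actually taken into account), including the control-fraction rule;
whether the original procedure used raw or filtered control depth is not
determinable, and filtered depth is the internally consistent choice.
Only the single best non-reference allele per site is eligible — genuinely
multi-allelic somatic sites are excluded by the third-allele rule by
design. The second-indel rule is applied per site, not per window.
"Independent reads" means distinct read tokens; duplicate removal is an
upstream (alignment pipeline) responsibility. Control tolerances are
configurable so a remission sample harbouring residual mutant reads can
serve as control.

Subclonal calls are reported, not suppressed: whenever the absolute read
thresholds pass but VAF ≤ 20%, the call is flagged `subclonal`. The
effective subclone floor is therefore depth-dependent, ~0.4% of reads at
5000×.

MRD detection requires ≥ 5 mutant reads **and** a mutant fraction ≥ 0.001.
The absolute floor of 5 reads is a package choice (no principled value is
universal); it makes the 0.1% sensitivity bound exact at 5000× filtered
depth and guards against single-read artefacts at lower depths. Both
knobs are in `CallerConfig`.

VCF output left-anchors indels on the site's reference base (insertion:
REF=R, ALT=R+seq; deletion: REF=R+seq, ALT=R); no further normalisation
(e.g. realignment-aware shifting) is attempted.

## Copy-number model

Normalised count = mean per-base depth over an amalgamated exon ÷ total
mapped reads × 10⁶. Amalgamation merges overlapping *or touching* exonic
intervals per gene. The pipeline stages:

* **Sample QC** — per gene, per-sample mean counts are screened with Tukey
  fences (both directions, linear-interpolated quartiles); a sample
  outlying in more than 3 genes is excluded. The 3-gene threshold reflects
  the observation that genuinely comparable captures stay within a few
  sporadic outlier genes while a failed capture is aberrant across most of
  the panel. With ~10 samples the fences are themselves noisy and a
  borderline good sample is occasionally excluded along with the aberrant
  one; this costs a little power but no specificity, and the threshold is
  configurable.
* **Exon CV** — CV = sample standard deviation (ddof = 1) ÷ mean across
  retained samples; a zero-mean exon gets CV 0 with a warning.
* **Tukey screen** — an exon is flagged iff CV > Q3 + 1.5·IQR (upper
  fence only, strict; quartiles by linear interpolation between order
  statistics — the oracle tests use the same declared method).
* **Gene flags** — a gene is reported when more than one of its exons is
  flagged *and* at least one retained sample shows a fold change vs the
  across-sample median beyond `gain_ratio` (default 1.4) or `loss_ratio`
  (default 0.7) at ≥ 2 flagged exons. The ratio defaults sit between the
  heterozygous expectations (1.5× gain, 0.5× loss) and 1 with a noise
  margin. The implicated-sample requirement is a package addition: pure
  CV noise can lift two exons of a gene over the fence without any sample
  showing a copy-number-scale deviation, and dropping such genes removes
  essentially all false positives at panel scale. X-linked genes are
  excluded from the autosomal screen (their dosage varies with sex by
  design) and are instead used for the female:male validation ratio.
  A flagged gene with fewer than 3 target exons triggers a warning:
  without flanking-region coverage such calls are weak.
* **Duplication segments** — maximal contiguous run (≥ 2 exons) with fold
  change ≥ `gain_ratio` vs the cohort median; single-exon events are below
  the detector's design resolution.
* **Allelic imbalance** — a SNP is informative when the comparator's
  minor-allele fraction is within [0.3, 0.7]; imbalanced when the tumour's
  minor-allele fraction drops by ≥ 0.15 *and* a two-sided Fisher exact
  test on the 2×2 allele table rejects at α = 0.05. The exact-test +
  fraction-delta combination is a package decision (the underlying
  comparison is inherently qualitative); ≥ 2 informative imbalanced SNPs
  give a "deletion-consistent" locus verdict, exactly 1 only "suggestive",
  since without a matched comparator a single SNP cannot rule out
  constitutive imbalance. Direction is reported per SNP as the reduced
  allele; alleles at different SNPs are unphased, so cross-SNP direction
  consistency is not enforced.

## Synthetic cohort

The generators emulate a 34-gene capture panel on a fictitious genome
with one contig per gene (exons of 150 bp every 500 bp), sequenced to
5000× — no reference download, alignment or BAM handling is involved.

* Dominant-clone events are planted at VAF 0.45, a typical heterozygous
  variant in a high-blast-count marrow; per-event VAFs are not otherwise
  constrained by the study design. Frameshifts are encoded as 1–4 bp
  indels, the recurrent NPM1 event as a TCTG 4-bp insertion, and one
  3-bp in-frame insertion represents the single amino-acid duplication.
* Subclonal substitutions are planted at 4.4% and 4.1% (a co-occurring
  pair in one sample) and 3.0% of reads; one remission sample is clean,
  the other carries its diagnostic mutations at 1.5/2.0/2.4% of reads.
* Planted read qualities are 35/60 so quality filtering is not the
  variable under test unless a fixture degrades them deliberately.
* Deterministic mode writes exact counts (`round(vaf × depth)`) and
  raises on unrepresentable plants; sampled mode draws Poisson depths and
  binomial alt counts; identical spec + seed gives byte-identical files.
  Pileups cover ±10 bp windows around planted sites (the control covers
  the union), which keeps the full seven-sample cohort generation and
  calling under a few seconds while exercising every rule.
* The count-matrix cohort has 10 samples (5 F / 4 M retained after QC):
  per-exon capture efficiency lognormal (σ = 0.2) shared across samples,
  Poisson counts around efficiency × copy ratio × library size, X-linked
  exons at half dosage in males, a whole-gene loss in each of three
  samples (CYP2D6 ×1, PTEN ×2, copy ratio 0.5), an exon 2–9 gain (ratio
  1.5) in one, and one sample with an independent per-gene lognormal
  (σ = 0.75) distortion emulating failed capture.

What the fixtures do **not** model: sequencing error, strand bias,
GC/capture bias correlated with sequence, alignment artefacts around
indels, duplicate reads, or inter-sample capture noise beyond Poisson
counting. Passing tests therefore demonstrate that the decision rules are
implemented exactly and behave correctly at realistic depths and effect
sizes — not that the thresholds are optimal on real instrument data.

## Numerical choices

Quartiles everywhere use linear interpolation (`numpy.percentile`,
`method="linear"`). Allele ties rank by (count desc, allele asc) and
indel ties by (count desc, identity asc) for determinism. Sites present
in only one pileup are skipped; an empty tumour/control intersection is
an error. Zero filtered depth at an MRD query yields fraction 0, not
detected. All simulation randomness flows through
`numpy.random.default_rng(seed)`; derived seeds stay below 2³¹.

## Problem sizes

The shipped cohort runs at full 5000× depth but restricts pileups to
windows around planted sites (~400 positions per comparison); the
count-matrix cohort is 10 samples × 296 exons, with 25 replicates for the
dosage-ratio check; oracle-equivalence tests use 1000 random CV vectors
and 100 random pileup sites. These sizes exercise every code path at the
study's depths while keeping the whole suite and the acceptance script in
the seconds-to-a-minute range.

## Known limitations

* Internal tandem duplications longer than the read-level indel tokens
  (e.g. FLT3-ITD) surface only as generic indel/substitution flags, not
  as assembled events; a dedicated assay is the appropriate follow-up.
* The CNV detector reports relative dosage against the cohort median; a
  germline CNV (as for CYP2D6) and a somatic event are indistinguishable
  without a matched normal.
* No GC correction or segmentation HMM: the screen is designed for small
  panels at high depth where per-exon fold changes are large.
* The caller assumes duplicate-marked, realigned input; PCR duplicates
  inflate "independent" read counts if upstream marking is skipped.
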