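# amlpanel

Targeted-panel analysis for acute myeloid leukaemia with a normal
karyotype (AML–NK): somatic variant calling from deep tumour/control
pileups, minimal-residual-disease (MRD) read mining, and read-depth
copy-number detection on a capture panel of 24 recurrently mutated AML
genes plus 10 controls.

## The problem

AML–NK carries no cytogenetically visible lesion; its classification and
prognosis rest on the combination of point mutations, small indels and
copy-number changes across a few dozen genes, often distributed over
multiple leukaemic subclones. Hybridisation capture of all exons of a gene
panel followed by deep sequencing (~5000× per base) makes every class of
lesion visible at once — if the downstream statistics are right. This
package implements that downstream analysis for anyone working from
aligned pileups: clinical-research bioinformaticians, method developers,
and anyone who needs a transparent, fully tested reference for
threshold-based deep-panel calling.

## The method

**Somatic calling.** At every position covered in both a tumour and a
control sample, only reads with base quality > 25 and mapping quality > 15
count, and the position must retain filtered depth ≥ 10 in both samples. A
substitution is reported when the best non-reference allele has ≥ 20
tumour reads and < 5% of control reads, unless a second non-reference
allele reaches one third of that evidence (a signature of misalignment).
An indel needs ≥ 10 tumour reads on the identical event, < 5 control
reads, and ≥ 10× more tumour than control reads; a site whose second indel
exceeds 40% of the first is discarded. Calls with variant allele fraction
(VAF) > 20% of reads are labelled *dominant* (main leukaemic clone), the
rest *subclonal* — at 5000× the absolute thresholds resolve subclones down
to ~0.4% of reads. MRD mining re-counts reads supporting known diagnostic
variants in remission samples, detecting ≥ 5 mutant reads at ≥ 0.1% of
filtered depth.

**Copy number.** Depth is averaged per amalgamated exon (all overlapping
annotated exons merged) and divided by the sample's total mapped reads.
After excluding samples whose per-gene means are Tukey-fence outliers in
more than 3 genes (failed capture), each exon's coefficient of
variability CV = s/x̄ across samples is screened against the upper Tukey
fence Q3 + 1.5·IQR; genes with > 1 flagged exon and a sample showing a
copy-number-scale fold change (≥ 1.4× or ≤ 0.7× the cohort median) are
reported. Follow-ups find contiguous duplicated exon runs (partial tandem
duplications), check the female:male dosage ratio of X-linked genes
(expected 2), and test allelic imbalance at heterozygous SNPs (Fisher
exact on the 2×2 allele table plus a minor-allele-fraction drop ≥ 0.15).

All inputs are plain text: 7-column extended pileup (`samtools mpileup
-s` dialect), BED4(+kind) targets, TSV sample sheets and count matrices;
calls are written as VCF 4.2.

## Worked example

The package ships generators for a fully synthetic cohort (a fictitious
genome with one contig per panel gene) whose truth is known exactly.

```bash
python examples/call_variants.py
```

```
4 somatic calls in P3 (tumour vs control):
  CEBPA:1031 GC>G  deletion     VAF 45.0%  dominant  exonic  (2250/5000 tumour reads, 0/5000 control)
  CEBPA:1096 T>TAAC  insertion    VAF 45.0%  dominant  exonic  (2250/5000 tumour reads, 0/5000 control)
  NRAS:1536 G>A  substitution VAF 45.0%  dominant  exonic  (2250/5000 tumour reads, 0/5000 control)
  WT1:1546 ACT>A  deletion     VAF 45.0%  dominant  exonic  (2250/5000 tumour reads, 0/5000 control)
```

Each line is one somatic event: 2250 of 5000 quality-filtered tumour reads
(45%) carry the variant, none in the control, so all four belong to the
dominant leukaemic clone. `examples/mrd_mining.py` shows residual disease
quantified at 1.5–2.4% of reads in a remission sample,
`examples/cnv_scan.py` recovers a CYP2D6 loss, two PTEN losses and an MLL
exon 2–9 partial tandem duplication from the simulated count matrix, and
`examples/allelic_imbalance.py` confirms a deletion through heterozygous
SNPs. The same workflow is scriptable via the thin CLI:

```bash
amlpanel run-all --outdir out/ --seed 7     # fixtures -> VCF + MRD + CNV + manifest
amlpanel call --tumour T.pileup --control C.pileup --targets panel.bed --out calls.vcf
```

## Layout

- `src/amlpanel/pileup_io.py` — extended-pileup and BED parsing, per-read quality filtering
- `src/amlpanel/calling.py` — tumour/control caller, clonality, MRD mining, VCF output
- `src/amlpanel/cnv.py` — normalised counts, QC, CV/Tukey screen, duplication segments, allelic imbalance
- `src/amlpanel/fixtures.py` — synthetic cohort generators with truth tables
- `src/amlpanel/cli.py` — `amlpanel` command-line wrapper
- `docs/methods.md` — models, parameter choices and limitations
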