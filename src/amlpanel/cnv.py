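"""Read-depth copy-number analysis on a targeted capture panel.

Depth is summarised per *amalgamated exon* (all overlapping annotated exons
of a gene merged into one interval) as the mean per-base read count divided
by the sample's total mapped reads, times a fixed scale (1e6 by default).
Copy-number screening then proceeds in four stages:

1. sample QC — a sample whose per-gene mean counts are Tukey-fence outliers
   (both directions) for more than ``max_outlier_genes`` genes is dropped,
   since capture efficiency differences would masquerade as copy number;
2. per-exon coefficient of variability (sample sd / mean, ddof=1) across
   the retained samples;
3. Tukey upper-fence screen on the CVs (flag iff CV > Q3 + 1.5*IQR,
   linear-interpolated quartiles); a gene is reported when more than one of
   its exons is flagged and at least one sample shows a copy-number-scale
   fold change vs the across-sample median (>= ``gain_ratio`` or
   <= ``loss_ratio``);
4. targeted follow-ups: contiguous duplication segments (partial tandem
   duplications), the X-linked female:male dosage check, and allelic
   imbalance at heterozygous SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pileup_io import TargetRegion


@dataclass(frozen=True)
class AmalgamatedExon:
    """A merged exonic interval; the unit of depth normalisation."""

    gene: str
    exon_index: int
    chrom: str
    start: int  # 0-based half-open
    end: int

    @property
    def key(self) -> str:
        return f"{self.gene}:{self.exon_index}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ExonCountMatrix:
    """Samples x amalgamated-exons normalised mean depths.

    ``values`` is a DataFrame indexed by sample id with one column per exon
    key (``gene:index``); ``exons`` is aligned with the columns;
    ``total_mapped_reads`` is indexed like ``values``.
    """

    values: pd.DataFrame
    exons: list[AmalgamatedExon]
    total_mapped_reads: pd.Series

    def __post_init__(self) -> None:
        keys = [e.key for e in self.exons]
        if list(self.values.columns) != keys:
            raise ValueError("matrix columns do not match exon list")
        if not self.values.index.equals(self.total_mapped_reads.index):
            raise ValueError("total_mapped_reads index does not match samples")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalised counts must be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def exons_of(self, gene: str) -> list[AmalgamatedExon]:
        return sorted(
            (e for e in self.exons if e.gene == gene), key=lambda e: e.exon_index
        )

    def gene_means(self, samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Per-gene mean normalised count, genes x samples."""
        vals = self.values if samples is None else self.values.loc[list(samples)]
        genes = pd.Index([e.gene for e in self.exons], name="gene")
        return vals.T.groupby(genes).mean()


@dataclass
class CnvFlag:
    """A gene-level copy-number finding."""

    gene: str
    flagged_exons: list[int]
    direction: str  # "gain" | "loss"
    implicated_samples: list[str]
    evidence: dict[int, dict] = field(default_factory=dict)  # exon -> {cv, fence, ratios}


@dataclass(frozen=True)
class SnpAllelicCounts:
    """Allele read counts for one SNP in tumour and comparator samples."""

    snp_id: str
    tumour_a: int
    tumour_b: int
    control_a: int
    control_b: int


@dataclass(frozen=True)
class SnpVerdict:
    snp_id: str
    informative: bool
    imbalanced: bool
    direction: Optional[str]  # "A" | "B": the allele reduced in the tumour
    p_value: Optional[float] = None


def amalgamate_exons(raw_exons: Iterable[TargetRegion]) -> list[AmalgamatedExon]:
    """Merge overlapping (or touching) exonic intervals per gene.

    Intronic control regions are ignored.  Indices are reassigned in
    genomic order per gene.
    """
    by_gene: dict[str, list[TargetRegion]] = {}
    for r in raw_exons:
        if r.kind != "exonic":
            continue
        by_gene.setdefault(r.gene, []).append(r)
    merged: list[AmalgamatedExon] = []
    for gene, regions in by_gene.items():
        regions.sort(key=lambda r: (r.chrom, r.start, r.end))
        runs: list[list] = []
        for r in regions:
            if runs and runs[-1][0] == r.chrom and r.start <= runs[-1][2]:
                runs[-1][2] = max(runs[-1][2], r.end)
            else:
                runs.append([r.chrom, r.start, r.end])
        for i, (chrom, start, end) in enumerate(runs, start=1):
            merged.append(AmalgamatedExon(gene, i, chrom, start, end))
    merged.sort(key=lambda e: (e.chrom, e.start))
    return merged


def normalize_counts(
    per_base_depths: Mapping[str, Mapping[tuple[str, int], float]],
    exons: Sequence[AmalgamatedExon],
    total_mapped_reads: Mapping[str, float],
    scale: float = 1e6,
) -> ExonCountMatrix:
    """Build the normalised count matrix from per-base depths.

    ``per_base_depths[sample]`` maps (chrom, 1-based pos) -> depth; absent
    positions count as 0.  value(sample, exon) = mean per-base depth over
    the exon / total_mapped_reads * scale.
    """
    samples = list(per_base_depths)
    data = np.zeros((len(samples), len(exons)))
    for si, s in enumerate(samples):
        depths = per_base_depths[s]
        total = total_mapped_reads[s]
        if total <= 0:
            raise ValueError(f"total_mapped_reads must be > 0 for sample {s}")
        for ei, e in enumerate(exons):
            acc = 0.0
            for pos in range(e.start + 1, e.end + 1):  # 1-based positions
                acc += depths.get((e.chrom, pos), 0.0)
            data[si, ei] = acc / len(e) / total * scale
    values = pd.DataFrame(data, index=pd.Index(samples, name="sample"),
                          columns=[e.key for e in exons])
    totals = pd.Series({s: float(total_mapped_reads[s]) for s in samples},
                       name="total_mapped_reads").loc[samples]
    return ExonCountMatrix(values=values, exons=list(exons), total_mapped_reads=totals)


def matrix_from_exon_depths(
    exon_depths: pd.DataFrame,
    exons: Sequence[AmalgamatedExon],
    total_mapped_reads: Mapping[str, float],
    scale: float = 1e6,
) -> ExonCountMatrix:
    """Build the matrix when the mean depth per exon is already known
    (e.g. simulated directly at exon level)."""
    totals = pd.Series({s: float(total_mapped_reads[s]) for s in exon_depths.index})
    values = exon_depths.div(totals, axis=0) * scale
    values.columns = [e.key for e in exons]
    return ExonCountMatrix(values=values, exons=list(exons),
                           total_mapped_reads=totals.loc[values.index])


def _tukey_fences(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def qc_samples(
    matrix: ExonCountMatrix, max_outlier_genes: int = 3
) -> tuple[list[str], dict[str, list[str]]]:
    """Drop samples with aberrant per-gene means in too many genes.

    Per gene, a sample is an outlier when its mean normalised count falls
    outside the Tukey fences (both directions) computed across samples.
    Samples outlying in more than ``max_outlier_genes`` genes are excluded.
    Returns (retained sample ids, {excluded sample -> outlier genes}).
    """
    if len(matrix.samples) < 4:
        raise ValueError("sample QC needs at least 4 samples")
    gm = matrix.gene_means()  # genes x samples
    outlier_genes: dict[str, list[str]] = {s: [] for s in matrix.samples}
    for gene, row in gm.iterrows():
        lo, hi = _tukey_fences(row.to_numpy())
        for s, v in row.items():
            if v < lo or v > hi:
                outlier_genes[s].append(gene)
    excluded = {
        s: genes for s, genes in outlier_genes.items() if len(genes) > max_outlier_genes
    }
    retained = [s for s in matrix.samples if s not in excluded]
    return retained, excluded


def exon_cv(
    matrix: ExonCountMatrix, samples: Optional[Sequence[str]] = None
) -> pd.Series:
    """Coefficient of variability (sample sd / mean) per exon across the
    retained samples.  A zero-mean exon gets CV 0 with a warning."""
    vals = matrix.values if samples is None else matrix.values.loc[list(samples)]
    if len(vals) < 3:
        raise ValueError("exon CV needs at least 3 samples")
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    zero = mean == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} exon(s) with zero mean count; CV set to 0",
            stacklevel=2,
        )
    cv = sd.divide(mean).where(~zero, 0.0)
    cv.name = "cv"
    return cv


def tukey_outlier_exons(cvs: pd.Series) -> tuple[set[str], float]:
    """Flag exons whose CV exceeds the upper Tukey fence Q3 + 1.5*IQR
    (strictly; only the upper fence is used).  Returns (flagged keys, fence).
    """
    if len(cvs) < 4:
        raise ValueError("Tukey screen needs at least 4 exons")
    arr = np.asarray(cvs, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    fence = q3 + 1.5 * (q3 - q1)
    flagged = {k for k, v in cvs.items() if v > fence}
    return flagged, fence


def flag_cnv_genes(
    matrix: ExonCountMatrix,
    flagged_exons: set[str],
    cvs: Optional[pd.Series] = None,
    fence: Optional[float] = None,
    samples: Optional[Sequence[str]] = None,
    gain_ratio: float = 1.4,
    loss_ratio: float = 0.7,
) -> list[CnvFlag]:
    """Report genes with more than one Tukey-flagged exon.

    Direction and implicated samples come from each sample's fold change vs
    the across-sample median at the flagged exons: a sample is implicated
    when its ratio clears ``gain_ratio`` (or ``loss_ratio``) at >= 2 flagged
    exons of the gene, or at every flagged exon for genes with exactly 2.
    A gene with >1 flagged exon but no implicated sample is dropped as CV
    noise without a copy-number-scale fold change.
    """
    vals = matrix.values if samples is None else matrix.values.loc[list(samples)]
    by_gene: dict[str, list[AmalgamatedExon]] = {}
    for e in matrix.exons:
        if e.key in flagged_exons:
            by_gene.setdefault(e.gene, []).append(e)
    flags: list[CnvFlag] = []
    for gene, exons in sorted(by_gene.items()):
        if len(exons) < 2:
            continue
        exons.sort(key=lambda e: e.exon_index)
        n_gene_exons = len(matrix.exons_of(gene))
        if n_gene_exons < 3:
            warnings.warn(
                f"gene {gene} flagged with only {n_gene_exons} target exon(s); "
                "without flanking-region coverage the copy-number call is weak",
                stacklevel=2,
            )
        ratios = {}
        for e in exons:
            col = vals[e.key]
            med = float(col.median())
            ratios[e.exon_index] = col / med if med > 0 else col * np.nan
        need = 2
        gains, losses = [], []
        for s in vals.index:
            g = sum(1 for r in ratios.values() if r[s] >= gain_ratio)
            l = sum(1 for r in ratios.values() if r[s] <= loss_ratio)
            if g >= need:
                gains.append(s)
            if l >= need:
                losses.append(s)
        direction: Optional[str] = None
        implicated: list[str] = []
        if gains and not losses:
            direction, implicated = "gain", gains
        elif losses and not gains:
            direction, implicated = "loss", losses
        elif gains and losses:
            # mixed evidence: report the direction with more implicated samples
            direction, implicated = (
                ("gain", gains) if len(gains) >= len(losses) else ("loss", losses)
            )
        if direction is None:
            continue
        evidence = {
            e.exon_index: {
                "cv": float(cvs[e.key]) if cvs is not None else None,
                "fence": fence,
                "ratios": {s: float(ratios[e.exon_index][s]) for s in implicated},
            }
            for e in exons
        }
        flags.append(
            CnvFlag(
                gene=gene,
                flagged_exons=[e.exon_index for e in exons],
                direction=direction,
                implicated_samples=implicated,
                evidence=evidence,
            )
        )
    return flags


def detect_duplication_segment(
    matrix: ExonCountMatrix,
    gene: str,
    sample: str,
    samples: Optional[Sequence[str]] = None,
    gain_ratio: float = 1.4,
) -> Optional[tuple[int, int, float]]:
    """Find a contiguous run of duplicated exons in one sample.

    Returns (first_exon, last_exon, mean fold change) for the maximal run
    (length >= 2) of exons whose normalised count is >= ``gain_ratio`` times
    the across-sample median, or None.  Single elevated exons are below the
    detector's design resolution.
    """
    exons = matrix.exons_of(gene)
    if len(exons) < 3:
        raise ValueError(f"gene {gene} has fewer than 3 exons")
    vals = matrix.values if samples is None else matrix.values.loc[list(samples)]
    folds = []
    for e in exons:
        med = float(vals[e.key].median())
        folds.append(float(vals.loc[sample, e.key]) / med if med > 0 else np.nan)
    best: Optional[tuple[int, int]] = None
    run_start = None
    for i, f in enumerate(folds + [np.nan]):  # sentinel terminates last run
        if not np.isnan(f) and f >= gain_ratio:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                if best is None or (i - run_start) > (best[1] - best[0] + 1):
                    best = (run_start, i - 1)
                run_start = None
    if best is None or best[1] - best[0] + 1 < 2:
        return None
    lo, hi = best
    mean_fold = float(np.mean(folds[lo : hi + 1]))
    return exons[lo].exon_index, exons[hi].exon_index, mean_fold


def sex_linked_ratio(
    matrix: ExonCountMatrix,
    sexes: Mapping[str, str],
    gene: str,
    samples: Optional[Sequence[str]] = None,
) -> float:
    """Female:male ratio of the per-gene mean normalised count.

    With two X copies in females and one in males, an X-linked gene should
    give a ratio near 2; autosomal genes near 1.
    """
    use = matrix.samples if samples is None else list(samples)
    females = [s for s in use if sexes[s].upper().startswith("F")]
    males = [s for s in use if sexes[s].upper().startswith("M")]
    if not females or not males:
        raise ValueError("need at least one sample of each sex")
    gm = matrix.gene_means(use)
    if gene not in gm.index:
        raise KeyError(f"gene {gene} not in matrix")
    row = gm.loc[gene]
    return float(row[females].mean() / row[males].mean())


def allelic_imbalance(
    snps: Sequence[SnpAllelicCounts],
    het_band: tuple[float, float] = (0.3, 0.7),
    delta: float = 0.15,
    alpha: float = 0.05,
) -> tuple[list[SnpVerdict], str]:
    """Assess allelic imbalance (copy loss) at heterozygous SNPs.

    A SNP is informative when the comparator's minor-allele fraction lies
    within ``het_band``; it is imbalanced when the tumour's minor-allele
    fraction drops by at least ``delta`` AND a two-sided Fisher exact test
    on the 2x2 allele table rejects at ``alpha``.  The locus verdict is
    ``deletion-consistent`` with >= 2 informative imbalanced SNPs,
    ``suggestive`` with exactly 1, else ``no-evidence``.
    """
    verdicts: list[SnpVerdict] = []
    n_imbalanced = 0
    for snp in snps:
        c_tot = snp.control_a + snp.control_b
        t_tot = snp.tumour_a + snp.tumour_b
        if c_tot == 0 or t_tot == 0:
            verdicts.append(SnpVerdict(snp.snp_id, False, False, None))
            continue
        mf_c = min(snp.control_a, snp.control_b) / c_tot
        informative = het_band[0] <= mf_c <= het_band[1]
        if not informative:
            verdicts.append(SnpVerdict(snp.snp_id, False, False, None))
            continue
        mf_t = min(snp.tumour_a, snp.tumour_b) / t_tot
        _, p = stats.fisher_exact(
            [[snp.tumour_a, snp.tumour_b], [snp.control_a, snp.control_b]],
            alternative="two-sided",
        )
        imbalanced = (mf_c - mf_t) >= delta and p < alpha
        direction = None
        if imbalanced:
            direction = "A" if snp.tumour_a / t_tot < snp.control_a / c_tot else "B"
            n_imbalanced += 1
        verdicts.append(SnpVerdict(snp.snp_id, True, imbalanced, direction, p))
    if n_imbalanced >= 2:
        locus = "deletion-consistent"
    elif n_imbalanced == 1:
        locus = "suggestive"
    else:
        locus = "no-evidence"
    return verdicts, locus


def coverage_summary(
    per_base_depths: Mapping[tuple[str, int], float],
    targets: Sequence[TargetRegion],
    thresholds: Sequence[int] = (1, 10, 100, 1000),
) -> dict:
    """Fraction of target bases covered at >= each threshold, plus mean depth.

    ``per_base_depths`` maps (chrom, 1-based pos) -> depth; target bases
    absent from the map count as depth 0.
    """
    depths: list[float] = []
    for t in targets:
        for pos in range(t.start + 1, t.end + 1):
            depths.append(per_base_depths.get((t.chrom, pos), 0.0))
    arr = np.asarray(depths, dtype=float)
    if arr.size == 0:
        raise ValueError("no target bases")
    return {
        "total_bases": int(arr.size),
        "mean_depth": float(arr.mean()),
        "fractions": {int(t): float((arr >= t).mean()) for t in thresholds},
    }


def autosomal_cnv_scan(
    matrix: ExonCountMatrix,
    x_genes: frozenset[str] | set[str] = frozenset(),
    max_outlier_genes: int = 3,
    gain_ratio: float = 1.4,
    loss_ratio: float = 0.7,
) -> dict:
    """End-to-end screen: sample QC, autosomal exon CVs, Tukey fence, gene
    flags.  X-linked genes are excluded from the CV screen (their dosage
    varies with sex by design) and used only via :func:`sex_linked_ratio`.

    Returns a dict with retained/excluded samples, the CV series, the fence
    and the list of :class:`CnvFlag`.
    """
    retained, excluded = qc_samples(matrix, max_outlier_genes=max_outlier_genes)
    cvs = exon_cv(matrix, samples=retained)
    autosomal = cvs[[e.key for e in matrix.exons if e.gene not in x_genes]]
    flagged, fence = tukey_outlier_exons(autosomal)
    flags = flag_cnv_genes(
        matrix,
        flagged,
        cvs=cvs,
        fence=fence,
        samples=retained,
        gain_ratio=gain_ratio,
        loss_ratio=loss_ratio,
    )
    return {
        "retained": retained,
        "excluded": excluded,
        "cvs": cvs,
        "fence": fence,
        "flagged_exons": flagged,
        "flags": flags,
    }
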