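"""Synthetic panel fixtures: pileups and count matrices with known truth.

The default fixture emulates a 34-gene targeted AML panel (24 recurrently
mutated AML genes plus 10 control genes) sequenced to ~5000x on a
fictitious genome with one contig per gene, so no reference download is
ever needed.  It plants:

* the dominant-clone mutation catalogue of seven diagnostic samples —
  20 exonic events (11 substitutions, 9 indels) plus one intronic
  substitution — at 45% VAF, a typical heterozygous blast fraction;
* subclonal substitutions at 4.4%/4.1% of reads (co-occurring pair in one
  sample) and ~3% in another;
* two remission samples: one mutation-free, one carrying its diagnostic
  mutations at residual fractions of 1.5-2.4% of reads;
* a 10-sample copy-number cohort with one globally aberrant (QC-fail)
  sample, one whole-gene CYP2D6 loss, two PTEN losses and an MLL exon 2-9
  gain (a partial tandem duplication), with X-linked genes scaled by sex.

Deterministic mode places exact read counts with qualities (35/60) safely
above the caller's filters; sampled mode draws Poisson depths and binomial
alt counts from a fixed seed.  Every generator writes a truth table so the
pipeline's output can be asserted event by event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cnv import AmalgamatedExon, ExonCountMatrix, SnpAllelicCounts, matrix_from_exon_depths
from .pileup_io import TargetRegion

# panel layout: gene -> (exon count, X-linked?)
PANEL_GENES: dict[str, tuple[int, bool]] = {
    # AML genes
    "NRAS": (4, False), "DNMT3A": (12, False), "SF3B1": (10, False),
    "IDH1": (5, False), "KIT": (10, False), "TET2": (8, False),
    "CSF1R": (10, False), "NPM1": (11, False), "EZH2": (10, False),
    "JAK2": (12, False), "PTEN": (9, False), "WT1": (10, False),
    "MLL": (14, False), "CBL": (8, False), "KRAS": (5, False),
    "PTPN11": (8, False), "FLT3": (12, False), "IDH2": (6, False),
    "TP53": (9, False), "NF1": (12, False), "CEBPA": (1, False),
    "ASXL1": (12, False), "RUNX1": (8, False), "KDM6A": (10, True),
    # control genes
    "UGT1A1": (5, False), "PIK3CA": (10, False), "IKZF1": (8, False),
    "EGFR": (12, False), "BRAF": (10, False), "XRCC2": (3, False),
    "PAX5": (10, False), "TLR4": (4, False), "CYP2D6": (9, False),
    "HPRT1": (9, True),
}

X_GENES = frozenset(g for g, (_, x) in PANEL_GENES.items() if x)

EXON_LEN = 150
EXON_SPACING = 500  # start-to-start
FIRST_EXON_START = 1000  # 0-based

PLANT_BASE_QUALITY = 35
PLANT_MAPPING_QUALITY = 60


def exon_start(exon_index: int) -> int:
    """0-based start of an exon on its gene's contig."""
    return FIRST_EXON_START + (exon_index - 1) * EXON_SPACING


def plant_position(exon_index: int, offset: int) -> int:
    """1-based position of an offset within an exon."""
    if not 0 <= offset < EXON_LEN:
        raise ValueError("offset outside exon")
    return exon_start(exon_index) + offset + 1


# NF1 intronic control stretch between exons 2 and 3 (captured intron)
NF1_INTRON_START = exon_start(2) + EXON_LEN + 50
NF1_INTRON_END = NF1_INTRON_START + 100


@dataclass(frozen=True)
class PlantedVariant:
    """One planted somatic event with its expected call."""

    sample: str
    gene: str
    pos: int  # 1-based on the gene's contig
    ref: str  # anchoring reference base
    vtype: str  # substitution | insertion | deletion
    alt_seq: str  # alt base for subs; inserted/deleted sequence for indels
    vaf: float
    clonality: str
    region: str  # exonic | intronic
    label: str

    @property
    def chrom(self) -> str:
        return self.gene

    @property
    def vcf_ref(self) -> str:
        return self.ref + self.alt_seq if self.vtype == "deletion" else self.ref

    @property
    def vcf_alt(self) -> str:
        if self.vtype == "substitution":
            return self.alt_seq
        if self.vtype == "insertion":
            return self.ref + self.alt_seq
        return self.ref


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sex: str  # "F" | "M"
    role: str  # tumour | control | remission
    total_mapped_reads: int = 100_000_000


@dataclass(frozen=True)
class PlantedCnv:
    sample: str
    gene: str
    first_exon: int
    last_exon: int
    copy_ratio: float  # 1.5 heterozygous gain, 0.5 heterozygous loss


@dataclass
class FixtureSpec:
    """Full description of the synthetic study conditions."""

    panel: dict[str, tuple[int, bool]]
    samples: list[SampleInfo]
    planted_variants: list[PlantedVariant]
    mrd_queries: dict[str, list[PlantedVariant]]  # remission sample -> variants mined
    cnv_samples: list[SampleInfo]
    qc_fail_sample: str
    planted_cnvs: list[PlantedCnv]
    depth: int = 5000
    seed: int = 7

    def dominant_events(self) -> list[PlantedVariant]:
        return [v for v in self.planted_variants if v.clonality == "dominant"]

    def dominant_exonic_events(self) -> list[PlantedVariant]:
        return [v for v in self.dominant_events() if v.region == "exonic"]


def _sub(sample, gene, exon, off, ref, alt, label, vaf=0.45, region="exonic"):
    clon = "dominant" if vaf > 0.20 else "subclonal"
    return PlantedVariant(sample, gene, plant_position(exon, off), ref,
                          "substitution", alt, vaf, clon, region, label)


def _ins(sample, gene, exon, off, ref, seq, label, vaf=0.45):
    clon = "dominant" if vaf > 0.20 else "subclonal"
    return PlantedVariant(sample, gene, plant_position(exon, off), ref,
                          "insertion", seq, vaf, clon, "exonic", label)


def _del(sample, gene, exon, off, ref, seq, label, vaf=0.45):
    clon = "dominant" if vaf > 0.20 else "subclonal"
    return PlantedVariant(sample, gene, plant_position(exon, off), ref,
                          "deletion", seq, vaf, clon, "exonic", label)


def build_default_spec() -> FixtureSpec:
    """The default study conditions: seven diagnostic samples with the
    dominant-clone catalogue, subclones, two remission samples and the
    10-sample copy-number cohort."""
    variants: list[PlantedVariant] = [
        # P1: NPM1-type 4bp insertion (TCTG), DNMT3A R882C-type, FLT3 D835Y-type
        _ins("P1", "NPM1", 11, 40, "A", "TCTG", "NPM1_L287fs"),
        _sub("P1", "DNMT3A", 10, 25, "C", "T", "DNMT3A_R882C"),
        _sub("P1", "FLT3", 9, 60, "G", "T", "FLT3_D835Y"),
        # P2: frameshift deletion, nonsense, missense + intronic substitution
        _del("P2", "ASXL1", 12, 35, "C", "G", "ASXL1_G642fs"),
        _sub("P2", "TET2", 6, 80, "T", "A", "TET2_L1119X"),
        _sub("P2", "KRAS", 4, 20, "G", "T", "KRAS_K117N"),
        PlantedVariant("P2", "NF1", NF1_INTRON_START + 51, "C", "substitution",
                       "T", 0.45, "dominant", "intronic", "NF1_intron2"),
        # P3: two CEBPA events (frameshift + in-frame 3bp insertion), WT1 fs, NRAS G12D
        _del("P3", "CEBPA", 1, 30, "G", "C", "CEBPA_A111fs"),
        _ins("P3", "CEBPA", 1, 95, "T", "AAC", "CEBPA_T310NT"),
        _del("P3", "WT1", 2, 45, "A", "CT", "WT1_R145fs"),
        _sub("P3", "NRAS", 2, 35, "G", "A", "NRAS_G12D"),
        # P4
        _ins("P4", "NPM1", 11, 40, "A", "TCTG", "NPM1_L287fs"),
        _sub("P4", "IDH2", 4, 50, "G", "A", "IDH2_R140Q"),
        # P5
        _ins("P5", "NPM1", 11, 40, "A", "TCTG", "NPM1_L287fs"),
        _sub("P5", "IDH1", 4, 42, "G", "A", "IDH1_R132H"),
        _sub("P5", "FLT3", 9, 60, "G", "T", "FLT3_D835Y"),
        # P6
        _sub("P6", "ASXL1", 12, 70, "C", "A", "ASXL1_C594X"),
        _ins("P6", "TET2", 5, 33, "G", "A", "TET2_P612fs"),
        _sub("P6", "KRAS", 2, 35, "G", "T", "KRAS_G12V"),
        # P7
        _del("P7", "DNMT3A", 9, 15, "C", "A", "DNMT3A_G590fs"),
        _sub("P7", "IDH2", 4, 77, "G", "A", "IDH2_R172K"),
        # subclones: co-occurring pair in P5 at 4.4%/4.1%, a ~3% event in P4
        _sub("P5", "NRAS", 2, 34, "G", "A", "NRAS_G12S", vaf=0.044),
        _sub("P5", "PTPN11", 8, 22, "A", "C", "PTPN11_Q506P", vaf=0.041),
        _sub("P4", "FLT3", 6, 12, "C", "A", "FLT3_N676K", vaf=0.03),
    ]
    tumours = [
        SampleInfo("P1", "F", "tumour"), SampleInfo("P2", "M", "tumour"),
        SampleInfo("P3", "M", "tumour"), SampleInfo("P4", "F", "tumour"),
        SampleInfo("P5", "M", "tumour"), SampleInfo("P6", "M", "tumour"),
        SampleInfo("P7", "F", "tumour"),
    ]
    control = SampleInfo("CTRL", "F", "control")
    remissions = [SampleInfo("R1", "F", "remission"), SampleInfo("R2", "M", "remission")]

    # R2 carries P2's three exonic diagnostic mutations at residual fractions
    p2_events = [v for v in variants if v.sample == "P2" and v.region == "exonic"]
    r2_fractions = [0.015, 0.020, 0.024]
    r2_variants = [
        PlantedVariant("R2", v.gene, v.pos, v.ref, v.vtype, v.alt_seq, f,
                       "subclonal", v.region, v.label + "_residual")
        for v, f in zip(sorted(p2_events, key=lambda v: (v.chrom, v.pos)), r2_fractions)
    ]
    variants.extend(r2_variants)
    p1_events = [v for v in variants if v.sample == "P1"]
    mrd_queries = {"R1": p1_events, "R2": [v for v in variants if v.sample == "P2"
                                           and v.region == "exonic"]}

    cnv_samples = [
        SampleInfo("C1", "F", "tumour"), SampleInfo("C2", "F", "tumour"),
        SampleInfo("C3", "F", "tumour"), SampleInfo("C4", "F", "tumour"),
        SampleInfo("C5", "F", "tumour"), SampleInfo("C6", "M", "tumour"),
        SampleInfo("C7", "M", "tumour"), SampleInfo("C8", "M", "tumour"),
        SampleInfo("C9", "M", "tumour"), SampleInfo("C10", "F", "tumour"),
    ]
    planted_cnvs = [
        PlantedCnv("C3", "CYP2D6", 1, 9, 0.5),   # whole-gene germline-type loss
        PlantedCnv("C2", "PTEN", 1, 9, 0.5),
        PlantedCnv("C7", "PTEN", 1, 9, 0.5),
        PlantedCnv("C6", "MLL", 2, 9, 1.5),      # partial tandem duplication
    ]
    return FixtureSpec(
        panel=dict(PANEL_GENES),
        samples=tumours + [control] + remissions,
        planted_variants=variants,
        mrd_queries=mrd_queries,
        cnv_samples=cnv_samples,
        qc_fail_sample="C10",
        planted_cnvs=planted_cnvs,
    )


def panel_regions(panel: Optional[dict[str, tuple[int, bool]]] = None) -> list[TargetRegion]:
    """All exonic target regions plus the captured NF1 intronic stretch."""
    panel = panel or PANEL_GENES
    regions: list[TargetRegion] = []
    for gene, (n_exons, _x) in panel.items():
        for i in range(1, n_exons + 1):
            s = exon_start(i)
            regions.append(TargetRegion(gene, s, s + EXON_LEN, gene, i, "exonic"))
    if "NF1" in panel:
        regions.append(TargetRegion("NF1", NF1_INTRON_START, NF1_INTRON_END,
                                    "NF1", 1, "intronic-control"))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def panel_exons(panel: Optional[dict[str, tuple[int, bool]]] = None) -> list[AmalgamatedExon]:
    """The panel's exons as (already disjoint) amalgamated exons."""
    panel = panel or PANEL_GENES
    out = []
    for gene, (n_exons, _x) in panel.items():
        for i in range(1, n_exons + 1):
            s = exon_start(i)
            out.append(AmalgamatedExon(gene, i, gene, s, s + EXON_LEN))
    out.sort(key=lambda e: (e.chrom, e.start))
    return out


def write_panel_bed(path, panel: Optional[dict[str, tuple[int, bool]]] = None) -> None:
    with open(path, "w") as fh:
        for r in panel_regions(panel):
            kind = "exon" if r.kind == "exonic" else "intron"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t{kind}\n")


def _default_ref(pos: int) -> str:
    return "ACGT"[pos % 4]


def _window(pos: int, flank: int = 10) -> range:
    return range(max(1, pos - flank), pos + flank + 1)


def _variant_windows(variants: Iterable[PlantedVariant], flank: int = 10
                     ) -> dict[str, set[int]]:
    sites: dict[str, set[int]] = {}
    for v in variants:
        sites.setdefault(v.chrom, set()).update(_window(v.pos, flank))
    return sites


def _build_ref_map(variants: Iterable[PlantedVariant]) -> dict[tuple[str, int], str]:
    refs: dict[tuple[str, int], str] = {}
    for v in variants:
        key = (v.chrom, v.pos)
        if key in refs and refs[key] != v.ref:
            raise ValueError(f"conflicting reference base planted at {key}")
        refs[key] = v.ref
    return refs


def _pileup_line(chrom: str, pos: int, ref: str, depth: int,
                 plants: list[tuple[PlantedVariant, int]]) -> str:
    """One pileup line with the planted alt tokens first, then reference."""
    tokens: list[str] = []
    n_alt = 0
    for v, count in plants:
        if v.vtype == "substitution":
            tok = v.alt_seq
        elif v.vtype == "insertion":
            tok = f".+{len(v.alt_seq)}{v.alt_seq}"
        else:
            tok = f".-{len(v.alt_seq)}{v.alt_seq}"
        tokens.append(tok * count)
        n_alt += count
    if n_alt > depth:
        raise ValueError(f"planted reads exceed depth at {chrom}:{pos}")
    tokens.append("." * (depth - n_alt))
    bq = chr(PLANT_BASE_QUALITY + 33) * depth
    mq = chr(PLANT_MAPPING_QUALITY + 33) * depth
    return f"{chrom}\t{pos}\t{ref}\t{depth}\t{''.join(tokens)}\t{bq}\t{mq}\n"


def generate_pileups(
    spec: FixtureSpec,
    outdir,
    mode: str = "deterministic",
    seed: int = 0,
    flank: int = 10,
) -> pd.DataFrame:
    """Write per-sample pileups around every planted site plus a clean
    control, and return the truth table.

    Deterministic mode plants exactly ``round(vaf * depth)`` alt reads at
    constant depth; an unrepresentable plant (fewer than one read) raises.
    Sampled mode draws Poisson(depth) depths and Binomial(depth, vaf) alt
    counts from ``seed``; identical spec+seed gives byte-identical files.
    """
    if mode not in ("deterministic", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    refs = _build_ref_map(spec.planted_variants)

    # control covers every site any sample needs (incl. MRD query windows)
    all_windows = _variant_windows(spec.planted_variants, flank)
    for qs in spec.mrd_queries.values():
        for chrom, positions in _variant_windows(qs, flank).items():
            all_windows.setdefault(chrom, set()).update(positions)

    def ref_at(chrom: str, pos: int) -> str:
        return refs.get((chrom, pos), _default_ref(pos))

    def write_sample(sample_id: str, windows: dict[str, set[int]],
                     plants: list[PlantedVariant]) -> None:
        by_site: dict[tuple[str, int], list[PlantedVariant]] = {}
        for v in plants:
            by_site.setdefault((v.chrom, v.pos), []).append(v)
        with open(outdir / f"{sample_id}.pileup", "w") as fh:
            for chrom in sorted(windows):
                for pos in sorted(windows[chrom]):
                    site_plants = by_site.get((chrom, pos), [])
                    if mode == "deterministic":
                        depth = spec.depth
                        counted = []
                        for v in site_plants:
                            k = round(v.vaf * depth)
                            if k < 1:
                                raise ValueError(
                                    f"unrepresentable plant {v.label}: "
                                    f"{v.vaf} x {depth} < 1 read"
                                )
                            counted.append((v, k))
                    else:
                        depth = max(1, int(rng.poisson(spec.depth)))
                        counted = [
                            (v, int(rng.binomial(depth, v.vaf))) for v in site_plants
                        ]
                    fh.write(_pileup_line(chrom, pos, ref_at(chrom, pos), depth, counted))

    # tumours and remission samples cover only their own relevant windows
    rows = []
    for s in spec.samples:
        if s.role == "control":
            write_sample(s.sample_id, all_windows, [])
            continue
        own = [v for v in spec.planted_variants if v.sample == s.sample_id]
        relevant = list(own)
        if s.sample_id in spec.mrd_queries:
            seen = {(v.chrom, v.pos) for v in relevant}
            relevant += [v for v in spec.mrd_queries[s.sample_id]
                         if (v.chrom, v.pos) not in seen]
        windows = _variant_windows(relevant, flank)
        if not windows:
            continue
        write_sample(s.sample_id, windows, own)
        for v in own:
            rows.append({
                "sample": v.sample, "chrom": v.chrom, "pos": v.pos,
                "ref": v.vcf_ref, "alt": v.vcf_alt, "type": v.vtype,
                "vaf": v.vaf, "clonality": v.clonality, "region": v.region,
                "label": v.label,
            })
    truth = pd.DataFrame(rows).sort_values(["sample", "chrom", "pos"]).reset_index(drop=True)
    truth.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    write_panel_bed(outdir / "panel.bed", spec.panel)
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("sample_id\tsex\trole\ttotal_mapped_reads\n")
        for s in spec.samples:
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.role}\t{s.total_mapped_reads}\n")
    return truth


def generate_count_matrix(
    spec: FixtureSpec, seed: int = 0, base_depth: Optional[int] = None
) -> tuple[ExonCountMatrix, pd.DataFrame]:
    """Simulate the normalised exon-count matrix for the CNV cohort.

    Per-exon capture efficiency is lognormal (sigma 0.2) and shared across
    samples; per-sample exon depths are Poisson around efficiency x copy
    ratio x library size.  X-linked genes carry 2 copies in females and 1
    in males; planted CNVs multiply the affected exons' means by their copy
    ratio; the QC-fail sample gets an independent lognormal (sigma 0.75)
    distortion per gene, emulating a failed capture.  Returns the matrix
    and a truth table of planted events.
    """
    rng = np.random.default_rng(seed)
    exons = panel_exons(spec.panel)
    depth = base_depth or spec.depth
    efficiency = rng.lognormal(mean=0.0, sigma=0.2, size=len(exons))
    samples = spec.cnv_samples
    totals = {s.sample_id: float(rng.uniform(0.8e8, 1.2e8)) for s in samples}
    t_ref = 1e8

    cnv_by_sample: dict[str, list[PlantedCnv]] = {}
    for c in spec.planted_cnvs:
        cnv_by_sample.setdefault(c.sample, []).append(c)

    qc_factors = {
        g: rng.lognormal(mean=0.0, sigma=0.75) for g in spec.panel
    }

    data = np.zeros((len(samples), len(exons)))
    for si, s in enumerate(samples):
        for ei, e in enumerate(exons):
            copy = 1.0
            if e.gene in X_GENES:
                copy = 1.0 if s.sex == "F" else 0.5
            for c in cnv_by_sample.get(s.sample_id, []):
                if c.gene == e.gene and c.first_exon <= e.exon_index <= c.last_exon:
                    copy *= c.copy_ratio
            lam = depth * efficiency[ei] * copy * totals[s.sample_id] / t_ref
            if s.sample_id == spec.qc_fail_sample:
                lam *= qc_factors[e.gene]
            data[si, ei] = rng.poisson(lam)
    exon_depths = pd.DataFrame(
        data, index=pd.Index([s.sample_id for s in samples], name="sample"),
        columns=[e.key for e in exons],
    )
    matrix = matrix_from_exon_depths(exon_depths, exons, totals)
    rows = [
        {"sample": c.sample, "gene": c.gene, "first_exon": c.first_exon,
         "last_exon": c.last_exon, "copy_ratio": c.copy_ratio,
         "direction": "gain" if c.copy_ratio > 1 else "loss"}
        for c in spec.planted_cnvs
    ]
    rows.append({"sample": spec.qc_fail_sample, "gene": "*", "first_exon": 0,
                 "last_exon": 0, "copy_ratio": float("nan"), "direction": "qc-fail"})
    return matrix, pd.DataFrame(rows)


def generate_snp_counts(case: str = "two-informative") -> list[SnpAllelicCounts]:
    """Deterministic intronic-SNP allele counts for the allelic-imbalance
    check (six SNPs flanking a tumour-suppressor locus).

    ``two-informative``: two heterozygous SNPs with one allele reduced in
    the tumour (matched-remission comparison) -> deletion-consistent.
    ``one-informative``: a single heterozygous SNP, reduced -> suggestive
    only, as without a matched normal confidence is limited.
    """
    if case == "two-informative":
        return [
            SnpAllelicCounts("snp1", 700, 300, 505, 495),
            SnpAllelicCounts("snp2", 290, 710, 498, 502),
            SnpAllelicCounts("snp3", 990, 10, 992, 8),
            SnpAllelicCounts("snp4", 8, 992, 12, 988),
            SnpAllelicCounts("snp5", 995, 5, 990, 10),
            SnpAllelicCounts("snp6", 7, 993, 9, 991),
        ]
    if case == "one-informative":
        return [
            SnpAllelicCounts("snp1", 695, 305, 502, 498),
            SnpAllelicCounts("snp2", 991, 9, 989, 11),
            SnpAllelicCounts("snp3", 6, 994, 10, 990),
            SnpAllelicCounts("snp4", 993, 7, 991, 9),
            SnpAllelicCounts("snp5", 11, 989, 12, 988),
            SnpAllelicCounts("snp6", 990, 10, 993, 7),
        ]
    raise ValueError(f"unknown case {case!r}")
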