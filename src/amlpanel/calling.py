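"""Tumour/control somatic calling on deep targeted pileups.

The caller compares quality-filtered allele evidence at each position
covered in both a tumour and a control sample.  All thresholds are the
documented defaults of :class:`CallerConfig` and are applied with the exact
strict/inclusive senses listed there:

* reads count only with base quality > 25 and mapping quality > 15;
* a position needs filtered coverage >= 10 in both samples;
* a substitution needs >= 20 tumour reads on the best non-reference allele
  and a control fraction of that allele < 5%; a site where the second-best
  non-reference allele reaches one-third (inclusive) of the best allele's
  evidence is discarded as a likely alignment artefact;
* an indel needs >= 10 tumour reads on the same indel, < 5 control reads on
  it, and >= 10x more tumour than control reads (a clean control passes);
  a site whose second indel exceeds 40% of the primary indel's evidence is
  discarded;
* calls at VAF > 20% are labelled ``dominant`` (main leukaemic clone),
  otherwise ``subclonal``.  At ~5000x depth the absolute read thresholds
  put the effective subclone floor near 0.4% of reads.

MRD (minimal residual disease) mining re-counts reads supporting known
diagnostic variants in a remission sample; a variant is ``detected`` when
at least ``mrd_min_reads`` mutant reads are seen and they make up at least
``mrd_sensitivity`` of filtered depth (defaults 5 reads and 0.1%, which
coincide exactly at 5000x).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .pileup_io import (
    AlleleEvidence,
    TargetRegion,
    read_pileup_evidence,
)

EvidenceMap = Mapping[tuple[str, int], AlleleEvidence]


@dataclass
class CallerConfig:
    """Tunable thresholds of the tumour/control caller.

    Control tolerances (``max_control_alt_fraction``,
    ``max_indel_reads_control``) can be raised when a remission sample that
    may harbour residual mutant reads is used as the control.
    """

    min_base_quality: int = 25
    min_mapping_quality: int = 15
    min_coverage_both: int = 10
    min_alt_reads_sub: int = 20
    max_control_alt_fraction: float = 0.05  # exclusive
    third_allele_fraction: float = 1.0 / 3.0  # inclusive discard
    min_indel_reads_tumour: int = 10
    max_indel_reads_control: int = 5  # exclusive
    min_indel_ratio: float = 10.0
    second_indel_fraction: float = 0.40  # exclusive discard
    dominant_vaf: float = 0.20  # exclusive: dominant iff vaf > this
    mrd_min_reads: int = 5
    mrd_sensitivity: float = 0.001

    def __post_init__(self) -> None:
        for name in (
            "min_base_quality",
            "min_mapping_quality",
            "min_coverage_both",
            "min_alt_reads_sub",
            "min_indel_reads_tumour",
            "max_indel_reads_control",
            "mrd_min_reads",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "max_control_alt_fraction",
            "third_allele_fraction",
            "second_indel_fraction",
            "dominant_vaf",
            "mrd_sensitivity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class VariantCall:
    """A called somatic event.  ``ref``/``alt`` follow the VCF convention:
    indels are left-anchored on the reference base of the anchoring site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    type: str  # "substitution" | "insertion" | "deletion"
    tumour_alt_reads: int
    tumour_depth: int
    control_alt_reads: int
    control_depth: int
    vaf: float
    clonality: str = "subclonal"  # "dominant" | "subclonal"
    region: str = "exonic"  # "exonic" | "intronic"
    sample_id: str = ""

    @property
    def is_indel(self) -> bool:
        return self.type != "substitution"


@dataclass
class MrdResult:
    """Read-mining result for one known variant in a remission sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    mutant_reads: int
    total_reads: int
    fraction: float
    detected: bool
    sample_id: str = ""


def _check_same_site(tumour: AlleleEvidence, control: AlleleEvidence) -> None:
    if (tumour.chrom, tumour.pos, tumour.ref_base) != (
        control.chrom,
        control.pos,
        control.ref_base,
    ):
        raise ValueError(
            f"tumour/control evidence refer to different sites: "
            f"{tumour.chrom}:{tumour.pos}:{tumour.ref_base} vs "
            f"{control.chrom}:{control.pos}:{control.ref_base}"
        )


def _ranked_nonref(ev: AlleleEvidence) -> list[tuple[str, int]]:
    """Non-reference base alleles ranked by (count desc, allele asc)."""
    items = [
        (a, c)
        for a, c in ev.base_counts.items()
        if a != ev.ref_base and a in ("A", "C", "G", "T")
    ]
    items.sort(key=lambda ac: (-ac[1], ac[0]))
    return items


def classify_clonality(vaf: float, cfg: CallerConfig) -> str:
    """Dominant-clone label: strictly more than ``dominant_vaf`` of reads."""
    return "dominant" if vaf > cfg.dominant_vaf else "subclonal"


def call_substitution(
    tumour: AlleleEvidence, control: AlleleEvidence, cfg: CallerConfig
) -> Optional[VariantCall]:
    """Apply the substitution rules at one site; None when any rule fails."""
    _check_same_site(tumour, control)
    if tumour.depth_filtered < cfg.min_coverage_both:
        return None
    if control.depth_filtered < cfg.min_coverage_both:
        return None
    ranked = _ranked_nonref(tumour)
    if not ranked:
        return None
    best_allele, best_count = ranked[0]
    if best_count < cfg.min_alt_reads_sub:
        return None
    # third-allele discard: inclusive ("at least one-third of this evidence")
    if len(ranked) > 1 and ranked[1][1] >= best_count * cfg.third_allele_fraction:
        return None
    ctrl_count = control.base_counts.get(best_allele, 0)
    if ctrl_count / control.depth_filtered >= cfg.max_control_alt_fraction:
        return None
    vaf = best_count / tumour.depth_filtered
    return VariantCall(
        chrom=tumour.chrom,
        pos=tumour.pos,
        ref=tumour.ref_base,
        alt=best_allele,
        type="substitution",
        tumour_alt_reads=best_count,
        tumour_depth=tumour.depth_filtered,
        control_alt_reads=ctrl_count,
        control_depth=control.depth_filtered,
        vaf=vaf,
        clonality=classify_clonality(vaf, cfg),
    )


def call_indel(
    tumour: AlleleEvidence, control: AlleleEvidence, cfg: CallerConfig
) -> Optional[VariantCall]:
    """Apply the indel rules at one site; None when any rule fails."""
    _check_same_site(tumour, control)
    if tumour.depth_filtered < cfg.min_coverage_both:
        return None
    if control.depth_filtered < cfg.min_coverage_both:
        return None
    if not tumour.indel_counts:
        return None
    ranked = sorted(tumour.indel_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    (kind, seq), best_count = ranked[0]
    if best_count < cfg.min_indel_reads_tumour:
        return None
    # second-indel discard: strictly more than 40% of the primary evidence
    if len(ranked) > 1 and ranked[1][1] > cfg.second_indel_fraction * best_count:
        return None
    ctrl_count = control.indel_counts.get((kind, seq), 0)
    if ctrl_count >= cfg.max_indel_reads_control:
        return None
    # >=10x more tumour reads than control; a clean control passes vacuously
    if ctrl_count > 0 and best_count < cfg.min_indel_ratio * ctrl_count:
        return None
    anchor = tumour.ref_base
    if kind == "ins":
        ref, alt, vtype = anchor, anchor + seq, "insertion"
    else:
        ref, alt, vtype = anchor + seq, anchor, "deletion"
    vaf = best_count / tumour.depth_filtered
    return VariantCall(
        chrom=tumour.chrom,
        pos=tumour.pos,
        ref=ref,
        alt=alt,
        type=vtype,
        tumour_alt_reads=best_count,
        tumour_depth=tumour.depth_filtered,
        control_alt_reads=ctrl_count,
        control_depth=control.depth_filtered,
        vaf=vaf,
        clonality=classify_clonality(vaf, cfg),
    )


def label_region(chrom: str, pos: int, targets: Sequence[TargetRegion]) -> str:
    """``exonic`` iff the position falls inside any exonic target region;
    anything else captured (intronic control stretches, flanks) is
    ``intronic``."""
    for t in targets:
        if t.kind == "exonic" and t.chrom == chrom and t.contains(pos):
            return "exonic"
    return "intronic"


def _as_evidence(
    source: Union[str, Path, EvidenceMap], cfg: CallerConfig
) -> EvidenceMap:
    if isinstance(source, (str, Path)):
        return read_pileup_evidence(
            source, cfg.min_base_quality, cfg.min_mapping_quality
        )
    return source


def call_sample(
    tumour: Union[str, Path, EvidenceMap],
    control: Union[str, Path, EvidenceMap],
    targets: Sequence[TargetRegion],
    cfg: Optional[CallerConfig] = None,
    sample_id: str = "",
) -> list[VariantCall]:
    """Run the full caller over every position covered in both samples.

    ``tumour``/``control`` may be pileup file paths or pre-parsed evidence
    maps (so a shared control is parsed once across many tumours).  Returns
    substitution and indel calls sorted by (chrom, pos), each labelled with
    clonality and exonic/intronic region.
    """
    cfg = cfg or CallerConfig()
    tev = _as_evidence(tumour, cfg)
    cev = _as_evidence(control, cfg)
    shared = sorted(set(tev) & set(cev))
    if not shared:
        raise ValueError("tumour and control pileups share no positions")
    calls: list[VariantCall] = []
    for key in shared:
        t, c = tev[key], cev[key]
        for call in (call_substitution(t, c, cfg), call_indel(t, c, cfg)):
            if call is None:
                continue
            call.region = label_region(call.chrom, call.pos, targets)
            call.sample_id = sample_id
            calls.append(call)
    calls.sort(key=lambda v: (v.chrom, v.pos, v.type))
    return calls


@dataclass(frozen=True)
class KnownVariant:
    """Identity of a diagnostic variant queried during MRD mining, in the
    same left-anchored ref/alt convention the caller emits."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "substitution"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"


def mine_known_variants(
    remission: Union[str, Path, EvidenceMap],
    variants: Iterable[KnownVariant],
    cfg: Optional[CallerConfig] = None,
    sample_id: str = "",
) -> list[MrdResult]:
    """Count quality-filtered reads supporting each known variant.

    ``detected`` requires both an absolute floor (``mrd_min_reads``) and a
    minimum mutant fraction (``mrd_sensitivity``) of filtered depth.
    """
    cfg = cfg or CallerConfig()
    ev_map = _as_evidence(remission, cfg)
    out: list[MrdResult] = []
    for v in variants:
        ev = ev_map.get((v.chrom, v.pos))
        if ev is None:
            mutant, total = 0, 0
        else:
            total = ev.depth_filtered
            if v.type == "substitution":
                mutant = ev.base_counts.get(v.alt, 0)
            elif v.type == "insertion":
                mutant = ev.indel_counts.get(("ins", v.alt[1:]), 0)
            else:
                mutant = ev.indel_counts.get(("del", v.ref[1:]), 0)
        fraction = mutant / total if total > 0 else 0.0
        detected = mutant >= cfg.mrd_min_reads and fraction >= cfg.mrd_sensitivity
        out.append(
            MrdResult(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                mutant_reads=mutant,
                total_reads=total,
                fraction=fraction,
                detected=detected,
                sample_id=sample_id,
            )
        )
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=amlpanel
##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type (substitution/insertion/deletion)">
##INFO=<ID=TAR,Number=1,Type=Integer,Description="Tumour alt-supporting reads (quality-filtered)">
##INFO=<ID=TDP,Number=1,Type=Integer,Description="Tumour filtered depth">
##INFO=<ID=CAR,Number=1,Type=Integer,Description="Control alt-supporting reads (quality-filtered)">
##INFO=<ID=CDP,Number=1,Type=Integer,Description="Control filtered depth">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Tumour variant allele fraction">
##INFO=<ID=CLON,Number=1,Type=String,Description="Clonality (dominant/subclonal)">
##INFO=<ID=REG,Number=1,Type=String,Description="Region label (exonic/intronic)">
##INFO=<ID=SID,Number=1,Type=String,Description="Tumour sample id">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Sequence[VariantCall], out) -> None:
    """Write calls as a VCF 4.2 text file.  Calls must already be sorted by
    (chrom, pos); unsorted input raises ValueError."""
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos) before writing VCF")
    header, columns_line = _VCF_HEADER.rsplit("#CHROM", 1)
    contigs = sorted({c.chrom for c in calls})
    with open(out, "w") as fh:
        fh.write(header)
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM" + columns_line)
        for c in calls:
            info = (
                f"TYPE={c.type};TAR={c.tumour_alt_reads};TDP={c.tumour_depth};"
                f"CAR={c.control_alt_reads};CDP={c.control_depth};"
                f"VAF={c.vaf:.6g};CLON={c.clonality};REG={c.region}"
            )
            if c.sample_id:
                info += f";SID={c.sample_id}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n"
            )


def read_vcf_calls(path) -> list[KnownVariant]:
    """Minimal VCF reader returning variant identities (for MRD queries)."""
    out: list[KnownVariant] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            out.append(KnownVariant(cols[0], int(cols[1]), cols[3], cols[4]))
    return out
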