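"""Reading extended pileup and BED target files.

The input dialect is the 7-column mpileup-with-MAPQ layout
(``samtools mpileup -s``): chrom, 1-based position, reference base, depth,
read-base string, base-quality string, mapping-quality string.  Both quality
strings are Phred+33 encoded, one character per read.  The read-base string
uses the standard tokens: ``.``/``,`` reference match, ``ACGTNacgtn``
mismatch, ``^X`` read start (X consumed, not a call), ``$`` read end,
``+N<seq>``/``-N<seq>`` insertion/deletion anchored to the preceding read,
``*`` a deletion placeholder that counts toward depth but never toward a
base allele.

Per-read records are ``(base, base_quality, mapping_quality, indel)`` tuples
where ``indel`` is ``None`` or an :class:`Indel`.  Quality filtering is
strict: a read contributes only when its base quality and mapping quality
are each strictly greater than the configured thresholds.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence, Union

PHRED_OFFSET = 33

_SIMPLE_CALLS = set(".,ACGTNacgtn*#")
_BASE_CHARS = set("ACGTNacgtn")


class PileupParseError(ValueError):
    """Raised when a pileup line violates the dialect or its own depth column."""


@dataclass(frozen=True)
class Indel:
    """An insertion or deletion observation anchored at a site.

    ``kind`` is ``"ins"`` or ``"del"``; ``seq`` is the inserted or deleted
    sequence, uppercase.
    """

    kind: str
    seq: str

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del"):
            raise ValueError(f"indel kind must be 'ins' or 'del', got {self.kind!r}")


# one aligned read at a site: (base, base_quality, mapping_quality, indel-or-None)
PileupRead = tuple[str, int, int, Optional[Indel]]


@dataclass
class PileupSite:
    """All reads overlapping one genomic position."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    reads: list[PileupRead]

    @property
    def depth(self) -> int:
        return len(self.reads)


@dataclass
class AlleleEvidence:
    """Quality-filtered allele counts at a site.

    ``base_counts`` maps base -> reads; deletion placeholders count toward
    ``depth_filtered`` but never appear in ``base_counts``.  ``indel_counts``
    maps ``(kind, seq)`` -> reads carrying that exact indel.
    """

    chrom: str
    pos: int
    ref_base: str
    depth_filtered: int
    base_counts: dict[str, int] = field(default_factory=dict)
    indel_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class TargetRegion:
    """One captured interval, BED-style 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    gene: str
    exon_index: int
    kind: str = "exonic"  # "exonic" | "intronic-control"

    def contains(self, pos: int) -> bool:
        """True if the 1-based position ``pos`` falls inside this region."""
        return self.start < pos <= self.end


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def parse_pileup_line(
    line: str,
    line_number: Optional[int] = None,
    quality_offset: int = PHRED_OFFSET,
) -> PileupSite:
    """Parse one extended-pileup line into a :class:`PileupSite`.

    Raises :class:`PileupParseError` if the token count disagrees with the
    depth column, a quality string has the wrong length, or an unknown token
    is encountered.
    """
    where = f" at line {line_number}" if line_number is not None else ""
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 7:
        raise PileupParseError(f"expected >=7 tab-separated columns{where}, got {len(cols)}")
    chrom, pos_s, ref, depth_s, bases, bquals, mquals = cols[:7]
    try:
        pos = int(pos_s)
        depth = int(depth_s)
    except ValueError as exc:
        raise PileupParseError(f"non-integer pos/depth{where}") from exc
    if pos < 1:
        raise PileupParseError(f"position must be >= 1{where}")
    if len(bquals) != depth or len(mquals) != depth:
        raise PileupParseError(
            f"quality-string length ({len(bquals)}/{len(mquals)}) does not match depth {depth}{where}"
        )
    ref = ref.upper()

    reads: list[PileupRead] = []
    special = ("^" in bases) or ("$" in bases) or ("+" in bases) or ("-" in bases)
    if not special:
        # every char is one call
        if not set(bases) <= _SIMPLE_CALLS:
            bad = next(c for c in bases if c not in _SIMPLE_CALLS)
            raise PileupParseError(f"unknown pileup token {bad!r}{where}")
        for c, bq, mq in zip(bases, bquals, mquals):
            if c in ".,":
                b = ref
            elif c in "*#":
                b = "*"
            else:
                b = c.upper()
            reads.append((b, ord(bq) - quality_offset, ord(mq) - quality_offset, None))
    else:
        i, n = 0, len(bases)
        ridx = 0
        while i < n:
            c = bases[i]
            if c == "^":
                if i + 1 >= n:
                    raise PileupParseError(f"dangling '^'{where}")
                i += 2  # '^' plus the read's mapping-quality character
                continue
            if c == "$":
                i += 1
                continue
            if c in "+-":
                raise PileupParseError(f"indel token with no anchoring read{where}")
            if c not in _SIMPLE_CALLS:
                raise PileupParseError(f"unknown pileup token {c!r}{where}")
            if c in ".,":
                b = ref
            elif c in "*#":
                b = "*"
            else:
                b = c.upper()
            i += 1
            indel: Optional[Indel] = None
            while i < n and bases[i] in "+-":
                kind = "ins" if bases[i] == "+" else "del"
                j = i + 1
                while j < n and bases[j].isdigit():
                    j += 1
                if j == i + 1:
                    raise PileupParseError(f"indel token missing length{where}")
                length = int(bases[i + 1 : j])
                seq = bases[j : j + length]
                if len(seq) != length:
                    raise PileupParseError(f"indel sequence truncated{where}")
                if indel is None:  # keep the first; >1 indel per read is not representable
                    indel = Indel(kind, seq.upper())
                i = j + length
            if ridx >= depth:
                raise PileupParseError(f"more read tokens than depth {depth}{where}")
            reads.append(
                (b, ord(bquals[ridx]) - quality_offset, ord(mquals[ridx]) - quality_offset, indel)
            )
            ridx += 1
    if len(reads) != depth:
        raise PileupParseError(f"read tokens ({len(reads)}) do not match depth {depth}{where}")
    return PileupSite(chrom=chrom, pos=pos, ref_base=ref, reads=reads)


def serialize_site(site: PileupSite, quality_offset: int = PHRED_OFFSET) -> str:
    """Render a :class:`PileupSite` back to a 7-column pileup line."""
    base_tokens: list[str] = []
    bq: list[str] = []
    mq: list[str] = []
    for b, q, m, indel in site.reads:
        if b == site.ref_base:
            tok = "."
        elif b == "*":
            tok = "*"
        else:
            tok = b
        if indel is not None:
            sign = "+" if indel.kind == "ins" else "-"
            tok += f"{sign}{len(indel.seq)}{indel.seq}"
        base_tokens.append(tok)
        bq.append(chr(q + quality_offset))
        mq.append(chr(m + quality_offset))
    return "\t".join(
        [
            site.chrom,
            str(site.pos),
            site.ref_base,
            str(len(site.reads)),
            "".join(base_tokens),
            "".join(bq),
            "".join(mq),
        ]
    )


def filter_evidence(
    site: PileupSite, min_base_quality: int, min_mapping_quality: int
) -> AlleleEvidence:
    """Count alleles over reads passing the strict quality thresholds.

    A read contributes iff base_quality > ``min_base_quality`` and
    mapping_quality > ``min_mapping_quality``.  Indel observations inherit
    the anchoring read's qualities.
    """
    depth = 0
    base_counts: dict[str, int] = {}
    indel_counts: dict[tuple[str, str], int] = {}
    for b, q, m, indel in site.reads:
        if q <= min_base_quality or m <= min_mapping_quality:
            continue
        depth += 1
        if b != "*":
            base_counts[b] = base_counts.get(b, 0) + 1
        if indel is not None:
            key = (indel.kind, indel.seq)
            indel_counts[key] = indel_counts.get(key, 0) + 1
    return AlleleEvidence(
        chrom=site.chrom,
        pos=site.pos,
        ref_base=site.ref_base,
        depth_filtered=depth,
        base_counts=base_counts,
        indel_counts=indel_counts,
    )


def _fast_evidence(
    cols: Sequence[str], min_bq: int, min_mq: int, quality_offset: int
) -> Optional[AlleleEvidence]:
    """Fused parse+filter for lines with no special tokens and uniformly
    passing (or failing) qualities; returns None when the general path is
    required.  Behaviour is identical to parse_pileup_line + filter_evidence
    (property-tested)."""
    bases, bquals, mquals = cols[4], cols[5], cols[6]
    if "^" in bases or "$" in bases or "+" in bases or "-" in bases:
        return None
    depth = int(cols[3])
    if len(bases) != depth or len(bquals) != depth or len(mquals) != depth:
        return None  # let the general path raise a precise error
    if depth:
        bq_lo = ord(min(bquals)) - quality_offset
        mq_lo = ord(min(mquals)) - quality_offset
        if bq_lo <= min_bq or mq_lo <= min_mq:
            return None  # mixed pass/fail needs the per-read loop
    if not set(bases) <= _SIMPLE_CALLS:
        return None
    ref = cols[2].upper()
    counts = Counter(bases)
    base_counts: dict[str, int] = {}
    star = 0
    for tok, n in counts.items():
        if tok in ".,":
            base_counts[ref] = base_counts.get(ref, 0) + n
        elif tok in "*#":
            star += n
        else:
            b = tok.upper()
            base_counts[b] = base_counts.get(b, 0) + n
    return AlleleEvidence(
        chrom=cols[0],
        pos=int(cols[1]),
        ref_base=ref,
        depth_filtered=depth,
        base_counts=base_counts,
        indel_counts={},
    )


def iter_pileup(path, quality_offset: int = PHRED_OFFSET) -> Iterator[PileupSite]:
    """Stream :class:`PileupSite` records from a pileup file (.gz ok)."""
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            yield parse_pileup_line(line, line_number=ln, quality_offset=quality_offset)


def read_pileup_evidence(
    path,
    min_base_quality: int,
    min_mapping_quality: int,
    quality_offset: int = PHRED_OFFSET,
) -> dict[tuple[str, int], AlleleEvidence]:
    """Parse a whole pileup file into quality-filtered evidence per site.

    Uses the fused fast path when a line has no indel/start/end tokens and
    all its qualities clear the thresholds; falls back to the general
    per-read path otherwise.
    """
    out: dict[tuple[str, int], AlleleEvidence] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise PileupParseError(f"expected >=7 columns at line {ln}")
            try:
                ev = _fast_evidence(cols, min_base_quality, min_mapping_quality, quality_offset)
            except ValueError:
                ev = None
            if ev is None:
                site = parse_pileup_line(line, line_number=ln, quality_offset=quality_offset)
                ev = filter_evidence(site, min_base_quality, min_mapping_quality)
            out[ev.site_key] = ev
    return out


def read_targets(path) -> list[TargetRegion]:
    """Read a BED4(+kind) file of captured regions.

    Column 4 is the gene name; an optional column 5 marks the region kind
    (``exon``/``exonic`` or ``intron``/``intronic``/``intronic-control``,
    default exonic).  Regions are returned sorted by (chrom, start) with
    ``exon_index`` assigned in genomic order per gene, counted separately
    for exonic regions and intronic control stretches.
    """
    raw: list[tuple[str, int, int, str, str]] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"BED line {ln}: need >=4 columns")
            chrom, start_s, end_s, gene = cols[:4]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(f"BED line {ln}: start >= end ({start} >= {end})")
            kind = "exonic"
            if len(cols) >= 5 and cols[4].lower().startswith("intron"):
                kind = "intronic-control"
            raw.append((chrom, start, end, gene, kind))
    raw.sort(key=lambda r: (r[0], r[1], r[2]))
    counters: dict[tuple[str, str], int] = {}
    regions: list[TargetRegion] = []
    for chrom, start, end, gene, kind in raw:
        counters[(gene, kind)] = counters.get((gene, kind), 0) + 1
        regions.append(TargetRegion(chrom, start, end, gene, counters[(gene, kind)], kind))
    return regions
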