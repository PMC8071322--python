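"""Back-splice junction detection from chimeric paired-end alignments.

A read that crosses a back-splice junction aligns against the linear reference
in two pieces on the same chromosome and strand: the piece covering the read's
start maps at the *downstream* genomic locus (ending exactly at the circle
end), while the remainder maps back *upstream* (starting exactly at the circle
start). The aligner records the second locus in the SA auxiliary tag. The
junction read's mate must align in between the two loci — inside the circle.
Fragments sharing the exact same breakpoint pair accumulate support; junctions
with at least ``min_reads`` distinct supporting fragments are reported and then
annotated against gene exon boundaries, which they must match exactly.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import AlignmentRecord, GeneModel, RegionString

__all__ = [
    "SplitReadEvidence",
    "BackspliceJunction",
    "CircRNA",
    "DetectDiagnostics",
    "extract_split_candidates",
    "require_mate_in_circle",
    "call_junctions",
    "annotate",
    "merge_cohort",
]

logger = logging.getLogger(__name__)

NOVEL = "NOVEL"

_CIGAR_OP_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR operations that consume reference bases
_REF_OPS = frozenset("MDN=X")
# operations that consume query (read) bases
_QUERY_OPS = frozenset("MIS=X")


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_OP_RE.findall(cigar)]
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_reference_span(pos: int, cigar: str) -> tuple[int, int]:
    """1-based inclusive reference interval consumed by an alignment."""
    length = sum(n for n, op in cigar_ops(cigar) if op in _REF_OPS)
    if length < 1:
        raise ValueError(f"CIGAR {cigar!r} consumes no reference bases")
    return pos, pos + length - 1

def _leading_clip(cigar: str) -> int:
    clip = 0
    for n, op in cigar_ops(cigar):
        if op in "SH":
            clip += n
        else:
            break
    return clip


def _trailing_clip(cigar: str) -> int:
    clip = 0
    for n, op in reversed(cigar_ops(cigar)):
        if op in "SH":
            clip += n
        else:
            break
    return clip


@dataclass(frozen=True)
class SplitReadEvidence:
    """One fragment's split-read support for a candidate circle."""

    fragment_name: str
    chrom: str
    strand: str
    upstream_segment: tuple[int, int]  # ends at the putative circle end
    downstream_segment: tuple[int, int]  # starts at the putative circle start
    mate_span: tuple[int, int]

    @property
    def circle_start(self) -> int:
        return self.downstream_segment[0]

    @property
    def circle_end(self) -> int:
        return self.upstream_segment[1]


@dataclass
class BackspliceJunction:
    """An exact-breakpoint circular region with supporting-fragment count."""

    region: RegionString
    strand: str
    support: int
    fragment_names: frozenset[str]


@dataclass
class CircRNA:
    """An annotated back-splice junction."""

    junction: BackspliceJunction
    gene_id: str = NOVEL
    gene_name: str = NOVEL
    exon_span: str = ""
    per_sample_support: dict[str, int] = field(default_factory=dict)

    @property
    def region(self) -> RegionString:
        return self.junction.region


@dataclass
class DetectDiagnostics:
    """Tallies of reads rejected per rule, for the diagnostics log."""

    n_records: int = 0
    no_sa: int = 0
    multiple_sa: int = 0
    different_chrom: int = 0
    different_strand: int = 0
    not_backsplice: int = 0
    unpaired: int = 0
    mate_missing: int = 0
    mate_outside: int = 0
    accepted: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def extract_split_candidates(
    records: Iterable[AlignmentRecord],
    diagnostics: DetectDiagnostics | None = None,
) -> list[SplitReadEvidence]:
    """Scan one sample's alignments for back-splice split-read configurations.

    Keeps reads whose primary alignment carries exactly one SA entry on the
    same chromosome and strand, with the two segments in back-splice order:
    the right-soft-clipped segment downstream of the left-soft-clipped one
    (a forward-splice chimera has the opposite order and is rejected). The
    mate's span is resolved from its own primary record in the stream.
    """
    diag = diagnostics if diagnostics is not None else DetectDiagnostics()
    primaries: list[AlignmentRecord] = []
    # mate lookup: primary, non-supplementary record per (name, read1/read2)
    mates: dict[tuple[str, bool], AlignmentRecord] = {}
    for rec in records:
        diag.n_records += 1
        if rec.is_supplementary:
            continue
        mates[(rec.read_name, rec.is_first_in_pair)] = rec
        primaries.append(rec)

    evidence: list[SplitReadEvidence] = []
    for rec in primaries:
        if not rec.sa_entries:
            diag.no_sa += 1
            continue
        if len(rec.sa_entries) > 1:
            diag.multiple_sa += 1
            continue
        if not rec.is_paired:
            diag.unpaired += 1
            continue
        sa_chrom, sa_pos, sa_strand, sa_cigar = rec.sa_entries[0]
        if sa_chrom != rec.chrom:
            diag.different_chrom += 1
            continue
        if sa_strand != rec.strand:
            diag.different_strand += 1
            continue
        segments = (
            (rec.pos, rec.cigar),
            (sa_pos, sa_cigar),
        )
        left_clipped = [s for s in segments if _leading_clip(s[1]) > _trailing_clip(s[1])]
        right_clipped = [s for s in segments if _trailing_clip(s[1]) > _leading_clip(s[1])]
        if len(left_clipped) != 1 or len(right_clipped) != 1:
            diag.not_backsplice += 1
            continue
        down = cigar_reference_span(*left_clipped[0])  # starts the circle
        up = cigar_reference_span(*right_clipped[0])  # ends the circle
        # back-splice order: the right-clipped (read-start) segment lies
        # downstream of the left-clipped (read-continuation) segment
        if not (down[0] < up[1] and down[0] <= up[0]):
            diag.not_backsplice += 1
            continue
        mate = mates.get((rec.read_name, not rec.is_first_in_pair))
        if mate is None:
            diag.mate_missing += 1
            continue
        if mate.chrom != rec.chrom:
            diag.mate_missing += 1
            continue
        evidence.append(
            SplitReadEvidence(
                fragment_name=rec.read_name,
                chrom=rec.chrom,
                strand=rec.strand,
                upstream_segment=up,
                downstream_segment=down,
                mate_span=cigar_reference_span(mate.pos, mate.cigar),
            )
        )
        diag.accepted += 1
    return evidence


def require_mate_in_circle(
    evidence: Iterable[SplitReadEvidence],
    containment: str = "full",
    diagnostics: DetectDiagnostics | None = None,
) -> list[SplitReadEvidence]:
    """Keep evidence whose mate aligns inside the candidate circle.

    ``containment="full"`` (default) demands the entire mate span within
    [circle_start, circle_end]; ``"overlap"`` accepts any overlap.
    """
    if containment not in {"full", "overlap"}:
        raise ValueError("containment must be 'full' or 'overlap'")
    kept = []
    for ev in evidence:
        lo, hi = ev.circle_start, ev.circle_end
        m0, m1 = ev.mate_span
        inside = (lo <= m0 and m1 <= hi) if containment == "full" else (m0 <= hi and m1 >= lo)
        if inside:
            kept.append(ev)
        elif diagnostics is not None:
            diagnostics.mate_outside += 1
            diagnostics.accepted -= 1
    return kept


def call_junctions(
    evidence: Iterable[SplitReadEvidence],
    min_reads: int = 5,
    stranded: bool = True,
    max_span: int | None = None,
) -> list[BackspliceJunction]:
    """Group evidence by exact breakpoint and keep well-supported junctions.

    Support counts distinct fragments (a read pair seen in several alignment
    lines contributes once). Junctions with ``support >= min_reads`` are
    returned sorted by region.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    groups: dict[tuple, set[str]] = defaultdict(set)
    strands: dict[tuple, str] = {}
    for ev in evidence:
        strand = ev.strand if stranded else "+"
        key = (ev.chrom, strand, ev.circle_start, ev.circle_end)
        groups[key].add(ev.fragment_name)
        strands[key] = ev.strand if stranded else "."
    junctions = []
    for (chrom, _, start, end), names in groups.items():
        if len(names) < min_reads:
            continue
        if max_span is not None and end - start + 1 > max_span:
            continue
        junctions.append(
            BackspliceJunction(
                region=RegionString(chrom, start, end),
                strand=strands[(chrom, _, start, end)],
                support=len(names),
                fragment_names=frozenset(names),
            )
        )
    junctions.sort(key=lambda j: (j.region.chrom, j.region.start, j.region.end, j.strand))
    return junctions


def annotate(
    junctions: Sequence[BackspliceJunction],
    genes: Sequence[GeneModel],
    slop: int = 0,
    stranded: bool = True,
) -> list[CircRNA]:
    """Assign junctions to genes by exact exon-boundary match.

    A junction is assigned to a gene iff its start equals an exon start and its
    end equals an exon end of that gene (same chromosome; same strand when the
    junction is stranded). Junctions matching several genes yield one CircRNA
    per gene with an ambiguity warning; unmatched junctions are kept as NOVEL.
    ``slop`` relaxes exactness for exploration only.
    """
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for gene in genes:
        by_chrom[gene.chrom].append(gene)

    out: list[CircRNA] = []
    for junc in junctions:
        hits: list[tuple[GeneModel, int, int]] = []
        for gene in by_chrom.get(junc.region.chrom, []):
            if stranded and junc.strand in "+-" and gene.strand != junc.strand:
                continue
            start_hit = None
            end_hit = None
            for num, es, ee in gene.exons:
                if abs(es - junc.region.start) <= slop:
                    start_hit = num
                if abs(ee - junc.region.end) <= slop:
                    end_hit = num
            if start_hit is not None and end_hit is not None:
                hits.append((gene, start_hit, end_hit))
        if not hits:
            out.append(CircRNA(junction=junc))
            continue
        if len(hits) > 1:
            logger.warning(
                "junction %s matches %d genes: %s",
                junc.region,
                len(hits),
                ",".join(g.gene_id for g, _, _ in hits),
            )
        for gene, start_num, end_num in hits:
            lo, hi = sorted((start_num, end_num))
            span = f"{lo}" if lo == hi else f"{lo}-{hi}"
            out.append(CircRNA(junction=junc, gene_id=gene.gene_id, gene_name=gene.gene_name, exon_span=span))
    return out


def merge_cohort(per_sample: Mapping[str, Sequence[CircRNA]]) -> tuple[list[CircRNA], pd.DataFrame]:
    """Merge per-sample circRNA calls into a cohort catalog and count matrix.

    circRNA identity is the exact (chrom, strand, start, end). Returns the
    catalog (one CircRNA per distinct region, with per-sample support filled
    in) and a circRNAs × samples junction-count DataFrame (0 where a region
    was not called in a sample), rows indexed by region string.
    """
    if len(per_sample) == 0:
        raise ValueError("merge_cohort requires at least one sample")
    samples = list(per_sample)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")

    catalog: dict[tuple, CircRNA] = {}
    counts: dict[tuple, dict[str, int]] = defaultdict(dict)
    for sample, circs in per_sample.items():
        for circ in circs:
            r = circ.region
            key = (r.chrom, circ.junction.strand, r.start, r.end, circ.gene_id)
            if key not in catalog:
                catalog[key] = CircRNA(
                    junction=BackspliceJunction(r, circ.junction.strand, 0, frozenset()),
                    gene_id=circ.gene_id,
                    gene_name=circ.gene_name,
                    exon_span=circ.exon_span,
                )
            counts[key][sample] = circ.junction.support
    ordered = sorted(catalog, key=lambda k: (k[0], k[2], k[3], k[1], k[4]))
    rows = []
    merged: list[CircRNA] = []
    for key in ordered:
        circ = catalog[key]
        circ.per_sample_support = {s: counts[key].get(s, 0) for s in samples}
        circ.junction.support = max(circ.per_sample_support.values())
        circ.junction.fragment_names = frozenset()
        merged.append(circ)
        rows.append([counts[key].get(s, 0) for s in samples])
    index = [str(catalog[k].region) for k in ordered]
    matrix = pd.DataFrame(rows, index=index, columns=samples, dtype=int)
    # regions annotated to several genes appear once in the matrix
    matrix = matrix[~matrix.index.duplicated(keep="first")]
    return merged, matrix
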