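"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 1-based inclusive, matching the region-string
convention ``chrom:start-end`` used throughout (e.g. ``chr11:33286413-33287512``).
Only BED export shifts to 0-based half-open.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import gffutils
import pandas as pd
import pysam

__all__ = [
    "AlignmentRecord",
    "GeneModel",
    "RegionString",
    "SamParseError",
    "GtfParseError",
    "read_sam",
    "read_gtf",
    "write_catalog",
]


class SamParseError(ValueError):
    """A malformed alignment record (bad CIGAR or SA field)."""


class GtfParseError(ValueError):
    """A malformed GTF line (e.g. missing gene_id)."""


_CIGAR_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$")
_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class RegionString:
    """A genomic region with 1-based inclusive endpoints."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "RegionString":
        m = _REGION_RE.match(text)
        if m is None:
            raise ValueError(f"not a region string: {text!r}")
        return cls(m["chrom"], int(m["start"]), int(m["end"]))

    def to_bed_interval(self) -> tuple[str, int, int]:
        """(chrom, 0-based start, end) under BED half-open convention."""
        return self.chrom, self.start - 1, self.end

    @classmethod
    def from_bed_interval(cls, chrom: str, start0: int, end: int) -> "RegionString":
        return cls(chrom, start0 + 1, end)


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM alignment line, with the SA auxiliary tag pre-parsed.

    ``sa_entries`` holds (chrom, pos, strand, cigar) tuples from the SA:Z tag;
    a read without chimeric alignments has an empty list.
    """

    read_name: str
    chrom: str
    pos: int  # 1-based leftmost mapped coordinate
    strand: str
    cigar: str
    is_first_in_pair: bool
    mate_chrom: str | None
    mate_pos: int | None  # 1-based
    sa_entries: tuple[tuple[str, int, str, str], ...]
    mapq: int
    is_supplementary: bool = False
    is_secondary: bool = False
    is_duplicate: bool = False
    is_paired: bool = True


@dataclass
class GeneModel:
    """A gene with transcript-collapsed exons in 1-based inclusive coordinates."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int, int]] = field(default_factory=list)  # (number, start, end)

    def exon_starts(self) -> dict[int, int]:
        return {start: num for num, start, end in self.exons}

    def exon_ends(self) -> dict[int, int]:
        return {end: num for num, start, end in self.exons}


def _parse_sa_tag(sa: str, read_name: str, line_no: int | None = None) -> tuple[tuple[str, int, str, str], ...]:
    entries = []
    for part in sa.rstrip(";").split(";"):
        if not part:
            continue
        fields = part.split(",")
        if len(fields) < 4:
            raise SamParseError(
                f"malformed SA entry {part!r} on read {read_name}"
                + (f" (line {line_no})" if line_no is not None else "")
            )
        chrom, pos, strand, cigar = fields[0], fields[1], fields[2], fields[3]
        if strand not in "+-" or not _CIGAR_RE.match(cigar):
            raise SamParseError(
                f"malformed SA entry {part!r} on read {read_name}"
                + (f" (line {line_no})" if line_no is not None else "")
            )
        entries.append((chrom, int(pos), strand, cigar))
    return tuple(entries)


def read_sam(source, ignore_duplicates: bool = True, min_mapq: int = 0) -> Iterator[AlignmentRecord]:
    """Iterate AlignmentRecords from a SAM/BAM path or open text stream.

    Unmapped and secondary records are skipped; supplementary records are kept
    (flag preserved) since the chimeric configuration can be read from either
    the primary line's SA tag or the supplementary line itself. Duplicate-marked
    records are dropped when ``ignore_duplicates`` is set.
    """
    tmp = None
    if hasattr(source, "read"):
        import tempfile

        text = source.read()
        tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
        tmp.write(text)
        tmp.close()
        path = tmp.name
    else:
        path = os.fspath(source)
    try:
        handle = pysam.AlignmentFile(path, require_index=False)
    except Exception as exc:
        raise SamParseError(f"cannot open alignment file {path}: {exc}") from exc
    try:
        yield from _iter_records(handle, ignore_duplicates, min_mapq)
    finally:
        handle.close()
        if tmp is not None:
            os.unlink(tmp.name)


def _iter_records(handle, ignore_duplicates: bool, min_mapq: int) -> Iterator[AlignmentRecord]:
    for i, aln in enumerate(handle.fetch(until_eof=True), start=1):
        if aln.is_unmapped or aln.is_secondary:
            continue
        if ignore_duplicates and aln.is_duplicate:
            continue
        if aln.mapping_quality < min_mapq:
            continue
        if aln.cigarstring is None:
            raise SamParseError(f"mapped record without CIGAR: {aln.query_name} (record {i})")
        sa = aln.get_tag("SA") if aln.has_tag("SA") else ""
        yield AlignmentRecord(
            read_name=aln.query_name,
            chrom=aln.reference_name,
            pos=aln.reference_start + 1,
            strand="-" if aln.is_reverse else "+",
            cigar=aln.cigarstring,
            is_first_in_pair=bool(aln.is_paired and aln.is_read1),
            mate_chrom=aln.next_reference_name if aln.is_paired and aln.next_reference_id >= 0 else None,
            mate_pos=aln.next_reference_start + 1 if aln.is_paired and aln.next_reference_start >= 0 else None,
            sa_entries=_parse_sa_tag(sa, aln.query_name, i) if sa else (),
            mapq=aln.mapping_quality,
            is_supplementary=aln.is_supplementary,
            is_secondary=aln.is_secondary,
            is_duplicate=aln.is_duplicate,
            is_paired=aln.is_paired,
        )


def read_gtf(source) -> list[GeneModel]:
    """Load gene models from a GTF (GENCODE dialect), collapsing exons per gene.

    Exons sharing identical coordinates across transcripts of one gene are
    merged to a single entry; exon numbers come from the ``exon_number``
    attribute (first occurrence wins).
    """
    if hasattr(source, "read"):
        data = source.read()
        from_string = True
    else:
        data = os.fspath(source)
        from_string = False
    try:
        db = gffutils.create_db(
            data,
            dbfn=":memory:",
            from_string=from_string,
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted internals on bad input
        raise GtfParseError(f"failed to parse GTF: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        if "gene_id" not in feat.attributes:
            raise GtfParseError(f"exon feature without gene_id at {feat.seqid}:{feat.start}")
        gene_id = feat.attributes["gene_id"][0]
        gene_name = feat.attributes.get("gene_name", [gene_id])[0]
        model = genes.get(gene_id)
        if model is None:
            model = genes[gene_id] = GeneModel(gene_id, gene_name, feat.seqid, feat.strand)
        try:
            exon_number = int(feat.attributes.get("exon_number", [len(model.exons) + 1])[0])
        except ValueError as exc:
            raise GtfParseError(f"bad exon_number for {gene_id}: {exc}") from exc
        if not any(start == feat.start and end == feat.end for _, start, end in model.exons):
            model.exons.append((exon_number, feat.start, feat.end))
    for model in genes.values():
        model.exons.sort(key=lambda e: (e[1], e[2]))
    return list(genes.values())


def write_catalog(circrnas: Sequence, path_prefix) -> tuple[str, str]:
    """Write an annotated circRNA catalog as TSV plus a companion BED6.

    ``circrnas`` is a sequence of CircRNA objects (see circ_detect). Returns the
    (tsv_path, bed_path) pair. The TSV keeps 1-based inclusive region strings;
    the BED uses the 0-based half-open convention.
    """
    path_prefix = os.fspath(path_prefix)
    tsv_path = path_prefix + ".catalog.tsv"
    bed_path = path_prefix + ".catalog.bed"
    rows = []
    bed_lines = []
    for circ in circrnas:
        region = circ.junction.region
        counts = circ.per_sample_support or {}
        rows.append(
            {
                "region": str(region),
                "strand": circ.junction.strand,
                "gene_id": circ.gene_id,
                "gene_name": circ.gene_name,
                "exons": circ.exon_span,
                "n_samples_present": sum(1 for v in counts.values() if v > 0),
                **{f"count_{s}": c for s, c in counts.items()},
            }
        )
        chrom, start0, end = region.to_bed_interval()
        name = circ.gene_name if circ.gene_name else circ.gene_id
        bed_lines.append(f"{chrom}\t{start0}\t{end}\t{name}\t{circ.junction.support}\t{circ.junction.strand}")
    frame = pd.DataFrame(
        rows,
        columns=(
            ["region", "strand", "gene_id", "gene_name", "exons", "n_samples_present"]
            + sorted({c for r in rows for c in r if c.startswith("count_")})
            if rows
            else ["region", "strand", "gene_id", "gene_name", "exons", "n_samples_present"]
        ),
    )
    frame.to_csv(tsv_path, sep="\t", index=False)
    with open(bed_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for line in bed_lines:
            fh.write(line + "\n")
    return tsv_path, bed_path
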