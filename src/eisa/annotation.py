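"""Gene models from GTF and derivation of constitutive exon/intron regions.

The analysis rests on two per-gene region sets:

* **constitutive exons** — bases exonic in *every* annotated isoform of the
  gene (the base-wise intersection of the per-isoform exon unions), which
  proxy mature mRNA;
* **constitutive introns** — bases within the gene span exonic in *no*
  isoform (the gaps of the all-isoform exon union), which proxy pre-mRNA and
  hence transcription.

Restricting to these regions avoids counting reads whose exon/intron status
depends on which isoform produced them, at the cost of ignoring alternative
splicing (deliberately out of scope).

Internal coordinates are 0-based half-open; GTF I/O converts from/to the
1-based inclusive convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .intervals import (
    Block,
    GenomicInterval,
    clip_blocks,
    gaps_between,
    intersect_blocks,
    intersect_many,
    merge_blocks,
    total_length,
    union_blocks,
)

DEFAULT_SOURCES = frozenset({"ensembl", "ensembl_havana"})

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;?')


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


class AnnotationError(ValueError):
    """Raised when parsed features violate gene/transcript invariants."""


@dataclass
class TranscriptModel:
    """One transcript isoform: ordered disjoint exons, optional CDS blocks."""

    transcript_id: str
    gene_id: str
    source: str
    chrom: str
    strand: str
    exons: list[Block]
    cds: list[Block] | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        if self.cds is not None:
            self.cds = sorted(self.cds)
            if intersect_blocks(self.cds, self.exon_union()) != self.cds:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS extends outside exons"
                )

    def exon_union(self) -> list[Block]:
        return merge_blocks(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    """A gene with its isoforms, all on one chromosome and strand."""

    gene_id: str
    gene_name: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"gene {self.gene_id}: transcripts on multiple chromosomes/strands "
                f"({sorted(chroms)}, {sorted(strands)})"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.start for t in self.transcripts)
        end = max(t.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(
            f"gene {self.gene_id} has no transcript {transcript_id!r}"
        )


@dataclass
class RegionSet:
    """Disjoint sorted intervals of one class for one gene."""

    gene_id: str
    kind: str  # constitutive_exon | constitutive_intron
    chrom: str
    strand: str
    intervals: list[Block]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(self.intervals, self.intervals[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"RegionSet {self.gene_id}/{self.kind}: overlapping intervals"
                )

    @property
    def total_length(self) -> int:
        return total_length(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class UtrRecord:
    gene_id: str
    canonical_transcript_id: str
    utr5_length: int | None
    utr3_length: int | None
    coding: bool = True


# ---------------------------------------------------------------------------
# GTF parsing


def _parse_attributes(attr_field: str, line_no: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs:
        raise GtfParseError(f"line {line_no}: cannot parse attribute string {attr_field!r}")
    return attrs


def parse_gtf(
    source: str | Path | TextIO | Iterable[str],
    allowed_sources: Iterable[str] | None = DEFAULT_SOURCES,
) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into gene models.

    Only transcripts whose source column is in ``allowed_sources`` (default:
    ensembl and ensembl_havana) are kept; genes left without transcripts are
    dropped.  Pass ``allowed_sources=None`` to keep everything.  Coordinates
    are converted from GTF 1-based inclusive to 0-based half-open.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return parse_gtf(handle, allowed_sources=allowed_sources)

    allowed = None if allowed_sources is None else frozenset(allowed_sources)

    exons: dict[str, list[Block]] = {}
    cds: dict[str, list[Block]] = {}
    tx_meta: dict[str, dict] = {}
    tx_bounds: dict[str, Block] = {}
    gene_names: dict[str, str] = {}
    gene_order: list[str] = []

    for line_no, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {line_no}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, feat_source, feature, start_s, end_s, _score, strand, _frame, attr_field = fields
        if feature not in ("gene", "transcript", "exon", "CDS"):
            continue
        try:
            start = int(start_s) - 1
            end = int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"line {line_no}: non-integer coordinates") from exc
        if start < 0 or start >= end:
            raise GtfParseError(f"line {line_no}: invalid coordinates {start_s}..{end_s}")
        attrs = _parse_attributes(attr_field, line_no)
        if "gene_id" not in attrs:
            raise GtfParseError(f"line {line_no}: missing gene_id attribute")
        gene_id = attrs["gene_id"]
        if gene_id not in gene_names:
            gene_order.append(gene_id)
        if "gene_name" in attrs:
            gene_names[gene_id] = attrs["gene_name"]
        else:
            gene_names.setdefault(gene_id, gene_id)
        if feature == "gene":
            continue
        if "transcript_id" not in attrs:
            raise GtfParseError(f"line {line_no}: missing transcript_id attribute")
        tx_id = attrs["transcript_id"]
        meta = tx_meta.setdefault(
            tx_id,
            {"gene_id": gene_id, "source": feat_source, "chrom": chrom, "strand": strand},
        )
        if feature == "transcript":
            meta["source"] = feat_source
            tx_bounds[tx_id] = (start, end)
        elif feature == "exon":
            exons.setdefault(tx_id, []).append((start, end))
        elif feature == "CDS":
            cds.setdefault(tx_id, []).append((start, end))

    genes: dict[str, list[TranscriptModel]] = {}
    for tx_id, meta in tx_meta.items():
        if tx_id not in exons:
            continue
        if allowed is not None and meta["source"] not in allowed:
            continue
        if tx_id in tx_bounds:
            lo, hi = tx_bounds[tx_id]
            for s, e in exons[tx_id]:
                if s < lo or e > hi:
                    raise AnnotationError(
                        f"transcript {tx_id}: exon [{s},{e}) outside declared "
                        f"transcript bounds [{lo},{hi})"
                    )
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=meta["gene_id"],
            source=meta["source"],
            chrom=meta["chrom"],
            strand=meta["strand"],
            exons=exons[tx_id],
            cds=cds.get(tx_id),
        )
        genes.setdefault(meta["gene_id"], []).append(tx)

    return [
        GeneModel(gene_id=gid, gene_name=gene_names.get(gid, gid), transcripts=genes[gid])
        for gid in gene_order
        if gid in genes
    ]


# ---------------------------------------------------------------------------
# Constitutive regions


def constitutive_exons(gene: GeneModel) -> RegionSet:
    """Bases exonic in every isoform: intersection of per-isoform exon unions."""
    intervals = intersect_many([t.exon_union() for t in gene.transcripts])
    return RegionSet(gene.gene_id, "constitutive_exon", gene.chrom, gene.strand, intervals)


def constitutive_introns(gene: GeneModel) -> RegionSet:
    """Bases within the gene span exonic in no isoform: gaps of the exon union."""
    union = union_blocks([t.exon_union() for t in gene.transcripts])
    span = gene.span
    intervals = clip_blocks(gaps_between(union), span.start, span.end)
    return RegionSet(gene.gene_id, "constitutive_intron", gene.chrom, gene.strand, intervals)


def utr_lengths(gene: GeneModel, canonical_id: str) -> UtrRecord:
    """UTR lengths of the gene's canonical transcript, summed across exons.

    The 5' UTR is the exonic sequence upstream of the CDS start and the 3' UTR
    the exonic sequence downstream of the CDS end, in transcript orientation.
    Transcripts without CDS annotation yield a record flagged non-coding with
    undefined lengths.
    """
    tx = gene.transcript(canonical_id)
    if not tx.cds:
        return UtrRecord(gene.gene_id, canonical_id, None, None, coding=False)
    exon_union = tx.exon_union()
    cds_start = tx.cds[0][0]
    cds_end = tx.cds[-1][1]
    before = total_length(clip_blocks(exon_union, tx.start, cds_start))
    after = total_length(clip_blocks(exon_union, cds_end, tx.end))
    if tx.strand == "+":
        utr5, utr3 = before, after
    else:
        utr5, utr3 = after, before
    return UtrRecord(gene.gene_id, canonical_id, utr5, utr3, coding=True)


def pick_canonical(gene: GeneModel, canonical_map: Mapping[str, str] | None = None) -> str:
    """Canonical transcript id: external map if given, else longest CDS.

    Fallback ties break to the lexicographically smallest transcript id;
    transcripts without CDS rank below all coding ones.
    """
    if canonical_map is not None and gene.gene_id in canonical_map:
        tx_id = canonical_map[gene.gene_id]
        gene.transcript(tx_id)  # raises KeyError if absent
        return tx_id
    best = min(
        gene.transcripts,
        key=lambda t: (-(total_length(t.cds) if t.cds else -1), t.transcript_id),
    )
    return best.transcript_id


# ---------------------------------------------------------------------------
# I/O: SAF-style region tables, canonical maps, UTR tables

SAF_COLUMNS = ["GeneID", "Chr", "Start", "End", "Strand"]


def write_region_annotation(regionsets: Sequence[RegionSet], path: str | Path) -> None:
    """Write region sets as a SAF-style table (1-based inclusive coordinates)."""
    rows = [
        (rs.gene_id, rs.chrom, start + 1, end, rs.strand)
        for rs in regionsets
        for start, end in rs.intervals
    ]
    pd.DataFrame(rows, columns=SAF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_region_annotation(path: str | Path, kind: str) -> list[RegionSet]:
    """Read a SAF-style table back into RegionSets (one per gene, input order)."""
    df = pd.read_csv(path, sep="\t", dtype={"GeneID": str, "Chr": str, "Strand": str})
    out: list[RegionSet] = []
    for gene_id, grp in df.groupby("GeneID", sort=False):
        chroms = grp["Chr"].unique()
        strands = grp["Strand"].unique()
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(f"gene {gene_id}: rows on multiple chromosomes/strands")
        intervals = [(int(s) - 1, int(e)) for s, e in zip(grp["Start"], grp["End"])]
        out.append(RegionSet(str(gene_id), kind, str(chroms[0]), str(strands[0]), intervals))
    return out


def read_canonical_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (gene_id, transcript_id) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "transcript_id"],
                     dtype=str, comment="#")
    return dict(zip(df["gene_id"], df["transcript_id"]))


def write_canonical_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id, tx_id in mapping.items():
            fh.write(f"{gene_id}\t{tx_id}\n")


def utr_table(
    genes: Sequence[GeneModel],
    canonical_map: Mapping[str, str] | None = None,
    intron_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene feature table: UTR lengths plus (optionally) total intron bp.

    Non-coding genes appear with NA lengths so downstream comparisons can
    exclude them explicitly.
    """
    rows = []
    for gene in genes:
        tx_id = pick_canonical(gene, canonical_map)
        rec = utr_lengths(gene, tx_id)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "canonical_transcript_id": rec.canonical_transcript_id,
                "utr5": rec.utr5_length,
                "utr3": rec.utr3_length,
                "coding": rec.coding,
                "total_intron_bp": (
                    intron_lengths.get(gene.gene_id)
                    if intron_lengths is not None
                    else constitutive_introns(gene).total_length
                ),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
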