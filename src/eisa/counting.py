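"""Assign uniquely mapped reads to constitutive exon or intron regions.

Counting is a separate pass per region class (the exon and intron annotations
are independent files, as when running featureCounts twice), so a
junction-spanning read may legitimately count at both levels.  Within one
level a read is assigned to a gene iff at least one aligned base overlaps
that gene's region set; reads hitting regions of more than one gene are
ambiguous and discarded; non-uniquely mapped reads are never counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import Block
from .annotation import RegionSet

logger = logging.getLogger(__name__)


@dataclass
class ReadAlignment:
    """A single read's aligned reference segments."""

    read_id: str
    sample: str
    chrom: str
    blocks: list[Block]
    mapq_unique: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id}: no aligned blocks")
        self.blocks = sorted(self.blocks)


@dataclass
class AssignmentStats:
    assigned: int = 0
    ambiguous: int = 0
    unassigned: int = 0

    @property
    def total(self) -> int:
        return self.assigned + self.ambiguous + self.unassigned


@dataclass
class CountMatrix:
    """Genes x samples integer counts for one region level."""

    level: str  # exon | intron
    counts: pd.DataFrame  # index gene_id, columns sample_id
    condition: dict[str, str] = field(default_factory=dict)  # sample -> control|treated

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(self.condition) - set(self.counts.columns)
        if unknown:
            raise ValueError(f"condition labels for unknown samples: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


class RegionIndex:
    """Interval index over the region sets of one level, for read assignment."""

    def __init__(self, regionsets: Sequence[RegionSet]):
        kinds = {rs.kind for rs in regionsets}
        if len(kinds) > 1:
            raise ValueError(f"region sets of mixed kinds: {sorted(kinds)}")
        self.gene_ids = [rs.gene_id for rs in regionsets]
        self._trees: dict[str, IntervalTree] = {}
        for rs in regionsets:
            tree = self._trees.setdefault(rs.chrom, IntervalTree())
            for start, end in rs.intervals:
                tree.addi(start, end, rs.gene_id)

    def overlapping_genes(self, chrom: str, blocks: Sequence[Block]) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        for start, end in blocks:
            for iv in tree.overlap(start, end):
                hits.add(iv.data)
        return hits


def assign_read(read: ReadAlignment, index: RegionIndex) -> tuple[str, str | None]:
    """Assign one read: ('assigned', gene_id) | ('ambiguous'|'unassigned', None)."""
    if not read.mapq_unique:
        return "unassigned", None
    genes = index.overlapping_genes(read.chrom, read.blocks)
    if not genes:
        return "unassigned", None
    if len(genes) > 1:
        return "ambiguous", None
    return "assigned", next(iter(genes))


def count_level(
    reads: Iterable[ReadAlignment],
    regionsets: Sequence[RegionSet],
    level: str,
    samples: Sequence[str] | None = None,
    condition: Mapping[str, str] | None = None,
) -> tuple[CountMatrix, dict[str, AssignmentStats]]:
    """Count reads per gene for one region level.

    Returns the count matrix plus per-sample assignment statistics satisfying
    assigned + ambiguous + unassigned == total reads.  Duplicate read ids
    within a sample are counted once (with a warning).
    """
    index = RegionIndex(regionsets)
    counts: dict[str, dict[str, int]] = {}
    stats: dict[str, AssignmentStats] = {}
    seen: dict[str, set[str]] = {}
    sample_order: list[str] = list(samples) if samples is not None else []

    for read in reads:
        if read.sample not in stats:
            stats[read.sample] = AssignmentStats()
            seen[read.sample] = set()
            if samples is None:
                sample_order.append(read.sample)
        if read.read_id in seen[read.sample]:
            logger.warning(
                "duplicate read id %r in sample %s; counted once", read.read_id, read.sample
            )
            continue
        seen[read.sample].add(read.read_id)
        fate, gene = assign_read(read, index)
        st = stats[read.sample]
        if fate == "assigned":
            st.assigned += 1
            counts.setdefault(gene, {}).setdefault(read.sample, 0)
            counts[gene][read.sample] += 1
        elif fate == "ambiguous":
            st.ambiguous += 1
        else:
            st.unassigned += 1

    for s in sample_order:
        stats.setdefault(s, AssignmentStats())
    mat = pd.DataFrame(
        [[counts.get(g, {}).get(s, 0) for s in sample_order] for g in index.gene_ids],
        index=pd.Index(index.gene_ids, name="gene_id"),
        columns=sample_order,
        dtype=int,
    )
    cm = CountMatrix(level=level, counts=mat, condition=dict(condition or {}))
    return cm, stats


# ---------------------------------------------------------------------------
# Readers


def read_sam(
    path: str | Path,
    sample: str,
    mapq_min: int = 255,
) -> list[ReadAlignment]:
    """Read a SAM/BAM file into alignments.

    Aligned blocks come from the CIGAR (N and D split/interrupt blocks;
    insertions and clips consume no reference).  Uniqueness uses the NH tag
    when present (NH == 1), else MAPQ >= ``mapq_min``.
    """
    import pysam

    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            blocks = rec.get_blocks()
            if not blocks:
                raise ValueError(f"read {rec.query_name}: unparseable or empty CIGAR")
            if rec.has_tag("NH"):
                unique = rec.get_tag("NH") == 1
            else:
                unique = rec.mapping_quality >= mapq_min
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    sample=sample,
                    chrom=rec.reference_name,
                    blocks=[(int(s), int(e)) for s, e in blocks],
                    mapq_unique=unique,
                )
            )
    return out


PLACEMENT_COLUMNS = ["read_id", "sample", "chrom", "blocks", "unique"]


def read_placements(path: str | Path) -> list[ReadAlignment]:
    """Read the simplified read-placement TSV.

    Columns: read_id, sample, chrom, blocks ("start-end[,start-end...]",
    0-based half-open), unique (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PLACEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"placement file missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        blocks = []
        for part in row.blocks.split(","):
            s, e = part.split("-")
            blocks.append((int(s), int(e)))
        out.append(
            ReadAlignment(
                read_id=row.read_id,
                sample=row.sample,
                chrom=row.chrom,
                blocks=blocks,
                mapq_unique=row.unique in ("1", "True", "true"),
            )
        )
    return out


def write_placements(reads: Sequence[ReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PLACEMENT_COLUMNS) + "\n")
        for r in reads:
            blocks = ",".join(f"{s}-{e}" for s, e in r.blocks)
            fh.write(f"{r.read_id}\t{r.sample}\t{r.chrom}\t{blocks}\t{int(r.mapq_unique)}\n")


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t")


def read_counts(
    path: str | Path, level: str, condition: Mapping[str, str] | None = None
) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return CountMatrix(level=level, counts=df.astype(int), condition=dict(condition or {}))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with columns sample_id, condition and optionally path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "condition" not in df.columns:
        raise ValueError("sample sheet needs columns sample_id and condition")
    bad = set(df["condition"]) - {"control", "treated"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    return df
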