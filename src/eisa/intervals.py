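"""Half-open genomic intervals and the block algebra used for region construction.

All coordinates are 0-based, half-open ``[start, end)``.  The algebra operates on
plain ``(start, end)`` tuples so it stays cheap inside tight loops; the
:class:`GenomicInterval` dataclass carries chromosome/strand context at module
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

Block = tuple[int, int]

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_blocks(blocks: Iterable[Block], merge_touching: bool = True) -> list[Block]:
    """Merge overlapping (and, by default, bookended) blocks into maximal runs."""
    blocks = sorted(blocks)
    if not blocks:
        return []
    out: list[Block] = [blocks[0]]
    for start, end in blocks[1:]:
        last_start, last_end = out[-1]
        joined = start <= last_end if merge_touching else start < last_end
        if joined:
            if end > last_end:
                out[-1] = (last_start, end)
        else:
            out.append((start, end))
    return out


def intersect_blocks(a: Sequence[Block], b: Sequence[Block]) -> list[Block]:
    """Base-wise intersection of two sorted disjoint block lists."""
    out: list[Block] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(block_lists: Sequence[Sequence[Block]]) -> list[Block]:
    """Intersection across any number of block lists (each sorted, disjoint)."""
    if not block_lists:
        return []
    acc = list(block_lists[0])
    for blocks in block_lists[1:]:
        if not acc:
            break
        acc = intersect_blocks(acc, blocks)
    return acc


def union_blocks(block_lists: Iterable[Sequence[Block]]) -> list[Block]:
    pooled: list[Block] = []
    for blocks in block_lists:
        pooled.extend(blocks)
    return merge_blocks(pooled)


def gaps_between(blocks: Sequence[Block]) -> list[Block]:
    """Gaps between consecutive disjoint sorted blocks (the 'introns' of a union)."""
    out: list[Block] = []
    for (_, left_end), (right_start, _) in zip(blocks, blocks[1:]):
        if left_end < right_start:
            out.append((left_end, right_start))
    return out


def clip_blocks(blocks: Sequence[Block], lo: int, hi: int) -> list[Block]:
    out: list[Block] = []
    for start, end in blocks:
        s, e = max(start, lo), min(end, hi)
        if s < e:
            out.append((s, e))
    return out


def total_length(blocks: Iterable[Block]) -> int:
    return sum(end - start for start, end in blocks)


def blocks_overlap(a: Sequence[Block], b: Sequence[Block]) -> bool:
    return bool(intersect_blocks(a, b))
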