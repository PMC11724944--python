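"""Census of non-reference MAF alignment blocks.

Multiple-alignment (MAF) files exported from a pangenome alignment carry, in
addition to the input assemblies, reconstructed ancestral genomes ("Anc0")
and the synthetic graph backbone ("MINIGRAPH").  To isolate alignment blocks
that do not touch the reference genome, every block containing a row from an
excluded genome (ancestral, synthetic, or the reference itself) is dropped;
the surviving blocks are then censused: total base pairs per assembly, and a
histogram of blocks by the number of distinct assemblies they contain.

Base pairs are counted from the s-line ``size`` field (ungapped sequence
length), not alignment columns, and multiplicity counts distinct genomes,
not rows.  Genome names are the ``src`` field up to the first ``.``
(hal2maf's ``genome.contig`` convention).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Union

from Bio import AlignIO

DEFAULT_EXCLUDE = frozenset({"Anc0", "MINIGRAPH", "GRCg7b"})


class MafFormatError(ValueError):
    """A MAF block violating the format's internal consistency rules."""


@dataclass
class MafRow:
    """One s-line: a gapped slice of one source sequence."""

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def genome(self) -> str:
        return self.src.split(".", 1)[0]


@dataclass
class MafBlock:
    rows: list[MafRow]
    score: float | None = None

    def genomes(self) -> set[str]:
        return {r.genome for r in self.rows}


@dataclass
class MafCensus:
    """Aggregate over retained blocks: bp per assembly, blocks by multiplicity."""

    per_assembly_bp: dict[str, int] = field(default_factory=dict)
    blocks_by_multiplicity: Counter = field(default_factory=Counter)
    retained_blocks: int = 0
    excluded_blocks: int = 0

    @property
    def total_bp(self) -> int:
        return sum(self.per_assembly_bp.values())

    @property
    def parsed_blocks(self) -> int:
        return self.retained_blocks + self.excluded_blocks

    def add(self, block: MafBlock) -> None:
        for row in block.rows:
            self.per_assembly_bp[row.genome] = (
                self.per_assembly_bp.get(row.genome, 0) + row.size
            )
        self.blocks_by_multiplicity[len(block.genomes())] += 1
        self.retained_blocks += 1


def parse_maf(source: Union[str, IO[str]]) -> Iterator[MafBlock]:
    """Stream alignment blocks from MAF text (plain or gzip by filename).

    Each block is validated: all rows must have equal gapped text length
    (guaranteed by the underlying reader) and each row's ``size`` field must
    equal its count of non-gap characters; a mismatch raises
    :class:`MafFormatError` naming the block and row.
    """
    if isinstance(source, str):
        opener = gzip.open if source.endswith(".gz") else open
        with opener(source, "rt") as fh:
            yield from parse_maf(fh)
        return

    for ordinal, aln in enumerate(AlignIO.parse(source, "maf"), start=1):
        rows = []
        for rec in aln:
            text = str(rec.seq)
            size = rec.annotations["size"]
            ungapped = len(text) - text.count("-")
            if size != ungapped:
                raise MafFormatError(
                    f"block {ordinal}, row {rec.id!r}: size field {size} != "
                    f"{ungapped} non-gap characters"
                )
            start = rec.annotations["start"]
            src_size = rec.annotations["srcSize"]
            if start + size > src_size:
                raise MafFormatError(
                    f"block {ordinal}, row {rec.id!r}: start {start} + size "
                    f"{size} exceeds srcSize {src_size}"
                )
            rows.append(
                MafRow(
                    src=rec.id,
                    start=start,
                    size=size,
                    strand="+" if rec.annotations["strand"] == 1 else "-",
                    src_size=src_size,
                    text=text,
                )
            )
        # a-line key=value fields live in the alignment's private annotation
        # dict (as strings) in current biopython
        ann = getattr(aln, "_annotations", None) or aln.annotations
        score = ann.get("score")
        yield MafBlock(rows=rows, score=float(score) if score is not None else None)


def block_is_excluded(block: MafBlock, exclude: frozenset[str]) -> bool:
    """A block is excluded iff ANY row's genome is in the exclusion set."""
    return any(r.genome in exclude for r in block.rows)


def filter_nonreference(
    blocks: Iterable[MafBlock], exclude: frozenset[str] = DEFAULT_EXCLUDE
) -> tuple[list[MafBlock], int]:
    """Drop blocks containing ancestral/synthetic/reference rows.

    Returns the retained blocks (unchanged) and the excluded-block count.
    An empty exclusion set is a configuration error.
    """
    exclude = frozenset(exclude)
    if not exclude:
        raise ValueError("exclusion set must not be empty")
    retained, excluded = [], 0
    for block in blocks:
        if block_is_excluded(block, exclude):
            excluded += 1
        else:
            retained.append(block)
    return retained, excluded


def census(blocks: Iterable[MafBlock]) -> MafCensus:
    """Census already-filtered blocks.

    A genome with several rows in one block contributes all its rows' sizes
    to its bp total but counts once toward the block's multiplicity.
    """
    out = MafCensus()
    for block in blocks:
        out.add(block)
    return out


def census_maf(
    source: Union[str, IO[str]], exclude: frozenset[str] = DEFAULT_EXCLUDE
) -> MafCensus:
    """Parse, filter and census a MAF stream in one constant-memory pass."""
    exclude = frozenset(exclude)
    if not exclude:
        raise ValueError("exclusion set must not be empty")
    out = MafCensus()
    for block in parse_maf(source):
        if block_is_excluded(block, exclude):
            out.excluded_blocks += 1
        else:
            out.add(block)
    return out
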