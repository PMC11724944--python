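"""Assembly summary statistics: size, N50/L50, GC content, percent-of-assembly.

N50 is the length of the scaffold at which the cumulative sorted-descending
sum first reaches half the assembly size; L50 is how many scaffolds that
takes.  ``nx_stats`` accepts an external total so the statistics can be
computed from a published per-chromosome length table even when the unplaced
scaffold lengths are not listed (valid as long as every unlisted scaffold is
shorter than the crossing length).

GC content is computed over unambiguous bases only: Ns and IUPAC ambiguity
codes count toward scaffold length but are excluded from both the GC
numerator and denominator.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser


@dataclass
class ScaffoldRecord:
    name: str
    length: int
    gc_count: int
    acgt_count: int
    n_count: int


@dataclass
class AssemblyReport:
    genome_size: int
    scaffold_count: int
    n50: int
    l50: int
    largest: int
    gc_percent: float
    per_scaffold: list[tuple[str, int, float]]


def scan_fasta(source: Union[str, IO[str]]) -> Iterator[ScaffoldRecord]:
    """Stream per-sequence base counts from FASTA text (plain or gzip).

    Base counting is case-insensitive.  Duplicate sequence names are an
    error; empty sequences yield a length-0 record.
    """
    if isinstance(source, str):
        opener = gzip.open if source.endswith(".gz") else open
        with opener(source, "rt") as fh:
            yield from scan_fasta(fh)
        return

    seen: set[str] = set()
    for title, seq in SimpleFastaParser(source):
        name = title.split()[0] if title.split() else title
        if name in seen:
            raise ValueError(f"duplicate sequence name {name!r}")
        seen.add(name)
        s = seq.upper()
        yield ScaffoldRecord(
            name=name,
            length=len(s),
            gc_count=s.count("G") + s.count("C"),
            acgt_count=sum(s.count(b) for b in "ACGT"),
            n_count=s.count("N"),
        )


def nx_stats(lengths: Sequence[int], total: int | None = None) -> tuple[int, int]:
    """Return (N50, L50) of a length multiset.

    ``total`` defaults to the sum of ``lengths``; pass the full assembly size
    when ``lengths`` covers only part of it (e.g. the chromosome-scale
    scaffolds of a table) and every omitted scaffold is shorter than N50.
    """
    if not lengths:
        raise ValueError("cannot compute N50 of an empty length list")
    if total is None:
        total = sum(lengths)
    half = total / 2
    cumulative = 0
    for count, length in enumerate(sorted(lengths, reverse=True), start=1):
        cumulative += length
        if cumulative >= half:
            return length, count
    raise ValueError(
        f"provided lengths sum to {cumulative} < half the total {total}; "
        "N50 cannot be determined from them"
    )


def percent_report(
    per_scaffold: Iterable[tuple[str, int]], total: int
) -> list[tuple[str, int, float]]:
    """Per-scaffold percent of the assembly: 100 * length / total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return [(name, length, 100.0 * length / total) for name, length in per_scaffold]


def gc_percent(records: Iterable[ScaffoldRecord]) -> float:
    """GC over unambiguous bases: 100 * sum(G+C) / sum(A+C+G+T)."""
    gc = acgt = 0
    for rec in records:
        gc += rec.gc_count
        acgt += rec.acgt_count
    if acgt == 0:
        raise ValueError("no unambiguous bases: GC percent undefined")
    return 100.0 * gc / acgt


def assembly_report(records: Iterable[ScaffoldRecord]) -> AssemblyReport:
    """Full summary of a scanned assembly."""
    records = list(records)
    if not records:
        raise ValueError("no sequences in assembly")
    lengths = [r.length for r in records]
    genome_size = sum(lengths)
    n50, l50 = nx_stats(lengths)
    return AssemblyReport(
        genome_size=genome_size,
        scaffold_count=len(records),
        n50=n50,
        l50=l50,
        largest=max(lengths),
        gc_percent=gc_percent(records),
        per_scaffold=percent_report(
            ((r.name, r.length) for r in records), genome_size
        ),
    )


def format_sigfig(x: float, digits: int = 10) -> str:
    """Format to a fixed number of significant digits, as length tables print."""
    return f"{x:.{digits}g}"
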