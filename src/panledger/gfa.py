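"""Parsing, validation and summary statistics for path-covered GFA v1.1 graphs.

A pangenome graph collapses shared sequence from many assemblies onto shared
nodes (GFA ``S`` records); each assembly's genome is spelled out by oriented
paths (``P`` or ``W`` records).  This module provides the in-memory graph
model used by every downstream accounting step, plus the per-sample
node-coverage sets that drive novel-sequence attribution.

Sample names are recovered from path names per the PanSN convention
(``sample#haplotype#contig``), with fallbacks for assemblies that use plain
or dotted contig names.  Walk (``W``) lines carry the sample name in a
dedicated field and are used verbatim.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

log = logging.getLogger(__name__)

_ORIENTS = ("+", "-")
_WALK_STEP = re.compile(r"([><])([^><]+)")


class GFAParseError(ValueError):
    """A record that cannot be interpreted as GFA v1.1."""


class GraphIntegrityError(ValueError):
    """A link endpoint or path step references an unknown segment."""


@dataclass
class Segment:
    """One graph node: an identifier plus its sequence or declared length."""

    id: str
    sequence: str | None = None
    length: int = 0

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if self.length and self.length != len(self.sequence):
                raise GFAParseError(
                    f"segment {self.id}: declared length {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
            self.length = len(self.sequence)
        elif self.length <= 0:
            raise GFAParseError(
                f"segment {self.id}: no sequence and no positive LN length"
            )


@dataclass
class Link:
    """One edge: an adjacency between two oriented segment ends."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap: str = "*"

    def __post_init__(self) -> None:
        if self.from_orient not in _ORIENTS or self.to_orient not in _ORIENTS:
            raise GFAParseError(
                f"link {self.from_id}->{self.to_id}: orientation must be + or -"
            )


@dataclass
class PathRecord:
    """One contig of one assembly: an ordered, oriented segment traversal.

    ``style`` records which GFA dialect the path came from (``"P"`` or
    ``"W"``) so that serialization round-trips the input instead of silently
    converting walks to paths.  For walks the original start/end/source-length
    fields are kept.
    """

    sample: str
    haplotype: str | None
    contig: str
    steps: list[tuple[str, str]]
    style: str = "P"
    orig_name: str | None = None
    walk_start: int | None = None
    walk_end: int | None = None

    def __post_init__(self) -> None:
        if not self.steps:
            raise GFAParseError(f"path {self.name!r}: empty step list")

    @property
    def name(self) -> str:
        if self.haplotype is not None:
            return f"{self.sample}#{self.haplotype}#{self.contig}"
        return f"{self.sample}#{self.contig}"


@dataclass
class PangenomeGraph:
    segments: dict[str, Segment] = field(default_factory=dict)
    links: list[Link] = field(default_factory=list)
    paths: list[PathRecord] = field(default_factory=list)

    def validate(self) -> None:
        """Check referential integrity of every link endpoint and path step."""
        for lk in self.links:
            for sid in (lk.from_id, lk.to_id):
                if sid not in self.segments:
                    raise GraphIntegrityError(
                        f"link {lk.from_id}{lk.from_orient}->"
                        f"{lk.to_id}{lk.to_orient} references unknown segment {sid!r}"
                    )
        for p in self.paths:
            for sid, _ in p.steps:
                if sid not in self.segments:
                    raise GraphIntegrityError(
                        f"path {p.name!r} references unknown segment {sid!r}"
                    )

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments.values())

    def sample_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.paths:
            seen.setdefault(p.sample, None)
        return list(seen)


@dataclass
class GraphStats:
    """Node/edge/length summary of a graph, as printed by ``vg stats``-style tools.

    ``mean_degree`` is edges per node (E/N); ``mean_incident_degree`` is the
    average number of edge endpoints incident to a node (2E/N).
    """

    node_count: int
    edge_count: int
    total_length: int
    mean_degree: float
    mean_incident_degree: float
    sample_count: int
    path_count: int


def split_path_name(name: str) -> tuple[str, str | None, str]:
    """Split a P-line path name into (sample, haplotype, contig).

    PanSN names split on ``#``; legacy dotted names split on the first ``.``;
    anything else is a bare sample name whose contig is the name itself.
    """
    if "#" in name:
        parts = name.split("#")
        if len(parts) >= 3:
            return parts[0], parts[1], "#".join(parts[2:])
        return parts[0], None, parts[1]
    if "." in name:
        sample, contig = name.split(".", 1)
        return sample, None, contig
    return name, None, name


def mean_degree(node_count: int, edge_count: int) -> float:
    """Edges per node; 0 for an empty graph (with a warning, not a crash)."""
    if node_count == 0:
        if edge_count:
            log.warning("mean degree undefined: %d edges but 0 nodes", edge_count)
        return 0.0
    return edge_count / node_count


def _parse_walk_steps(walk: str, lineno: int) -> list[tuple[str, str]]:
    steps = []
    pos = 0
    for m in _WALK_STEP.finditer(walk):
        if m.start() != pos:
            raise GFAParseError(f"line {lineno}: malformed walk string {walk!r}")
        pos = m.end()
        steps.append((m.group(2), "+" if m.group(1) == ">" else "-"))
    if pos != len(walk) or not steps:
        raise GFAParseError(f"line {lineno}: malformed walk string {walk!r}")
    return steps


def parse_gfa(source: Union[str, IO[str], Iterable[str]]) -> PangenomeGraph:
    """Parse GFA v1.1 text into a :class:`PangenomeGraph`.

    ``source`` may be a filename, an open text handle, or any iterable of
    lines.  Record order is free (S lines may follow the L/P/W lines that use
    them); referential integrity is checked once the whole stream is read.
    Unknown record types are skipped and counted in a warning.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return parse_gfa(fh)

    graph = PangenomeGraph()
    skipped: dict[str, int] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        rtype = fields[0]
        if rtype == "H":
            continue
        if rtype == "S":
            graph_add = _parse_segment(fields, lineno)
            if graph_add.id in graph.segments:
                raise GFAParseError(
                    f"line {lineno}: duplicate segment id {graph_add.id!r}"
                )
            graph.segments[graph_add.id] = graph_add
        elif rtype == "L":
            if len(fields) < 6:
                raise GFAParseError(f"line {lineno}: L record needs 6 fields")
            graph.links.append(
                Link(fields[1], fields[2], fields[3], fields[4], fields[5])
            )
        elif rtype == "P":
            if len(fields) < 3:
                raise GFAParseError(f"line {lineno}: P record needs 3 fields")
            sample, hap, contig = split_path_name(fields[1])
            steps = []
            for step in fields[2].split(","):
                if not step or step[-1] not in _ORIENTS:
                    raise GFAParseError(
                        f"line {lineno}: malformed path step {step!r}"
                    )
                steps.append((step[:-1], step[-1]))
            graph.paths.append(
                PathRecord(sample, hap, contig, steps, style="P", orig_name=fields[1])
            )
        elif rtype == "W":
            if len(fields) < 7:
                raise GFAParseError(f"line {lineno}: W record needs 7 fields")
            graph.paths.append(
                PathRecord(
                    sample=fields[1],
                    haplotype=fields[2],
                    contig=fields[3],
                    steps=_parse_walk_steps(fields[6], lineno),
                    style="W",
                    walk_start=int(fields[4]),
                    walk_end=int(fields[5]),
                )
            )
        else:
            skipped[rtype] = skipped.get(rtype, 0) + 1
    for rtype, n in sorted(skipped.items()):
        log.warning("skipped %d unsupported %r records", n, rtype)
    graph.validate()
    return graph


def _parse_segment(fields: list[str], lineno: int) -> Segment:
    if len(fields) < 3:
        raise GFAParseError(f"line {lineno}: S record needs id and sequence")
    sid, seq = fields[1], fields[2]
    if seq == "*":
        for tag in fields[3:]:
            if tag.startswith("LN:i:"):
                try:
                    return Segment(sid, None, int(tag[5:]))
                except (ValueError, GFAParseError) as exc:
                    raise GFAParseError(f"line {lineno}: {exc}") from exc
        raise GFAParseError(
            f"line {lineno}: segment {sid!r} has no sequence and no LN:i tag"
        )
    return Segment(sid, seq)


def write_gfa(graph: PangenomeGraph, stream: IO[str]) -> None:
    """Serialize a graph as GFA v1.1, preserving each path's input dialect."""
    stream.write("H\tVN:Z:1.1\n")
    for seg in graph.segments.values():
        if seg.sequence is not None:
            stream.write(f"S\t{seg.id}\t{seg.sequence}\n")
        elif seg.length > 0:
            stream.write(f"S\t{seg.id}\t*\tLN:i:{seg.length}\n")
        else:
            raise GFAParseError(
                f"segment {seg.id!r}: cannot serialize without sequence or length"
            )
    for lk in graph.links:
        stream.write(
            f"L\t{lk.from_id}\t{lk.from_orient}\t{lk.to_id}\t{lk.to_orient}"
            f"\t{lk.overlap}\n"
        )
    for p in graph.paths:
        if p.style == "W":
            walk = "".join(
                (">" if o == "+" else "<") + sid for sid, o in p.steps
            )
            start = p.walk_start if p.walk_start is not None else 0
            end = p.walk_end if p.walk_end is not None else 0
            hap = p.haplotype if p.haplotype is not None else "0"
            stream.write(f"W\t{p.sample}\t{hap}\t{p.contig}\t{start}\t{end}\t{walk}\n")
        else:
            steps = ",".join(sid + o for sid, o in p.steps)
            stream.write(f"P\t{p.orig_name or p.name}\t{steps}\t*\n")


def graph_stats(graph: PangenomeGraph) -> GraphStats:
    """Count nodes, edges and total sequence, and derive degree statistics."""
    n = len(graph.segments)
    e = len(graph.links)
    return GraphStats(
        node_count=n,
        edge_count=e,
        total_length=graph.total_length,
        mean_degree=mean_degree(n, e),
        mean_incident_degree=mean_degree(n, 2 * e),
        sample_count=len(graph.sample_names()),
        path_count=len(graph.paths),
    )


def sample_coverage(graph: PangenomeGraph) -> dict[str, set[str]]:
    """Map each sample to the set of segment ids any of its paths traverses.

    Orientation and traversal multiplicity are ignored: a node is one piece
    of sequence regardless of strand or how many times a path visits it.
    """
    cov: dict[str, set[str]] = {}
    for p in graph.paths:
        bucket = cov.setdefault(p.sample, set())
        bucket.update(sid for sid, _ in p.steps)
    return cov
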