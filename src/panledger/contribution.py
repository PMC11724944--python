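"""Iterative attribution of pangenome sequence to the assemblies that carry it.

The procedure mirrors how novel sequence is accounted in multi-assembly
pangenomes: all nodes covered by the designated reference assembly are
attributed to it first; then, repeatedly, the assembly whose *remaining*
(still unattributed) covered nodes hold the most base pairs claims those
nodes, until every assembly has been evaluated.  Assemblies left with zero
remaining sequence are still recorded, at 0 bp.  Nodes covered by no path at
all accumulate into ``unassigned_bp`` so the ledger always conserves the
graph's total sequence.

Ties on remaining bp are broken lexicographically by sample name, which makes
the ledger deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gfa import PangenomeGraph, sample_coverage


@dataclass
class ContributionEntry:
    sample: str
    bp: int
    node_count: int
    round_index: int


@dataclass
class ContributionLedger:
    """Ordered attribution of graph sequence: reference first, then greedily."""

    reference_sample: str
    entries: list[ContributionEntry]
    unassigned_bp: int
    total_bp: int

    def bp_by_sample(self) -> dict[str, int]:
        return {e.sample: e.bp for e in self.entries}

    @property
    def reference_bp(self) -> int:
        return self.entries[0].bp

    def check_conservation(self) -> None:
        attributed = sum(e.bp for e in self.entries)
        if attributed + self.unassigned_bp != self.total_bp:
            raise AssertionError(
                f"ledger does not conserve sequence: {attributed} attributed "
                f"+ {self.unassigned_bp} unassigned != {self.total_bp} total"
            )


def attribute_novel_sequence(
    graph: PangenomeGraph, reference_sample: str
) -> ContributionLedger:
    """Attribute every covered node's sequence to exactly one assembly.

    Parameters
    ----------
    graph:
        A validated pangenome graph with per-sample paths.
    reference_sample:
        The assembly whose coverage is removed first (e.g. the species
        reference the graph was built against).

    Returns
    -------
    ContributionLedger
        Entry 0 is the reference; subsequent entries are in greedy selection
        order with non-increasing bp.  The ledger conserves
        ``reference + sum(samples) + unassigned == total graph bp``.
    """
    cov = sample_coverage(graph)
    if reference_sample not in cov:
        raise ValueError(
            f"reference sample {reference_sample!r} has no paths in the graph; "
            f"available samples: {sorted(cov)}"
        )
    lengths = {sid: seg.length for sid, seg in graph.segments.items()}

    ref_nodes = cov.pop(reference_sample)
    entries = [
        ContributionEntry(
            sample=reference_sample,
            bp=sum(lengths[s] for s in ref_nodes),
            node_count=len(ref_nodes),
            round_index=0,
        )
    ]
    claimed = set(ref_nodes)
    remaining = {name: nodes - claimed for name, nodes in cov.items()}

    round_index = 0
    while remaining:
        round_index += 1
        # Greedy: largest remaining bp wins; ties go to the smaller name.
        pick = min(
            remaining,
            key=lambda name: (-sum(lengths[s] for s in remaining[name]), name),
        )
        nodes = remaining.pop(pick)
        entries.append(
            ContributionEntry(
                sample=pick,
                bp=sum(lengths[s] for s in nodes),
                node_count=len(nodes),
                round_index=round_index,
            )
        )
        if nodes:
            claimed |= nodes
            for other in remaining:
                remaining[other] -= nodes

    total_bp = graph.total_length
    ledger = ContributionLedger(
        reference_sample=reference_sample,
        entries=entries,
        unassigned_bp=total_bp - sum(lengths[s] for s in claimed),
        total_bp=total_bp,
    )
    ledger.check_conservation()
    return ledger


def ledger_report(ledger: ContributionLedger) -> pd.DataFrame:
    """Tabulate a ledger: reference first, then samples by attributed bp.

    Zero-bp samples are kept — every evaluated assembly gets a row.
    """
    rows = sorted(
        ledger.entries,
        key=lambda e: (e.round_index != 0, -e.bp, e.sample),
    )
    return pd.DataFrame(
        {
            "rank": range(1, len(rows) + 1),
            "sample": [e.sample for e in rows],
            "bp": [e.bp for e in rows],
            "nodes": [e.node_count for e in rows],
            "round": [e.round_index for e in rows],
        }
    )
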