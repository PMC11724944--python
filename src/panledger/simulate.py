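"""Seeded generator of miniature ground-truthed pangenome bundles.

A bundle emulates the file structure a graph-based pangenome pipeline
produces — per-sample FASTA, a path-covered GFA v1.1 graph, a multi-sample
VCF of the planted variants, and a MAF of the novel-sequence alignment
blocks (including ancestral "Anc0" and synthetic "MINIGRAPH" decoy rows) —
together with an exact :class:`TruthBundle` so every analysis stage can be
checked against planted values without external data.

The model is a single chromosome: a shared reference core split into
backbone segments traversed by every sample, with non-overlapping bubbles
planted between backbone stretches.  Insertions add carrier-only segments
(novel sequence), deletions make carriers skip a reference segment, and SNVs
are 1-bp two-allele bubbles.  Per-sample unique insertions are segments
traversed by exactly one sample.  Nested or overlapping variation is out of
scope; bubbles are separated by at least one backbone segment.

All randomness flows from one numpy PCG64 stream seeded by
``SimParams.seed``; the same seed yields byte-identical files.
"""

from __future__ import annotations

import io
import json
import os
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import contribution, maf, sv
from .gfa import parse_gfa, graph_stats, write_gfa

_BASES = np.array(list("ACGT"))

# Thresholds used when computing planted truth classes (the classifier
# defaults): SV at >= 50 bp length difference, indel below 1 kb.
_TRUTH_SV_MIN = 50
_TRUTH_INDEL_MAX = 1000

_MIN_SPACER = 30


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic pangenome bundle.

    ``n_samples`` counts the reference; ``n_samples=1`` is the degenerate
    reference-only pangenome (all variant counts must then be zero).
    Lengths are (min, max) bp, drawn uniformly inclusive.
    """

    n_samples: int = 6
    reference_name: str = "REF"
    core_length: int = 24_000
    core_segment_count: int = 48
    unique_insertions_per_sample: int = 2
    unique_insertion_len: tuple[int, int] = (300, 1500)
    shared_insertion_count: int = 5
    shared_insertion_len: tuple[int, int] = (30, 1200)
    carrier_fraction: float = 0.5
    deletion_count: int = 5
    deletion_len: tuple[int, int] = (30, 1200)
    snv_count: int = 12
    seed: int = 0
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("unique_insertion_len", "shared_insertion_len", "deletion_len"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name}: need 1 <= min <= max, got ({lo}, {hi})")
        for name in (
            "unique_insertions_per_sample",
            "shared_insertion_count",
            "deletion_count",
            "snv_count",
            "core_length",
            "core_segment_count",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must be in (0, 1]")
        if self.n_samples == 1 and (
            self.shared_insertion_count
            or self.deletion_count
            or self.snv_count
            or self.unique_insertions_per_sample
        ):
            raise ValueError(
                "a reference-only pangenome (n_samples=1) cannot carry variants"
            )

    @property
    def sample_names(self) -> list[str]:
        return [self.reference_name] + [
            f"S{i}" for i in range(1, self.n_samples)
        ]


@dataclass
class PlantedVariant:
    chrom: str
    pos: int  # 1-based VCF position
    ref: str
    alt: str
    carriers: list[str]
    expected_class: str
    expected_is_sv: bool


@dataclass
class TruthBundle:
    """Exact expected values for every analysis stage."""

    reference_bp: int
    per_sample_novel_bp: dict[str, int]
    expected_ledger_bp: dict[str, int]
    graph_counts: tuple[int, int, int]  # (nodes, edges, total bp)
    planted_variants: list[PlantedVariant]
    maf_per_assembly_bp: dict[str, int]
    maf_multiplicity: dict[int, int]
    maf_retained: int
    maf_excluded: int

    def to_json(self) -> str:
        payload = {
            "reference_bp": self.reference_bp,
            "per_sample_novel_bp": self.per_sample_novel_bp,
            "expected_ledger_bp": self.expected_ledger_bp,
            "graph_counts": list(self.graph_counts),
            "planted_variants": [vars(v) for v in self.planted_variants],
            "maf_per_assembly_bp": self.maf_per_assembly_bp,
            "maf_multiplicity": {str(k): v for k, v in self.maf_multiplicity.items()},
            "maf_retained": self.maf_retained,
            "maf_excluded": self.maf_excluded,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class PangenomeBundle:
    params: SimParams
    ref_seq: str
    sample_seqs: dict[str, str]
    gfa_text: str
    vcf_text: str
    maf_text: str
    truth: TruthBundle

    def write(self, outdir: str) -> None:
        os.makedirs(os.path.join(outdir, "samples"), exist_ok=True)
        chrom = self.params.chrom_name
        with open(os.path.join(outdir, "ref.fa"), "w") as fh:
            _write_fasta(fh, chrom, self.ref_seq)
        for name, seq in self.sample_seqs.items():
            if name == self.params.reference_name:
                continue
            with open(os.path.join(outdir, "samples", f"{name}.fa"), "w") as fh:
                _write_fasta(fh, chrom, seq)
        for fname, text in (
            ("graph.gfa", self.gfa_text),
            ("variants.vcf", self.vcf_text),
            ("aln.maf", self.maf_text),
            ("truth.json", self.truth.to_json() + "\n"),
        ):
            with open(os.path.join(outdir, fname), "w") as fh:
                fh.write(text)


def _write_fasta(fh, name: str, seq: str, width: int = 70) -> None:
    fh.write(f">{name}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# generation

@dataclass
class _Event:
    kind: str  # "ins" | "del" | "snv" | "uins"
    length: int
    carriers: list[str]
    # filled during layout:
    pos: int = 0  # 1-based VCF position
    ref_allele: str = ""
    alt_allele: str = ""
    node_id: str | None = None  # inserted-sequence node, for MAF emission


@dataclass
class _Node:
    id: str
    seq: str
    samples: list[str]  # samples (incl. reference where applicable) covering it


def _draw_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _draw_carriers(
    rng: np.random.Generator, samples: Sequence[str], fraction: float
) -> list[str]:
    mask = rng.random(len(samples)) < fraction
    if not mask.any():
        mask[rng.integers(0, len(samples))] = True
    return [s for s, m in zip(samples, mask) if m]


def generate(params: SimParams) -> PangenomeBundle:
    """Build one bundle; identical params (incl. seed) give identical bytes."""
    rng = np.random.default_rng(params.seed)
    chrom = params.chrom_name
    ref = params.reference_name
    samples = params.sample_names
    nonref = samples[1:]

    # --- draw events ------------------------------------------------------
    events: list[_Event] = []
    for _ in range(params.shared_insertion_count):
        lo, hi = params.shared_insertion_len
        events.append(
            _Event("ins", int(rng.integers(lo, hi + 1)),
                   _draw_carriers(rng, nonref, params.carrier_fraction))
        )
    for _ in range(params.deletion_count):
        lo, hi = params.deletion_len
        events.append(
            _Event("del", int(rng.integers(lo, hi + 1)),
                   _draw_carriers(rng, nonref, params.carrier_fraction))
        )
    for _ in range(params.snv_count):
        events.append(
            _Event("snv", 1, _draw_carriers(rng, nonref, params.carrier_fraction))
        )
    for s in nonref:
        for _ in range(params.unique_insertions_per_sample):
            lo, hi = params.unique_insertion_len
            events.append(_Event("uins", int(rng.integers(lo, hi + 1)), [s]))
    if events:
        events = [events[i] for i in rng.permutation(len(events))]

    # --- lay events out on the reference, separated by backbone spacers ---
    ref_footprint = sum(
        e.length if e.kind == "del" else (1 if e.kind == "snv" else 0)
        for e in events
    )
    n_spacers = len(events) + 1
    budget = params.core_length - ref_footprint
    if budget < n_spacers * _MIN_SPACER:
        raise ValueError(
            f"core_length {params.core_length} too small for "
            f"{len(events)} non-overlapping bubbles "
            f"(reference footprint {ref_footprint}, need >= "
            f"{ref_footprint + n_spacers * _MIN_SPACER})"
        )
    extra = budget - n_spacers * _MIN_SPACER
    if n_spacers > 1 and extra > 0:
        cuts = np.sort(rng.integers(0, extra + 1, size=n_spacers - 1))
        shares = np.diff(np.concatenate(([0], cuts, [extra])))
    else:
        shares = np.array([extra])
    spacers = [_MIN_SPACER + int(s) for s in shares]

    ref_seq = _draw_seq(rng, params.core_length)

    # --- build graph columns ---------------------------------------------
    seg_target = max(1, round(params.core_length / max(1, params.core_segment_count)))
    nodes: list[_Node] = []
    columns: list[list[_Node]] = []  # each column: alternative nodes side by side
    next_id = [0]

    def new_node(seq: str, covering: list[str]) -> _Node:
        next_id[0] += 1
        node = _Node(str(next_id[0]), seq, covering)
        nodes.append(node)
        return node

    def add_backbone(seq: str) -> None:
        # split long spacers into ~seg_target pieces so the backbone has
        # roughly core_segment_count segments overall
        for i in range(0, len(seq), seg_target):
            columns.append([new_node(seq[i : i + seg_target], list(samples))])

    cursor = 0
    add_backbone(ref_seq[: spacers[0]])
    cursor += spacers[0]
    for idx, ev in enumerate(events):
        noncarriers = [ref] + [s for s in nonref if s not in ev.carriers]
        if ev.kind == "snv":
            ref_base = ref_seq[cursor]
            alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            ev.pos = cursor + 1
            ev.ref_allele, ev.alt_allele = ref_base, alt_base
            columns.append(
                [new_node(ref_base, noncarriers), new_node(alt_base, ev.carriers)]
            )
            cursor += 1
        elif ev.kind == "del":
            span = ref_seq[cursor : cursor + ev.length]
            ev.pos = cursor  # anchor base precedes the span
            ev.ref_allele = ref_seq[cursor - 1] + span
            ev.alt_allele = ref_seq[cursor - 1]
            columns.append([new_node(span, noncarriers)])
            cursor += ev.length
        else:  # ins / uins
            ins_seq = _draw_seq(rng, ev.length)
            ev.pos = cursor
            ev.ref_allele = ref_seq[cursor - 1]
            ev.alt_allele = ref_seq[cursor - 1] + ins_seq
            node = new_node(ins_seq, list(ev.carriers))
            ev.node_id = node.id
            columns.append([node])
        add_backbone(ref_seq[cursor : cursor + spacers[idx + 1]])
        cursor += spacers[idx + 1]
    assert cursor == params.core_length

    # --- paths, sequences, links, MAF row coordinates ---------------------
    sample_paths: dict[str, list[str]] = {}
    sample_seqs: dict[str, str] = {}
    ins_offsets: dict[tuple[int, str], int] = {}  # (node index, sample) -> start
    node_by_id = {n.id: n for n in nodes}
    for s in samples:
        path: list[str] = []
        offset = 0
        parts: list[str] = []
        for col in columns:
            for node in col:
                if s in node.samples:
                    path.append(node.id)
                    ins_offsets[(int(node.id), s)] = offset
                    offset += len(node.seq)
                    parts.append(node.seq)
        sample_paths[s] = path
        sample_seqs[s] = "".join(parts)
    assert sample_seqs[ref] == ref_seq

    links: list[tuple[str, str]] = []
    seen_links: set[tuple[str, str]] = set()
    for s in samples:
        path = sample_paths[s]
        for a, b in zip(path, path[1:]):
            if (a, b) not in seen_links:
                seen_links.add((a, b))
                links.append((a, b))

    # --- GFA text (reference as a P line, samples as W walks) -------------
    out = io.StringIO()
    out.write("H\tVN:Z:1.1\n")
    for node in nodes:
        out.write(f"S\t{node.id}\t{node.seq}\n")
    for a, b in links:
        out.write(f"L\t{a}\t+\t{b}\t+\t*\n")
    out.write(
        f"P\t{ref}#0#{chrom}\t" + ",".join(x + "+" for x in sample_paths[ref]) + "\t*\n"
    )
    for s in nonref:
        walk = "".join(">" + x for x in sample_paths[s])
        out.write(f"W\t{s}\t0\t{chrom}\t0\t{len(sample_seqs[s])}\t{walk}\n")
    gfa_text = out.getvalue()

    # --- VCF of planted variants ------------------------------------------
    planted: list[PlantedVariant] = []
    for ev in sorted(events, key=lambda e: e.pos):
        delta = len(ev.alt_allele) - len(ev.ref_allele)
        if ev.kind == "snv":
            cls = "snv"
        elif abs(delta) >= _TRUTH_INDEL_MAX:
            cls = "insertion" if delta > 0 else "deletion"
        else:
            cls = "indel"
        planted.append(
            PlantedVariant(
                chrom=chrom,
                pos=ev.pos,
                ref=ev.ref_allele,
                alt=ev.alt_allele,
                carriers=sorted(ev.carriers),
                expected_class=cls,
                expected_is_sv=abs(delta) >= _TRUTH_SV_MIN,
            )
        )
    header_cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if nonref:
        header_cols += "\tFORMAT\t" + "\t".join(nonref)
    vcf_lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={params.core_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        header_cols,
    ]
    for pv in planted:
        gts = "\t".join("1" if s in pv.carriers else "0" for s in nonref)
        vcf_lines.append(
            f"{pv.chrom}\t{pv.pos}\t.\t{pv.ref}\t{pv.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    vcf_text = "\n".join(vcf_lines) + "\n"

    # --- MAF: one block per novel insertion, plus excluded decoys ---------
    maf_out = io.StringIO()
    maf_out.write("##maf version=1\n")
    ins_events = [ev for ev in events if ev.kind in ("ins", "uins")]
    maf_per_assembly: dict[str, int] = {}
    maf_mult: Counter = Counter()
    for ev in ins_events:
        maf_out.write("a score=0.000000\n")
        seq = node_by_id[ev.node_id].seq
        for s in sorted(ev.carriers):
            start = ins_offsets[(int(ev.node_id), s)]
            maf_out.write(
                f"s {s}.{chrom} {start} {ev.length} + {len(sample_seqs[s])} {seq}\n"
            )
            maf_per_assembly[s] = maf_per_assembly.get(s, 0) + ev.length
        maf_mult[len(set(ev.carriers))] += 1
        maf_out.write("\n")
    # decoy blocks: each contains an excluded genome so the filter drops it
    decoy_seq = ref_seq[:_MIN_SPACER]
    partner = nonref[0] if nonref else ref
    n_decoys = 0
    for decoy in ("Anc0", "MINIGRAPH", ref):
        maf_out.write("a score=0.000000\n")
        maf_out.write(
            f"s {decoy}.{chrom} 0 {len(decoy_seq)} + {params.core_length} {decoy_seq}\n"
        )
        if partner != decoy:
            maf_out.write(
                f"s {partner}.{chrom} 0 {len(decoy_seq)} + "
                f"{len(sample_seqs[partner])} {decoy_seq}\n"
            )
        maf_out.write("\n")
        n_decoys += 1
    maf_text = maf_out.getvalue()

    # --- truth -------------------------------------------------------------
    node_lengths = {n.id: len(n.seq) for n in nodes}
    exclusive: dict[str, int] = {s: 0 for s in nonref}
    for n in nodes:
        if ref not in n.samples and len(set(n.samples)) == 1:
            exclusive[n.samples[0]] += len(n.seq)
    truth = TruthBundle(
        reference_bp=params.core_length,
        per_sample_novel_bp=exclusive,
        expected_ledger_bp=_greedy_ledger(
            {n.id: set(n.samples) for n in nodes}, node_lengths, ref, nonref
        ),
        graph_counts=(len(nodes), len(links), sum(node_lengths.values())),
        planted_variants=planted,
        maf_per_assembly_bp=maf_per_assembly,
        maf_multiplicity=dict(maf_mult),
        maf_retained=len(ins_events),
        maf_excluded=n_decoys,
    )
    return PangenomeBundle(
        params=params,
        ref_seq=ref_seq,
        sample_seqs=sample_seqs,
        gfa_text=gfa_text,
        vcf_text=vcf_text,
        maf_text=maf_text,
        truth=truth,
    )


def _greedy_ledger(
    node_samples: dict[str, set[str]],
    node_lengths: dict[str, int],
    reference: str,
    nonref: list[str],
) -> dict[str, int]:
    """Independent greedy attribution over the planted carrier sets."""
    claimed = {n for n, ss in node_samples.items() if reference in ss}
    ledger = {reference: sum(node_lengths[n] for n in claimed)}
    remaining = {
        s: {n for n, ss in node_samples.items() if s in ss} - claimed for s in nonref
    }
    while remaining:
        pick = min(
            remaining,
            key=lambda s: (-sum(node_lengths[n] for n in remaining[s]), s),
        )
        nodes = remaining.pop(pick)
        ledger[pick] = sum(node_lengths[n] for n in nodes)
        for other in remaining:
            remaining[other] -= nodes
    return ledger


# ---------------------------------------------------------------------------
# verification

@dataclass
class CheckResult:
    name: str
    passed: bool
    expected: object
    observed: object


@dataclass
class VerificationReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name: str, expected, observed) -> None:
        self.checks.append(CheckResult(name, expected == observed, expected, observed))

    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed]


def verify(bundle: PangenomeBundle, workdir: str | None = None) -> VerificationReport:
    """Run every analysis stage on the bundle and compare with planted truth."""
    params = bundle.params
    ref = params.reference_name
    report = VerificationReport()

    graph = parse_gfa(io.StringIO(bundle.gfa_text))
    stats = graph_stats(graph)
    report.add(
        "graph_counts",
        bundle.truth.graph_counts,
        (stats.node_count, stats.edge_count, stats.total_length),
    )

    buf = io.StringIO()
    write_gfa(graph, buf)
    reparsed = parse_gfa(io.StringIO(buf.getvalue()))
    report.add("gfa_roundtrip", True, graph == reparsed)

    ledger = contribution.attribute_novel_sequence(graph, ref)
    report.add("ledger_reference_bp", bundle.truth.reference_bp, ledger.reference_bp)
    report.add("ledger_bp_by_sample", bundle.truth.expected_ledger_bp,
               ledger.bp_by_sample())
    report.add(
        "ledger_conservation",
        ledger.total_bp,
        sum(e.bp for e in ledger.entries) + ledger.unassigned_bp,
    )

    with tempfile.TemporaryDirectory() as tmp:
        vcf_path = os.path.join(workdir or tmp, "variants.vcf")
        with open(vcf_path, "w") as fh:
            fh.write(bundle.vcf_text)
        for s in params.sample_names[1:]:
            expected = Counter(
                pv.expected_class
                for pv in bundle.truth.planted_variants
                if s in pv.carriers
            )
            expected_sv = sum(
                1
                for pv in bundle.truth.planted_variants
                if s in pv.carriers and pv.expected_is_sv
            )
            got, _ = sv.classify_sample_vcf(vcf_path, s)
            report.add(f"sv_class_counts[{s}]", dict(expected), dict(got.counts))
            report.add(f"sv_sv_count[{s}]", expected_sv, got.sv_count)

    exclude = frozenset({"Anc0", "MINIGRAPH", ref})
    cen = maf.census_maf(io.StringIO(bundle.maf_text), exclude)
    report.add("maf_per_assembly_bp", bundle.truth.maf_per_assembly_bp,
               cen.per_assembly_bp)
    report.add("maf_multiplicity", bundle.truth.maf_multiplicity,
               dict(cen.blocks_by_multiplicity))
    report.add("maf_retained", bundle.truth.maf_retained, cen.retained_blocks)
    report.add("maf_excluded", bundle.truth.maf_excluded, cen.excluded_blocks)
    return report
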