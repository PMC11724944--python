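import io

import pytest

from panledger.contribution import attribute_novel_sequence
from panledger.gfa import graph_stats, parse_gfa
from panledger.maf import census_maf
from panledger.simulate import PangenomeBundle, SimParams, generate, verify


def reparse(bundle):
    return parse_gfa(io.StringIO(bundle.gfa_text))


def test_same_seed_byte_identical():
    a, b = generate(SimParams(seed=42)), generate(SimParams(seed=42))
    assert a.gfa_text == b.gfa_text
    assert a.vcf_text == b.vcf_text
    assert a.maf_text == b.maf_text
    assert a.ref_seq == b.ref_seq


def test_different_seeds_differ():
    assert generate(SimParams(seed=1)).gfa_text != generate(SimParams(seed=2)).gfa_text


def test_reference_only_degenerate_bundle():
    params = SimParams(
        n_samples=1,
        shared_insertion_count=0,
        deletion_count=0,
        snv_count=0,
        unique_insertions_per_sample=0,
        seed=0,
    )
    bundle = generate(params)
    graph = reparse(bundle)
    assert graph_stats(graph).total_length == params.core_length
    ledger = attribute_novel_sequence(graph, "REF")
    assert ledger.reference_bp == params.core_length
    assert len(ledger.entries) == 1


def test_reference_only_with_variants_rejected():
    with pytest.raises(ValueError):
        SimParams(n_samples=1)


def test_single_unique_insertion_recovered():
    params = SimParams(
        n_samples=2,
        shared_insertion_count=0,
        deletion_count=0,
        snv_count=0,
        unique_insertions_per_sample=1,
        unique_insertion_len=(1000, 1000),
        seed=0,
    )
    bundle = generate(params)
    assert bundle.truth.per_sample_novel_bp == {"S1": 1000}
    ledger = attribute_novel_sequence(reparse(bundle), "REF")
    assert ledger.bp_by_sample()["S1"] == 1000


def test_planted_counts_match_graph_stats():
    bundle = generate(SimParams(seed=9))
    stats = graph_stats(reparse(bundle))
    assert bundle.truth.graph_counts == (
        stats.node_count,
        stats.edge_count,
        stats.total_length,
    )


def test_sample_fasta_matches_declared_walk_lengths():
    bundle = generate(SimParams(seed=4))
    for line in bundle.gfa_text.splitlines():
        if line.startswith("W\t"):
            fields = line.split("\t")
            assert int(fields[5]) == len(bundle.sample_seqs[fields[1]])


def test_decoy_blocks_always_present():
    bundle = generate(SimParams(seed=6))
    assert bundle.truth.maf_excluded >= 1
    assert "Anc0." in bundle.maf_text and "MINIGRAPH." in bundle.maf_text


def test_verify_passes_across_seed_sweep():
    for seed in range(20):
        report = verify(generate(SimParams(seed=seed)))
        assert report.ok, [
            (c.name, c.expected, c.observed) for c in report.failures()
        ]


def test_verify_detects_flipped_genotype():
    bundle = generate(SimParams(seed=3))
    lines = bundle.vcf_text.splitlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            cols = line.split("\t")
            cols[9] = "1" if cols[9] == "0" else "0"
            lines[i] = "\t".join(cols)
            break
    tampered = PangenomeBundle(
        params=bundle.params,
        ref_seq=bundle.ref_seq,
        sample_seqs=bundle.sample_seqs,
        gfa_text=bundle.gfa_text,
        vcf_text="\n".join(lines) + "\n",
        maf_text=bundle.maf_text,
        truth=bundle.truth,
    )
    report = verify(tampered)
    failed = {c.name for c in report.failures()}
    assert any(name.startswith("sv_") for name in failed)
    assert not any(name.startswith(("maf_", "graph", "ledger")) for name in failed)


def test_verify_detects_ancestral_row_in_retained_block():
    bundle = generate(SimParams(seed=3))
    lines = bundle.maf_text.splitlines(keepends=True)
    out, injected = [], False
    for line in lines:
        out.append(line)
        if not injected and line.startswith("s S"):
            fields = line.split()
            out.append(
                f"s Anc0.decoy {fields[2]} {fields[3]} + {fields[5]} {fields[6]}\n"
            )
            injected = True
    assert injected
    tampered = PangenomeBundle(
        params=bundle.params,
        ref_seq=bundle.ref_seq,
        sample_seqs=bundle.sample_seqs,
        gfa_text=bundle.gfa_text,
        vcf_text=bundle.vcf_text,
        maf_text="".join(out),
        truth=bundle.truth,
    )
    report = verify(tampered)
    failed = {c.name for c in report.failures()}
    assert any(name.startswith("maf_") for name in failed)
    assert not any(name.startswith("sv_") for name in failed)


def test_bundle_write_roundtrip(tmp_path):
    bundle = generate(SimParams(seed=2))
    outdir = tmp_path / "bundle"
    bundle.write(str(outdir))
    assert (outdir / "graph.gfa").read_text() == bundle.gfa_text
    assert (outdir / "variants.vcf").read_text() == bundle.vcf_text
    assert (outdir / "truth.json").exists()
    graph = parse_gfa(str(outdir / "graph.gfa"))
    assert graph_stats(graph).node_count == bundle.truth.graph_counts[0]
    # census straight from the written file
    exclude = frozenset({"Anc0", "MINIGRAPH", "REF"})
    cen = census_maf(str(outdir / "aln.maf"), exclude)
    assert cen.per_assembly_bp == bundle.truth.maf_per_assembly_bp


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SimParams(carrier_fraction=0.0)
    with pytest.raises(ValueError):
        SimParams(deletion_len=(10, 5))
    with pytest.raises(ValueError):
        generate(SimParams(core_length=500))  # no room for bubbles
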