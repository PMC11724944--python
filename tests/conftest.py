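import io
import textwrap

import pytest

from panledger.gfa import parse_gfa


@pytest.fixture
def toy_gfa_text():
    """Three segments (4, 5, 6 bp), two links, one PanSN-named path."""
    return textwrap.dedent(
        """\
        H\tVN:Z:1.1
        S\t1\tACGT
        S\t2\tACGTA
        S\t3\tACGTAC
        L\t1\t+\t2\t+\t*
        L\t2\t+\t3\t+\t*
        P\tREF#0#chr1\t1+,2+,3+\t*
        """
    )


@pytest.fixture
def toy_graph(toy_gfa_text):
    return parse_gfa(io.StringIO(toy_gfa_text))


@pytest.fixture
def contrib_gfa_text():
    """Nodes A(10), B(5), C(3), D(7); paths REF:[A], S1:[A,B,C], S2:[A,C,D]."""
    return textwrap.dedent(
        """\
        H\tVN:Z:1.1
        S\tA\t*\tLN:i:10
        S\tB\t*\tLN:i:5
        S\tC\t*\tLN:i:3
        S\tD\t*\tLN:i:7
        P\tREF#0#c\tA+\t*
        P\tS1#0#c\tA+,B+,C+\t*
        P\tS2#0#c\tA+,C+,D+\t*
        """
    )


@pytest.fixture
def contrib_graph(contrib_gfa_text):
    return parse_gfa(io.StringIO(contrib_gfa_text))


VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000>
    ##contig=<ID=chr2,length=100000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    """
)


@pytest.fixture
def make_vcf(tmp_path):
    """Write a small VCF; rows are (chrom, pos, ref, alts, {sample: gt})."""

    def _make(rows, samples=("S1", "S2"), name="test.vcf"):
        path = tmp_path / name
        lines = [VCF_HEADER.rstrip("\n")]
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
        )
        for chrom, pos, ref, alts, gts in rows:
            gt_cols = "\t".join(gts.get(s, "0") for s in samples)
            lines.append(
                f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT\t{gt_cols}"
            )
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    return _make
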