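"""Per-sample variant extraction from multi-sample VCFs and allele-length
classification into insertion / deletion / indel / snv / mnv / complex.

Classification follows the length-difference convention used for pangenome
VCFs: an allele pair is a structural variant when the reference and
alternate lengths differ by at least ``sv_min_delta`` (default 50 bp), and a
length-changing variant below ``indel_max_len`` (default 1 kb) is an indel,
while changes of at least 1 kb are called insertions or deletions by sign.
Length-preserving variants are SNVs (1 bp) or MNVs.  A length-changing
allele pair that remains heavily substituted after anchor trimming (strip the
shared leading base, then the shared trailing run) is labelled complex.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
import pysam

log = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^[ACGTNacgtn]+$")

VARIANT_CLASSES = ("insertion", "deletion", "indel", "snv", "mnv", "complex")


@dataclass(frozen=True)
class ClassifierConfig:
    """Length thresholds for SV calling and indel-vs-large categorization."""

    sv_min_delta: int = 50
    indel_max_len: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.sv_min_delta < self.indel_max_len):
            raise ValueError(
                f"need 0 < sv_min_delta < indel_max_len, got "
                f"{self.sv_min_delta} / {self.indel_max_len}"
            )


DEFAULT_CONFIG = ClassifierConfig()


@dataclass
class VariantRecord:
    """One VCF record trimmed down to the alleles one sample carries."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    genotypes: dict[str, tuple[int | None, ...]]


@dataclass
class ClassifiedVariant:
    chrom: str | None
    pos: int | None
    ref_len: int
    alt_len: int
    delta: int
    variant_class: str
    is_sv: bool


@dataclass
class ClassTally:
    """Per-class and per-chromosome x class counts over classified variants."""

    counts: Counter = field(default_factory=Counter)
    per_chrom: dict[str, Counter] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def sv_count(self) -> int:
        return self._sv

    _sv: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": chrom, "class": cls, "count": n}
            for chrom, counter in sorted(self.per_chrom.items())
            for cls, n in sorted(counter.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "class", "count"])


def _trim_anchor(ref: str, alt: str) -> tuple[str, str]:
    """Strip the shared leading run (anchor bases), then the shared trailing run.

    A pure anchored insertion/deletion trims down to an empty allele on one
    side; whatever remains on both sides is genuine substitution.
    """
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return ref, alt


def classify_allele(
    ref_allele: str,
    alt_allele: str,
    config: ClassifierConfig = DEFAULT_CONFIG,
    chrom: str | None = None,
    pos: int | None = None,
) -> ClassifiedVariant:
    """Classify one ref/alt allele pair by the length rules.

    Raises
    ------
    ValueError
        If either allele contains characters outside A, C, G, T, N (symbolic
        alleles such as ``<DEL>`` are not sequence-resolved and are rejected).
    """
    for allele in (ref_allele, alt_allele):
        if not _ALLELE_RE.match(allele):
            raise ValueError(f"allele {allele!r} is not a plain ACGTN string")
    ref_len, alt_len = len(ref_allele), len(alt_allele)
    delta = alt_len - ref_len
    is_sv = abs(delta) >= config.sv_min_delta

    if delta == 0:
        cls = "snv" if ref_len == 1 else "mnv"
    else:
        t_ref, t_alt = _trim_anchor(ref_allele, alt_allele)
        if len(t_ref) > 1 and len(t_alt) > 1:
            cls = "complex"
        elif abs(delta) < config.indel_max_len:
            cls = "indel"
        else:
            cls = "insertion" if delta > 0 else "deletion"
    return ClassifiedVariant(
        chrom=chrom,
        pos=pos,
        ref_len=ref_len,
        alt_len=alt_len,
        delta=delta,
        variant_class=cls,
        is_sv=is_sv,
    )


def extract_sample_variants(
    vcf_path: str,
    sample: str,
    exclusive: bool = False,
    skip_counts: dict[str, int] | None = None,
) -> Iterator[VariantRecord]:
    """Yield records where ``sample`` carries a non-reference allele.

    Alt alleles the sample does not carry are dropped and the genotype
    indices renumbered, emulating ``bcftools view -a -s <sample>`` style
    subsetting.  Records whose sample genotype is homozygous reference or
    fully missing are discarded.  With ``exclusive=True``, records where any
    other sample also carries a non-reference allele are discarded too.

    Symbolic or malformed alleles and unreadable genotypes are skipped with
    a warning; ``skip_counts`` (if given) accumulates per-reason tallies.
    """
    counts = skip_counts if skip_counts is not None else {}
    with pysam.VariantFile(vcf_path) as vcf:
        header_samples = list(vcf.header.samples)
        if sample not in header_samples:
            raise ValueError(
                f"sample {sample!r} not in VCF header; "
                f"header samples: {header_samples}"
            )
        for rec in vcf:
            try:
                gt = rec.samples[sample]["GT"]
            except (KeyError, ValueError):
                counts["bad_genotype"] = counts.get("bad_genotype", 0) + 1
                log.warning("%s:%d skipped: unreadable genotype", rec.chrom, rec.pos)
                continue
            carried = sorted({i for i in gt if i is not None and i > 0})
            if not carried:
                continue
            alts = rec.alts or ()
            if any(i > len(alts) for i in carried):
                counts["bad_genotype"] = counts.get("bad_genotype", 0) + 1
                log.warning("%s:%d skipped: allele index out of range", rec.chrom, rec.pos)
                continue
            carried_alleles = [alts[i - 1] for i in carried]
            if any(not _ALLELE_RE.match(a or "") for a in carried_alleles):
                counts["symbolic_allele"] = counts.get("symbolic_allele", 0) + 1
                log.warning("%s:%d skipped: symbolic/non-ACGTN allele", rec.chrom, rec.pos)
                continue
            if exclusive:
                others = (
                    i
                    for name in header_samples
                    if name != sample
                    for i in (rec.samples[name]["GT"] or ())
                )
                if any(i is not None and i > 0 for i in others):
                    continue
            renumber = {0: 0, **{old: new + 1 for new, old in enumerate(carried)}}
            new_gt = tuple(
                renumber.get(i) if i is not None else None for i in gt
            )
            yield VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_alleles=carried_alleles,
                genotypes={sample: new_gt},
            )


def classify_record(
    record: VariantRecord, config: ClassifierConfig = DEFAULT_CONFIG
) -> list[ClassifiedVariant]:
    """One classification per distinct carried alt allele of the record."""
    return [
        classify_allele(record.ref_allele, alt, config, record.chrom, record.pos)
        for alt in record.alt_alleles
    ]


def tally(classified: Iterable[ClassifiedVariant]) -> ClassTally:
    """Count classifications per class and per chromosome x class."""
    out = ClassTally()
    for cv in classified:
        out.counts[cv.variant_class] += 1
        if cv.chrom is not None:
            out.per_chrom.setdefault(cv.chrom, Counter())[cv.variant_class] += 1
        if cv.is_sv:
            out._sv += 1
    return out


def classify_sample_vcf(
    vcf_path: str,
    sample: str,
    config: ClassifierConfig = DEFAULT_CONFIG,
    exclusive: bool = False,
) -> tuple[ClassTally, list[ClassifiedVariant]]:
    """Extract, classify and tally every variant one sample carries."""
    classified: list[ClassifiedVariant] = []
    for rec in extract_sample_variants(vcf_path, sample, exclusive=exclusive):
        classified.extend(classify_record(rec, config))
    return tally(classified), classified
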