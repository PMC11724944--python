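import pytest

from panledger.sv import (
    ClassifierConfig,
    classify_allele,
    classify_record,
    classify_sample_vcf,
    extract_sample_variants,
    tally,
)


class TestClassifyAllele:
    def test_large_deletion_below_1kb_is_sv_indel(self):
        ref = "A" + "C" * 119
        cv = classify_allele(ref, "A")
        assert cv.delta == -119
        assert cv.is_sv is True
        assert cv.variant_class == "indel"

    def test_1500bp_insertion_is_insertion_class(self):
        cv = classify_allele("A", "A" + "G" * 1500)
        assert cv.delta == 1500
        assert cv.is_sv is True
        assert cv.variant_class == "insertion"

    def test_large_deletion_at_least_1kb(self):
        cv = classify_allele("A" + "T" * 1000, "A")
        assert cv.variant_class == "deletion"
        assert cv.is_sv is True

    def test_snv(self):
        cv = classify_allele("A", "T")
        assert (cv.delta, cv.variant_class, cv.is_sv) == (0, "snv", False)

    def test_mnv(self):
        cv = classify_allele("AC", "TG")
        assert cv.variant_class == "mnv"

    def test_small_indel_not_sv(self):
        cv = classify_allele("A" * 10, "A" * 10 + "C" * 20)
        assert (cv.delta, cv.is_sv, cv.variant_class) == (20, False, "indel")

    @pytest.mark.parametrize(
        "delta,expect_sv", [(49, False), (50, True), (51, True)]
    )
    @pytest.mark.parametrize("sign", [1, -1])
    def test_sv_threshold_boundary(self, delta, expect_sv, sign):
        ref, alt = "A", "A" + "C" * delta
        if sign < 0:
            ref, alt = alt, ref
        cv = classify_allele(ref, alt)
        assert cv.is_sv is expect_sv
        assert cv.delta == sign * delta

    @pytest.mark.parametrize(
        "delta,expect_class", [(999, "indel"), (1000, "insertion")]
    )
    def test_indel_vs_large_boundary(self, delta, expect_class):
        cv = classify_allele("A", "A" + "T" * delta)
        assert cv.variant_class == expect_class
        cv_del = classify_allele("A" + "T" * delta, "A")
        assert cv_del.variant_class == ("indel" if delta == 999 else "deletion")

    def test_heavily_substituted_length_change_is_complex(self):
        # anchor-trim leaves both alleles > 1 bp: complex
        cv = classify_allele("ACCCCG", "ATTTT")
        assert cv.variant_class == "complex"

    def test_anchored_pure_insertion_is_not_complex(self):
        cv = classify_allele("A", "ACCCGG")
        assert cv.variant_class == "indel"

    def test_symbolic_allele_rejected(self):
        with pytest.raises(ValueError):
            classify_allele("A", "<DEL>")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClassifierConfig(sv_min_delta=0)
        with pytest.raises(ValueError):
            ClassifierConfig(sv_min_delta=2000, indel_max_len=1000)

    def test_custom_thresholds_respected(self):
        config = ClassifierConfig(sv_min_delta=10, indel_max_len=100)
        assert classify_allele("A", "A" + "C" * 10, config).is_sv
        assert classify_allele("A", "A" + "C" * 100, config).variant_class == "insertion"


class TestExtraction:
    def test_homref_and_missing_dropped(self, make_vcf):
        path = make_vcf(
            [
                ("chr1", 5, "A", ["T"], {"S1": "0/0", "S2": "0/1"}),
                ("chr1", 9, "G", ["C"], {"S1": "./.", "S2": "1/1"}),
            ]
        )
        assert list(extract_sample_variants(path, "S1")) == []
        assert len(list(extract_sample_variants(path, "S2"))) == 2

    def test_trim_and_renumber(self, make_vcf):
        path = make_vcf([("chr1", 5, "A", ["T", "ACCT"], {"S1": "0/2"})])
        (rec,) = extract_sample_variants(path, "S1")
        assert rec.alt_alleles == ["ACCT"]
        assert rec.genotypes["S1"] == (0, 1)

    def test_unknown_sample_lists_header(self, make_vcf):
        path = make_vcf([("chr1", 5, "A", ["T"], {})])
        with pytest.raises(ValueError, match="S1"):
            list(extract_sample_variants(path, "NOPE"))

    def test_multiallelic_genotype_yields_two_classifications(self, make_vcf):
        path = make_vcf([("chr1", 5, "A", ["T", "ACCT"], {"S1": "1/2"})])
        (rec,) = extract_sample_variants(path, "S1")
        assert rec.alt_alleles == ["T", "ACCT"]
        classes = {cv.variant_class for cv in classify_record(rec)}
        assert classes == {"snv", "indel"}

    def test_symbolic_allele_counted_and_skipped(self, make_vcf):
        path = make_vcf([("chr1", 5, "A", ["<DEL>"], {"S1": "0/1"})])
        counts = {}
        assert list(extract_sample_variants(path, "S1", skip_counts=counts)) == []
        assert counts == {"symbolic_allele": 1}

    def test_phased_and_unphased_equivalent(self, make_vcf):
        path = make_vcf(
            [
                ("chr1", 5, "A", ["T"], {"S1": "0|1"}),
                ("chr1", 9, "G", ["C"], {"S1": "0/1"}),
            ]
        )
        assert len(list(extract_sample_variants(path, "S1"))) == 2

    def test_exclusive_filters_shared_records(self, make_vcf):
        path = make_vcf(
            [
                ("chr1", 5, "A", ["T"], {"S1": "0/1", "S2": "0/1"}),
                ("chr1", 9, "G", ["C"], {"S1": "0/1", "S2": "0/0"}),
            ]
        )
        carried = list(extract_sample_variants(path, "S1"))
        only = list(extract_sample_variants(path, "S1", exclusive=True))
        assert len(carried) == 2
        assert len(only) == 1 and only[0].pos == 9

    def test_idempotence_of_trimmed_classification(self, make_vcf):
        # classifying the trimmed record equals classifying the carried allele
        path = make_vcf([("chr1", 5, "A", ["T", "ACCT"], {"S1": "0/2"})])
        (rec,) = extract_sample_variants(path, "S1")
        direct = classify_allele("A", "ACCT")
        (via_record,) = classify_record(rec)
        assert (via_record.variant_class, via_record.delta, via_record.is_sv) == (
            direct.variant_class,
            direct.delta,
            direct.is_sv,
        )


class TestTally:
    def test_empty(self):
        t = tally([])
        assert t.total == 0 and t.sv_count == 0

    def test_hand_counts(self):
        cvs = [
            classify_allele("A", "A" + "C" * 1000, chrom="chr1"),
            classify_allele("A", "A" + "C" * 1001, chrom="chr1"),
            classify_allele("A" + "G" * 1000, "A", chrom="chr2"),
        ]
        t = tally(cvs)
        assert t.counts == {"insertion": 2, "deletion": 1}
        assert dict(t.per_chrom["chr1"]) == {"insertion": 2}
        assert dict(t.per_chrom["chr2"]) == {"deletion": 1}
        assert t.total == 3

    def test_partition_invariant(self, make_vcf):
        path = make_vcf(
            [
                ("chr1", 5, "A", ["T"], {"S1": "0/1"}),
                ("chr1", 50, "G", ["G" + "A" * 60], {"S1": "1/1"}),
                ("chr2", 7, "C" + "T" * 30, ["C"], {"S1": "0/1"}),
            ]
        )
        t, classified = classify_sample_vcf(path, "S1")
        assert t.total == len(classified) == 3
        assert sum(t.counts.values()) == t.total
        assert t.sv_count == 1
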