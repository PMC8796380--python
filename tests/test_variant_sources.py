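import pytest

from satmut.errors import InputError
from satmut.ranges import GenomicRange
from satmut.reference import ReferenceSequence
from satmut.variant_sources import (
    CustomVariantSource,
    ProtectionEdit,
    apply_protection,
    load_custom_variants,
    load_protection_edits,
    parse_manifest,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chrT,length=3000>\n"
    '##INFO=<ID=TAG,Number=1,Type=String,Description="x">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(path, *rows):
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in rows))
    return path


def source_for(path, tag=None):
    return CustomVariantSource("test", str(path), tag)


TARGETON = GenomicRange("chrT", 1, 3000, "+")


def test_parse_fixture_manifest(fx):
    sources = parse_manifest(fx.paths["manifest"])
    assert [s.alias for s in sources] == ["custom1", "custom2"]
    assert sources[0].id_info_tag is None
    assert sources[1].id_info_tag == "ALLELEID"
    # relative paths resolve against the manifest's directory
    assert sources[0].vcf_path == str(fx.paths["custom_vcf_1"])


def test_manifest_duplicate_alias_rejected(tmp_path, fx):
    path = tmp_path / "m.csv"
    vcf = fx.paths["custom_vcf_1"]
    path.write_text(f"alias,vcf_path\na,{vcf}\na,{vcf}\n")
    with pytest.raises(InputError, match="duplicate alias"):
        parse_manifest(path)


def test_manifest_missing_vcf_rejected(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("alias,vcf_path\na,/nonexistent/x.vcf\n")
    with pytest.raises(InputError, match="does not exist"):
        parse_manifest(path)


def test_manifest_missing_columns_rejected(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("alias,file\na,x.vcf\n")
    with pytest.raises(InputError, match="must have columns"):
        parse_manifest(path)


def test_substitution_passes_through_unchanged(tmp_path):
    vcf = write_vcf(tmp_path / "v.vcf", "chrT\t100\tv1\tA\tG\t.\t.\t.")
    (rec,) = load_custom_variants(source_for(vcf), TARGETON)
    assert (rec.position, rec.ref_seq, rec.alt_seq, rec.type) == (
        100,
        "A",
        "G",
        "snv",
    )
    assert rec.variant_id == "v1"
    assert rec.source == "test"


def test_anchored_deletion_normalized_to_first_deleted_base(tmp_path):
    # VCF: POS 10 REF ATT ALT A deletes bases 11-12
    vcf = write_vcf(tmp_path / "v.vcf", "chrT\t10\td\tATT\tA\t.\t.\t.")
    (rec,) = load_custom_variants(source_for(vcf), TARGETON)
    assert (rec.position, rec.ref_seq, rec.alt_seq, rec.type) == (
        11,
        "TT",
        "",
        "deletion",
    )
    assert rec.end == 12


def test_anchored_insertion_normalized_to_following_position(tmp_path):
    # VCF: POS 10 REF A ALT ACG inserts CG after base 10
    vcf = write_vcf(tmp_path / "v.vcf", "chrT\t10\ti\tA\tACG\t.\t.\t.")
    (rec,) = load_custom_variants(source_for(vcf), TARGETON)
    assert (rec.position, rec.ref_seq, rec.alt_seq, rec.type) == (
        11,
        "",
        "CG",
        "insertion",
    )


def test_multi_nucleotide_substitution_kept_as_indel(tmp_path):
    vcf = write_vcf(tmp_path / "v.vcf", "chrT\t10\tm\tAC\tGT\t.\t.\t.")
    (rec,) = load_custom_variants(source_for(vcf), TARGETON)
    assert (rec.position, rec.ref_seq, rec.alt_seq, rec.type) == (
        10,
        "AC",
        "GT",
        "indel",
    )


def test_multi_allelic_record_split_per_alternate(tmp_path):
    vcf = write_vcf(tmp_path / "v.vcf", "chrT\t50\tv\tA\tC,G\t.\t.\t.")
    recs = load_custom_variants(source_for(vcf), TARGETON)
    assert [(r.position, r.alt_seq) for r in recs] == [(50, "C"), (50, "G")]


def test_symbolic_alternate_skipped(tmp_path):
    vcf = write_vcf(
        tmp_path / "v.vcf",
        "chrT\t50\tv\tA\t<DEL>\t.\t.\t.",
        "chrT\t60\tw\tA\tG\t.\t.\t.",
    )
    recs = load_custom_variants(source_for(vcf), TARGETON)
    assert [r.position for r in recs] == [60]


def test_variant_must_start_and_end_inside_targeton(tmp_path):
    vcf = write_vcf(
        tmp_path / "v.vcf",
        "chrT\t99\tbefore\tA\tG\t.\t.\t.",
        "chrT\t100\tat_start\tA\tG\t.\t.\t.",
        "chrT\t199\tdel_crossing_end\tATT\tA\t.\t.\t.",  # deletes 200-201
        "chrT\t200\tat_end\tA\tG\t.\t.\t.",
        "chrT\t201\tafter\tA\tG\t.\t.\t.",
    )
    recs = load_custom_variants(
        source_for(vcf), GenomicRange("chrT", 100, 200, "+")
    )
    assert [r.variant_id for r in recs] == ["at_start", "at_end"]


def test_other_chromosome_ignored(tmp_path):
    vcf = write_vcf(tmp_path / "v.vcf", "chrX\t50\tv\tA\tG\t.\t.\t.")
    assert load_custom_variants(source_for(vcf), TARGETON) == []


def test_identifier_taken_from_info_tag_when_configured(tmp_path):
    vcf = write_vcf(tmp_path / "v.vcf", "chrT\t50\tvcf_id\tA\tG\t.\t.\tTAG=987")
    (rec,) = load_custom_variants(source_for(vcf, tag="TAG"), TARGETON)
    assert rec.variant_id == "987"
    (rec2,) = load_custom_variants(source_for(vcf), TARGETON)
    assert rec2.variant_id == "vcf_id"


def test_fixture_custom2_uses_alleleid(fx):
    sources = parse_manifest(fx.paths["manifest"])
    recs = load_custom_variants(sources[1], GenomicRange("chrT", 1110, 1354, "-"))
    assert len(recs) == 1
    assert recs[0].variant_id == "12345"
    assert recs[0].position == 1340


def test_protection_edits_grouped_by_sgrna(fx):
    groups = load_protection_edits(fx.paths["protection_vcf"])
    assert set(groups) == {"sgRNA_ex2"}
    edits = groups["sgRNA_ex2"]
    assert [e.position for e in edits] == [1240, 1245]
    for e in edits:
        assert e.ref_base == fx.sequence[e.position - 1]
        assert e.alt_base != e.ref_base


def test_protection_record_without_sgrna_tag_rejected(tmp_path):
    vcf = write_vcf(tmp_path / "p.vcf", "chrT\t10\t.\tA\tG\t.\t.\t.")
    with pytest.raises(InputError, match="SGRNA"):
        load_protection_edits(vcf)


def test_protection_record_must_be_snv(tmp_path):
    path = tmp_path / "p.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chrT,length=3000>\n"
        '##INFO=<ID=SGRNA,Number=1,Type=String,Description="x">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chrT\t10\t.\tAT\tA\t.\t.\tSGRNA=sg1\n"
    )
    with pytest.raises(InputError, match="single-nucleotide"):
        load_protection_edits(path)


def reference(start, bases, preceding="T"):
    return ReferenceSequence(
        range=GenomicRange("chrT", start, start + len(bases) - 1, "+"),
        bases=bases,
        preceding_base=preceding if start > 1 else None,
    )


def test_apply_protection_changes_only_the_edited_positions():
    ref = reference(100, "ACGTACGT")
    edits = [
        ProtectionEdit("sg", 101, "C", "T"),
        ProtectionEdit("sg", 105, "C", "A"),
    ]
    out = apply_protection(ref, edits)
    assert out.bases == "ATGTAAGT"
    assert out.range == ref.range
    assert apply_protection(ref, list(reversed(edits))).bases == out.bases


def test_apply_protection_rejects_duplicate_positions():
    ref = reference(100, "ACGT")
    edits = [
        ProtectionEdit("a", 101, "C", "T"),
        ProtectionEdit("b", 101, "C", "G"),
    ]
    with pytest.raises(InputError, match="multiple protection edits"):
        apply_protection(ref, edits)


def test_apply_protection_rejects_out_of_range_edit():
    ref = reference(100, "ACGT")
    with pytest.raises(InputError, match="outside targeton"):
        apply_protection(ref, [ProtectionEdit("a", 99, "A", "G")])


def test_apply_protection_rejects_reference_mismatch():
    ref = reference(100, "ACGT")
    with pytest.raises(InputError, match="edit expects"):
        apply_protection(ref, [ProtectionEdit("a", 100, "G", "T")])


def test_protection_edit_must_be_single_base():
    with pytest.raises(InputError, match="single-nucleotide"):
        ProtectionEdit("a", 100, "AT", "A")
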