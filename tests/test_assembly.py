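import csv

import pysam
import pytest

from satmut.assembly import (
    AssemblyOptions,
    METADATA_COLUMNS,
    assemble,
    assemble_all,
    deduplicate,
    filter_max_length,
    vcf_alleles,
    write_outputs,
)
from satmut.codons import revcomp
from satmut.mutators import RegionVariant, VariantRecord
from satmut.ranges import GenomicRange
from satmut.reference import ReferenceSequence


def reference(start, bases, strand="+", preceding="T"):
    return ReferenceSequence(
        range=GenomicRange("chrT", start, start + len(bases) - 1, strand),
        bases=bases,
        preceding_base=preceding if start > 1 else None,
    )


def snv(pos, ref, alt, source="snv"):
    return RegionVariant(
        region="r2",
        mutator="snv",
        variant=VariantRecord(
            source=source, position=pos, ref_seq=ref, alt_seq=alt, type="snv"
        ),
    )


def deletion(pos, ref, source="1del"):
    return RegionVariant(
        region="r1",
        mutator="1del",
        variant=VariantRecord(
            source=source, position=pos, ref_seq=ref, alt_seq="", type="deletion"
        ),
    )


OPTS = AssemblyOptions(adapter_5="AATGATACGG", adapter_3="CAAGCAGAAG")


def test_adapters_flank_the_mutated_targeton():
    ref = reference(100, "ACGTACGT")
    oligo = assemble(ref, snv(102, "G", "T"), OPTS, "stem")
    assert oligo.mutated_seq == "ACTTACGT"
    assert oligo.final_sequence == "AATGATACGG" + "ACTTACGT" + "CAAGCAGAAG"
    assert not oligo.revcomp_applied


def test_minus_strand_revcomp_spares_the_adapters():
    ref = reference(100, "ACGTACGT", strand="-")
    opts = AssemblyOptions(
        adapter_5="AAA", adapter_3="TTT", revcomp_minus_strand=True
    )
    oligo = assemble(ref, snv(102, "G", "T"), opts, "stem")
    assert oligo.revcomp_applied
    assert oligo.final_sequence == "AAA" + revcomp("ACTTACGT") + "TTT"
    # without the option nothing is reverse-complemented
    plain = assemble(ref, snv(102, "G", "T"), OPTS, "stem")
    assert not plain.revcomp_applied
    assert "ACTTACGT" in plain.final_sequence


def test_plus_strand_never_reverse_complemented():
    ref = reference(100, "ACGTACGT", strand="+")
    opts = AssemblyOptions(revcomp_minus_strand=True)
    oligo = assemble(ref, snv(102, "G", "T"), opts, "stem")
    assert not oligo.revcomp_applied


def test_assemble_rejects_reference_mismatch():
    ref = reference(100, "ACGTACGT")
    with pytest.raises(ValueError, match="reference mismatch"):
        assemble(ref, snv(103, "A", "T"), OPTS, "stem")


def test_duplicate_oligo_names_get_suffixes():
    ref = reference(100, "ACGTACGT")
    oligos = assemble_all(
        ref, [snv(102, "G", "T"), snv(102, "G", "T")], OPTS, "stem"
    )
    names = [o.oligo_name for o in oligos]
    assert len(set(names)) == 2
    assert names[1] == names[0] + "_1"


def test_length_filter_is_strictly_greater_than():
    ref = reference(100, "A" * 50)
    oligos = [
        assemble(ref, snv(100 + i, "A", "G"), AssemblyOptions(), "s")
        for i in range(3)
    ]
    kept, excluded = filter_max_length(oligos, max_length=50)
    assert len(kept) == 3 and excluded == []
    kept, excluded = filter_max_length(oligos, max_length=49)
    assert kept == [] and len(excluded) == 3
    with pytest.raises(ValueError):
        filter_max_length(oligos, max_length=0)


def test_deduplicate_keeps_first_occurrence_and_counts():
    ref = reference(100, "ACGTACGT")
    # two different single-base deletions of the AA..-free sequence can
    # coincide only if bases repeat; construct an explicit collision
    ref2 = reference(100, "AAGT")
    d1 = assemble(ref2, deletion(100, "A"), OPTS, "s")
    d2 = assemble(ref2, deletion(101, "A"), OPTS, "s")
    other = assemble(ref, snv(102, "G", "T"), OPTS, "s")
    unique, mult = deduplicate([d1, d2, other])
    assert [o.oligo_name for o in unique] == [d1.oligo_name, other.oligo_name]
    assert mult[d1.final_sequence] == 2
    assert mult[other.final_sequence] == 1


def test_vcf_alleles_substitution_is_unanchored():
    ref = reference(100, "ACGTACGT")
    v = snv(102, "G", "T").variant
    assert vcf_alleles(v, ref) == (102, "G", "T")


def test_vcf_alleles_deletion_anchors_on_preceding_base():
    ref = reference(100, "ACGTACGT")
    v = deletion(103, "TA").variant  # deletes 103-104
    assert vcf_alleles(v, ref) == (102, "GTA", "G")


def test_vcf_alleles_insertion_anchors_on_preceding_base():
    ref = reference(100, "ACGTACGT")
    v = VariantRecord(
        source="c", position=103, ref_seq="", alt_seq="CC", type="insertion"
    )
    assert vcf_alleles(v, ref) == (102, "G", "GCC")


def test_vcf_alleles_targeton_start_uses_retrieved_preceding_base():
    ref = reference(100, "ACGTACGT", preceding="T")
    v = deletion(100, "AC").variant
    assert vcf_alleles(v, ref) == (99, "TAC", "T")


def test_vcf_alleles_contig_position_one_anchors_on_following_base():
    ref = reference(1, "ACGTACGT")
    v = deletion(1, "AC").variant  # deletes 1-2; anchor is base 3 (G)
    assert vcf_alleles(v, ref) == (1, "ACG", "G")
    ins = VariantRecord(
        source="c", position=1, ref_seq="", alt_seq="TT", type="insertion"
    )
    assert vcf_alleles(ins, ref) == (1, "A", "TTA")


def test_write_outputs_three_or_four_files(tmp_path):
    ref = reference(100, "ACGTACGT")
    oligos = [assemble(ref, snv(102, "G", "T"), OPTS, "s")]
    paths = write_outputs(tmp_path / "a", "s", oligos, [], ref)
    assert set(paths) == {"metadata", "unique", "vcf"}
    paths4 = write_outputs(tmp_path / "b", "s", oligos, oligos, ref)
    assert set(paths4) == {"metadata", "unique", "vcf", "excluded"}
    for p in paths4.values():
        assert p.exists()


def test_metadata_uses_internal_deletion_dialect(tmp_path):
    """In metadata a deletion starts at the first deleted base with an
    empty alt, while the VCF re-anchors it on the preceding base."""
    ref = reference(100, "ACGTACGT")
    oligos = [assemble(ref, deletion(103, "TA"), OPTS, "s")]
    paths = write_outputs(tmp_path, "s", oligos, [], ref)
    rows = list(csv.DictReader(paths["metadata"].open()))
    assert rows[0]["position"] == "103"
    assert rows[0]["ref"] == "TA"
    assert rows[0]["alt"] == ""
    assert list(rows[0]) == list(METADATA_COLUMNS)
    vcf_lines = [
        l for l in paths["vcf"].read_text().splitlines() if not l.startswith("#")
    ]
    chrom, pos, _, vref, valt = vcf_lines[0].split("\t")[:5]
    assert (pos, vref, valt) == ("102", "GTA", "G")


def test_full_run_vcf_is_readable_and_matches_reference(sge_run):
    """pysam parses the emitted VCFs and every REF matches the protected
    targeton sequence at its position."""
    results, _ = sge_run
    for result in results:
        with pysam.VariantFile(str(result.output_paths["vcf"])) as vcf:
            records = list(vcf)
        assert records
        rng = result.protected.range
        seen = set()
        for rec in records:
            key = (rec.pos, rec.ref, rec.alts)
            assert key not in seen  # VCF rows are unique
            seen.add(key)
            end = rec.pos + len(rec.ref) - 1
            if rec.pos >= rng.start and end <= rng.end:
                assert rec.ref == result.protected.slice(rec.pos, end)
            elif rec.pos == rng.start - 1:
                assert rec.ref[0] == result.protected.preceding_base
        assert [r.pos for r in records] == sorted(r.pos for r in records)


def test_full_run_metadata_row_count_matches_oligos(sge_run):
    results, _ = sge_run
    for result in results:
        rows = list(csv.DictReader(result.output_paths["metadata"].open()))
        assert len(rows) == len(result.oligos)
        unique_rows = list(csv.DictReader(result.output_paths["unique"].open()))
        assert len(unique_rows) == len({o.final_sequence for o in result.oligos})
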