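import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satmut.codons import ALL_CODONS, revcomp, translate
from satmut.errors import InputError
from satmut.mutators import (
    apply_variant,
    mutate_aa_scan,
    mutate_codon_scan,
    mutate_inframe,
    mutate_single_del,
    mutate_snv,
    mutate_snvre,
    mutate_tandem_del,
    run_action_vector,
)
from satmut.ranges import GenomicRange
from satmut.targeton import TargetonSpec, partition
from satmut.transcript import (
    CdsFeature,
    TranscriptAnnotation,
    build_cdna_coding_context,
    build_coding_context,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


def plus_context(record_seq, region_start, region_end, frame=0):
    region = GenomicRange("rec", region_start, region_end, "+")
    seq = record_seq[region_start - 1 : region_end]
    return build_cdna_coding_context(region, seq, frame, record_seq)


def minus_codon_context(codon_plus):
    """A minus-strand context whose middle codon is ``codon_plus``."""
    annotation = TranscriptAnnotation(
        gene_id="g",
        transcript_id="t",
        strand="-",
        cds_features=(CdsFeature(GenomicRange("c", 1, 9, "-"), 0),),
    )
    flank = "ACT"
    full = flank + codon_plus + flank
    region = GenomicRange("c", 4, 6, "-")
    return build_coding_context(
        annotation, region, codon_plus, lambda p: full[p - 1]
    )


@given(seq=dna)
@settings(max_examples=100, derandomize=True)
def test_count_laws(seq):
    """|snv| = 3L, |1del| = L, |2del0| = floor(L/2), |2del1| = floor((L-1)/2)."""
    L = len(seq)
    assert len(mutate_snv(seq, 1)) == 3 * L
    assert len(mutate_single_del(seq, 1)) == L
    assert len(mutate_tandem_del(seq, 1, 0)) == L // 2
    assert len(mutate_tandem_del(seq, 1, 1)) == max(L - 1, 0) // 2


@given(seq=st.text(alphabet="ACGT", min_size=1, max_size=40))
@settings(max_examples=60, derandomize=True)
def test_records_distinct_and_change_the_sequence(seq):
    for records in (
        mutate_snv(seq, 1),
        mutate_single_del(seq, 1),
        mutate_tandem_del(seq, 1, 0),
        mutate_tandem_del(seq, 1, 1),
    ):
        keys = {r.key() for r in records}
        assert len(keys) == len(records)
        for r in records:
            assert apply_variant(seq, 1, r) != seq


def test_snv_on_25bp_region_yields_75():
    assert len(mutate_snv("ACGTG" * 5, 101)) == 75


def test_tandem_deletions_tile_without_overlap():
    records = mutate_tandem_del("ACGTACGTA", 1, 0)  # 9 bp -> 4 pairs
    assert [r.position for r in records] == [1, 3, 5, 7]
    records1 = mutate_tandem_del("AC", 1, 1)  # no pair fits after offset
    assert records1 == []


def test_snv_annotation_through_liminal_context(tables):
    """SNVs in a partial codon are annotated via the flanking bases."""
    # record: ATG | GCT | TAA ; region covers only the last 2 bases of GCT
    ctx = plus_context("ATGGCTTAA", 5, 6, frame=1)
    records = mutate_snv(ctx.region_seq, 5, ctx, tables.snv_table)
    assert len(records) == 6
    rec = next(r for r in records if r.position == 6 and r.alt_seq == "A")
    # GCT (Ala) -> GCA (Ala): synonymous, resolved only via context
    assert (rec.ref_aa, rec.alt_aa, rec.consequence) == ("A", "A", "synonymous")


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("codon", ALL_CODONS)
def test_snvre_synonymous_closure(codon, strand, tables):
    """snv-reachable synonymous codons plus snvre extras cover every
    synonymous alternative of the wild-type codon exactly once."""
    if strand == "+":
        ctx = plus_context("ATG" + codon + "TAA", 4, 6, frame=0)
    else:
        ctx = minus_codon_context(codon)
    records = mutate_snvre(
        ctx, tables.snv_table, tables.snvre_tables, tables.freq_table
    )
    start = ctx.region.start
    snv_syn = {
        codon[: r.position - start] + r.alt_seq + codon[r.position - start + 1 :]
        for r in records
        if r.type == "snv" and r.consequence == "synonymous"
    }
    extra_syn = [
        r.alt_seq
        for r in records
        if r.type == "codon_substitution" and r.consequence == "synonymous"
    ]
    assert len(set(extra_syn)) == len(extra_syn)
    expected = {
        c for c in ALL_CODONS if c != codon and translate(c, strand) == translate(codon, strand)
    }
    assert snv_syn | set(extra_syn) == expected
    assert snv_syn.isdisjoint(extra_syn)


@pytest.mark.parametrize(
    "codon,swapped", [("TGA", "TAG"), ("TAG", "TGA")]
)
def test_snvre_stop_swap(codon, swapped, tables):
    ctx = plus_context("ATG" + codon + "TAA", 4, 6, frame=0)
    records = mutate_snvre(
        ctx, tables.snv_table, tables.snvre_tables, tables.freq_table
    )
    subs = [r for r in records if r.type == "codon_substitution"]
    assert any(r.alt_seq == swapped and r.consequence == "synonymous" for r in subs)


def test_snvre_redundant_missense_uses_top_frequency_codon(tables):
    """A missense SNV outcome gains one backup codon for the same amino
    acid, chosen as the most frequent codon of that amino acid."""
    ctx = plus_context("ATGTTTTAA", 4, 6, frame=0)  # codon TTT (Phe)
    records = mutate_snvre(
        ctx, tables.snv_table, tables.snvre_tables, tables.freq_table
    )
    leu_backups = [
        r
        for r in records
        if r.type == "codon_substitution" and r.alt_aa == "L"
    ]
    # snv reaches Leu via TTA/TTG; the backup is the top leucine codon CTG
    assert len(leu_backups) == 1
    assert leu_backups[0].alt_seq == "CTG"
    assert leu_backups[0].consequence == "missense"


def test_snvre_no_backup_for_non_degenerate_outcomes(tables):
    """Missense outcomes to Met (single-codon amino acid) get no backup."""
    # AAG -> ATG (pos 2 A->T) is the Lys->Met missense; Met has no alternative
    ctx = plus_context("ATGAAGTAA", 4, 6, frame=0)
    records = mutate_snvre(
        ctx, tables.snv_table, tables.snvre_tables, tables.freq_table
    )
    assert not any(
        r.type == "codon_substitution" and r.alt_aa == "M" for r in records
    )


def test_snvre_emits_no_codon_records_for_partial_codons(tables):
    ctx = plus_context("ATGGCTTAA", 5, 6, frame=1)  # only partial codon
    records = mutate_snvre(
        ctx, tables.snv_table, tables.snvre_tables, tables.freq_table
    )
    assert all(r.type == "snv" for r in records)


def test_inframe_deletes_each_complete_codon():
    ctx = plus_context("ATGGCTTAAACG", 4, 12, frame=0)  # 9 bp, frame 0
    assert len(mutate_inframe(ctx)) == 3
    # 8 bp with one liminal base each end -> 2 complete codons
    ctx2 = plus_context("ATGGCTTAAACGACG", 5, 12, frame=1)
    records = mutate_inframe(ctx2)
    assert len(records) == 2
    assert all(r.type == "codon_deletion" and r.alt_seq == "" for r in records)


def test_alanine_scan_skips_codons_already_top_alanine(freq_table, tables):
    ctx = plus_context("GCCGCCGCC", 1, 9, frame=0)  # top human Ala is GCC
    assert mutate_codon_scan(ctx, freq_table, "alanine") == []
    ctx2 = plus_context("GATGCCAAA", 1, 9, frame=0)
    records = mutate_codon_scan(ctx2, freq_table, "alanine")
    assert [r.ref_seq for r in records] == ["GAT", "AAA"]
    assert all(r.alt_seq == "GCC" for r in records)


def test_stop_scan_uses_top_stop_codon(freq_table):
    ctx = plus_context("AAATAAGGG", 1, 9, frame=0)
    records = mutate_codon_scan(ctx, freq_table, "stop")
    # top human stop is TGA; all three codons differ from it
    assert all(r.alt_seq == "TGA" for r in records)
    assert len(records) == 3
    ctx2 = plus_context("TGA", 1, 3, frame=0)
    assert mutate_codon_scan(ctx2, freq_table, "stop") == []


def test_codon_scan_orientation_on_minus_strand(freq_table, tables):
    """On the minus strand the replacement triplet is reverse-complemented
    into positive-strand coordinates."""
    ctx = minus_codon_context("AGC")  # reads GCT = Ala on the minus strand
    records = mutate_codon_scan(ctx, freq_table, "alanine")
    assert [r.alt_seq for r in records] == ["GGC"]  # revcomp of GCC
    ctx2 = minus_codon_context("GGC")  # already the top alanine
    assert mutate_codon_scan(ctx2, freq_table, "alanine") == []


def test_aa_scan_covers_nineteen_other_amino_acids(freq_table):
    ctx = plus_context("ATGATGTAA", 4, 6, frame=0)  # codon ATG (Met)
    records = mutate_aa_scan(ctx, freq_table)
    assert len(records) == 19
    assert all(r.alt_aa not in ("M", "*") for r in records)
    assert len({r.alt_aa for r in records}) == 19
    assert all(r.consequence == "missense" for r in records)


def test_aa_scan_larger_region(freq_table):
    # 18 complete codons -> 18 * 19 records (no codon equals a target top codon
    # of a different amino acid by construction of substitution targets)
    ctx = plus_context("ATG" + "GAT" * 18 + "TAA", 4, 57, frame=0)
    assert len(mutate_aa_scan(ctx, freq_table)) == 18 * 19


def test_action_vector_rejects_cds_mutator_on_noncoding_region(tables):
    spec = TargetonSpec(
        ref_range=GenomicRange("c", 1, 30, "+"),
        r2_range=GenomicRange("c", 11, 20, "+"),
        ext_vector=(5, 5),
        action_vector=((), ("ala",), ()),
    )
    part = partition(spec)
    with pytest.raises(InputError, match="coding"):
        run_action_vector(
            part,
            spec.action_vector,
            {"r1": "A" * 5, "r2": "A" * 10, "r3": "A" * 5},
            {"r1": False, "r2": False, "r3": False},
            {"r1": None, "r2": None, "r3": None},
            tables,
        )


def test_empty_action_vector_yields_no_records(tables):
    spec = TargetonSpec(
        ref_range=GenomicRange("c", 1, 30, "+"),
        r2_range=GenomicRange("c", 11, 20, "+"),
        ext_vector=(5, 5),
        action_vector=((), (), ()),
    )
    part = partition(spec)
    out = run_action_vector(
        part,
        spec.action_vector,
        {"r1": "A" * 5, "r2": "A" * 10, "r3": "A" * 5},
        {"r1": False, "r2": False, "r3": False},
        {"r1": None, "r2": None, "r3": None},
        tables,
    )
    assert out == []
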