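"""Systematic mutator functions over targeton regions.

Eight mutators are provided. The basic ones ignore reading frame and act
on any region: ``snv`` (every substitution at every position), ``1del``
(every single-base deletion), ``2del0``/``2del1`` (non-overlapping tandem
dinucleotide deletions phased at offset 0 or 1). The CDS-specific ones
need a :class:`~satmut.transcript.CodingContext`: ``snvre`` (snv plus
synonymous-set completion and redundant-codon missense backups),
``inframe`` (codon deletions), ``ala``/``stop`` (codon scans to the
top-ranking alanine/stop codon) and ``aa`` (substitution to the most
frequent codon of every other amino acid).

Codon-level substitutions and deletions act only on complete codons;
partial (liminal) codons at region or exon boundaries still receive SNVs,
annotated using the adjacent exonic context, but are never replaced.

All records are expressed on the positive strand. Deletions report the
deleted bases with an empty alternative and insertions the inserted bases
with an empty reference, starting at the first affected position (the
metadata convention); the output VCF re-anchors them per VCF 4.2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .codons import (
    BASES,
    MISSENSE,
    STOP,
    CodonFrequencyTable,
    SnvAnnotationTable,
    SynonymousSubstitutionTable,
    build_snv_annotation_table,
    build_snvre_tables,
    classify,
    revcomp,
    translate,
)
from .errors import InputError
from .ranges import MINUS, GenomicRange
from .targeton import BASIC_MUTATORS, CDS_MUTATORS, RegionPartition
from .transcript import Codon, CodingContext

SNV = "snv"
DELETION = "deletion"
INSERTION = "insertion"
INDEL = "indel"
CODON_SUBSTITUTION = "codon_substitution"
CODON_DELETION = "codon_deletion"


@dataclass(frozen=True)
class VariantRecord:
    """One mutation event on the positive strand.

    ``position`` is the 1-based first affected position (for insertions,
    the position the inserted bases will occupy). ``ref_seq`` is empty for
    insertions and ``alt_seq`` empty for deletions.
    """

    source: str
    position: int
    ref_seq: str
    alt_seq: str
    type: str
    variant_id: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    consequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_seq == self.alt_seq:
            raise ValueError("variant must change the sequence")

    @property
    def end(self) -> int:
        """Last reference position affected (== position - 1 for insertions)."""
        return self.position + len(self.ref_seq) - 1

    def key(self) -> Tuple[int, str, str]:
        return (self.position, self.ref_seq, self.alt_seq)


def apply_variant(sequence: str, seq_start: int, variant: VariantRecord) -> str:
    """Apply a variant to a sequence beginning at 1-based ``seq_start``."""
    off = variant.position - seq_start
    if off < 0 or off > len(sequence):
        raise ValueError(
            f"variant at {variant.position} outside sequence starting at "
            f"{seq_start}"
        )
    found = sequence[off : off + len(variant.ref_seq)]
    if found != variant.ref_seq:
        raise ValueError(
            f"reference mismatch at {variant.position}: expected "
            f"{variant.ref_seq!r}, found {found!r}"
        )
    return sequence[:off] + variant.alt_seq + sequence[off + len(variant.ref_seq) :]


def _check_bases(sequence: str) -> None:
    bad = set(sequence) - set(BASES)
    if bad:
        raise InputError(
            f"region contains bases outside ACGT: {sorted(bad)!r}; "
            "mutating unknown bases is undefined"
        )


def mutate_snv(
    region_sequence: str,
    region_start: int,
    context: Optional[CodingContext] = None,
    snv_table: Optional[SnvAnnotationTable] = None,
) -> List[VariantRecord]:
    """All 3L single-nucleotide substitutions over an L-base region.

    With a coding context and SNV annotation table, each record carries
    its amino-acid change and consequence class; liminal codons are
    annotated through the flanking exonic context bases.
    """
    _check_bases(region_sequence)
    records: List[VariantRecord] = []
    for i, ref_base in enumerate(region_sequence):
        position = region_start + i
        for alt_base in BASES:
            if alt_base == ref_base:
                continue
            ref_aa = alt_aa = consequence = None
            if context is not None and snv_table is not None:
                codon, offset = context.codon_at(position)
                ann = snv_table.lookup(
                    context.strand, codon.bases, offset, alt_base
                )
                ref_aa, alt_aa = ann.ref_aa, ann.alt_aa
                consequence = ann.consequence
            records.append(
                VariantRecord(
                    source=SNV,
                    position=position,
                    ref_seq=ref_base,
                    alt_seq=alt_base,
                    type=SNV,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    consequence=consequence,
                )
            )
    return records


def mutate_single_del(region_sequence: str, region_start: int) -> List[VariantRecord]:
    """Delete each single base of the region in turn (L records)."""
    return [
        VariantRecord(
            source="1del",
            position=region_start + i,
            ref_seq=base,
            alt_seq="",
            type=DELETION,
        )
        for i, base in enumerate(region_sequence)
    ]


def mutate_tandem_del(
    region_sequence: str, region_start: int, offset: int
) -> List[VariantRecord]:
    """Non-overlapping tandem dinucleotide deletions phased at ``offset``.

    Pairs start at the offset and tile the region; a trailing unpaired
    base is ignored. Yields floor((L - offset) / 2) records.
    """
    if offset not in (0, 1):
        raise ValueError("tandem deletion offset must be 0 or 1")
    records: List[VariantRecord] = []
    i = offset
    while i + 2 <= len(region_sequence):
        records.append(
            VariantRecord(
                source=f"2del{offset}",
                position=region_start + i,
                ref_seq=region_sequence[i : i + 2],
                alt_seq="",
                type=DELETION,
            )
        )
        i += 2
    return records


def _oriented(codon_plus: str, strand: str) -> str:
    return revcomp(codon_plus) if strand == MINUS else codon_plus


def _codon_substitution(
    source: str,
    codon: Codon,
    alt_plus: str,
    strand: str,
) -> VariantRecord:
    ref_aa = translate(codon.bases, strand)
    alt_aa = translate(alt_plus, strand)
    return VariantRecord(
        source=source,
        position=codon.positions[0],
        ref_seq=codon.bases,
        alt_seq=alt_plus,
        type=CODON_SUBSTITUTION,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=classify(ref_aa, alt_aa),
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def mutate_snvre(
    context: CodingContext,
    snv_table: SnvAnnotationTable,
    snvre_tables: SynonymousSubstitutionTable,
    freq_table: CodonFrequencyTable,
) -> List[VariantRecord]:
    """The snvre mutator: snv plus codon-level synonymous and redundant records.

    Beyond the full annotated SNV set, for every complete codon it (a)
    completes the synonymous codon set with the alternatives not reachable
    by a single substitution (6-fold degenerate codons and the TGA<->TAG
    stop swap), and (b) for each missense amino acid reached by an SNV,
    adds one redundant codon encoding the same amino acid via the most
    frequent codon of that amino acid (or the next most frequent when the
    SNV itself produced the most frequent). No codon-level record is
    emitted for partial (liminal) codons.
    """
    strand = context.strand
    # the snv portion keeps its own source tag: library composition
    # reports single-nucleotide records under "snv" and only the
    # codon-level extras under "snvre"
    records = mutate_snv(
        context.region_seq, context.region.start, context, snv_table
    )
    for codon in context.complete_codons():
        if codon.bases != codon.bases.upper() or set(codon.bases) - set(BASES):
            raise InputError(f"invalid codon bases {codon.bases!r}")
        reachable = {
            rec.alt_codon
            for rec in snv_table.for_codon(strand, codon.bases)
        }
        # (a) synonymous completion
        synonymous = snvre_tables.synonymous(strand, codon.bases)
        for alt_plus in sorted(synonymous - reachable):
            records.append(
                _codon_substitution("snvre", codon, alt_plus, strand)
            )
        # (b) redundant codons for missense SNV outcomes
        emitted: set = set()
        for rec in snv_table.for_codon(strand, codon.bases):
            if rec.consequence != MISSENSE:
                continue
            ranked = freq_table.codons_for(rec.alt_aa)
            snv_codon_oriented = _oriented(rec.alt_codon, strand)
            candidate = None
            for cand in ranked:
                if cand != snv_codon_oriented:
                    candidate = cand
                    break
            if candidate is None:
                continue  # non-degenerate amino acid already made by snv
            cand_plus = _oriented(candidate, strand)
            if _hamming(cand_plus, codon.bases) == 1:
                continue  # snv alone already yields this codon
            key = (codon.positions[0], cand_plus)
            if key in emitted:
                continue
            emitted.add(key)
            records.append(
                _codon_substitution("snvre", codon, cand_plus, strand)
            )
    return records


def mutate_inframe(context: CodingContext) -> List[VariantRecord]:
    """Delete each complete codon in turn; partial codons are never deleted."""
    records: List[VariantRecord] = []
    for codon in context.complete_codons():
        ref_aa = translate(codon.bases, context.strand)
        records.append(
            VariantRecord(
                source="inframe",
                position=codon.positions[0],
                ref_seq=codon.bases,
                alt_seq="",
                type=CODON_DELETION,
                ref_aa=ref_aa,
            )
        )
    return records


_SCAN_TARGETS = {"alanine": "A", "stop": STOP}


def mutate_codon_scan(
    context: CodingContext,
    freq_table: CodonFrequencyTable,
    target: str,
) -> List[VariantRecord]:
    """Replace every complete codon with the top-ranking codon of ``target``.

    ``target`` is ``"alanine"`` or ``"stop"``. A codon already equal to
    the top-ranking target codon is skipped: the product would be the
    wild-type sequence, not a variant.
    """
    try:
        target_aa = _SCAN_TARGETS[target]
    except KeyError:
        raise ValueError(
            f"scan target must be one of {sorted(_SCAN_TARGETS)}, got {target!r}"
        ) from None
    source = "ala" if target == "alanine" else "stop"
    top_oriented = freq_table.top_codon(target_aa)
    top_plus = _oriented(top_oriented, context.strand)
    records: List[VariantRecord] = []
    for codon in context.complete_codons():
        if codon.bases == top_plus:
            continue
        records.append(
            _codon_substitution(source, codon, top_plus, context.strand)
        )
    return records


def mutate_aa_scan(
    context: CodingContext, freq_table: CodonFrequencyTable
) -> List[VariantRecord]:
    """Exchange each complete codon for the top codon of every other amino acid.

    Stop is excluded as a target (the ``stop`` mutator covers it), giving
    19 substitutions per codon under the standard code.
    """
    records: List[VariantRecord] = []
    amino_acids = [aa for aa in freq_table.amino_acids if aa != STOP]
    for codon in context.complete_codons():
        ref_aa = translate(codon.bases, context.strand)
        for aa in amino_acids:
            if aa == ref_aa:
                continue
            alt_plus = _oriented(freq_table.top_codon(aa), context.strand)
            if alt_plus == codon.bases:
                continue
            records.append(
                _codon_substitution("aa", codon, alt_plus, context.strand)
            )
    return records


@dataclass(frozen=True)
class MutatorTables:
    """The precomputed tables shared by all codon-aware mutators."""

    freq_table: CodonFrequencyTable
    snv_table: SnvAnnotationTable
    snvre_tables: SynonymousSubstitutionTable


def build_tables(
    freq_table: CodonFrequencyTable, strands: Sequence[str]
) -> MutatorTables:
    """Precompute the SNV annotation and synonymous tables for a run."""
    return MutatorTables(
        freq_table=freq_table,
        snv_table=build_snv_annotation_table(strands),
        snvre_tables=build_snvre_tables(freq_table, strands),
    )


@dataclass(frozen=True)
class RegionVariant:
    """A variant tagged with the region and mutator that produced it."""

    region: str
    mutator: str
    variant: VariantRecord


def run_mutator(
    name: str,
    region_seq: str,
    region_start: int,
    coding: bool,
    context: Optional[CodingContext],
    tables: MutatorTables,
) -> List[VariantRecord]:
    """Dispatch one mutator over one region."""
    if name in CDS_MUTATORS:
        if not coding or context is None:
            raise InputError(
                f"mutator {name!r} requires a coding region with transcript "
                "annotation"
            )
    if name == "snv":
        return mutate_snv(
            region_seq,
            region_start,
            context if coding else None,
            tables.snv_table if coding else None,
        )
    if name == "1del":
        return mutate_single_del(region_seq, region_start)
    if name == "2del0":
        return mutate_tandem_del(region_seq, region_start, 0)
    if name == "2del1":
        return mutate_tandem_del(region_seq, region_start, 1)
    if name == "snvre":
        return mutate_snvre(
            context, tables.snv_table, tables.snvre_tables, tables.freq_table
        )
    if name == "inframe":
        return mutate_inframe(context)
    if name == "ala":
        return mutate_codon_scan(context, tables.freq_table, "alanine")
    if name == "stop":
        return mutate_codon_scan(context, tables.freq_table, "stop")
    if name == "aa":
        return mutate_aa_scan(context, tables.freq_table)
    raise InputError(f"unknown mutator {name!r}")


def run_action_vector(
    part: RegionPartition,
    action_vector: Sequence[Sequence[str]],
    sequences: Dict[str, str],
    coding_flags: Dict[str, bool],
    contexts: Dict[str, Optional[CodingContext]],
    tables: MutatorTables,
) -> List[RegionVariant]:
    """Run each region's mutator list and concatenate the tagged records.

    The constant regions receive no mutators. Within a region, mutator
    order follows the action vector and records keep each mutator's
    deterministic internal order.
    """
    out: List[RegionVariant] = []
    region_names = ("r1", "r2", "r3")
    for name, mutator_list in zip(region_names, action_vector):
        rng = part.mutable_regions().get(name)
        if rng is None:
            if mutator_list:
                raise InputError(
                    f"mutators {list(mutator_list)} assigned to empty "
                    f"region {name}"
                )
            continue
        seq = sequences[name]
        coding = coding_flags.get(name, False)
        context = contexts.get(name)
        for mutator in mutator_list:
            for record in run_mutator(
                mutator, seq, rng.start, coding, context, tables
            ):
                out.append(RegionVariant(name, mutator, record))
    return out
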