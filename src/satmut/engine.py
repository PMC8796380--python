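"""End-to-end library generation for genomic (SGE / prime-editing) runs.

For each targeton: retrieve the reference sequence, apply its sgRNAs'
protection edits, partition into c1-r1-r2-r3-c2, resolve reading frames
for coding regions, run the per-region mutator lists on the protected
sequence, ingest custom variants over the whole targeton (constant
regions included), assemble and length-filter the oligos, and write the
per-targeton output files plus the execution-wide QC report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .assembly import (
    AssemblyOptions,
    OligoRecord,
    assemble_all,
    filter_max_length,
    write_outputs,
)
from .codons import CodonFrequencyTable, load_codon_table
from .errors import InputError
from .mutators import (
    MutatorTables,
    RegionVariant,
    build_tables,
    run_action_vector,
)
from .ranges import GenomicRange
from .reference import ReferenceReader, ReferenceSequence, write_qc_report
from .targeton import (
    CDS_MUTATORS,
    RegionPartition,
    TargetonSpec,
    parse_targeton_file,
    partition,
    targeton_file_stem,
    validate_region_homogeneity,
)
from .transcript import (
    CodingContext,
    TranscriptAnnotation,
    build_coding_context,
    load_annotation,
)
from .variant_sources import (
    CustomVariantSource,
    ProtectionEdit,
    apply_protection,
    load_custom_variants,
    load_protection_edits,
    parse_manifest,
)

logger = logging.getLogger(__name__)


@dataclass
class SgeConfig:
    """Inputs and options for one genomic run."""

    targeton_file: str
    fasta: str
    gtf: Optional[str] = None
    protection_vcf: Optional[str] = None
    manifest: Optional[str] = None
    codon_table: Optional[str] = None
    adapter_5: str = ""
    adapter_3: str = ""
    max_length: int = 300
    revcomp_minus_strand: bool = False
    out_dir: str = "."


@dataclass
class TargetonResult:
    """All records produced for one targeton."""

    spec: TargetonSpec
    stem: str
    wildtype: ReferenceSequence
    protected: ReferenceSequence
    oligos: List[OligoRecord]
    excluded: List[OligoRecord]
    output_paths: Dict[str, Path] = field(default_factory=dict)


def _select_transcript(
    annotations: Dict[str, TranscriptAnnotation],
    region: GenomicRange,
) -> TranscriptAnnotation:
    matches = [
        a
        for a in annotations.values()
        if all(a.is_coding_position(p) for p in region.positions())
    ]
    if not matches:
        raise InputError(
            f"no transcript covers coding region "
            f"{region.chromosome}:{region.start}-{region.end}"
        )
    if len(matches) > 1:
        raise InputError(
            f"region {region.chromosome}:{region.start}-{region.end} is "
            "covered by more than one transcript"
        )
    return matches[0]


def process_targeton(
    spec: TargetonSpec,
    reader: ReferenceReader,
    annotations: Dict[str, TranscriptAnnotation],
    protection: Dict[str, List[ProtectionEdit]],
    custom_sources: Sequence[CustomVariantSource],
    tables: MutatorTables,
    options: AssemblyOptions,
) -> TargetonResult:
    """Generate all oligos for one targeton (no files written)."""
    stem = targeton_file_stem(spec)
    wildtype = reader.fetch_range(spec.ref_range)

    edits: List[ProtectionEdit] = []
    for sgrna_id in spec.sgrna_ids:
        if sgrna_id not in protection:
            raise InputError(
                f"targeton {stem}: sgRNA id {sgrna_id!r} has no protection "
                "edits in the protection VCF"
            )
        edits.extend(protection[sgrna_id])
    protected = apply_protection(wildtype, edits)

    part = partition(spec)
    flags = validate_region_homogeneity(part, annotations)

    requested_cds = any(
        m in CDS_MUTATORS
        for region_mutators in spec.action_vector
        for m in region_mutators
    )
    if requested_cds and not annotations:
        raise InputError(
            f"targeton {stem}: CDS mutators requested but no transcript "
            "annotation was provided"
        )

    protected_by_pos = {
        e.position: e.alt_base for e in edits
    }

    def base_lookup(position: int) -> str:
        """Positive-strand base outside the region, protection applied."""
        if position in protected_by_pos:
            return protected_by_pos[position]
        if protected.range.contains(position):
            return protected.base_at(position)
        return reader.fetch_base(spec.ref_range.chromosome, position)

    sequences: Dict[str, str] = {}
    contexts: Dict[str, Optional[CodingContext]] = {}
    for name, rng in part.mutable_regions().items():
        if rng is None:
            continue
        seq = protected.slice(rng.start, rng.end)
        region_index = ("r1", "r2", "r3").index(name)
        if spec.action_vector[region_index] and set(seq) - set("ACGT"):
            raise InputError(
                f"targeton {stem}: region {name} contains non-ACGT bases; "
                "mutating unknown bases is undefined"
            )
        sequences[name] = seq
        if flags.get(name):
            transcript = _select_transcript(annotations, rng)
            if transcript.strand != spec.strand:
                raise InputError(
                    f"targeton {stem}: strand {spec.strand!r} does not match "
                    f"transcript {transcript.transcript_id} strand "
                    f"{transcript.strand!r}"
                )
            contexts[name] = build_coding_context(
                transcript, rng, seq, base_lookup
            )
        else:
            contexts[name] = None

    tagged: List[RegionVariant] = run_action_vector(
        part, spec.action_vector, sequences, flags, contexts, tables
    )

    # Custom variants describe the genome, so their REF is checked against
    # the original reference; application happens on top of the protected
    # sequence (rewriting REF where a protection edit falls inside it).
    for source in custom_sources:
        for variant in load_custom_variants(source, spec.ref_range):
            if variant.ref_seq:
                original = wildtype.slice(variant.position, variant.end)
                if original != variant.ref_seq:
                    raise InputError(
                        f"custom variant {source.alias}:"
                        f"{variant.variant_id or variant.position}: REF "
                        f"{variant.ref_seq!r} does not match reference "
                        f"{original!r}"
                    )
                protected_ref = protected.slice(variant.position, variant.end)
                if protected_ref != variant.ref_seq:
                    logger.warning(
                        "custom variant at %d overlaps a protection edit; "
                        "applied on top of the protected sequence",
                        variant.position,
                    )
                    if protected_ref == variant.alt_seq:
                        logger.warning(
                            "custom variant at %d is a no-op on the "
                            "protected sequence; skipped",
                            variant.position,
                        )
                        continue
                    variant = replace(variant, ref_seq=protected_ref)
            region_name = part.region_of(variant.position) or "c1"
            tagged.append(RegionVariant(region_name, source.alias, variant))

    oligos = assemble_all(protected, tagged, options, stem, src_type="ref")
    kept, excluded = filter_max_length(oligos, options.max_length)
    return TargetonResult(
        spec=spec,
        stem=stem,
        wildtype=wildtype,
        protected=protected,
        oligos=kept,
        excluded=excluded,
    )


def run_sge(config: SgeConfig) -> List[TargetonResult]:
    """Run a full genomic library generation and write all output files."""
    specs = parse_targeton_file(config.targeton_file)
    annotations = (
        load_annotation(config.gtf) if config.gtf is not None else {}
    )
    protection = (
        load_protection_edits(config.protection_vcf)
        if config.protection_vcf is not None
        else {}
    )
    custom_sources = (
        parse_manifest(config.manifest) if config.manifest is not None else []
    )
    freq_table = load_codon_table(config.codon_table)
    strands = sorted({spec.strand for spec in specs}) or ["+"]
    tables = build_tables(freq_table, strands)
    options = AssemblyOptions(
        adapter_5=config.adapter_5.upper(),
        adapter_3=config.adapter_3.upper(),
        max_length=config.max_length,
        revcomp_minus_strand=config.revcomp_minus_strand,
    )

    results: List[TargetonResult] = []
    with ReferenceReader(config.fasta) as reader:
        for spec in specs:
            result = process_targeton(
                spec,
                reader,
                annotations,
                protection,
                custom_sources,
                tables,
                options,
            )
            result.output_paths = write_outputs(
                config.out_dir,
                result.stem,
                result.oligos,
                result.excluded,
                result.protected,
                contig_length=reader.contig_length(
                    spec.ref_range.chromosome
                ),
            )
            results.append(result)

    qc_path = Path(config.out_dir) / "sequences_qc.csv"
    write_qc_report(
        qc_path,
        [r.stem for r in results],
        [r.wildtype.bases for r in results],
    )
    return results
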