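"""Oligo assembly, length filtering, deduplication and output files.

Each variant is applied to the PAM/protospacer-protected positive-strand
targeton sequence. For minus-strand targetons the mutated targeton
portion can optionally be reverse-complemented; adapters are appended
last and are never reverse-complemented. Oligos exceeding the maximum
synthesis length are segregated into an excluded-metadata file, and the
unique file lists each distinct final sequence once (the library
complexity relevant to synthesis).

Output per targeton: a metadata CSV of all records, a unique-sequence
CSV, a VCF 4.2 of all generated variants (standard anchoring, using the
retrieved preceding base for events at the targeton start) and, when
non-empty, an excluded CSV. A single execution-wide QC file reports the
retrieved wild-type sequences.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .codons import revcomp
from .errors import InputError
from .mutators import RegionVariant, VariantRecord, apply_variant
from .ranges import MINUS
from .reference import ReferenceSequence

logger = logging.getLogger(__name__)

DEFAULT_MAX_LENGTH = 300

METADATA_COLUMNS = (
    "oligo_name",
    "src_type",
    "region",
    "source",
    "variant_id",
    "var_type",
    "position",
    "ref",
    "alt",
    "ref_aa",
    "alt_aa",
    "consequence",
    "revcomp",
    "sequence",
    "length",
)


@dataclass(frozen=True)
class OligoRecord:
    """One assembled oligo with its full metadata row."""

    oligo_name: str
    stem: str
    src_type: str  # "ref" (genomic) or "cdna"
    region: str
    source: str  # mutator name or custom-variant alias
    variant: VariantRecord
    mutated_seq: str  # mutated targeton, positive strand, no adapters
    final_sequence: str  # after optional revcomp and adapters
    revcomp_applied: bool

    @property
    def length(self) -> int:
        return len(self.final_sequence)


@dataclass(frozen=True)
class AssemblyOptions:
    adapter_5: str = ""
    adapter_3: str = ""
    max_length: int = DEFAULT_MAX_LENGTH
    revcomp_minus_strand: bool = False


def assemble(
    protected_reference: ReferenceSequence,
    tagged: RegionVariant,
    options: AssemblyOptions,
    stem: str,
    src_type: str = "ref",
    name_suffix: str = "",
) -> OligoRecord:
    """Apply one variant to the protected reference and build the oligo.

    The mutated targeton is built on the positive strand; when the
    targeton is on the minus strand and the reverse-complement option is
    set, the targeton portion (never the adapters) is reverse-complemented
    before the adapters are appended.
    """
    variant = tagged.variant
    rng = protected_reference.range
    mutated = apply_variant(protected_reference.bases, rng.start, variant)
    do_revcomp = options.revcomp_minus_strand and rng.strand == MINUS
    body = revcomp(mutated) if do_revcomp else mutated
    final = options.adapter_5 + body + options.adapter_3
    name = (
        f"{stem}_{tagged.region}_{tagged.mutator}_{variant.position}_"
        f"{variant.type}{name_suffix}"
    )
    return OligoRecord(
        oligo_name=name,
        stem=stem,
        src_type=src_type,
        region=tagged.region,
        source=tagged.variant.source,
        variant=variant,
        mutated_seq=mutated,
        final_sequence=final,
        revcomp_applied=do_revcomp,
    )


def assemble_all(
    protected_reference: ReferenceSequence,
    tagged_variants: Sequence[RegionVariant],
    options: AssemblyOptions,
    stem: str,
    src_type: str = "ref",
) -> List[OligoRecord]:
    """Assemble every variant, ensuring unique oligo names within the run."""
    counts: Dict[str, int] = {}
    oligos: List[OligoRecord] = []
    for tagged in tagged_variants:
        base = (
            f"{tagged.region}_{tagged.mutator}_{tagged.variant.position}_"
            f"{tagged.variant.type}"
        )
        n = counts.get(base, 0)
        counts[base] = n + 1
        suffix = "" if n == 0 else f"_{n}"
        oligos.append(
            assemble(
                protected_reference,
                tagged,
                options,
                stem,
                src_type=src_type,
                name_suffix=suffix,
            )
        )
    return oligos


def filter_max_length(
    oligos: Sequence[OligoRecord], max_length: int = DEFAULT_MAX_LENGTH
) -> Tuple[List[OligoRecord], List[OligoRecord]]:
    """Split oligos into (kept, excluded) by strict length cut-off.

    Oligos strictly longer than ``max_length`` are excluded from the
    standard outputs (their metadata is preserved separately) with a
    warning.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    kept: List[OligoRecord] = []
    excluded: List[OligoRecord] = []
    for oligo in oligos:
        if oligo.length > max_length:
            logger.warning(
                "oligo %s length %d exceeds max length %d; excluded",
                oligo.oligo_name,
                oligo.length,
                max_length,
            )
            excluded.append(oligo)
        else:
            kept.append(oligo)
    return kept, excluded


def deduplicate(
    kept_oligos: Sequence[OligoRecord],
) -> Tuple[List[OligoRecord], Dict[str, int]]:
    """Unique final sequences (first occurrence) plus per-sequence multiplicity."""
    first: Dict[str, OligoRecord] = {}
    multiplicity: Dict[str, int] = {}
    for oligo in kept_oligos:
        multiplicity[oligo.final_sequence] = (
            multiplicity.get(oligo.final_sequence, 0) + 1
        )
        first.setdefault(oligo.final_sequence, oligo)
    return list(first.values()), multiplicity


def _metadata_row(oligo: OligoRecord) -> List[str]:
    v = oligo.variant
    return [
        oligo.oligo_name,
        oligo.src_type,
        oligo.region,
        oligo.source,
        v.variant_id or "",
        v.type,
        str(v.position),
        v.ref_seq,
        v.alt_seq,
        v.ref_aa or "",
        v.alt_aa or "",
        v.consequence or "",
        "1" if oligo.revcomp_applied else "0",
        oligo.final_sequence,
        str(oligo.length),
    ]


def _write_metadata_csv(path: Path, oligos: Sequence[OligoRecord]) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(METADATA_COLUMNS)
        for oligo in oligos:
            writer.writerow(_metadata_row(oligo))


def vcf_alleles(
    variant: VariantRecord, protected_reference: ReferenceSequence
) -> Tuple[int, str, str]:
    """Re-anchor an internal variant to VCF 4.2 (POS, REF, ALT).

    Deletions and insertions are anchored on the base preceding the
    event; at the start of the targeton the retrieved preceding base
    serves as the anchor, and at position one of a contig the following
    base is used instead, per VCF convention.
    """
    if variant.ref_seq and variant.alt_seq:
        return variant.position, variant.ref_seq, variant.alt_seq
    rng = protected_reference.range
    pos = variant.position
    if pos > 1:
        anchor_pos = pos - 1
        if rng.contains(anchor_pos):
            anchor = protected_reference.base_at(anchor_pos)
        elif anchor_pos == rng.start - 1:
            if protected_reference.preceding_base is None:
                raise InputError(
                    "no preceding base available to anchor a liminal variant"
                )
            anchor = protected_reference.preceding_base
        else:
            raise InputError(
                f"cannot anchor variant at {pos}: position {anchor_pos} "
                "not retrieved"
            )
        if variant.alt_seq == "":  # deletion
            return anchor_pos, anchor + variant.ref_seq, anchor
        return anchor_pos, anchor, anchor + variant.alt_seq  # insertion
    # event at contig position 1: anchor on the following base
    if variant.alt_seq == "":
        following_pos = variant.end + 1
        following = protected_reference.base_at(following_pos)
        return 1, variant.ref_seq + following, following
    following = protected_reference.base_at(1)
    return 1, following, variant.alt_seq + following


def _write_vcf(
    path: Path,
    oligos: Sequence[OligoRecord],
    protected_reference: ReferenceSequence,
    contig_length: Optional[int] = None,
) -> None:
    chrom = protected_reference.range.chromosome
    lines = [
        "##fileformat=VCFv4.2",
        "##source=satmut",
        (
            f"##contig=<ID={chrom},length={contig_length}>"
            if contig_length
            else f"##contig=<ID={chrom}>"
        ),
        '##INFO=<ID=SOURCE,Number=1,Type=String,Description='
        '"Mutator or custom variant source">',
        '##INFO=<ID=OLIGO,Number=1,Type=String,Description="Oligo name">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    seen: set = set()
    rows: List[Tuple[int, str, str, str, str]] = []
    for oligo in oligos:
        pos, ref, alt = vcf_alleles(oligo.variant, protected_reference)
        key = (pos, ref, alt)
        if key in seen:
            continue
        seen.add(key)
        variant_id = oligo.variant.variant_id or "."
        rows.append(
            (
                pos,
                variant_id,
                ref,
                alt,
                f"SOURCE={oligo.source};OLIGO={oligo.oligo_name}",
            )
        )
    rows.sort(key=lambda r: (r[0], r[2], r[3]))
    for pos, vid, ref, alt, info in rows:
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t{info}")
    path.write_text("\n".join(lines) + "\n")


def write_outputs(
    out_dir: str | Path,
    stem: str,
    oligos: Sequence[OligoRecord],
    excluded: Sequence[OligoRecord],
    protected_reference: ReferenceSequence,
    contig_length: Optional[int] = None,
) -> Dict[str, Path]:
    """Write the per-targeton output files; returns their paths by kind.

    The excluded file is only produced when there are excluded records,
    so three or four files result per targeton.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    meta_path = out_dir / f"{stem}_meta.csv"
    _write_metadata_csv(meta_path, oligos)
    paths["metadata"] = meta_path

    unique, _ = deduplicate(oligos)
    unique_path = out_dir / f"{stem}_unique.csv"
    with open(unique_path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["oligo_name", "sequence"])
        for oligo in unique:
            writer.writerow([oligo.oligo_name, oligo.final_sequence])
    paths["unique"] = unique_path

    vcf_path = out_dir / f"{stem}.vcf"
    _write_vcf(
        vcf_path,
        list(oligos) + list(excluded),
        protected_reference,
        contig_length,
    )
    paths["vcf"] = vcf_path

    if excluded:
        excluded_path = out_dir / f"{stem}_excluded.csv"
        _write_metadata_csv(excluded_path, excluded)
        paths["excluded"] = excluded_path
    return paths
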