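"""Custom variant ingestion and PAM/protospacer protection edits.

Custom variants come from VCF files listed in a CSV manifest; each file
gets an alias preserving provenance, and identifiers are read from the
VCF ID field or, optionally, a named INFO tag (e.g. ``ALLELEID`` for
ClinVar). Only simple variants (substitutions, insertions, deletions,
indels) are supported; symbolic or structural alternates are skipped with
a warning. Variants must start and end within the targeton to be applied,
and they are applied everywhere in it, including the constant regions.

Protection edits are single-nucleotide substitutions grouped by an SGRNA
INFO tag. All edits for the sgRNAs named on a targeton are applied to its
retrieved reference, and the protected sequence is the basis for every
subsequent mutation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .errors import InputError
from .mutators import DELETION, INDEL, INSERTION, SNV, VariantRecord
from .ranges import GenomicRange
from .reference import ReferenceSequence

logger = logging.getLogger(__name__)

_SIMPLE_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class CustomVariantSource:
    """One VCF file of custom variants with its provenance alias."""

    alias: str
    vcf_path: str
    id_info_tag: Optional[str] = None  # None: use the VCF ID field


@dataclass(frozen=True)
class ProtectionEdit:
    """A single-nucleotide protection substitution tied to one sgRNA."""

    sgrna_id: str
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if len(self.ref_base) != 1 or len(self.alt_base) != 1:
            raise InputError(
                "protection edits must be single-nucleotide substitutions"
            )


def parse_manifest(csv_source: str | Path) -> List[CustomVariantSource]:
    """Parse the custom-variant manifest (columns: alias, vcf_path[, id_info_tag])."""
    sources: List[CustomVariantSource] = []
    seen: set = set()
    base_dir = Path(csv_source).parent
    with open(csv_source, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            return sources
        required = {"alias", "vcf_path"}
        if not required.issubset(reader.fieldnames):
            raise InputError(
                f"manifest {csv_source} must have columns {sorted(required)}"
            )
        for i, row in enumerate(reader, start=2):
            alias = row["alias"].strip()
            if not alias:
                raise InputError(f"manifest row {i}: empty alias")
            if alias in seen:
                raise InputError(f"manifest row {i}: duplicate alias {alias!r}")
            seen.add(alias)
            path = Path(row["vcf_path"].strip())
            if not path.is_absolute():
                path = base_dir / path
            if not path.exists():
                raise InputError(
                    f"manifest row {i}: VCF {path} does not exist"
                )
            tag = (row.get("id_info_tag") or "").strip() or None
            sources.append(CustomVariantSource(alias, str(path), tag))
    return sources


def _classify_allele(pos: int, ref: str, alt: str) -> Tuple[int, str, str, str]:
    """Normalize a VCF allele pair to the internal (position, ref, alt, type).

    VCF anchors indels on a shared leading base; internally deletions
    start at the first deleted position with an empty alternative, and
    insertions at the position the inserted bases will occupy with an
    empty reference.
    """
    if len(ref) == len(alt) == 1:
        return pos, ref, alt, SNV
    if len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0]:
        # anchored: strip the shared leading base
        ref_, alt_ = ref[1:], alt[1:]
        if not alt_:
            return pos + 1, ref_, "", DELETION
        if not ref_:
            return pos + 1, "", alt_, INSERTION
        return pos + 1, ref_, alt_, INDEL
    if len(ref) == len(alt):
        return pos, ref, alt, INDEL
    return pos, ref, alt, INDEL


def load_custom_variants(
    source: CustomVariantSource, targeton_range: GenomicRange
) -> List[VariantRecord]:
    """Custom variants of one source falling fully inside the targeton.

    Multi-allelic records are split into one event per alternate allele;
    symbolic or structural alternates are skipped with a warning, as are
    variants overlapping a targeton boundary.
    """
    records: List[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(source.vcf_path)
    except (OSError, ValueError) as exc:
        raise InputError(
            f"cannot read VCF {source.vcf_path} (alias {source.alias!r}): {exc}"
        ) from exc
    with vcf:
        for rec in vcf:
            if rec.chrom != targeton_range.chromosome:
                continue
            if rec.ref is None or not rec.alts:
                continue
            for alt in rec.alts:
                if alt is None or set(alt.upper()) - _SIMPLE_BASES:
                    logger.warning(
                        "skipping symbolic/structural ALT %r at %s:%s in %s",
                        alt,
                        rec.chrom,
                        rec.pos,
                        source.alias,
                    )
                    continue
                pos, ref_seq, alt_seq, var_type = _classify_allele(
                    rec.pos, rec.ref.upper(), alt.upper()
                )
                end = pos + len(ref_seq) - 1
                if not (
                    targeton_range.start <= pos
                    and max(end, pos) <= targeton_range.end
                ):
                    logger.debug(
                        "dropping variant at %s:%s (%s): outside targeton "
                        "%s-%s",
                        rec.chrom,
                        rec.pos,
                        source.alias,
                        targeton_range.start,
                        targeton_range.end,
                    )
                    continue
                variant_id: Optional[str] = rec.id
                if source.id_info_tag is not None:
                    try:
                        raw = rec.info.get(source.id_info_tag)
                    except (KeyError, ValueError):
                        # tag absent from the VCF header
                        raw = None
                    if isinstance(raw, tuple):
                        raw = raw[0] if raw else None
                    variant_id = str(raw) if raw is not None else None
                records.append(
                    VariantRecord(
                        source=source.alias,
                        position=pos,
                        ref_seq=ref_seq,
                        alt_seq=alt_seq,
                        type=var_type,
                        variant_id=variant_id,
                    )
                )
    return records


def load_protection_edits(vcf_source: str | Path) -> Dict[str, List[ProtectionEdit]]:
    """Load PAM/protospacer protection SNVs grouped by their SGRNA tag."""
    edits: Dict[str, List[ProtectionEdit]] = {}
    try:
        vcf = pysam.VariantFile(str(vcf_source))
    except (OSError, ValueError) as exc:
        raise InputError(
            f"cannot read protection VCF {vcf_source}: {exc}"
        ) from exc
    with vcf:
        for rec in vcf:
            try:
                sgrna = rec.info.get("SGRNA")
            except (KeyError, ValueError):
                # SGRNA absent from the VCF header entirely
                sgrna = None
            if isinstance(sgrna, tuple):
                sgrna = sgrna[0] if sgrna else None
            if sgrna is None:
                raise InputError(
                    f"protection VCF record at {rec.chrom}:{rec.pos} lacks "
                    "the SGRNA INFO tag"
                )
            if rec.ref is None or not rec.alts or len(rec.alts) != 1:
                raise InputError(
                    f"protection VCF record at {rec.chrom}:{rec.pos} must "
                    "have exactly one alternate allele"
                )
            alt = rec.alts[0]
            if len(rec.ref) != 1 or alt is None or len(alt) != 1:
                raise InputError(
                    f"protection VCF record at {rec.chrom}:{rec.pos} is not "
                    "a single-nucleotide substitution"
                )
            edits.setdefault(str(sgrna), []).append(
                ProtectionEdit(
                    sgrna_id=str(sgrna),
                    position=rec.pos,
                    ref_base=rec.ref.upper(),
                    alt_base=alt.upper(),
                )
            )
    return edits


def apply_protection(
    reference: ReferenceSequence, edits: Sequence[ProtectionEdit]
) -> ReferenceSequence:
    """Apply protection edits to a retrieved reference sequence.

    Every edit must fall inside the range and match the reference base;
    two edits at one position are rejected. The result is the base
    sequence for all subsequent mutation.
    """
    positions = [e.position for e in edits]
    dup = {p for p in positions if positions.count(p) > 1}
    if dup:
        raise InputError(
            f"multiple protection edits at position(s) {sorted(dup)}"
        )
    bases = list(reference.bases)
    for edit in edits:
        if not reference.range.contains(edit.position):
            raise InputError(
                f"protection edit at {edit.position} outside targeton "
                f"{reference.range.start}-{reference.range.end}"
            )
        idx = edit.position - reference.range.start
        if bases[idx] != edit.ref_base:
            raise InputError(
                f"protection edit at {edit.position}: reference is "
                f"{bases[idx]!r}, edit expects {edit.ref_base!r}"
            )
        bases[idx] = edit.alt_base
    return ReferenceSequence(
        range=reference.range,
        bases="".join(bases),
        preceding_base=reference.preceding_base,
    )
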