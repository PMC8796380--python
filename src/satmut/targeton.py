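"""Targeton parameter file parsing and c1-r1-r2-r3-c2 partitioning.

Each row of the BED-like, tab-delimited parameter file describes one
targeton: the full genomic range (``ref_start``/``ref_end``, 1-based
inclusive despite the BED resemblance), a core mutable range r2, an
extension vector deriving r1 and r3 by flanking r2, three per-region
mutator lists and optional sgRNA identifiers for PAM/protospacer
protection. Whatever remains of the targeton outside r1-r3 forms the
constant regions c1 and c2, which receive no systematic mutators.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import InputError
from .ranges import MINUS, PLUS, GenomicRange
from .transcript import TranscriptAnnotation

# mutators applicable to any region
BASIC_MUTATORS = ("snv", "1del", "2del0", "2del1")
# mutators requiring reading-frame information
CDS_MUTATORS = ("snvre", "inframe", "ala", "stop", "aa")
ALL_MUTATORS = BASIC_MUTATORS + CDS_MUTATORS

REGION_NAMES = ("c1", "r1", "r2", "r3", "c2")

TARGETON_COLUMNS = (
    "ref_chr",
    "ref_strand",
    "ref_start",
    "ref_end",
    "r2_start",
    "r2_end",
    "ext_vector",
    "action_vector",
    "sgrna_ids",
)


@dataclass(frozen=True)
class TargetonSpec:
    """One row of the targeton parameter file."""

    ref_range: GenomicRange
    r2_range: GenomicRange
    ext_vector: Tuple[int, int]  # (r1 length, r3 length)
    action_vector: Tuple[Tuple[str, ...], Tuple[str, ...], Tuple[str, ...]]
    sgrna_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        r1_len, r3_len = self.ext_vector
        if r1_len < 0 or r3_len < 0:
            raise InputError("extension vector lengths must be >= 0")
        if self.r2_range.chromosome != self.ref_range.chromosome:
            raise InputError("r2 chromosome differs from targeton chromosome")
        if not (
            self.ref_range.start <= self.r2_range.start - r1_len
            and self.r2_range.end + r3_len <= self.ref_range.end
        ):
            raise InputError(
                f"extended r2 range [{self.r2_range.start - r1_len}, "
                f"{self.r2_range.end + r3_len}] exceeds targeton range "
                f"[{self.ref_range.start}, {self.ref_range.end}]"
            )
        for region_mutators in self.action_vector:
            for name in region_mutators:
                if name not in ALL_MUTATORS:
                    raise InputError(f"unknown mutator {name!r}")
            if len(set(region_mutators)) != len(region_mutators):
                raise InputError(
                    f"duplicate mutator in region list {region_mutators}"
                )

    @property
    def strand(self) -> str:
        return self.ref_range.strand


@dataclass(frozen=True)
class RegionPartition:
    """The five adjacent regions of a targeton, in genomic order.

    Empty regions are ``None``. The regions tile the targeton exactly:
    c1 | r1 | r2 | r3 | c2.
    """

    c1: Optional[GenomicRange]
    r1: Optional[GenomicRange]
    r2: GenomicRange
    r3: Optional[GenomicRange]
    c2: Optional[GenomicRange]

    def regions(self) -> Dict[str, Optional[GenomicRange]]:
        return {
            "c1": self.c1,
            "r1": self.r1,
            "r2": self.r2,
            "r3": self.r3,
            "c2": self.c2,
        }

    def mutable_regions(self) -> Dict[str, Optional[GenomicRange]]:
        return {"r1": self.r1, "r2": self.r2, "r3": self.r3}

    def region_of(self, position: int) -> Optional[str]:
        for name, rng in self.regions().items():
            if rng is not None and rng.contains(position):
                return name
        return None


def _parse_int(value: str, column: str, row: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise InputError(
            f"targeton file row {row}: column {column!r} is not an "
            f"integer: {value!r}"
        ) from None


def _parse_mutator_list(text: str) -> Tuple[str, ...]:
    text = text.strip()
    if not text:
        return ()
    return tuple(part.strip() for part in text.split(",") if part.strip())


def parse_targeton_file(tsv_source: str | Path) -> List[TargetonSpec]:
    """Parse the tab-delimited targeton parameter file.

    The ``ext_vector`` column holds two comma-separated lengths
    (``"25,25"``), ``action_vector`` three ``|``-separated comma lists
    (``"2del1,snv,1del|snvre,inframe|2del0"``; a component may be empty)
    and ``sgrna_ids`` a possibly empty comma list.
    """
    specs: List[TargetonSpec] = []
    with open(tsv_source, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return specs
        missing = set(TARGETON_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise InputError(
                f"targeton file {tsv_source} lacks columns: {sorted(missing)}"
            )
        for i, row in enumerate(reader, start=2):
            strand = row["ref_strand"].strip()
            if strand not in (PLUS, MINUS):
                raise InputError(
                    f"targeton file row {i}: strand must be '+' or '-', "
                    f"got {strand!r}"
                )
            chrom = row["ref_chr"].strip()
            ext_parts = [p.strip() for p in row["ext_vector"].split(",")]
            if len(ext_parts) != 2:
                raise InputError(
                    f"targeton file row {i}: ext_vector must hold two "
                    f"comma-separated lengths, got {row['ext_vector']!r}"
                )
            action_parts = row["action_vector"].split("|")
            if len(action_parts) != 3:
                raise InputError(
                    f"targeton file row {i}: action_vector must hold three "
                    f"'|'-separated mutator lists, got {row['action_vector']!r}"
                )
            sgrna = tuple(
                s.strip() for s in row["sgrna_ids"].split(",") if s.strip()
            )
            try:
                spec = TargetonSpec(
                    ref_range=GenomicRange(
                        chrom,
                        _parse_int(row["ref_start"], "ref_start", i),
                        _parse_int(row["ref_end"], "ref_end", i),
                        strand,
                    ),
                    r2_range=GenomicRange(
                        chrom,
                        _parse_int(row["r2_start"], "r2_start", i),
                        _parse_int(row["r2_end"], "r2_end", i),
                        strand,
                    ),
                    ext_vector=(
                        _parse_int(ext_parts[0], "ext_vector", i),
                        _parse_int(ext_parts[1], "ext_vector", i),
                    ),
                    action_vector=tuple(
                        _parse_mutator_list(p) for p in action_parts
                    ),
                    sgrna_ids=sgrna,
                )
            except (InputError, ValueError) as exc:
                raise InputError(f"targeton file row {i}: {exc}") from exc
            specs.append(spec)
    return specs


def partition(spec: TargetonSpec) -> RegionPartition:
    """Split the targeton range into c1 | r1 | r2 | r3 | c2."""
    chrom = spec.ref_range.chromosome
    strand = spec.strand
    r1_len, r3_len = spec.ext_vector

    def make(start: int, end: int) -> Optional[GenomicRange]:
        if start > end:
            return None
        return GenomicRange(chrom, start, end, strand)

    r1 = make(spec.r2_range.start - r1_len, spec.r2_range.start - 1)
    r3 = make(spec.r2_range.end + 1, spec.r2_range.end + r3_len)
    c1 = make(spec.ref_range.start, spec.r2_range.start - r1_len - 1)
    c2 = make(spec.r2_range.end + r3_len + 1, spec.ref_range.end)
    return RegionPartition(c1=c1, r1=r1, r2=spec.r2_range, r3=r3, c2=c2)


def find_transcript(
    annotations: Dict[str, TranscriptAnnotation], region: GenomicRange
) -> Optional[TranscriptAnnotation]:
    """The transcript whose CDS covers the region fully, if any."""
    for annotation in annotations.values():
        if all(annotation.is_coding_position(p) for p in region.positions()):
            return annotation
    return None


def validate_region_homogeneity(
    part: RegionPartition,
    annotations: Dict[str, TranscriptAnnotation],
) -> Dict[str, bool]:
    """Flag each mutable region as coding or non-coding.

    A mutable region may not span both coding and non-coding positions
    (UTR counts as non-coding); the constant regions c1/c2 may. Raises
    InputError naming the offending region on a violation.
    """
    flags: Dict[str, bool] = {}
    for name, rng in part.mutable_regions().items():
        if rng is None:
            continue
        coding = [
            any(a.is_coding_position(p) for a in annotations.values())
            for p in rng.positions()
        ]
        if all(coding):
            flags[name] = True
        elif not any(coding):
            flags[name] = False
        else:
            raise InputError(
                f"region {name} ({rng.chromosome}:{rng.start}-{rng.end}) "
                "spans both coding and non-coding sequence"
            )
    return flags


def targeton_file_stem(spec: TargetonSpec) -> str:
    """File-name stem reporting chromosome, coordinates, strand and sgRNAs."""
    chrom = spec.ref_range.chromosome
    if not chrom.startswith("chr"):
        chrom = f"chr{chrom}"
    strand = "plus" if spec.strand == PLUS else "minus"
    stem = f"{chrom}_{spec.ref_range.start}_{spec.ref_range.end}_{strand}"
    if spec.sgrna_ids:
        stem += "_" + "_".join(spec.sgrna_ids)
    return stem
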