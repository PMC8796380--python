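"""Transcript annotation, reading frames and liminal-codon context.

Only CDS, UTR and stop-codon features of the GTF/GFF2 are considered, and
exactly one transcript per gene is allowed, so a target range maps to at
most one reading frame. UTR positions are treated like intronic positions
(non-coding).

The frame ``f`` of a target range is the number of bases missing from the
codon at its genomic-left end::

    f_target = (f_exon + (s_target - s_exon)) mod 3      (s_target >= s_exon)

and the numbers of extra context bases needed at either end to complete
the flanking codons are::

    l_ext5 = f_target
    l_ext3 = (3 - (l_target + f_target) mod 3) mod 3

For minus-strand transcripts the stored coordinates and bases remain
positive-strand; ``f_exon`` is the genomic-left phase derived from the
spliced CDS walked in transcript order, so the same arithmetic applies on
both strands. The context bases may come from the same or the adjacent
exon (a codon split across the splice junction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import pyranges

from .errors import InputError
from .ranges import MINUS, PLUS, GenomicRange


@dataclass(frozen=True)
class CdsFeature:
    range: GenomicRange
    frame: int  # genomic-left phase: bases missing from the codon at range.start

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript of one gene: ordered CDS features plus UTR/stop."""

    gene_id: str
    transcript_id: str
    strand: str
    cds_features: Tuple[CdsFeature, ...]
    utr_features: Tuple[GenomicRange, ...] = ()
    stop_feature: Optional[GenomicRange] = None
    _spliced_positions: Tuple[int, ...] = field(init=False, repr=False, compare=False)
    _position_index: Dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        feats = sorted(self.cds_features, key=lambda f: f.range.start)
        for a, b in zip(feats, feats[1:]):
            if a.range.end >= b.range.start:
                raise InputError(
                    f"overlapping CDS features in transcript "
                    f"{self.transcript_id}"
                )
        object.__setattr__(self, "cds_features", tuple(feats))
        positions: List[int] = []
        ordered = feats if self.strand == PLUS else list(reversed(feats))
        for feat in ordered:
            pos = list(feat.range.positions())
            if self.strand == MINUS:
                pos.reverse()
            positions.extend(pos)
        object.__setattr__(self, "_spliced_positions", tuple(positions))
        object.__setattr__(
            self, "_position_index", {p: i for i, p in enumerate(positions)}
        )

    @property
    def chromosome(self) -> str:
        return self.cds_features[0].range.chromosome

    def is_coding_position(self, position: int) -> bool:
        return position in self._position_index

    def codon_positions_at(self, position: int) -> Tuple[int, ...]:
        """Genomic positions (ascending) of the codon containing ``position``.

        Raises InputError when the codon is incomplete in the transcript
        (annotation truncated mid-codon).
        """
        try:
            idx = self._position_index[position]
        except KeyError:
            raise InputError(
                f"position {position} is non-coding in transcript "
                f"{self.transcript_id}"
            ) from None
        start = 3 * (idx // 3)
        codon = self._spliced_positions[start : start + 3]
        if len(codon) != 3:
            raise InputError(
                f"codon at position {position} is incomplete in transcript "
                f"{self.transcript_id}"
            )
        return tuple(sorted(codon))

    def frame_at(self, position: int) -> int:
        """Bases missing at the genomic-left end of a target starting here."""
        codon = self.codon_positions_at(position)
        return sum(1 for p in codon if p < position)


def frame_from_exon(f_exon: int, s_exon: int, s_target: int) -> int:
    """Frame of a target from its exon's frame and start offset."""
    if s_target < s_exon:
        raise ValueError("target start precedes exon start")
    return (f_exon + (s_target - s_exon)) % 3


def codon_extensions(l_target: int, f_target: int) -> Tuple[int, int]:
    """Context bases needed 5' and 3' to complete the flanking codons."""
    if l_target < 1:
        raise ValueError("target length must be >= 1")
    if f_target not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    l_ext5 = f_target
    l_ext3 = (3 - (l_target + f_target) % 3) % 3
    return l_ext5, l_ext3


_CDS_FEATURES = {"CDS"}
_UTR_FEATURES = {"UTR", "five_prime_utr", "three_prime_utr", "5UTR", "3UTR"}
_STOP_FEATURES = {"stop_codon"}


def _left_phase(strand: str, gtf_frame: int, length: int) -> int:
    """Convert a GTF frame (phase at the transcript 5' end) to genomic-left phase."""
    if strand == PLUS:
        return gtf_frame % 3
    # minus strand: transcript 5' end is the genomic-right end of the feature
    return (3 - (gtf_frame + length)) % 3


def load_annotation(gtf_source: str | Path) -> Dict[str, TranscriptAnnotation]:
    """Parse a GTF/GFF2 file into one :class:`TranscriptAnnotation` per gene.

    Feature types other than CDS, UTR and stop_codon are ignored. Two
    transcripts for one gene are rejected to avoid ambiguities in matching
    target regions. A missing frame column ('.') is computed by walking
    the spliced CDS from the transcript start.
    """
    with open(gtf_source) as handle:
        if not any(line.strip() and not line.startswith("#") for line in handle):
            return {}
    try:
        gr = pyranges.read_gtf(str(gtf_source))
    except Exception as exc:  # pyranges raises a mix of types on bad input
        raise InputError(f"cannot parse GTF {gtf_source}: {exc}") from exc
    df = gr.df if len(gr) else None
    annotations: Dict[str, TranscriptAnnotation] = {}
    if df is None or df.empty:
        return annotations
    for col in ("gene_id", "transcript_id"):
        if col not in df.columns:
            raise InputError(f"GTF {gtf_source} lacks mandatory {col} attribute")
    df = df[df["Feature"].isin(_CDS_FEATURES | _UTR_FEATURES | _STOP_FEATURES)]
    for gene_id, gene_df in df.groupby("gene_id", observed=True, sort=True):
        transcripts = sorted(set(gene_df["transcript_id"]))
        if len(transcripts) > 1:
            raise InputError(
                f"gene {gene_id!r} has {len(transcripts)} transcripts "
                f"({', '.join(transcripts)}); one transcript per gene is allowed"
            )
        strands = set(gene_df["Strand"])
        if len(strands) != 1 or not strands <= {PLUS, MINUS}:
            raise InputError(f"gene {gene_id!r} has inconsistent strand")
        strand = strands.pop()
        cds_rows = gene_df[gene_df["Feature"].isin(_CDS_FEATURES)]
        if cds_rows.empty:
            raise InputError(f"gene {gene_id!r} has no CDS features")
        # pyranges exposes 0-based half-open Start/End; convert back
        raw = sorted(
            (int(r.Start) + 1, int(r.End), str(r.Frame))
            for r in cds_rows.itertuples()
        )
        cds = _build_cds_features(
            str(gene_id), strand, raw, gene_df["Chromosome"].iloc[0]
        )
        utrs = tuple(
            GenomicRange(str(r.Chromosome), int(r.Start) + 1, int(r.End), strand)
            for r in gene_df[gene_df["Feature"].isin(_UTR_FEATURES)].itertuples()
        )
        stops = [
            GenomicRange(str(r.Chromosome), int(r.Start) + 1, int(r.End), strand)
            for r in gene_df[gene_df["Feature"].isin(_STOP_FEATURES)].itertuples()
        ]
        annotations[str(gene_id)] = TranscriptAnnotation(
            gene_id=str(gene_id),
            transcript_id=transcripts[0],
            strand=strand,
            cds_features=cds,
            utr_features=utrs,
            stop_feature=stops[0] if stops else None,
        )
    return annotations


def _build_cds_features(
    gene_id: str,
    strand: str,
    raw: List[Tuple[int, int, str]],
    chromosome: str,
) -> Tuple[CdsFeature, ...]:
    chromosome = str(chromosome)
    # transcript order for the cumulative walk
    ordered = raw if strand == PLUS else list(reversed(raw))
    cumulative = 0
    frames: List[int] = []
    for start, end, frame_str in ordered:
        length = end - start + 1
        if frame_str in (".", "nan", ""):
            gtf_frame = (3 - cumulative % 3) % 3 if cumulative % 3 else 0
        else:
            try:
                gtf_frame = int(float(frame_str))
            except ValueError:
                raise InputError(
                    f"gene {gene_id!r}: malformed frame value {frame_str!r}"
                ) from None
        frames.append(_left_phase(strand, gtf_frame, length))
        cumulative += length
    if strand == MINUS:
        frames.reverse()
    return tuple(
        CdsFeature(GenomicRange(chromosome, start, end, strand), frame)
        for (start, end, _), frame in zip(raw, frames)
    )


def frame_at(annotation: TranscriptAnnotation, s_target: int) -> int:
    """Frame at a coding position (bases missing from the 5' codon)."""
    return annotation.frame_at(s_target)


def liminal_context(
    annotation: TranscriptAnnotation,
    base_lookup: Callable[[int], str],
    target_range: GenomicRange,
) -> Tuple[Tuple[str, Tuple[int, ...]], Tuple[str, Tuple[int, ...]]]:
    """Coding context bases flanking a target, in transcript splicing.

    Returns ``((bases_5prime, positions_5prime), (bases_3prime,
    positions_3prime))`` where the 5'/3' sides are genomic left/right,
    bases are positive-strand and positions ascend. Crossing an exon
    boundary pulls bases from the neighbouring CDS feature.
    """
    left_codon = annotation.codon_positions_at(target_range.start)
    right_codon = annotation.codon_positions_at(target_range.end)
    left = tuple(p for p in left_codon if p < target_range.start)
    right = tuple(p for p in right_codon if p > target_range.end)
    left_bases = "".join(base_lookup(p) for p in left)
    right_bases = "".join(base_lookup(p) for p in right)
    return (left_bases, left), (right_bases, right)


@dataclass(frozen=True)
class Codon:
    """One codon overlapping a mutable region."""

    positions: Tuple[int, ...]  # ascending, length 3
    bases: str  # positive-strand bases in ascending position order
    complete: bool  # all three positions inside the region


@dataclass(frozen=True)
class CodingContext:
    """Frame-resolved view of a coding region for codon-aware mutators.

    ``codons`` covers every codon overlapping the region, genomic-ascending,
    with bases taken from the (PAM-protected) sequence; liminal codons
    carry context bases from outside the region.
    """

    strand: str
    region: GenomicRange
    region_seq: str
    codons: Tuple[Codon, ...]

    def __post_init__(self) -> None:
        if len(self.region_seq) != len(self.region):
            raise ValueError("region sequence length does not match range")

    def complete_codons(self) -> Tuple[Codon, ...]:
        return tuple(c for c in self.codons if c.complete)

    def codon_at(self, position: int) -> Tuple[Codon, int]:
        """The codon containing ``position`` and the offset of it within."""
        for codon in self.codons:
            if position in codon.positions:
                return codon, codon.positions.index(position)
        raise ValueError(f"position {position} not covered by any codon")


def build_coding_context(
    annotation: TranscriptAnnotation,
    region: GenomicRange,
    region_seq: str,
    base_lookup: Callable[[int], str],
) -> CodingContext:
    """Assemble the :class:`CodingContext` for a coding region.

    ``region_seq`` is the positive-strand (protected) sequence of the
    region; ``base_lookup`` supplies positive-strand bases for context
    positions outside it (applying any protection edits that fall there).
    """

    def base_at(p: int) -> str:
        if region.contains(p):
            return region_seq[p - region.start]
        return base_lookup(p)

    codons: List[Codon] = []
    seen = set()
    for position in region.positions():
        positions = annotation.codon_positions_at(position)
        if positions in seen:
            continue
        seen.add(positions)
        bases = "".join(base_at(p) for p in positions)
        complete = all(region.contains(p) for p in positions)
        codons.append(Codon(positions=positions, bases=bases, complete=complete))
    codons.sort(key=lambda c: c.positions)
    return CodingContext(
        strand=annotation.strand,
        region=region,
        region_seq=region_seq,
        codons=tuple(codons),
    )


def build_cdna_coding_context(
    region: GenomicRange,
    region_seq: str,
    frame: int,
    record_seq: str,
) -> CodingContext:
    """Coding context for a cDNA mutagenesis range with a user-stated frame.

    Coordinates are relative to the cDNA record (1-based); the reading
    frame of the range start is given directly and context bases come
    from the surrounding record sequence, which is assumed coding.
    """
    if frame not in (0, 1, 2):
        raise InputError(f"frame must be 0, 1 or 2, got {frame}")
    first_codon_start = region.start - frame
    if first_codon_start < 1:
        raise InputError(
            f"frame {frame} at position {region.start} requires context "
            "before the start of the record"
        )

    def base_at(p: int) -> str:
        if region.contains(p):
            return region_seq[p - region.start]
        if not 1 <= p <= len(record_seq):
            raise InputError(
                f"codon context position {p} outside the cDNA record"
            )
        return record_seq[p - 1]

    codons: List[Codon] = []
    start = first_codon_start
    while start <= region.end:
        positions = (start, start + 1, start + 2)
        bases = "".join(base_at(p) for p in positions)
        complete = all(region.contains(p) for p in positions)
        codons.append(Codon(positions=positions, bases=bases, complete=complete))
        start += 3
    return CodingContext(
        strand=PLUS, region=region, region_seq=region_seq, codons=tuple(codons)
    )
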