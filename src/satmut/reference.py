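"""Reference sequence retrieval from local FASTA files.

Sequences are fetched on the positive strand and uppercased. Unless a
range starts at position one, the single nucleotide preceding it is also
retrieved: it anchors the REF/ALT fields of liminal variants (events
touching the first position of the range) in the output VCF.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from .errors import InputError
from .ranges import GenomicRange

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReferenceSequence:
    """Positive-strand bases for a range plus the preceding anchor base."""

    range: GenomicRange
    bases: str
    preceding_base: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.range):
            raise ValueError(
                f"sequence length {len(self.bases)} does not match range "
                f"length {len(self.range)}"
            )
        if (self.preceding_base is None) != (self.range.start == 1):
            raise ValueError(
                "preceding_base must be present exactly when start > 1"
            )

    def base_at(self, position: int) -> str:
        if not self.range.contains(position):
            raise ValueError(f"position {position} outside {self.range}")
        return self.bases[position - self.range.start]

    def slice(self, start: int, end: int) -> str:
        """Bases for the 1-based inclusive sub-range [start, end]."""
        if start > end:
            return ""
        if not (self.range.contains(start) and self.range.contains(end)):
            raise ValueError(
                f"[{start}, {end}] outside {self.range}"
            )
        off = self.range.start
        return self.bases[start - off : end - off + 1]


class ReferenceReader:
    """Random access to an indexed FASTA file."""

    def __init__(self, fasta_path: str | Path):
        self._path = str(fasta_path)
        try:
            self._fasta = pysam.FastaFile(self._path)
        except OSError as exc:
            raise InputError(f"cannot open FASTA {self._path}: {exc}") from exc

    def close(self) -> None:
        self._fasta.close()

    def __enter__(self) -> "ReferenceReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def contig_length(self, chromosome: str) -> int:
        if chromosome not in self._fasta.references:
            raise InputError(
                f"chromosome {chromosome!r} not found in {self._path}"
            )
        return self._fasta.get_reference_length(chromosome)

    def fetch_base(self, chromosome: str, position: int) -> str:
        """Single positive-strand base at a 1-based position."""
        return self.fetch_range(
            GenomicRange(chromosome, position, position)
        ).bases

    def fetch_range(self, rng: GenomicRange) -> ReferenceSequence:
        """Retrieve positive-strand bases for ``rng`` plus its anchor base.

        The range is validated against the contig bounds; bases are
        uppercased (soft-masked references are accepted) and any base
        outside ``{A, C, G, T, N}`` is rejected.
        """
        contig_len = self.contig_length(rng.chromosome)
        if rng.end > contig_len:
            raise InputError(
                f"range end {rng.end} exceeds length {contig_len} of "
                f"chromosome {rng.chromosome!r}"
            )
        fetch_start = rng.start - 1 if rng.start > 1 else rng.start
        raw = self._fasta.fetch(rng.chromosome, fetch_start - 1, rng.end)
        raw = raw.upper()
        bad = set(raw) - _VALID_BASES
        if bad:
            raise InputError(
                f"invalid bases {sorted(bad)!r} in {rng.chromosome}:"
                f"{rng.start}-{rng.end}"
            )
        if rng.start > 1:
            return ReferenceSequence(rng, raw[1:], preceding_base=raw[0])
        return ReferenceSequence(rng, raw, preceding_base=None)


def fetch_range(fasta_source: str | Path, rng: GenomicRange) -> ReferenceSequence:
    """One-shot :meth:`ReferenceReader.fetch_range`."""
    with ReferenceReader(fasta_source) as reader:
        return reader.fetch_range(rng)


def write_qc_report(
    path: str | Path,
    targeton_ids: Sequence[str],
    wildtype_sequences: Iterable[str],
) -> None:
    """Write the execution-wide sequence QC file.

    One CSV row per executed targeton reporting the retrieved wild-type
    sequence, so the user can verify retrieval before synthesis.
    """
    sequences = list(wildtype_sequences)
    if len(sequences) != len(targeton_ids):
        raise ValueError("one wild-type sequence per targeton required")
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["targeton_id", "sequence"])
        for tid, seq in zip(targeton_ids, sequences):
            writer.writerow([tid, seq])
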