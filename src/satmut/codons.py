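"""Codon-frequency tables, strand-aware translation and SNV metadata tables.

Codon-level mutators need to know, for every codon, which single-nucleotide
substitutions are synonymous, missense or nonsense, and which alternative
codons encode the same amino acid. Because the number of codons reachable
by one SNV is small (three per base per codon per strand, 3*3*64 = 576 per
strand, 1152 for both), these annotations are precomputed at start-up into
small tables indexed by codon, and looked up during variant generation.

Codons are stored as positive-strand triplets in ascending genomic order.
Translation on the minus strand reverse-complements first: the nucleotide
change of a substitution is strand-independent but its amino-acid
consequence is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .errors import InputError
from .ranges import MINUS, PLUS, STRANDS

BASES = "ACGT"
ALL_CODONS = tuple("".join(c) for c in product(BASES, repeat=3))
STOP = "*"

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"

# Standard nuclear genetic code, codon -> single-letter amino acid ('*' stop).
GENETIC_CODE: Mapping[str, str] = {
    **standard_dna_table.forward_table,
    **{c: STOP for c in standard_dna_table.stop_codons},
}


def revcomp(seq: str) -> str:
    return reverse_complement(seq)


def translate(codon: str, strand: str = PLUS) -> str:
    """Translate a positive-strand codon as read on ``strand``."""
    if strand not in STRANDS:
        raise ValueError(f"unknown strand {strand!r}")
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise InputError(f"not a codon over ACGT: {codon!r}")
    if strand == MINUS:
        codon = revcomp(codon)
    return GENETIC_CODE[codon]


def classify(ref_aa: str, alt_aa: str) -> str:
    """Consequence class of an amino-acid change.

    Stop-retaining changes are synonymous, stop-gains are nonsense and
    everything else (including stop-loss) is reported as missense.
    """
    if ref_aa == alt_aa:
        return SYNONYMOUS
    if alt_aa == STOP:
        return NONSENSE
    return MISSENSE


class CodonFrequencyTable:
    """Relative codon usage with a deterministic within-amino-acid ranking.

    Ties in frequency are broken by lexicographic codon order so that the
    "most frequent" codon of an amino acid is always well defined.
    """

    def __init__(self, fractions: Mapping[str, Tuple[str, float]]):
        missing = set(ALL_CODONS) - set(fractions)
        if missing:
            raise InputError(
                f"codon table is missing {len(missing)} codons, "
                f"e.g. {sorted(missing)[:3]}"
            )
        extra = set(fractions) - set(ALL_CODONS)
        if extra:
            raise InputError(f"invalid codons in table: {sorted(extra)[:3]}")
        for codon, (aa, frac) in fractions.items():
            if aa != GENETIC_CODE[codon]:
                raise InputError(
                    f"codon {codon} annotated as {aa!r} but encodes "
                    f"{GENETIC_CODE[codon]!r} in the standard code"
                )
            if frac < 0:
                raise InputError(f"negative frequency for codon {codon}")
        self._fraction: Dict[str, float] = {
            c: f for c, (_, f) in fractions.items()
        }
        self._by_aa: Dict[str, List[str]] = {}
        for codon in ALL_CODONS:
            self._by_aa.setdefault(GENETIC_CODE[codon], []).append(codon)
        # rank 0 = most frequent; ties broken lexicographically
        self._ranked: Dict[str, List[str]] = {
            aa: sorted(codons, key=lambda c: (-self._fraction[c], c))
            for aa, codons in self._by_aa.items()
        }

    def fraction(self, codon: str) -> float:
        return self._fraction[codon]

    def amino_acid(self, codon: str) -> str:
        return GENETIC_CODE[codon]

    @property
    def amino_acids(self) -> Tuple[str, ...]:
        return tuple(sorted(self._by_aa))

    def codons_for(self, amino_acid: str) -> Tuple[str, ...]:
        """Codons of an amino acid, most frequent first."""
        try:
            return tuple(self._ranked[amino_acid])
        except KeyError:
            raise InputError(f"unknown amino acid {amino_acid!r}") from None

    def top_codon(self, amino_acid: str) -> str:
        return self.codons_for(amino_acid)[0]

    def rank(self, codon: str) -> int:
        return self._ranked[GENETIC_CODE[codon]].index(codon)


def load_codon_table(csv_source: Optional[str | Path] = None) -> CodonFrequencyTable:
    """Load a codon-frequency table from CSV, or the built-in human default.

    The CSV must have columns ``codon``, ``amino_acid`` (single letter,
    ``*`` for stop) and ``fraction``, covering all 64 codons exactly once.
    The bundled default holds standard published human codon-usage
    fractions.
    """
    if csv_source is None:
        with resources.files("satmut.data").joinpath(
            "codon_usage_human.csv"
        ).open() as handle:
            df = pd.read_csv(handle)
    else:
        df = pd.read_csv(csv_source)
    required = {"codon", "amino_acid", "fraction"}
    if not required.issubset(df.columns):
        raise InputError(
            f"codon table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    codons = df["codon"].str.upper()
    dup = codons[codons.duplicated()]
    if not dup.empty:
        raise InputError(f"duplicate codons in table: {sorted(set(dup))}")
    fractions = {
        str(c): (str(a), float(f))
        for c, a, f in zip(codons, df["amino_acid"], df["fraction"])
    }
    return CodonFrequencyTable(fractions)


@dataclass(frozen=True)
class SnvAnnotationRecord:
    """One single-nucleotide substitution within a codon, consequence-classed."""

    strand: str
    ref_codon: str
    position_in_codon: int  # 0-based offset within the positive-strand triplet
    ref_base: str
    alt_base: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str


class SnvAnnotationTable:
    """All 3 x 3 x 64 single-SNV codon changes per requested strand."""

    def __init__(self, strands: Iterable[str]):
        strands = tuple(strands)
        if not strands or any(s not in STRANDS for s in strands):
            raise ValueError(f"strands must be a non-empty subset of {STRANDS}")
        self._records: List[SnvAnnotationRecord] = []
        self._index: Dict[Tuple[str, str, int, str], SnvAnnotationRecord] = {}
        for strand in strands:
            for codon in ALL_CODONS:
                ref_aa = translate(codon, strand)
                for pos in range(3):
                    for alt in BASES:
                        if alt == codon[pos]:
                            continue
                        alt_codon = codon[:pos] + alt + codon[pos + 1 :]
                        alt_aa = translate(alt_codon, strand)
                        rec = SnvAnnotationRecord(
                            strand=strand,
                            ref_codon=codon,
                            position_in_codon=pos,
                            ref_base=codon[pos],
                            alt_base=alt,
                            alt_codon=alt_codon,
                            ref_aa=ref_aa,
                            alt_aa=alt_aa,
                            consequence=classify(ref_aa, alt_aa),
                        )
                        self._records.append(rec)
                        self._index[(strand, codon, pos, alt)] = rec

    def __len__(self) -> int:
        return len(self._records)

    @property
    def records(self) -> Tuple[SnvAnnotationRecord, ...]:
        return tuple(self._records)

    def lookup(
        self, strand: str, ref_codon: str, position_in_codon: int, alt_base: str
    ) -> SnvAnnotationRecord:
        return self._index[(strand, ref_codon, position_in_codon, alt_base)]

    def for_codon(self, strand: str, ref_codon: str) -> List[SnvAnnotationRecord]:
        return [
            r
            for r in self._records
            if r.strand == strand and r.ref_codon == ref_codon
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self._records])


def build_snv_annotation_table(strands: Iterable[str]) -> SnvAnnotationTable:
    return SnvAnnotationTable(strands)


class SynonymousSubstitutionTable:
    """Per (strand, codon): all synonymous alternatives and the top-ranked one.

    Alternatives are positive-strand triplets; "synonymous" is judged after
    strand-aware translation, and ranking follows the codon-frequency table
    applied to the codon as read on its strand.
    """

    def __init__(self, freq_table: CodonFrequencyTable, strands: Iterable[str]):
        strands = tuple(strands)
        if not strands or any(s not in STRANDS for s in strands):
            raise ValueError(f"strands must be a non-empty subset of {STRANDS}")
        self._freq = freq_table
        self._syn: Dict[Tuple[str, str], FrozenSet[str]] = {}
        self._top: Dict[Tuple[str, str], Optional[str]] = {}
        for strand in strands:
            for codon in ALL_CODONS:
                aa = translate(codon, strand)
                alts = frozenset(
                    alt
                    for alt in ALL_CODONS
                    if alt != codon and translate(alt, strand) == aa
                )
                self._syn[(strand, codon)] = alts
                self._top[(strand, codon)] = self._rank_top(strand, alts)

    def _oriented(self, strand: str, codon: str) -> str:
        return revcomp(codon) if strand == MINUS else codon

    def _rank_top(self, strand: str, alts: FrozenSet[str]) -> Optional[str]:
        if not alts:
            return None
        return min(
            alts,
            key=lambda c: (
                -self._freq.fraction(self._oriented(strand, c)),
                self._oriented(strand, c),
            ),
        )

    def synonymous(self, strand: str, codon: str) -> FrozenSet[str]:
        return self._syn[(strand, codon)]

    def top_ranking(self, strand: str, codon: str) -> Optional[str]:
        return self._top[(strand, codon)]


def build_snvre_tables(
    freq_table: CodonFrequencyTable, strands: Iterable[str]
) -> SynonymousSubstitutionTable:
    return SynonymousSubstitutionTable(freq_table, strands)
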