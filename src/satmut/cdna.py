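"""cDNA deep-mutational-scanning mode.

The same mutator engine runs over user-supplied cDNA sequences (for
example a CDS cloned into an expression vector) instead of a genomic
reference. Coordinates are relative to each FASTA record (1-based), the
reading frame of the mutagenesis range is stated directly in the
annotation file, there is no PAM protection and custom VCF variants are
not supported. The output VCF uses the FASTA record id as its contig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .assembly import (
    AssemblyOptions,
    OligoRecord,
    assemble_all,
    filter_max_length,
    write_outputs,
)
from .codons import load_codon_table
from .engine import TargetonResult
from .errors import InputError
from .mutators import build_tables, run_action_vector
from .ranges import PLUS, GenomicRange
from .reference import ReferenceSequence, write_qc_report
from .targeton import TargetonSpec, partition
from .transcript import CodingContext, build_cdna_coding_context

logger = logging.getLogger(__name__)

CDNA_ANNOTATION_COLUMNS = (
    "record_id",
    "targeton_start",
    "targeton_end",
    "r2_start",
    "r2_end",
    "ext_vector",
    "action_vector",
    "frame",
)


@dataclass
class CdnaConfig:
    fasta: str
    annotation: str
    codon_table: Optional[str] = None
    adapter_5: str = ""
    adapter_3: str = ""
    max_length: int = 300
    out_dir: str = "."


def _parse_mutators(text: str) -> Tuple[str, ...]:
    text = str(text).strip()
    if not text:
        return ()
    return tuple(p.strip() for p in text.split(",") if p.strip())


def parse_cdna_inputs(
    multi_fasta: str | Path, annotation_csv: str | Path
) -> List[Tuple[TargetonSpec, int, str]]:
    """Parse the cDNA targeton FASTA and annotation CSV.

    Returns (spec, r2_frame, record_sequence) triples with relative,
    1-based coordinates; ``frame`` is the number of bases missing from
    the codon at the start of r2.
    """
    records = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(multi_fasta), "fasta")
    }
    if not records:
        raise InputError(f"no FASTA records in {multi_fasta}")
    df = pd.read_csv(annotation_csv, dtype=str, keep_default_na=False)
    missing = set(CDNA_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(
            f"cDNA annotation {annotation_csv} lacks columns {sorted(missing)}"
        )
    out: List[Tuple[TargetonSpec, int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        record_id = row.record_id.strip()
        if record_id not in records:
            raise InputError(
                f"cDNA annotation row {i}: record {record_id!r} not in "
                f"{multi_fasta}"
            )
        seq = records[record_id]
        ext_parts = [p.strip() for p in row.ext_vector.split(",")]
        if len(ext_parts) != 2:
            raise InputError(
                f"cDNA annotation row {i}: ext_vector must hold two lengths"
            )
        action_parts = row.action_vector.split("|")
        if len(action_parts) != 3:
            raise InputError(
                f"cDNA annotation row {i}: action_vector must hold three "
                "'|'-separated lists"
            )
        try:
            spec = TargetonSpec(
                ref_range=GenomicRange(
                    record_id,
                    int(row.targeton_start),
                    int(row.targeton_end),
                    PLUS,
                ),
                r2_range=GenomicRange(
                    record_id, int(row.r2_start), int(row.r2_end), PLUS
                ),
                ext_vector=(int(ext_parts[0]), int(ext_parts[1])),
                action_vector=tuple(_parse_mutators(p) for p in action_parts),
                sgrna_ids=(),
            )
            frame = int(row.frame)
        except (InputError, ValueError) as exc:
            raise InputError(f"cDNA annotation row {i}: {exc}") from exc
        if spec.ref_range.end > len(seq):
            raise InputError(
                f"cDNA annotation row {i}: targeton end "
                f"{spec.ref_range.end} exceeds record length {len(seq)}"
            )
        out.append((spec, frame, seq))
    return out


def run_cdna(config: CdnaConfig) -> List[TargetonResult]:
    """Run cDNA library generation and write all output files.

    Mutator behaviour, assembly, filtering and outputs match the genomic
    mode; positions in all outputs are relative to the cDNA record.
    """
    parsed = parse_cdna_inputs(config.fasta, config.annotation)
    freq_table = load_codon_table(config.codon_table)
    tables = build_tables(freq_table, [PLUS])
    options = AssemblyOptions(
        adapter_5=config.adapter_5.upper(),
        adapter_3=config.adapter_3.upper(),
        max_length=config.max_length,
        revcomp_minus_strand=False,
    )
    results: List[TargetonResult] = []
    for spec, frame, record_seq in parsed:
        rng = spec.ref_range
        stem = f"{rng.chromosome}_{rng.start}_{rng.end}_plus"
        reference = ReferenceSequence(
            range=rng,
            bases=record_seq[rng.start - 1 : rng.end],
            preceding_base=record_seq[rng.start - 2] if rng.start > 1 else None,
        )
        part = partition(spec)
        sequences: Dict[str, str] = {}
        contexts: Dict[str, Optional[CodingContext]] = {}
        flags: Dict[str, bool] = {}
        for name, region in part.mutable_regions().items():
            if region is None:
                continue
            seq = reference.slice(region.start, region.end)
            sequences[name] = seq
            if name == "r2":
                flags[name] = True
                contexts[name] = build_cdna_coding_context(
                    region, seq, frame, record_seq
                )
            else:
                # extension regions in cDNA mode are non-coding for
                # frame purposes; only basic mutators apply
                flags[name] = False
                contexts[name] = None
        tagged = run_action_vector(
            part, spec.action_vector, sequences, flags, contexts, tables
        )
        oligos = assemble_all(
            reference, tagged, options, stem, src_type="cdna"
        )
        kept, excluded = filter_max_length(oligos, options.max_length)
        result = TargetonResult(
            spec=spec,
            stem=stem,
            wildtype=reference,
            protected=reference,
            oligos=kept,
            excluded=excluded,
        )
        result.output_paths = write_outputs(
            config.out_dir,
            stem,
            kept,
            excluded,
            reference,
            contig_length=len(record_seq),
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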