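"""Deterministic synthetic fixtures: a mini genome with annotation and VCFs.

Generates a small chromosome carrying two two-exon protein-coding
transcripts — one on the minus strand and one on the plus strand, both
with a codon split across the exon junction — together with a matching
GTF, a PAM/protospacer protection VCF, custom-variant VCFs with a
manifest, a targeton parameter file mirroring a typical exon design
(25 bp extensions around a 54 bp coding core), and a small cDNA input
pair. Everything is derived from a single integer seed, so two calls
with the same seed produce byte-identical files; this makes the whole
tool testable without downloading any reference data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import pysam

from .codons import ALL_CODONS, GENETIC_CODE, STOP, revcomp

CHROM = "chrT"
CHROM_LENGTH = 3000

# minus-strand transcript: transcript order is exon_hi then exon_lo
MINUS_EXON_HI = (1201, 1280)  # 80 bp, transcript 5'
MINUS_EXON_LO = (1001, 1055)  # 55 bp, transcript 3' (junction splits a codon)
# plus-strand transcript
PLUS_EXON_1 = (2001, 2061)  # 61 bp
PLUS_EXON_2 = (2161, 2219)  # 59 bp

_SENSE_CODONS = tuple(c for c in ALL_CODONS if GENETIC_CODE[c] != STOP)
_ALT_BASE = {"A": "G", "C": "T", "G": "A", "T": "C"}


@dataclass
class Fixture:
    """Generated fixture files plus ground truth for oracle checks."""

    seed: int
    chromosome: str
    sequence: str  # full positive-strand chromosome sequence
    minus_exons: Tuple[Tuple[int, int], Tuple[int, int]]
    plus_exons: Tuple[Tuple[int, int], Tuple[int, int]]
    minus_cds_transcript: str  # spliced CDS, transcript orientation
    plus_cds_transcript: str
    cdna_record_id: str
    cdna_sequence: str
    paths: Dict[str, Path] = field(default_factory=dict)


def _random_cds(rng: random.Random, n_codons: int) -> str:
    """A CDS of ``n_codons`` codons: ATG start, stop end, no internal stop."""
    codons = ["ATG"]
    codons += [rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2)]
    codons.append(rng.choice(("TAA", "TAG", "TGA")))
    return "".join(codons)


def _exon_len(exon: Tuple[int, int]) -> int:
    return exon[1] - exon[0] + 1


def build_fixture(seed: int) -> Fixture:
    """Construct the fixture content in memory (no files written)."""
    rng = random.Random(seed)
    background = [rng.choice("ACGT") for _ in range(CHROM_LENGTH)]

    # minus-strand gene: 135 bp CDS = 45 codons, junction after 80 bases
    minus_cds = _random_cds(rng, 45)
    hi_len = _exon_len(MINUS_EXON_HI)
    exon_hi_genomic = revcomp(minus_cds[:hi_len])
    exon_lo_genomic = revcomp(minus_cds[hi_len:])
    background[MINUS_EXON_HI[0] - 1 : MINUS_EXON_HI[1]] = list(exon_hi_genomic)
    background[MINUS_EXON_LO[0] - 1 : MINUS_EXON_LO[1]] = list(exon_lo_genomic)

    # plus-strand gene: 120 bp CDS = 40 codons, junction after 61 bases
    plus_cds = _random_cds(rng, 40)
    e1_len = _exon_len(PLUS_EXON_1)
    background[PLUS_EXON_1[0] - 1 : PLUS_EXON_1[1]] = list(plus_cds[:e1_len])
    background[PLUS_EXON_2[0] - 1 : PLUS_EXON_2[1]] = list(plus_cds[e1_len:])

    sequence = "".join(background)

    # cDNA record: the plus-strand CDS inside 30 bp of vector either side
    vector_5 = "".join(rng.choice("ACGT") for _ in range(30))
    vector_3 = "".join(rng.choice("ACGT") for _ in range(30))
    cdna_sequence = vector_5 + plus_cds + vector_3

    return Fixture(
        seed=seed,
        chromosome=CHROM,
        sequence=sequence,
        minus_exons=(MINUS_EXON_HI, MINUS_EXON_LO),
        plus_exons=(PLUS_EXON_1, PLUS_EXON_2),
        minus_cds_transcript=minus_cds,
        plus_cds_transcript=plus_cds,
        cdna_record_id="vector_tx2",
        cdna_sequence=cdna_sequence,
    )


def _gtf_line(
    feature: str, start: int, end: int, strand: str, frame: str, gene: str, tx: str
) -> str:
    attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
    return f"{CHROM}\tsatmut\t{feature}\t{start}\t{end}\t.\t{strand}\t{frame}\t{attrs}"


def _write_fasta(path: Path, fixture: Fixture) -> None:
    lines = [f">{CHROM}"]
    seq = fixture.sequence
    for i in range(0, len(seq), 60):
        lines.append(seq[i : i + 60])
    path.write_text("\n".join(lines) + "\n")
    pysam.faidx(str(path))


def _write_gtf(path: Path) -> None:
    lines = [
        # minus-strand gene: frames are GTF phases at the transcript 5' end
        _gtf_line("CDS", *MINUS_EXON_HI, "-", "0", "GENE1", "TX1"),
        _gtf_line("CDS", *MINUS_EXON_LO, "-", "1", "GENE1", "TX1"),
        _gtf_line("stop_codon", MINUS_EXON_LO[0], MINUS_EXON_LO[0] + 2, "-", "0", "GENE1", "TX1"),
        _gtf_line("UTR", MINUS_EXON_HI[1] + 1, MINUS_EXON_HI[1] + 40, "-", ".", "GENE1", "TX1"),
        _gtf_line("UTR", MINUS_EXON_LO[0] - 40, MINUS_EXON_LO[0] - 1, "-", ".", "GENE1", "TX1"),
        # exon rows must be ignored by the loader
        _gtf_line("exon", MINUS_EXON_HI[0], MINUS_EXON_HI[1] + 40, "-", ".", "GENE1", "TX1"),
        # plus-strand gene
        _gtf_line("CDS", *PLUS_EXON_1, "+", "0", "GENE2", "TX2"),
        _gtf_line("CDS", *PLUS_EXON_2, "+", "2", "GENE2", "TX2"),
        _gtf_line("exon", PLUS_EXON_1[0], PLUS_EXON_1[1], "+", ".", "GENE2", "TX2"),
    ]
    path.write_text("\n".join(lines) + "\n")


_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    f"##contig=<ID={CHROM},length={CHROM_LENGTH}>",
]


def _write_protection_vcf(path: Path, fixture: Fixture) -> None:
    seq = fixture.sequence
    lines = list(_VCF_HEADER) + [
        '##INFO=<ID=SGRNA,Number=1,Type=String,Description="sgRNA id">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for pos in (1240, 1245):
        ref = seq[pos - 1]
        lines.append(
            f"{CHROM}\t{pos}\t.\t{ref}\t{_ALT_BASE[ref]}\t.\t.\tSGRNA=sgRNA_ex2"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_custom_vcfs(
    dir_path: Path, fixture: Fixture, rng: random.Random
) -> Tuple[Path, Path, Path]:
    seq = fixture.sequence

    def base(p: int) -> str:
        return seq[p - 1]

    long_insert = "".join(rng.choice("ACGT") for _ in range(70))
    vcf1 = dir_path / "custom1.vcf"
    lines1 = list(_VCF_HEADER) + [
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        # substitution inside constant region c1 of the default targeton
        f"{CHROM}\t1120\tv_sub_c1\t{base(1120)}\t{_ALT_BASE[base(1120)]}\t.\t.\t.",
        # 2 bp deletion inside r1 (anchored per VCF)
        f"{CHROM}\t1189\tv_del_r1\t{base(1189)}{base(1190)}{base(1191)}\t{base(1189)}\t.\t.\t.",
        # 3 bp insertion inside c2
        f"{CHROM}\t1299\tv_ins_c2\t{base(1299)}\t{base(1299)}ACG\t.\t.\t.",
        # 70 bp insertion inside r2: pushes the oligo over 300 bp
        f"{CHROM}\t1229\tv_ins_long\t{base(1229)}\t{base(1229)}{long_insert}\t.\t.\t.",
    ]
    vcf1.write_text("\n".join(lines1) + "\n")

    vcf2 = dir_path / "custom2.vcf"
    lines2 = list(_VCF_HEADER) + [
        '##INFO=<ID=ALLELEID,Number=1,Type=String,Description="Allele id">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        f"{CHROM}\t1340\t.\t{base(1340)}\t{_ALT_BASE[base(1340)]}\t.\t.\tALLELEID=12345",
    ]
    vcf2.write_text("\n".join(lines2) + "\n")

    manifest = dir_path / "manifest.csv"
    manifest.write_text(
        "alias,vcf_path,id_info_tag\n"
        "custom1,custom1.vcf,\n"
        "custom2,custom2.vcf,ALLELEID\n"
    )
    return vcf1, vcf2, manifest


_TARGETON_HEADER = (
    "ref_chr\tref_strand\tref_start\tref_end\tr2_start\tr2_end\t"
    "ext_vector\taction_vector\tsgrna_ids\n"
)

# exon-style design on the minus-strand gene: 54 bp coding core with
# liminal codons at both ends (one split across the exon junction),
# 25 bp extensions (r1 intronic, r3 coding), constant flanks
DEFAULT_TARGETON_ROW = (
    f"{CHROM}\t-\t1110\t1354\t1201\t1254\t25,25\t"
    "2del1,snv,1del|snvre,inframe,ala,stop,1del|2del0,snv,1del\tsgRNA_ex2\n"
)
PLUS_TARGETON_ROW = (
    f"{CHROM}\t+\t2120\t2240\t2161\t2202\t10,10\t"
    "snv|snvre,aa|1del\t\n"
)


def _write_targeton_file(path: Path) -> None:
    path.write_text(_TARGETON_HEADER + DEFAULT_TARGETON_ROW + PLUS_TARGETON_ROW)


def _write_cdna_inputs(dir_path: Path, fixture: Fixture) -> Tuple[Path, Path]:
    fasta = dir_path / "cdna.fa"
    fasta.write_text(f">{fixture.cdna_record_id}\n{fixture.cdna_sequence}\n")
    annotation = dir_path / "cdna_annotation.csv"
    # CDS occupies record positions 31..150; r2 is the first 81 coding bases
    annotation.write_text(
        "record_id,targeton_start,targeton_end,r2_start,r2_end,"
        "ext_vector,action_vector,frame\n"
        f"{fixture.cdna_record_id},21,160,31,111,\"0,0\","
        "\"|snv,1del,snvre,inframe,ala,stop,aa|\",0\n"
    )
    return fasta, annotation


def generate_fixture(seed: int, out_dir: str | Path) -> Fixture:
    """Write the full fixture set under ``out_dir`` and return its description."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fixture = build_fixture(seed)
    rng = random.Random(seed + 1)  # variant inserts, independent of the genome

    fasta = out_dir / "genome.fa"
    _write_fasta(fasta, fixture)
    gtf = out_dir / "annotation.gtf"
    _write_gtf(gtf)
    protection = out_dir / "protection.vcf"
    _write_protection_vcf(protection, fixture)
    vcf1, vcf2, manifest = _write_custom_vcfs(out_dir, fixture, rng)
    targetons = out_dir / "targetons.tsv"
    _write_targeton_file(targetons)
    cdna_fasta, cdna_annotation = _write_cdna_inputs(out_dir, fixture)

    fixture.paths = {
        "fasta": fasta,
        "gtf": gtf,
        "protection_vcf": protection,
        "custom_vcf_1": vcf1,
        "custom_vcf_2": vcf2,
        "manifest": manifest,
        "targeton_file": targetons,
        "cdna_fasta": cdna_fasta,
        "cdna_annotation": cdna_annotation,
    }
    return fixture
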