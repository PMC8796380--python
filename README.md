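# satmut

Design engine for saturation-mutagenesis oligonucleotide libraries.

## The problem

Saturation genome editing (SGE) and related deep mutational scanning
experiments measure the functional effect of every possible variant in a
genomic region. The experiment needs a synthesized library of oligos in
which each oligo carries exactly one engineered variant of a *targeton*
— a stretch of reference sequence (typically an exon plus flanking
intronic sequence) that is replaced in the cell by homology-directed
repair or a prime-editing RTT. Designing such a library by hand is
error-prone: every single-nucleotide variant, deletion and codon-level
substitution must be enumerated against the correct reading frame, the
sgRNA's PAM/protospacer must be silently mutated in *every* oligo so the
edited allele is not re-cut, clinically observed variants from external
VCFs must be spiked in, and each final sequence must respect the
synthesis length limit.

`satmut` automates this. A targeton is partitioned into five
sub-regions, `c1-r1-r2-r3-c2`: a mutated core `r2`, optional mutated
extensions `r1`/`r3`, and constant flanks `c1`/`c2`. Each mutable region
gets its own list of *mutators*:

| mutator | effect | needs CDS annotation |
|---|---|---|
| `snv` | every single-nucleotide substitution | no (annotated if available) |
| `1del` | every 1-base deletion | no |
| `2del0`, `2del1` | tiled 2-base deletions, offset 0 / 1 | no |
| `snvre` | SNVs plus synonymous-codon completion and one backup codon per missense outcome | yes |
| `inframe` | in-frame deletion of each complete codon | yes |
| `ala` | alanine scan (top-frequency alanine codon) | yes |
| `stop` | stop scan (top-frequency stop codon) | yes |
| `aa` | substitution to all 19 other amino acids | yes |

Reading frames are resolved from a GTF on either strand, including
codons split across exon junctions; partial ("liminal") codons at region
edges receive SNVs but never codon-level substitutions. A cDNA mode runs
the same mutators on plasmid/vector sequences with relative coordinates
and an explicitly stated frame.

## Worked example

The package ships a deterministic fixture generator that writes a
complete synthetic input set (mini genome, GTF, protection VCF, custom
variant VCFs with manifest, targeton file, cDNA inputs) from one seed:

```
$ satmut fixture --seed 0 -o fixture
$ satmut sge fixture/targetons.tsv \
    --fasta fixture/genome.fa \
    --gtf fixture/annotation.gtf \
    --protection-vcf fixture/protection.vcf \
    --manifest fixture/manifest.csv \
    --adapter-5 AATGATACGGCGACCACCGA \
    --adapter-3 CAAGCAGAAGACGGCATACGAGAT \
    --revcomp-minus-strand -o out
2 targeton(s): 1088 oligos kept (971 unique), 1 excluded
```

Per targeton this writes a metadata CSV, a unique-sequence CSV, a VCF
4.2 of all generated variants, and (only when oligos exceed the length
limit) an excluded-metadata CSV, plus one run-wide `sequences_qc.csv`
of retrieved wild-type sequences:

```
$ ls out
chrT_1110_1354_minus_sgRNA_ex2.vcf
chrT_1110_1354_minus_sgRNA_ex2_excluded.csv
chrT_1110_1354_minus_sgRNA_ex2_meta.csv
chrT_1110_1354_minus_sgRNA_ex2_unique.csv
chrT_2120_2240_plus.vcf
chrT_2120_2240_plus_meta.csv
chrT_2120_2240_plus_unique.csv
sequences_qc.csv

$ head -2 out/chrT_1110_1354_minus_sgRNA_ex2_meta.csv | cut -c1-120
oligo_name,src_type,region,source,variant_id,var_type,position,ref,alt,ref_aa,alt_aa,consequence,revcomp,sequence,length
chrT_1110_1354_minus_sgRNA_ex2_r1_2del1_1177_deletion,ref,r1,2del1,,deletion,1177,GA,,,,,1,AATGATACGGCGACCACCGACGAC
```

The first targeton is a canonical exon design on the minus strand: a
54 bp coding core (`r2`) with 25 bp extensions (`r1` intronic, `r3`
coding). Its per-region oligo counts follow the closed-form laws — 3·L
SNVs, L single-base deletions, ⌊L/2⌋ and ⌊(L−1)/2⌋ tandem deletions:

```
region r1 (25 bp): snv 75, 1del 25, 2del1 12
region r2 (54 bp): snv 162, 1del 54, inframe 17, ala 17, stop 17, snvre 101
region r3 (25 bp): snv 75, 1del 25, 2del0 12
custom VCF variants: 4 (one per manifest entry and region they fall in)
```

cDNA mode uses relative coordinates and no genome:

```
$ satmut cdna fixture/cdna.fa fixture/cdna_annotation.csv -o out_cdna
1 targeton(s): 1315 oligos kept
```

Options can also be supplied in a flat YAML file via `--config`;
explicit command-line flags win over config values, which win over
defaults.

## Reproduction

The repository's single numeric acceptance target (the `2del1` count of
12 tandem two-base deletions on the 25 bp `r1` region of the canonical
exon targeton) is recomputed from scratch — fixture generation through
the full pipeline — by:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes `{"t4": {"value": 12, "n": 25}}`. The value is
seed-independent because it is a combinatorial property of the design
geometry, not of the random sequence. The full test suite runs with
`python -m pytest tests/`.

See `docs/methods.md` for the underlying model and its limitations.
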