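# Methods

This note states the model implemented by `satmut`, the parameters it
exposes, the numerical/representational choices made, and the scope and
limits of the bundled synthetic data. It makes no empirical claims
beyond what the code computes.

## Targeton model

A targeton is a contiguous reference range with strand, partitioned by
two parameters — the core range `r2` and the extension vector
`(l_ext5, l_ext3)` — into five adjacent sub-regions
`c1 | r1 | r2 | r3 | c2` on the positive strand:

- `r1` spans the `l_ext5` bases immediately before `r2`, `r3` the
  `l_ext3` bases immediately after (either may be empty);
- `c1`/`c2` are whatever remains to the targeton boundaries and are
  never mutated (only custom VCF variants may fall there).

The partition is validated to tile the targeton exactly; `r2` plus
extensions must fit inside it. Each of `r1`, `r2`, `r3` carries its own
ordered mutator list (the *action vector*).

## Reading frame

For coding regions the frame is derived from a GTF annotation
(CDS/UTR/stop_codon features; one transcript per gene is enforced).
Internally every CDS is flattened into a *spliced positional map*: the
genomic positions of coding bases in transcript order (ascending on the
plus strand, descending on the minus strand). A codon is then three
consecutive map entries, stored as ascending genomic positions; the
frame of a target region is the number of codon-mates of its
transcript-5' base that precede it. This single representation makes
the textbook frame equation

```
f_target = (f_exon + (s_target − s_exon)) mod 3
```

and the codon-completing extensions

```
l_ext5 = f_target
l_ext3 = (3 − (l_target + f_target) mod 3) mod 3
```

hold on both strands, and it handles codons split across exon junctions
without special cases. GTF phase (defined at the transcript 5' end of a
feature) is converted to this "genomic-left phase" as
`(3 − (phase + length)) mod 3` on the minus strand; a missing phase
(`.`) is computed by walking the spliced CDS.

Codons only partially inside a region ("liminal" codons) are completed
from adjacent reference context — possibly across an exon junction —
for SNV consequence annotation, but are never targets of codon-level
substitution or deletion. Each region must be homogeneous (entirely
coding or entirely non-coding); mixed regions are rejected rather than
silently split.

## Mutators

Position dialect: internally a deletion starts at its first deleted
base with an empty ALT, and an insertion at the position the inserted
bases will occupy with an empty REF. Output VCFs re-anchor events on
the preceding base per VCF 4.2 (using the retrieved base before the
targeton for events at its first position, and the following base at
contig position 1). Metadata files keep the internal dialect.

Sequence-independent count laws (length L): `snv` 3L, `1del` L,
`2del0` ⌊L/2⌋, `2del1` ⌊(L−1)/2⌋.

Codon-aware mutators operate on the complete codons of the region:

- `inframe` deletes each complete codon.
- `ala` / `stop` substitute each complete codon by the top-frequency
  alanine / stop codon, skipping codons that already equal the target
  (so counts can fall below the number of complete codons).
- `aa` substitutes each complete codon by the top-frequency codon of
  each of the 19 other amino acids; stop is not an `aa` target (stop
  gain is covered by `stop`), and the wild-type amino acid is skipped.
- `snvre` emits all SNVs (reported under source `snv`) and adds
  codon-level substitutions: (a) the synonymous codons *not* reachable
  by one SNV, so SNVs plus additions cover every synonymous alternative
  exactly once — for stop codons this includes the TGA↔TAG swap; and
  (b) for each missense SNV outcome, one backup codon encoding the same
  alternative amino acid, chosen as that amino acid's top-frequency
  codon (the next-ranked one if the SNV already produced the top
  codon), skipped when the backup would itself be one SNV away from the
  wild-type codon, and de-duplicated across SNVs reaching the same
  amino acid.

All substitutions are computed in transcript orientation and stored as
positive-strand alleles (reverse-complemented on the minus strand).

Codon ranking uses a codon-usage table (CSV: codon, amino acid,
fraction), validated against the standard genetic code. The bundled
default is a standard human codon-usage table; ties in fraction break
lexicographically so ranking is total and deterministic. Consequence
classification is syn / missense / nonsense by translating reference
and alternative codons; stop-loss is reported as missense of `*`.

## Protection and custom variants

PAM/protospacer protection edits are single-nucleotide substitutions
read from a VCF, grouped by an `SGRNA` INFO tag. All edits of the
sgRNAs named on a targeton are applied to its retrieved reference
first; the protected sequence is the basis for **every** generated
oligo, and liminal-codon context lookups also see the edits. An sgRNA
named on a targeton but absent from the protection VCF is an error.

Custom variants come from VCFs listed in a CSV manifest
(`alias, vcf_path[, id_info_tag]`); identifiers come from the VCF ID
field or the named INFO tag. Multi-allelic records are split; symbolic
alternates are skipped with a warning; a variant must start *and* end
inside the targeton. REF is checked against the original (unprotected)
reference, since public VCFs describe the genome; where a custom
variant overlaps a protection edit it is re-expressed on the protected
sequence, and variants that become no-ops are dropped with a warning.

## Assembly and outputs

Each variant is applied to the protected positive-strand targeton; for
minus-strand targetons the mutated targeton portion (never the
adapters) can be reverse-complemented (`--revcomp-minus-strand`);
adapters are appended last. Oligos strictly longer than the maximum
length (default 300 nt) are segregated into an excluded-metadata file.
Outputs per targeton: full metadata CSV, unique-final-sequence CSV
(library complexity), VCF 4.2 of all variants (unique, sorted), and the
excluded CSV only when non-empty; plus one run-wide QC CSV of retrieved
wild-type sequences.

## cDNA mode

The same mutator engine runs on user FASTA records with 1-based
coordinates relative to the record and the `r2` frame stated directly
in the annotation CSV. Extension regions are treated as non-coding.
There is no protection step, and custom VCF variants are intentionally
unsupported (the CLI does not expose a manifest option) because their
genomic coordinate semantics do not transfer to relative coordinates.
Output VCFs use the record id as contig; records are typed `cdna`.

## Synthetic data scope

The fixture generator builds, from one integer seed, a 3 kb chromosome
with two two-exon CDSs (one per strand, each with a junction-split
codon), matching GTF, protection VCF, custom-variant VCFs plus
manifest, a targeton file, and a cDNA input pair — byte-identical for
equal seeds. It exists to exercise every code path (frames on both
strands, junction-crossing context, protection, custom variants,
length exclusion) without downloading reference data. It is not a
biological dataset: exon sizes, variant positions and codon content
are arbitrary, and sequence-dependent counts (`ala`, `stop`, `snvre`
extras, unique-sequence totals) vary with the seed. Design-geometry
counts (`snv`, `1del`, `2del0`, `2del1`, `inframe`, `aa`) do not.

## Limitations

- One transcript per gene; overlapping transcript isoforms must be
  resolved upstream.
- Mutable regions may not mix coding and non-coding bases; such
  designs must be split into separate targetons.
- Regions containing `N` bases cannot be mutated.
- The backup-codon rule in `snvre` is one defensible choice (top
  codon-usage rank, hamming-distance-1 exclusion); other selection
  rules would yield different but equally valid libraries.
- No off-target, secondary-structure or synthesis-feasibility scoring
  is performed; the length filter is the only synthesis constraint.
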