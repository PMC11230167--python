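# Methods

## Problem and model

A MAVE score set pairs a submitter-supplied *target sequence* (DNA or
protein) with a matrix of MAVE-HGVS variants and functional scores. The
variants are positions on the target, not on any versioned reference, and
the target itself may be non-reference-identical (codon-optimized),
chimeric (assay adapters), or spliced (a processed transcript laid over
distant exons). The mapping model treats a variant as a located allele on a
digest-identified sequence and asks for the equivalent allele on a
reference sequence, keeping both. Identity of an allele is the digest of
its normalized content, so equality of representation is equality of
identifier, and the assayed and mapped forms are distinct objects by
construction.

## Pipeline assumptions

- Alignment blocks are gapless and conserve length; within a minus-strand
  block, ascending target positions map to descending reference positions.
  Minus-strand PSL query offsets are flipped to plus-query orientation at
  parse time so only one convention exists downstream.
- Mapping is always against the configured assembly (GRCh38 accession
  table built in); the metadata `assembly_id` is provenance only.
- Multi-unit alleles are lifted by their full span. A span crossing an
  alignment-block edge is refused with `SPANS_BLOCK_BOUNDARY` rather than
  split into per-block events; splitting would require a policy for the
  intervening intronic sequence that no current community recommendation
  fixes, and refusal keeps the unmappable accounting explicit.
- Protein variants are expanded to codon spans (frame 0 from the reconciled
  offset) for the boundary check, so a multi-residue deletion whose codons
  straddle an exon junction is refused even though the protein-level lift
  itself needs no blocks.
- On the minus strand both alleles are reverse-complemented and spans are
  end-anchored; an insertion's junction flips to the corresponding genomic
  junction (between the same two target bases, which sit in reversed order
  on the chromosome).
- The success criterion — equality of pre- and post-mapped
  `vrs_ref_allele_seq`, reverse-complemented for minus-strand nucleotide
  variants — is enforced as a postcondition. A row that fails it (a variant
  sitting exactly on a target/reference difference) is demoted to
  `UNALIGNED_REGION` with a message naming the mismatch, since
  non-homologous target content preventing a reference match is the class
  such rows belong to.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| seed length (fixture aligner) | 20 | nt | long enough that a 10 kb fixture genome has no chance collisions; short enough to re-seed between isolated mismatches |
| chaining gap limit | 2000 | nt | fixture-scale intron bound; separates spliced-exon chains from decoy placements |
| protein seed | 10 | residues | substring seed used to place the target protein in the reference protein; first occurrence wins, multiplicity is logged |
| aligner provenance | q=dna\|prot, minScore 20 | — | recorded invocation parameters for external PSL input (minimum score lowered from the tool default of 30 so short targets return hits); the aligner itself is not executed |
| hit score | matches − mismatches − gap counts | — | PSL carries no score column; this is the standard BLAT score formula |

Normalization is the SPDI overprecision-correction algorithm in its fully
justified form: trim the shared prefix then the shared suffix; a resulting
pure indel is rolled across its repeat context in both directions and
expanded to the whole ambiguity interval. Trim order (prefix first) is
fixed and frozen by golden tests. HGVS rendering re-trims to the 3'-most
minimal representation, which is what the HGVS convention expects, so a
fully justified deletion prints at its rightmost equivalent position.

Digest-relevant serialization is canonical JSON (identify-relevant fields
only, keys sorted, UTF-8, no whitespace, nested identifiable objects
replaced by their digests) — frozen by golden-file tests. Cross-tool byte
compatibility with other serializers is explicitly not an invariant.

## Design choices where the design was open

- **Discordance correction.** When the score matrix's expected reference
  residues disagree with the target, the smallest non-negative shift that
  satisfies *every* expected residue is applied to the offset; negative
  shifts (a matrix starting before the target) are rejected, and no valid
  shift is an explicit `irreconcilable discordance` error. This is the most
  conservative reading of "the offset was modified".
- **First published.** Publication dates are not operationally defined in
  the stores this package reads; a `pub_order` ordinal column stands in and
  only ever breaks exact length ties.
- **`_wt` / `_sy` rows.** Target-identical and synonymous markers are
  parsed as identity events and emitted as text variations, preserving
  score-row alignment without fabricating alleles.
- **Both variant columns.** A score set with `hgvs_nt` and `hgvs_pro`
  yields two mapping sets, one per column, mapped independently; no
  cross-column consistency check is attempted.
- **Pre-mapped normalization.** Pre-mapped alleles are normalized against
  the target sequence exactly as post-mapped ones are against the
  reference, so equivalent shifted submissions converge on both sides.
- **Stores.** The network services a production deployment would use
  (sequence repository, transcript archive, gene normalizer) are behind
  three narrow contracts with plain-file implementations (FASTA + TSV), so
  the algorithmics are testable offline; UniProt canonical sequences are
  ordinary `uniprot:`-namespaced store entries rather than a web lookup.
  Intermediate and final outputs are deterministic JSON (gzip with fixed
  mtime), not pickles.

## The synthetic fixtures

The generator emulates, per score set: a 10 kb chromosome (reserved
`NC_TEST*` accession namespace so fixture data can never be mistaken for
real reference data) carrying a three-exon gene (exon lengths 120/90/150 nt,
codon multiples, introns 400 nt) on either strand; one MANE Select
transcript, a shorter non-MANE coding transcript, a non-coding transcript,
and a distant copy of exon 1 as a competing placement. The target is carved
from the CDS at residue offset 5, trimmed 5 residues before the stop, with
two synonymous codon swaps (kept >25 nt from exon edges so alignment blocks
stay exact) and a 30 nt non-homologous 3' adapter. Adapters sit at the 3'
end only: the offset procedure seeds on the first ten translated residues,
so 5' adapter content would fail the whole protein pass rather than
individual rows — the 3' placement exercises unaligned-content rows at the
nucleotide layer and flips `full_match` to false at the protein layer, which
is the behavior worth testing. Intron bases adjacent to each splice
junction are resampled to differ from the exonic continuation, so greedy
block extension cannot run past a junction.

Default row mix (200 rows): 5% each of adapter-region, boundary-spanning,
past-target-length, and synonymous-site variants; the rest
reference-identical substitutions, deletions, insertions and two-member
cis-groups, placed at sites chosen to be roll-unambiguous (checked by
string equality on both the target and reference contexts) and clear of
block edges and codon swaps, so the truth table can state normalized spans
exactly. The truth table is computed from the generator's own layout
arithmetic (exon placement and a direct per-base walk), sharing no lifting
code with the pipeline.

What the fixtures do **not** emulate: realistic score distributions,
sequencing error, gapped (indel-containing) alignments, multi-isoform
ambiguity, or genome-scale repeat content. Passing tests therefore
demonstrate the correctness of the mapping arithmetic and normalization
under controlled homology structure, not robustness to noisy real-world
alignments; real deployments also depend on live store contents and an
external aligner, both outside these tests.

## Numerical and degenerate-input conventions

- Positions are 1-based in variant strings, interbase everywhere inside
  the VRS layer; the conversion happens exactly once, at allele
  construction.
- Percent coverage and identity are rounded to 2 decimals; identity with
  zero aligned bases is an error, not 0.
- Translation uses the standard codon table; stops render `*` and
  translation continues (targets may tile past a stop); a trailing partial
  codon is dropped; ambiguous bases are an error naming the codon index.
- Unknown residue codes in variant strings raise rather than guess.
- Equidistant HSPs and equal-score hits keep input order.
- Empty scores stay missing end to end (never coerced to 0).

## Problem sizes used in tests and the acceptance script

Ten generated score sets (seeds 1-5 x both strands, 200 rows each,
10 kb genome), 1000 random indel contexts for the normalization oracle,
101 byte strings for the digest oracle. These sizes exercise every code
path deliberately placed in the fixtures while keeping the whole suite in
the low seconds; agreement is exact (100%) at these sizes, so larger
fixture corpora would add runtime, not information, under the same
generator assumptions.

## Known limitations

- The headline corpus statistics of a full-repository run (millions of
  variants, hundreds of score sets) require the live repository, a genome
  aligner and reference services, and are out of scope offline.
- No gap-aware lifting through reference insertions/deletions: blocks are
  gapless by construction.
- VRS-2.x object shapes, copy-number classes and composed sequence
  expressions are not modeled; unsupported classes survive as text
  variations.
- The fixture aligner is a stand-in for BLAT on controlled fixtures; it is
  not a general-purpose aligner and makes no sensitivity claims.
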