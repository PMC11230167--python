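# mave-anchor

Map variants from multiplexed assays of variant effect (MAVEs) onto human
reference sequences.

MAVE repositories such as MaveDB store thousands of functional scores per
experiment, but the variants are described in MAVE-HGVS against an
**assay-specific target sequence** (`p.Ala40Ser`, `n.2G>A`) rather than a
versioned reference accession. Target sequences may differ from the
reference (synonymous codon optimization), may carry assay-specific adapter
content that does not exist in the genome, and may splice across exons that
are far apart on the chromosome. `mave-anchor` lifts each variant onto a
reference sequence while preserving the original representation: every score
row yields a **pre-mapped** allele (on the digest-identified target
sequence) and a **post-mapped** allele (on a RefSeq protein or GRCh38
chromosome accession), both as digest-identified VRS-style objects, so the
assayed and reference-anchored forms have distinct, stable, computable
identifiers.

It is written for curators and tool builders who want MAVE scores to
interoperate with reference-based resources (genome browsers, variant
annotators, clinical variant databases) without losing provenance.

## Method

The workflow runs in three phases:

1. **Alignment.** The target sequence is aligned to the genome (BLAT-style
   PSL input is parsed; a built-in deterministic aligner covers the bundled
   fixture genome). When a UniProt accession is available it is normalized
   to a gene symbol and chromosome, and the hit on that chromosome is kept;
   among several block sets the one whose first block starts nearest the
   gene start wins. Without gene context the top-scoring hit is used.
2. **Transcript selection and offset.** Transcripts overlapping every
   alignment block are intersected; non-coding records are dropped; the
   survivor is chosen by rank — MANE Select, then MANE Plus Clinical, then
   the longest transcript, with first publication breaking ties. The (DNA
   targets: translated) target protein is located in the reference protein
   by a 10-residue seed, giving the residue offset `r`; a discordance pass
   compares the score matrix's expected reference residues (e.g.
   `{1: M, 2: A, ...}`) to the target and corrects `r` by the smallest
   consistent shift. Regulatory / other noncoding score sets skip this phase.
3. **Variant mapping.** Each row is parsed (semicolon cis-groups become
   haplotypes, unsupported classes become text variations), positions are
   lifted — protein: `pos + r`; nucleotide: through the alignment blocks,
   end-anchored on the minus strand — and both representations are
   normalized with the SPDI overprecision-correction algorithm (fully
   justified indels), digest-identified with `sha512t24u`
   (base64url(SHA-512(x)[:24])), annotated with `vrs_ref_allele_seq`, and
   the post-mapped allele gets an HGVS expression such as
   `NC_000006.12:g.37808023C>A`.

A mapping is **successful** when the pre- and post-mapped reference alleles
agree (reverse-complemented for minus-strand nucleotide variants, e.g. pre
`GAT` / post `ATC`); the pipeline enforces this as a postcondition. Variants
that cannot be lifted are kept with an explicit reason from a closed
taxonomy: `SPANS_BLOCK_BOUNDARY` (protein change across an exon boundary),
`UNALIGNED_REGION` (non-homologous target content), `OUTSIDE_TARGET`
(position past the target length), `NO_TRANSCRIPT`, `NO_HIT`.

## Worked example

Generate a synthetic score set with a known-answer truth table, map it, and
validate the result:

```
$ mave-anchor fixtures --seed 1 --out demo
wrote urn:mavedb:90000001-p-1: 200 rows under demo

$ mave-anchor map --meta demo/META.json --scores demo/SCORES.csv \
      --stores demo/stores --out demo/mapped.json.gz
urn:mavedb:90000001-p-1 [p]: 50/60 rows mapped
urn:mavedb:90000001-p-1 [g]: 120/140 rows mapped

$ mave-anchor validate demo/mapped.json.gz
{"pairs": 170, "pairs_valid": 170, "bad_identifiers": 0}
```

The score set has 200 rows: 60 protein-layer rows (50 mappable by design,
10 deletions spanning exon boundaries) and 140 nucleotide-layer rows (120
mappable, 10 in the non-aligning 3' adapter, 10 beyond the target length) —
so 170/200 rows map, exactly the designed 85%, and every mapped pre/post
pair passes the reference-allele check. One mapped row from the output:

```json
{
  "row": 0,
  "pre_mapped": {
    "id": "ga4gh:VA.e4Qe-AiEyD7f0XiheYFfQ3Rfarp9Kpfs",
    "location": {"sequence_id": "ga4gh:SQ.FmliCHdezu9t2o143QjlLNrC9tTynBrV",
                 "start": 14, "end": 15},
    "state": {"type": "LiteralSequenceExpression", "sequence": "K"},
    "vrs_ref_allele_seq": "F"
  },
  "post_mapped": {
    "id": "ga4gh:VA.KY10oTQr2qFY6lL0nBt83pANeprPkqso",
    "location": {"sequence_id": "ga4gh:SQ.y6hqdjQeIRLrHWvZ8vZvHaABEhc-g1HT",
                 "start": 19, "end": 20},
    "state": {"type": "LiteralSequenceExpression", "sequence": "K"},
    "vrs_ref_allele_seq": "F",
    "expressions": ["NP_TEST001.1:p.Phe20Lys"]
  },
  "score": 0.353
}
```

The row's `p.Phe15Lys` on the target maps to residue 20 of the reference
protein (the target was carved at residue offset 5); pre- and post-mapped
objects carry the same reference residue `F` but distinct identifiers, one
anchored to the target-sequence digest and one to `NP_TEST001.1`.

The same `map` command accepts real inputs: a MaveDB-style metadata JSON,
a `hgvs_nt`/`hgvs_pro`/`score` CSV, a BLAT PSL file via `--psl`, and a
store directory (FASTA sequences plus transcript/gene/identifier TSV
tables) standing in for the sequence-repository and transcript-archive
services.

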