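"""Deterministic synthetic reference + score-set generator with known answers.

Builds a small genome (one fixture chromosome in a reserved ``NC_TEST*``
accession namespace) carrying a multi-exon protein-coding gene on either
strand, the matching transcript/gene/protein store tables, and score sets
whose rows exercise every mapping challenge: reference-identical variants,
synonymous codon differences between target and reference, non-aligning
assay adapters, protein changes spanning exon boundaries, and variants past
the target length.  Every generated row comes with an independently
constructed truth entry (expected post-mapped span/alleles or unmappable
reason) derived purely from the generator's own layout arithmetic — the
generator shares no lifting code with the pipeline, so truth agreement is a
real end-to-end check.

Everything is a pure function of the seed.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .errors import MaveAnchorError
from .pipeline import ScoreRow, ScoreSetMetadata
from .stores import ReferenceStores

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS]

_AA_1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic score set.

    Fractions allocate variant rows to the challenge classes; the remainder
    are reference-identical, plainly mappable variants.  The seed fully
    determines every output byte.
    """

    seed: int = 1
    n_exons: int = 3
    exon_lengths: tuple[int, ...] = (120, 90, 150)
    strand: str = "+"
    n_variants: int = 200
    frac_synonymous: float = 0.05
    frac_adapter: float = 0.05
    frac_boundary: float = 0.05
    frac_outside: float = 0.05
    chrom_len: int = 10_000
    gene_start: int = 2_000
    intron_len: int = 400
    adapter_len: int = 30
    core_start_res: int = 5     # residue offset of the carved target in the protein
    core_trim_res: int = 5      # residues trimmed off the protein's tail
    target_type: str = "protein_coding"
    target_sequence_type: str = "dna"
    chromosome: str = "chrT"
    chrom_accession: str = "NC_TEST00.1"

    def __post_init__(self) -> None:
        if self.frac_synonymous + self.frac_adapter + self.frac_boundary + self.frac_outside > 1:
            raise MaveAnchorError("variant class fractions sum to more than 1")
        if self.strand not in "+-":
            raise MaveAnchorError(f"bad strand {self.strand!r}")
        adjusted = tuple(max(30, l - l % 3) for l in self.exon_lengths[: self.n_exons])
        if adjusted != tuple(self.exon_lengths[: self.n_exons]):
            logger.info("exon lengths adjusted to codon multiples: %s", adjusted)
        object.__setattr__(self, "exon_lengths", adjusted)

    @property
    def urn(self) -> str:
        return f"urn:mavedb:9{self.seed:07d}-{self.strand == '-' and 'm' or 'p'}-1"


@dataclass
class FixtureReference:
    """The generated genome plus the layout facts the truth table needs."""

    spec: FixtureSpec
    chrom_seq: str
    exons: list[tuple[int, int]]        # genomic interbase spans, genomic order
    cds: str                            # transcript-space coding sequence
    protein: str
    directory: Path | None = None

    @property
    def strand(self) -> str:
        return self.spec.strand

    def genomic_of_cds(self, j: int) -> int:
        """Genomic coordinate (interbase start of the base) of CDS index ``j``."""
        total = sum(e - s for s, e in self.exons)
        concat_idx = j if self.strand == "+" else total - 1 - j
        cursor = 0
        for g_start, g_end in self.exons:
            size = g_end - g_start
            if concat_idx < cursor + size:
                return g_start + (concat_idx - cursor)
            cursor += size
        raise MaveAnchorError(f"CDS index {j} outside exons")


def generate_reference(spec: FixtureSpec, out_dir: str | Path) -> FixtureReference:
    """Write the fixture store files (FASTA + TSVs) and return the layout.

    The fixture gene gets one MANE Select transcript covering all exons, a
    shorter non-MANE coding decoy, and a non-coding decoy; a copy of the
    first exon is planted far from the gene so hit selection has a competing
    placement to reject.  Intron bases flanking each splice junction are
    forced to differ from the adjacent exonic continuation so alignment
    blocks end exactly at exon boundaries.
    """
    rng = random.Random(f"ref-{spec.seed}-{spec.strand}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_res = sum(spec.exon_lengths) // 3
    codons = ["ATG"] + [rng.choice(_CODONS) for _ in range(n_res - 1)]
    cds = "".join(codons)
    protein = str(Seq(cds).translate())

    exons = []
    cursor = spec.gene_start
    for length in spec.exon_lengths:
        exons.append((cursor, cursor + length))
        cursor += length + spec.intron_len
    gene_end = exons[-1][1]
    if gene_end + 3000 > spec.chrom_len:
        raise MaveAnchorError("chromosome too short for the requested gene")

    chrom = [rng.choice(_BASES) for _ in range(spec.chrom_len)]
    concat = cds if spec.strand == "+" else _rc(cds)
    cursor = 0
    for g_start, g_end in exons:
        size = g_end - g_start
        chrom[g_start:g_end] = concat[cursor : cursor + size]
        cursor += size
    # splice distinguishability: intron edges differ from exonic continuation
    cursor = 0
    for i in range(len(exons) - 1):
        cursor += exons[i][1] - exons[i][0]
        first_next = concat[cursor]                 # first base of next exon content
        last_prev = concat[cursor - 1]              # last base of this exon content
        intron_first = exons[i][1]
        intron_last = exons[i + 1][0] - 1
        chrom[intron_first] = rng.choice([b for b in _BASES if b != first_next])
        chrom[intron_last] = rng.choice([b for b in _BASES if b != last_prev])
    # decoy placement: copy of the first exon, far beyond chaining reach
    decoy_start = spec.chrom_len - 1500
    e0_start, e0_end = exons[0]
    chrom[decoy_start : decoy_start + (e0_end - e0_start)] = chrom[e0_start:e0_end]
    chrom_seq = "".join(chrom)

    # short coding decoy over the first two exons (genomic order)
    t2_exons = exons[:2]
    t2_concat = chrom_seq[t2_exons[0][0]:t2_exons[0][1]] + chrom_seq[t2_exons[1][0]:t2_exons[1][1]]
    t2_tx = t2_concat if spec.strand == "+" else _rc(t2_concat)
    t2_protein = str(Seq(t2_tx[: len(t2_tx) - len(t2_tx) % 3]).translate())

    def exon_str(spans):
        return ";".join(f"{s}-{e}" for s, e in spans)

    (out / "genome.fa").write_text(f">{spec.chromosome}\n{chrom_seq}\n")
    (out / "proteins.fa").write_text(
        f">NP_TEST001.1\n{protein}\n"
        f">NP_TEST002.1\n{t2_protein}\n"
        f">uniprot:TEST01\n{protein}\n"
    )
    header = "tx_accession\tprotein_accession\tis_coding\tmane_status\tlength\tpub_order\tchromosome\tgene\tstrand\texons"
    rows = [
        ["NM_TEST001.1", "NP_TEST001.1", "true", "MANE Select",
         str(sum(spec.exon_lengths)), "1", spec.chromosome, "TGT1", spec.strand, exon_str(exons)],
        ["NM_TEST002.1", "NP_TEST002.1", "true", "none",
         str(sum(e - s for s, e in t2_exons)), "2", spec.chromosome, "TGT1", spec.strand, exon_str(t2_exons)],
        ["NR_TEST003.1", "", "false", "none",
         str(sum(spec.exon_lengths)), "3", spec.chromosome, "TGT1", spec.strand, exon_str(exons)],
    ]
    (out / "transcripts.tsv").write_text(
        header + "\n" + "\n".join("\t".join(r) for r in rows) + "\n"
    )
    (out / "genes.tsv").write_text(
        "symbol\tuniprot\tchromosome\tstart\tend\n"
        f"TGT1\tTEST01\t{spec.chromosome}\t{exons[0][0]}\t{gene_end}\n"
        "BRK1\tBROKEN1\t\t0\t0\n"
    )
    (out / "identifiers.tsv").write_text(
        "label\tassembly\taccession\n"
        f"{spec.chromosome}\tGRCh38\t{spec.chrom_accession}\n"
    )
    return FixtureReference(
        spec=spec, chrom_seq=chrom_seq, exons=exons, cds=cds, protein=protein,
        directory=out,
    )


def _synonymous_swap(codon: str, rng: random.Random) -> str | None:
    """A codon encoding the same residue but differing in sequence, if any."""
    aa = str(Seq(codon).translate())
    options = [c for c in _CODONS if c != codon and str(Seq(c).translate()) == aa]
    return rng.choice(options) if options else None


def _deletion_is_ambiguous(context: str, start: int, end: int) -> bool:
    """True if deleting ``[start, end)`` can roll left or right in ``context``."""
    d = end - start
    left = start > 0 and context[start - 1] == context[start - 1 + d]
    right = end < len(context) and context[end] == context[end - d]
    return left or right


def _insertion_is_ambiguous(context: str, pos: int, ins: str) -> bool:
    left = pos > 0 and context[pos - 1] == ins[-1]
    right = pos < len(context) and context[pos] == ins[0]
    return left or right


@dataclass
class TruthEntry:
    """Expected outcome for one generated score row (one layer)."""

    row: int
    layer: str                  # "nt" | "pro"
    hgvs: str
    outcome: str                # "allele" | "haplotype" | an unmappable reason code
    accession: str = ""
    starts: list[int] = field(default_factory=list)     # interbase, post-mapped
    ends: list[int] = field(default_factory=list)
    refs: list[str] = field(default_factory=list)       # plus-strand reference alleles
    alts: list[str] = field(default_factory=list)

    def to_csv_row(self) -> list[str]:
        return [
            str(self.row), self.layer, self.hgvs, self.outcome, self.accession,
            ";".join(map(str, self.starts)), ";".join(map(str, self.ends)),
            ";".join(self.refs), ";".join(self.alts),
        ]


def generate_scoreset(
    spec: FixtureSpec,
    ref: FixtureReference,
    out_dir: str | Path | None = None,
) -> tuple[ScoreSetMetadata, list[ScoreRow], list[TruthEntry]]:
    """Carve a target from the fixture transcript and draw variant rows.

    The target is a codon-aligned slice of the CDS, optionally with
    synonymous codon swaps (the target then differs from the reference at
    the nucleotide layer but not the protein layer) and a 3' non-homologous
    adapter.  Rows are drawn per the requested class fractions; the truth
    entries give, per row, the expected post-mapped accession/span/alleles
    (plus-strand, normalized) or the expected unmappable reason code.
    """
    rng = random.Random(f"scores-{spec.seed}-{spec.strand}")
    ccs = spec.core_start_res * 3
    cce = len(ref.cds) - spec.core_trim_res * 3
    core = ref.cds[ccs:cce]
    core_nt = len(core)
    core_res = core_nt // 3
    offset = spec.core_start_res

    # exon junction positions in target nt space (1-based: junction after j);
    # transcript exon order is the reverse of genomic order on the minus strand
    tx_lengths = (
        spec.exon_lengths if spec.strand == "+" else tuple(reversed(spec.exon_lengths))
    )
    junctions = []
    cursor = 0
    for length in tx_lengths[:-1]:
        cursor += length
        junctions.append(cursor - ccs)

    # synonymous codon swaps, well inside one exon block
    swap_residues: list[int] = []   # 1-based target-protein residues
    target = core
    if spec.frac_synonymous > 0:
        n_swaps = 2
        candidates = [
            r for r in range(1, core_res + 1)
            if all(abs((r - 1) * 3 - j) > 25 and abs(r * 3 - j) > 25 for j in junctions)
            and (r - 1) * 3 > 25 and r * 3 < core_nt - 25
        ]
        rng.shuffle(candidates)
        chars = list(target)
        for r in candidates:
            if len(swap_residues) == n_swaps:
                break
            codon = target[(r - 1) * 3 : r * 3]
            swapped = _synonymous_swap(codon, rng)
            if swapped is None:
                continue
            chars[(r - 1) * 3 : r * 3] = swapped
            swap_residues.append(r)
        target = "".join(chars)

    # 3' non-homologous adapter (a 5' adapter would break the protein seed)
    if spec.frac_adapter > 0:
        adapter = "".join(rng.choice(_BASES) for _ in range(spec.adapter_len))
        # forbid alignment-block extension across the core/adapter junction
        if spec.strand == "+":
            adj = ref.chrom_seq[ref.genomic_of_cds(cce - 1) + 1]
            banned = adj
        else:
            adj = ref.chrom_seq[ref.genomic_of_cds(cce - 1) - 1]
            banned = adj.translate(_COMPLEMENT)
        if adapter[0] == banned:
            adapter = rng.choice([b for b in _BASES if b != banned]) + adapter[1:]
        target = target + adapter

    target_protein = str(Seq(target[: len(target) - len(target) % 3]).translate())
    swap_nt = {
        p for r in swap_residues for p in range((r - 1) * 3 + 1, r * 3 + 1)
    }

    def gmap(t: int) -> int:
        """1-based target nt position -> genomic coordinate (interbase start)."""
        return ref.genomic_of_cds(ccs + t - 1)

    def block_of(t: int) -> int:
        b = 0
        for j in junctions:
            if t > j:
                b += 1
        return b

    def post_nt(span_start: int, span_end: int, alt: str) -> tuple[int, int, str, str]:
        """Target nt span (1-based incl.) + alt -> plus-strand genomic allele."""
        g1, g2 = gmap(span_start), gmap(span_end)
        lo, hi = (g1, g2 + 1) if spec.strand == "+" else (g2, g1 + 1)
        ref_seq = ref.chrom_seq[lo:hi]
        post_alt = alt if spec.strand == "+" else _rc(alt)
        return lo, hi, ref_seq, post_alt

    n = spec.n_variants
    n_adapter = round(spec.frac_adapter * n)
    n_boundary = round(spec.frac_boundary * n)
    n_outside = round(spec.frac_outside * n)
    n_syn = round(spec.frac_synonymous * n) if swap_residues else 0
    n_plain = n - n_adapter - n_boundary - n_outside - n_syn
    plan = (
        ["plain_nt_sub"] * (n_plain * 40 // 100)
        + ["plain_nt_del"] * (n_plain * 15 // 100)
        + ["plain_nt_ins"] * (n_plain * 15 // 100)
        + ["plain_pro_del"] * (n_plain * 5 // 100)
        + ["plain_cis"] * (n_plain * 5 // 100)
    )
    plan += ["plain_pro_sub"] * (n_plain - len(plan))
    plan += ["syn_pro_sub"] * n_syn
    plan += ["boundary_pro_del"] * n_boundary
    plan += ["adapter_nt_sub"] * n_adapter
    plan += ["outside_nt_sub"] * n_outside
    rng.shuffle(plan)

    def sample_plain_nt(width: int) -> int:
        """1-based start such that [start, start+width-1] sits inside one
        block, clear of swaps and block edges."""
        for _ in range(1000):
            s = rng.randint(6, core_nt - width - 5)
            span = range(s, s + width)
            if any(p in swap_nt or p - 1 in swap_nt or p + 1 in swap_nt for p in span):
                continue
            if block_of(s) != block_of(s + width - 1):
                continue
            if any(abs(s - j) <= 5 or abs(s + width - 1 - j) <= 5 for j in junctions):
                continue
            return s
        raise MaveAnchorError("could not place a plain nucleotide variant")

    def other_base(b: str) -> str:
        return rng.choice([x for x in _BASES if x != b])

    def other_res(r: str) -> str:
        return rng.choice([x for x in _RESIDUES if x != r])

    rows: list[ScoreRow] = []
    truth: list[TruthEntry] = []

    for idx, kind in enumerate(plan):
        score = None if rng.random() < 0.03 else round(rng.gauss(0.0, 1.0), 4)
        if kind == "plain_nt_sub":
            s = sample_plain_nt(1)
            ref_b = target[s - 1]
            alt_b = other_base(ref_b)
            hgvs = f"c.{s}{ref_b}>{alt_b}"
            lo, hi, rseq, aseq = post_nt(s, s, alt_b)
            rows.append(ScoreRow(hgvs_nt=hgvs, score=score))
            truth.append(TruthEntry(idx, "nt", hgvs, "allele", spec.chrom_accession,
                                    [lo], [hi], [rseq], [aseq]))
        elif kind == "plain_nt_del":
            for _ in range(1000):
                d = rng.randint(1, 3)
                s = sample_plain_nt(d)
                if not _deletion_is_ambiguous(target, s - 1, s - 1 + d):
                    break
            hgvs = f"c.{s}del" if d == 1 else f"c.{s}_{s + d - 1}del"
            lo, hi, rseq, aseq = post_nt(s, s + d - 1, "")
            rows.append(ScoreRow(hgvs_nt=hgvs, score=score))
            truth.append(TruthEntry(idx, "nt", hgvs, "allele", spec.chrom_accession,
                                    [lo], [hi], [rseq], [aseq]))
        elif kind == "plain_nt_ins":
            for _ in range(1000):
                ins = "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 2)))
                s = sample_plain_nt(2)  # junction between s and s+1, same block
                if not _insertion_is_ambiguous(target, s, ins):
                    break
            hgvs = f"c.{s}_{s + 1}ins{ins}"
            g1 = gmap(s)
            pos = g1 + 1 if spec.strand == "+" else g1
            post_alt = ins if spec.strand == "+" else _rc(ins)
            rows.append(ScoreRow(hgvs_nt=hgvs, score=score))
            truth.append(TruthEntry(idx, "nt", hgvs, "allele", spec.chrom_accession,
                                    [pos], [pos], [""], [post_alt]))
        elif kind == "plain_cis":
            s1 = sample_plain_nt(1)
            s2 = sample_plain_nt(1)
            while abs(s2 - s1) < 3:
                s2 = sample_plain_nt(1)
            s1, s2 = sorted((s1, s2))
            r1, r2 = target[s1 - 1], target[s2 - 1]
            a1, a2 = other_base(r1), other_base(r2)
            hgvs = f"c.[{s1}{r1}>{a1};{s2}{r2}>{a2}]"
            lo1, hi1, rs1, as1 = post_nt(s1, s1, a1)
            lo2, hi2, rs2, as2 = post_nt(s2, s2, a2)
            rows.append(ScoreRow(hgvs_nt=hgvs, score=score))
            truth.append(TruthEntry(idx, "nt", hgvs, "haplotype", spec.chrom_accession,
                                    [lo1, lo2], [hi1, hi2], [rs1, rs2], [as1, as2]))
        elif kind in ("plain_pro_sub", "syn_pro_sub"):
            if kind == "syn_pro_sub":
                r = rng.choice(swap_residues)
            else:
                for _ in range(1000):
                    r = rng.randint(1, core_res)
                    if r not in swap_residues:
                        break
            ref_r = target_protein[r - 1]
            alt_r = other_res(ref_r)
            hgvs = f"p.{_AA_1TO3[ref_r]}{r}{_AA_1TO3[alt_r]}"
            rows.append(ScoreRow(hgvs_pro=hgvs, score=score))
            truth.append(TruthEntry(idx, "pro", hgvs, "allele", "NP_TEST001.1",
                                    [r - 1 + offset], [r + offset], [ref_r], [alt_r]))
        elif kind == "plain_pro_del":
            for _ in range(1000):
                width = rng.randint(2, 3)
                r1 = rng.randint(3, core_res - width - 2)
                r2 = r1 + width - 1
                if block_of((r1 - 1) * 3 + 1) != block_of(r2 * 3):
                    continue
                if any(r in swap_residues for r in range(r1 - 1, r2 + 2)):
                    continue
                amb_t = _deletion_is_ambiguous(target_protein, r1 - 1, r2)
                amb_r = _deletion_is_ambiguous(
                    ref.protein, r1 - 1 + offset, r2 + offset
                )
                if not amb_t and not amb_r:
                    break
            seg = target_protein[r1 - 1 : r2]
            hgvs = f"p.{_AA_1TO3[seg[0]]}{r1}_{_AA_1TO3[seg[-1]]}{r2}del"
            rows.append(ScoreRow(hgvs_pro=hgvs, score=score))
            truth.append(TruthEntry(idx, "pro", hgvs, "allele", "NP_TEST001.1",
                                    [r1 - 1 + offset], [r2 + offset], [seg], [""]))
        elif kind == "boundary_pro_del":
            j = rng.choice(junctions)
            jr = j // 3
            r1 = jr - rng.randint(0, 1)
            r2 = jr + 1 + rng.randint(0, 1)
            seg = target_protein[r1 - 1 : r2]
            hgvs = f"p.{_AA_1TO3[seg[0]]}{r1}_{_AA_1TO3[seg[-1]]}{r2}del"
            rows.append(ScoreRow(hgvs_pro=hgvs, score=score))
            truth.append(TruthEntry(idx, "pro", hgvs, "SPANS_BLOCK_BOUNDARY"))
        elif kind == "adapter_nt_sub":
            s = rng.randint(core_nt + 3, len(target) - 2)
            ref_b = target[s - 1]
            alt_b = other_base(ref_b)
            hgvs = f"c.{s}{ref_b}>{alt_b}"
            rows.append(ScoreRow(hgvs_nt=hgvs, score=score))
            truth.append(TruthEntry(idx, "nt", hgvs, "UNALIGNED_REGION"))
        elif kind == "outside_nt_sub":
            s = rng.randint(len(target) + 1, len(target) + 20)
            ref_b = rng.choice(_BASES)
            hgvs = f"c.{s}{ref_b}>{other_base(ref_b)}"
            rows.append(ScoreRow(hgvs_nt=hgvs, score=score))
            truth.append(TruthEntry(idx, "nt", hgvs, "OUTSIDE_TARGET"))
        else:  # pragma: no cover
            raise MaveAnchorError(f"unknown plan entry {kind!r}")

    meta = ScoreSetMetadata(
        urn=spec.urn,
        target_sequence=target,
        target_sequence_type="dna",
        target_name="TGT1",
        assembly_id="GRCh38",
        uniprot_id="TEST01",
        target_type=spec.target_type,
    )
    if out_dir is not None:
        _write_scoreset_files(Path(out_dir), meta, rows, truth)
    return meta, rows, truth


def generate_noncoding_scoreset(
    spec: FixtureSpec,
    ref: FixtureReference,
    region: tuple[int, int] = (4500, 4800),
    n_variants: int = 40,
) -> tuple[ScoreSetMetadata, list[ScoreRow], list[TruthEntry]]:
    """A regulatory/other-noncoding score set: a contiguous intergenic slice
    (reverse-complemented for minus-strand specs), nucleotide variants only,
    no UniProt context — transcript selection is skipped downstream."""
    rng = random.Random(f"noncoding-{spec.seed}-{spec.strand}")
    lo, hi = region
    slice_seq = ref.chrom_seq[lo:hi]
    target = slice_seq if spec.strand == "+" else _rc(slice_seq)
    L = len(target)

    def gmap(t: int) -> int:
        return lo + t - 1 if spec.strand == "+" else hi - t

    rows, truth = [], []
    for idx in range(n_variants):
        score = round(rng.gauss(0.0, 1.0), 4)
        s = rng.randint(2, L - 1)
        ref_b = target[s - 1]
        alt_b = rng.choice([x for x in _BASES if x != ref_b])
        hgvs = f"n.{s}{ref_b}>{alt_b}"
        g = gmap(s)
        post_alt = alt_b if spec.strand == "+" else _rc(alt_b)
        rows.append(ScoreRow(hgvs_nt=hgvs, score=score))
        truth.append(TruthEntry(idx, "nt", hgvs, "allele", spec.chrom_accession,
                                [g], [g + 1], [ref.chrom_seq[g]], [post_alt]))
    meta = ScoreSetMetadata(
        urn=spec.urn.replace("-1", "-nc"),
        target_sequence=target,
        target_sequence_type="dna",
        target_name="TGT1 promoter",
        assembly_id="GRCh38",
        uniprot_id=None,
        target_type="regulatory_other_noncoding",
    )
    return meta, rows, truth


def _write_scoreset_files(
    out: Path, meta: ScoreSetMetadata, rows: list[ScoreRow], truth: list[TruthEntry]
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "META.json").write_text(json.dumps({
        "urn": meta.urn,
        "target_sequence": meta.target_sequence,
        "target_sequence_type": meta.target_sequence_type,
        "target_name": meta.target_name,
        "assembly_id": meta.assembly_id,
        "uniprot_id": meta.uniprot_id,
        "target_type": meta.target_type,
    }, indent=2))
    lines = ["hgvs_nt,hgvs_pro,score"]
    for r in rows:
        score = "" if r.score is None else repr(r.score)
        lines.append(f"{r.hgvs_nt or ''},{r.hgvs_pro or ''},{score}")
    (out / "SCORES.csv").write_text("\n".join(lines) + "\n")
    header = "row\tlayer\thgvs\toutcome\taccession\tstarts\tends\trefs\talts"
    (out / "TRUTH.csv").write_text(
        header + "\n" + "\n".join("\t".join(t.to_csv_row()) for t in truth) + "\n"
    )


def generate_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[ReferenceStores, ScoreSetMetadata, list[ScoreRow], list[TruthEntry]]:
    """Reference + score set + loaded stores in one call (used by tests/CLI)."""
    ref = generate_reference(spec, Path(out_dir) / "stores")
    meta, rows, truth = generate_scoreset(spec, ref, Path(out_dir))
    stores = ReferenceStores.load(Path(out_dir) / "stores")
    return stores, meta, rows, truth
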