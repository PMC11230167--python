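"""PSL alignment parsing, hit/HSP selection, and a fixture aligner.

Target sequences are aligned to the genome with BLAT (query type ``dna`` or
``prot``, minimum score lowered to 20 so short targets still return hits);
this package consumes BLAT's 21-column PSL output rather than running the
aligner itself.  A deterministic k-mer seed aligner over the fixture genome
stands in for BLAT in tests, so no external binary is required.

All block coordinates are 0-based half-open.  Minus-strand query offsets are
flipped to plus-query orientation at parse time, so downstream lifting sees a
single convention: within a minus-strand block, ascending query positions map
to descending reference positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AlignmentError, NoCompatibleHitError
from .stores import GeneContext, ReferenceStores

# Provenance of the (unexecuted) BLAT invocation these parsers expect.
BLAT_PARAMS = {"q": "dna|prot", "minScore": 20, "default_minScore": 30}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SEED_LENGTH = 20          # exact k-mer seed for the fixture aligner
MAX_INTRON = 2000         # fixture-scale block-chaining gap limit


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapless aligned block: query span <-> reference span, equal lengths."""

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if self.query_end - self.query_start != self.ref_end - self.ref_start:
            raise AlignmentError(
                f"block spans differ: query [{self.query_start},{self.query_end}) "
                f"vs ref [{self.ref_start},{self.ref_end})"
            )
        if self.query_end <= self.query_start:
            raise AlignmentError("block spans must be strictly positive")

    @property
    def size(self) -> int:
        return self.query_end - self.query_start


@dataclass
class AlignmentHit:
    """One PSL row: a block set (HSP) on one chromosome and strand."""

    chromosome: str
    strand: str
    score: int
    matches: int
    mismatches: int
    blocks: list[AlignmentBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks.sort(key=lambda b: b.query_start)
        prev_end = -1
        for b in self.blocks:
            if b.query_start < prev_end:
                raise AlignmentError("hit blocks overlap on the query")
            prev_end = b.query_end

    @property
    def ref_span(self) -> tuple[int, int]:
        return (min(b.ref_start for b in self.blocks), max(b.ref_end for b in self.blocks))

    @property
    def aligned_query_bases(self) -> int:
        return sum(b.size for b in self.blocks)


@dataclass
class AlignmentResult:
    """Selected alignment for one target sequence, ready for lifting."""

    chromosome: str
    strand: str
    target_name: str
    target_type: str
    uniprot_id: str | None
    percent_coverage: float
    percent_identity: float
    blocks: list[AlignmentBlock]

    def __post_init__(self) -> None:
        for value in (self.percent_coverage, self.percent_identity):
            if not 0.0 <= value <= 100.0:
                raise AlignmentError(f"percentage {value} outside [0, 100]")


def parse_psl(stream) -> list[AlignmentHit]:
    """Parse a BLAT PSL stream (21 columns, with or without the 5-line header).

    Protein-query rows (two-character strand field from ``q=prot``) have their
    query coordinates scaled by 3 into nucleotide space so all downstream
    block arithmetic uses one unit.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [line.rstrip("\n") for line in stream]
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        first = line.split("\t")[0].split(" ")[0]
        if not first or not first.lstrip("-").isdigit():
            continue  # header / separator lines
        fields = line.split("\t")
        if len(fields) != 21:
            raise AlignmentError(
                f"PSL line {lineno}: expected 21 columns, got {len(fields)}"
            )
        (matches, mismatches, rep_matches, _n_count,
         q_num_insert, _q_base_insert, t_num_insert, _t_base_insert,
         strand_field, _q_name, q_size, _q_start, _q_end,
         t_name, _t_size, _t_start, _t_end,
         block_count, block_sizes, q_starts, t_starts) = fields
        matches = int(matches) + int(rep_matches)
        mismatches = int(mismatches)
        q_size = int(q_size)
        protein_query = len(strand_field) == 2
        unit = 3 if protein_query else 1
        strand = strand_field[-1]
        sizes = [int(x) for x in block_sizes.rstrip(",").split(",")]
        qs = [int(x) for x in q_starts.rstrip(",").split(",")]
        ts = [int(x) for x in t_starts.rstrip(",").split(",")]
        if not (len(sizes) == len(qs) == len(ts) == int(block_count)):
            raise AlignmentError(f"PSL line {lineno}: block lists disagree with blockCount")
        blocks = []
        for size, q0, t0 in zip(sizes, qs, ts):
            if strand == "-" and not protein_query:
                q0 = q_size - q0 - size  # flip to plus-query orientation
            blocks.append(
                AlignmentBlock(
                    query_start=q0 * unit,
                    query_end=(q0 + size) * unit,
                    ref_start=t0,
                    ref_end=t0 + size * unit,
                )
            )
        score = matches - mismatches - int(q_num_insert) - int(t_num_insert)
        hits.append(
            AlignmentHit(
                chromosome=t_name,
                strand=strand,
                score=score,
                matches=matches,
                mismatches=mismatches,
                blocks=blocks,
            )
        )
    return hits


def select_hit(hits: list[AlignmentHit], gene: GeneContext | None = None) -> AlignmentHit:
    """Choose the chromosomal hit for a target.

    With gene context the hit must lie on the gene's chromosome (several
    same-chromosome hits keep the highest-scoring; :func:`select_hsp` refines
    further by gene start).  Without gene context — typical for regulatory /
    other noncoding targets whose names carry no gene symbol — the top-scoring
    hit is taken.
    """
    if not hits:
        raise AlignmentError("no alignment hits to select from")
    if gene is not None:
        candidates = [h for h in hits if h.chromosome == gene.chromosome]
        if not candidates:
            raise NoCompatibleHitError(
                f"no hit on gene chromosome {gene.chromosome!r} "
                f"(hits on: {sorted({h.chromosome for h in hits})})"
            )
    else:
        candidates = hits
    return max(candidates, key=lambda h: h.score)


def select_hsp(hsps: list[AlignmentHit], gene_start: int) -> AlignmentHit:
    """Among HSPs on the chosen chromosome, pick the one whose first block
    starts nearest the gene's start coordinate; ties keep input order."""
    if not hsps:
        raise AlignmentError("no HSPs to select from")
    return min(hsps, key=lambda h: abs(h.blocks[0].ref_start - gene_start))


def coverage_identity(hit: AlignmentHit, query_len: int) -> tuple[float, float]:
    """Percent coverage (aligned query bases / query length) and percent
    identity (matches / (matches + mismatches)), each rounded to 2 decimals."""
    if query_len <= 0:
        raise AlignmentError("query length must be positive")
    denom = hit.matches + hit.mismatches
    if denom == 0:
        raise AlignmentError("identity undefined: no aligned bases")
    coverage = round(100.0 * hit.aligned_query_bases / query_len, 2)
    identity = round(100.0 * hit.matches / denom, 2)
    return coverage, identity


# ---------------------------------------------------------------------------
# Fixture aligner: deterministic k-mer seeding over the fixture genome.
# ---------------------------------------------------------------------------


def _seed_blocks(query: str, ref: str) -> list[AlignmentBlock]:
    """Collect maximal same-diagonal seed runs of ``query`` against ``ref``.

    Seeds are exact SEED_LENGTH-mers at every query offset; seeds sharing a
    diagonal (ref offset − query offset) merge into one block spanning the
    outermost seeds, then extend outward over directly matching characters.
    Isolated mismatches inside a block are tolerated (they simply have no
    seeds); blocks report their true match/mismatch make-up later.
    """
    k = SEED_LENGTH
    diagonals: dict[int, list[int]] = {}
    for q0 in range(0, len(query) - k + 1):
        kmer = query[q0 : q0 + k]
        r0 = ref.find(kmer)
        while r0 != -1:
            diagonals.setdefault(r0 - q0, []).append(q0)
            r0 = ref.find(kmer, r0 + 1)
    blocks = []
    for diag, q_offsets in diagonals.items():
        q_start, q_end = min(q_offsets), max(q_offsets) + k
        # greedy extension over exact matches
        while q_start > 0 and 0 <= q_start - 1 + diag and query[q_start - 1] == ref[q_start - 1 + diag]:
            q_start -= 1
        while q_end < len(query) and q_end + diag < len(ref) and query[q_end] == ref[q_end + diag]:
            q_end += 1
        blocks.append(
            AlignmentBlock(
                query_start=q_start,
                query_end=q_end,
                ref_start=q_start + diag,
                ref_end=q_end + diag,
            )
        )
    return sorted(blocks, key=lambda b: (b.query_start, b.ref_start))


def _chain_blocks(blocks: list[AlignmentBlock], strand: str) -> list[list[AlignmentBlock]]:
    """Chain query-compatible, intron-scale-proximal blocks into hits."""
    chains: list[list[AlignmentBlock]] = []
    for block in blocks:
        placed = False
        for chain in chains:
            last = chain[-1]
            if block.query_start < last.query_end:
                continue
            if strand == "+":
                gap = block.ref_start - last.ref_end
            else:
                gap = last.ref_start - block.ref_end
            if 0 <= gap <= MAX_INTRON:
                chain.append(block)
                placed = True
                break
        if not placed:
            chains.append([block])
    return chains


def _hit_from_chain(
    chain: list[AlignmentBlock], query: str, ref: str, chromosome: str, strand: str,
    query_len: int,
) -> AlignmentHit:
    matches = mismatches = 0
    out_blocks = []
    for b in chain:
        qseq = query[b.query_start : b.query_end]
        rseq = ref[b.ref_start : b.ref_end]
        m = sum(1 for a, c in zip(qseq, rseq) if a == c)
        matches += m
        mismatches += b.size - m
        if strand == "-":
            # flip query span from minus-query to plus-query orientation
            b = AlignmentBlock(
                query_start=query_len - b.query_end,
                query_end=query_len - b.query_start,
                ref_start=b.ref_start,
                ref_end=b.ref_end,
            )
        out_blocks.append(b)
    return AlignmentHit(
        chromosome=chromosome,
        strand=strand,
        score=matches - mismatches - max(0, len(chain) - 1),
        matches=matches,
        mismatches=mismatches,
        blocks=out_blocks,
    )


def fixture_align(target: str, stores: ReferenceStores) -> list[AlignmentHit]:
    """Place a nucleotide target on the fixture genome, both strands.

    Emits one hit per chained placement: single-block hits for contiguous
    matches and multi-block hits when the target matches a spliced transcript
    laid over a fixture gene (seeds cannot cross intron junctions, so each
    exon contributes its own block).  Non-homologous adapter content simply
    produces no seeds and stays unaligned.  Returns an empty list when the
    target places nowhere.
    """
    target = target.upper()
    hits: list[AlignmentHit] = []
    for chrom in _genome_chromosomes(stores):
        ref = stores.sequences.get_sequence(chrom)
        for strand in "+-":
            query = target if strand == "+" else revcomp(target)
            blocks = _seed_blocks(query, ref)
            for chain in _chain_blocks(blocks, "+"):
                hits.append(_hit_from_chain(chain, query, ref, chrom, strand, len(target)))
    hits.sort(key=lambda h: -h.score)
    return hits


def fixture_align_protein(target_protein: str, stores: ReferenceStores) -> list[AlignmentHit]:
    """Place a protein target via the fixture transcript set (BLAT ``q=prot``
    stand-in).

    Finds the target as a substring of each coding transcript's protein, then
    projects the covered CDS span through the transcript's exon table to
    genomic blocks.  Query coordinates are emitted in nucleotide space
    (residue index x 3), matching how protein-query PSL rows are parsed.
    """
    hits: list[AlignmentHit] = []
    for rec in stores.transcripts.records:
        if not rec.is_coding or rec.protein_accession not in stores.sequences:
            continue
        protein = stores.sequences.get_sequence(rec.protein_accession)
        offset = protein.find(target_protein)
        if offset == -1:
            continue
        cds_start, cds_end = 3 * offset, 3 * (offset + len(target_protein))
        blocks = _project_cds_span(rec, cds_start, cds_end)
        n_aligned = 3 * len(target_protein)
        hits.append(
            AlignmentHit(
                chromosome=rec.chromosome,
                strand=rec.strand,
                score=n_aligned,
                matches=n_aligned,
                mismatches=0,
                blocks=blocks,
            )
        )
    hits.sort(key=lambda h: -h.score)
    return hits


def _project_cds_span(rec, cds_start: int, cds_end: int) -> list[AlignmentBlock]:
    """Map a transcript CDS interbase span to genomic blocks via the exon table.

    The query side of each block is the CDS span re-based to the target
    (query position 0 == ``cds_start``).
    """
    exons = list(rec.exons)
    spans = []  # (cds_lo, cds_hi, genomic exon, orientation) walk
    if rec.strand == "+":
        cursor = 0
        for g_start, g_end in exons:
            size = g_end - g_start
            spans.append((cursor, cursor + size, g_start, g_end))
            cursor += size
    else:
        cursor = 0
        for g_start, g_end in reversed(exons):
            size = g_end - g_start
            spans.append((cursor, cursor + size, g_start, g_end))
            cursor += size
    blocks = []
    for c_lo, c_hi, g_start, g_end in spans:
        lo, hi = max(cds_start, c_lo), min(cds_end, c_hi)
        if lo >= hi:
            continue
        if rec.strand == "+":
            r_start = g_start + (lo - c_lo)
            r_end = g_start + (hi - c_lo)
        else:
            r_end = g_end - (lo - c_lo)
            r_start = g_end - (hi - c_lo)
        blocks.append(
            AlignmentBlock(
                query_start=lo - cds_start,
                query_end=hi - cds_start,
                ref_start=r_start,
                ref_end=r_end,
            )
        )
    return sorted(blocks, key=lambda b: b.query_start)


def _genome_chromosomes(stores: ReferenceStores) -> list[str]:
    chroms = {rec.chromosome for rec in stores.transcripts.records}
    chroms |= {
        acc for acc in getattr(stores.sequences, "_seqs", {})
        if acc.startswith("chr")
    }
    return sorted(c for c in chroms if c in stores.sequences)
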