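"""End-to-end mapping: metadata -> alignment -> transcript selection ->
per-row variant mapping -> validation -> JSON output.

The workflow runs in three phases.  Phase 1 aligns the target sequence to
the genome (PSL input or the fixture aligner) and selects the hit/HSP using
gene context when a UniProt accession is available.  Phase 2 — skipped for
regulatory/other noncoding score sets, whose targets map to a contiguous
chromosomal region — selects a reference transcript/protein and computes the
target's residue offset, corrected for score-matrix discordance.  Phase 3
converts every score row into a pre-mapped (assayed) and post-mapped
(reference-anchored) digest-identified variation object, annotates reference
alleles and HGVS expressions, and enforces the success criterion: the
pre- and post-mapped reference alleles must agree (reverse-complemented for
minus-strand nucleotide variants).

Per-row failures never abort a set; they carry an explicit unmappable
reason.  Set-level failures (no alignment hit, broken UniProt linkage) fail
the whole score set.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignment import (
    AlignmentResult,
    coverage_identity,
    fixture_align,
    fixture_align_protein,
    parse_psl,
    select_hit,
    select_hsp,
)
from .errors import (
    MaveAnchorError,
    NoCompatibleHitError,
    NoLinkageError,
    ParseError,
    ScoresetMappingError,
    StoreError,
    TranscriptSelectionError,
    UnsupportedVariantError,
)
from .lifting import (
    UnmappableReason,
    classify_unmappable,
    lift_nucleotide_position,
    lift_protein_position,
    reverse_complement,
)
from .mavehgvs import VariantGroup, expected_reference_map, parse_variant
from .stores import ReferenceStores, sequence_digest_id
from .transcripts import (
    TranscriptSelection,
    compute_offset,
    reconcile_offset,
    select_transcript,
    translate_dna,
)
from .vrs import (
    TextVariation,
    VrsAllele,
    VrsHaplotype,
    annotate_ref_allele,
    build_allele,
    build_haplotype,
    to_hgvs,
)

logger = logging.getLogger(__name__)

ASSEMBLY = "GRCh38"


@dataclass
class ScoreSetMetadata:
    """The seven score-set fields needed to locate a target genomically."""

    urn: str
    target_sequence: str
    target_sequence_type: str          # "dna" | "protein"
    target_name: str
    assembly_id: str | None = None     # recorded in provenance; mapping uses ASSEMBLY
    uniprot_id: str | None = None
    target_type: str = "protein_coding"  # "protein_coding" | "regulatory_other_noncoding"

    def __post_init__(self) -> None:
        seq = self.target_sequence
        if not seq:
            raise MaveAnchorError(f"{self.urn}: empty target sequence")
        alphabet = set("ACGTN") if self.target_sequence_type == "dna" else set("ACDEFGHIKLMNPQRSTVWY*X")
        bad = set(seq.upper()) - alphabet
        if bad:
            raise MaveAnchorError(
                f"{self.urn}: target sequence contains {sorted(bad)} "
                f"inconsistent with type {self.target_sequence_type!r}"
            )

    @property
    def is_protein_coding(self) -> bool:
        return "protein" in self.target_type


@dataclass
class ScoreRow:
    """One score-matrix row; at least one variant column must be present."""

    hgvs_nt: str | None = None
    hgvs_pro: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.hgvs_nt and not self.hgvs_pro:
            raise MaveAnchorError("score row has neither hgvs_nt nor hgvs_pro")


@dataclass
class MappedVariant:
    """Pre-/post-mapped representations of one score row in one pass."""

    row: int
    pre_mapped: VrsAllele | VrsHaplotype | TextVariation
    post_mapped: VrsAllele | VrsHaplotype | TextVariation | UnmappableReason
    score: float | None = None

    @property
    def is_mapped(self) -> bool:
        return isinstance(self.post_mapped, (VrsAllele, VrsHaplotype))

    def to_dict(self) -> dict:
        return {
            "row": self.row,
            "pre_mapped": _variation_to_dict(self.pre_mapped),
            "post_mapped": _variation_to_dict(self.post_mapped),
            "score": self.score,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MappedVariant":
        return cls(
            row=d["row"],
            pre_mapped=_variation_from_dict(d["pre_mapped"]),
            post_mapped=_variation_from_dict(d["post_mapped"]),
            score=d["score"],
        )


@dataclass
class MappedScoreset:
    """One mapping pass over one score set (one variant column)."""

    urn: str
    layer: str                          # "p" or "n"/"g": the column mapped
    computed_reference_sequence: dict   # sequence, sequence_type, sequence_id
    mapped_reference_sequence: dict     # sequence_accession, sequence_type, sequence_id
    mapped_scores: list[MappedVariant] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "urn": self.urn,
            "layer": self.layer,
            "computed_reference_sequence": dict(self.computed_reference_sequence),
            "mapped_reference_sequence": dict(self.mapped_reference_sequence),
            "mapped_scores": [mv.to_dict() for mv in self.mapped_scores],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MappedScoreset":
        return cls(
            urn=d["urn"],
            layer=d["layer"],
            computed_reference_sequence=dict(d["computed_reference_sequence"]),
            mapped_reference_sequence=dict(d["mapped_reference_sequence"]),
            mapped_scores=[MappedVariant.from_dict(x) for x in d["mapped_scores"]],
        )


def _variation_to_dict(obj) -> dict:
    if isinstance(obj, UnmappableReason):
        return {"type": "Unmappable", "code": obj.code, "detail": obj.detail}
    return obj.to_dict()


def _variation_from_dict(d: dict):
    t = d["type"]
    if t == "Allele":
        return VrsAllele.from_dict(d)
    if t == "Haplotype":
        return VrsHaplotype.from_dict(d)
    if t == "Text":
        return TextVariation.from_dict(d)
    if t == "Unmappable":
        return UnmappableReason(code=d["code"], detail=d.get("detail", ""))
    raise MaveAnchorError(f"unknown variation type {t!r}")


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> ScoreSetMetadata:
    d = json.loads(Path(path).read_text())
    return ScoreSetMetadata(**d)


def read_scores(path: str | Path) -> list[ScoreRow]:
    df = pd.read_csv(path, dtype={"hgvs_nt": "string", "hgvs_pro": "string"})
    rows = []
    for _, rec in df.iterrows():
        def cell(name):
            v = rec.get(name)
            return None if v is None or pd.isna(v) or v == "" else str(v)
        score = rec.get("score")
        score = None if score is None or (isinstance(score, float) and math.isnan(score)) else float(score)
        rows.append(ScoreRow(hgvs_nt=cell("hgvs_nt"), hgvs_pro=cell("hgvs_pro"), score=score))
    return rows


# ---------------------------------------------------------------------------
# Phase 1-2 helpers
# ---------------------------------------------------------------------------


def _resolve_alignment(
    meta: ScoreSetMetadata, stores: ReferenceStores, psl: str | Path | None
):
    """Run phase 1: obtain hits, select the hit/HSP, assemble AlignmentResult."""
    gene = None
    if meta.uniprot_id:
        query = meta.uniprot_id if ":" in meta.uniprot_id else f"uniprot:{meta.uniprot_id}"
        try:
            gene = stores.genes.normalize_gene(query)
        except NoLinkageError as exc:
            raise ScoresetMappingError(f"{meta.urn}: {exc}") from exc
        except StoreError:
            gene = None  # unknown accession: fall back to top-scoring hit
    if psl is not None:
        text = Path(psl).read_text() if not isinstance(psl, str) or "\n" not in psl else psl
        hits = parse_psl(text)
    elif meta.target_sequence_type == "protein":
        hits = fixture_align_protein(meta.target_sequence.upper(), stores)
    else:
        hits = fixture_align(meta.target_sequence.upper(), stores)
    if not hits:
        raise ScoresetMappingError(f"{meta.urn}: NO_HIT: target returned no alignment hit")
    try:
        hit = select_hit(hits, gene)
        if gene is not None:
            same_chrom = [h for h in hits if h.chromosome == gene.chromosome]
            if len(same_chrom) > 1:
                hit = select_hsp(same_chrom, gene.start)
    except NoCompatibleHitError as exc:
        raise ScoresetMappingError(f"{meta.urn}: {exc}") from exc
    query_len_nt = len(meta.target_sequence) * (3 if meta.target_sequence_type == "protein" else 1)
    cov, ident = coverage_identity(hit, query_len_nt)
    result = AlignmentResult(
        chromosome=hit.chromosome,
        strand=hit.strand,
        target_name=meta.target_name,
        target_type=meta.target_type,
        uniprot_id=meta.uniprot_id,
        percent_coverage=cov,
        percent_identity=ident,
        blocks=list(hit.blocks),
    )
    return result, gene


def _select_reference_protein(
    meta: ScoreSetMetadata,
    aln: AlignmentResult,
    gene,
    stores: ReferenceStores,
    pro_groups: list[VariantGroup],
) -> tuple[TranscriptSelection | None, str | None]:
    """Run phase 2; returns (selection, reference protein accession) or
    (None, None) when no compatible transcript exists."""
    per_block = [
        stores.transcripts.transcripts_in_region(
            aln.chromosome, b.ref_start, b.ref_end, gene.symbol if gene else None
        )
        for b in aln.blocks
    ]
    try:
        record = select_transcript(per_block)
    except TranscriptSelectionError as exc:
        logger.warning("%s: %s", meta.urn, exc)
        return None, None
    protein_acc = record.protein_accession
    source = "refseq"
    if protein_acc not in stores.sequences:
        # fall back to the canonical UniProt sequence held in the store
        if meta.uniprot_id:
            uni = meta.uniprot_id if meta.uniprot_id.startswith("uniprot:") else f"uniprot:{meta.uniprot_id}"
            if uni in stores.sequences:
                protein_acc, source = uni, "uniprot"
            else:
                return None, None
        else:
            return None, None
    reference_protein = stores.sequences.get_sequence(protein_acc)
    target_protein = (
        translate_dna(meta.target_sequence)
        if meta.target_sequence_type == "dna"
        else meta.target_sequence.upper()
    )
    try:
        offset, full_match = compute_offset(target_protein, reference_protein)
        expected = expected_reference_map(pro_groups)
        offset = reconcile_offset(target_protein, expected, offset)
    except (TranscriptSelectionError, ParseError) as exc:
        logger.warning("%s: protein offset failed: %s", meta.urn, exc)
        return None, None
    selection = TranscriptSelection(
        tx_accession=record.tx_accession,
        protein_accession=protein_acc,
        mane_status=record.mane_status,
        offset=offset,
        full_match=full_match,
        sequence_source=source,
    )
    return selection, protein_acc


# ---------------------------------------------------------------------------
# Phase 3: per-row mapping
# ---------------------------------------------------------------------------


def _member_interbase(m) -> tuple[int, int]:
    """1-based inclusive member span -> interbase span on its own sequence."""
    if m.kind == "insertion":
        return (m.start, m.start)
    return (m.start - 1, m.end)


def _build_pre_allele(m, seq_id: str, stores: ReferenceStores) -> VrsAllele:
    start, end = _member_interbase(m)
    allele = build_allele(seq_id, start, end, m.alt_allele, stores.sequences)
    return annotate_ref_allele(allele, stores.sequences)


def passthrough_if_anchored(
    group: VariantGroup, stores: ReferenceStores, score: float | None, row: int
) -> MappedVariant | None:
    """Handle variants already described on a recognized reference accession
    (e.g. ``NP_009225.1:p.Pro1659Leu``): pre- and post-mapped representations
    are the identical allele.  Returns ``None`` for accession-less variants;
    unknown accessions raise."""
    acc = group.accession
    if acc is None:
        return None
    if acc not in stores.sequences:
        raise ScoresetMappingError(f"variant accession {acc!r} unknown to the sequence store")
    seq_digest = sequence_digest_id(stores.sequences.get_sequence(acc))
    alleles = []
    for m in group.members:
        start, end = _member_interbase(m)
        allele = build_allele(seq_digest, start, end, m.alt_allele, stores.sequences)
        allele = annotate_ref_allele(allele, stores.sequences)
        layer = "p" if m.layer == "p" else "g"
        allele.expressions = [to_hgvs(allele, acc, layer, stores.sequences)]
        alleles.append(allele)
    variation = alleles[0] if len(alleles) == 1 else build_haplotype(alleles)
    return MappedVariant(row=row, pre_mapped=variation, post_mapped=variation, score=score)


def validate_pair(pre, post, strand: str = "+") -> bool:
    """The mapping success criterion: the pre- and post-mapped reference
    alleles agree — directly on the plus strand and for proteins, or as
    reverse complements for minus-strand nucleotide variants."""
    if isinstance(pre, VrsHaplotype) != isinstance(post, VrsHaplotype):
        return False
    pre_members = pre.members if isinstance(pre, VrsHaplotype) else [pre]
    post_members = post.members if isinstance(post, VrsHaplotype) else [post]
    if len(pre_members) != len(post_members):
        return False
    for a, b in zip(pre_members, post_members):
        if a.vrs_ref_allele_seq is None or b.vrs_ref_allele_seq is None:
            return False
        if strand == "-":
            if b.vrs_ref_allele_seq != reverse_complement(a.vrs_ref_allele_seq):
                return False
        elif a.vrs_ref_allele_seq != b.vrs_ref_allele_seq:
            return False
    return True


class _PassContext:
    """Everything one mapping pass (one variant column) needs per row."""

    def __init__(
        self,
        meta: ScoreSetMetadata,
        layer: str,                     # "nt" | "pro"
        aln: AlignmentResult,
        stores: ReferenceStores,
        selection: TranscriptSelection | None,
        pre_sequence: str,
        pre_sequence_label: str,
    ):
        self.meta = meta
        self.layer = layer
        self.aln = aln
        self.stores = stores
        self.selection = selection
        self.pre_sequence = pre_sequence
        self.pre_seq_id = stores.sequences.add(pre_sequence_label, pre_sequence)
        if layer == "nt":
            self.post_accession = stores.identifiers.translate_identifier(
                aln.chromosome, ASSEMBLY
            )
            chrom_seq = stores.sequences.get_sequence(aln.chromosome)
            self.post_seq_id = sequence_digest_id(chrom_seq)
            self.hgvs_layer = "g"
        else:
            self.post_accession = selection.protein_accession if selection else None
            self.post_seq_id = (
                sequence_digest_id(stores.sequences.get_sequence(self.post_accession))
                if self.post_accession
                else None
            )
            self.hgvs_layer = "p"

    @property
    def target_len_units(self) -> int:
        return len(self.pre_sequence)

    def lift_member(self, m) -> tuple[int, int, str]:
        """Member -> (interbase start, interbase end, post alt) on the post sequence."""
        if self.layer == "pro":
            off = self.selection.offset
            if m.kind == "insertion":
                pos = lift_protein_position(m.start, off)
                return (pos, pos, m.alt_allele)
            return (
                lift_protein_position(m.start, off) - 1,
                lift_protein_position(m.end, off),
                m.alt_allele,
            )
        blocks, strand = self.aln.blocks, self.aln.strand
        if m.kind == "insertion":
            g1 = lift_nucleotide_position(m.start, blocks, strand)
            pos = g1 + 1 if strand == "+" else g1
            alt = m.alt_allele if strand == "+" else reverse_complement(m.alt_allele)
            return (pos, pos, alt)
        g1 = lift_nucleotide_position(m.start, blocks, strand)
        g2 = lift_nucleotide_position(m.end, blocks, strand)
        if strand == "+":
            span = (g1, g2 + 1)
            alt = m.alt_allele
        else:
            span = (g2, g1 + 1)
            alt = reverse_complement(m.alt_allele)
        return (span[0], span[1], alt)


def _map_row(
    ctx: _PassContext, idx: int, cell: str, score: float | None
) -> MappedVariant:
    layer_hint = "p" if ctx.layer == "pro" else "n"
    try:
        group = parse_variant(cell, layer_hint=layer_hint)
    except UnsupportedVariantError:
        return MappedVariant(idx, TextVariation(cell), TextVariation(cell), score)
    except ParseError as exc:
        logger.warning("row %d: %s", idx, exc)
        return MappedVariant(idx, TextVariation(cell), TextVariation(cell), score)

    if all(m.kind == "identity" for m in group.members):
        return MappedVariant(idx, TextVariation(cell), TextVariation(cell), score)

    if group.accession is not None:
        try:
            return passthrough_if_anchored(group, ctx.stores, score, idx)
        except ScoresetMappingError as exc:
            logger.warning("row %d: %s", idx, exc)
            return MappedVariant(
                idx, TextVariation(cell),
                UnmappableReason("NO_TRANSCRIPT", str(exc)), score,
            )

    is_protein_member = ctx.layer == "pro"
    reason = classify_unmappable(
        group, ctx.aln.blocks, ctx.target_len_units, "p" if is_protein_member else "n"
    )
    if reason is not None and reason.code == "OUTSIDE_TARGET":
        return MappedVariant(idx, TextVariation(cell), reason, score)

    pre_alleles = [_build_pre_allele(m, ctx.pre_seq_id, ctx.stores) for m in group.members]
    pre = pre_alleles[0] if len(pre_alleles) == 1 else build_haplotype(pre_alleles)

    if is_protein_member and ctx.selection is None:
        reason = UnmappableReason("NO_TRANSCRIPT", "no compatible reference protein")
    if reason is not None:
        logger.info("row %d unmappable: %s (%s)", idx, reason.code, reason.detail)
        return MappedVariant(idx, pre, reason, score)

    post_alleles = []
    for m in group.members:
        start, end, alt = ctx.lift_member(m)
        allele = build_allele(ctx.post_seq_id, start, end, alt, ctx.stores.sequences)
        allele = annotate_ref_allele(allele, ctx.stores.sequences)
        allele.expressions = [
            to_hgvs(allele, ctx.post_accession, ctx.hgvs_layer, ctx.stores.sequences)
        ]
        post_alleles.append(allele)
    post = post_alleles[0] if len(post_alleles) == 1 else build_haplotype(post_alleles)

    strand = ctx.aln.strand if ctx.layer == "nt" else "+"
    if not validate_pair(pre, post, strand):
        reason = UnmappableReason(
            "UNALIGNED_REGION",
            "pre/post reference-allele mismatch: target is not reference-identical "
            "at the variant site",
        )
        logger.info("row %d failed reference-allele validation", idx)
        return MappedVariant(idx, pre, reason, score)
    return MappedVariant(idx, pre, post, score)


def map_scoreset(
    meta: ScoreSetMetadata,
    rows: list[ScoreRow],
    stores: ReferenceStores,
    psl: str | Path | None = None,
) -> list[MappedScoreset]:
    """Map one score set; returns one :class:`MappedScoreset` per variant
    column present (``hgvs_pro`` and/or ``hgvs_nt``).

    Protein-coding sets run all three phases; regulatory/other noncoding sets
    skip transcript selection and map nucleotide variants directly through
    the alignment blocks.  Rows that cannot be mapped carry an explicit
    reason and are never dropped; scores pass through unaltered.
    """
    aln, gene = _resolve_alignment(meta, stores, psl)
    target = meta.target_sequence.upper()

    has_pro = any(r.hgvs_pro for r in rows)
    has_nt = any(r.hgvs_nt for r in rows)

    selection = None
    if meta.is_protein_coding and has_pro:
        pro_groups = []
        for r in rows:
            if not r.hgvs_pro:
                continue
            try:
                g = parse_variant(r.hgvs_pro, layer_hint="p")
            except (ParseError, UnsupportedVariantError):
                continue
            if g.accession is None and not all(m.kind == "identity" for m in g.members):
                pro_groups.append(g)
        selection, _ = _select_reference_protein(meta, aln, gene, stores, pro_groups)

    out: list[MappedScoreset] = []
    passes: list[tuple[str, str, str]] = []  # (layer, pre sequence, pre type)
    if has_pro:
        pre_protein = (
            translate_dna(target) if meta.target_sequence_type == "dna" else target
        )
        passes.append(("pro", pre_protein, "protein"))
    if has_nt:
        passes.append(("nt", target, "dna"))

    for layer, pre_seq, pre_type in passes:
        ctx = _PassContext(
            meta=meta,
            layer=layer,
            aln=aln,
            stores=stores,
            selection=selection if layer == "pro" else None,
            pre_sequence=pre_seq,
            pre_sequence_label=f"computed:{meta.urn}:{layer}",
        )
        mapped: list[MappedVariant] = []
        n_failed = 0
        for idx, row in enumerate(rows):
            cell = row.hgvs_pro if layer == "pro" else row.hgvs_nt
            if not cell:
                continue
            mv = _map_row(ctx, idx, cell, row.score)
            mapped.append(mv)
            n_failed += 0 if mv.is_mapped else 1
        logger.info(
            "%s [%s pass]: %d rows, %d not mapped",
            meta.urn, layer, len(mapped), n_failed,
        )
        post_type = "protein" if layer == "pro" else "dna"
        out.append(
            MappedScoreset(
                urn=meta.urn,
                layer="p" if layer == "pro" else "g",
                computed_reference_sequence={
                    "sequence": pre_seq,
                    "sequence_type": pre_type,
                    "sequence_id": ctx.pre_seq_id,
                },
                mapped_reference_sequence={
                    "sequence_accession": ctx.post_accession,
                    "sequence_type": post_type,
                    "sequence_id": ctx.post_seq_id,
                },
                mapped_scores=mapped,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_output(mapped: list[MappedScoreset], path: str | Path) -> None:
    """Write mapping sets as deterministic gzipped JSON (sorted keys, fixed
    mtime) so identical inputs give byte-identical archives."""
    payload = json.dumps(
        {"mapping_sets": [m.to_dict() for m in mapped]},
        sort_keys=True,
        separators=(",", ":"),
    ).encode("utf-8")
    buf = io.BytesIO()
    with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as fh:
        fh.write(payload)
    Path(path).write_bytes(buf.getvalue())


def read_output(path: str | Path) -> list[MappedScoreset]:
    with gzip.open(path, "rt") as fh:
        d = json.load(fh)
    return [MappedScoreset.from_dict(x) for x in d["mapping_sets"]]
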