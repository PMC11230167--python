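"""Coordinate lifting from target-sequence space to reference space.

Protein positions lift by residue offset; nucleotide positions lift through
the selected alignment blocks, end-anchored on the minus strand.  Variants
that cannot be lifted are classified into a closed taxonomy rather than
silently dropped: spans crossing alignment-block (exon) boundaries,
positions in non-homologous (unaligned) target content, and positions past
the target length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import AlignmentBlock, revcomp  # noqa: F401  (re-exported)
from .errors import LiftError
from .mavehgvs import VariantGroup

REASON_CODES = (
    "SPANS_BLOCK_BOUNDARY",
    "OUTSIDE_TARGET",
    "UNALIGNED_REGION",
    "NO_TRANSCRIPT",
    "NO_HIT",
)


@dataclass(frozen=True)
class UnmappableReason:
    code: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.code not in REASON_CODES:
            raise ValueError(f"unknown unmappable reason code {self.code!r}")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet; other characters raise."""
    if any(c not in "ACGTNacgtn" for c in seq):
        bad = next(c for c in seq if c not in "ACGTNacgtn")
        raise LiftError(f"cannot reverse-complement character {bad!r}")
    return revcomp(seq)


def lift_protein_position(pos: int, offset: int) -> int:
    """1-based target-protein residue -> 1-based reference-protein residue."""
    if pos < 1 or offset < 0:
        raise LiftError(f"invalid protein lift: pos={pos}, offset={offset}")
    return pos + offset


def _block_for(pos: int, blocks: list[AlignmentBlock]) -> AlignmentBlock | None:
    for b in blocks:
        if b.query_start < pos <= b.query_end:
            return b
    return None


def lift_nucleotide_position(
    pos: int, blocks: list[AlignmentBlock], strand: str
) -> int:
    """Lift a 1-based target nucleotide to the interbase start of the affected
    reference base.

    Within the containing block, the distance from the block's query start is
    added to the block's reference start on the plus strand, or subtracted
    from its (inclusive) reference end on the minus strand.
    """
    target_len = max(b.query_end for b in blocks) if blocks else 0
    block = _block_for(pos, blocks)
    if block is None:
        code = "UNALIGNED_REGION" if pos <= target_len else "OUTSIDE_TARGET"
        raise LiftError(f"{code}: position {pos} lies in no alignment block")
    d = (pos - 1) - block.query_start
    if strand == "+":
        return block.ref_start + d
    return (block.ref_end - 1) - d


def inverse_lift_nucleotide_position(
    ref_pos: int, blocks: list[AlignmentBlock], strand: str
) -> int:
    """Inverse of :func:`lift_nucleotide_position` (reference interbase start
    of a base -> 1-based target position)."""
    for b in blocks:
        if b.ref_start <= ref_pos < b.ref_end:
            if strand == "+":
                d = ref_pos - b.ref_start
            else:
                d = (b.ref_end - 1) - ref_pos
            return b.query_start + d + 1
    raise LiftError(f"reference position {ref_pos} lies in no alignment block")


def classify_unmappable(
    group: VariantGroup,
    blocks: list[AlignmentBlock],
    target_len: int,
    layer: str,
) -> UnmappableReason | None:
    """Decide whether a variant group can be lifted through ``blocks``.

    ``target_len`` is in the group's own units (residues for protein-layer
    groups, nucleotides otherwise).  Protein members are expanded to codon
    spans in target nucleotide space (frame 0 from the reconciled offset)
    before the block-boundary check.  Precedence: OUTSIDE_TARGET, then
    SPANS_BLOCK_BOUNDARY, then UNALIGNED_REGION; ``None`` means liftable.

    Multi-unit alleles are lifted by their full span; a span crossing block
    edges is refused with an explicit reason rather than split into per-block
    events.
    """
    for m in group.members:
        if m.end > target_len:
            return UnmappableReason(
                "OUTSIDE_TARGET",
                f"position {m.end} past target length {target_len}",
            )
    if not blocks:
        return UnmappableReason("NO_HIT", "no alignment blocks available")
    for m in group.members:
        if layer == "p":
            nt_start = (m.start - 1) * 3 + 1
            nt_end = m.end * 3
        else:
            nt_start, nt_end = m.start, m.end
        if m.kind == "insertion":
            # the junction must lie inside (or at the edge of) one block
            nt_end = nt_start
        b_start = _block_for(nt_start, blocks)
        b_end = _block_for(nt_end, blocks)
        if b_start is None or b_end is None:
            return UnmappableReason(
                "UNALIGNED_REGION",
                f"positions {nt_start}..{nt_end} fall in non-aligning target content",
            )
        if b_start is not b_end:
            return UnmappableReason(
                "SPANS_BLOCK_BOUNDARY",
                f"span {nt_start}..{nt_end} crosses an alignment-block edge",
            )
    return None
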