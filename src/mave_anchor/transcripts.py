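"""Transcript selection and target-protein offset computation.

Phase 2 of the mapping workflow: query transcripts per alignment block,
intersect, rank (MANE Select > MANE Plus Clinical > longest > first
published), translate the DNA target, locate it in the reference protein via
a 10-residue seed, and correct the offset when the score matrix disagrees
with the target sequence (discordance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import TranscriptSelectionError
from .stores import TranscriptRecord

logger = logging.getLogger(__name__)

SEED_RESIDUES = 10

_MANE_RANK = {"MANE Select": 0, "MANE Plus Clinical": 1}


@dataclass
class TranscriptSelection:
    """Chosen transcript/protein pair plus the target's placement within it.

    ``offset`` is the 0-based residue offset of the (translated) target inside
    the reference protein; ``full_match`` is true iff the entire target is an
    exact substring of the reference protein at that offset.
    """

    tx_accession: str
    protein_accession: str
    mane_status: str
    offset: int
    full_match: bool
    sequence_source: str = "refseq"   # refseq | uniprot

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise TranscriptSelectionError(f"negative offset {self.offset}")


def translate_dna(seq: str) -> str:
    """Translate with the standard codon table; stop codons render ``*`` and
    translation continues (targets may tile past a stop).  A trailing partial
    codon is dropped; ambiguous bases raise, naming the codon index."""
    if len(seq) < 3:
        raise TranscriptSelectionError(f"sequence too short to translate ({len(seq)} nt)")
    seq = seq.upper()
    usable = seq[: len(seq) - len(seq) % 3]
    for i in range(0, len(usable), 3):
        codon = usable[i : i + 3]
        if any(base not in "ACGT" for base in codon):
            raise TranscriptSelectionError(
                f"ambiguous base in codon {i // 3} ({codon!r})"
            )
    return str(Seq(usable).translate())


def select_transcript(per_block_lists: list[list[TranscriptRecord]]) -> TranscriptRecord:
    """Intersect per-block transcript lists and rank the survivors.

    Non-coding records are dropped before intersection.  Ranking: any MANE
    Select record wins; else MANE Plus Clinical; else the longest transcript,
    with the smallest publication ordinal breaking length ties.  An empty
    intersection is a whole-score-set failure.
    """
    if not per_block_lists:
        raise TranscriptSelectionError("no per-block transcript lists supplied")
    coding_lists = [
        {rec.tx_accession: rec for rec in lst if rec.is_coding}
        for lst in per_block_lists
    ]
    common = set(coding_lists[0])
    for d in coding_lists[1:]:
        common &= set(d)
    if not common:
        raise TranscriptSelectionError(
            "no compatible transcript: empty intersection across alignment blocks"
        )
    records = [coding_lists[0][acc] for acc in common]
    mane = [r for r in records if r.mane_status in _MANE_RANK]
    if mane:
        return min(mane, key=lambda r: _MANE_RANK[r.mane_status])
    return min(records, key=lambda r: (-r.length, r.pub_order))


def compute_offset(target_protein: str, reference_protein: str) -> tuple[int, bool]:
    """Locate the target protein in the reference protein.

    The first :data:`SEED_RESIDUES` residues (or the whole target if shorter)
    are searched with plain substring ``find`` — first occurrence wins, and
    multiplicity is logged as a warning.  Returns ``(offset, full_match)``
    where ``full_match`` reports whether the *entire* target matches at the
    seed offset.  A missing seed makes the score set unmappable at the
    protein layer.
    """
    if not target_protein:
        raise TranscriptSelectionError("empty target protein")
    seed = target_protein[:SEED_RESIDUES]
    offset = reference_protein.find(seed)
    if offset == -1:
        raise TranscriptSelectionError(
            f"seed not found: first {len(seed)} target residues absent from reference protein"
        )
    if reference_protein.find(seed, offset + 1) != -1:
        logger.warning("protein seed %r occurs more than once; first occurrence used", seed)
    full_match = (
        reference_protein[offset : offset + len(target_protein)] == target_protein
    )
    return offset, full_match


def reconcile_offset(
    target_protein: str, expected: dict[int, str], offset: int
) -> int:
    """Correct the offset when the score matrix disagrees with the target.

    ``expected`` maps 1-based matrix positions to the reference residues the
    matrix claims (e.g. a matrix reporting ``p.Arg100His`` over a target with
    Leu at position 100).  If every claim already matches the target, the
    offset is returned unchanged; otherwise the smallest non-negative shift
    ``s`` aligning all claims (``target[pos-1+s] == residue``) is applied and
    ``offset + s`` returned.  Negative shifts are rejected; no valid shift is
    an irreconcilable discordance.
    """
    if not expected:
        return offset
    max_pos = max(expected)
    for shift in range(0, len(target_protein) - max_pos + 1):
        if all(
            0 <= pos - 1 + shift < len(target_protein)
            and target_protein[pos - 1 + shift] == res
            for pos, res in expected.items()
        ):
            if shift:
                logger.info("discordance corrected with shift %d", shift)
            return offset + shift
    raise TranscriptSelectionError(
        "irreconcilable discordance: no shift aligns the score matrix's "
        "expected residues with the target sequence"
    )
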