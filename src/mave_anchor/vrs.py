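"""Digest-identified variation objects (VRS-style alleles and haplotypes).

Variants are identified by content digests so the assayed (pre-mapped) and
reference-anchored (post-mapped) representations of one variant get distinct,
stable, computable identifiers.  The digest is sha512t24u (SHA-512 truncated
to 24 bytes, base64url), applied to a canonical serialization defined here:
identify-relevant fields only, keys sorted, UTF-8, no whitespace, nested
identifiable objects replaced by their digest strings.  The serialization is
frozen by golden-file tests; cross-compatibility with other serializers is
not an invariant of this package.

Alleles are normalized with the SPDI Variant Overprecision Correction
Algorithm (fully-justified form): trim shared flanks (prefix first, then
suffix), and roll pure indels across their repeat context, expanding to the
full ambiguity interval so every shifted representation of an ambiguous
indel converges to one allele and one identifier.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

from .errors import MaveAnchorError, RangeError
from .mavehgvs import one_to_three
from .stores import SequenceStore, sha512t24u

ID_PATTERN = re.compile(r"^ga4gh:(VA|VH|SQ)\.[A-Za-z0-9_-]{32}$")


def _canonical_json(obj) -> bytes:
    return json.dumps(obj, sort_keys=True, separators=(",", ":")).encode("utf-8")


@dataclass(frozen=True)
class SequenceLocation:
    """Interbase span on a digest-identified sequence."""

    sequence_id: str            # "ga4gh:SQ."-prefixed digest identifier
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise RangeError(f"bad location [{self.start}, {self.end})")

    def digest(self) -> str:
        return sha512t24u(
            _canonical_json(
                {
                    "sequence_id": self.sequence_id.removeprefix("ga4gh:SQ."),
                    "start": self.start,
                    "end": self.end,
                    "type": "SequenceLocation",
                }
            )
        )


@dataclass
class VrsAllele:
    """A digest-identified allele: location + literal replacement state."""

    id: str
    location: SequenceLocation
    state: str
    vrs_ref_allele_seq: str | None = None
    expressions: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "id": self.id,
            "type": "Allele",
            "location": {
                "sequence_id": self.location.sequence_id,
                "start": self.location.start,
                "end": self.location.end,
            },
            "state": {"type": "LiteralSequenceExpression", "sequence": self.state},
        }
        if self.vrs_ref_allele_seq is not None:
            out["vrs_ref_allele_seq"] = self.vrs_ref_allele_seq
        if self.expressions:
            out["expressions"] = list(self.expressions)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "VrsAllele":
        loc = d["location"]
        return cls(
            id=d["id"],
            location=SequenceLocation(loc["sequence_id"], loc["start"], loc["end"]),
            state=d["state"]["sequence"],
            vrs_ref_allele_seq=d.get("vrs_ref_allele_seq"),
            expressions=list(d.get("expressions", [])),
        )


@dataclass
class VrsHaplotype:
    """Two or more in-cis alleles on one sequence, digest-identified."""

    id: str
    members: list[VrsAllele]

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "type": "Haplotype",
            "members": [m.to_dict() for m in self.members],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VrsHaplotype":
        return cls(id=d["id"], members=[VrsAllele.from_dict(m) for m in d["members"]])


@dataclass
class TextVariation:
    """A variant we keep but cannot assign a computable identifier to."""

    definition: str
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.definition:
            raise MaveAnchorError("text variation requires a non-empty definition")

    def to_dict(self) -> dict:
        out = {"type": "Text", "definition": self.definition}
        if self.id:
            out["id"] = self.id
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "TextVariation":
        return cls(definition=d["definition"], id=d.get("id"))


def normalize_allele(
    start: int, end: int, alt: str, context: str
) -> tuple[int, int, str, str]:
    """SPDI overprecision correction, fully-justified form.

    ``[start, end)`` is an interbase span on ``context`` whose reference
    content is replaced by ``alt``.  Shared flanks are trimmed (prefix, then
    suffix).  A resulting pure insertion or deletion is rolled left and right
    over its repeat context and expanded to the full ambiguity interval, so
    all shifted representations of the same edit normalize identically.
    Substitutions/delins with no shared flanks are returned unchanged.
    Idempotent.  Returns ``(start, end, ref, alt)``.
    """
    if not (0 <= start <= end <= len(context)):
        raise RangeError(f"span [{start}, {end}) outside context of length {len(context)}")
    ref = context[start:end]
    while ref and alt and ref[0] == alt[0]:
        start += 1
        ref, alt = ref[1:], alt[1:]
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    end = start + len(ref)
    if (ref and alt) or (not ref and not alt):
        return start, end, ref, alt
    if ref:  # pure deletion: roll the deleted unit over the repeat context
        d = len(ref)
        left, right = start, end
        while left > 0 and context[left - 1] == context[left - 1 + d]:
            left -= 1
        while right < len(context) and context[right] == context[right - d]:
            right += 1
        return left, right, context[left:right], context[left : right - d]
    # pure insertion: roll the inserted unit (with rotation) over the context
    right, right_ins = start, alt
    while right < len(context) and context[right] == right_ins[0]:
        right_ins = right_ins[1:] + context[right]
        right += 1
    left, left_ins = start, alt
    while left > 0 and context[left - 1] == left_ins[-1]:
        left_ins = context[left - 1] + left_ins[:-1]
        left -= 1
    return left, right, context[left:right], context[left:right] + right_ins


def build_allele(
    sequence_id: str,
    start: int,
    end: int,
    alt: str,
    store: SequenceStore,
) -> VrsAllele:
    """Normalize an allele against its sequence and mint its digest identifier.

    ``sequence_id`` must resolve in ``store`` (a registered accession digest
    for pre-mapped target sequences, or a reference accession's digest for
    post-mapped alleles).  Equal inputs give equal identifiers; equivalent
    shifted indels converge via :func:`normalize_allele`.
    """
    context = store.get_sequence(sequence_id)
    n_start, n_end, _ref, n_alt = normalize_allele(start, end, alt, context)
    location = SequenceLocation(sequence_id=sequence_id, start=n_start, end=n_end)
    digest = sha512t24u(
        _canonical_json(
            {
                "location": location.digest(),
                "state": n_alt,
                "type": "Allele",
            }
        )
    )
    return VrsAllele(id=f"ga4gh:VA.{digest}", location=location, state=n_alt)


def build_haplotype(alleles: list[VrsAllele]) -> VrsHaplotype:
    """Combine >=2 alleles into a haplotype; identifier is order-invariant
    (member ids are sorted before digesting).  Duplicate members raise."""
    if len(alleles) < 2:
        raise MaveAnchorError("a haplotype needs at least 2 members")
    ids = [a.id for a in alleles]
    if len(set(ids)) != len(ids):
        raise MaveAnchorError("duplicate haplotype members")
    digest = sha512t24u(
        _canonical_json({"members": sorted(ids), "type": "Haplotype"})
    )
    return VrsHaplotype(id=f"ga4gh:VH.{digest}", members=list(alleles))


def annotate_ref_allele(allele: VrsAllele, store: SequenceStore) -> VrsAllele:
    """Attach ``vrs_ref_allele_seq``: the store slice under the allele span."""
    seq = store.get_sequence(
        allele.location.sequence_id, allele.location.start, allele.location.end
    )
    return replace(allele, vrs_ref_allele_seq=seq)


def _minimal_right(start: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim to the 3'-most minimal representation for HGVS rendering."""
    while ref and alt and ref[0] == alt[0]:
        start += 1
        ref, alt = ref[1:], alt[1:]
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return start, ref, alt


def to_hgvs(allele: VrsAllele, accession: str, layer: str, store: SequenceStore | None = None) -> str:
    """Render a post-mapped allele as an HGVS expression on ``accession``.

    ``layer`` is ``g`` (1-based genomic) or ``p`` (three-letter protein).
    Fully-justified alleles are re-trimmed to the 3'-most minimal form, the
    convention HGVS expects.  Requires ``vrs_ref_allele_seq``; protein
    insertions additionally need ``store`` for their flanking residues.
    Pre-mapped, digest-only sequences have no accession and cannot be
    rendered.
    """
    if allele.vrs_ref_allele_seq is None:
        raise MaveAnchorError("annotate_ref_allele must run before to_hgvs")
    if accession.startswith("ga4gh:"):
        raise MaveAnchorError("HGVS expressions are rendered for post-mapped accessions only")
    start, ref, alt = _minimal_right(
        allele.location.start, allele.vrs_ref_allele_seq, allele.state
    )
    if layer == "g":
        return _hgvs_g(accession, start, ref, alt)
    if layer == "p":
        return _hgvs_p(accession, start, ref, alt, allele, store)
    raise MaveAnchorError(f"unsupported HGVS layer {layer!r}")


def _hgvs_g(accession: str, start: int, ref: str, alt: str) -> str:
    pos = start + 1  # interbase -> 1-based
    if len(ref) == 1 and len(alt) == 1:
        return f"{accession}:g.{pos}{ref}>{alt}"
    if ref and not alt:
        return (
            f"{accession}:g.{pos}del"
            if len(ref) == 1
            else f"{accession}:g.{pos}_{pos + len(ref) - 1}del"
        )
    if alt and not ref:
        return f"{accession}:g.{start}_{pos}ins{alt}"
    if ref and alt:
        span = f"{pos}" if len(ref) == 1 else f"{pos}_{pos + len(ref) - 1}"
        return f"{accession}:g.{span}delins{alt}"
    return f"{accession}:g.{pos}="


def _hgvs_p(
    accession: str, start: int, ref: str, alt: str,
    allele: VrsAllele, store: SequenceStore | None,
) -> str:
    pos = start + 1

    def three(seq: str) -> str:
        return "".join(one_to_three(r) for r in seq)

    if len(ref) == 1 and len(alt) == 1:
        return f"{accession}:p.{three(ref)}{pos}{three(alt)}"
    if ref and not alt:
        if len(ref) == 1:
            return f"{accession}:p.{three(ref[0])}{pos}del"
        last = pos + len(ref) - 1
        return f"{accession}:p.{three(ref[0])}{pos}_{three(ref[-1])}{last}del"
    if alt and not ref:
        if store is None:
            raise MaveAnchorError("protein insertion rendering needs a sequence store")
        seq_id = allele.location.sequence_id
        left = store.get_sequence(seq_id, start - 1, start)
        right = store.get_sequence(seq_id, start, start + 1)
        return f"{accession}:p.{three(left)}{start}_{three(right)}{pos}ins{three(alt)}"
    if ref and alt:
        if len(ref) == 1:
            return f"{accession}:p.{three(ref[0])}{pos}delins{three(alt)}"
        last = pos + len(ref) - 1
        return f"{accession}:p.{three(ref[0])}{pos}_{three(ref[-1])}{last}delins{three(alt)}"
    return f"{accession}:p.{pos}="
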