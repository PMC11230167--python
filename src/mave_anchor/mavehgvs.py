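"""Parsing and formatting of MAVE-HGVS variant strings.

MaveDB score matrices describe variants (``p.Ala40Ser``, ``n.2G>A``) relative
to an assay-specific target sequence rather than a reference accession.  This
module turns those strings into structured descriptions, renders them back,
and derives the expected-reference-residue map used to detect discordance
between a score matrix and its target sequence.

Positions are 1-based on the described sequence throughout this module;
conversion to interbase coordinates happens only when VRS objects are built.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError, UnsupportedVariantError

# One-letter <-> three-letter residue tables (Ter/* included; unknown codes raise).
_AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
_AA_1TO3 = {one: three for three, one in _AA_3TO1.items()}

_LAYERS = ("p", "c", "n", "g")
_IDENTITY_TOKENS = ("_wt", "_sy")

_AA3_RE = r"(?:%s|\*)" % "|".join(_AA_3TO1)
_NT_RE = r"[ACGTNacgtn]"

_P_SUB = re.compile(rf"^(?P<ref>{_AA3_RE})(?P<pos>\d+)(?P<alt>{_AA3_RE}|=)$")
_P_DEL = re.compile(
    rf"^(?P<r1>{_AA3_RE})(?P<p1>\d+)(?:_(?P<r2>{_AA3_RE})(?P<p2>\d+))?del$"
)
_P_INS = re.compile(
    rf"^(?P<r1>{_AA3_RE})(?P<p1>\d+)_(?P<r2>{_AA3_RE})(?P<p2>\d+)"
    rf"ins(?P<alt>(?:{_AA3_RE})+)$"
)
_P_DELINS = re.compile(
    rf"^(?P<r1>{_AA3_RE})(?P<p1>\d+)(?:_(?P<r2>{_AA3_RE})(?P<p2>\d+))?"
    rf"delins(?P<alt>(?:{_AA3_RE})+)$"
)
_N_SUB = re.compile(rf"^(?P<pos>\d+)(?P<ref>{_NT_RE}+)>(?P<alt>{_NT_RE}+)$")
_N_DEL = re.compile(rf"^(?P<p1>\d+)(?:_(?P<p2>\d+))?del(?P<ref>{_NT_RE}+)?$")
_N_INS = re.compile(rf"^(?P<p1>\d+)_(?P<p2>\d+)ins(?P<alt>{_NT_RE}+)$")
_N_DELINS = re.compile(
    rf"^(?P<p1>\d+)(?:_(?P<p2>\d+))?delins(?P<alt>{_NT_RE}+)$"
)
_UNSUPPORTED = re.compile(r"(dup|inv|con|\[\d+\]|ext|fs)")


@dataclass
class VariantDescription:
    """One parsed MAVE-HGVS event on a target sequence.

    ``ref_allele`` holds residues fully stated by (or implied contiguously
    from) the string; protein range events state only their endpoint residues,
    kept in ``stated_start_res``/``stated_end_res`` for round-trip formatting
    and discordance checks.  Protein alleles use one-letter residues.
    """

    layer: str                      # p | c | n | g
    kind: str                       # substitution | deletion | insertion | delins | identity
    start: int                      # 1-based
    end: int                        # 1-based inclusive (== start for single-residue events)
    ref_allele: str = ""
    alt_allele: str = ""
    accession: str | None = None
    raw: str = ""
    stated_start_res: str = ""      # protein range/insertion flank residues
    stated_end_res: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ParseError(f"position must be >= 1, got {self.start} in {self.raw!r}")
        if self.end < self.start:
            raise ParseError(f"end {self.end} precedes start {self.start} in {self.raw!r}")

    @property
    def span(self) -> tuple[int, int]:
        """Inclusive 1-based residue/base span occupied on the target.

        Insertions occupy no residue; their span is the empty interval at the
        junction, so adjacent events do not count as overlapping.
        """
        if self.kind == "insertion":
            return (self.end, self.start)  # empty interval
        return (self.start, self.end)


@dataclass
class VariantGroup:
    """One score-matrix row: a single variant or a semicolon cis-group."""

    members: list[VariantDescription] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ParseError("variant group has no members")
        self.members.sort(key=lambda m: (m.start, m.end))
        last_end = 0
        for m in self.members:
            lo, hi = m.span
            if lo <= last_end and hi >= lo:
                raise ParseError(
                    f"overlapping members in cis-group at position {m.start} ({m.raw!r})"
                )
            last_end = max(last_end, hi)

    @property
    def is_haplotype(self) -> bool:
        return len(self.members) > 1

    @property
    def layer(self) -> str:
        return self.members[0].layer

    @property
    def accession(self) -> str | None:
        return self.members[0].accession


def three_to_one(res: str) -> str:
    """Convert a three-letter residue code (or ``*``) to one-letter."""
    if res == "*":
        return "*"
    try:
        return _AA_3TO1[res]
    except KeyError:
        raise ParseError(f"unknown residue code {res!r}") from None


def one_to_three(res: str) -> str:
    try:
        return _AA_1TO3[res]
    except KeyError:
        raise ParseError(f"unknown residue letter {res!r}") from None


def _split_aa3(seq: str) -> list[str]:
    out = []
    i = 0
    while i < len(seq):
        if seq[i] == "*":
            out.append("*")
            i += 1
        else:
            out.append(seq[i : i + 3])
            i += 3
    return out


def _parse_protein_body(body: str, accession: str | None, raw: str) -> VariantDescription:
    if body in ("=", "(=)"):
        return VariantDescription("p", "identity", 1, 1, accession=accession, raw=raw)
    m = _P_SUB.match(body)
    if m:
        ref = three_to_one(m["ref"])
        pos = int(m["pos"])
        if m["alt"] == "=":
            return VariantDescription(
                "p", "identity", pos, pos, ref_allele=ref, alt_allele=ref,
                accession=accession, raw=raw,
            )
        return VariantDescription(
            "p", "substitution", pos, pos, ref_allele=ref,
            alt_allele=three_to_one(m["alt"]), accession=accession, raw=raw,
        )
    m = _P_DEL.match(body)
    if m:
        p1 = int(m["p1"])
        r1 = three_to_one(m["r1"])
        if m["p2"] is None:
            return VariantDescription(
                "p", "deletion", p1, p1, ref_allele=r1, accession=accession, raw=raw,
                stated_start_res=r1, stated_end_res=r1,
            )
        p2 = int(m["p2"])
        return VariantDescription(
            "p", "deletion", p1, p2, accession=accession, raw=raw,
            stated_start_res=r1, stated_end_res=three_to_one(m["r2"]),
        )
    m = _P_INS.match(body)
    if m:
        p1, p2 = int(m["p1"]), int(m["p2"])
        if p2 != p1 + 1:
            raise ParseError(f"insertion flanks must be adjacent in {raw!r}")
        alt = "".join(three_to_one(r) for r in _split_aa3(m["alt"]))
        return VariantDescription(
            "p", "insertion", p1, p2, alt_allele=alt, accession=accession, raw=raw,
            stated_start_res=three_to_one(m["r1"]),
            stated_end_res=three_to_one(m["r2"]),
        )
    m = _P_DELINS.match(body)
    if m:
        p1 = int(m["p1"])
        p2 = int(m["p2"]) if m["p2"] is not None else p1
        r1 = three_to_one(m["r1"])
        r2 = three_to_one(m["r2"]) if m["r2"] is not None else r1
        alt = "".join(three_to_one(r) for r in _split_aa3(m["alt"]))
        return VariantDescription(
            "p", "delins", p1, p2, ref_allele=r1 if p1 == p2 else "",
            alt_allele=alt, accession=accession, raw=raw,
            stated_start_res=r1, stated_end_res=r2,
        )
    raise ParseError(f"cannot parse protein variant token {body!r} in {raw!r}")


def _parse_nucleotide_body(layer: str, body: str, accession: str | None, raw: str) -> VariantDescription:
    if body == "=":
        return VariantDescription(layer, "identity", 1, 1, accession=accession, raw=raw)
    m = _N_SUB.match(body)
    if m:
        ref, alt = m["ref"].upper(), m["alt"].upper()
        if len(ref) != len(alt):
            raise ParseError(f"substitution alleles differ in length in {raw!r}")
        pos = int(m["pos"])
        return VariantDescription(
            layer, "substitution", pos, pos + len(ref) - 1,
            ref_allele=ref, alt_allele=alt, accession=accession, raw=raw,
        )
    m = _N_DEL.match(body)
    if m:
        p1 = int(m["p1"])
        p2 = int(m["p2"]) if m["p2"] is not None else p1
        ref = (m["ref"] or "").upper()
        if ref and len(ref) != p2 - p1 + 1:
            raise ParseError(f"deleted bases do not fit span in {raw!r}")
        return VariantDescription(
            layer, "deletion", p1, p2, ref_allele=ref, accession=accession, raw=raw,
        )
    m = _N_INS.match(body)
    if m:
        p1, p2 = int(m["p1"]), int(m["p2"])
        if p2 != p1 + 1:
            raise ParseError(f"insertion flanks must be adjacent in {raw!r}")
        return VariantDescription(
            layer, "insertion", p1, p2, alt_allele=m["alt"].upper(),
            accession=accession, raw=raw,
        )
    m = _N_DELINS.match(body)
    if m:
        p1 = int(m["p1"])
        p2 = int(m["p2"]) if m["p2"] is not None else p1
        return VariantDescription(
            layer, "delins", p1, p2, alt_allele=m["alt"].upper(),
            accession=accession, raw=raw,
        )
    raise ParseError(f"cannot parse nucleotide variant token {body!r} in {raw!r}")


def _parse_one(layer: str, body: str, accession: str | None, raw: str) -> VariantDescription:
    if _UNSUPPORTED.search(body):
        raise UnsupportedVariantError(f"unsupported variant class in {raw!r}: {body!r}")
    if layer == "p":
        return _parse_protein_body(body, accession, raw)
    return _parse_nucleotide_body(layer, body, accession, raw)


def parse_variant(raw: str, layer_hint: str = "n") -> VariantGroup:
    """Parse a MaveDB ``hgvs_nt``/``hgvs_pro`` cell into a :class:`VariantGroup`.

    An accession prefix before the final ``:`` (``NP_009225.1:p.Pro1659Leu``)
    is captured onto every member.  Semicolon cis-groups (``c.[1A>T;6del]``)
    produce multi-member groups.  The bare MAVE-HGVS tokens ``_wt`` and
    ``_sy`` parse as identity events at the layer given by ``layer_hint``.

    Raises :class:`ParseError` for malformed strings and
    :class:`UnsupportedVariantError` for variant classes outside the model
    (duplications, inversions, copy number, frameshifts).
    """
    if not raw or not raw.strip():
        raise ParseError("empty variant string")
    s = "".join(raw.split())  # strip all whitespace
    if s in _IDENTITY_TOKENS:
        return VariantGroup([
            VariantDescription(layer_hint, "identity", 1, 1, raw=s)
        ])
    accession: str | None = None
    if ":" in s:
        accession, s = s.rsplit(":", 1)
    m = re.match(r"^([A-Za-z])\.(.*)$", s)
    if not m:
        raise ParseError(f"missing layer prefix in {raw!r}")
    layer = m.group(1).lower()
    if layer not in _LAYERS:
        raise ParseError(f"unknown layer prefix {m.group(1)!r} in {raw!r}")
    body = m.group(2)
    if body.startswith("[") and body.endswith("]"):
        tokens = body[1:-1].split(";")
        members = [_parse_one(layer, t, accession, raw) for t in tokens]
        return VariantGroup(members)
    return VariantGroup([_parse_one(layer, body, accession, raw)])


def _format_member(m: VariantDescription) -> str:
    if m.layer == "p":
        if m.kind == "identity":
            return f"{one_to_three(m.ref_allele)}{m.start}=" if m.ref_allele else "="
        if m.kind == "substitution":
            return f"{one_to_three(m.ref_allele)}{m.start}{one_to_three(m.alt_allele)}"
        alt3 = "".join(one_to_three(a) for a in m.alt_allele)
        left = f"{one_to_three(m.stated_start_res)}{m.start}"
        right = f"{one_to_three(m.stated_end_res)}{m.end}"
        if m.kind == "deletion":
            return f"{left}del" if m.start == m.end else f"{left}_{right}del"
        if m.kind == "insertion":
            return f"{left}_{right}ins{alt3}"
        if m.kind == "delins":
            return f"{left}delins{alt3}" if m.start == m.end else f"{left}_{right}delins{alt3}"
    else:
        if m.kind == "identity":
            return "="
        if m.kind == "substitution":
            return f"{m.start}{m.ref_allele}>{m.alt_allele}"
        pos = f"{m.start}" if m.start == m.end else f"{m.start}_{m.end}"
        if m.kind == "deletion":
            return f"{pos}del"
        if m.kind == "insertion":
            return f"{m.start}_{m.end}ins{m.alt_allele}"
        if m.kind == "delins":
            return f"{pos}delins{m.alt_allele}"
    raise ParseError(f"cannot format variant kind {m.kind!r}")


def format_variant(group: VariantGroup) -> str:
    """Render a group back to canonical MAVE-HGVS.

    Inverse of :func:`parse_variant` on canonical inputs (bare ``_wt``/``_sy``
    rows render as their original token).
    """
    if len(group.members) == 1 and group.members[0].raw in _IDENTITY_TOKENS:
        return group.members[0].raw
    layer = group.layer
    prefix = f"{group.accession}:" if group.accession else ""
    bodies = [_format_member(m) for m in group.members]
    if group.is_haplotype:
        return f"{prefix}{layer}.[{';'.join(bodies)}]"
    return f"{prefix}{layer}.{bodies[0]}"


def expected_reference_map(rows: list[VariantGroup]) -> dict[int, str]:
    """Assemble the expected reference residue at each protein position.

    Walks every parsed protein-layer member and records the residues the score
    matrix claims for the target (e.g. ``{1: "M", 2: "A"}``).  Protein range
    events contribute their stated endpoint residues; insertions contribute
    their flanks.  Conflicting claims for one position raise a ``ParseError``
    naming the position and both residues.  Order-independent in its input.
    """
    expected: dict[int, str] = {}

    def put(pos: int, res: str) -> None:
        if not res or res == "*":
            return
        prev = expected.get(pos)
        if prev is not None and prev != res:
            raise ParseError(
                f"conflicting expected residues at position {pos}: {prev!r} vs {res!r}"
            )
        expected[pos] = res

    for group in rows:
        for m in group.members:
            if m.layer != "p" or m.raw in _IDENTITY_TOKENS:
                continue
            if m.kind in ("substitution",) or (m.kind == "identity" and m.ref_allele):
                put(m.start, m.ref_allele)
            elif m.kind in ("deletion", "delins", "insertion"):
                if m.stated_start_res:
                    put(m.start, m.stated_start_res)
                if m.stated_end_res:
                    put(m.end, m.stated_end_res)
    return expected
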