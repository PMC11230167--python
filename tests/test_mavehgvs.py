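import pytest
from hypothesis import given, settings, strategies as st

from mave_anchor import (
    ParseError,
    UnsupportedVariantError,
    expected_reference_map,
    format_variant,
    parse_variant,
)


class TestParse:
    def test_protein_substitution(self):
        g = parse_variant("p.Ala40Ser")
        (m,) = g.members
        assert (m.layer, m.kind, m.start, m.ref_allele, m.alt_allele) == (
            "p", "substitution", 40, "A", "S",
        )
        assert not g.is_haplotype

    def test_nucleotide_substitution(self):
        (m,) = parse_variant("n.2G>A").members
        assert (m.layer, m.kind, m.start, m.ref_allele, m.alt_allele) == (
            "n", "substitution", 2, "G", "A",
        )

    def test_accession_prefix_captured(self):
        (m,) = parse_variant("NP_009225.1:p.Pro1659Leu").members
        assert m.accession == "NP_009225.1"
        assert (m.start, m.ref_allele, m.alt_allele) == (1659, "P", "L")

    def test_cis_group(self):
        g = parse_variant("c.[1A>T;6del]")
        assert g.is_haplotype and len(g.members) == 2
        assert [m.kind for m in g.members] == ["substitution", "deletion"]

    @pytest.mark.parametrize(
        "raw,kind,start,end",
        [
            ("p.Ala40del", "deletion", 40, 40),
            ("p.Ala40_Leu42del", "deletion", 40, 42),
            ("p.Ala40_Leu41insGly", "insertion", 40, 41),
            ("p.Ala40delinsGlyVal", "delins", 40, 40),
            ("c.6_8del", "deletion", 6, 8),
            ("c.6_7insAT", "insertion", 6, 7),
            ("c.6_8delinsTT", "delins", 6, 8),
            ("g.100A>C", "substitution", 100, 100),
        ],
    )
    def test_event_kinds(self, raw, kind, start, end):
        (m,) = parse_variant(raw).members
        assert (m.kind, m.start, m.end) == (kind, start, end)

    @pytest.mark.parametrize("token", ["_wt", "_sy"])
    def test_special_identity_tokens(self, token):
        g = parse_variant(token, layer_hint="p")
        assert g.members[0].kind == "identity"
        assert format_variant(g) == token

    @pytest.mark.parametrize(
        "raw", ["", "p.Ala40", "x.1A>T", "c.1A>TT", "p.Xyz40Ser", "c.7_6insA"]
    )
    def test_malformed_raises(self, raw):
        with pytest.raises(ParseError):
            parse_variant(raw)

    @pytest.mark.parametrize("raw", ["c.1_3dup", "c.4_6inv", "p.Met1ext-5"])
    def test_unsupported_classes(self, raw):
        with pytest.raises(UnsupportedVariantError):
            parse_variant(raw)

    def test_overlapping_members_raise(self):
        with pytest.raises(ParseError):
            parse_variant("c.[1_5del;3A>T]")


_NT = st.sampled_from("ACGT")
_AA3 = st.sampled_from(
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val".split()
)


@st.composite
def canonical_strings(draw):
    layer = draw(st.sampled_from(["c", "n", "g", "p"]))
    pos = draw(st.integers(1, 500))
    if layer == "p":
        choice = draw(st.integers(0, 3))
        a, b = draw(_AA3), draw(_AA3)
        if choice == 0:
            return f"p.{a}{pos}{b}"
        if choice == 1:
            return f"p.{a}{pos}del"
        if choice == 2:
            ins = "".join(draw(st.lists(_AA3, min_size=1, max_size=2)))
            return f"p.{a}{pos}_{b}{pos + 1}ins{ins}"
        ins = "".join(draw(st.lists(_AA3, min_size=1, max_size=2)))
        return f"p.{a}{pos}_{b}{pos + 2}delins{ins}"
    choice = draw(st.integers(0, 3))
    if choice == 0:
        ref, alt = draw(_NT), draw(_NT)
        return f"{layer}.{pos}{ref}>{alt}" if ref != alt else f"{layer}.{pos}A>G"
    if choice == 1:
        width = draw(st.integers(0, 3))
        return f"{layer}.{pos}del" if width == 0 else f"{layer}.{pos}_{pos + width}del"
    if choice == 2:
        ins = "".join(draw(st.lists(_NT, min_size=1, max_size=3)))
        return f"{layer}.{pos}_{pos + 1}ins{ins}"
    ins = "".join(draw(st.lists(_NT, min_size=1, max_size=3)))
    return f"{layer}.{pos}_{pos + 2}delins{ins}"


class TestFormat:
    @pytest.mark.parametrize(
        "raw",
        ["p.Ala40Ser", "n.2G>A", "c.6del", "c.[1A>T;6del]",
         "NP_009225.1:p.Pro1659Leu", "p.[Ala40Ser;Leu42del]"],
    )
    def test_round_trip_examples(self, raw):
        assert format_variant(parse_variant(raw)) == raw

    @settings(max_examples=300, deadline=None)
    @given(canonical_strings())
    def test_round_trip_generated_corpus(self, raw):
        assert format_variant(parse_variant(raw)) == raw


class TestExpectedReferenceMap:
    def test_position_to_residue_map(self):
        rows = [parse_variant("p.Met1Leu"), parse_variant("p.Ala2Val")]
        assert expected_reference_map(rows) == {1: "M", 2: "A"}

    def test_single_row(self):
        assert expected_reference_map([parse_variant("p.Arg100His")]) == {100: "R"}

    def test_empty(self):
        assert expected_reference_map([]) == {}

    def test_order_independent(self):
        rows = [parse_variant(s) for s in ("p.Met1Leu", "p.Ala2Val", "p.Gly3Ser")]
        assert expected_reference_map(rows) == expected_reference_map(rows[::-1])

    def test_conflict_names_position_and_residues(self):
        rows = [parse_variant("p.Arg100His"), parse_variant("p.Leu100Pro")]
        with pytest.raises(ParseError, match="100"):
            expected_reference_map(rows)

    def test_range_events_contribute_endpoints(self):
        rows = [parse_variant("p.Ala40_Leu42del")]
        assert expected_reference_map(rows) == {40: "A", 42: "L"}

    def test_nucleotide_rows_ignored(self):
        assert expected_reference_map([parse_variant("c.4A>T")]) == {}
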