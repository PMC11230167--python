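import random

import pytest
from hypothesis import given, settings, strategies as st

from mave_anchor import (
    MaveAnchorError,
    RangeError,
    SequenceStore,
    annotate_ref_allele,
    build_allele,
    build_haplotype,
    normalize_allele,
    sha512t24u,
    to_hgvs,
)
from mave_anchor.vrs import ID_PATTERN
from oracles import digest_oracle

# vectors computed independently with openssl (sha512 -> 24 bytes -> base64url)
OPENSSL_VECTORS = {
    b"": "z4PhNX7vuL3xVChQ1m2AB9Yg5AULVxXc",
    b"A": "IbT0vZ5k7TVcPrZ2oo6-2vbY8XvcNlmV",
    b"ACGT": "aKF498dAxcJAqme6QYQ7EZ07-fiw8Kw2",
    b"hello world": "MJ7MSJwS1utMxA9QyQLytNDtd-5RGnx6",
}


class TestDigest:
    @pytest.mark.parametrize("data,want", sorted(OPENSSL_VECTORS.items()))
    def test_openssl_frozen_vectors(self, data, want):
        assert sha512t24u(data) == want

    def test_random_bytes_match_stepwise_oracle(self):
        rng = random.Random(42)
        for _ in range(100):
            data = bytes(rng.randrange(256) for _ in range(rng.randrange(0, 64)))
            assert sha512t24u(data) == digest_oracle(data)

    def test_shape_and_determinism(self):
        d = sha512t24u(b"x")
        assert len(d) == 32 and d == sha512t24u(b"x")
        assert sha512t24u(b"A") != sha512t24u(b"C")


def brute_equivalents(context, start, end, alt):
    """All minimal representations producing the same edited string."""
    edited = context[:start] + alt + context[end:]
    reps = []
    if len(alt) < end - start:  # deletion
        d = (end - start) - len(alt)
        for s in range(len(context) - d + 1):
            if context[:s] + context[s + d:] == edited:
                reps.append((s, s + d, ""))
    else:  # insertion
        d = len(alt) - (end - start)
        for s in range(len(context) + 1):
            ins = edited[s : s + d]
            if context[:s] + ins + context[s:] == edited:
                reps.append((s, s, ins))
    return reps


class TestNormalizeAllele:
    def test_substitution_unchanged(self):
        assert normalize_allele(4, 5, "A", "CAAATGG") == (4, 5, "T", "A")

    def test_deletion_in_run_fully_justified(self):
        # deleting any single A from CAAAT gives the same expanded allele
        for start in (1, 2, 3):
            assert normalize_allele(start, start + 1, "", "CAAAT") == (1, 4, "AAA", "AA")

    def test_insertion_in_run_fully_justified(self):
        for junction in (1, 2, 3, 4):
            assert normalize_allele(junction, junction, "A", "CAAAT") == (
                1, 4, "AAA", "AAAA",
            )

    def test_out_of_range(self):
        with pytest.raises(RangeError):
            normalize_allele(0, 99, "A", "CAAAT")

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_idempotent(self, data):
        context = data.draw(st.text(alphabet="ACGT", min_size=4, max_size=30))
        start = data.draw(st.integers(0, len(context)))
        end = data.draw(st.integers(start, len(context)))
        alt = data.draw(st.text(alphabet="ACGT", max_size=4))
        s1, e1, r1, a1 = normalize_allele(start, end, alt, context)
        assert normalize_allele(s1, e1, a1, context) == (s1, e1, r1, a1)

    def test_equivalent_shifted_indels_converge_to_oracle(self):
        """All shifted representations of 400 random indels in random repeat
        contexts normalize to one allele, equal to the brute-force roll
        oracle."""
        from oracles import justify_oracle

        rng = random.Random(7)
        for _ in range(400):
            unit = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
            context = "".join(
                rng.choice(["A", "C", "G", "T", unit, unit * 2])
                for _ in range(rng.randint(4, 12))
            )
            if rng.random() < 0.5 and len(context) > len(unit):
                start = rng.randrange(len(context) - len(unit))
                spec = (start, start + len(unit), "")
            else:
                start = rng.randrange(len(context) + 1)
                spec = (start, start, unit)
            want = justify_oracle(context, *spec)
            outputs = set()
            for s, e, a in brute_equivalents(context, *spec):
                outputs.add(normalize_allele(s, e, a, context))
            assert outputs == {normalize_allele(*spec, context)} == {want}


@pytest.fixture()
def toy_store():
    store = SequenceStore()
    seq_id = store.add("toy", "CAAATGGGTTTACCA")
    return store, seq_id


class TestBuildAllele:
    def test_deterministic_ids_golden(self, toy_store):
        store, seq_id = toy_store
        assert seq_id == "ga4gh:SQ.sXnLhioyGJF9GDq19D4xsQj_HR93bMzv"
        a = build_allele(seq_id, 4, 5, "A", store)
        assert a.id == "ga4gh:VA.oIMZxYuP_EH9jgywfTVGzumfO6atdAuw"
        assert build_allele(seq_id, 4, 5, "A", store).id == a.id

    def test_pre_and_post_sequences_give_distinct_ids(self, toy_store):
        store, seq_id = toy_store
        other_id = store.add("other", "CAAATGGGTTTACCAG")
        a = build_allele(seq_id, 4, 5, "A", store)
        b = build_allele(other_id, 4, 5, "A", store)
        assert a.id != b.id

    def test_equivalent_shifted_indels_same_id(self, toy_store):
        store, seq_id = toy_store
        ids = {build_allele(seq_id, s, s + 1, "", store).id for s in (1, 2, 3)}
        assert ids == {"ga4gh:VA.uhr9G7EhaZSQPm6Rq4c1NfQg1kP28NdJ"}

    def test_id_pattern(self, toy_store):
        store, seq_id = toy_store
        a = build_allele(seq_id, 0, 1, "G", store)
        assert ID_PATTERN.match(a.id) and ID_PATTERN.match(seq_id)


class TestBuildHaplotype:
    def test_order_invariant_golden(self, toy_store):
        store, seq_id = toy_store
        a = build_allele(seq_id, 4, 5, "A", store)
        c = build_allele(seq_id, 9, 10, "C", store)
        h1, h2 = build_haplotype([a, c]), build_haplotype([c, a])
        assert h1.id == h2.id == "ga4gh:VH.xDaTh8cO7ruLWTDmQaw3cveuixegY5Kq"

    def test_two_member_group(self, toy_store):
        store, seq_id = toy_store
        a = build_allele(seq_id, 4, 5, "A", store)
        c = build_allele(seq_id, 9, 10, "C", store)
        assert len(build_haplotype([a, c]).members) == 2

    def test_single_member_rejected(self, toy_store):
        store, seq_id = toy_store
        a = build_allele(seq_id, 4, 5, "A", store)
        with pytest.raises(MaveAnchorError):
            build_haplotype([a])

    def test_duplicate_member_rejected(self, toy_store):
        store, seq_id = toy_store
        a = build_allele(seq_id, 4, 5, "A", store)
        with pytest.raises(MaveAnchorError):
            build_haplotype([a, a])


class TestAnnotateAndHgvs:
    def test_ref_allele_annotation(self, toy_store):
        store, seq_id = toy_store
        a = annotate_ref_allele(build_allele(seq_id, 4, 5, "A", store), store)
        assert a.vrs_ref_allele_seq == "T"
        assert len(a.vrs_ref_allele_seq) == a.location.end - a.location.start

    def test_zero_length_insertion_annotation(self, toy_store):
        store, seq_id = toy_store
        a = annotate_ref_allele(build_allele(seq_id, 7, 7, "C", store), store)
        assert a.vrs_ref_allele_seq == ""

    def test_genomic_substitution_rendering(self):
        """The printed form of a chromosome-anchored C>A substitution."""
        store = SequenceStore()
        seq = "N" * 37808022 + "C" + "N" * 5
        # large synthetic context is wasteful; splice a focused fake instead
        store._seqs["NC_000006.12"] = seq
        a = build_allele("NC_000006.12", 37808022, 37808023, "A", store)
        a = annotate_ref_allele(a, store)
        assert to_hgvs(a, "NC_000006.12", "g") == "NC_000006.12:g.37808023C>A"

    def test_protein_substitution_rendering(self):
        store = SequenceStore()
        store._seqs["NP_009225.1"] = "A" * 1658 + "P" + "A" * 5
        a = build_allele("NP_009225.1", 1658, 1659, "L", store)
        a = annotate_ref_allele(a, store)
        assert to_hgvs(a, "NP_009225.1", "p") == "NP_009225.1:p.Pro1659Leu"

    def test_single_base_deletion_rendering(self, toy_store):
        store, _ = toy_store
        store.add("ACC1", "CTGGA")
        a = annotate_ref_allele(build_allele("ACC1", 1, 2, "", store), store)
        assert to_hgvs(a, "ACC1", "g") == "ACC1:g.2del"
        # an ambiguous deletion renders at its 3'-most equivalent position
        b = annotate_ref_allele(build_allele("ACC1", 2, 3, "", store), store)
        assert to_hgvs(b, "ACC1", "g") == "ACC1:g.4del"

    def test_pre_mapped_digest_sequence_rejected(self, toy_store):
        store, seq_id = toy_store
        a = annotate_ref_allele(build_allele(seq_id, 4, 5, "A", store), store)
        with pytest.raises(MaveAnchorError):
            to_hgvs(a, seq_id, "g")
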