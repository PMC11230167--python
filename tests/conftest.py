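from __future__ import annotations

import pytest

from mave_anchor import (
    FixtureSpec,
    generate_fixture,
    map_scoreset,
)
from mave_anchor.lifting import UnmappableReason
from mave_anchor.vrs import VrsHaplotype


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Seed-1 plus-strand fixture: stores, metadata, rows, truth, mapping."""
    d = tmp_path_factory.mktemp("fixture-plus")
    stores, meta, rows, truth = generate_fixture(FixtureSpec(seed=1, strand="+"), d)
    mapped = map_scoreset(meta, rows, stores)
    return {
        "stores": stores, "meta": meta, "rows": rows, "truth": truth,
        "mapped": mapped, "dir": d,
    }


@pytest.fixture(scope="session")
def fixture_bundle_minus(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture-minus")
    stores, meta, rows, truth = generate_fixture(FixtureSpec(seed=1, strand="-"), d)
    mapped = map_scoreset(meta, rows, stores)
    return {
        "stores": stores, "meta": meta, "rows": rows, "truth": truth,
        "mapped": mapped, "dir": d,
    }


def truth_disagreements(mapped_sets, truth):
    """Compare a mapping run against the generator's truth table.

    Returns a list of disagreement descriptions (empty == 100% agreement):
    designed-mappable rows must yield the expected accession/spans/alleles
    and designed-unmappable rows the expected reason code.
    """
    by_key = {}
    for m in mapped_sets:
        layer = "pro" if m.layer == "p" else "nt"
        for mv in m.mapped_scores:
            by_key[(mv.row, layer)] = (mv, m)
    bad = []
    for t in truth:
        if (t.row, t.layer) not in by_key:
            bad.append((t.row, t.layer, "row missing from mapping output"))
            continue
        mv, ms = by_key[(t.row, t.layer)]
        post = mv.post_mapped
        if t.outcome in ("allele", "haplotype"):
            if not mv.is_mapped:
                bad.append((t.row, t.layer, t.hgvs, "not mapped", post))
                continue
            if ms.mapped_reference_sequence["sequence_accession"] != t.accession:
                bad.append((t.row, t.layer, "wrong accession"))
                continue
            members = post.members if isinstance(post, VrsHaplotype) else [post]
            got = [
                (a.location.start, a.location.end, a.vrs_ref_allele_seq, a.state)
                for a in members
            ]
            want = list(zip(t.starts, t.ends, t.refs, t.alts))
            if got != want:
                bad.append((t.row, t.layer, t.hgvs, got, want))
        else:
            if not isinstance(post, UnmappableReason) or post.code != t.outcome:
                bad.append((t.row, t.layer, t.hgvs, "expected", t.outcome, "got", post))
    return bad
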