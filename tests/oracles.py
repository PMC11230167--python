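"""Independent oracles used by the test suite.

These deliberately re-derive expected values by brute force or first
principles, sharing no code path with the implementation they check.
"""

from __future__ import annotations

import base64
import hashlib

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def digest_oracle(data: bytes) -> str:
    """Step-by-step SHA-512 -> truncate 24 bytes -> base64url, no padding."""
    full = hashlib.sha512(data).digest()
    return base64.urlsafe_b64encode(full[:24]).decode("ascii")


def justify_oracle(context: str, start: int, end: int, alt: str):
    """Fully-justified normalization by brute-force enumeration.

    Enumerates every minimal representation producing the same edited string
    (plain string equality, no rolling logic) and expands to the outermost
    interval.  Returns ``(start, end, ref, alt)``.
    """
    ref = context[start:end]
    while ref and alt and ref[0] == alt[0]:
        start += 1
        ref, alt = ref[1:], alt[1:]
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    end = start + len(ref)
    if (ref and alt) or (not ref and not alt):
        return start, end, ref, alt
    edited = context[:start] + alt + context[end:]
    if ref:  # deletion of d characters
        d = len(ref)
        starts = [
            s for s in range(len(context) - d + 1)
            if context[:s] + context[s + d :] == edited
        ]
        lo, hi = min(starts), max(starts) + d
    else:  # insertion of d characters
        d = len(alt)
        starts = [
            s for s in range(len(context) + 1)
            if context[:s] + edited[s : s + d] + context[s:] == edited
        ]
        lo, hi = min(starts), max(starts)
    full_ref = context[lo:hi]
    full_alt = edited[lo : hi + len(edited) - len(context)]
    return lo, hi, full_ref, full_alt


def per_base_lift_map(blocks, strand: str) -> dict[int, int]:
    """Walk alignment blocks base by base: 1-based query position ->
    genomic coordinate of the affected base."""
    out: dict[int, int] = {}
    for b in blocks:
        for i in range(b.query_end - b.query_start):
            pos = b.query_start + i + 1
            out[pos] = b.ref_start + i if strand == "+" else (b.ref_end - 1) - i
    return out


def revcomp_oracle(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def shift_scan_oracle(target_protein: str, expected: dict[int, str]):
    """All shifts (any size) under which every expected residue matches."""
    hits = []
    for s in range(len(target_protein)):
        if all(
            pos - 1 + s < len(target_protein) and target_protein[pos - 1 + s] == res
            for pos, res in expected.items()
        ):
            hits.append(s)
    return hits
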