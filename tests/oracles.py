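"""Independent brute-force oracles used by several test modules."""

from __future__ import annotations


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as gapped string pairs
    (no column may gap both sequences)."""
    if not a and not b:
        yield ("", "")
        return
    if a and b:
        for x, y in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + x, b[0] + y)
    if a:
        for x, y in enumerate_alignments(a[1:], b):
            yield (a[0] + x, "-" + y)
    if b:
        for x, y in enumerate_alignments(a, b[1:]):
            yield ("-" + x, b[0] + y)


def score_alignment(ag: str, bg: str, match: float, mismatch: float, gap: float) -> float:
    total = 0.0
    for x, y in zip(ag, bg):
        if x == "-" or y == "-":
            total += gap
        elif x == y:
            total += match
        else:
            total += mismatch
    return total


def best_alignment_score(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Optimal global alignment score by exhaustive enumeration; only
    feasible for short strings."""
    return max(
        score_alignment(ag, bg, match, mismatch, gap)
        for ag, bg in enumerate_alignments(a, b)
    )
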