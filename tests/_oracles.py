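"""Independent brute-force references used to check the fast implementations."""

from __future__ import annotations

from functools import lru_cache


def brute_force_tag_score(
    tag: str,
    prefix: str,
    mismatch: int = -1,
    gap_open: int = -3,
    gap_extend: int = -1,
) -> int:
    """Reference for the truncation-tolerant semi-global tag score.

    Enumerates every tag-suffix start s (5' truncation, free) and recursively
    explores all alignments of tag[s:] against the prefix starting at its
    first base, where the alignment must consume the tag to its 3' end,
    trailing prefix bases are free, matches score +1, mismatches ``mismatch``
    and gap runs ``gap_open`` for the first base then ``gap_extend`` per
    additional base.  Floored at 0 (the whole tag overhanging before the read
    start aligns nothing); empty prefix is defined as -|tag| (the all-gap
    alignment).
    """
    m, n = len(tag), len(prefix)
    if n == 0:
        return -m

    # prev: 0 = match/mismatch, 1 = gap in prefix (tag base unaligned),
    # 2 = gap in tag (prefix base unaligned)
    @lru_cache(maxsize=None)
    def f(i: int, j: int, prev: int) -> float:
        if i == m:
            return 0
        best = -float("inf")
        if j < n:
            sub = 1 if tag[i] == prefix[j] else mismatch
            best = max(best, sub + f(i + 1, j + 1, 0))
            cost = gap_extend if prev == 2 else gap_open
            best = max(best, cost + f(i, j + 1, 2))
        cost = gap_extend if prev == 1 else gap_open
        best = max(best, cost + f(i + 1, j, 1))
        return best

    best = 0.0
    for s in range(m):
        best = max(best, f(s, 0, 0))
    return int(best)


def brute_force_bh(pvalues: list[float]) -> list[float]:
    """Step-up false-discovery-rate adjustment, straight from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted
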