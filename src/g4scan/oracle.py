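"""Exhaustive reference matcher for the PQS grammar.

Test oracle, independent of the production scanner: at each candidate
offset it enumerates *every* decomposition into tracts and loops the
grammar permits, then picks the winner by an explicit lexicographic
preference over the decision sequence — the chronological preference of
a backtracking engine with greedy tracts, lazy loops and a greedy
repeat: earlier decisions dominate, a longer tract is preferred at each
tract decision, a shorter loop at each loop decision, and continuing
with a further unit is preferred over stopping.  Intended for sequences
up to a few hundred nt.
"""

from __future__ import annotations

from math import inf
from typing import Iterator, Optional

from .pattern import (
    PQSMatch,
    PQSPattern,
    _validate,
    reverse_complement,
)

__all__ = ["oracle_scan", "oracle_scan_both_strands"]


def _run_lengths(s: str) -> list[int]:
    """rl[i] = number of consecutive Gs starting at i."""
    n = len(s)
    rl = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        if s[i] == "G":
            rl[i] = rl[i + 1] + 1
    return rl


def _chain_table(s: str, rl: list[int], pat: PQSPattern) -> list[int]:
    """chain[i] = achievable number of tract+loop units starting a tract
    at offset i, capped at pat.min_tracts (pruning table)."""
    n = len(s)
    cap = pat.min_tracts
    lmin, lmax = pat._loop_bounds
    exact_t = pat.exact_tract_len
    min_t = pat.min_tract_len
    chain = [0] * (n + 2 + max(lmax, 1))
    for i in range(n - 1, -1, -1):
        if exact_t is not None:
            if rl[i] != exact_t or (i > 0 and s[i - 1] == "G"):
                continue
            lo_k, hi_k = i + exact_t + lmin, i + exact_t + lmax
        else:
            if rl[i] < min_t:
                continue
            lo_k, hi_k = i + min_t + lmin, i + rl[i] + lmax
        best = 1
        for k in range(lo_k, min(hi_k, n - 1) + 1):
            if chain[k] > 0 and 1 + chain[k] > best:
                best = 1 + chain[k]
                if best >= cap:
                    break
        chain[i] = min(best, cap)
    return chain


def _parses(
    s: str,
    i: int,
    units: int,
    pat: PQSPattern,
    rl: list[int],
    chain: list[int],
) -> Iterator[tuple[tuple, int, int]]:
    """Yield every complete parse starting a tract at *i* as
    (preference_key, end, n_tracts).

    The key interleaves (-tract_len, loop_len, ...) in decision order and
    terminates with +inf, so that tuple ``min`` implements the
    chronological preference (larger tract first, then shorter loop,
    with continuation preferred over stopping since any finite loop
    length sorts before the terminator).
    """
    n = len(s)
    exact_t = pat.exact_tract_len
    min_t = pat.min_tract_len
    lmin, lmax = pat._loop_bounds
    min_units = pat.min_tracts

    def rec(i: int, units: int, prefix: tuple) -> Iterator[tuple[tuple, int, int]]:
        if exact_t is not None:
            tls = (exact_t,) if (rl[i] == exact_t and not (i > 0 and s[i - 1] == "G")) else ()
        else:
            tls = range(min_t, rl[i] + 1) if rl[i] >= min_t else ()
        for tl in tls:
            j = i + tl
            u = units + 1
            if u >= min_units:
                yield (prefix + (-tl, inf), j, u)
            needed = max(1, min_units - u)
            for ll in range(lmin, lmax + 1):
                k = j + ll
                if k < n and chain[k] >= needed:
                    yield from rec(k, u, prefix + (-tl, ll))

    yield from rec(i, units, ())


def oracle_scan(
    seq: str, pattern: Optional[PQSPattern] = None, seq_id: Optional[str] = None
) -> list[PQSMatch]:
    """Reference scan of the forward strand (exhaustive enumeration).

    Returns the same leftmost, non-overlapping match list the production
    scanner must produce; scanning resumes after each accepted match.
    """
    pat = pattern if pattern is not None else PQSPattern()
    s = _validate(seq)
    n = len(s)
    rl = _run_lengths(s)
    chain = _chain_table(s, rl, pat)
    out: list[PQSMatch] = []
    pos = 0
    while pos < n:
        start = next(
            (i for i in range(pos, n) if chain[i] >= pat.min_tracts), None
        )
        if start is None:
            break
        best = min(_parses(s, start, 0, pat, rl, chain))
        _, end, n_tracts = best
        out.append(PQSMatch(seq_id, start, end, "+", s[start:end], n_tracts))
        pos = end
    return out


def oracle_scan_both_strands(
    seq: str, pattern: Optional[PQSPattern] = None, seq_id: Optional[str] = None
) -> list[PQSMatch]:
    """Reference both-strand scan with the same coordinate mapping
    contract as the production scanner."""
    s = _validate(seq)
    n = len(s)
    plus = oracle_scan(s, pattern, seq_id)
    minus = [
        PQSMatch(seq_id, n - m.end, n - m.start, "-", m.matched_seq, m.n_tracts)
        for m in oracle_scan(reverse_complement(s), pattern, seq_id)
    ]
    return sorted(plus + minus, key=lambda m: (m.start, m.strand))
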