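"""Putative G-quadruplex sequence (PQS) pattern matching.

The canonical PQS grammar is ``G>=3 (N1-7 G>=3) x >=3`` — at least four
guanine tracts of three or more Gs, separated by loops of one to seven
nucleotides of any base (including G).  The production scanner reproduces
the disambiguation semantics of a backtracking regular-expression engine
applied to the pattern ``G{3,}(.{1,7}?G{3,}){3,}`` under repeated global
matching:

* G-tracts are *greedy* — each absorbs the longest run of Gs it can,
  giving bases back only when the rest of the match would otherwise fail;
* loops are *lazy* — each prefers the shortest spacer, lengthening only
  when needed;
* the tract+loop repeat is *greedy* — a match extends over as many units
  as possible before stopping;
* matches are leftmost-first and non-overlapping: after a match is
  accepted, scanning resumes at its end offset.

A consequence of loops admitting G is that tract boundaries follow the
backtracking order, not run maximality.  Worked example: in
``GGGGAGGGAGGGAGGGAGGG`` the first tract greedily takes all four leading
Gs and the greedy repeat then absorbs all four remaining units, so the
single reported match has five tracts.
"""

from __future__ import annotations

import re as _re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "PQSPattern",
    "PQSMatch",
    "InvalidSequenceError",
    "reverse_complement",
    "scan_forward",
    "scan_both_strands",
    "fullmatch",
]

#: IUPAC nucleotide one-letter codes accepted in input sequences.
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")

_BAD_CHAR = _re.compile(r"[^ACGTUNRYSWKMBDHV]")
_G_RUN = _re.compile(r"G+")

# Watson-Crick complement over the IUPAC alphabet (U -> A, N -> N,
# ambiguity codes map to their complementary ambiguity class).
_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


class InvalidSequenceError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide codes."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid nucleotide {char!r} at position {position} "
            f"(0-based); allowed: IUPAC codes {''.join(sorted(IUPAC_NUCLEOTIDES))}"
        )


def _validate(seq: str) -> str:
    """Uppercase *seq* and reject non-IUPAC characters (soft-masked
    lowercase bases are thereby scanned like any other)."""
    s = seq.upper()
    m = _BAD_CHAR.search(s)
    if m is not None:
        raise InvalidSequenceError(seq[m.start()], m.start())
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (N maps to N)."""
    return _validate(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PQSPattern:
    """Parameters of the PQS motif grammar.

    Defaults encode the canonical grammar (tracts of >=3 G, loops of 1-7
    of any base, >=4 tracts).  ``exact_tract_len`` / ``exact_loop_len``
    restrict to the subclass with tracts of exactly that many Gs (the
    tract must then be a maximal G-run, i.e. not extendable on either
    side) and loops of exactly that length — e.g. (3, 1) selects motifs
    built from G3 tracts and 1-nt loops.
    """

    min_tract_len: int = 3
    loop_min: int = 1
    loop_max: int = 7
    min_tracts: int = 4
    exact_tract_len: Optional[int] = None
    exact_loop_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_tract_len < 1:
            raise ValueError("min_tract_len must be >= 1")
        if not (0 <= self.loop_min <= self.loop_max):
            raise ValueError("need 0 <= loop_min <= loop_max")
        if self.min_tracts < 2:
            raise ValueError("min_tracts must be >= 2")
        if self.exact_tract_len is not None and self.exact_tract_len < self.min_tract_len:
            raise ValueError("exact_tract_len must be >= min_tract_len")
        if self.exact_loop_len is not None and not (
            self.loop_min <= self.exact_loop_len <= self.loop_max
        ):
            raise ValueError("exact_loop_len must lie within [loop_min, loop_max]")

    @property
    def _tract_need(self) -> int:
        return self.exact_tract_len if self.exact_tract_len is not None else self.min_tract_len

    @property
    def _loop_bounds(self) -> tuple[int, int]:
        if self.exact_loop_len is not None:
            return self.exact_loop_len, self.exact_loop_len
        return self.loop_min, self.loop_max

    def to_regex(self) -> str:
        """The equivalent regular expression (for cross-checking spans;
        exact-length variants are not expressible as a plain regex
        because of the run-maximality requirement)."""
        if self.exact_tract_len is not None or self.exact_loop_len is not None:
            raise ValueError("exact-length patterns have no plain-regex equivalent")
        return (
            f"G{{{self.min_tract_len},}}"
            f"(?:.{{{self.loop_min},{self.loop_max}}}?G{{{self.min_tract_len},}})"
            f"{{{self.min_tracts - 1},}}"
        )


@dataclass(frozen=True)
class PQSMatch:
    """A PQS occurrence on a scanned sequence.

    ``start``/``end`` are 0-based half-open offsets on the forward
    (as-given) sequence; ``matched_seq`` reads 5'->3' on the matched
    strand (for minus-strand matches it is the reverse complement of the
    forward-sequence slice).
    """

    seq_id: Optional[str]
    start: int
    end: int
    strand: str  # "+" or "-" relative to the as-given sequence
    matched_seq: str
    n_tracts: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError("need 0 <= start < end")
        if self.end - self.start != len(self.matched_seq):
            raise ValueError("span does not equal matched_seq length")


def _match_at(s: str, i0: int, pat: PQSPattern) -> Optional[tuple[int, int]]:
    """First-preference (chronological backtracking) parse of a match
    anchored at offset *i0*.  Returns ``(end, n_tracts)`` or None.
    """
    n = len(s)
    exact_t = pat.exact_tract_len
    min_t = pat.min_tract_len
    lmin, lmax = pat._loop_bounds
    min_units = pat.min_tracts
    need = pat._tract_need

    def run_len(i: int) -> int:
        j = i
        while j < n and s[j] == "G":
            j += 1
        return j - i

    def attempt(i: int, units: int) -> Optional[tuple[int, int]]:
        r = run_len(i)
        if exact_t is not None:
            # tract must be a maximal run of exactly exact_t Gs
            if r != exact_t or (i > 0 and s[i - 1] == "G"):
                return None
            lens = (exact_t,)
        else:
            if r < min_t:
                return None
            lens = range(r, min_t - 1, -1)  # greedy: longest first
        for tl in lens:
            j = i + tl
            u = units + 1
            # greedy repeat: prefer continuing with a further loop+tract
            for ll in range(lmin, lmax + 1):  # lazy loop: shortest first
                k = j + ll
                if k + need > n:
                    break
                res = attempt(k, u)
                if res is not None:
                    return res
            if u >= min_units:
                return (j, u)
        return None

    return attempt(i0, 0)


def scan_forward(
    seq: str, pattern: Optional[PQSPattern] = None, seq_id: Optional[str] = None
) -> list[PQSMatch]:
    """Scan the given strand for PQS motifs (all matches strand '+').

    Returns leftmost, mutually non-overlapping matches in start order;
    an empty sequence yields an empty list.
    """
    pat = pattern if pattern is not None else PQSPattern()
    s = _validate(seq)
    need = pat._tract_need
    out: list[PQSMatch] = []
    pos = 0
    for run in _G_RUN.finditer(s):
        if run.end() <= pos:
            continue
        start = max(run.start(), pos)
        if run.end() - start < need:
            continue
        res = _match_at(s, start, pat)
        if res is not None:
            end, n_tracts = res
            out.append(PQSMatch(seq_id, start, end, "+", s[start:end], n_tracts))
            pos = end
    return out


def scan_both_strands(
    seq: str, pattern: Optional[PQSPattern] = None, seq_id: Optional[str] = None
) -> list[PQSMatch]:
    """Scan both strands; minus-strand matches are mapped back into
    forward coordinates ([s, e) on the reverse complement becomes
    [L - e, L - s) forward).  Sorted by forward start, '+' before '-'.
    """
    s = _validate(seq)
    n = len(s)
    plus = scan_forward(s, pattern, seq_id)
    minus = [
        PQSMatch(seq_id, n - m.end, n - m.start, "-", m.matched_seq, m.n_tracts)
        for m in scan_forward(reverse_complement(s), pattern, seq_id)
    ]
    return sorted(plus + minus, key=lambda m: (m.start, m.strand))


def fullmatch(seq: str, pattern: Optional[PQSPattern] = None) -> Optional[int]:
    """Does *seq* parse, in its entirety, under the grammar?

    Unlike :func:`scan_forward` this requires the parse to consume the
    whole string (any parse, not the backtracking-first one).  Returns
    the tract count of such a parse, or None.  Used for subclass
    filtering (e.g. "G3 tracts with 1-nt loops").
    """
    pat = pattern if pattern is not None else PQSPattern()
    s = _validate(seq)
    n = len(s)
    if n == 0:
        return None
    exact_t = pat.exact_tract_len
    min_t = pat.min_tract_len
    lmin, lmax = pat._loop_bounds
    min_units = pat.min_tracts

    def run_len(i: int) -> int:
        j = i
        while j < n and s[j] == "G":
            j += 1
        return j - i

    def attempt(i: int, units: int) -> Optional[int]:
        r = run_len(i)
        if exact_t is not None:
            if r != exact_t or (i > 0 and s[i - 1] == "G"):
                return None
            lens = (exact_t,)
        else:
            if r < min_t:
                return None
            lens = range(r, min_t - 1, -1)
        for tl in lens:
            j = i + tl
            u = units + 1
            if j == n and u >= min_units:
                return u
            for ll in range(lmin, lmax + 1):
                res = attempt(j + ll, u) if j + ll < n else None
                if res is not None:
                    return res
        return None

    return attempt(0, 0)
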