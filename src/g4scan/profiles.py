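"""Distributional statistics of PQS occurrence around gene boundaries.

* windowed frequency metaprofiles, normalized to occurrences per 100
  sequences within a window (100 nt by default);
* strand-split 20-nt-resolution profiles of the first 1000 nt
  downstream of the TES;
* cumulative motif counts and percent PQS-positive genes as a function
  of upstream distance from the TSS;
* per-species percent-positive summaries and the exact-G3/1-nt-loop
  subclass count.

A motif is binned by its representative coordinate (the anchor
coordinate of its match start, i.e. its most distal base on upstream
flanks) and contributes to a cumulative distance d only when wholly
contained within [-d, -1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .flanks import AnchoredMatch, FlankRegion
from .pattern import PQSMatch, PQSPattern, fullmatch, scan_both_strands

__all__ = [
    "FrequencyProfile",
    "CumulativeCurve",
    "frequency_profile",
    "tes_strand_insert_profile",
    "cumulative_distribution",
    "percent_positive",
    "subclass_count",
    "species_summary",
]

STRAND_SCOPES = ("both", "non-template", "template")


@dataclass(frozen=True)
class FrequencyProfile:
    """Windowed occurrence frequencies, per 100 sequences.

    Window bounds are inclusive anchor coordinates in ascending order
    (upstream: from -L up to -1; downstream: from +1 up to +L).  The
    most anchor-distal window may be partial when the window size does
    not divide the flank length (``partial_last`` is then set).
    """

    anchor: str
    side: str
    window: int
    n_sequences: int
    strand_scope: str
    window_starts: np.ndarray
    window_ends: np.ndarray
    counts: np.ndarray
    partial_last: bool = False

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences * 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": self.window_starts,
                "window_end": self.window_ends,
                "count": self.counts,
                "frequency_per_100_sequences": self.frequencies,
            }
        )


@dataclass(frozen=True)
class CumulativeCurve:
    """Cumulative motif count and percent PQS-positive genes, outward
    from the TSS (distances 1..L bp)."""

    distances: np.ndarray
    cum_motifs: np.ndarray
    cum_positive_pct: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance": self.distances,
                "cum_motifs": self.cum_motifs,
                "cum_positive_pct": self.cum_positive_pct,
            }
        )


def _check_scope(anchored: Sequence[AnchoredMatch]) -> tuple[str, str]:
    pairs = {(a.anchor, a.side) for a in anchored}
    if len(pairs) > 1:
        raise ValueError(f"mixed anchors/sides in input: {sorted(pairs)}")
    return next(iter(pairs))


def frequency_profile(
    anchored: Sequence[AnchoredMatch],
    n_sequences: int,
    window: int = 100,
    strand_scope: str = "both",
    flank_len: int = 5000,
    anchor: Optional[str] = None,
    side: Optional[str] = None,
) -> FrequencyProfile:
    """Windowed frequency profile of anchored matches.

    Each motif is counted once, in the window containing its
    representative coordinate; frequency = count / n_sequences * 100.
    ``anchor``/``side`` only need to be given when *anchored* is empty.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if strand_scope not in STRAND_SCOPES:
        raise ValueError(f"strand_scope must be one of {STRAND_SCOPES}")
    if window < 1:
        raise ValueError("window must be >= 1")
    if anchored:
        anchor, side = _check_scope(anchored)
    elif anchor is None or side is None:
        anchor, side = "TSS", "upstream"

    n_windows = -(-flank_len // window)  # ceil
    partial = flank_len % window != 0
    counts = np.zeros(n_windows, dtype=np.int64)
    for a in anchored:
        if strand_scope != "both" and a.strand_class != strand_scope:
            continue
        depth = -a.coord if side == "upstream" else a.coord  # 1..L
        if depth < 1 or depth > flank_len:
            raise ValueError(f"coord {a.coord} outside flank of length {flank_len}")
        counts[(depth - 1) // window] += 1

    # windows indexed by proximity to the anchor; present them in
    # ascending coordinate order
    idx = np.arange(n_windows)
    near = idx * window + 1  # |coord| of window's anchor-proximal edge
    far = np.minimum((idx + 1) * window, flank_len)
    if side == "upstream":
        order = idx[::-1]
        starts, ends = -far[order], -near[order]
        counts = counts[order]
    else:
        starts, ends = near, far
    return FrequencyProfile(
        anchor=anchor,
        side=side,
        window=window,
        n_sequences=n_sequences,
        strand_scope=strand_scope,
        window_starts=starts,
        window_ends=ends,
        counts=counts,
        partial_last=partial,
    )


def tes_strand_insert_profile(
    anchored: Sequence[AnchoredMatch],
    n_sequences: int,
    region_len: int = 1000,
    window: int = 20,
) -> tuple[FrequencyProfile, FrequencyProfile]:
    """Strand-split 20-nt-resolution profiles of the region just
    downstream of the TES (non-template profile first)."""
    if anchored:
        anchor, side = _check_scope(anchored)
        if side != "downstream":
            raise ValueError("TES insert profiles require TES-downstream matches")
    kept = [a for a in anchored if a.coord <= region_len]
    profiles = tuple(
        frequency_profile(
            kept,
            n_sequences,
            window=window,
            strand_scope=scope,
            flank_len=region_len,
            anchor="TES",
            side="downstream",
        )
        for scope in ("non-template", "template")
    )
    return profiles  # type: ignore[return-value]


def cumulative_distribution(
    anchored: Sequence[AnchoredMatch],
    gene_universe: Sequence[str],
    max_distance: int = 5000,
) -> CumulativeCurve:
    """Cumulative motif count and percent positive genes vs upstream
    distance d = 1..max_distance.

    A motif with representative coordinate c contributes at distance d
    iff |c| <= d (whole-motif containment).  Both strand classes are
    counted.  The per-gene first occurrence reproduces a hash-set
    accumulation over the motif list sorted by descending coordinate.
    """
    universe = list(dict.fromkeys(gene_universe))
    if len(universe) != len(gene_universe):
        raise ValueError("duplicate gene ids in gene_universe")
    if not universe:
        raise ValueError("gene_universe is empty")
    uni = set(universe)
    depths = []
    for a in anchored:
        if a.side != "upstream":
            raise ValueError("cumulative distribution requires upstream matches")
        if a.gene_id not in uni:
            raise ValueError(f"gene {a.gene_id!r} missing from gene_universe")
        depths.append((-a.coord, a.gene_id))
    depths.sort(key=lambda t: t[0])  # ascending |coord| == descending coordinate

    motif_depths = np.array([d for d, _ in depths], dtype=np.int64)
    first_seen: dict[str, int] = {}
    for d, g in depths:
        if g not in first_seen:
            first_seen[g] = d
    gene_depths = np.sort(np.array(list(first_seen.values()), dtype=np.int64))

    distances = np.arange(1, max_distance + 1, dtype=np.int64)
    cum_motifs = np.searchsorted(motif_depths, distances, side="right")
    cum_genes = np.searchsorted(gene_depths, distances, side="right")
    return CumulativeCurve(
        distances=distances,
        cum_motifs=cum_motifs,
        cum_positive_pct=cum_genes / len(universe) * 100.0,
        n_genes=len(universe),
    )


def percent_positive(
    anchored: Sequence[AnchoredMatch],
    gene_universe: Sequence[str],
    max_distance: int = 5000,
) -> float:
    """Percent of genes with >= 1 wholly-contained motif within
    max_distance bp upstream of the TSS (both strands counted); equals
    the endpoint of :func:`cumulative_distribution`."""
    curve = cumulative_distribution(anchored, gene_universe, max_distance)
    return float(curve.cum_positive_pct[-1])


def subclass_count(
    matches: Iterable[Union[PQSMatch, str]],
    exact_tract_len: int = 3,
    exact_loop_len: int = 1,
    min_tracts: int = 4,
) -> int:
    """Count motifs whose full extent parses as exact-length tracts and
    loops (default: G3 tracts with 1-nt loops, >= 4 tracts).

    Tracts must be maximal G-runs of exactly ``exact_tract_len`` — a
    motif containing a longer tract, or any loop of a different length,
    is not counted.
    """
    pat = PQSPattern(
        min_tract_len=exact_tract_len,
        loop_min=min(exact_loop_len, 1),
        loop_max=max(exact_loop_len, 7),
        min_tracts=min_tracts,
        exact_tract_len=exact_tract_len,
        exact_loop_len=exact_loop_len,
    )
    n = 0
    for m in matches:
        seq = m.matched_seq if isinstance(m, PQSMatch) else m
        if fullmatch(seq, pat) is not None:
            n += 1
    return n


def species_summary(
    flank_sets: Sequence[tuple[str, Sequence[FlankRegion]]],
    pattern: Optional[PQSPattern] = None,
    max_distance: int = 5000,
) -> pd.DataFrame:
    """Per-species percent of PQS-positive genes in the upstream flanks.

    Takes (species_label, flanks) pairs; only TSS-upstream flanks are
    used.  Row order preserves the input configuration order.
    """
    from .flanks import anchor_matches

    labels = [lab for lab, _ in flank_sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species label")
    rows = []
    for label, flanks in flank_sets:
        ups = [f for f in flanks if f.side == "upstream"]
        if not ups:
            raise ValueError(f"species {label!r}: no upstream flanks")
        anchored: list[AnchoredMatch] = []
        for f in ups:
            anchored.extend(anchor_matches(f, scan_both_strands(f.seq, pattern, f.gene_id)))
        universe = [f.gene_id for f in ups]
        rows.append(
            {
                "species": label,
                "n_genes": len(universe),
                "percent_positive": percent_positive(anchored, universe, max_distance)
                if anchored
                else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["species", "n_genes", "percent_positive"])
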