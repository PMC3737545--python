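"""Gene-flank extraction and anchor-relative coordinates.

A *flank* is the fixed-length region upstream of a gene's transcription
start site (TSS) or downstream of its transcription end site (TES),
always reported 5'->3' on the gene's sense (non-template) strand.  The
gene denotes the transcribed region (UTRs, exons and introns), one
TSS/TES per gene id.

Anchor-relative coordinates follow the field convention: upstream bases
are -1 (immediately 5' of the TSS) down to -L; downstream bases are +1
(immediately 3' of the TES) up to +L.  A multi-base motif is represented
by the anchor coordinate of its match start offset — for upstream flanks
that is its most anchor-distal (most negative) base, so a motif counts
as lying "within d bp" only when wholly contained.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pattern import PQSMatch, reverse_complement

__all__ = [
    "FlankRegion",
    "AnchoredMatch",
    "GeneRecord",
    "extract_flanks",
    "anchor_matches",
    "read_flank_fasta",
    "write_flank_fasta",
    "read_genes_bed",
    "read_genes_gff3",
]

ANCHOR_SIDE = {"TSS": "upstream", "TES": "downstream"}


@dataclass(frozen=True)
class GeneRecord:
    """A gene's transcribed region: 0-based half-open [start, end) on
    *chrom*, with the strand it is transcribed from."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: need 0 <= start < end")


@dataclass(frozen=True)
class FlankRegion:
    """A sense-strand flank sequence around a gene boundary."""

    gene_id: str
    anchor: str  # 'TSS' or 'TES'
    side: str  # 'upstream' or 'downstream'
    length: int  # requested length, bp
    seq: str
    gene_strand: str  # '+' or '-' on the source chromosome
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.anchor not in ANCHOR_SIDE:
            raise ValueError("anchor must be 'TSS' or 'TES'")
        if self.side != ANCHOR_SIDE[self.anchor]:
            raise ValueError("upstream pairs with TSS, downstream with TES")
        if not self.truncated and len(self.seq) != self.length:
            raise ValueError(
                f"flank {self.gene_id}: |seq|={len(self.seq)} != length={self.length} "
                "but truncated flag not set"
            )
        if self.truncated and len(self.seq) >= self.length:
            raise ValueError("truncated flank must be shorter than requested length")

    @property
    def realized_length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AnchoredMatch:
    """A PQS match re-expressed in anchor-relative coordinates.

    ``coord`` is the anchor coordinate of the match start offset
    (strictly negative upstream, strictly positive downstream);
    ``strand_class`` is 'non-template' for matches on the sense-oriented
    flank's plus strand, 'template' for minus-strand matches.
    """

    gene_id: str
    anchor: str
    side: str
    coord: int
    span: int
    strand_class: str

    def __post_init__(self) -> None:
        if self.side == "upstream" and self.coord >= 0:
            raise ValueError("upstream coords must be strictly negative")
        if self.side == "downstream" and self.coord <= 0:
            raise ValueError("downstream coords must be strictly positive")
        if self.strand_class not in ("non-template", "template"):
            raise ValueError("strand_class must be 'non-template' or 'template'")
        if self.span < 1:
            raise ValueError("span must be >= 1")


def extract_flanks(
    genome: Mapping[str, str],
    genes: Sequence[GeneRecord],
    anchor: str,
    length: int = 5000,
) -> list[FlankRegion]:
    """Extract TSS-upstream or TES-downstream flanks from a genome.

    For a + strand gene [g0, g1): TSS-upstream = genome[g0-L, g0),
    TES-downstream = genome[g1, g1+L), as given.  For a - strand gene
    the roles of the two sides swap and the slice is reverse
    complemented, so flanks always read 5'->3' on the sense strand.
    Overhang beyond a chromosome edge is truncated and flagged.
    """
    if anchor not in ANCHOR_SIDE:
        raise ValueError("anchor must be 'TSS' or 'TES'")
    side = ANCHOR_SIDE[anchor]
    seen: dict[str, int] = {}
    for g in genes:
        seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate gene_id(s): {', '.join(dups)}")

    out: list[FlankRegion] = []
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom!r} not in genome")
        chrom_seq = genome[g.chrom]
        n = len(chrom_seq)
        if g.end > n:
            raise ValueError(f"gene {g.gene_id}: coordinates exceed chromosome length")
        # forward-genome slice for the requested flank
        if (g.strand == "+") == (side == "upstream"):
            lo, hi = g.start - length, g.start
        else:
            lo, hi = g.end, g.end + length
        lo_c, hi_c = max(lo, 0), min(hi, n)
        piece = chrom_seq[lo_c:hi_c]
        if g.strand == "-":
            piece = reverse_complement(piece)
        out.append(
            FlankRegion(
                gene_id=g.gene_id,
                anchor=anchor,
                side=side,
                length=length,
                seq=piece,
                gene_strand=g.strand,
                truncated=(hi_c - lo_c) < length,
            )
        )
    return out


def anchor_matches(flank: FlankRegion, matches: Iterable[PQSMatch]) -> list[AnchoredMatch]:
    """Map matches found on *flank.seq* (both strands) into
    anchor-relative coordinates and strand classes.

    For an upstream flank of realized length L, offset i maps to i - L
    (the last base abuts the TSS at -1); for a downstream flank, offset
    i maps to i + 1.
    """
    L = flank.realized_length
    out: list[AnchoredMatch] = []
    for m in matches:
        if not (0 <= m.start < m.end <= L):
            raise ValueError(
                f"match [{m.start},{m.end}) out of bounds for flank "
                f"{flank.gene_id} of length {L}"
            )
        coord = m.start - L if flank.side == "upstream" else m.start + 1
        out.append(
            AnchoredMatch(
                gene_id=flank.gene_id,
                anchor=flank.anchor,
                side=flank.side,
                coord=coord,
                span=m.end - m.start,
                strand_class="non-template" if m.strand == "+" else "template",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Flank FASTA dialect:  >gene_id|anchor|side|length|gene_strand
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_flank_fasta(flanks: Iterable[FlankRegion], path: Union[str, Path]) -> None:
    """Write flanks in the package's FASTA header dialect."""
    records = [
        SeqRecord(
            Seq(f.seq),
            id=f"{f.gene_id}|{f.anchor}|{f.side}|{f.length}|{f.gene_strand}",
            description="",
        )
        for f in flanks
    ]
    with _open_maybe_gzip(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_flank_fasta(path: Union[str, Path]) -> list[FlankRegion]:
    """Read flanks written in the dialect ``>gene_id|anchor|side|length|strand``.

    Sequences are assumed already sense-strand oriented.  Malformed
    headers raise with the record index; duplicate (gene_id, anchor,
    side) triples are rejected.
    """
    out: list[FlankRegion] = []
    seen: set[tuple[str, str, str]] = set()
    with _open_maybe_gzip(path) as fh:
        for idx, rec in enumerate(SeqIO.parse(fh, "fasta")):
            parts = rec.id.split("|")
            if len(parts) != 5:
                raise ValueError(
                    f"record {idx}: malformed flank header {rec.id!r} "
                    "(expected gene_id|anchor|side|length|strand)"
                )
            gene_id, anchor, side, length_s, strand = parts
            try:
                length = int(length_s)
            except ValueError:
                raise ValueError(f"record {idx}: non-integer length in header {rec.id!r}")
            if strand not in ("+", "-"):
                raise ValueError(f"record {idx}: bad strand in header {rec.id!r}")
            key = (gene_id, anchor, side)
            if key in seen:
                raise ValueError(f"record {idx}: duplicate flank {key}")
            seen.add(key)
            seq = str(rec.seq)
            out.append(
                FlankRegion(
                    gene_id=gene_id,
                    anchor=anchor,
                    side=side,
                    length=length,
                    seq=seq,
                    gene_strand=strand,
                    truncated=len(seq) < length,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Gene annotation readers
# ---------------------------------------------------------------------------


def read_genes_bed(path: Union[str, Path]) -> list[GeneRecord]:
    """Gene records from BED6 (0-based half-open, as BED is defined)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        GeneRecord(gene_id=r.name, chrom=r.chrom, start=int(r.start), end=int(r.end), strand=r.strand)
        for r in df.itertuples(index=False)
    ]


def read_genes_gff3(path: Union[str, Path], feature_type: str = "gene") -> list[GeneRecord]:
    """Gene records from GFF3 (1-based inclusive coordinates converted
    to 0-based half-open internally).  Uses the ``ID`` attribute as the
    gene id."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        out.append(
            GeneRecord(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return out


def anchored_to_frame(anchored: Iterable[AnchoredMatch]) -> pd.DataFrame:
    """Anchored matches as a DataFrame (gene_id, anchor, side, coord,
    span, strand_class) — the TSV export layout."""
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "anchor": a.anchor,
                "side": a.side,
                "coord": a.coord,
                "span": a.span,
                "strand_class": a.strand_class,
            }
            for a in anchored
        ],
        columns=["gene_id", "anchor", "side", "coord", "span", "strand_class"],
    )
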