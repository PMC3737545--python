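"""Tabular export of scan results (BED6 / TSV) and FASTA reading."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO

from .pattern import PQSMatch

__all__ = ["read_fasta", "matches_to_bed", "matches_to_frame", "write_matches_tsv", "write_matches_bed"]


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a plain or gzipped FASTA file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def matches_to_frame(matches: Iterable[PQSMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": m.seq_id,
                "start": m.start,
                "end": m.end,
                "strand": m.strand,
                "n_tracts": m.n_tracts,
                "matched_seq": m.matched_seq,
            }
            for m in matches
        ],
        columns=["seq_id", "start", "end", "strand", "n_tracts", "matched_seq"],
    )


def matches_to_bed(matches: Iterable[PQSMatch]) -> str:
    """BED6 text: 0-based half-open, name = motif sequence, score =
    tract count, strand column per match."""
    lines = [
        f"{m.seq_id}\t{m.start}\t{m.end}\t{m.matched_seq}\t{m.n_tracts}\t{m.strand}"
        for m in matches
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_matches_bed(matches: Iterable[PQSMatch], fh: TextIO, header: Optional[str] = None) -> None:
    if header:
        fh.write(header)
    fh.write(matches_to_bed(matches))


def write_matches_tsv(matches: Iterable[PQSMatch], fh: TextIO, header: Optional[str] = None) -> None:
    if header:
        fh.write(header)
    matches_to_frame(matches).to_csv(fh, sep="\t", index=False)
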