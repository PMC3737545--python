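"""Synthetic gene-flank and decay data with exact ground truth.

The generator emulates the data regime the genomic analysis assumes:
per-gene fixed-length flanks upstream of the TSS and downstream of the
TES, with PQS motif instances planted at position-dependent density —
a background rate plus a TSS-proximal step enrichment (five-fold by
default, mirroring a promoter-proximal peak over background) and a flat
profile downstream of the TES.  The background is made free of runs of
three or more G or C, so every match found by the scanner is a planted
motif and recall/false-positive accounting is exact.

Plants on the same flank keep >= 8 nt clearance so neighbouring motifs
can never merge into one match under the non-overlapping scan policy,
and each plant is written with a 2-nt 'A' buffer on both sides so that
stray background G/C next to a motif edge cannot extend a tract and
shift the matched coordinates.

All randomness derives from a single root seed via numpy Generators;
identical configuration yields byte-identical output.
"""

from __future__ import annotations

import re as _re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decay import DecayDataset
from .flanks import FlankRegion, GeneRecord
from .pattern import PQSPattern, reverse_complement

__all__ = [
    "SyntheticConfig",
    "sample_pqs_instance",
    "generate_flank_set",
    "generate_genome_set",
    "generate_decay_dataset",
    "DEFAULT_DECAY_DISTANCES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RUN3 = _re.compile(r"GGG|CCC")

#: default promoter-to-motif separations (bp) for simulated decay data,
#: spanning the 0-2500 bp range over which induction has been measured
DEFAULT_DECAY_DISTANCES = (0, 100, 200, 400, 600, 800, 1000, 1250, 1500, 2000, 2500)


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for the synthetic flank generator.

    Rates are per-position expected planted-motif counts (per nt of
    eligible start position).  The defaults give ~0.9 expected upstream
    plants per gene — about 60% of genes carrying at least one motif in
    a 5-kb upstream flank, with a five-fold step enrichment within
    1000 bp of the TSS and a flat profile downstream of the TES.
    """

    n_genes: int = 1000
    flank_len: int = 5000
    background_composition: tuple[float, float, float, float] = (0.30, 0.20, 0.20, 0.30)
    g_run_free: bool = True
    upstream_rate: float = 1e-4
    upstream_fold: float = 5.0
    upstream_enrich_width: int = 1000
    downstream_rate: float = 1e-4
    downstream_fold: float = 1.0
    downstream_enrich_width: int = 0
    strand_probability: float = 0.5  # chance a plant goes on the template strand
    clearance: int = 8
    sides: tuple[str, ...] = ("upstream", "downstream")
    #: when set, plant exactly one motif per gene on the upstream flank
    #: with its distal base at this coordinate (overrides the density)
    fixed_upstream_coord: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.background_composition, float)
        if comp.shape != (4,) or np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("background_composition must be 4 probabilities summing to 1")
        if not (0.0 <= self.strand_probability <= 1.0):
            raise ValueError("strand_probability must lie in [0, 1]")
        for r, f in (
            (self.upstream_rate, self.upstream_fold),
            (self.downstream_rate, self.downstream_fold),
        ):
            if r < 0 or f < 0:
                raise ValueError("rates and folds must be >= 0")
        if self.n_genes < 1 or self.flank_len < 1:
            raise ValueError("n_genes and flank_len must be >= 1")
        for s in self.sides:
            if s not in ("upstream", "downstream"):
                raise ValueError(f"unknown side {s!r}")


def sample_pqs_instance(pattern: Optional[PQSPattern] = None, rng=None) -> str:
    """Sample a motif instance that parses under the grammar.

    Tract count uniform in [min_tracts, min_tracts + 2], tract lengths
    in [min_tract_len, min_tract_len + 1], loop lengths in
    [loop_min, loop_max]; loop characters are drawn from {A, C, T} (no
    G, so the planned parse is unique) rejecting runs of three Cs (so
    the reverse complement of a plant cannot itself contain a G tract).
    """
    pat = pattern if pattern is not None else PQSPattern()
    rng = np.random.default_rng() if rng is None else rng
    if pat.exact_tract_len is not None:
        tract_lens = [pat.exact_tract_len]
    else:
        tract_lens = [pat.min_tract_len, pat.min_tract_len + 1]
    lmin, lmax = pat._loop_bounds
    lmin = max(lmin, 1)
    n_tracts = int(rng.integers(pat.min_tracts, pat.min_tracts + 3))
    parts = []
    loop_alphabet = "ACT"
    for t in range(n_tracts):
        parts.append("G" * int(rng.choice(tract_lens)))
        if t < n_tracts - 1:
            ll = int(rng.integers(lmin, lmax + 1))
            while True:
                loop = "".join(loop_alphabet[i] for i in rng.integers(0, 3, size=ll))
                if "CCC" not in loop:
                    break
            parts.append(loop)
    return "".join(parts)


def _background(rng, length: int, comp_cum: np.ndarray, g_run_free: bool) -> np.ndarray:
    """Random background as a uint8 ASCII array; when g_run_free, runs
    of >= 3 G (or C) are broken by overwriting the run's interior."""
    idx = np.searchsorted(comp_cum, rng.random(length), side="right")
    arr = _BASES[idx]
    if not g_run_free:
        return arr.copy()
    arr = arr.copy()
    for bad, filler in ((ord("G"), ord("A")), (ord("C"), ord("T"))):
        while True:
            m = arr == bad
            if length < 3:
                break
            run3 = m[:-2] & m[1:-1] & m[2:]
            starts = np.flatnonzero(run3)
            if starts.size == 0:
                break
            arr[starts + 1] = filler
    return arr


def _sample_depth(rng, lo: int, hi: int, width: int, fold: float) -> Optional[int]:
    """Sample a plant depth (|coord| for upstream, coord for downstream)
    from the step density over the inclusive range [lo, hi]; depths
    <= width are enriched ``fold``-fold.  Returns None if no room."""
    if lo > hi:
        return None
    w_hi = min(width, hi)
    n_enr = max(0, w_hi - lo + 1)
    n_bg = (hi - lo + 1) - n_enr
    w_enr = fold * n_enr
    tot = w_enr + n_bg
    if tot <= 0:
        return None
    if rng.random() < w_enr / tot:
        return int(rng.integers(lo, lo + n_enr))
    return int(rng.integers(lo + n_enr, hi + 1))


def _plant_flank(
    rng,
    gene_id: str,
    side: str,
    cfg: SyntheticConfig,
    comp_cum: np.ndarray,
    pattern: PQSPattern,
    truth_rows: list,
) -> str:
    L = cfg.flank_len
    arr = _background(rng, L, comp_cum, cfg.g_run_free)
    if side == "upstream":
        rate, fold, width = cfg.upstream_rate, cfg.upstream_fold, cfg.upstream_enrich_width
        anchor = "TSS"
    else:
        rate, fold, width = cfg.downstream_rate, cfg.downstream_fold, cfg.downstream_enrich_width
        anchor = "TES"
    width = min(width, L)
    fixed = cfg.fixed_upstream_coord if side == "upstream" else None
    if fixed is not None:
        if not (-L <= fixed <= -1):
            raise ValueError("fixed_upstream_coord must lie in [-flank_len, -1]")
        n_plants = 1
    else:
        expected = rate * ((L - width) + fold * width)
        n_plants = int(rng.poisson(expected))
    placed: list[tuple[int, int]] = []  # offset intervals [s, e)
    for _ in range(n_plants):
        motif = sample_pqs_instance(pattern, rng)
        span = len(motif)
        if fixed is not None and -fixed < span:
            raise ValueError("fixed_upstream_coord too close to the TSS for the motif")
        for _attempt in range(100):
            if fixed is not None:
                depth = -fixed
            elif side == "upstream":
                # depth = |coord| of the distal base; fit needs depth >= span
                depth = _sample_depth(rng, span, L, width, fold)
            else:
                # depth = coord of the start base; fit needs depth <= L-span+1
                depth = _sample_depth(rng, 1, L - span + 1, width, fold)
            if depth is None:
                raise ValueError("flank too short for a motif instance")
            if side == "upstream":
                s = L - depth
                coord = -depth
            else:
                s = depth - 1
                coord = depth
            e = s + span
            if all(e + cfg.clearance <= ps or s >= pe + cfg.clearance for ps, pe in placed):
                break
        else:
            raise ValueError(
                "could not satisfy plant clearance after 100 retries; lower the density"
            )
        template = rng.random() < cfg.strand_probability
        inserted = reverse_complement(motif) if template else motif
        arr[s:e] = np.frombuffer(inserted.encode(), dtype=np.uint8)
        # 2-nt neutral buffer so background G/C cannot extend a tract
        arr[max(0, s - 2) : s] = ord("A")
        arr[e : min(L, e + 2)] = ord("A")
        placed.append((s, e))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "anchor": anchor,
                "side": side,
                "coord": coord,
                "span": span,
                "strand_class": "template" if template else "non-template",
                "motif": motif,
            }
        )
    return arr.tobytes().decode("ascii")


_TRUTH_COLUMNS = ["gene_id", "anchor", "side", "coord", "span", "strand_class", "motif"]


def _sort_truth(rows: list) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    return df.sort_values(["gene_id", "side", "coord"], kind="mergesort").reset_index(
        drop=True
    )


def generate_flank_set(
    config: SyntheticConfig, pattern: Optional[PQSPattern] = None
) -> tuple[list[FlankRegion], pd.DataFrame]:
    """Generate sense-strand flanks plus the ground-truth plant table.

    Returns (flanks, truth) where truth has columns gene_id, anchor,
    side, coord, span, strand_class, motif.  Fully reproducible from
    ``config.seed``.
    """
    pat = pattern if pattern is not None else PQSPattern()
    rng = np.random.default_rng(config.seed)
    comp_cum = np.cumsum(np.asarray(config.background_composition, float))
    comp_cum[-1] = 1.0
    flanks: list[FlankRegion] = []
    truth_rows: list = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:0{width}d}"
        gene_strand = "+" if rng.random() < 0.5 else "-"
        for side in config.sides:
            seq = _plant_flank(rng, gene_id, side, config, comp_cum, pat, truth_rows)
            flanks.append(
                FlankRegion(
                    gene_id=gene_id,
                    anchor="TSS" if side == "upstream" else "TES",
                    side=side,
                    length=config.flank_len,
                    seq=seq,
                    gene_strand=gene_strand,
                )
            )
    return flanks, _sort_truth(truth_rows)


def generate_genome_set(
    config: SyntheticConfig,
    pattern: Optional[PQSPattern] = None,
    gene_len: int = 2000,
    spacer: int = 100,
) -> tuple[dict[str, str], list[GeneRecord], pd.DataFrame]:
    """Generate a synthetic chromosome with annotated genes on both
    strands whose extracted flanks reproduce the planted ground truth.

    Genes are laid out with enough spacing that no flank overlaps a
    neighbouring gene's flanks; gene bodies are plant-free background.
    Returns (genome, gene records, truth table).
    """
    pat = pattern if pattern is not None else PQSPattern()
    rng = np.random.default_rng(config.seed)
    comp_cum = np.cumsum(np.asarray(config.background_composition, float))
    comp_cum[-1] = 1.0
    L = config.flank_len
    pieces: list[str] = []
    genes: list[GeneRecord] = []
    truth_rows: list = []
    pos = 0
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:0{width}d}"
        gene_strand = "+" if rng.random() < 0.5 else "-"
        up = _plant_flank(rng, gene_id, "upstream", config, comp_cum, pat, truth_rows)
        body = _background(rng, gene_len, comp_cum, config.g_run_free).tobytes().decode()
        down = _plant_flank(rng, gene_id, "downstream", config, comp_cum, pat, truth_rows)
        unit_sense = up + body + down
        if gene_strand == "+":
            pieces.append(unit_sense)
            g0 = pos + L
        else:
            pieces.append(reverse_complement(unit_sense))
            g0 = pos + L  # revcomp swaps the flanks symmetrically
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                chrom="chr1",
                start=g0,
                end=g0 + gene_len,
                strand=gene_strand,
            )
        )
        pos += len(unit_sense)
        gap = _background(rng, spacer, comp_cum, config.g_run_free).tobytes().decode()
        pieces.append(gap)
        pos += spacer
    genome = {"chr1": "".join(pieces)}
    return genome, genes, _sort_truth(truth_rows)


def generate_decay_dataset(
    max_: float = 59.0,
    d_half: float = 489.0,
    plateau: float = 40.0,
    distances: Sequence[float] = DEFAULT_DECAY_DISTANCES,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[DecayDataset]:
    """Simulate %qDNA decay datasets from Y = max*exp(-k X) + plateau
    with k = ln(2)/d_half and additive Gaussian noise (sd in percentage
    points), clamped to [0, 100]."""
    if d_half <= 0:
        raise ValueError("d_half must be > 0")
    rng = np.random.default_rng(seed)
    x = np.asarray(distances, dtype=float)
    k = np.log(2) / d_half
    clean = max_ * np.exp(-k * x) + plateau
    out = []
    for _ in range(n_replicates):
        y = clean + (rng.normal(0.0, noise_sd, size=x.shape) if noise_sd > 0 else 0.0)
        out.append(DecayDataset(x, np.clip(y, 0.0, 100.0)))
    return out
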