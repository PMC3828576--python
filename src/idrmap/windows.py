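"""Windowed genome statistics.

Chromosomes are cut either into fixed non-overlapping windows (0.5 Mb by
default) or into the fragments of an empirical genetic map, and each
window aggregates its member genes (assigned by midpoint) into:

* segment frequency — long disordered segments per open reading frame;
* disordered-residue frequency — residues inside long segments over all
  residues of the member proteins;
* G+C_disordered frequency — G+C bases inside long segments over total
  CDS length;
* recombination rate — the fragment's cM divided by its size in Mb
  (map windows only).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

from .gc import GcPartition
from .segments import MIN_SEGMENT_LENGTH, extract_segments
from .types import DisorderMask, GeneLocus, GeneticMapInterval


@dataclass(frozen=True)
class Window:
    chromosome: str
    start: int
    end: int
    source: str  # {fixed, map_fragment}
    cm: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty window {self.chromosome}:{self.start}-{self.end}")


def normalize_recombination(interval: GeneticMapInterval) -> float:
    """Recombination rate in cM/Mb: genetic length over physical length."""
    return interval.cm / interval.length_mb


def make_windows(
    chrom_lengths: dict[str, int],
    mode: str = "fixed",
    size: int = 500_000,
    map_intervals: list[GeneticMapInterval] | None = None,
) -> list[Window]:
    """Tile chromosomes with fixed windows, or adopt genetic-map fragments.

    Fixed windows are disjoint, cover each chromosome exactly, and the
    last window is truncated at the chromosome end.  Map windows coincide
    with the map intervals and carry their cM.
    """
    if mode == "fixed":
        if size <= 0:
            raise ValueError("window size must be positive")
        out = []
        for chrom in sorted(chrom_lengths):
            length = chrom_lengths[chrom]
            for start in range(0, length, size):
                out.append(Window(chrom, start, min(start + size, length), "fixed"))
        return out
    if mode == "map":
        if not map_intervals:
            raise ValueError("map mode requires map intervals")
        out = []
        for iv in map_intervals:
            if iv.chromosome not in chrom_lengths:
                raise ValueError(
                    f"map chromosome {iv.chromosome!r} absent from chrom_lengths"
                )
            out.append(Window(iv.chromosome, iv.start, iv.end, "map_fragment", iv.cm))
        return out
    raise ValueError(f"unknown window mode {mode!r}")


def assign_genes(
    windows: list[Window], loci: list[GeneLocus]
) -> tuple[dict[int, list[GeneLocus]], list[GeneLocus]]:
    """Assign each gene to the unique window containing its midpoint.

    Windows are half-open, so a midpoint exactly on a boundary belongs to
    the upper window.  Genes whose midpoint falls in no window (gaps of a
    genetic map) are returned unassigned.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, w in enumerate(windows):
        by_chrom.setdefault(w.chromosome, []).append((w.start, w.end, idx))
    for lst in by_chrom.values():
        lst.sort()
    assignment: dict[int, list[GeneLocus]] = {i: [] for i in range(len(windows))}
    unassigned: list[GeneLocus] = []
    for locus in loci:
        lst = by_chrom.get(locus.chromosome, [])
        starts = [s for s, _e, _i in lst]
        pos = bisect_right(starts, locus.midpoint) - 1
        if pos >= 0 and locus.midpoint < lst[pos][1]:
            assignment[lst[pos][2]].append(locus)
        else:
            unassigned.append(locus)
    return assignment, unassigned


@dataclass(frozen=True)
class WindowStat:
    """Aggregate disorder/GC/recombination statistics of one window.

    Frequencies are NaN when the window holds no genes; such windows are
    excluded from correlations and regressions downstream.
    """

    window: Window
    n_genes: int
    n_segments: int
    segment_frequency: float
    disordered_residue_frequency: float
    gc_disordered_frequency: float
    recombination_rate: float | None

    @property
    def defined(self) -> bool:
        return self.n_genes > 0


def window_statistics(
    windows: list[Window],
    assignment: dict[int, list[GeneLocus]],
    masks: dict[str, DisorderMask],
    gc_partitions: dict[str, GcPartition] | None = None,
    min_len: int = MIN_SEGMENT_LENGTH,
) -> list[WindowStat]:
    """Per-window disorder and composition statistics.

    Every assigned gene must have a disorder mask; G+C statistics are NaN
    for genes lacking a :class:`GcPartition` (or when none are supplied).
    """
    out = []
    for idx, window in enumerate(windows):
        genes = assignment.get(idx, [])
        rate = (normalize_recombination(
                    GeneticMapInterval(window.chromosome, window.start,
                                       window.end, window.cm))
                if window.cm is not None else None)
        if not genes:
            out.append(WindowStat(window, 0, 0, math.nan, math.nan, math.nan, rate))
            continue
        n_segments = 0
        n_seg_residues = 0
        n_residues = 0
        gc_dis = 0
        gene_nt = 0
        have_gc = False
        for locus in genes:
            mask = masks.get(locus.protein_id)
            if mask is None:
                raise KeyError(f"gene {locus.gene_id}: no disorder mask for "
                               f"protein {locus.protein_id}")
            segs = extract_segments(mask, min_len)
            n_segments += len(segs)
            n_seg_residues += sum(s.length for s in segs)
            n_residues += len(mask)
            if gc_partitions is not None:
                part = gc_partitions.get(locus.protein_id)
                if part is not None:
                    gc_dis += part.gc_disordered
                    gene_nt += part.gene_length
                    have_gc = True
        out.append(WindowStat(
            window=window,
            n_genes=len(genes),
            n_segments=n_segments,
            segment_frequency=n_segments / len(genes),
            disordered_residue_frequency=n_seg_residues / n_residues,
            gc_disordered_frequency=(gc_dis / gene_nt) if have_gc else math.nan,
            recombination_rate=rate,
        ))
    return out
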