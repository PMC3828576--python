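"""Conservation of disordered-segment content across paralogue pairs.

A pair *conserves* its disorder when both members carry the same number
of long (L >= 30) disordered segments; pairs that gain or lose segments
are non-conserved.  Pairs can additionally be stratified by the
chromosomal location of an anchor member: centromeric (class A, within a
0.5 Mb window around the centromere by default), proximal arm (class B)
and distal arm (class C) — recombination is suppressed near centromeres,
so the strata probe the recombination dependence of disorder turnover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .segments import MIN_SEGMENT_LENGTH, extract_segments
from .types import DisorderMask, GeneLocus, ParalogPair

LOCATION_CLASSES = ("A_centromeric", "B_arm_proximal", "C_arm_distal")


@dataclass(frozen=True)
class ConservationSummary:
    n_pairs: int
    n_conserved: int
    n_nonconserved: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.n_conserved + self.n_nonconserved != self.n_pairs:
            raise ValueError("conserved + non-conserved must equal pair count")

    @property
    def pct_conserved(self) -> float:
        return 100.0 * self.n_conserved / self.n_pairs

    @property
    def pct_nonconserved(self) -> float:
        return 100.0 * self.n_nonconserved / self.n_pairs


def pair_is_conserved(
    mask_a: DisorderMask,
    mask_b: DisorderMask,
    min_len: int = MIN_SEGMENT_LENGTH,
    count_tolerance: int = 0,
) -> bool:
    """True when the two members' long-segment counts differ by at most
    ``count_tolerance`` (strict equality by default)."""
    na = len(extract_segments(mask_a, min_len))
    nb = len(extract_segments(mask_b, min_len))
    return abs(na - nb) <= count_tolerance


def summarize_conservation(
    pairs: list[ParalogPair],
    masks: dict[str, DisorderMask],
    min_len: int = MIN_SEGMENT_LENGTH,
    count_tolerance: int = 0,
) -> ConservationSummary:
    """Score every pair with both masks available; others are skipped with a
    warning and tallied."""
    n_cons = n_non = n_skip = 0
    for pair in pairs:
        ma, mb = masks.get(pair.id_a), masks.get(pair.id_b)
        if ma is None or mb is None:
            missing = pair.id_a if ma is None else pair.id_b
            warnings.warn(f"pair ({pair.id_a},{pair.id_b}): no mask for "
                          f"{missing}; skipped", stacklevel=2)
            n_skip += 1
            continue
        if pair_is_conserved(ma, mb, min_len, count_tolerance):
            n_cons += 1
        else:
            n_non += 1
    if n_cons + n_non == 0:
        raise ValueError("no scorable pairs (all skipped)")
    return ConservationSummary(n_cons + n_non, n_cons, n_non, n_skip)


def classify_location(
    locus: GeneLocus,
    centromere_bp: int,
    chrom_length: int,
    centromeric_radius: int = 250_000,
    proximal_fraction: float = 0.25,
) -> str:
    """Assign a gene to location class A, B or C on its chromosome.

    Class A: gene midpoint within ``centromeric_radius`` of the centromere
    (a 0.5 Mb centromeric window by default).  Outside that window the arm
    runs from the window edge to the telomere; class B covers the
    ``proximal_fraction`` of the arm nearest the window, class C the rest.
    """
    if not 0 <= centromere_bp <= chrom_length:
        raise ValueError(f"centromere {centromere_bp} outside [0,{chrom_length}]")
    mid = locus.midpoint
    if not 0 <= mid < chrom_length:
        raise ValueError(
            f"gene {locus.gene_id}: midpoint {mid} outside chromosome "
            f"[0,{chrom_length})"
        )
    if abs(mid - centromere_bp) <= centromeric_radius:
        return "A_centromeric"
    if mid < centromere_bp:
        edge = centromere_bp - centromeric_radius
        arm_length = edge  # left arm: [0, edge)
        dist = edge - mid
    else:
        edge = centromere_bp + centromeric_radius
        arm_length = chrom_length - edge
        dist = mid - edge
    if arm_length > 0 and dist <= proximal_fraction * arm_length:
        return "B_arm_proximal"
    return "C_arm_distal"


def conservation_by_location(
    pairs: list[ParalogPair],
    masks: dict[str, DisorderMask],
    loci: dict[str, GeneLocus],
    centromeres: dict[str, int],
    chrom_lengths: dict[str, int],
    min_len: int = MIN_SEGMENT_LENGTH,
    centromeric_radius: int = 250_000,
    proximal_fraction: float = 0.25,
    count_tolerance: int = 0,
) -> dict[str, ConservationSummary | None]:
    """Per-location-class conservation summaries.

    Each pair takes the class of its anchor member (``id_a``); pairs whose
    anchor has no locus, or whose chromosome lacks a declared centromere,
    are skipped and tallied in every class's ``n_skipped``.  A class with
    no pairs maps to None.
    """
    counts = {label: [0, 0] for label in LOCATION_CLASSES}  # [conserved, non]
    n_skip = 0
    for pair in pairs:
        ma, mb = masks.get(pair.id_a), masks.get(pair.id_b)
        locus = loci.get(pair.id_a)
        if ma is None or mb is None or locus is None:
            n_skip += 1
            continue
        cen = centromeres.get(locus.chromosome)
        clen = chrom_lengths.get(locus.chromosome)
        if cen is None or clen is None:
            n_skip += 1
            continue
        label = classify_location(locus, cen, clen, centromeric_radius,
                                  proximal_fraction)
        conserved = pair_is_conserved(ma, mb, min_len, count_tolerance)
        counts[label][0 if conserved else 1] += 1
    out: dict[str, ConservationSummary | None] = {}
    for label, (nc, nn) in counts.items():
        out[label] = (ConservationSummary(nc + nn, nc, nn, n_skip)
                      if nc + nn else None)
    return out
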