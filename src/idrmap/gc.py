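"""G+C partitioning of coding sequences by disorder state.

Three per-gene quantities are computed: GC_total (G+C bases over the whole
CDS), GC_disordered (G+C bases whose codons encode residues inside long
disordered segments) and GC_ordered = GC_total - GC_disordered.  The
GC_disordered *frequency* divides GC_disordered by the CDS nucleotide
length, making it comparable across genes and poolable per genome window.

The enrichment test contrasts the per-gene G+C percentage of the
disordered region with that of the ordered region; because both regions
come from the same gene a paired Student's t test is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .segments import MIN_SEGMENT_LENGTH, extract_segments
from .types import CdsRecord, DisorderMask, PairingError


def project_mask_to_cds(
    mask: DisorderMask,
    cds: CdsRecord,
    min_len: int | None = MIN_SEGMENT_LENGTH,
) -> np.ndarray:
    """Boolean flag per CDS nucleotide: True inside a long disordered segment.

    Nucleotide ``i`` is flagged iff residue ``i // 3`` lies in an extracted
    segment of length >= ``min_len`` (``min_len=None`` admits all disordered
    residues).  A trailing stop codon, having no residue, is ordered.
    """
    n_res = len(mask)
    if cds.length not in (3 * n_res, 3 * n_res + 3):
        raise PairingError(
            f"{mask.protein_id}: CDS length {cds.length} incompatible with "
            f"{n_res} residues"
        )
    residue_flags = np.zeros(n_res, dtype=bool)
    if min_len is None:
        residue_flags[:] = mask.calls
    else:
        for seg in extract_segments(mask, min_len):
            residue_flags[seg.start:seg.end] = True
    flags = np.zeros(cds.length, dtype=bool)
    flags[: 3 * n_res] = np.repeat(residue_flags, 3)
    return flags


@dataclass(frozen=True)
class GcPartition:
    """Per-gene G+C base counts split by disorder state.

    Invariant: ``gc_ordered == gc_total - gc_disordered`` exactly.
    Region percentages are NaN when the region is empty.
    """

    gene_id: str
    gc_total: int
    gc_disordered: int
    gene_length: int
    n_disordered_nt: int

    def __post_init__(self) -> None:
        if not 0 <= self.gc_disordered <= self.gc_total <= self.gene_length:
            raise ValueError(f"{self.gene_id}: inconsistent GC counts")

    @property
    def gc_ordered(self) -> int:
        return self.gc_total - self.gc_disordered

    @property
    def gc_disordered_frequency(self) -> float:
        return self.gc_disordered / self.gene_length

    @property
    def pct_gc_disordered_region(self) -> float:
        if self.n_disordered_nt == 0:
            return math.nan
        return 100.0 * self.gc_disordered / self.n_disordered_nt

    @property
    def pct_gc_ordered_region(self) -> float:
        n_ord = self.gene_length - self.n_disordered_nt
        if n_ord == 0:
            return math.nan
        return 100.0 * self.gc_ordered / n_ord

    @property
    def pct_gc_total(self) -> float:
        return 100.0 * self.gc_total / self.gene_length


def gc_partition(cds: CdsRecord, projected: np.ndarray) -> GcPartition:
    """Count G+C bases in the whole CDS and in the flagged (disordered) part.

    N bases count as non-GC.
    """
    projected = np.asarray(projected, dtype=bool)
    if projected.size != cds.length:
        raise ValueError(
            f"{cds.id}: flag vector length {projected.size} != CDS length "
            f"{cds.length}"
        )
    seq = np.frombuffer(cds.sequence.encode(), dtype="S1")
    is_gc = (seq == b"G") | (seq == b"C")
    return GcPartition(
        gene_id=cds.id,
        gc_total=int(is_gc.sum()),
        gc_disordered=int((is_gc & projected).sum()),
        gene_length=cds.length,
        n_disordered_nt=int(projected.sum()),
    )


@dataclass(frozen=True)
class GcEnrichmentResult:
    """Disordered-vs-ordered G+C contrast over a gene cohort.

    ``mean_difference`` is the mean of per-gene (disordered% - ordered%),
    the "+x%" enrichment figure; ``shapiro_w``/``shapiro_p`` report a
    normality check of the tested values, never used to gate the test.
    """

    n_genes: int
    mean_difference: float
    t_statistic: float
    p_value: float
    shapiro_w: float
    shapiro_p: float
    paired: bool


def gc_enrichment_test(
    partitions: list[GcPartition], paired: bool = True
) -> GcEnrichmentResult:
    """Student's t test of G+C enrichment in disordered vs ordered regions.

    Uses only genes where both regions are non-empty; needs at least 3.
    Degenerate all-equal input follows the convention t = 0, p = 1.
    """
    usable = [p for p in partitions
              if not math.isnan(p.pct_gc_disordered_region)
              and not math.isnan(p.pct_gc_ordered_region)]
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 genes with both regions non-empty, have {len(usable)}"
        )
    dis = np.array([p.pct_gc_disordered_region for p in usable])
    ordd = np.array([p.pct_gc_ordered_region for p in usable])
    diff = dis - ordd
    mean_diff = float(diff.mean())
    if paired:
        tested = diff
        if np.allclose(diff.std(ddof=1), 0.0):
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = stats.ttest_rel(dis, ordd)
    else:
        tested = np.concatenate([dis, ordd])
        if np.allclose(dis.std(ddof=1), 0.0) and np.allclose(ordd.std(ddof=1), 0.0):
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = stats.ttest_ind(dis, ordd)
    sw, swp = stats.shapiro(tested) if np.ptp(tested) > 0 else (1.0, 1.0)
    return GcEnrichmentResult(
        n_genes=len(usable),
        mean_difference=mean_diff,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        shapiro_w=float(sw),
        shapiro_p=float(swp),
        paired=paired,
    )
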