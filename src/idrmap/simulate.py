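"""Synthetic genome bundles with known ground truth.

The generator emulates the statistical structure the analysis assumes in
real plant genomes:

* chromosomes tiled by windows whose recombination rates follow a gamma
  distribution, with a few hotspot windows multiplied up;
* genes placed with Dirichlet-weighted regional density (real chromosomes
  are gene-dense in arms and sparse around centromeres), whose expected
  number of long (L >= 30) disordered segments rises linearly with the
  recombination rate of their window
  (``Poisson(lambda0 + beta_rec * rate)``);
* coding sequences whose G+C content rises with disordered fraction,
  because disordered residues are preferentially drawn from Arg/Gly/Ala/Pro
  with fully-G+C codons — the codon-composition mechanism that couples
  disorder to G+C in real coding sequences;
* structural-domain annotations placed independently of disorder;
* paralogue pairs that conserve their long-segment count with a
  location-class-dependent probability (centromeric pairs more conserved
  than arm pairs), else gain or lose exactly one segment.

Every quantity the pipeline estimates has its true value recorded in
:class:`GroundTruth`, enabling parameter-recovery tests.  Output is fully
determined by the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from . import io as iio
from .conservation import classify_location, summarize_conservation
from .gc import gc_partition, project_mask_to_cds
from .segments import extract_segments
from .stats import index_of_dispersion, multiple_regression, pearson
from .types import (
    CdsRecord,
    DisorderMask,
    DomainAnnotation,
    GeneLocus,
    GeneticMapInterval,
    ParalogPair,
    ProteinRecord,
)
from .windows import assign_genes, make_windows, window_statistics

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: sense codons per amino acid (standard table)
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    CODONS_BY_AA.setdefault(aa, []).append(codon)
for _codons in CODONS_BY_AA.values():
    _codons.sort()

#: disorder-prone amino acids and their fully-G+C codons
RGAP_CODONS = {"R": ["CGC", "CGG"], "G": ["GGC", "GGG"],
               "A": ["GCC", "GCG"], "P": ["CCC", "CCG"]}


def _gc_fraction(codon: str) -> float:
    return sum(c in "GC" for c in codon) / 3.0


#: mean codon G+C under uniform amino acid and uniform synonymous codon choice
UNIFORM_CODON_GC = float(np.mean(
    [np.mean([_gc_fraction(c) for c in CODONS_BY_AA[aa]]) for aa in AA20]
))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome; the defaults are the study conditions.

    One 12 Mb chromosome in 0.5 Mb windows (24 windows) carrying 1200
    genes (~50 per window) of mean length 400 residues; gamma-distributed
    recombination rates (mean 4 cM/Mb) with 2 five-fold hotspots; a
    baseline of 0.8 long segments per gene rising by ``beta_rec`` = 0.5
    segments per cM/Mb; disordered residues drawn from G+C-rich
    Arg/Gly/Ala/Pro codons with probability ``p_rgap`` = 0.055, which
    yields a disordered-region G+C enrichment of about +3 percentage
    points, the magnitude seen in monocot coding sequences; paralogue
    conservation probabilities mirroring the centromere/arm contrast
    (A 0.85, B 0.66, C 0.64).
    """

    n_chromosomes: int = 1
    chrom_length_bp: int = 12_000_000
    n_genes: int = 1200
    mean_protein_length: int = 400
    min_protein_length: int = 80
    window_size_bp: int = 500_000
    rec_shape: float = 2.0
    rec_scale: float = 2.0
    hotspot_count: int = 2
    hotspot_multiplier: float = 5.0
    lambda0: float = 0.8
    beta_rec: float = 0.5
    seg_len_min: int = 30
    seg_len_geom_mean: float = 20.0
    short_disorder_rate: float = 1.0
    p_rgap: float = 0.055
    gc_noise_sd: float = 0.08
    gene_density_alpha: float = 50.0
    domains_per_protein: float = 1.2
    domain_mean_length: int = 120
    n_pairs: int = 600
    p_conserve: dict[str, float] = field(default_factory=lambda: {
        "A_centromeric": 0.85, "B_arm_proximal": 0.66, "C_arm_distal": 0.64,
    })
    centromeric_radius: int = 250_000
    proximal_fraction: float = 0.25
    emit_sequences: bool = True
    seed: int = 0

    @property
    def delta_gc(self) -> float:
        """True increment of codon G+C fraction per unit disordered fraction."""
        return self.p_rgap * (1.0 - UNIFORM_CODON_GC)

    def validate(self) -> None:
        if self.min_protein_length < self.seg_len_min + 2:
            raise ValueError("proteins too short to hold one segment")
        for name in ("rec_shape", "rec_scale", "lambda0", "beta_rec",
                     "short_disorder_rate", "domains_per_protein"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for label, p in self.p_conserve.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_conserve[{label}] outside [0,1]")
        if not 0.0 <= self.p_rgap <= 1.0:
            raise ValueError("p_rgap outside [0,1]")


@dataclass
class GroundTruth:
    """True generative parameters and realized latent variables."""

    config: SimulationConfig
    window_rates: dict[str, list[float]]  # per chromosome, cM/Mb per window
    gene_segments: dict[str, list[tuple[int, int]]]  # long segments per protein
    pair_conserved: dict[tuple[str, str], bool]
    pair_class: dict[tuple[str, str], str]

    @property
    def beta_rec(self) -> float:
        return self.config.beta_rec

    @property
    def delta_gc(self) -> float:
        return self.config.delta_gc


@dataclass
class Bundle:
    """One complete synthetic input set, mirroring the real-data formats."""

    proteins: list[ProteinRecord]
    cds: list[CdsRecord]
    masks: list[DisorderMask]
    domains: list[DomainAnnotation]
    loci: list[GeneLocus]
    map_intervals: list[GeneticMapInterval]
    pairs: list[ParalogPair]
    centromeres: dict[str, int]
    chrom_lengths: dict[str, int]
    truth: GroundTruth | None = None

    def mask_dict(self) -> dict[str, DisorderMask]:
        return {m.protein_id: m for m in self.masks}

    def locus_dict(self) -> dict[str, GeneLocus]:
        return {g.protein_id: g for g in self.loci}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.proteins:
            iio.write_fasta(self.proteins, outdir / "proteins.fasta")
        if self.cds:
            iio.write_fasta(self.cds, outdir / "cds.fasta")
        iio.write_mask_fasta(self.masks, outdir / "masks.fasta")
        iio.write_domains(self.domains, outdir / "domains.tsv")
        iio.write_gene_gff3(self.loci, outdir / "genes.gff3", self.chrom_lengths)
        iio.write_genetic_map(self.map_intervals, outdir / "map.tsv")
        iio.write_pairs(self.pairs, outdir / "pairs.tsv")
        iio.write_centromeres(self.centromeres, outdir / "centromeres.tsv")
        if self.truth is not None:
            truth = {
                "config": dataclasses.asdict(self.truth.config),
                "window_rates": self.truth.window_rates,
                "gene_segments": {k: [list(s) for s in v]
                                  for k, v in self.truth.gene_segments.items()},
                "pair_conserved": {f"{a}|{b}": v for (a, b), v
                                   in self.truth.pair_conserved.items()},
                "pair_class": {f"{a}|{b}": v for (a, b), v
                               in self.truth.pair_class.items()},
            }
            (outdir / "ground_truth.json").write_text(json.dumps(truth))


def read_bundle(indir: str | Path) -> Bundle:
    """Load a written bundle back through the standard readers."""
    indir = Path(indir)
    proteins = (iio.read_protein_fasta(indir / "proteins.fasta")
                if (indir / "proteins.fasta").exists() else [])
    cds = (iio.read_cds_fasta(indir / "cds.fasta")
           if (indir / "cds.fasta").exists() else [])
    truth = None
    tp = indir / "ground_truth.json"
    if tp.exists():
        raw = json.loads(tp.read_text())
        truth = GroundTruth(
            config=SimulationConfig(**raw["config"]),
            window_rates=raw["window_rates"],
            gene_segments={k: [tuple(s) for s in v]
                           for k, v in raw["gene_segments"].items()},
            pair_conserved={tuple(k.split("|")): v
                            for k, v in raw["pair_conserved"].items()},
            pair_class={tuple(k.split("|")): v
                        for k, v in raw["pair_class"].items()},
        )
    return Bundle(
        proteins=proteins,
        cds=cds,
        masks=iio.read_disorder_masks(indir / "masks.fasta", "mask_fasta"),
        domains=iio.read_domains(indir / "domains.tsv"),
        loci=iio.read_gene_loci(indir / "genes.gff3", "gff3"),
        map_intervals=iio.read_genetic_map(indir / "map.tsv"),
        pairs=iio.read_pairs(indir / "pairs.tsv"),
        centromeres=iio.read_centromeres(indir / "centromeres.tsv"),
        chrom_lengths=iio.read_sequence_regions(indir / "genes.gff3"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# generation internals

def _segment_lengths(rng: np.random.Generator, k: int, cfg: SimulationConfig,
                     protein_length: int) -> list[int]:
    """k segment lengths (min + geometric tail), shrunk to fit the protein
    with >= 1 ordered residue between consecutive segments."""
    p = 1.0 / max(cfg.seg_len_geom_mean, 1.0)
    lengths = [cfg.seg_len_min + int(rng.geometric(p)) - 1 for _ in range(k)]
    budget = protein_length - (k - 1)
    while sum(lengths) > budget:
        j = int(np.argmax(lengths))
        if lengths[j] == cfg.seg_len_min:
            # all at minimum and still over budget: caller capped k wrongly
            raise ValueError("infeasible segment layout")
        lengths[j] = max(cfg.seg_len_min, lengths[j] - (sum(lengths) - budget))
    return lengths


def _place_segments(rng: np.random.Generator, lengths: list[int],
                    protein_length: int) -> list[tuple[int, int]]:
    """Place segments left to right with random slack in the k+1 gaps."""
    k = len(lengths)
    if k == 0:
        return []
    slack = protein_length - sum(lengths) - (k - 1)
    gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
    segs = []
    pos = 0
    for i, length in enumerate(lengths):
        pos += int(gaps[i]) + (1 if i > 0 else 0)
        segs.append((pos, pos + length))
        pos += length
    return segs


def _add_short_runs(rng: np.random.Generator, mask: np.ndarray,
                    cfg: SimulationConfig) -> None:
    """Sprinkle short (<30) disordered runs that never touch existing runs,
    so the long-segment count is unchanged and the L>=30 filter has work."""
    n_short = int(rng.poisson(cfg.short_disorder_rate))
    L = mask.size
    for _ in range(n_short):
        length = int(rng.integers(3, 15))
        if L <= length + 2:
            continue
        for _attempt in range(10):
            s = int(rng.integers(1, L - length - 1))
            if not mask[s - 1:s + length + 1].any():
                mask[s:s + length] = True
                break


#: per amino acid, its synonymous codons sorted by ascending G+C
_CODONS_GC_SORTED = {
    aa: sorted(CODONS_BY_AA[aa], key=_gc_fraction) for aa in AA20
}


def _sample_residues(rng: np.random.Generator, disordered: np.ndarray,
                     cfg: SimulationConfig, gc_bias: float) -> tuple[str, str]:
    """Amino-acid string and codon string for one protein.

    Ordered positions: uniform amino acid, uniform synonymous codon.
    Disordered positions: with probability ``p_rgap`` a uniform choice of
    Arg/Gly/Ala/Pro encoded by a fully-G+C codon, else as ordered.
    ``gc_bias`` is a per-gene synonymous-codon bias: with probability
    ``|gc_bias|`` the most (bias > 0) or least (bias < 0) G+C-rich
    synonymous codon is used instead of a uniform one, emulating the
    gene-to-gene G+C variation of real genomes that is independent of
    disorder content.
    """
    n = disordered.size
    aa_idx = rng.integers(0, 20, size=n)
    codon_pick = rng.random(n)
    use_rgap = disordered & (rng.random(n) < cfg.p_rgap)
    rgap_idx = rng.integers(0, 4, size=n)
    use_bias = rng.random(n) < min(abs(gc_bias), 1.0)
    extreme = -1 if gc_bias > 0 else 0
    aas = []
    codons = []
    rgap_aas = "RGAP"
    for i in range(n):
        if use_rgap[i]:
            aa = rgap_aas[rgap_idx[i]]
            codons.append(RGAP_CODONS[aa][int(codon_pick[i] * 2)])
        else:
            aa = AA20[aa_idx[i]]
            if use_bias[i]:
                codons.append(_CODONS_GC_SORTED[aa][extreme])
            else:
                codon_list = CODONS_BY_AA[aa]
                codons.append(codon_list[int(codon_pick[i] * len(codon_list))])
        aas.append(aa)
    return "".join(aas), "".join(codons)


def simulate(config: SimulationConfig | None = None) -> Bundle:
    """Generate one complete bundle; fully determined by ``config.seed``."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chrom_lengths = {c: cfg.chrom_length_bp for c in chrom_names}
    centromeres = {c: cfg.chrom_length_bp // 2 for c in chrom_names}

    # --- per-window recombination rates (cM/Mb), with hotspots
    window_rates: dict[str, list[float]] = {}
    map_intervals: list[GeneticMapInterval] = []
    for chrom in chrom_names:
        bounds = list(range(0, cfg.chrom_length_bp, cfg.window_size_bp))
        n_w = len(bounds)
        rates = rng.gamma(cfg.rec_shape, cfg.rec_scale, size=n_w)
        if cfg.hotspot_count and n_w:
            hot = rng.choice(n_w, size=min(cfg.hotspot_count, n_w), replace=False)
            rates[hot] *= cfg.hotspot_multiplier
        window_rates[chrom] = [float(r) for r in rates]
        for start, rate in zip(bounds, rates):
            end = min(start + cfg.window_size_bp, cfg.chrom_length_bp)
            cm = float(rate) * (end - start) / 1e6
            map_intervals.append(GeneticMapInterval(chrom, start, end, cm))

    # --- gene skeleton: protein lengths, chromosome, position
    n = cfg.n_genes
    extra = max(cfg.mean_protein_length - cfg.min_protein_length, 1)
    prot_len = cfg.min_protein_length + rng.poisson(extra, size=n)
    gene_chrom = rng.integers(0, cfg.n_chromosomes, size=n)

    # --- paralogue pairs: partners copy the anchor's protein length so a
    #     conserved segment count always fits
    if 2 * cfg.n_pairs > n:
        raise ValueError("n_pairs too large for n_genes")
    pair_idx = rng.choice(n, size=2 * cfg.n_pairs, replace=False)
    anchors, partners = pair_idx[:cfg.n_pairs], pair_idx[cfg.n_pairs:]
    prot_len[partners] = prot_len[anchors]

    cds_len = 3 * prot_len + 3  # stop codon included
    # regional gene density: Dirichlet weights over windows per chromosome,
    # lower alpha = stronger clustering
    window_weights = {
        chrom: rng.dirichlet(np.full(len(window_rates[chrom]),
                                     cfg.gene_density_alpha))
        for chrom in chrom_names
    }
    gene_start = np.empty(n, dtype=np.int64)
    for i in range(n):
        chrom = chrom_names[gene_chrom[i]]
        w = int(rng.choice(len(window_weights[chrom]),
                           p=window_weights[chrom]))
        w_start = w * cfg.window_size_bp
        w_end = min(w_start + cfg.window_size_bp, chrom_lengths[chrom])
        start = int(rng.integers(w_start, w_end))
        gene_start[i] = min(start, chrom_lengths[chrom] - int(cds_len[i]))

    gene_ids = [f"g{i:05d}" for i in range(n)]
    prot_ids = [f"p{i:05d}" for i in range(n)]
    loci = [
        GeneLocus(gene_ids[i], chrom_names[gene_chrom[i]], int(gene_start[i]),
                  int(gene_start[i] + cds_len[i]), "+" if rng.random() < 0.5 else "-",
                  prot_ids[i])
        for i in range(n)
    ]

    # --- expected long-segment count per gene from its window's rate
    def rate_of(i: int) -> float:
        chrom = chrom_names[gene_chrom[i]]
        w = min(loci[i].midpoint // cfg.window_size_bp,
                len(window_rates[chrom]) - 1)
        return window_rates[chrom][w]

    cap = (prot_len + 1) // (cfg.seg_len_min + 1)
    k_seg = np.array([
        min(int(rng.poisson(cfg.lambda0 + cfg.beta_rec * rate_of(i))), int(cap[i]))
        for i in range(n)
    ])

    # --- conservation: partner's count tracks the anchor's
    pair_conserved: dict[tuple[str, str], bool] = {}
    pair_class: dict[tuple[str, str], str] = {}
    pairs: list[ParalogPair] = []
    for a, b in zip(anchors, partners):
        locus = loci[a]
        label = classify_location(locus, centromeres[locus.chromosome],
                                  chrom_lengths[locus.chromosome],
                                  cfg.centromeric_radius, cfg.proximal_fraction)
        conserved = bool(rng.random() < cfg.p_conserve[label])
        ka = int(k_seg[a])
        if conserved:
            k_seg[b] = ka
        elif ka == 0:
            k_seg[b] = 1
        elif ka >= cap[b]:
            k_seg[b] = ka - 1
        else:
            k_seg[b] = ka + (1 if rng.random() < 0.5 else -1)
        key = (prot_ids[a], prot_ids[b])
        pairs.append(ParalogPair(*key))
        pair_conserved[key] = conserved
        pair_class[key] = label

    # --- masks
    masks: list[DisorderMask] = []
    gene_segments: dict[str, list[tuple[int, int]]] = {}
    for i in range(n):
        L = int(prot_len[i])
        lengths = _segment_lengths(rng, int(k_seg[i]), cfg, L)
        segs = _place_segments(rng, lengths, L)
        calls = np.zeros(L, dtype=bool)
        for s, e in segs:
            calls[s:e] = True
        _add_short_runs(rng, calls, cfg)
        masks.append(DisorderMask(prot_ids[i], calls))
        gene_segments[prot_ids[i]] = segs

    # --- sequences
    proteins: list[ProteinRecord] = []
    cds: list[CdsRecord] = []
    if cfg.emit_sequences:
        gene_gc_bias = rng.normal(0.0, cfg.gc_noise_sd, size=n)
        for i in range(n):
            aa, codons = _sample_residues(rng, masks[i].calls, cfg,
                                          float(gene_gc_bias[i]))
            proteins.append(ProteinRecord(prot_ids[i], aa))
            cds.append(CdsRecord(prot_ids[i], codons + "TAA"))

    # --- domains, independent of disorder
    domains: list[DomainAnnotation] = []
    for i in range(n):
        L = int(prot_len[i])
        for j in range(int(rng.poisson(cfg.domains_per_protein))):
            dlen = min(L - 1, 30 + int(rng.geometric(1.0 / cfg.domain_mean_length)))
            start = int(rng.integers(0, L - dlen))
            domains.append(DomainAnnotation(
                prot_ids[i], f"SF{rng.integers(0, 500):04d}", start, start + dlen))

    truth = GroundTruth(cfg, window_rates, gene_segments, pair_conserved,
                        pair_class)
    return Bundle(proteins, cds, masks, domains, loci, map_intervals, pairs,
                  centromeres, chrom_lengths, truth)


# ---------------------------------------------------------------------------
# recovery

def recovery_report(bundle: Bundle) -> dict:
    """Run the full pipeline on a bundle and compare estimates to truth.

    Returns a flat dict of estimated quantities (correlations, regression
    slopes, conservation fractions, dispersion indices) alongside the true
    generative parameters where the bundle carries ground truth.  Fails
    hard if the pipeline cannot process the generator's own output.
    """
    masks = bundle.mask_dict()
    windows = make_windows(bundle.chrom_lengths, "map",
                           map_intervals=bundle.map_intervals)
    assignment, unassigned = assign_genes(windows, bundle.loci)

    gc_parts = None
    if bundle.cds:
        paired, _excl = iio.pair_proteins_cds(bundle.proteins, bundle.cds)
        gc_parts = {}
        for pid, (_prot, c) in paired.items():
            flags = project_mask_to_cds(masks[pid], c)
            gc_parts[pid] = gc_partition(c, flags)

    stats = window_statistics(windows, assignment, masks, gc_parts)
    usable = [s for s in stats
              if s.defined and s.recombination_rate is not None]
    if len(usable) < 3:
        raise ValueError(
            f"only {len(usable)} usable windows: correlation analysis "
            "requires at least 3 windows with genes and recombination rates"
        )
    seg_freq = np.array([s.segment_frequency for s in usable])
    rates = np.array([s.recombination_rate for s in usable])
    corr = pearson(seg_freq, rates)
    beta_rec_hat = float(np.polyfit(rates, seg_freq, 1)[0])

    report: dict = {
        "n_windows": len(usable),
        "n_unassigned_genes": len(unassigned),
        "disorder_recombination_r": corr.r,
        "disorder_recombination_p": corr.p,
        "disorder_recombination_stars": corr.stars,
        "beta_rec_hat": beta_rec_hat,
    }

    # per-chromosome dispersion of disorder-containing genes in 0.5 Mb windows
    fixed = make_windows(bundle.chrom_lengths, "fixed", size=500_000)
    fixed_assign, _ = assign_genes(fixed, bundle.loci)
    vmr = {}
    for chrom in bundle.chrom_lengths:
        counts = [
            sum(1 for g in fixed_assign[i]
                if extract_segments(masks[g.protein_id]))
            for i, w in enumerate(fixed) if w.chromosome == chrom
        ]
        vmr[chrom] = index_of_dispersion(counts)
    report["dispersion_index"] = vmr

    if gc_parts:
        # per-gene slope of G+C fraction on disordered fraction -> delta_gc
        dis_frac = np.array([masks[pid].calls.mean() for pid in gc_parts])
        gcfrac = np.array([p.gc_total / p.gene_length
                           for p in gc_parts.values()])
        report["delta_gc_hat"] = float(np.polyfit(dis_frac, gcfrac, 1)[0])
        reg_rows = [s for s in usable if not np.isnan(s.gc_disordered_frequency)]
        reg = multiple_regression(
            [s.disordered_residue_frequency for s in reg_rows],
            [s.gc_disordered_frequency for s in reg_rows],
            [s.recombination_rate for s in reg_rows],
        )
        report["regression_r2"] = reg.multiple_r2
        report["regression_gc_p"] = reg.anova_p["gc"]
        report["regression_rec_p"] = reg.anova_p["rec"]
        report["regression_beta_gc"] = reg.params["gc"]
        report["regression_beta_rec"] = reg.params["rec"]

    if bundle.pairs:
        summary = summarize_conservation(bundle.pairs, masks)
        report["conserved_fraction_hat"] = summary.n_conserved / summary.n_pairs

    if bundle.truth is not None:
        t = bundle.truth
        report["beta_rec_true"] = t.beta_rec
        report["delta_gc_true"] = t.delta_gc
        report["p_conserve_true"] = dict(t.config.p_conserve)
        if t.pair_conserved:
            report["conserved_fraction_realized"] = float(
                np.mean(list(t.pair_conserved.values()))
            )
    return report
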