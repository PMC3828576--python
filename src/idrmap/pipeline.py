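"""End-to-end orchestration: read one input set, run every analysis stage,
write the stage TSVs.  The CLI wraps these functions; they are equally
usable from Python.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import io as iio
from .conservation import conservation_by_location, summarize_conservation
from .gc import gc_enrichment_test, gc_partition, project_mask_to_cds
from .segments import (classify_disordered_residues, extract_segments,
                       summarize_breakdowns)
from .stats import index_of_dispersion, multiple_regression, pearson
from .windows import assign_genes, make_windows, window_statistics


@dataclass
class RunConfig:
    """Validated paths and knobs for a full run."""

    proteins: Path
    masks: Path
    mask_format: str = "mask_fasta"
    cds: Path | None = None
    domains: Path | None = None
    loci: Path | None = None
    loci_format: str = "gff3"
    genetic_map: Path | None = None
    centromeres: Path | None = None
    pairs: Path | None = None
    min_seg_len: int = 30
    window_mode: str = "map"
    window_size: int = 500_000
    centromeric_radius: int = 250_000
    proximal_fraction: float = 0.25
    out_dir: Path = Path("idrmap_out")

    def __post_init__(self) -> None:
        for name in ("proteins", "masks", "cds", "domains", "loci",
                     "genetic_map", "centromeres", "pairs"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, Path(val))
        self.out_dir = Path(self.out_dir)
        for name in ("proteins", "masks"):
            if not getattr(self, name).exists():
                raise FileNotFoundError(f"{name} file not found: {getattr(self, name)}")
        for name in ("cds", "domains", "loci", "genetic_map", "centromeres",
                     "pairs"):
            val = getattr(self, name)
            if val is not None and not val.exists():
                raise FileNotFoundError(f"{name} file not found: {val}")

    def digest(self) -> str:
        payload = {k: str(v) for k, v in vars(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def provenance_lines(config: RunConfig) -> list[str]:
    return [f"## idrmap {__version__} config={config.digest()}"]


def _write_tsv(path: Path, config: RunConfig, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(config):
            fh.write(line + "\n")
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_all(config: RunConfig) -> Path:
    """Execute every applicable stage in order and write one TSV per stage.

    Stages needing absent optional inputs are skipped and noted in the run
    report; non-fatal exclusions (unmatched CDS, empty windows, skipped
    pairs) are summarized there too.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: list[str] = [f"idrmap {__version__} run, config {config.digest()}"]

    proteins = iio.read_protein_fasta(config.proteins)
    masks = {m.protein_id: m
             for m in iio.read_disorder_masks(config.masks, config.mask_format)}
    prot_by_id = {p.id: p for p in proteins}

    # --- segments
    seg_rows = []
    for pid in sorted(masks):
        for seg in extract_segments(masks[pid], config.min_seg_len):
            seg_rows.append((pid, seg.start, seg.end, seg.length))
    _write_tsv(out / "segments.tsv", config,
               ["protein_id", "start", "end", "length"], seg_rows)
    report.append(f"segments: {len(seg_rows)} segments over {len(masks)} proteins")

    loci = (iio.read_gene_loci(config.loci, config.loci_format)
            if config.loci else None)
    chrom_of = {g.protein_id: g.chromosome for g in loci} if loci else {}

    # --- domain table (per chromosome when loci are present)
    if config.domains:
        domains_by_pid: dict[str, list] = {}
        for d in iio.read_domains(config.domains):
            domains_by_pid.setdefault(d.protein_id, []).append(d)
        groups: dict[str, list[str]] = {}
        for pid in masks:
            if pid in domains_by_pid and pid in prot_by_id:
                groups.setdefault(chrom_of.get(pid, "all"), []).append(pid)
        rows = []
        for chrom in sorted(groups):
            breakdowns, total = [], 0
            for pid in groups[chrom]:
                b = classify_disordered_residues(
                    masks[pid], domains_by_pid[pid], prot_by_id[pid].length)
                if b.n_disordered:
                    breakdowns.append(b)
                    total += prot_by_id[pid].length
            if not breakdowns:
                continue
            s = summarize_breakdowns(breakdowns, total)
            rows.append((chrom, s.n_proteins,
                         *(f"{x:.2f}" for x in (s.pct_total_disorder,
                                                s.pct_in_domain, s.pct_outside,
                                                s.pct_linker, s.pct_nterm,
                                                s.pct_cterm))))
        _write_tsv(out / "domain_table.tsv", config,
                   ["chromosome", "n_proteins", "pct_total_disorder",
                    "pct_in_domain", "pct_outside", "pct_linker", "pct_nterm",
                    "pct_cterm"], rows)
        report.append(f"domain table: {len(rows)} chromosome rows")
    else:
        report.append("domain table: skipped (no domain annotations)")

    # --- conservation
    if config.pairs:
        pairs = iio.read_pairs(config.pairs)
        summary = summarize_conservation(pairs, masks, config.min_seg_len)
        rows = [("all", summary.n_pairs, summary.n_conserved,
                 summary.n_nonconserved, f"{summary.pct_conserved:.1f}",
                 f"{summary.pct_nonconserved:.1f}", summary.n_skipped)]
        if loci and config.centromeres:
            centromeres = iio.read_centromeres(config.centromeres)
            chrom_lengths = (iio.read_sequence_regions(config.loci)
                             if config.loci_format == "gff3" else
                             {g.chromosome: max(x.end for x in loci
                                                if x.chromosome == g.chromosome)
                              for g in loci})
            per_class = conservation_by_location(
                pairs, masks, {g.protein_id: g for g in loci}, centromeres,
                chrom_lengths, config.min_seg_len, config.centromeric_radius,
                config.proximal_fraction)
            for label, s in per_class.items():
                if s is None:
                    rows.append((label, 0, 0, 0, "nan", "nan", 0))
                else:
                    rows.append((label, s.n_pairs, s.n_conserved,
                                 s.n_nonconserved, f"{s.pct_conserved:.1f}",
                                 f"{s.pct_nonconserved:.1f}", s.n_skipped))
        _write_tsv(out / "conservation.tsv", config,
                   ["class", "n_pairs", "n_conserved", "n_nonconserved",
                    "pct_conserved", "pct_nonconserved", "n_skipped"], rows)
        report.append(f"conservation: {summary.n_pairs} scorable pairs, "
                      f"{summary.n_skipped} skipped")

    # --- G+C
    gc_parts = None
    if config.cds:
        cds = iio.read_cds_fasta(config.cds)
        paired, excluded = iio.pair_proteins_cds(proteins, cds)
        gc_parts = {}
        for pid, (_p, c) in paired.items():
            if pid not in masks:
                continue
            flags = project_mask_to_cds(masks[pid], c, config.min_seg_len)
            gc_parts[pid] = gc_partition(c, flags)
        _write_tsv(out / "gc.tsv", config,
                   ["gene_id", "gc_total", "gc_disordered", "gc_ordered",
                    "gene_length", "gc_disordered_frequency",
                    "pct_gc_disordered_region", "pct_gc_ordered_region"],
                   ((p.gene_id, p.gc_total, p.gc_disordered, p.gc_ordered,
                     p.gene_length, f"{p.gc_disordered_frequency:.6f}",
                     f"{p.pct_gc_disordered_region:.3f}",
                     f"{p.pct_gc_ordered_region:.3f}")
                    for p in gc_parts.values()))
        try:
            enr = gc_enrichment_test(list(gc_parts.values()))
            report.append(
                f"gc enrichment: +{enr.mean_difference:.2f}% "
                f"(t={enr.t_statistic:.2f}, p={enr.p_value:.3g}, "
                f"n={enr.n_genes})")
        except ValueError as exc:
            report.append(f"gc enrichment: not computed ({exc})")
        report.append(f"gc: {len(excluded)} protein/CDS exclusions")

    # --- windows and statistics
    if loci and (config.genetic_map or config.window_mode == "fixed"):
        map_intervals = (iio.read_genetic_map(config.genetic_map)
                         if config.genetic_map else None)
        if config.loci_format == "gff3":
            chrom_lengths = iio.read_sequence_regions(config.loci)
        else:
            chrom_lengths = {}
            for g in loci:
                chrom_lengths[g.chromosome] = max(
                    chrom_lengths.get(g.chromosome, 0), g.end)
        windows = make_windows(chrom_lengths, config.window_mode,
                               config.window_size, map_intervals)
        assignment, unassigned = assign_genes(windows, loci)
        stats = window_statistics(windows, assignment, masks, gc_parts,
                                  config.min_seg_len)
        _write_tsv(out / "windows.tsv", config,
                   ["chromosome", "start", "end", "n_genes", "n_segments",
                    "segment_frequency", "disordered_residue_frequency",
                    "gc_disordered_frequency", "recombination_cM_per_Mb"],
                   ((s.window.chromosome, s.window.start, s.window.end,
                     s.n_genes, s.n_segments,
                     f"{s.segment_frequency:.6f}",
                     f"{s.disordered_residue_frequency:.6f}",
                     f"{s.gc_disordered_frequency:.6f}",
                     "" if s.recombination_rate is None
                     else f"{s.recombination_rate:.6f}")
                    for s in stats))
        n_empty = sum(1 for s in stats if not s.defined)
        report.append(f"windows: {len(stats)} windows, {n_empty} empty, "
                      f"{len(unassigned)} genes unassigned")

        usable = [s for s in stats
                  if s.defined and s.recombination_rate is not None]
        corr_rows = []
        chroms = sorted({s.window.chromosome for s in usable})
        for scope, subset in [("pooled", usable)] + [
                (c, [s for s in usable if s.window.chromosome == c])
                for c in chroms]:
            if len(subset) < 3:
                continue
            for xname, yname, xs, ys in [
                ("segment_frequency", "recombination",
                 [s.segment_frequency for s in subset],
                 [s.recombination_rate for s in subset]),
                ("gc_disordered_frequency", "recombination",
                 [s.gc_disordered_frequency for s in subset],
                 [s.recombination_rate for s in subset]),
                ("disordered_residue_frequency", "gc_disordered_frequency",
                 [s.disordered_residue_frequency for s in subset],
                 [s.gc_disordered_frequency for s in subset]),
            ]:
                xa, ya = np.asarray(xs), np.asarray(ys)
                ok = ~(np.isnan(xa) | np.isnan(ya))
                if ok.sum() < 3 or np.ptp(xa[ok]) == 0 or np.ptp(ya[ok]) == 0:
                    continue
                res = pearson(xa[ok], ya[ok])
                corr_rows.append((scope, xname, yname, f"{res.r:.4f}",
                                  res.n, f"{res.p:.4g}", res.stars))
        _write_tsv(out / "correlations.tsv", config,
                   ["scope", "x", "y", "r", "n", "p", "stars"], corr_rows)

        # dispersion: disorder-containing genes per fixed 0.5 Mb window
        fixed = make_windows(chrom_lengths, "fixed", size=500_000)
        fixed_assign, _ = assign_genes(fixed, loci)
        disp_rows = []
        for chrom in sorted(chrom_lengths):
            counts = [sum(1 for g in fixed_assign[i]
                          if extract_segments(masks[g.protein_id],
                                              config.min_seg_len))
                      for i, w in enumerate(fixed) if w.chromosome == chrom]
            try:
                disp_rows.append((chrom, len(counts),
                                  f"{index_of_dispersion(counts):.4f}"))
            except ValueError:
                disp_rows.append((chrom, len(counts), "nan"))
        _write_tsv(out / "dispersion.tsv", config,
                   ["chromosome", "n_windows", "vmr"], disp_rows)

        # regression needs G+C per window
        reg_rows = [s for s in usable
                    if not math.isnan(s.gc_disordered_frequency)]
        if len(reg_rows) > 3:
            reg = multiple_regression(
                [s.disordered_residue_frequency for s in reg_rows],
                [s.gc_disordered_frequency for s in reg_rows],
                [s.recombination_rate for s in reg_rows])
            _write_tsv(out / "regression.tsv", config,
                       ["term", "estimate", "std_error", "p_value", "anova_p"],
                       [("intercept", f"{reg.params['intercept']:.6g}",
                         f"{reg.bse['intercept']:.6g}",
                         f"{reg.pvalues['intercept']:.4g}", ""),
                        ("gc", f"{reg.params['gc']:.6g}",
                         f"{reg.bse['gc']:.6g}",
                         f"{reg.pvalues['gc']:.4g}",
                         f"{reg.anova_p['gc']:.4g}"),
                        ("rec", f"{reg.params['rec']:.6g}",
                         f"{reg.bse['rec']:.6g}",
                         f"{reg.pvalues['rec']:.4g}",
                         f"{reg.anova_p['rec']:.4g}"),
                        ("multiple_r2", f"{reg.multiple_r2:.4f}", "", "", ""),
                        ("breusch_pagan", f"{reg.bp_lm_stat:.4f}", "",
                         f"{reg.bp_lm_p:.4g}", ""),
                        ("shapiro", f"{reg.shapiro_w:.4f}", "",
                         f"{reg.shapiro_p:.4g}", "")])
            report.append(f"regression: r2={reg.multiple_r2:.3f} "
                          f"gc p={reg.anova_p['gc']:.3g} "
                          f"rec p={reg.anova_p['rec']:.3g}")

    (out / "run_report.txt").write_text("\n".join(report) + "\n")
    return out
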