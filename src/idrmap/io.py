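"""Readers and writers for every input format.

This is the single conversion site between on-disk conventions and the
package's internal 0-based half-open coordinates:

* GFF3 and all TSV dialects (gene loci, domains, genetic map, centromeres)
  are 1-based inclusive on disk and converted on read; writers convert back.
* Disorder predictions arrive either as DISOPRED-style horizontal files
  (``index residue mark score`` per line, ``*`` disordered / ``.`` ordered,
  one file per protein, protein id taken from the filename stem) or as a
  FASTA-like multi-record mask file with symbols ``D`` (disordered) and
  ``-`` (ordered).
* TSV files are tab-separated with a single header line beginning ``#``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
from Bio import SeqIO

from .types import (
    CdsRecord,
    DisorderMask,
    DomainAnnotation,
    FormatError,
    GeneLocus,
    GeneticMapInterval,
    PairingError,
    ParalogPair,
    ProteinRecord,
)

__all__ = [
    "read_protein_fasta",
    "read_cds_fasta",
    "write_fasta",
    "read_disorder_masks",
    "write_mask_fasta",
    "write_diso",
    "read_domains",
    "write_domains",
    "read_gene_loci",
    "write_gene_loci_tsv",
    "write_gene_gff3",
    "read_sequence_regions",
    "read_genetic_map",
    "write_genetic_map",
    "read_pairs",
    "write_pairs",
    "read_centromeres",
    "write_centromeres",
    "pair_proteins_cds",
]


# ---------------------------------------------------------------------------
# FASTA

def _read_fasta_ids_seqs(path: str | Path) -> list[tuple[str, str]]:
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            rid = rec.id  # first whitespace-delimited token of the header
            if rid in seen:
                raise FormatError(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            records.append((rid, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; a trailing stop symbol ``*`` is stripped."""
    out = []
    for rid, seq in _read_fasta_ids_seqs(path):
        if seq.endswith("*"):
            seq = seq[:-1]
        out.append(ProteinRecord(rid, seq))
    return out


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    return [CdsRecord(rid, seq) for rid, seq in _read_fasta_ids_seqs(path)]


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Disorder masks

def _read_diso_file(path: Path) -> DisorderMask:
    """Parse one DISOPRED-style per-protein file; residue numbering 1-based."""
    calls: list[bool] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 'index residue mark [score]'")
            idx, mark = int(parts[0]), parts[2]
            if idx != len(calls) + 1:
                raise FormatError(
                    f"{path}:{lineno}: residue index {idx} breaks contiguous "
                    f"1-based numbering (expected {len(calls) + 1})"
                )
            if mark == "*":
                calls.append(True)
            elif mark == ".":
                calls.append(False)
            else:
                raise FormatError(f"{path}:{lineno}: unknown disorder mark {mark!r}")
    if not calls:
        raise FormatError(f"{path}: empty disorder file")
    return DisorderMask(path.stem, np.array(calls, dtype=bool))


def read_disorder_masks(path: str | Path,
                        format: str = "mask_fasta") -> list[DisorderMask]:
    """Read disorder calls.

    ``format='disopred_diso'`` accepts a single ``.diso`` file or a
    directory of them; ``format='mask_fasta'`` a multi-record ``D``/``-``
    mask file.
    """
    path = Path(path)
    if format == "disopred_diso":
        files = sorted(path.glob("*.diso")) if path.is_dir() else [path]
        if not files:
            raise FormatError(f"{path}: no .diso files found")
        return [_read_diso_file(f) for f in files]
    if format == "mask_fasta":
        masks = []
        for rid, sym in _read_fasta_ids_seqs(path):
            bad = set(sym) - {"D", "-"}
            if bad:
                raise FormatError(
                    f"{path}: mask {rid!r} has unknown symbols {sorted(bad)}"
                )
            masks.append(DisorderMask(rid, np.frombuffer(sym.encode(), dtype="S1") == b"D"))
        return masks
    raise ValueError(f"unknown mask format {format!r}")


def write_mask_fasta(masks: Iterable[DisorderMask], path: str | Path,
                     width: int = 60) -> None:
    with open(path, "w") as fh:
        for m in masks:
            sym = "".join("D" if c else "-" for c in m.calls)
            fh.write(f">{m.protein_id}\n")
            for i in range(0, len(sym), width):
                fh.write(sym[i:i + width] + "\n")


def write_diso(mask: DisorderMask, path: str | Path,
               sequence: str | None = None) -> None:
    """Write one DISOPRED-style file; residue letters default to ``X``."""
    seq = sequence if sequence is not None else "X" * len(mask)
    if len(seq) != len(mask):
        raise ValueError(f"{mask.protein_id}: sequence/mask length mismatch")
    with open(path, "w") as fh:
        for i, call in enumerate(mask.calls):
            mark = "*" if call else "."
            score = 0.9 if call else 0.1
            fh.write(f"{i + 1:5d} {seq[i]} {mark} {score:.2f}\n")


# ---------------------------------------------------------------------------
# TSV helpers

def _iter_tsv_rows(path: str | Path, n_cols: int):
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"{path}: missing '#'-prefixed header line")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated "
                    f"columns, found {len(parts)}"
                )
            yield lineno, parts


def _write_tsv(path: str | Path, header: Sequence[str],
               rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Domains

def read_domains(path: str | Path) -> list[DomainAnnotation]:
    """Domain TSV: protein_id, domain_id, start, end (1-based inclusive)."""
    out = []
    for lineno, (pid, did, start, end) in _iter_tsv_rows(path, 4):
        s, e = int(start) - 1, int(end)
        if s >= e:
            raise FormatError(f"{path}:{lineno}: empty domain interval")
        out.append(DomainAnnotation(pid, did, s, e))
    return out


def write_domains(domains: Iterable[DomainAnnotation], path: str | Path) -> None:
    _write_tsv(path, ["protein_id", "domain_id", "start", "end"],
               ((d.protein_id, d.domain_id, d.start + 1, d.end) for d in domains))


# ---------------------------------------------------------------------------
# Gene loci

def read_gene_loci(path: str | Path, format: str = "gff3") -> list[GeneLocus]:
    """Read gene placements from GFF3 (``gene`` features only) or TSV.

    GFF3 gene features must carry ``ID`` and ``protein_id`` attributes
    (``protein_id`` falls back to ``ID``).
    """
    if format == "tsv":
        out = []
        for _lineno, (gid, chrom, start, end, strand, pid) in _iter_tsv_rows(path, 6):
            out.append(GeneLocus(gid, chrom, int(start) - 1, int(end), strand, pid))
        return out
    if format == "gff3":
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                merge_strategy="error", keep_order=True)
        out = []
        for feat in db.features_of_type("gene"):
            pid = feat.attributes.get("protein_id", feat.attributes["ID"])[0]
            out.append(GeneLocus(feat.id, feat.seqid, feat.start - 1, feat.end,
                                 feat.strand, pid))
        if not out:
            raise FormatError(f"{path}: no gene features found")
        return out
    raise ValueError(f"unknown loci format {format!r}")


def write_gene_loci_tsv(loci: Iterable[GeneLocus], path: str | Path) -> None:
    _write_tsv(path, ["gene_id", "chromosome", "start", "end", "strand", "protein_id"],
               ((g.gene_id, g.chromosome, g.start + 1, g.end, g.strand, g.protein_id)
                for g in loci))


def write_gene_gff3(loci: Iterable[GeneLocus], path: str | Path,
                    chrom_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in loci:
            attrs = f"ID={g.gene_id};protein_id={g.protein_id}"
            fh.write(f"{g.chromosome}\tidrmap\tgene\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\t{attrs}\n")


def read_sequence_regions(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from ``##sequence-region`` pragmas of a GFF3 file."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()
                lengths[chrom] = int(end)
            elif not line.startswith("#"):
                break
    if not lengths:
        raise FormatError(f"{path}: no ##sequence-region pragmas")
    return lengths


# ---------------------------------------------------------------------------
# Genetic map

def read_genetic_map(path: str | Path) -> list[GeneticMapInterval]:
    """Map TSV: chromosome, start_bp, end_bp, cM (1-based inclusive bp).

    Intervals on one chromosome must not overlap (half-open adjacency is
    allowed); output is sorted per chromosome.
    """
    out = []
    for _lineno, (chrom, start, end, cm) in _iter_tsv_rows(path, 4):
        out.append(GeneticMapInterval(chrom, int(start) - 1, int(end), float(cm)))
    out.sort(key=lambda iv: (iv.chromosome, iv.start))
    for prev, cur in zip(out, out[1:]):
        if cur.chromosome == prev.chromosome and cur.start < prev.end:
            raise FormatError(
                f"{path}: overlapping map intervals on {cur.chromosome}: "
                f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
            )
    return out


def write_genetic_map(intervals: Iterable[GeneticMapInterval],
                      path: str | Path) -> None:
    _write_tsv(path, ["chromosome", "start_bp", "end_bp", "cM"],
               ((iv.chromosome, iv.start + 1, iv.end, repr(iv.cm))
                for iv in intervals))


# ---------------------------------------------------------------------------
# Pairs and centromeres

def read_pairs(path: str | Path) -> list[ParalogPair]:
    return [ParalogPair(a, b) for _ln, (a, b) in _iter_tsv_rows(path, 2)]


def write_pairs(pairs: Iterable[ParalogPair], path: str | Path) -> None:
    _write_tsv(path, ["id_a", "id_b"], ((p.id_a, p.id_b) for p in pairs))


def read_centromeres(path: str | Path) -> dict[str, int]:
    """Centromere TSV: chromosome, position_bp (1-based) -> 0-based position."""
    return {chrom: int(pos) - 1
            for _ln, (chrom, pos) in _iter_tsv_rows(path, 2)}


def write_centromeres(centromeres: dict[str, int], path: str | Path) -> None:
    _write_tsv(path, ["chromosome", "position_bp"],
               ((c, p + 1) for c, p in centromeres.items()))


# ---------------------------------------------------------------------------
# Protein/CDS pairing

def pair_proteins_cds(
    proteins: Iterable[ProteinRecord],
    cds: Iterable[CdsRecord],
) -> tuple[dict[str, tuple[ProteinRecord, CdsRecord]], list[str]]:
    """Pair proteins with coding sequences by exact id.

    A CDS must be 3L or 3L+3 nucleotides (optional stop codon) for a
    protein of L residues.  Incompatible or unmatched entries are excluded
    from G+C analyses with a warning, never fatal: real proteomes contain
    annotation glitches.

    Returns (paired mapping, list of excluded ids).
    """
    prot_by_id = {p.id: p for p in proteins}
    cds_by_id = {c.id: c for c in cds}
    paired: dict[str, tuple[ProteinRecord, CdsRecord]] = {}
    excluded: list[str] = []
    for pid, prot in prot_by_id.items():
        c = cds_by_id.get(pid)
        if c is None:
            excluded.append(pid)
            continue
        if c.length not in (3 * prot.length, 3 * prot.length + 3):
            warnings.warn(
                f"{pid}: CDS length {c.length} incompatible with protein "
                f"length {prot.length}; excluded from G+C analyses",
                stacklevel=2,
            )
            excluded.append(pid)
            continue
        paired[pid] = (prot, c)
    return paired, excluded
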