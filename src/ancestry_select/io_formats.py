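"""Readers, writers and coordinate utilities for the ancestry-selection pipeline.

The pipeline starts from a multi-sample VCF of haploid genotypes (two parental
reference panels plus one or more admixed populations), a recombination map,
gene annotation intervals and a gene-to-GO-term table.  This module loads those
formats into the in-memory containers the rest of the package consumes and
provides the bp <-> cM interpolation used everywhere genetic distance matters.

Conventions
-----------
* Internal coordinates are 0-based half-open; positions are converted to
  1-based only at the I/O boundary (VCF, observation files, reported tables).
* Haploid genotypes are coded 0 (ref), 1 (alt), -1 (missing).
* Genetic positions are in centiMorgans; inter-site distances written to the
  observation format are in Morgans, per the Ancestry_HMM convention.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class DataError(ValueError):
    """Raised when a file parses but its content violates a data contract."""


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VariantTable:
    """Biallelic haploid SNP matrix.

    Attributes
    ----------
    chrom : array of str, per site
    pos : int array, 1-based bp positions, strictly increasing per chromosome
    ref, alt : arrays of single-character alleles
    genotypes : int8 array of shape (n_sites, n_samples); 0/1/-1 (missing)
    samples : list of sample names
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (self.pos.size, len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites x samples")
        bad = ~np.isin(self.genotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("genotypes must be 0, 1 or -1 (missing)")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def subset_samples(self, names: Sequence[str]) -> "VariantTable":
        idx = [self.samples.index(n) for n in names]
        return VariantTable(self.chrom, self.pos, self.ref, self.alt,
                            self.genotypes[:, idx], list(names))

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ref_count, alt_count) over non-missing calls."""
        g = self.genotypes
        alt = (g == 1).sum(axis=1)
        ref = (g == 0).sum(axis=1)
        return ref, alt


def _haploid_allele(call: list, sample: str, chrom: str, pos: int) -> int:
    """Extract the single allele from a cyvcf2 genotype entry.

    cyvcf2 yields ``[allele, phased]`` for haploid calls and
    ``[a1, a2, phased]`` for diploid calls.  Homozygous diploid calls are
    accepted as haploid (drones are sometimes emitted as 0/0 by callers);
    heterozygous diploid calls violate the haploid-sample contract.
    """
    alleles = call[:-1]
    if len(alleles) == 1:
        return int(alleles[0])
    uniq = {a for a in alleles if a >= 0}
    if len(uniq) > 1:
        raise DataError(
            f"heterozygous diploid call for haploid sample {sample} at {chrom}:{pos}")
    return int(next(iter(uniq))) if uniq else MISSING


def read_vcf_haploid(vcf_path: str, maf_min: float = 0.05,
                     indel_buffer: int = 5,
                     samples: Sequence[str] | None = None) -> VariantTable:
    """Read haploid genotypes from a VCF, applying the study's site filters.

    Retains only biallelic SNPs whose minor allele frequency (over all
    non-missing haploid calls) is strictly greater than ``maf_min`` and whose
    position is strictly more than ``indel_buffer`` bp away from any indel
    record in the file.  Missing genotypes are kept and coded -1.
    """
    try:
        vcf = VCF(vcf_path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise FormatError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    if samples is not None:
        vcf.set_samples(list(samples))
    names = list(vcf.samples)

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    indel_pos: dict[str, list[int]] = {}

    for var in vcf:
        if var.is_indel:
            # An indel occupies [POS, POS + len(longest allele)); guard both ends.
            span = max(len(var.REF), max((len(a) for a in var.ALT), default=1))
            indel_pos.setdefault(var.CHROM, []).extend(
                range(var.POS, var.POS + span))
            continue
        if not var.is_snp or len(var.ALT) != 1 or len(var.REF) != 1:
            continue
        calls = np.array(
            [_haploid_allele(c, names[i], var.CHROM, var.POS)
             for i, c in enumerate(var.genotypes)], dtype=np.int8)
        n_called = int((calls >= 0).sum())
        if n_called == 0:
            continue
        af = float((calls == 1).sum()) / n_called
        if min(af, 1.0 - af) <= maf_min:
            continue
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(calls)

    keep = np.ones(len(positions), dtype=bool)
    for i, (c, p) in enumerate(zip(chroms, positions)):
        near = indel_pos.get(c)
        if near and any(abs(p - q) <= indel_buffer for q in near):
            keep[i] = False

    order = np.lexsort((np.array(positions)[keep],
                        np.array(chroms, dtype=object)[keep]))
    chrom_arr = np.array(chroms, dtype=object)[keep][order]
    pos_arr = np.array(positions, dtype=np.int64)[keep][order]
    geno = (np.array(rows, dtype=np.int8)[keep][order]
            if rows else np.zeros((0, len(names)), dtype=np.int8))
    return VariantTable(chrom_arr, pos_arr,
                        np.array(refs, dtype=object)[keep][order],
                        np.array(alts, dtype=object)[keep][order],
                        geno, names)


def write_vcf_haploid(table: VariantTable, path: str,
                      contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a VariantTable back out as an uncompressed haploid VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = dict(contig_lengths or {})
        for c in pd.unique(table.chrom):
            length = contigs.get(c, int(table.pos[table.chrom == c].max()) + 1)
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        code = {0: "0", 1: "1", MISSING: "."}
        for i in range(table.n_sites):
            gts = "\t".join(code[int(g)] for g in table.genotypes[i])
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t"
                     f"{table.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------

class RecombinationMap:
    """Piecewise-linear bp <-> cM map per chromosome.

    Anchors must be non-decreasing in both coordinates with at least two per
    chromosome.  Queries outside the anchored span clamp to the terminal
    anchor's cM (zero-rate extrapolation), so genetic distance never goes
    negative or explodes at chromosome ends.
    """

    def __init__(self, anchors: Mapping[str, tuple[Sequence[float], Sequence[float]]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValueError(f"{chrom}: need at least 2 map anchors")
            if np.any(np.diff(bp) < 0) or np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: map anchors must be non-decreasing")
            self._anchors[chrom] = (bp, cm)

    @classmethod
    def uniform(cls, chrom_lengths_bp: Mapping[str, int],
                rate_cm_per_mb: float) -> "RecombinationMap":
        """Constant-rate map (e.g. 20 cM/Mb to emulate the honey bee's
        exceptionally high genome-wide recombination rate)."""
        return cls({c: ([0.0, float(L)], [0.0, rate_cm_per_mb * L / 1e6])
                    for c, L in chrom_lengths_bp.items()})

    @classmethod
    def read_tsv(cls, path: str) -> "RecombinationMap":
        """Read a (chrom, bp, cM) whitespace-separated table."""
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "bp", "cm"])
        return cls({str(c): (g["bp"].to_numpy(float), g["cm"].to_numpy(float))
                    for c, g in df.groupby("chrom", sort=False)})

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, (bp, cm) in self._anchors.items():
                for b, c in zip(bp, cm):
                    fh.write(f"{chrom}\t{b:.0f}\t{c:.8g}\n")

    @property
    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    def genetic_position(self, chrom: str, position) -> np.ndarray | float:
        """Interpolated cM at bp ``position`` (scalar or array)."""
        if chrom not in self._anchors:
            raise KeyError(f"chromosome {chrom!r} not in recombination map")
        bp, cm = self._anchors[chrom]
        # np.interp clamps to terminal values, matching the zero-rate policy.
        out = np.interp(np.asarray(position, dtype=float), bp, cm)
        return float(out) if np.isscalar(position) else out


def genetic_position(recmap: RecombinationMap, chrom: str, position):
    """Functional alias for :meth:`RecombinationMap.genetic_position`."""
    return recmap.genetic_position(chrom, position)


# ---------------------------------------------------------------------------
# Ancestry_HMM-style observation format
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ObservationTable:
    """One row per ancestry-informative site: panel allele counts, inter-site
    genetic distance, and per-sample haploid allele observations."""

    chrom: np.ndarray            # str per site
    pos: np.ndarray              # 1-based bp
    panel_a: np.ndarray          # (n_sites, 2) ref/alt counts
    panel_b: np.ndarray          # (n_sites, 2)
    distance_morgans: np.ndarray  # 0 at the first site of each chromosome
    genotypes: np.ndarray        # (n_sites, n_samples) 0/1/-1
    samples: list[str]

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)


def write_observations(panel_a_counts, panel_b_counts, sample_genotypes,
                       genetic_distances, path: str,
                       chrom=None, pos=None,
                       samples: Sequence[str] | None = None) -> None:
    """Write the tab-separated observation format.

    Columns: chrom, pos, A_ref, A_alt, B_ref, B_alt, distance (Morgans, 0 at
    the first site of each chromosome), then two columns per sample holding
    ref/alt allele observation counts (1 0, 0 1, or 0 0 for missing) — the
    haploid-genotype specialisation of the Ancestry_HMM read-count format.
    """
    a = np.asarray(panel_a_counts, dtype=np.int64)
    b = np.asarray(panel_b_counts, dtype=np.int64)
    g = np.asarray(sample_genotypes, dtype=np.int8)
    d = np.asarray(genetic_distances, dtype=float)
    n = a.shape[0]
    if not (b.shape[0] == g.shape[0] == d.shape[0] == n):
        raise ValueError("site-count mismatch across observation inputs")
    chrom = np.asarray(chrom if chrom is not None else ["chr1"] * n, dtype=object)
    pos = np.asarray(pos if pos is not None else np.arange(1, n + 1), dtype=np.int64)
    n_samples = g.shape[1]
    names = list(samples) if samples is not None else [
        f"sample{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        header = ["#chrom", "pos", "A_ref", "A_alt", "B_ref", "B_alt", "dist_M"]
        for s in names:
            header += [f"{s}_ref", f"{s}_alt"]
        fh.write("\t".join(header) + "\n")
        for i in range(n):
            row = [str(chrom[i]), str(int(pos[i])),
                   str(int(a[i, 0])), str(int(a[i, 1])),
                   str(int(b[i, 0])), str(int(b[i, 1])),
                   f"{d[i]:.10g}"]
            for j in range(n_samples):
                gt = int(g[i, j])
                row += {0: ["1", "0"], 1: ["0", "1"]}.get(gt, ["0", "0"])
            fh.write("\t".join(row) + "\n")


def read_observations(path: str) -> ObservationTable:
    """Read the observation format written by :func:`write_observations`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 7 or (len(header) - 7) % 2:
            raise FormatError(f"{path}: malformed observation header")
        names = [h[:-4] for h in header[7::2]]
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    n = len(rows)
    chrom = np.array([r[0] for r in rows], dtype=object)
    pos = np.array([int(r[1]) for r in rows], dtype=np.int64)
    a = np.array([[int(r[2]), int(r[3])] for r in rows], dtype=np.int64)
    b = np.array([[int(r[4]), int(r[5])] for r in rows], dtype=np.int64)
    d = np.array([float(r[6]) for r in rows], dtype=float)
    geno = np.full((n, len(names)), MISSING, dtype=np.int8)
    for i, r in enumerate(rows):
        for j in range(len(names)):
            ref, alt = int(r[7 + 2 * j]), int(r[8 + 2 * j])
            if ref + alt > 0:
                geno[i, j] = 1 if alt > ref else 0
    return ObservationTable(chrom, pos, a, b, d, geno, names)


# ---------------------------------------------------------------------------
# Gene annotation and GO table
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneAnnotation:
    """Gene intervals, internally 0-based half-open.

    ``exons`` optionally maps gene_id -> list of (start, end) sub-intervals in
    the same convention; when absent, the gene body stands in for its exons.
    """

    gene_id: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    exons: dict[str, list[tuple[int, int]]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.start > self.end):
            raise DataError("gene interval with start > end")
        ids, counts = np.unique(np.asarray(self.gene_id), return_counts=True)
        if np.any(counts > 1):
            raise DataError(f"duplicate gene ids: {ids[counts > 1][:5]}")

    @property
    def n_genes(self) -> int:
        return int(len(self.gene_id))

    def exon_intervals(self, gene: str) -> list[tuple[int, int]]:
        if gene in self.exons:
            return self.exons[gene]
        i = int(np.flatnonzero(np.asarray(self.gene_id) == gene)[0])
        return [(int(self.start[i]), int(self.end[i]))]


def read_gene_annotation(path: str, dialect: str = "BED") -> GeneAnnotation:
    """Read BED4 (0-based half-open) or GFF3 gene lines (1-based closed).

    GFF3 coordinates are converted to the internal 0-based half-open
    convention; only ``gene`` features are taken as gene bodies, with ``exon``
    features attached to their ``Parent``/``gene_id`` when present.
    """
    if dialect.upper() == "BED":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         usecols=[0, 1, 2, 3],
                         names=["chrom", "start", "end", "gene"])
        return GeneAnnotation(df["gene"].to_numpy(object),
                              df["chrom"].to_numpy(object),
                              df["start"].to_numpy(), df["end"].to_numpy())
    if dialect.upper() != "GFF3":
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[tuple[str, str, int, int]] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}: short GFF3 line")
            chrom, _, ftype, start, end, _, _, _, attrs = f[:9]
            lo, hi = int(start) - 1, int(end)  # 1-based closed -> half-open
            tags = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = tags.get("ID") or tags.get("gene_id")
                if gid is None:
                    raise FormatError(f"{path}: gene line without ID")
                genes.append((gid, chrom, lo, hi))
            elif ftype == "exon":
                parent = tags.get("Parent") or tags.get("gene_id")
                if parent:
                    exons.setdefault(parent, []).append((lo, hi))
    return GeneAnnotation(np.array([g[0] for g in genes], dtype=object),
                          np.array([g[1] for g in genes], dtype=object),
                          np.array([g[2] for g in genes], dtype=np.int64),
                          np.array([g[3] for g in genes], dtype=np.int64),
                          exons)


def read_go_table(path: str) -> dict[str, set[str]]:
    """Read a two-column gene<TAB>GO:term table into gene -> term-set."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected gene and GO term")
            gene, term = parts[0], parts[1]
            if not (term.startswith("GO:") and len(term) == 10
                    and term[3:].isdigit()):
                raise DataError(f"{path}:{ln}: malformed GO id {term!r}")
            table.setdefault(gene, set()).add(term)
    return table


def write_go_table(table: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for gene in sorted(table):
            for term in sorted(table[gene]):
                fh.write(f"{gene}\t{term}\n")
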