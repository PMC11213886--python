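"""Reading, filtering and writing of the standard formats the pipeline touches.

The central in-memory container is :class:`GenotypePanel`: a samples x
variants matrix of diploid alt-allele dosages (0/1/2, -1 for missing) with an
optional phased haplotype matrix (2*n_samples x variants, rows ``2i`` and
``2i+1`` belonging to sample ``i``).  Variant metadata lives in a pandas
DataFrame with 1-based VCF coordinates; all window and region arithmetic
elsewhere in the package is 0-based half-open, and the conversion happens
only at the file boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypePanel",
    "PopulationMap",
    "GeneRecord",
    "FilterReport",
    "read_contigs",
    "read_vcf",
    "read_popmap",
    "read_genes",
    "write_vcf",
    "write_regions_bed",
    "allele_counts",
    "major_minor_counts",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class FilterReport:
    """Per-reason counts of variant records dropped while reading a VCF."""

    multiallelic: int = 0
    non_autosomal: int = 0
    non_snp: int = 0

    @property
    def total(self) -> int:
        return self.multiallelic + self.non_autosomal + self.non_snp


@dataclass
class GenotypePanel:
    """Diploid genotype matrix plus variant metadata for one cohort.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    variants
        DataFrame with columns ``chrom, pos, ref, alt``; ``pos`` is 1-based
        and strictly increasing within each chromosome.
    genotypes
        ``(n_samples, n_variants)`` int8 array of alt-allele dosages, with
        ``-1`` marking missing calls.
    haplotypes
        Optional ``(2 * n_samples, n_variants)`` int8 array of phased
        alleles; row pairs belong to consecutive samples.
    phased
        True iff every genotype in the source data was phased.
    """

    samples: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None
    phased: bool = False

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ValueError("panel needs at least one sample")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError("genotype matrix shape does not match samples/variants")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
                raise ValueError("haplotype matrix shape mismatch")
            summed = self.haplotypes[0::2] + self.haplotypes[1::2]
            ok = self.genotypes == MISSING
            if not np.array_equal(np.where(ok, summed, summed), np.where(ok, summed, self.genotypes)):
                raise ValueError("genotypes disagree with haplotype sums")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e} not in panel") from e

    def take_variants(self, mask_or_index) -> "GenotypePanel":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return GenotypePanel(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
            phased=self.phased,
        )

    def take_samples(self, ids) -> "GenotypePanel":
        idx = self.sample_index(ids)
        hap = None
        if self.haplotypes is not None:
            hrows = np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))
            hap = self.haplotypes[hrows]
        return GenotypePanel(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            genotypes=self.genotypes[idx],
            haplotypes=hap,
            phased=self.phased,
        )


class PopulationMap:
    """Mapping of sample id -> population label."""

    def __init__(self, mapping: dict[str, str]):
        if not mapping:
            raise FormatError("no samples in population map")
        self._map = dict(mapping)
        pops: dict[str, list[str]] = {}
        for s, p in self._map.items():
            pops.setdefault(p, []).append(s)
        self._pops = pops

    def __getitem__(self, sample: str) -> str:
        return self._map[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def populations(self) -> list[str]:
        return list(self._pops)

    def samples(self, pop: str) -> list[str]:
        return list(self._pops[pop])

    def items(self):
        return self._map.items()

    def check_panel(self, panel: GenotypePanel) -> None:
        missing = [s for s in panel.samples if s not in self._map]
        if missing:
            raise FormatError(f"panel samples absent from population map: {missing}")


@dataclass(frozen=True)
class GeneRecord:
    """One gene with 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"gene {self.gene_id}: end < start")


def read_contigs(path) -> dict[str, int]:
    """Read a FAI-style file: contig name and length in the first two columns."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            out[parts[0]] = int(parts[1])
    if not out:
        raise FormatError(f"{path}: no contigs")
    return out


def read_popmap(path) -> PopulationMap:
    """Two-column whitespace text: sample id, population label."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected two columns")
            sample, pop = parts
            if sample in mapping:
                raise FormatError(f"{path}:{ln}: duplicate sample {sample!r}")
            mapping[sample] = pop
    if not mapping:
        raise FormatError(f"{path}: no samples")
    return PopulationMap(mapping)


def read_vcf(path, autosomes=None, popmap: PopulationMap | None = None):
    """Read a VCF, keeping only biallelic SNPs on the listed autosomes.

    Parameters
    ----------
    path
        VCF or VCF.gz with GT fields.
    autosomes
        Iterable of contig names to retain.  ``None`` keeps every contig
        (the caller vouches that the file is autosome-only).
    popmap
        Optional; if given, every VCF sample must be mapped.

    Returns
    -------
    (GenotypePanel, FilterReport)
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as e:
        raise FormatError(f"cannot read VCF {path}: {e}") from e
    samples = list(vcf.samples)
    if popmap is not None:
        unmapped = [s for s in samples if s not in popmap]
        if unmapped:
            raise FormatError(f"VCF samples absent from population map: {unmapped}")
    auto = None if autosomes is None else set(autosomes)
    report = FilterReport()
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gts: list[np.ndarray] = []
    haps: list[np.ndarray] = []
    phased_all = True
    for rec in vcf:
        if auto is not None and rec.CHROM not in auto:
            report.non_autosomal += 1
            continue
        if len(rec.ALT) != 1:
            report.multiallelic += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1 or rec.ALT[0] not in "ACGT":
            report.non_snp += 1
            continue
        g = rec.genotype.array()  # (n, 3): allele_a, allele_b, phased
        a, b = g[:, 0].astype(np.int16), g[:, 1].astype(np.int16)
        dose = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        phased_all = phased_all and bool(np.all(g[:, 2] == 1))
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gts.append(dose)
        haps.append(np.ravel(np.column_stack([a, b])).astype(np.int8))
    vcf.close()
    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    if len(variants):
        order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
        variants = variants.iloc[order].reset_index(drop=True)
        G = np.stack(gts, axis=1)[:, order]
        H = np.stack(haps, axis=1)[:, order] if phased_all else None
    else:
        G = np.zeros((len(samples), 0), dtype=np.int8)
        H = np.zeros((2 * len(samples), 0), dtype=np.int8) if phased_all else None
    panel = GenotypePanel(
        samples=samples, variants=variants, genotypes=G,
        haplotypes=H if phased_all else None, phased=phased_all and len(variants) > 0,
    )
    return panel, report


def read_genes(path) -> list[GeneRecord]:
    """Read gene records from GFF3 (``gene`` features) or BED4.

    BED input (0-based half-open) is converted to the 1-based inclusive
    convention used internally.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        return _read_genes_gff3(path)
    if path.endswith(".bed"):
        return _read_genes_bed(path)
    raise FormatError(f"unknown gene-annotation extension: {path}")


def _read_genes_bed(path) -> list[GeneRecord]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED4 needs 4 columns")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "."
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{ln}: end < start")
            out.append(GeneRecord(name, chrom, start_i + 1, end_i, strand))
    return out


def _read_genes_gff3(path) -> list[GeneRecord]:
    out = []
    saw_feature = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{ln}: GFF3 needs 9 columns")
            saw_feature = True
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("Name") or attrs.get("gene_id") or attrs.get("ID")
            if gene_id is None:
                gene_id = f"gene_{ln}"
            start, end = int(parts[3]), int(parts[4])
            if end < start:
                raise FormatError(f"{path}:{ln}: end < start")
            out.append(GeneRecord(gene_id, parts[0], start, end, parts[6]))
    if saw_feature and not out:
        warnings.warn(f"{path}: no 'gene' features found", stacklevel=2)
    return out


def write_vcf(panel: GenotypePanel, path, contigs: dict[str, int] | None = None) -> None:
    """Write the panel as a minimal VCF 4.2 text file (phased if possible)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        sep = "|" if panel.haplotypes is not None else "/"
        var = panel.variants
        G = panel.genotypes
        H = panel.haplotypes
        for j in range(panel.n_variants):
            row = [
                str(var.at[j, "chrom"]), str(var.at[j, "pos"]), ".",
                var.at[j, "ref"], var.at[j, "alt"], ".", "PASS", ".", "GT",
            ]
            for i in range(panel.n_samples):
                if G[i, j] == MISSING:
                    row.append(f".{sep}.")
                elif H is not None:
                    row.append(f"{H[2 * i, j]}{sep}{H[2 * i + 1, j]}")
                else:
                    g = G[i, j]
                    row.append(("0/0", "0/1", "1/1")[g])
            fh.write("\t".join(row) + "\n")


def write_regions_bed(regions, path) -> None:
    """Write scan regions as BED6, score = peak |score| scaled x1000.

    ``regions`` is an iterable of objects with ``chrom, start, end,
    statistic, peak_score`` attributes; internal coordinates are 0-based
    half-open and pass straight through.
    """
    rows = sorted(regions, key=lambda r: (r.chrom, r.start))
    with open(path, "w") as fh:
        for r in rows:
            score = int(round(abs(r.peak_score) * 1000))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.statistic}\t{score}\t.\n")


def allele_counts(panel: GenotypePanel, sample_idx) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele copies and total non-missing allele calls per variant."""
    G = panel.genotypes[np.asarray(sample_idx, dtype=int)]
    ok = G != MISSING
    alt = np.where(ok, G, 0).sum(axis=0)
    tot = 2 * ok.sum(axis=0)
    return alt.astype(np.int64), tot.astype(np.int64)


def major_minor_counts(panel: GenotypePanel, popmap: PopulationMap, pop: str):
    """Per-variant (n_MAJ, n_MIN): copies of the most / least abundant allele
    within one population, from genotype allele counts."""
    idx = panel.sample_index(popmap.samples(pop))
    alt, tot = allele_counts(panel, idx)
    ref = tot - alt
    n_maj = np.maximum(ref, alt)
    n_min = np.minimum(ref, alt)
    return n_maj, n_min
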