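"""Sliding-window runs-of-homozygosity calling, F_RoH and length classes.

The caller follows the classic genotype-window heuristic: windows of
``window_snp`` consecutive SNPs tolerating ``window_het`` heterozygotes vote
on every SNP they cover; SNPs supported by at least ``window_hit_fraction``
of their windows seed candidate runs, which are then split at excess
heterozygotes and at physical gaps, and filtered on SNP count, length and
SNP density.  Missing genotypes count as neither homozygous nor
heterozygous and do not break runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popio import MISSING, GenotypePanel

__all__ = ["RoHParams", "RoHSegment", "call_roh", "froh", "roh_categories"]


@dataclass
class RoHParams:
    window_snp: int = 50
    window_het: int = 1
    min_snp: int = 10
    min_kb: float = 100.0
    density_kb_per_snp: float = 10.0
    max_gap_kb: float = 100.0
    window_hit_fraction: float = 0.05

    def __post_init__(self) -> None:
        if min(self.window_snp, self.min_snp) <= 0 or min(
                self.min_kb, self.density_kb_per_snp, self.max_gap_kb,
                self.window_hit_fraction) <= 0:
            raise ValueError("RoH parameters must be positive")
        if self.window_het >= self.window_snp:
            raise ValueError("window_het must be smaller than window_snp")


@dataclass(frozen=True)
class RoHSegment:
    sample: str
    chrom: str
    start: int           # bp of first SNP, 1-based
    end: int             # bp of last SNP, 1-based inclusive
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def _hit_snps(status: np.ndarray, params: RoHParams) -> np.ndarray:
    """Boolean hit mask per SNP from the voting windows.

    status: 0 = homozygous, 1 = heterozygous, -1 = missing.
    """
    n = status.size
    w = params.window_snp
    if n < w:
        return np.zeros(n, dtype=bool)
    is_het = (status == 1).astype(np.int32)
    csum = np.concatenate([[0], np.cumsum(is_het)])
    hets_in_window = csum[w:] - csum[:-w]          # window k covers SNPs [k, k+w)
    passing = hets_in_window <= params.window_het
    # windows covering SNP i: k in [max(0, i-w+1), min(i, n-w)]
    pcum = np.concatenate([[0], np.cumsum(passing.astype(np.int64))])
    i = np.arange(n)
    k_lo = np.maximum(0, i - w + 1)
    k_hi = np.minimum(i, n - w)
    n_windows = (k_hi - k_lo + 1).astype(float)
    n_pass = pcum[k_hi + 1] - pcum[k_lo]
    return n_pass / n_windows >= params.window_hit_fraction


def _split_runs(pos: np.ndarray, status: np.ndarray, hit: np.ndarray,
                params: RoHParams):
    """Yield (start_idx, end_idx_inclusive) of final runs before filtering."""
    n = pos.size
    i = 0
    max_gap_bp = params.max_gap_kb * 1000
    while i < n:
        if not hit[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hit[j + 1]:
            j += 1
        # split [i, j] at large gaps, then by heterozygote allowance
        seg_start = i
        for k in range(i, j + 1):
            if k > seg_start and pos[k] - pos[k - 1] > max_gap_bp:
                yield from _split_hets(seg_start, k - 1, status, params)
                seg_start = k
        yield from _split_hets(seg_start, j, status, params)
        i = j + 1


def _split_hets(a: int, b: int, status: np.ndarray, params: RoHParams):
    """Split [a, b] so each piece holds at most window_het heterozygotes."""
    hets = 0
    start = a
    for k in range(a, b + 1):
        if status[k] == 1:
            hets += 1
            if hets > params.window_het:
                if k - 1 >= start:
                    yield (start, k - 1)
                start = k + 1
                hets = 0
    if b >= start:
        yield (start, b)


def call_roh(panel: GenotypePanel, params: RoHParams | None = None) -> list[RoHSegment]:
    """Call runs of homozygosity for every sample on every contig."""
    params = params or RoHParams()
    segments: list[RoHSegment] = []
    var = panel.variants
    for chrom, grp in var.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        offset = grp.index[0]
        sl = slice(offset, offset + len(grp))
        for si, sample in enumerate(panel.samples):
            g = panel.genotypes[si, sl]
            status = np.where(g == MISSING, -1, np.where(g == 1, 1, 0)).astype(np.int8)
            hit = _hit_snps(status, params)
            for a, b in _split_runs(pos, status, hit, params):
                n_snps = b - a + 1
                seg = RoHSegment(sample, str(chrom), int(pos[a]), int(pos[b]), n_snps)
                if n_snps < params.min_snp:
                    continue
                if seg.length_kb < params.min_kb:
                    continue
                if seg.length_kb / n_snps > params.density_kb_per_snp:
                    continue
                segments.append(seg)
    return segments


def froh(segments: list[RoHSegment], autosome_length_bp: int,
         samples: list[str] | None = None) -> pd.Series:
    """F_RoH per sample: summed run length over total autosome length."""
    if autosome_length_bp <= 0:
        raise ValueError("autosome_length_bp must be positive")
    by_sample: dict[str, list[RoHSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    totals: dict[str, float] = {}
    for sample, segs in by_sample.items():
        segs = sorted(segs, key=lambda s: (s.chrom, s.start))
        for prev, cur in zip(segs, segs[1:]):
            if prev.chrom == cur.chrom and cur.start <= prev.end:
                raise ValueError(f"overlapping RoH segments for sample {sample}")
        totals[sample] = sum(s.length_bp for s in segs) / autosome_length_bp
    if samples is not None:
        totals = {s: totals.get(s, 0.0) for s in samples}
    return pd.Series(totals, name="f_roh", dtype=float)


_CLASSES = [(0.1, 0.25), (0.25, 0.5), (0.5, 1.0), (1.0, float("inf"))]
_CLASS_LABELS = ["0.1-0.25", ">0.25-0.5", ">0.5-1", ">1"]


def roh_categories(segments: list[RoHSegment]) -> pd.DataFrame:
    """Counts and mean lengths per length class (Mb), closed upper bounds."""
    lengths_mb = np.array([s.length_bp / 1e6 for s in segments])
    rows = []
    for label, (lo, hi) in zip(_CLASS_LABELS, _CLASSES):
        if hi == float("inf"):
            mask = lengths_mb > lo
        else:
            mask = lengths_mb <= hi if lo == 0.1 else (lengths_mb > lo) & (lengths_mb <= hi)
        vals = lengths_mb[mask]
        rows.append({"class_mb": label, "count": int(mask.sum()),
                     "mean_length_mb": float(vals.mean()) if vals.size else float("nan"),
                     "total_mb": float(vals.sum())})
    return pd.DataFrame(rows)
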