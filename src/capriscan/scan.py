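"""Selection-signature scanning: windowed pooled heterozygosity (Hp/ZHp),
windowed Weir-Cockerham ZF_ST, cross-population extended haplotype
homozygosity (XP-EHH), candidate/top-tier calling, region merging, gene
overlap and cross-method gene intersection.

Statistics
----------
Hp for a window is ``2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))^2``
where n_MAJ / n_MIN count copies of the most / least abundant allele at each
SNP within one population; low Hp marks diversity valleys.  Windowed F_ST is
the ratio of summed Weir-Cockerham variance components.  Both are
Z-standardised genome-wide across retained windows (windows with fewer than
``min_snps`` SNPs are discarded first).  XP-EHH is the log-ratio of the
integrated site-EHH of two populations at each core SNP, standardised
genome-wide, with two-sided normal p-values.

Candidate calling uses two tiers: the candidate tier at ZHp < -3.9,
ZF_ST > 4 and |XP-EHH| >= 5 (or the top 0.001% of the empirical |XP-EHH|
distribution, whichever admits more), and a stricter top tier at
ZHp <= -7, ZF_ST >= 7 and |XP-EHH| >= 6.  All thresholds are configurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._windows import window_slices
from .popio import GenotypePanel, GeneRecord, PopulationMap, major_minor_counts
from .structure import pop_site_stats, site_wc_components

__all__ = [
    "Thresholds",
    "ScanRegion",
    "windowed_hp",
    "z_transform",
    "windowed_fst",
    "ehh",
    "xpehh",
    "call_candidates",
    "merge_regions",
    "overlap_genes",
    "intersect_gene_lists",
]


@dataclass
class Thresholds:
    """Score cut-offs for the two candidate tiers (all configurable)."""

    zhp_candidate: float = -3.9
    zfst_candidate: float = 4.0
    xpehh_candidate: float = 5.0
    xpehh_top_quantile: float = 1e-5   # top 0.001% of the empirical |score|
    zhp_top: float = -7.0
    zfst_top: float = 7.0
    xpehh_top: float = 6.0

    def __post_init__(self) -> None:
        if self.zhp_candidate >= 0 or self.zhp_top >= 0:
            raise ValueError("ZHp cut-offs must be negative")
        if min(self.zfst_candidate, self.xpehh_candidate, self.zfst_top,
               self.xpehh_top) <= 0:
            raise ValueError("ZF_ST and XP-EHH cut-offs must be positive")


@dataclass
class ScanRegion:
    """A merged candidate region; coordinates 0-based half-open."""

    chrom: str
    start: int
    end: int
    statistic: str
    peak_score: float
    n_constituents: int
    genes: list[str] = field(default_factory=list)


def windowed_hp(panel: GenotypePanel, popmap: PopulationMap, pop: str,
                window: int = 100_000, step: int = 50_000, min_snps: int = 10,
                contigs: dict[str, int] | None = None) -> pd.DataFrame:
    """Windowed pooled heterozygosity for one population.

    Windows with fewer than ``min_snps`` SNPs are discarded before the
    Z-transform; call :func:`z_transform` on the result to add ``z``.
    """
    n_maj, n_min = major_minor_counts(panel, popmap, pop)
    rows = []
    for chrom, grp in panel.variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        offset = grp.index[0]
        span = contigs[chrom] if contigs else int(pos.max())
        for start, end, lo, hi in window_slices(pos, span, window, step):
            n = hi - lo
            if n < min_snps:
                continue
            smaj = int(n_maj[offset + lo: offset + hi].sum())
            smin = int(n_min[offset + lo: offset + hi].sum())
            tot = smaj + smin
            hp = 2 * smaj * smin / tot ** 2 if tot > 0 else float("nan")
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "n_snps": n, "hp": hp})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "hp"])


def z_transform(stats: pd.DataFrame, column: str) -> pd.DataFrame:
    """Genome-wide Z-standardisation of one column (sample SD)."""
    vals = stats[column].to_numpy(dtype=float)
    if np.sum(np.isfinite(vals)) < 2:
        raise ValueError("need >= 2 retained windows for Z-transform")
    mu = np.nanmean(vals)
    sd = np.nanstd(vals, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate distribution: zero variance")
    out = stats.copy()
    out["z"] = (vals - mu) / sd
    return out


def windowed_fst(panel: GenotypePanel, popmap: PopulationMap,
                 pop_a: str, pop_b: str, window: int = 100_000,
                 step: int = 50_000, min_snps: int = 10,
                 contigs: dict[str, int] | None = None,
                 per_site_z: bool = False) -> pd.DataFrame:
    """Windowed Weir-Cockerham F_ST between two populations, Z-transformed.

    Default order: ratio-of-sums per window, then genome-wide Z.  With
    ``per_site_z`` the per-SNP F_ST values are Z-standardised first and the
    window value is their mean.
    """
    for pop in (pop_a, pop_b):
        if len(popmap.samples(pop)) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 samples")
    n1, p1, h1 = pop_site_stats(panel, popmap, pop_a)
    n2, p2, h2 = pop_site_stats(panel, popmap, pop_b)
    a, b, c = site_wc_components(n1, p1, h1, n2, p2, h2)
    usable = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    bc = a + b + c
    if per_site_z:
        with np.errstate(divide="ignore", invalid="ignore"):
            site_fst = np.where(bc != 0, a / bc, np.nan)
        mu, sd = np.nanmean(site_fst), np.nanstd(site_fst, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError("degenerate per-site F_ST distribution")
        site_z = (site_fst - mu) / sd
    rows = []
    for chrom, grp in panel.variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        offset = grp.index[0]
        span = contigs[chrom] if contigs else int(pos.max())
        for start, end, lo, hi in window_slices(pos, span, window, step):
            n = hi - lo
            if n < min_snps:
                continue
            sl = slice(offset + lo, offset + hi)
            if per_site_z:
                fst = float(np.nanmean(site_z[sl]))
            else:
                denom = bc[sl].sum()
                fst = float(a[sl].sum() / denom) if denom != 0 else float("nan")
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "n_snps": n, "fst": fst})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fst"])
    if per_site_z:
        out = df.rename(columns={"fst": "z"})
        out["fst"] = np.nan
        return out[["chrom", "start", "end", "n_snps", "fst", "z"]]
    return z_transform(df, "fst")


def _group_sizes(ids: np.ndarray) -> np.ndarray:
    return np.unique(ids, return_counts=True)[1]


def _homozygosity(ids: np.ndarray) -> float:
    """sum C(e_i, 2) / C(n, 2) over haplotype groups of identical cores."""
    n = ids.size
    if n < 2:
        return float("nan")
    counts = _group_sizes(ids)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(haplotypes: np.ndarray, positions: np.ndarray, core_idx: int,
        core_allele: int | None = None, direction: str = "both") -> dict:
    """EHH profile from a core SNP outward.

    With ``core_allele`` given, the profile is conditioned on carriers of
    that allele (EHH(core) = 1); with ``core_allele=None`` the site version
    is computed over all haplotypes, with groups seeded by the core alleles.

    Returns a dict with keys among {"left", "right"}, each a DataFrame of
    (pos, ehh) starting at the core; the profile is non-increasing outward.
    """
    H = np.asarray(haplotypes)
    pos = np.asarray(positions)
    if core_allele is not None:
        rows = np.nonzero(H[:, core_idx] == core_allele)[0]
        if rows.size < 2:
            raise ValueError("fewer than 2 carriers of the core allele")
        H = H[rows]
        seed = np.zeros(H.shape[0], dtype=np.int64)
    else:
        seed = H[:, core_idx].astype(np.int64)
    out = {}
    dirs = {"left": -1, "right": +1} if direction == "both" else {direction: {"left": -1, "right": +1}[direction]}
    for name, stepdir in dirs.items():
        ids = seed.copy()
        recs = [(int(pos[core_idx]), _homozygosity(ids) if core_allele is None else 1.0)]
        j = core_idx + stepdir
        while 0 <= j < H.shape[1]:
            ids = _refine(ids, H[:, j])
            recs.append((int(pos[j]), _homozygosity(ids)))
            j += stepdir
        out[name] = pd.DataFrame(recs, columns=["pos", "ehh"])
    return out


def _refine(ids: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Split haplotype groups by the allele at one more marker."""
    combo = ids * 2 + alleles.astype(np.int64)
    _, inv = np.unique(combo, return_inverse=True)
    return inv.astype(np.int64)


def _pop_hap_rows(panel: GenotypePanel, popmap: PopulationMap, pop: str) -> np.ndarray:
    idx = panel.sample_index(popmap.samples(pop))
    return np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))


def _hom3(ids: np.ndarray, na: int) -> tuple[float, float, float]:
    """(EHH_A, EHH_B, EHH_combined) from pooled group ids; A = first na rows."""
    n = ids.size
    ca = np.bincount(ids[:na])
    cb = np.bincount(ids[na:])
    cc = np.bincount(ids)
    e_a = float((ca * (ca - 1)).sum() / (na * (na - 1)))
    e_b = float((cb * (cb - 1)).sum() / ((n - na) * (n - na - 1)))
    e_c = float((cc * (cc - 1)).sum() / (n * (n - 1)))
    return e_a, e_b, e_c


_CHUNK = 16


def _walk_ihh(HT: np.ndarray, pos: np.ndarray, poly_idx: np.ndarray, core: int,
              na: int, stepdir: int, min_ehh: float,
              max_extend_bp: int | None) -> tuple[float, float]:
    """Integrate EHH_A and EHH_B away from ``core`` in one direction.

    Group refinement happens only at markers polymorphic in the pooled
    sample (others cannot split any group); refinement is applied in chunks
    of markers at a time, with the EHH staircase evaluated at chunk ends and
    marker-by-marker at the chunk where the combined EHH crosses the
    truncation threshold.
    """
    if stepdir > 0:
        seq = poly_idx[np.searchsorted(poly_idx, core, side="right"):]
    else:
        seq = poly_idx[: np.searchsorted(poly_idx, core, side="left")][::-1]
    if max_extend_bp is not None and seq.size:
        seq = seq[np.abs(pos[seq] - pos[core]) <= max_extend_bp]
    ids = np.unique(HT[core], return_inverse=True)[1]
    e_a, e_b, e_c = _hom3(ids, na)
    if e_c < min_ehh:
        return 0.0, 0.0
    ihh_a = ihh_b = 0.0
    last_pos = int(pos[core])
    end_pos = last_pos + stepdir * max_extend_bp if max_extend_bp is not None else None
    for k0 in range(0, seq.size, _CHUNK):
        chunk = seq[k0: k0 + _CHUNK]
        packed = np.zeros(HT.shape[1], dtype=np.int64)
        for j in chunk:
            packed = (packed << 1) | HT[j]
        combo = ids.astype(np.int64) * (1 << len(chunk)) + packed
        new_ids = np.unique(combo, return_inverse=True)[1]
        ea2, eb2, ec2 = _hom3(new_ids, na)
        p_end = int(pos[chunk[-1]])
        if ec2 >= min_ehh:
            d = abs(p_end - last_pos)
            ihh_a += 0.5 * (e_a + ea2) * d
            ihh_b += 0.5 * (e_b + eb2) * d
            ids, e_a, e_b = new_ids, ea2, eb2
            last_pos = p_end
            continue
        # threshold crossed inside this chunk: replay marker by marker
        for j in chunk:
            combo = ids.astype(np.int64) * 2 + HT[j]
            new_ids = np.unique(combo, return_inverse=True)[1]
            ea2, eb2, ec2 = _hom3(new_ids, na)
            if ec2 < min_ehh:
                return ihh_a, ihh_b
            d = abs(int(pos[j]) - last_pos)
            ihh_a += 0.5 * (e_a + ea2) * d
            ihh_b += 0.5 * (e_b + eb2) * d
            ids, e_a, e_b = new_ids, ea2, eb2
            last_pos = int(pos[j])
        return ihh_a, ihh_b
    # ran out of polymorphic markers (or hit the cap): EHH is flat beyond the
    # last refining marker, so extend to the cap / chromosome end
    tail_end = int(pos[seq[-1]]) if seq.size else last_pos
    if end_pos is not None:
        lo, hi = sorted((int(pos[0]), int(pos[-1])))
        tail_end = min(max(end_pos, lo), hi)
    d = abs(tail_end - last_pos)
    ihh_a += e_a * d
    ihh_b += e_b * d
    return ihh_a, ihh_b


def xpehh(panel: GenotypePanel, popmap: PopulationMap, pop_a: str, pop_b: str,
          min_ehh: float = 0.05, core_step: int = 1,
          max_extend_bp: int | None = 1_000_000) -> pd.DataFrame:
    """XP-EHH at every ``core_step``-th SNP between two populations.

    For each core SNP the site-EHH of each population is integrated
    (trapezoids over bp, both directions) out to where the combined-sample
    EHH drops below ``min_ehh`` or ``max_extend_bp`` is reached; the raw
    statistic is ``ln(iHH_A / iHH_B)``, standardised genome-wide, with
    two-sided standard-normal p-values.  Cores where either integral is
    zero are flagged (``ok=False``) and excluded from standardisation.
    Positive scores mean longer haplotypes in ``pop_a``.
    """
    if panel.haplotypes is None:
        raise ValueError("XP-EHH needs a phased panel")
    rows_a = _pop_hap_rows(panel, popmap, pop_a)
    rows_b = _pop_hap_rows(panel, popmap, pop_b)
    rows_all = np.concatenate([rows_a, rows_b])
    na = rows_a.size
    out = []
    for chrom, grp in panel.variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        offset = grp.index[0]
        # marker-major layout: HT[j] is the pooled allele vector at marker j
        HT = np.ascontiguousarray(
            panel.haplotypes[rows_all, offset: offset + len(grp)].T.astype(np.int64))
        n_mark = HT.shape[0]
        colsum = HT.sum(axis=1)
        poly_idx = np.nonzero((colsum > 0) & (colsum < rows_all.size))[0]
        for core in range(0, n_mark, core_step):
            la, lb = _walk_ihh(HT, pos, poly_idx, core, na, -1, min_ehh, max_extend_bp)
            ra, rb = _walk_ihh(HT, pos, poly_idx, core, na, +1, min_ehh, max_extend_bp)
            ihh_a, ihh_b = la + ra, lb + rb
            ok = ihh_a > 0 and ihh_b > 0
            raw = float(np.log(ihh_a / ihh_b)) if ok else float("nan")
            out.append({"chrom": chrom, "pos": int(pos[core]), "ihh_a": ihh_a,
                        "ihh_b": ihh_b, "raw": raw, "ok": ok})
    df = pd.DataFrame(out, columns=["chrom", "pos", "ihh_a", "ihh_b", "raw", "ok"])
    good = df["ok"] & np.isfinite(df["raw"])
    mu = df.loc[good, "raw"].mean()
    sd = df.loc[good, "raw"].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        df["std"] = np.nan
        df["p"] = np.nan
        return df
    df["std"] = (df["raw"] - mu) / sd
    df["p"] = 2 * norm.sf(np.abs(df["std"]))
    return df


def call_candidates(scores, statistic: str,
                    thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Apply the two-tier cut-offs to a score vector.

    ``statistic`` is one of ``zhp``, ``zfst``, ``xpehh``.  Returns a
    DataFrame with boolean columns ``candidate`` and ``topmost``.
    """
    th = thresholds or Thresholds()
    z = np.asarray(scores, dtype=float)
    if statistic == "zhp":
        cand = z < th.zhp_candidate
        top = z <= th.zhp_top
    elif statistic == "zfst":
        cand = z > th.zfst_candidate
        top = z >= th.zfst_top
    elif statistic == "xpehh":
        az = np.abs(z)
        cand = az >= th.xpehh_candidate
        finite = az[np.isfinite(az)]
        if finite.size:
            q = np.quantile(finite, 1 - th.xpehh_top_quantile)
            cand = cand | (az >= q)
        top = az >= th.xpehh_top
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    cand = cand & np.isfinite(z)
    top = top & np.isfinite(z)
    return pd.DataFrame({"candidate": cand, "topmost": top})


def merge_regions(hits: pd.DataFrame, statistic: str,
                  score_column: str = "z", max_gap: int = 200_000) -> list[ScanRegion]:
    """Merge significant windows or SNPs into candidate regions.

    Window rows (``start``/``end`` columns, 0-based half-open) merge when
    overlapping or book-ended; SNP rows (``pos`` column, 1-based) merge when
    within ``max_gap`` bp.  The peak score is the constituent with the
    largest magnitude; the constituent count is preserved across merging.
    """
    if len(hits) == 0:
        return []
    is_windows = "start" in hits.columns
    regions: list[ScanRegion] = []
    for chrom, grp in hits.groupby("chrom", sort=False):
        if is_windows:
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(dtype=int)
            ends = grp["end"].to_numpy(dtype=int)
        else:
            grp = grp.sort_values("pos")
            starts = grp["pos"].to_numpy(dtype=int) - 1
            ends = starts + 1
        scores = grp[score_column].to_numpy(dtype=float)
        cs, ce, peak, n = starts[0], ends[0], scores[0], 1
        gap = 0 if is_windows else max_gap
        for k in range(1, len(grp)):
            if starts[k] <= ce + gap:
                ce = max(ce, ends[k])
                if abs(scores[k]) > abs(peak):
                    peak = scores[k]
                n += 1
            else:
                regions.append(ScanRegion(str(chrom), int(cs), int(ce),
                                          statistic, float(peak), n))
                cs, ce, peak, n = starts[k], ends[k], scores[k], 1
        regions.append(ScanRegion(str(chrom), int(cs), int(ce),
                                  statistic, float(peak), n))
    return regions


def overlap_genes(regions: list[ScanRegion],
                  genes: list[GeneRecord]) -> list[ScanRegion]:
    """Annotate regions with every gene overlapping them by >= 1 bp.

    Gene coordinates are 1-based inclusive; regions are 0-based half-open.
    Regions may legitimately end up with no genes.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for r in regions:
        hits = []
        for g in by_chrom.get(r.chrom, []):
            g0, g1 = g.start - 1, g.end  # to 0-based half-open
            if g0 < r.end and g1 > r.start:
                hits.append(g.gene_id)
        r.genes = sorted(set(hits))
    return regions


def intersect_gene_lists(lists_by_method: dict[str, list[str]]):
    """Exact Venn decomposition of per-method gene lists.

    Returns
    -------
    (counts, membership)
        ``counts``: DataFrame with one row per non-empty method combination
        (exclusive regions of the Venn diagram) and the gene count;
        ``membership``: dict combination-label -> sorted gene list.
    """
    if len(lists_by_method) < 2:
        raise ValueError("need >= 2 gene lists")
    sets = {m: set(v) for m, v in lists_by_method.items()}
    methods = list(sets)
    rows, membership = [], {}
    for k in range(len(methods), 0, -1):
        for combo in itertools.combinations(methods, k):
            inside = set.intersection(*(sets[m] for m in combo))
            outside = set.union(set(), *(sets[m] for m in methods if m not in combo))
            excl = inside - outside
            label = "&".join(combo)
            rows.append({"methods": label, "n_genes": len(excl)})
            membership[label] = sorted(excl)
    return pd.DataFrame(rows), membership
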