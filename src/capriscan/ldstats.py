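"""Pairwise r-squared, LD decay, LD pruning, and the LD-based Ne trajectory.

r-squared is the squared Pearson correlation of genotype dosage vectors
(composite LD, phase-free).  The historical effective population size is
read off the decay curve through a Sved-type relation: a distance bin with
genetic length c Morgans speaks for generation t = 1/(2c), and
``Ne = (1/(4c)) * (1/r2_adj - alpha)`` with the sample-size correction
``r2_adj = mean_r2 - 1/(2n)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .popio import MISSING, GenotypePanel

__all__ = ["pairwise_r2", "ld_decay", "ld_prune", "estimate_ne"]


def _corr_matrix(X: np.ndarray) -> np.ndarray:
    """Correlation matrix of columns; columns must have no missing values."""
    Xc = X - X.mean(axis=0)
    sd = np.sqrt((Xc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc.T @ Xc) / np.outer(sd, sd)
    return R


def _r2_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Pairwise-complete r2 of two dosage vectors; NaN if degenerate."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return float("nan")
    return float(np.corrcoef(xv, yv)[0, 1] ** 2)


def pairwise_r2(panel: GenotypePanel, max_dist: int = 1_000_000,
                max_snps_per_chrom: int | None = None) -> pd.DataFrame:
    """All intra-contig dosage r2 for SNP pairs within ``max_dist`` bp.

    ``max_snps_per_chrom`` thins SNPs by a deterministic stride before
    pairing, which keeps pair counts tractable on dense panels without
    biasing the distance distribution.  Zero-variance and degenerate pairs
    are skipped.

    Returns a DataFrame with columns ``dist`` and ``r2``.
    """
    dists, r2s = [], []
    has_missing = bool((panel.genotypes == MISSING).any())
    for chrom, grp in panel.variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        offset = grp.index[0]
        take = np.arange(len(grp))
        if max_snps_per_chrom is not None and len(grp) > max_snps_per_chrom:
            take = np.unique(np.linspace(0, len(grp) - 1, max_snps_per_chrom).astype(int))
        pos = pos[take]
        G = panel.genotypes[:, offset + take].astype(float)
        m = pos.size
        if m < 2:
            continue
        if not has_missing:
            keep = G.std(axis=0) > 0
            G, pos = G[:, keep], pos[keep]
            m = pos.size
            if m < 2:
                continue
            R2 = _corr_matrix(G) ** 2
            hi = np.searchsorted(pos, pos + max_dist, side="right")
            for i in range(m - 1):
                js = np.arange(i + 1, hi[i])
                if js.size == 0:
                    continue
                dists.append(pos[js] - pos[i])
                r2s.append(R2[i, js])
        else:
            for i in range(m - 1):
                j = i + 1
                while j < m and pos[j] - pos[i] <= max_dist:
                    r2 = _r2_pair(panel.genotypes[:, offset + take[i]],
                                  panel.genotypes[:, offset + take[j]])
                    if not np.isnan(r2):
                        dists.append(np.array([pos[j] - pos[i]]))
                        r2s.append(np.array([r2]))
                    j += 1
    if not dists:
        return pd.DataFrame(columns=["dist", "r2"])
    return pd.DataFrame({"dist": np.concatenate(dists),
                         "r2": np.concatenate(r2s)})


def ld_decay(pairs: pd.DataFrame, n_bins: int = 20,
             max_dist: int | None = None) -> pd.DataFrame:
    """Equal-width distance bins with mean r2 and pair count per bin.

    Empty bins carry count 0 and NaN mean.
    """
    if len(pairs) == 0:
        raise ValueError("no LD pairs to bin")
    top = max_dist if max_dist is not None else int(pairs["dist"].max())
    edges = np.linspace(0, top, n_bins + 1)
    idx = np.clip(np.digitize(pairs["dist"], edges) - 1, 0, n_bins - 1)
    inside = pairs["dist"] <= top
    rows = []
    for b in range(n_bins):
        sel = inside & (idx == b)
        n = int(sel.sum())
        rows.append({
            "bin_mid": float((edges[b] + edges[b + 1]) / 2),
            "mean_r2": float(pairs.loc[sel, "r2"].mean()) if n else float("nan"),
            "n_pairs": n,
        })
    return pd.DataFrame(rows)


def ld_prune(panel: GenotypePanel, window: int = 50_000, step: int = 10_000,
             r2_max: float = 0.01) -> GenotypePanel:
    """Greedy left-to-right LD pruning in sliding windows.

    Within each window, for every retained pair with r2 > ``r2_max`` the
    later SNP is removed; windows are swept repeatedly until no retained
    intra-window pair exceeds the threshold.
    """
    keep = np.ones(panel.n_variants, dtype=bool)
    var = panel.variants
    has_missing = bool((panel.genotypes == MISSING).any())
    # one left-to-right sweep is enough: a removal is permanent and cannot
    # raise the r2 of any surviving pair, and overlapping windows (step <
    # window) guarantee every within-window pair is co-examined once
    for chrom, grp in var.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        offset = grp.index[0]
        for wstart in range(0, int(pos.max()), step):
            lo = np.searchsorted(pos, wstart + 1, side="left")
            hi = np.searchsorted(pos, wstart + window, side="right")
            cols = [offset + k for k in range(lo, hi) if keep[offset + k]]
            if len(cols) < 2:
                continue
            if not has_missing:
                G = panel.genotypes[:, cols].astype(float)
                with np.errstate(divide="ignore", invalid="ignore"):
                    R2 = _corr_matrix(G) ** 2
                carr = np.asarray(cols)
                for a in range(len(cols)):
                    if not keep[carr[a]]:
                        continue
                    hit = R2[a, a + 1:] > r2_max
                    if hit.any():
                        keep[carr[a + 1:][hit]] = False
            else:
                for a in range(len(cols)):
                    if not keep[cols[a]]:
                        continue
                    for b in range(a + 1, len(cols)):
                        if not keep[cols[b]]:
                            continue
                        r2 = _r2_pair(panel.genotypes[:, cols[a]],
                                      panel.genotypes[:, cols[b]])
                        if not np.isnan(r2) and r2 > r2_max:
                            keep[cols[b]] = False
    return panel.take_variants(keep)


def estimate_ne(curve: pd.DataFrame, sample_n: int,
                recomb_rate_cM_Mb: float = 1.0, alpha: float = 2.0,
                min_pairs: int = 100, max_t: float = 1000.0) -> pd.DataFrame:
    """Effective-population-size trajectory from an LD decay curve.

    Bins with fewer than ``min_pairs`` pairs or non-positive adjusted r2
    are dropped (with a warning for the latter); the trajectory is
    truncated to generations t <= ``max_t``.
    """
    rows = []
    for _, row in curve.iterrows():
        if row["n_pairs"] < min_pairs or not np.isfinite(row["mean_r2"]):
            continue
        c = row["bin_mid"] * recomb_rate_cM_Mb * 1e-8  # Morgans
        if c <= 0:
            continue
        r2_adj = row["mean_r2"] - 1.0 / (2 * sample_n)
        if r2_adj <= 0:
            warnings.warn(f"bin at {row['bin_mid']:.0f} bp dropped: "
                          "adjusted r2 <= 0", stacklevel=2)
            continue
        t = 1.0 / (2 * c)
        if t > max_t:
            continue
        ne = (1.0 / (4 * c)) * (1.0 / r2_adj - alpha)
        rows.append({"t": t, "ne": ne, "bin_mid": row["bin_mid"],
                     "mean_r2": row["mean_r2"], "n_pairs": int(row["n_pairs"])})
    return pd.DataFrame(rows, columns=["t", "ne", "bin_mid", "mean_r2", "n_pairs"])
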