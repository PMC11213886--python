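"""Population structure: PCA on a pruned panel, pairwise Weir-Cockerham
F_ST, and a neighbour-joining tree on the F_ST distance matrix.

The per-site Weir-Cockerham variance components (a, b, c) implemented here
are also the building blocks of the windowed ZF_ST selection scan; the
"weighted" estimator reported everywhere is the ratio of sums
``sum(a) / sum(a + b + c)`` over the sites involved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popio import MISSING, GenotypePanel, PopulationMap, allele_counts

__all__ = [
    "PCAResult",
    "pca",
    "site_wc_components",
    "pop_site_stats",
    "fst_matrix",
    "nj_tree",
    "read_qmatrix",
]


@dataclass
class PCAResult:
    samples: list[str]
    coords: np.ndarray          # (n_samples, K)
    explained_pct: np.ndarray   # (K,) percent of total variance
    eigenvalues: np.ndarray     # all eigenvalues, descending


def pca(panel: GenotypePanel, k: int = 10) -> PCAResult:
    """PCA of the dosage matrix, centred by 2p and scaled by sqrt(2p(1-p)).

    Monomorphic SNPs are dropped before scaling; missing dosages are mean-
    imputed (equivalently, contribute zero after centring).
    """
    if panel.n_samples < k + 1:
        raise ValueError("PCA needs at least K+1 samples")
    D = panel.genotypes.astype(float)
    D[D == MISSING] = np.nan
    p = np.nanmean(D, axis=0) / 2
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    D, p = D[:, poly], p[poly]
    X = (D - 2 * p) / np.sqrt(2 * p * (1 - p))
    X = np.nan_to_num(X, nan=0.0)
    C = (X @ X.T) / X.shape[1]
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    total = vals.sum()
    pct = 100 * vals[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(list(panel.samples), coords, pct, vals)


def pop_site_stats(panel: GenotypePanel, popmap: PopulationMap, pop: str):
    """Per-site (n diploids with data, alt freq, observed het freq)."""
    idx = panel.sample_index(popmap.samples(pop))
    G = panel.genotypes[idx]
    ok = G != MISSING
    n = ok.sum(axis=0).astype(float)
    alt, tot = allele_counts(panel, idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / tot
        h = ((G == 1) & ok).sum(axis=0) / n
    return n, p, h


def site_wc_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham (1984) variance components a, b, c per site, r = 2.

    Inputs are per-site arrays: diploid sample sizes with data, alt-allele
    frequencies, and observed heterozygote frequencies for the two
    populations.  Sites with fewer than two usable chromosomes in either
    population come back NaN and should be excluded from sums.
    """
    r = 2.0
    n1, p1, h1 = (np.asarray(x, dtype=float) for x in (n1, p1, h1))
    n2, p2, h2 = (np.asarray(x, dtype=float) for x in (n2, p2, h2))
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def pairwise_fst(panel: GenotypePanel, popmap: PopulationMap,
                 pop_a: str, pop_b: str) -> float:
    """Weighted (ratio-of-sums) Weir-Cockerham F_ST between two populations."""
    for pop in (pop_a, pop_b):
        if len(popmap.samples(pop)) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 samples for F_ST")
    n1, p1, h1 = pop_site_stats(panel, popmap, pop_a)
    n2, p2, h2 = pop_site_stats(panel, popmap, pop_b)
    a, b, c = site_wc_components(n1, p1, h1, n2, p2, h2)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def fst_matrix(panel: GenotypePanel, popmap: PopulationMap) -> pd.DataFrame:
    """Symmetric population-by-population F_ST matrix with zero diagonal."""
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("F_ST matrix needs >= 2 populations")
    M = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        v = pairwise_fst(panel, popmap, a, b)
        M.loc[a, b] = M.loc[b, a] = v
    return M


def nj_tree(dist: pd.DataFrame, clamp_negative_input: bool = True) -> str:
    """Saitou-Nei neighbour joining; returns an unrooted Newick string.

    Negative input distances (slightly negative F_ST estimates) are clamped
    to zero by default, since NJ expects a dissimilarity; negative branch
    lengths produced by the algorithm are likewise clamped.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    M = dist.to_numpy(dtype=float)
    if M.shape[0] < 3:
        raise ValueError("NJ needs >= 3 taxa")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(M), 0):
        raise ValueError("distance matrix diagonal must be zero")
    if clamp_negative_input:
        M = np.clip(M, 0, None)
        np.fill_diagonal(M, 0.0)
    tree = _nj(DistanceMatrix(M, list(dist.index)), neg_as_zero=True)
    return str(tree).strip()


def read_qmatrix(path, sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Read an ancestry-fraction (Q) matrix: one row per sample, K columns
    of cluster fractions summing to 1.  Rows may optionally start with a
    sample id; otherwise ids are taken from ``sample_ids`` or invented."""
    rows, ids = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                ids.append(parts[0])
                vals = [float(x) for x in parts[1:]]
            rows.append(vals)
    Q = pd.DataFrame(rows)
    if ids and len(ids) == len(Q):
        Q.index = ids
    elif sample_ids is not None:
        Q.index = sample_ids
    sums = Q.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("Q-matrix rows must sum to 1")
    Q.columns = [f"Q{k + 1}" for k in range(Q.shape[1])]
    return Q
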