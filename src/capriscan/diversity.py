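"""Within-population diversity: Ho, He, windowed pi, SNP density, F_HOM and
the allele-sharing distance D = 1 - DST.

Expected heterozygosity uses the unbiased small-sample correction
``2*p*q * n_chr / (n_chr - 1)`` (n_chr = non-missing allele calls), which
makes windowed pi identical to the mean pairwise Hamming distance among the
sampled chromosomes divided by window length.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from ._windows import window_slices
from .popio import MISSING, GenotypePanel, PopulationMap, allele_counts

__all__ = [
    "het_stats",
    "windowed_pi",
    "snp_density",
    "f_hom",
    "dst_distance",
    "diversity_summary",
]


def _pop_indices(panel: GenotypePanel, popmap: PopulationMap) -> dict[str, np.ndarray]:
    popmap.check_panel(panel)
    out = {}
    for pop in popmap.populations:
        in_panel = [s for s in popmap.samples(pop) if s in panel.samples]
        if not in_panel:
            raise ValueError(f"population {pop!r} has no samples in panel")
        out[pop] = panel.sample_index(in_panel)
    return out


def _unbiased_het(alt: np.ndarray, tot: np.ndarray) -> np.ndarray:
    """Per-site 2*p*q*n/(n-1) with NaN where fewer than 2 allele calls."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / tot
        het = 2 * p * (1 - p) * tot / (tot - 1)
    het[tot < 2] = np.nan
    return het


def het_stats(panel: GenotypePanel, popmap: PopulationMap):
    """Per-site and mean observed/expected heterozygosity per population.

    Sites with fewer than two non-missing genotypes in a population are
    skipped for that population (NaN in the per-site frame).

    Returns
    -------
    (per_site, summary)
        ``per_site``: dict pop -> DataFrame(ho, he);
        ``summary``: DataFrame indexed by pop with columns ho_mean, he_mean.
    """
    per_site = {}
    rows = []
    for pop, idx in _pop_indices(panel, popmap).items():
        G = panel.genotypes[idx]
        ok = G != MISSING
        n = ok.sum(axis=0).astype(float)
        n_het = ((G == 1) & ok).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = n_het / n
        ho[n < 2] = np.nan
        alt, tot = allele_counts(panel, idx)
        he = _unbiased_het(alt.astype(float), tot.astype(float))
        he[n < 2] = np.nan
        per_site[pop] = pd.DataFrame({"ho": ho, "he": he})
        rows.append({"pop": pop, "ho_mean": np.nanmean(ho), "he_mean": np.nanmean(he)})
    return per_site, pd.DataFrame(rows).set_index("pop")


def windowed_pi(panel: GenotypePanel, popmap: PopulationMap,
                window: int = 20_000, step: int = 10_000,
                contigs: dict[str, int] | None = None) -> dict[str, pd.DataFrame]:
    """Sliding-window nucleotide diversity per population.

    pi(window) = sum over sites of the unbiased per-site heterozygosity,
    divided by the full window length in bp (trailing partial windows are
    normalised by the same full length).
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    out = {}
    var = panel.variants
    for pop, idx in _pop_indices(panel, popmap).items():
        alt, tot = allele_counts(panel, idx)
        het = _unbiased_het(alt.astype(float), tot.astype(float))
        het = np.nan_to_num(het, nan=0.0)
        rows = []
        for chrom, grp in var.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            offset = grp.index[0]
            span = contigs[chrom] if contigs else int(pos.max())
            for start, end, lo, hi in window_slices(pos, span, window, step):
                s = het[offset + lo: offset + hi].sum()
                rows.append({"chrom": chrom, "start": start, "end": end,
                             "n_snps": hi - lo, "pi": s / window})
        out[pop] = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "pi"])
    return out


def snp_density(variants: pd.DataFrame, bin_bp: int = 1000,
                contigs: dict[str, int] | None = None):
    """Variant counts per fixed-width bin over each covered contig.

    Returns
    -------
    (bins, mean, sd)
        ``bins``: DataFrame(chrom, start, end, n_snps); mean and sample SD
        are taken across all bins of all contigs with at least one variant.
    """
    rows = []
    for chrom, grp in variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if pos.size == 0:
            continue
        span = contigs[chrom] if contigs else int(pos.max())
        n_bins = int(np.ceil(span / bin_bp))
        counts, _ = np.histogram(pos - 1, bins=n_bins, range=(0, n_bins * bin_bp))
        for k, c in enumerate(counts):
            rows.append({"chrom": chrom, "start": k * bin_bp,
                         "end": (k + 1) * bin_bp, "n_snps": int(c)})
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])
    if len(bins) == 0:
        return bins, float("nan"), float("nan")
    vals = bins["n_snps"].to_numpy(dtype=float)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return bins, float(vals.mean()), sd


def f_hom(panel: GenotypePanel, popmap: PopulationMap) -> pd.DataFrame:
    """Per-sample inbreeding coefficient from homozygous-site excess.

    F = (O_hom - E_hom) / (L - E_hom), with E_hom = sum over used sites of
    (1 - unbiased expected heterozygosity) computed from the sample's own
    population frequencies.  NaN when L == E_hom (degenerate).
    """
    rows = []
    for pop, idx in _pop_indices(panel, popmap).items():
        alt, tot = allele_counts(panel, idx)
        he = _unbiased_het(alt.astype(float), tot.astype(float))
        for i in idx:
            g = panel.genotypes[i]
            used = (g != MISSING) & ~np.isnan(he)
            L = int(used.sum())
            o_hom = int(((g == 0) | (g == 2))[used].sum())
            e_hom = float((1 - he[used]).sum())
            denom = L - e_hom
            f = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else float("nan")
            rows.append({"sample": panel.samples[i], "pop": pop, "n_sites": L,
                         "o_hom": o_hom, "e_hom": e_hom, "f_hom": f})
    return pd.DataFrame(rows)


def dst_distance(panel: GenotypePanel, popmap: PopulationMap):
    """Allele-sharing distance D = 1 - DST for within-population pairs.

    DST = (IBS2 + 0.5*IBS1) / (IBS0 + IBS1 + IBS2) over co-non-missing
    sites, with IBS state 2 - |g1 - g2| for dosage genotypes.

    Returns
    -------
    (pairs, summary)
        ``pairs``: DataFrame(pop, sample_a, sample_b, n_sites, dst, d);
        ``summary``: per-population mean of D.
    """
    rows = []
    for pop, idx in _pop_indices(panel, popmap).items():
        if idx.size < 2:
            raise ValueError(f"population {pop!r} needs >= 2 samples for DST")
        for a, b in itertools.combinations(idx, 2):
            ga, gb = panel.genotypes[a], panel.genotypes[b]
            ok = (ga != MISSING) & (gb != MISSING)
            n = int(ok.sum())
            if n == 0:
                warnings.warn(
                    f"no co-non-missing sites for {panel.samples[a]}/{panel.samples[b]}",
                    stacklevel=2)
                continue
            diff = np.abs(ga[ok].astype(int) - gb[ok].astype(int))
            ibs1 = int((diff == 1).sum())
            ibs2 = int((diff == 0).sum())
            dst = (ibs2 + 0.5 * ibs1) / n
            rows.append({"pop": pop, "sample_a": panel.samples[a],
                         "sample_b": panel.samples[b], "n_sites": n,
                         "dst": dst, "d": 1 - dst})
    pairs = pd.DataFrame(rows, columns=["pop", "sample_a", "sample_b",
                                        "n_sites", "dst", "d"])
    summary = pairs.groupby("pop")["d"].mean().rename("d_mean")
    return pairs, summary


def diversity_summary(panel: GenotypePanel, popmap: PopulationMap,
                      contigs: dict[str, int] | None = None,
                      pi_window: int = 20_000, pi_step: int = 10_000,
                      density_bin: int = 1000) -> pd.DataFrame:
    """One-row-per-population summary mirroring a cohort diversity table."""
    _, het = het_stats(panel, popmap)
    pi = windowed_pi(panel, popmap, pi_window, pi_step, contigs)
    fh = f_hom(panel, popmap)
    _, d_mean = dst_distance(panel, popmap)
    rows = []
    for pop in popmap.populations:
        idx = panel.sample_index([s for s in popmap.samples(pop) if s in panel.samples])
        alt, tot = allele_counts(panel, idx)
        seg = (alt > 0) & (alt < tot)
        bins, dens_mean, dens_sd = snp_density(
            panel.variants[seg].reset_index(drop=True), density_bin, contigs)
        grp = fh[fh["pop"] == pop]["f_hom"]
        rows.append({
            "pop": pop,
            "n": int(idx.size),
            "pi_mean": float(pi[pop]["pi"].mean()) if len(pi[pop]) else float("nan"),
            "ho_mean": float(het.loc[pop, "ho_mean"]),
            "he_mean": float(het.loc[pop, "he_mean"]),
            "d_mean": float(d_mean.get(pop, float("nan"))),
            "f_hom_mean": float(grp.mean()),
            "f_hom_sd": float(grp.std(ddof=1)) if len(grp) > 1 else 0.0,
            "snp_density_mean": dens_mean,
            "snp_density_sd": dens_sd,
        })
    return pd.DataFrame(rows).set_index("pop")
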