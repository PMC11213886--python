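"""Pipeline orchestration: one config, all stages, deterministic outputs.

Stages run in dependency order (simulate -> filter -> diversity / roh / ld /
structure -> scan -> annotate -> venn), each writing TSV outputs into the
run directory; a JSON manifest records the resolved config, per-stage record
counts and a SHA-256 checksum of every output file, so re-running an
unchanged config can be verified byte-for-byte.  Every number written here
is produced by a library call in the other modules; the orchestrator only
routes data.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, ldstats, popio, roh, scan, simpop, structure

log = logging.getLogger("capriscan.pipeline")

__all__ = ["DEFAULTS", "validate_config", "run_pipeline"]

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "capriscan_run",
    "input": {  # either give these paths, or a simulate block
        "vcf": None,
        "popmap": None,
        "genes": None,
        "contigs": None,
        "autosomes": None,
    },
    "simulate": None,  # dict of simpop.SimConfig fields
    "diversity": {"pi_window": 20_000, "pi_step": 10_000, "density_bin": 1000},
    "roh": {
        "window_snp": 50, "window_het": 1, "min_snp": 10, "min_kb": 100.0,
        "density_kb_per_snp": 10.0, "max_gap_kb": 100.0,
        "window_hit_fraction": 0.05,
    },
    "ld": {
        "max_dist": 1_000_000, "n_bins": 20, "max_snps_per_chrom": 3000,
        "recomb_rate_cM_Mb": 1.0, "alpha": 2.0, "min_pairs": 100,
        "max_t": 1000.0,
    },
    "prune": {"window": 50_000, "step": 10_000, "r2_max": 0.01},
    "structure": {"pca_k": 10},
    "scan": {
        "populations": None,   # default: every population in the map
        "window": 100_000, "step": 50_000, "min_snps": 10,
        "xpehh_core_step": 1, "merge_gap": 200_000,
        "thresholds": {
            "zhp_candidate": -3.9, "zfst_candidate": 4.0,
            "xpehh_candidate": 5.0, "xpehh_top_quantile": 1e-5,
            "zhp_top": -7.0, "zfst_top": 7.0, "xpehh_top": 6.0,
        },
    },
}


def _merge(defaults, user, path=""):
    if user is None:
        return copy.deepcopy(defaults)
    if not isinstance(defaults, dict):
        return copy.deepcopy(user)
    if not isinstance(user, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults and path not in ("simulate",):
            raise ValueError(f"unknown config key: {path + key!r}")
        if key in ("simulate",) or (key in defaults and isinstance(defaults[key], dict)):
            if key == "simulate":
                out[key] = copy.deepcopy(val)
            else:
                out[key] = _merge(defaults[key], val, path + key + ".")
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(config: dict | None) -> dict:
    """Merge with defaults and validate; returns the resolved config.

    Raises ValueError listing every violation found.
    """
    cfg = _merge(DEFAULTS, config)
    errors = []
    if cfg["simulate"] is not None:
        try:
            simpop.SimConfig(**{**cfg["simulate"], "seed": cfg["simulate"].get("seed", cfg["seed"])})
        except (TypeError, ValueError) as e:
            errors.append(f"simulate: {e}")
    else:
        for key in ("vcf", "popmap"):
            if not cfg["input"][key]:
                errors.append(f"input.{key} is required without a simulate block")
            elif not Path(cfg["input"][key]).exists():
                errors.append(f"input.{key}: file not found: {cfg['input'][key]}")
        for key in ("genes", "contigs"):
            if cfg["input"][key] and not Path(cfg["input"][key]).exists():
                errors.append(f"input.{key}: file not found: {cfg['input'][key]}")
    sc = cfg["scan"]
    if sc["step"] > sc["window"]:
        errors.append("scan.step must not exceed scan.window")
    dv = cfg["diversity"]
    if dv["pi_step"] > dv["pi_window"]:
        errors.append("diversity.pi_step must not exceed diversity.pi_window")
    try:
        scan.Thresholds(**sc["thresholds"])
    except (TypeError, ValueError) as e:
        errors.append(f"scan.thresholds: {e}")
    try:
        roh.RoHParams(**cfg["roh"])
    except (TypeError, ValueError) as e:
        errors.append(f"roh: {e}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    log.info("resolved config: %s", json.dumps(cfg, default=str, sort_keys=True))
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None, out_dir: str | Path | None = None) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    cfg = validate_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # --- acquire inputs -------------------------------------------------
    genes = None
    if cfg["simulate"] is not None:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", cfg["seed"])
        sim_cfg = simpop.SimConfig(**sim_kwargs)
        panel0, popmap, truth = simpop.simulate_panel(sim_cfg)
        simpop.write_sim_vcf(panel0, out / "sim.vcf", sim_cfg)
        simpop.write_popmap(popmap, out / "popmap.tsv")
        truth.to_tsv(out / "truth.tsv")
        contigs = {sim_cfg.chrom: sim_cfg.chrom_length_bp}
        vcf_path = out / "sim.vcf"
        autosomes = list(contigs)
        genes = simpop.synthetic_gene_track(sim_cfg)
        with open(out / "genes.bed", "w") as fh:
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
        log.info("simulate: %d variants, %d samples", panel0.n_variants, panel0.n_samples)
        counts["simulated_variants"] = panel0.n_variants
    else:
        vcf_path = Path(cfg["input"]["vcf"])
        popmap = popio.read_popmap(cfg["input"]["popmap"])
        contigs = popio.read_contigs(cfg["input"]["contigs"]) if cfg["input"]["contigs"] else None
        autosomes = cfg["input"]["autosomes"] or (list(contigs) if contigs else None)
        if cfg["input"]["genes"]:
            genes = popio.read_genes(cfg["input"]["genes"])

    # --- filter ---------------------------------------------------------
    panel, report = popio.read_vcf(vcf_path, autosomes=autosomes, popmap=popmap)
    counts["variants_in_panel"] = panel.n_variants
    counts["variants_dropped"] = report.total
    log.info("filter: kept %d variants (dropped %d: %d multiallelic, "
             "%d non-autosomal, %d non-SNP)", panel.n_variants, report.total,
             report.multiallelic, report.non_autosomal, report.non_snp)

    # --- diversity ------------------------------------------------------
    dv = cfg["diversity"]
    summary = diversity.diversity_summary(
        panel, popmap, contigs, dv["pi_window"], dv["pi_step"], dv["density_bin"])
    _write_tsv(summary.reset_index(), out / "diversity.tsv",
               f"pi_window={dv['pi_window']} pi_step={dv['pi_step']}")
    pi = diversity.windowed_pi(panel, popmap, dv["pi_window"], dv["pi_step"], contigs)
    for pop, df in pi.items():
        _write_tsv(df, out / f"pi_{pop}.tsv")

    # --- roh ------------------------------------------------------------
    params = roh.RoHParams(**cfg["roh"])
    segments = roh.call_roh(panel, params)
    seg_df = pd.DataFrame(
        [{"sample": s.sample, "chrom": s.chrom, "start": s.start, "end": s.end,
          "n_snps": s.n_snps, "length_kb": s.length_kb} for s in segments])
    _write_tsv(seg_df, out / "roh_segments.tsv")
    total_len = sum(contigs.values()) if contigs else int(panel.variants["pos"].max())
    fr = roh.froh(segments, total_len, samples=panel.samples)
    _write_tsv(fr.rename_axis("sample").reset_index(), out / "froh.tsv")
    _write_tsv(roh.roh_categories(segments), out / "roh_classes.tsv")
    counts["roh_segments"] = len(segments)

    # --- ld / ne --------------------------------------------------------
    ld = cfg["ld"]
    for pop in popmap.populations:
        sub = panel.take_samples(popmap.samples(pop))
        pairs = ldstats.pairwise_r2(sub, ld["max_dist"], ld["max_snps_per_chrom"])
        if len(pairs) == 0:
            continue
        curve = ldstats.ld_decay(pairs, ld["n_bins"], ld["max_dist"])
        _write_tsv(curve, out / f"ld_decay_{pop}.tsv")
        ne = ldstats.estimate_ne(curve, sample_n=sub.n_samples,
                                 recomb_rate_cM_Mb=ld["recomb_rate_cM_Mb"],
                                 alpha=ld["alpha"], min_pairs=ld["min_pairs"],
                                 max_t=ld["max_t"])
        _write_tsv(ne, out / f"ne_{pop}.tsv")

    # --- structure ------------------------------------------------------
    pr = cfg["prune"]
    pruned = ldstats.ld_prune(panel, pr["window"], pr["step"], pr["r2_max"])
    counts["variants_after_prune"] = pruned.n_variants
    log.info("prune: %d -> %d variants", panel.n_variants, pruned.n_variants)
    k = min(cfg["structure"]["pca_k"], pruned.n_samples - 1)
    res = structure.pca(pruned, k)
    pca_df = pd.DataFrame(res.coords, columns=[f"PC{i + 1}" for i in range(k)])
    pca_df.insert(0, "sample", res.samples)
    _write_tsv(pca_df, out / "pca.tsv",
               "explained_pct=" + ",".join(f"{x:.4f}" for x in res.explained_pct))
    M = structure.fst_matrix(panel, popmap)
    _write_tsv(M.rename_axis("pop").reset_index(), out / "fst_matrix.tsv")
    if len(M) >= 3:  # NJ needs at least three taxa
        (out / "nj_tree.nwk").write_text(structure.nj_tree(M) + "\n")
    else:
        log.info("structure: <3 populations, NJ tree skipped")

    # --- scan / annotate / venn ----------------------------------------
    sc = cfg["scan"]
    th = scan.Thresholds(**sc["thresholds"])
    scan_pops = sc["populations"] or popmap.populations
    gene_lists: dict[str, list[str]] = {"zhp": [], "zfst": [], "xpehh": []}
    all_regions: list[scan.ScanRegion] = []
    for pop in scan_pops:
        hp = scan.windowed_hp(panel, popmap, pop, sc["window"], sc["step"],
                              sc["min_snps"], contigs)
        hp = scan.z_transform(hp, "hp")
        _write_tsv(hp, out / f"zhp_{pop}.tsv")
        tiers = scan.call_candidates(hp["z"], "zhp", th)
        regions = scan.merge_regions(hp[tiers["candidate"].to_numpy()], "ZHp",
                                     max_gap=sc["merge_gap"])
        if genes:
            scan.overlap_genes(regions, genes)
        for r in regions:
            gene_lists["zhp"].extend(r.genes)
        all_regions.extend(regions)
    import itertools as _it
    for pop_a, pop_b in _it.combinations(scan_pops, 2):
        tag = f"{pop_a}_vs_{pop_b}"
        fst = scan.windowed_fst(panel, popmap, pop_a, pop_b, sc["window"],
                                sc["step"], sc["min_snps"], contigs)
        _write_tsv(fst, out / f"zfst_{tag}.tsv")
        tiers = scan.call_candidates(fst["z"], "zfst", th)
        regions = scan.merge_regions(fst[tiers["candidate"].to_numpy()], "ZFst",
                                     max_gap=sc["merge_gap"])
        if panel.phased:
            xp = scan.xpehh(panel, popmap, pop_a, pop_b,
                            core_step=sc["xpehh_core_step"])
            _write_tsv(xp, out / f"xpehh_{tag}.tsv")
            xt = scan.call_candidates(xp["std"], "xpehh", th)
            xr = scan.merge_regions(xp[xt["candidate"].to_numpy()], "XP-EHH",
                                    score_column="std", max_gap=sc["merge_gap"])
            regions = regions + xr
        if genes:
            scan.overlap_genes(regions, genes)
        for r in regions:
            key = {"ZFst": "zfst", "XP-EHH": "xpehh", "ZHp": "zhp"}[r.statistic]
            gene_lists[key].extend(r.genes)
        all_regions.extend(regions)
    reg_df = pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end,
          "statistic": r.statistic, "peak_score": r.peak_score,
          "n_constituents": r.n_constituents, "genes": ",".join(r.genes)}
         for r in all_regions])
    _write_tsv(reg_df, out / "regions.tsv")
    popio.write_regions_bed(all_regions, out / "regions.bed")
    counts["candidate_regions"] = len(all_regions)
    venn, membership = scan.intersect_gene_lists(gene_lists)
    venn = venn.copy()
    venn["genes"] = [",".join(membership[m]) for m in venn["methods"]]
    _write_tsv(venn, out / "venn.tsv")

    # --- manifest -------------------------------------------------------
    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": cfg,
        "counts": counts,
        "checksums": {p.name: _checksum(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str,
                                                  sort_keys=True))
    return manifest
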