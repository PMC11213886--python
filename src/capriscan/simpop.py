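"""Seeded forward-in-time generator of multi-population diploid SNP panels.

The generator emulates the post-variant-calling structure of a multi-breed
resequencing cohort: several populations of a few diploids each, biallelic
SNPs on one autosome, drift-driven divergence between populations,
recombination-limited LD, background nucleotide diversity on the pi ~ 0.002
scale typical of livestock genomes, and (optionally) localized selective
sweeps in single populations.

Model
-----
Standing variation is initialised by drawing per-site allele frequencies
from the neutral 1/i site-frequency spectrum over the ``2*Ne`` ancestral
haplotypes, at linkage equilibrium.  Each population then evolves by
discrete-generation Wright-Fisher reproduction: every offspring draws two
gametes from randomly chosen diploid parents (the same parent for both
gametes during selfing generations), each gamete being a single-crossover
recombinant of the parent's two haplotypes with crossover probability equal
to the chromosome's genetic length in Morgans.  No new mutation enters
during drift; the initial site count is calibrated so that the *sampled*
panel hits the target pi after the expected heterozygosity decay of
``(1 - 1/(2Ne))^t``.

Sweeps are imposed post hoc by haplotype copying (:func:`inject_sweep`),
which creates the low-heterozygosity / long-shared-haplotype signal
structure that the selection scans detect, fully deterministically.

All randomness flows from the single ``numpy`` generator seeded by
``SimConfig.seed``; draws happen in a fixed documented order, so identical
configs give bit-identical VCF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popio import GenotypePanel, PopulationMap, write_vcf

__all__ = ["SimConfig", "TruthTable", "simulate_panel", "inject_sweep", "write_sim_vcf"]


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Defaults mirror the study conditions the package is exercised under:
    small populations of five diploids, a 20 Mb autosome, pi ~ 0.002 and a
    uniform 1 cM/Mb recombination map.
    """

    n_pops: int = 3
    samples_per_pop: int = 5
    ancestral_Ne: int = 100            # diploids per population during drift
    split_generations: int = 50
    chrom_length_bp: int = 20_000_000
    mutation_target_pi: float = 0.002
    recomb_rate_cM_Mb: float = 1.0
    selfing_generations: int = 0
    sweep_specs: list = field(default_factory=list)  # (pop, position_bp, final_freq)
    sweep_width_bp: int = 300_000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pops, self.samples_per_pop, self.ancestral_Ne,
               self.chrom_length_bp) <= 0:
            raise ValueError("counts must be positive")
        if self.split_generations < 0 or self.selfing_generations < 0:
            raise ValueError("generation counts must be non-negative")
        if self.mutation_target_pi < 0:
            raise ValueError("target pi must be non-negative")
        for pop, pos, freq in self.sweep_specs:
            if not (0 < pos <= self.chrom_length_bp):
                raise ValueError(f"sweep position {pos} outside chromosome")
            if not (0 < freq <= 1):
                raise ValueError("sweep final frequency must be in (0, 1]")

    @property
    def pop_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]


@dataclass
class TruthTable:
    """Ground truth emitted next to each simulated panel."""

    sweeps: pd.DataFrame            # pop, position_bp, final_freq, realized_freq
    pop_freqs: dict                 # pop -> per-variant sampled alt-allele freq
    expected_fst: float             # drift expectation 1 - (1 - 1/(2Ne))^t

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# expected_pairwise_fst\t{self.expected_fst:.6f}\n")
            self.sweeps.to_csv(fh, sep="\t", index=False)


def _required_sites(cfg: SimConfig) -> int:
    """Initial segregating-site count needed to hit the target pi."""
    if cfg.mutation_target_pi == 0:
        return 0
    n2 = 2 * cfg.ancestral_Ne
    i = np.arange(1, n2)
    w = (1.0 / i) / np.sum(1.0 / i)
    p = i / n2
    e_het = float(np.sum(w * 2 * p * (1 - p)))
    t = cfg.split_generations + cfg.selfing_generations
    decay = (1 - 1 / n2) ** t
    s0 = int(round(cfg.mutation_target_pi * cfg.chrom_length_bp / (e_het * decay)))
    if s0 > cfg.chrom_length_bp // 2:
        raise ValueError(
            f"target pi {cfg.mutation_target_pi} needs {s0} sites, more than "
            f"half the {cfg.chrom_length_bp} bp chromosome can hold"
        )
    return s0


def _meiosis(H: np.ndarray, parents: np.ndarray, rng: np.random.Generator,
             morgans: float) -> np.ndarray:
    """One gamete per entry of ``parents`` (diploid indices) from matrix H.

    Crossover count per meiosis is Poisson with mean equal to the
    chromosome's genetic length; breakpoints fall uniformly over the marker
    grid (markers are uniform in bp, so this matches a uniform map).
    """
    n = parents.size
    start = rng.integers(0, 2, n)
    C = H[2 * parents + start].copy()
    ncross = rng.poisson(morgans, n)
    for i in np.nonzero(ncross)[0]:
        bps = np.sort(rng.integers(0, H.shape[1] + 1, ncross[i]))
        cur = start[i]
        for b in bps:
            cur = 1 - cur
            C[i, b:] = H[2 * parents[i] + cur, b:]
    return C


def _drift(H: np.ndarray, generations: int, selfing: int,
           rng: np.random.Generator, morgans: float) -> np.ndarray:
    n_dip = H.shape[0] // 2
    for g in range(generations + selfing):
        self_gen = g >= generations
        mothers = rng.integers(0, n_dip, n_dip)
        fathers = mothers if self_gen else rng.integers(0, n_dip, n_dip)
        ga = _meiosis(H, mothers, rng, morgans)
        gb = _meiosis(H, fathers, rng, morgans)
        nxt = np.empty_like(H)
        nxt[0::2] = ga
        nxt[1::2] = gb
        H = nxt
    return H


_REF_ALT = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def simulate_panel(config: SimConfig):
    """Simulate a cohort.

    Returns
    -------
    (GenotypePanel, PopulationMap, TruthTable)
        The panel is phased; sites monomorphic across the whole sample are
        dropped.  Identical configs (including seed) give identical output.
    """
    cfg = config
    s0 = _required_sites(cfg)
    rng = np.random.default_rng(cfg.seed)
    n2 = 2 * cfg.ancestral_Ne
    L_morgans = cfg.chrom_length_bp * cfg.recomb_rate_cM_Mb * 1e-8

    # Draw order: positions, ancestral frequencies, ancestral alleles, then
    # per-population drift in pop order.
    positions = np.sort(rng.choice(cfg.chrom_length_bp, size=s0, replace=False) + 1) \
        if s0 else np.array([], dtype=int)
    if s0:
        i = np.arange(1, n2)
        w = (1.0 / i) / np.sum(1.0 / i)
        freqs = rng.choice(i, size=s0, p=w) / n2
        ancestral = (rng.random((n2, s0)) < freqs[None, :]).astype(np.int8)
    else:
        ancestral = np.zeros((n2, 0), dtype=np.int8)

    sample_rows = []
    for _pop in range(cfg.n_pops):
        Hp = _drift(ancestral, cfg.split_generations, cfg.selfing_generations,
                    rng, L_morgans)
        sample_rows.append(Hp[: 2 * cfg.samples_per_pop].copy())
    H = np.concatenate(sample_rows, axis=0)

    # Drop sites invisible in the sample.
    seg = (H.sum(axis=0) > 0) & (H.sum(axis=0) < H.shape[0])
    H = H[:, seg]
    positions = positions[seg]
    n_var = H.shape[1]

    ra = [_REF_ALT[k % 4] for k in range(n_var)]
    variants = pd.DataFrame({
        "chrom": [cfg.chrom] * n_var,
        "pos": positions.astype(int),
        "ref": [x[0] for x in ra],
        "alt": [x[1] for x in ra],
    })
    samples, mapping = [], {}
    for pop in cfg.pop_labels:
        for k in range(cfg.samples_per_pop):
            sid = f"{pop}_s{k + 1}"
            samples.append(sid)
            mapping[sid] = pop
    genotypes = (H[0::2] + H[1::2]).astype(np.int8)
    panel = GenotypePanel(samples=samples, variants=variants,
                          genotypes=genotypes, haplotypes=H, phased=True)
    popmap = PopulationMap(mapping)

    sweep_rows = []
    for pop, pos, freq in cfg.sweep_specs:
        panel = inject_sweep(panel, popmap, pop, pos, freq, cfg.sweep_width_bp)
        sweep_rows.append({"pop": pop, "position_bp": pos, "final_freq": freq})

    pop_freqs = {}
    for pop in cfg.pop_labels:
        ridx = panel.sample_index(popmap.samples(pop))
        hap_rows = np.ravel(np.column_stack([2 * ridx, 2 * ridx + 1]))
        pop_freqs[pop] = panel.haplotypes[hap_rows].mean(axis=0)
    sweeps = pd.DataFrame(sweep_rows, columns=["pop", "position_bp", "final_freq"])
    if len(sweeps):
        realized = []
        for _, row in sweeps.iterrows():
            j = int(np.argmin(np.abs(panel.variants["pos"].to_numpy() - row.position_bp)))
            ridx = panel.sample_index(popmap.samples(row["pop"]))
            hap_rows = np.ravel(np.column_stack([2 * ridx, 2 * ridx + 1]))
            donor_allele = panel.haplotypes[hap_rows[0], j]
            realized.append(
                float((panel.haplotypes[hap_rows, j] == donor_allele).mean()))
        sweeps["realized_freq"] = realized
    expected_fst = 1 - (1 - 1 / n2) ** cfg.split_generations
    truth = TruthTable(sweeps=sweeps, pop_freqs=pop_freqs, expected_fst=expected_fst)
    return panel, popmap, truth


def inject_sweep(panel: GenotypePanel, popmap: PopulationMap, pop: str,
                 position_bp: int, final_freq: float,
                 sweep_width_bp: int = 300_000) -> GenotypePanel:
    """Copy a core haplotype onto a fraction of one population's haplotypes.

    The first haplotype of the target population acts as donor.  Recipient
    ``j`` (of ``m - 1``) receives the donor's alleles over an interval
    centred on ``position_bp`` whose width shrinks linearly from
    ``sweep_width_bp`` to ~0 across recipients, so shared-haplotype length
    tapers away from the core the way recombination erodes a real sweep.
    Deterministic; other populations are untouched.
    """
    if pop not in popmap.populations:
        raise KeyError(f"population {pop!r} not in map")
    pos = panel.variants["pos"].to_numpy()
    if not (pos.size and pos[0] <= position_bp <= panel.variants["pos"].iloc[-1] + 1):
        if not (0 < position_bp):
            raise ValueError("sweep position outside panel span")
    if panel.haplotypes is None:
        raise ValueError("sweep injection needs a phased panel")
    ridx = panel.sample_index(popmap.samples(pop))
    hap_rows = np.ravel(np.column_stack([2 * ridx, 2 * ridx + 1]))
    m = int(round(final_freq * hap_rows.size))
    if m <= 1:
        return panel
    H = panel.haplotypes.copy()
    donor = hap_rows[0]
    for j in range(1, m):
        width = sweep_width_bp * (m - j) / m
        lo = np.searchsorted(pos, position_bp - width / 2, side="left")
        hi = np.searchsorted(pos, position_bp + width / 2, side="right")
        H[hap_rows[j], lo:hi] = H[donor, lo:hi]
    genotypes = (H[0::2] + H[1::2]).astype(np.int8)
    return GenotypePanel(samples=list(panel.samples), variants=panel.variants.copy(),
                         genotypes=genotypes, haplotypes=H, phased=True)


def write_sim_vcf(panel: GenotypePanel, path, config: SimConfig | None = None) -> None:
    """Write the phased panel as VCF; header lists the simulated contig."""
    contigs = None
    if config is not None:
        contigs = {config.chrom: config.chrom_length_bp}
    write_vcf(panel, path, contigs=contigs)


def synthetic_gene_track(config: SimConfig, spacing_bp: int = 60_000,
                         width_bp: int = 25_000) -> list:
    """Deterministic evenly spaced synthetic gene annotation for the
    simulated chromosome — a stand-in track so gene-overlap and
    intersection stages have something to annotate against."""
    from .popio import GeneRecord

    genes = []
    k = 0
    start = 10_000
    while start + width_bp <= config.chrom_length_bp:
        k += 1
        genes.append(GeneRecord(f"simgene{k:05d}", config.chrom,
                                start + 1, start + width_bp, "+"))
        start += spacing_bp
    return genes


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")
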