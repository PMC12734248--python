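"""Synthetic two-population data generator.

Emulates the study design the toolkit is built for: a nuclear reference
panel of two diverged populations (Africa-like vs Asia-like) genotyped
at thousands of biallelic SNPs with realistic depth and missingness, and
a region-structured COI barcode compilation with optional planted
mitonuclear discordance.  Everything is seed-deterministic.

Neutral loci follow a Balding–Nichols model: a shared ancestral
frequency per locus, population frequencies drawn from a Beta
distribution concentrated around it, with the concentration set by the
target differentiation (``divergence`` ≈ expected FST).  Diagnostic loci
are planted at exact population frequencies.  Depth is negative
binomial, mirroring the overdispersion of shotgun sequencing at the
~10× target depth of the study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import BarcodeAlignment, GenotypeLikelihoods, GenotypeTable, REGIONS


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters for the nuclear genotype simulator.

    divergence is the Balding–Nichols F parameter, approximately the
    expected FST between the two populations' allele frequencies.
    depth_mean / depth_overdispersion parameterize a negative binomial
    (variance = mean + mean²/overdispersion).
    """

    n_pop_a: int = 60
    n_pop_b: int = 60
    n_sites: int = 1000
    planted_sites: int = 0
    planted_freqs: tuple[float, float] = (0.02, 0.98)
    divergence: float = 0.1
    missing_rate: float = 0.01
    depth_mean: float = 10.0
    depth_overdispersion: float = 5.0
    seed: int = 0
    labels: tuple[str, str] = ("Africa", "Asia")
    chrom: str = "chr1"

    def validate(self) -> None:
        if min(self.n_pop_a, self.n_pop_b, self.n_sites) <= 0:
            raise ValueError("population sizes and site count must be positive")
        if self.planted_sites < 0 or self.planted_sites > self.n_sites:
            raise ValueError("planted_sites must be in [0, n_sites]")
        for p in (*self.planted_freqs, self.divergence, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.depth_mean < 0 or self.depth_overdispersion <= 0:
            raise ValueError("invalid depth model")


@dataclass
class HaplotypeSimConfig:
    """Parameters for the COI barcode simulator.

    ``haplotypes`` is the shared haplotype set (equal-length sequences);
    ``haplotype_pools`` maps each region to a frequency vector over that
    set.  ``discordance_rate`` is the fraction of individuals whose
    mitochondrial haplotype is drawn from a different region's pool than
    their recorded (nuclear) region — planted mitonuclear discordance.
    """

    regions: dict[str, int] = field(default_factory=lambda: {"Africa": 60, "Southeast Asia": 60})
    haplotypes: list[str] = field(default_factory=list)
    haplotype_pools: dict[str, list[float]] = field(default_factory=dict)
    mutation_rate: float = 0.002
    barcode_length: int = 684
    discordance_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.regions:
            raise ValueError("at least one region required")
        for r in self.regions:
            if r not in REGIONS:
                raise ValueError(f"unknown region {r!r}")
        if not self.haplotypes:
            raise ValueError("haplotype set is empty")
        L = len(self.haplotypes[0])
        if any(len(h) != L for h in self.haplotypes):
            raise ValueError("haplotype pool/sequence length mismatch")
        if L != self.barcode_length:
            raise ValueError(
                f"haplotype length {L} does not match barcode_length {self.barcode_length}"
            )
        for r, freqs in self.haplotype_pools.items():
            if len(freqs) != len(self.haplotypes):
                raise ValueError(f"pool for {r!r} has wrong length")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError(f"pool frequencies for {r!r} must sum to 1")
        if not 0.0 <= self.discordance_rate <= 1.0:
            raise ValueError("discordance_rate must be in [0, 1]")
        missing = set(self.regions) - set(self.haplotype_pools)
        if missing:
            raise ValueError(f"regions without haplotype pools: {sorted(missing)}")


def _scrub_stops(seq_idx: np.ndarray) -> np.ndarray:
    """Remove frame-1 internal stop codons (invertebrate mito code).

    TAA/TAG codons (indices T=3, A=0, G=2 over ACGT) get their third
    base set to C (TAC, tyrosine), keeping sequences coding-plausible
    so curation does not reject clean simulator output.
    """
    for i in range(0, len(seq_idx) - 2, 3):
        if seq_idx[i] == 3 and seq_idx[i + 1] == 0 and seq_idx[i + 2] in (0, 2):
            seq_idx[i + 2] = 1
    return seq_idx


def random_haplotype_set(
    n_haplotypes: int,
    length: int = 684,
    divergence: float = 0.02,
    seed: int = 0,
) -> list[str]:
    """Generate a set of haplotypes mutated from a common ancestor.

    Each haplotype differs from the ancestral sequence at a Binomial
    (length, divergence) number of positions, giving expected pairwise
    distance ≈ 2·divergence·length between haplotypes.  Sequences are
    kept free of frame-1 internal stop codons, mimicking a functional
    protein-coding barcode.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    anc = _scrub_stops(rng.integers(0, 4, size=length))
    haps = []
    for _ in range(n_haplotypes):
        h = anc.copy()
        mut = rng.random(length) < divergence
        h[mut] = (h[mut] + rng.integers(1, 4, size=mut.sum())) % 4
        haps.append("".join(bases[_scrub_stops(h)]))
    return haps


def disjoint_pool_config(
    region_counts: dict[str, int],
    haps_per_region: int = 2,
    length: int = 684,
    hap_divergence: float = 0.02,
    mutation_rate: float = 0.002,
    discordance_rate: float = 0.0,
    seed: int = 0,
) -> HaplotypeSimConfig:
    """Convenience constructor: disjoint haplotype pools per region.

    Region r's pool puts uniform mass on its own ``haps_per_region``
    haplotypes and zero elsewhere — the idealized case where each
    region has private mitochondrial lineages.
    """
    n_regions = len(region_counts)
    haps = random_haplotype_set(n_regions * haps_per_region, length, hap_divergence, seed)
    pools = {}
    for i, r in enumerate(region_counts):
        f = [0.0] * len(haps)
        for j in range(i * haps_per_region, (i + 1) * haps_per_region):
            f[j] = 1.0 / haps_per_region
        pools[r] = f
    return HaplotypeSimConfig(
        regions=dict(region_counts),
        haplotypes=haps,
        haplotype_pools=pools,
        mutation_rate=mutation_rate,
        barcode_length=length,
        discordance_rate=discordance_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Nuclear genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeTable, list[str]]:
    """Simulate a two-population diploid genotype table.

    Returns the table (with ``class_label`` set to the true population)
    and the list of planted (diagnostic) site ids.  The first
    ``planted_sites`` sites carry the exact frequency pair
    ``planted_freqs``; the rest are neutral Balding–Nichols loci.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pop_a + cfg.n_pop_b
    m = cfg.n_sites

    p_pop = np.empty((2, m))
    anc = rng.uniform(0.1, 0.9, size=m)
    if cfg.divergence > 0:
        c = (1.0 - cfg.divergence) / cfg.divergence
        for k in range(2):
            p_pop[k] = rng.beta(anc * c, (1.0 - anc) * c)
    else:
        p_pop[0] = p_pop[1] = anc
    planted = list(range(cfg.planted_sites))
    p_pop[0, planted] = cfg.planted_freqs[0]
    p_pop[1, planted] = cfg.planted_freqs[1]

    pop = np.array([0] * cfg.n_pop_a + [1] * cfg.n_pop_b)
    geno = rng.binomial(2, p_pop[pop]).astype(float)

    # negative binomial depth: variance = mean + mean^2 / overdispersion
    r = cfg.depth_overdispersion
    p_nb = r / (r + cfg.depth_mean)
    depth = rng.negative_binomial(r, p_nb, size=(n, m))

    miss = rng.random((n, m)) < cfg.missing_rate
    geno[miss | (depth == 0)] = np.nan

    individuals = [f"{cfg.labels[0][:3].upper()}{i:04d}" for i in range(cfg.n_pop_a)] + [
        f"{cfg.labels[1][:3].upper()}{i:04d}" for i in range(cfg.n_pop_b)
    ]
    sites = [f"{cfg.chrom}:{1000 * (j + 1)}" for j in range(m)]
    table = GenotypeTable(
        individuals=individuals,
        sites=sites,
        geno=geno,
        depth=depth,
        class_label=[cfg.labels[k] for k in pop],
        ref=["A"] * m,
        alt=["G"] * m,
    )
    return table, [sites[j] for j in planted]


def hudson_fst(geno: np.ndarray, pop: np.ndarray) -> float:
    """Hudson's FST estimator (ratio of averages) from dosage data.

    ``geno`` is the n×m dosage matrix (nan = missing); ``pop`` a 0/1
    population indicator.  Used as an independent check that realized
    differentiation tracks the configured divergence.
    """
    g1, g2 = geno[pop == 0], geno[pop == 1]
    n1 = np.sum(~np.isnan(g1), axis=0) * 2
    n2 = np.sum(~np.isnan(g2), axis=0) * 2
    ok = (n1 > 1) & (n2 > 1)
    p1 = np.nansum(g1, axis=0)[ok] / n1[ok]
    p2 = np.nansum(g2, axis=0)[ok] / n2[ok]
    n1, n2 = n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den.sum() == 0:
        return 0.0
    return float(num.sum() / den.sum())


# ---------------------------------------------------------------------------
# COI barcodes
# ---------------------------------------------------------------------------

def simulate_barcodes(cfg: HaplotypeSimConfig) -> tuple[BarcodeAlignment, "pd.DataFrame"]:
    """Simulate a region-structured COI barcode alignment.

    Each individual draws a haplotype from its region's pool and accrues
    per-site mutations at ``mutation_rate``.  A ``discordance_rate``
    fraction of individuals instead draw from a uniformly chosen *other*
    region's pool while keeping their recorded region label — planted
    mitonuclear discordance.  Returns the (gapless) alignment and a
    truth table with columns id, region, haplotype, pool_region,
    discordant.
    """
    import pandas as pd

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    bases = np.array(list("ACGT"))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    hap_arrays = [np.array([base_idx[c] for c in h]) for h in cfg.haplotypes]
    region_names = list(cfg.regions)

    ids, seqs, regions = [], [], []
    truth = []
    counter = 0
    for r in region_names:
        for _ in range(cfg.regions[r]):
            counter += 1
            uid = f"SIM{counter:04d}"
            discordant = rng.random() < cfg.discordance_rate
            pool_region = r
            if discordant and len(region_names) > 1:
                others = [x for x in region_names if x != r]
                pool_region = others[rng.integers(len(others))]
            hap_id = rng.choice(len(cfg.haplotypes), p=cfg.haplotype_pools[pool_region])
            seq = hap_arrays[hap_id].copy()
            mut = rng.random(cfg.barcode_length) < cfg.mutation_rate
            seq[mut] = (seq[mut] + rng.integers(1, 4, size=mut.sum())) % 4
            seq = _scrub_stops(seq)
            ids.append(uid)
            seqs.append("".join(bases[seq]))
            regions.append(r)
            truth.append((uid, r, int(hap_id), pool_region, bool(discordant)))

    aln = BarcodeAlignment(ids=ids, seqs=seqs, region=regions)
    truth_df = pd.DataFrame(
        truth, columns=["id", "region", "haplotype", "pool_region", "discordant"]
    )
    return aln, truth_df


# ---------------------------------------------------------------------------
# Genotype likelihoods from genotypes
# ---------------------------------------------------------------------------

def emit_beagle_from_genotypes(
    gt: GenotypeTable, error_rate: float = 0.001, seed: int = 0
) -> GenotypeLikelihoods:
    """Compute genotype likelihoods under a symmetric base-error model.

    For each called genotype, the number of alternate-allele reads is
    drawn Binomial(depth, p_alt(g)) with p_alt = error, 1/2, 1−error for
    dosage 0, 1, 2; the likelihood of each candidate dosage is then the
    binomial probability of the drawn read split.  Missing genotypes get
    the uninformative triple (1/3, 1/3, 1/3).  At high depth the true
    genotype's normalized likelihood approaches 1.
    """
    from scipy.stats import binom

    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n, m = gt.geno.shape
    p_alt = np.array([error_rate, 0.5, 1.0 - error_rate])

    gl = np.full((n, m, 3), 1.0 / 3.0)
    called = ~np.isnan(gt.geno) & (gt.depth > 0)
    g = gt.geno[called].astype(int)
    if error_rate == 0.0:
        # noise-free limit: reads identify the genotype exactly
        onehot = np.zeros((g.size, 3))
        onehot[np.arange(g.size), g] = 1.0
        gl[called] = onehot
        return GenotypeLikelihoods(
            individuals=list(gt.individuals), sites=list(gt.sites), gl=gl
        )
    d = gt.depth[called]
    k = rng.binomial(d, p_alt[g])  # alt-supporting read count
    lik = np.stack([binom.pmf(k, d, p_alt[c]) for c in range(3)], axis=1)
    tot = lik.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    gl[called] = lik / tot
    return GenotypeLikelihoods(
        individuals=list(gt.individuals), sites=list(gt.sites), gl=gl
    )


# ---------------------------------------------------------------------------
# Minimal VCF writer (simulator output only)
# ---------------------------------------------------------------------------

def write_vcf(gt: GenotypeTable, path) -> None:
    """Write a GenotypeTable as an uncompressed VCF 4.2 with GT:DP."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        chroms = {s.rsplit(":", 1)[0] for s in gt.sites}
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.individuals)
            + "\n"
        )
        for j, site in enumerate(gt.sites):
            chrom, pos = site.rsplit(":", 1)
            ref = gt.ref[j] if gt.ref else "A"
            alt = gt.alt[j] if gt.alt else "G"
            cells = []
            for i in range(gt.n_ind):
                g = gt.geno[i, j]
                gstr = "./." if np.isnan(g) else code[g]
                cells.append(f"{gstr}:{gt.depth[i, j]}")
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(cells) + "\n"
            )
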