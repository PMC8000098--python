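"""Founder genomes with linkage disequilibrium.

Founder haplotypes are produced by a forward-in-time neutral Wright-Fisher
burn-in over a tracked set of candidate sites per chromosome: drift,
recombination on a linear cM map and recurrent mutation generate the LD
structure that the downstream imputation experiment needs.  Effective size
follows a simple schedule (large ancestral epoch, small recent epoch), a
desk-scale stand-in for the unpublished history of a closed commercial
rabbit line.

Candidate sites are placed uniformly on the physical map; each site stands
for the ``chrom_length_bp / n_candidate_sites`` base pairs around it, so the
per-site mutation probability per meiosis is ``mutation_rate_per_bp`` times
that span.  Only sites segregating among the emitted founder haplotypes are
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeConfig",
    "ChromosomeHaplotypes",
    "HaplotypePool",
    "SiteShortfallError",
    "simulate_founders",
    "draw_diploid_founders",
    "write_haplotype_matrix",
    "write_vcf",
]

UNKNOWN_PARENT = 0


class SiteShortfallError(RuntimeError):
    """Raised when a chromosome ends the burn-in with too few segregating sites."""


@dataclass
class GenomeConfig:
    """Parameters of the founder-genome simulation.

    Defaults mirror the simulated rabbit genome: 20 chromosomes of 100 cM /
    124.43 Mb, 2000 founder haplotypes per chromosome, per-site recombination
    8.57e-9 and mutation 1.74e-9 per bp.
    """

    n_chromosomes: int = 20
    chrom_length_cm: float = 100.0
    chrom_length_bp: float = 124.43e6
    recomb_rate_per_bp: float = 8.57e-9
    mutation_rate_per_bp: float = 1.74e-9
    n_founder_haplotypes: int = 2000
    n_candidate_sites: int = 5000
    burn_in_generations: int = 150
    #: (first generation, diploid effective size) epochs, in forward order.
    effective_size_schedule: tuple[tuple[int, int], ...] = ((0, 300), (100, 100))
    #: "sfs": initial allele frequencies drawn from the neutral 1/x spectrum
    #: (sites start segregating, burn-in shapes LD); "monomorphic": all sites
    #: start fixed for the 0 allele and only mutation creates polymorphism.
    init: str = "sfs"
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_cm": self.chrom_length_cm,
            "chrom_length_bp": self.chrom_length_bp,
            "recomb_rate_per_bp": self.recomb_rate_per_bp,
            "n_founder_haplotypes": self.n_founder_haplotypes,
            "n_candidate_sites": self.n_candidate_sites,
            "burn_in_generations": self.burn_in_generations,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.mutation_rate_per_bp < 0:
            raise ValueError("mutation_rate_per_bp must be non-negative")
        if self.n_founder_haplotypes % 2:
            raise ValueError("n_founder_haplotypes must be even (haplotypes pair into diploids)")
        if self.init not in ("sfs", "monomorphic"):
            raise ValueError(f"init must be 'sfs' or 'monomorphic', got {self.init!r}")
        if not self.effective_size_schedule:
            raise ValueError("effective_size_schedule must contain at least one epoch")
        for gen, ne in self.effective_size_schedule:
            if ne <= 0:
                raise ValueError("effective sizes must be strictly positive")

    @property
    def cm_per_bp(self) -> float:
        return self.chrom_length_cm / self.chrom_length_bp

    def ne_at(self, generation: int) -> int:
        ne = self.effective_size_schedule[0][1]
        for start, size in self.effective_size_schedule:
            if generation >= start:
                ne = size
        return ne


@dataclass
class ChromosomeHaplotypes:
    """Founder haplotypes for one chromosome, segregating sites only."""

    haplotypes: np.ndarray  # (n_haplotypes, n_sites) uint8 in {0, 1}
    positions_bp: np.ndarray  # int64, strictly increasing, within [0, L_bp)
    positions_cm: np.ndarray  # float64, linear map of positions_bp

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class HaplotypePool:
    config: GenomeConfig
    chromosomes: list[ChromosomeHaplotypes] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return self.chromosomes[0].haplotypes.shape[0]

    def n_segregating(self) -> list[int]:
        return [c.n_sites for c in self.chromosomes]


def _initial_population(rng: np.random.Generator, n_hap: int, n_sites: int, init: str) -> np.ndarray:
    if init == "monomorphic":
        return np.zeros((n_hap, n_sites), dtype=np.uint8)
    # Neutral site-frequency spectrum: allele count x with weight 1/x.
    counts = np.arange(1, n_hap)
    weights = 1.0 / counts
    freqs = rng.choice(counts, size=n_sites, p=weights / weights.sum()) / n_hap
    return (rng.random((n_hap, n_sites)) < freqs).astype(np.uint8)


def _gamete_batch(
    rng: np.random.Generator,
    parents: np.ndarray,  # (n_gametes,) diploid indices into pop
    pop: np.ndarray,  # (2N, n_sites)
    positions_cm: np.ndarray,
    length_cm: float,
) -> np.ndarray:
    """Drop one gamete per requested parent, vectorised over gametes.

    Crossovers form a Poisson process on the cM map (no interference); the
    active parental haplotype along the chromosome is the parity of the
    crossover count to the left of each site, starting from a random
    haplotype.
    """
    n_gametes = parents.shape[0]
    n_sites = pop.shape[1]
    n_xo = rng.poisson(length_cm / 100.0, size=n_gametes)
    switches = np.zeros((n_gametes, n_sites), dtype=np.int8)
    total = int(n_xo.sum())
    if total:
        xo_pos = rng.uniform(0.0, length_cm, size=total)
        # site index at/after which the crossover takes effect
        site_idx = np.searchsorted(positions_cm, xo_pos)
        gamete_idx = np.repeat(np.arange(n_gametes), n_xo)
        keep = site_idx < n_sites
        np.add.at(switches, (gamete_idx[keep], site_idx[keep]), 1)
    start = rng.integers(0, 2, size=n_gametes).astype(np.int8)
    active = (start[:, None] + np.cumsum(switches, axis=1)) & 1
    hap_rows = 2 * parents[:, None] + active
    return pop[hap_rows, np.arange(n_sites)[None, :]]


def _mutate(rng: np.random.Generator, gametes: np.ndarray, mu_site: float) -> None:
    if mu_site <= 0:
        return
    n = gametes.size
    k = rng.poisson(n * mu_site)
    if k:
        flat = rng.integers(0, n, size=k)
        rows, cols = np.unravel_index(flat, gametes.shape)
        gametes[rows, cols] ^= 1


def _simulate_chromosome(config: GenomeConfig, rng: np.random.Generator) -> ChromosomeHaplotypes:
    n_sites = config.n_candidate_sites
    positions_bp = np.floor(
        (np.arange(n_sites) + 0.5) * config.chrom_length_bp / n_sites
    ).astype(np.int64)
    positions_cm = positions_bp * config.cm_per_bp
    mu_site = config.mutation_rate_per_bp * config.chrom_length_bp / n_sites

    ne0 = config.ne_at(0)
    pop = _initial_population(rng, 2 * ne0, n_sites, config.init)
    for gen in range(config.burn_in_generations):
        ne_next = config.ne_at(gen + 1)
        ne_cur = pop.shape[0] // 2
        parents = rng.integers(0, ne_cur, size=2 * ne_next)
        gametes = _gamete_batch(rng, parents, pop, positions_cm, config.chrom_length_cm)
        _mutate(rng, gametes, mu_site)
        pop = np.empty((2 * ne_next, n_sites), dtype=np.uint8)
        pop[0::2] = gametes[:ne_next]
        pop[1::2] = gametes[ne_next:]

    # Expand the final generation into the founder haplotype sample through
    # one more round of meiosis, so founders are a closed-line cross-section.
    n_out = config.n_founder_haplotypes
    ne_cur = pop.shape[0] // 2
    parents = rng.integers(0, ne_cur, size=n_out)
    founders = _gamete_batch(rng, parents, pop, positions_cm, config.chrom_length_cm)
    _mutate(rng, founders, mu_site)

    counts = founders.sum(axis=0)
    seg = (counts > 0) & (counts < n_out)
    return ChromosomeHaplotypes(
        haplotypes=np.ascontiguousarray(founders[:, seg]),
        positions_bp=positions_bp[seg],
        positions_cm=positions_cm[seg],
    )


def simulate_founders(config: GenomeConfig, min_segregating_per_chromosome: int = 1) -> HaplotypePool:
    """Simulate founder haplotypes for every chromosome.

    Deterministic given ``config.seed``: each chromosome draws from its own
    child stream so chromosomes are independently reproducible.

    Raises
    ------
    SiteShortfallError
        If any chromosome retains fewer segregating sites than
        ``min_segregating_per_chromosome``.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_chromosomes)
    pool = HaplotypePool(config=config)
    for chrom, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        chap = _simulate_chromosome(config, rng)
        if chap.n_sites < min_segregating_per_chromosome:
            raise SiteShortfallError(
                f"chromosome {chrom}: {chap.n_sites} segregating sites after burn-in, "
                f"need at least {min_segregating_per_chromosome}; increase "
                "mutation_rate_per_bp, n_candidate_sites or the effective sizes"
            )
        pool.chromosomes.append(chap)
    return pool


def draw_diploid_founders(pool: HaplotypePool, n_individuals: int, seed: int) -> list[tuple[int, int]]:
    """Pair founder haplotypes into diploid individuals without replacement.

    Returns a list of (haplotype index a, haplotype index b) pairs; the same
    pairing applies on every chromosome.
    """
    n_hap = pool.n_haplotypes
    if 2 * n_individuals > n_hap:
        raise ValueError(
            f"cannot draw {n_individuals} diploids from {n_hap} founder haplotypes"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_hap)[: 2 * n_individuals]
    return [(int(order[2 * i]), int(order[2 * i + 1])) for i in range(n_individuals)]


def write_haplotype_matrix(pool: HaplotypePool, path) -> None:
    """Plain whitespace matrix export: rows = haplotypes, columns = sites."""
    full = np.hstack([c.haplotypes for c in pool.chromosomes])
    np.savetxt(path, full, fmt="%d")


def write_vcf(pool: HaplotypePool, path) -> None:
    """Phased-GT VCF export, one contig per chromosome, haplotypes paired 2i/2i+1."""
    n_hap = pool.n_haplotypes
    samples = [f"F{i:04d}" for i in range(n_hap // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cunigs-founder-genome\n")
        for i, c in enumerate(pool.chromosomes):
            fh.write(f"##contig=<ID=chr{i + 1},length={int(pool.config.chrom_length_bp)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i, c in enumerate(pool.chromosomes):
            hap = c.haplotypes
            for j in range(c.n_sites):
                gts = "\t".join(
                    f"{hap[2 * k, j]}|{hap[2 * k + 1, j]}" for k in range(n_hap // 2)
                )
                fh.write(
                    f"chr{i + 1}\t{int(c.positions_bp[j]) + 1}\tchr{i + 1}_{j}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
                )
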