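"""Genetic architecture of litter size: QTN positions, effects, variances.

The trait is strictly additive.  QTNs are drawn at random from the
segregating founder sites, an equal number per chromosome (QTN_5 and QTN_44
architectures use 5 and 44 per chromosome).  Absolute effect sizes follow a
Gamma(shape 0.60, scale 0.80) distribution with random +/- signs; effects
are then rescaled by a single constant so the variance of true breeding
values over the founder diploids equals the base additive variance
(0.675).  Residual variance follows from the heritability (0.113):
``sigma2_e = sigma2_a * (1 - h2) / h2``.

Litter size is sex-limited: only does receive phenotypic records, one
record per doe, ``y = mu + TBV + N(0, sigma2_e)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .founder_genome import HaplotypePool

__all__ = ["TraitArchitecture", "sample_qtns", "sample_effects", "scale_variances",
           "true_breeding_value", "phenotype", "founder_qtn_dosages"]

GAMMA_SHAPE = 0.60
GAMMA_SCALE = 0.80
BASE_GENETIC_VARIANCE = 0.675
BASE_HERITABILITY = 0.113


@dataclass
class TraitArchitecture:
    qtn_per_chromosome: int
    #: per-chromosome arrays of site indices into the pool's segregating sites
    qtn_site_indices: list[np.ndarray]
    qtn_effects: np.ndarray | None = None  # concatenated over chromosomes
    qtn_freqs: np.ndarray | None = None  # founder allele frequencies at QTNs
    gamma_shape: float = GAMMA_SHAPE
    gamma_scale: float = GAMMA_SCALE
    target_base_variance: float = BASE_GENETIC_VARIANCE
    heritability: float = BASE_HERITABILITY
    residual_variance: float | None = None
    scaling_constant: float | None = None
    mu: float = 10.0  # arbitrary population mean, kits; only differences matter

    def __post_init__(self) -> None:
        if not 0 < self.heritability < 1:
            raise ValueError("heritability must lie strictly between 0 and 1")
        counts = {len(idx) for idx in self.qtn_site_indices}
        if counts != {self.qtn_per_chromosome}:
            raise ValueError("every chromosome must carry the same QTN count")

    @property
    def n_qtn(self) -> int:
        return self.qtn_per_chromosome * len(self.qtn_site_indices)

    @property
    def lambda_ratio(self) -> float:
        """Residual-to-additive variance ratio used in the mixed model."""
        if self.residual_variance is None:
            raise ValueError("variances not scaled yet")
        return self.residual_variance / self.target_base_variance

    def to_table(self, path) -> None:
        """Serialize (chromosome, site index, effect) as whitespace text."""
        rows = []
        k = 0
        for chrom, sites in enumerate(self.qtn_site_indices):
            for s in sites:
                eff = self.qtn_effects[k] if self.qtn_effects is not None else float("nan")
                rows.append(f"{chrom}\t{int(s)}\t{eff:.10g}")
                k += 1
        with open(path, "w") as fh:
            fh.write("chromosome\tsite_index\teffect\n")
            fh.write("\n".join(rows) + "\n")


def sample_qtns(pool: HaplotypePool, qtn_per_chromosome: int, seed: int) -> TraitArchitecture:
    """Draw QTN positions: ``qtn_per_chromosome`` random segregating sites per chromosome."""
    rng = np.random.default_rng(seed)
    indices: list[np.ndarray] = []
    for chrom, chap in enumerate(pool.chromosomes):
        if chap.n_sites < qtn_per_chromosome:
            raise ValueError(
                f"chromosome {chrom} has only {chap.n_sites} segregating sites, "
                f"cannot place {qtn_per_chromosome} QTNs"
            )
        picks = np.sort(rng.choice(chap.n_sites, size=qtn_per_chromosome, replace=False))
        indices.append(picks.astype(np.int64))
    return TraitArchitecture(qtn_per_chromosome=qtn_per_chromosome, qtn_site_indices=indices)


def sample_effects(arch: TraitArchitecture, seed: int) -> TraitArchitecture:
    """Attach signed Gamma effects: |e| ~ Gamma(0.60, 0.80), sign +/-1 with prob 1/2."""
    rng = np.random.default_rng(seed)
    mag = rng.gamma(arch.gamma_shape, arch.gamma_scale, size=arch.n_qtn)
    sign = rng.choice([-1.0, 1.0], size=arch.n_qtn)
    arch.qtn_effects = mag * sign
    return arch


def founder_qtn_dosages(pool: HaplotypePool, arch: TraitArchitecture) -> np.ndarray:
    """Dosages (n_diploids x n_qtn) of the implicit founder diploids (haplotypes 2i, 2i+1)."""
    blocks = []
    for chap, sites in zip(pool.chromosomes, arch.qtn_site_indices):
        hap = chap.haplotypes[:, sites]
        blocks.append(hap[0::2].astype(np.int16) + hap[1::2])
    return np.hstack(blocks)


def scale_variances(arch: TraitArchitecture, founder_dosages: np.ndarray) -> TraitArchitecture:
    """Rescale effects so founder TBV variance equals the base additive variance.

    Also records founder allele frequencies (the centering constants for all
    later TBV computation) and sets the residual variance from h2.
    Idempotent: a second call re-derives a scaling constant of 1.
    """
    if arch.qtn_effects is None:
        raise ValueError("effects must be sampled before scaling")
    freqs = founder_dosages.mean(axis=0) / 2.0
    tbv = (founder_dosages - 2.0 * freqs) @ arch.qtn_effects
    raw_var = float(np.var(tbv))
    if raw_var <= 0:
        raise ValueError(
            "founder TBV variance is zero (all QTNs fixed or all effects zero); "
            "cannot scale to the target base variance"
        )
    c = np.sqrt(arch.target_base_variance / raw_var)
    arch.qtn_effects = arch.qtn_effects * c
    arch.scaling_constant = float(c)
    arch.qtn_freqs = freqs
    arch.residual_variance = arch.target_base_variance * (1 - arch.heritability) / arch.heritability
    return arch


def true_breeding_value(dosages: np.ndarray, arch: TraitArchitecture) -> np.ndarray | float:
    """Additive TBV: sum over QTNs of (dosage - 2p) * effect, p = founder frequency.

    ``dosages`` may be a single (n_qtn,) vector or an (n, n_qtn) matrix.
    """
    if arch.qtn_effects is None or arch.qtn_freqs is None:
        raise ValueError("architecture must carry scaled effects and founder frequencies")
    d = np.asarray(dosages, dtype=np.float64)
    if d.shape[-1] != arch.n_qtn:
        raise ValueError(f"expected {arch.n_qtn} QTN dosages, got {d.shape[-1]}")
    centered = d - 2.0 * arch.qtn_freqs
    out = centered @ arch.qtn_effects
    return float(out) if out.ndim == 0 else out


def phenotype(sex: str, tbv: float, arch: TraitArchitecture, rng: np.random.Generator) -> float | None:
    """One litter-size record for a doe; bucks never express the trait."""
    if sex == "M":
        return None
    if arch.residual_variance is None:
        raise ValueError("residual variance not set; call scale_variances first")
    return arch.mu + tbv + rng.normal(0.0, np.sqrt(arch.residual_variance))
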