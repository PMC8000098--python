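"""SNP panels, genotyping strategies and cost accounting.

Three nested platforms are carved out of the tracked markers: the HD panel,
an MD panel drawn at random from HD (30% of HD sites) and an LD panel drawn
at random from MD (0.3% of HD sites).  Sites are allocated per chromosome
proportionally to the HD count and panels never overlap QTNs.  The MD and
LD missing rates relative to HD are therefore 70% and 99.7%.

Each genotyping strategy assigns a platform (HD/MD/LD or none) to the five
pedigree roles of the last three generations — grand-dams, grand-sires,
dams, sires and candidate does.  Observed genotypes are exact gene-drop
dosages (no genotyping-error model); everything else is missing.

Costs are flat per animal: the platform price (EUR 9600 / 4800 / 1056) over
its 96 chips, i.e. EUR 100 / 50 / 11 per animal for HD / MD / LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .breeding_program import GenomeStore, Pedigree

__all__ = [
    "MarkerPanel",
    "ScenarioSpec",
    "CostTable",
    "GenotypeMatrix",
    "SCENARIO_IDS",
    "build_panels",
    "scenario",
    "assign_roles",
    "apply_scenario",
    "scenario_cost",
    "DEFAULT_ROLE_COUNTS",
]

MISSING = -1

SCENARIO_IDS = ("S1", "S2", "S3", "S3_A", "S4", "S5", "S6", "S7", "BLUP")

ROLES = ("grand_dams", "grand_sires", "dams", "sires", "progeny")

DEFAULT_ROLE_COUNTS = {
    "grand_dams": 150, "grand_sires": 35, "dams": 150, "sires": 35, "progeny": 1500,
}


@dataclass
class MarkerPanel:
    """Nested marker panels in global tracked-column coordinates."""

    hd_by_chrom: list[np.ndarray]
    md_by_chrom: list[np.ndarray]
    ld_by_chrom: list[np.ndarray]
    md_fraction: float = 0.30
    ld_fraction: float = 0.003

    def __post_init__(self) -> None:
        for md, hd in zip(self.md_by_chrom, self.hd_by_chrom):
            if not np.isin(md, hd).all():
                raise ValueError("MD panel must nest inside HD")
        for ld, md in zip(self.ld_by_chrom, self.md_by_chrom):
            if not np.isin(ld, md).all():
                raise ValueError("LD panel must nest inside MD")
        self.hd_sites = np.concatenate(self.hd_by_chrom)
        self.md_sites = np.concatenate(self.md_by_chrom)
        self.ld_sites = np.concatenate(self.ld_by_chrom)

    def sites(self, platform: str) -> np.ndarray:
        return {"HD": self.hd_sites, "MD": self.md_sites, "LD": self.ld_sites}[platform]

    def missing_rate(self, platform: str) -> float:
        """Fraction of HD sites not covered by the given platform."""
        return 1.0 - len(self.sites(platform)) / len(self.hd_sites)

    def hd_local(self, platform: str) -> np.ndarray:
        """Indices of a platform's sites within the HD panel ordering."""
        lookup = {int(s): k for k, s in enumerate(self.hd_sites)}
        return np.array([lookup[int(s)] for s in self.sites(platform)], dtype=np.int64)


def build_panels(
    segregating_per_chrom: list[np.ndarray],
    hd_per_chromosome: int,
    qtn_site_indices: list[np.ndarray],
    seed: int,
    md_fraction: float = 0.30,
    ld_fraction: float = 0.003,
    col_offsets: list[int] | None = None,
) -> MarkerPanel:
    """Draw nested HD ⊃ MD ⊃ LD panels per chromosome, avoiding QTN sites.

    ``segregating_per_chrom`` lists the eligible site indices per chromosome
    (local coordinates); ``col_offsets`` maps them to global tracked columns
    (defaults to cumulative chromosome sizes of the provided lists).
    """
    if not 0 < ld_fraction <= md_fraction <= 1:
        raise ValueError("need 0 < ld_fraction <= md_fraction <= 1 (nested panels)")
    rng = np.random.default_rng(seed)
    n_md = int(round(md_fraction * hd_per_chromosome))
    n_ld = max(1, int(round(ld_fraction * hd_per_chromosome)))
    hd_by, md_by, ld_by = [], [], []
    offset = 0
    for chrom, (sites, qtns) in enumerate(zip(segregating_per_chrom, qtn_site_indices)):
        eligible = np.setdiff1d(np.asarray(sites), np.asarray(qtns))
        if len(eligible) < hd_per_chromosome:
            raise ValueError(
                f"chromosome {chrom}: {len(eligible)} non-QTN segregating sites, "
                f"need {hd_per_chromosome} for the HD panel"
            )
        base = col_offsets[chrom] if col_offsets is not None else offset
        hd = np.sort(rng.choice(eligible, size=hd_per_chromosome, replace=False)) + base
        md = np.sort(rng.choice(hd, size=n_md, replace=False))
        ld = np.sort(rng.choice(md, size=n_ld, replace=False))
        hd_by.append(hd)
        md_by.append(md)
        ld_by.append(ld)
        offset += len(sites)
    return MarkerPanel(hd_by, md_by, ld_by, md_fraction=md_fraction, ld_fraction=ld_fraction)


@dataclass
class ScenarioSpec:
    scenario_id: str
    platforms: dict[str, str]  # role -> HD | MD | LD | NG
    progeny_split: float = 1.0  # fraction of candidate does genotyped
    whole_genome_for_ungenotyped: bool = False  # S3_A: NG half gets whole-genome copies
    female_ancestor_genotypes_used_in_g: bool = True
    parent_average_for_ungenotyped: bool = False  # S3: NG half ranked on parent-average EBV

    def __post_init__(self) -> None:
        if self.platforms.get("grand_sires", "HD") != "HD" or self.platforms.get("sires", "HD") != "HD":
            if self.scenario_id != "BLUP":
                raise ValueError("grand-sires and sires are always HD-genotyped")


_STRATEGY_TABLE = {
    # id: (grand_dams, dams, progeny, split, whole_genome, females_in_G, parent_avg)
    "S1": ("HD", "HD", "MD", 1.0, False, True, False),
    "S2": ("HD", "HD", "LD", 1.0, False, True, False),
    "S3": ("MD", "HD", "LD", 0.5, False, False, True),
    "S3_A": ("MD", "HD", "LD", 0.5, True, False, False),
    "S4": ("MD", "MD", "LD", 1.0, False, False, False),
    "S5": ("LD", "LD", "LD", 1.0, False, False, False),
    "S6": ("NG", "MD", "LD", 1.0, False, False, False),
    "S7": ("NG", "NG", "LD", 1.0, False, False, False),
}


def scenario(scenario_id: str) -> ScenarioSpec:
    """The genotyping strategy table, one spec per scenario id."""
    if scenario_id == "BLUP":
        return ScenarioSpec(
            "BLUP",
            {r: "NG" for r in ROLES},
            progeny_split=0.0,
            female_ancestor_genotypes_used_in_g=False,
        )
    if scenario_id not in _STRATEGY_TABLE:
        raise ValueError(f"unknown scenario id {scenario_id!r}")
    gd, dams, prog, split, wg, fem_g, pavg = _STRATEGY_TABLE[scenario_id]
    return ScenarioSpec(
        scenario_id,
        {"grand_dams": gd, "grand_sires": "HD", "dams": dams, "sires": "HD", "progeny": prog},
        progeny_split=split,
        whole_genome_for_ungenotyped=wg,
        female_ancestor_genotypes_used_in_g=fem_g,
        parent_average_for_ungenotyped=pavg,
    )


def assign_roles(pedigree: Pedigree, candidate_generation: int | None = None) -> dict[str, list[int]]:
    """Resolve the genotyping roles from the pedigree's last three generations.

    Grand-dams/dams are the full female cohorts two and one generation before
    the candidates; grand-sires/sires are the actual sires of the dam and
    candidate cohorts.  Candidates are the does of the final generation
    (males are never genotyped).
    """
    gen = candidate_generation or max(pedigree.cohorts)
    return {
        "grand_dams": pedigree.females(gen - 2),
        "grand_sires": pedigree.sires_of(gen - 1),
        "dams": pedigree.females(gen - 1),
        "sires": pedigree.sires_of(gen),
        "progeny": pedigree.females(gen),
    }


@dataclass
class GenotypeMatrix:
    """Masked dosages over the HD panel; MISSING (-1) marks untyped entries."""

    ids: list[int]
    sites: np.ndarray  # global tracked columns (the HD panel)
    dosages: np.ndarray  # (n_ids, n_sites) int8, values {0,1,2,MISSING}
    roles: dict[int, str] = field(default_factory=dict)
    platform_of: dict[int, str] = field(default_factory=dict)

    def row(self, iid: int) -> np.ndarray:
        return self.dosages[self.ids.index(iid)]

    def typed_mask(self) -> np.ndarray:
        return self.dosages != MISSING


def apply_scenario(
    spec: ScenarioSpec,
    pedigree: Pedigree,
    panel: MarkerPanel,
    store: GenomeStore,
    seed: int,
    candidate_generation: int | None = None,
) -> GenotypeMatrix:
    """Mask true gene-drop dosages according to the scenario's role platforms.

    The half-cohort split of S3 / S3_A is drawn from ``seed`` alone, so the
    two scenarios share the identical genotyped half within a replicate.
    """
    roles = assign_roles(pedigree, candidate_generation)
    hd = panel.hd_sites
    ids: list[int] = []
    role_of: dict[int, str] = {}
    platform_of: dict[int, str] = {}
    for role in ROLES:
        platform = spec.platforms[role]
        members = roles[role]
        if role == "progeny" and spec.progeny_split < 1.0:
            rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
            n_typed = int(round(spec.progeny_split * len(members)))
            typed = set(np.array(sorted(members))[rng.permutation(len(members))[:n_typed]].tolist())
        else:
            typed = set(members)
        for iid in members:
            if iid in role_of:  # a sire can also be a grand-sire; keep denser typing
                continue
            ids.append(iid)
            role_of[iid] = role
            if platform == "NG" or (role == "progeny" and iid not in typed):
                platform_of[iid] = "NG"
            else:
                platform_of[iid] = platform
    dosages = np.full((len(ids), len(hd)), MISSING, dtype=np.int8)
    local = {p: panel.hd_local(p) for p in ("HD", "MD", "LD")}
    true_d = store.dosages(ids, cols=hd)
    for k, iid in enumerate(ids):
        p = platform_of[iid]
        if p == "NG":
            continue
        cols = local[p]
        dosages[k, cols] = true_d[k, cols]
    return GenotypeMatrix(ids=ids, sites=hd, dosages=dosages, roles=role_of, platform_of=platform_of)


def write_dosage_matrix(gm: GenotypeMatrix, path) -> None:
    """Whitespace dosage matrix, one row per animal; MISSING stays -1."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"s{int(s)}" for s in gm.sites) + "\n")
        for k, iid in enumerate(gm.ids):
            fh.write(str(iid) + "\t" + "\t".join(map(str, gm.dosages[k])) + "\n")


def write_vcf(gm: GenotypeMatrix, path, contig_of=None) -> None:
    """Unphased-GT VCF of the masked dosages; missing entries become ./."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=cunigs-genotyping-scenarios\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"A{iid}" for iid in gm.ids) + "\n"
        )
        for j, site in enumerate(gm.sites):
            chrom = contig_of(site) if contig_of else "chr1"
            calls = "\t".join(gt[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{chrom}\t{int(site) + 1}\tsite{int(site)}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n")


@dataclass
class CostTable:
    platform_price: dict[str, float] = field(
        default_factory=lambda: {"HD": 9600.0, "MD": 4800.0, "LD": 1056.0}
    )
    chips_per_platform: int = 96

    @property
    def per_animal(self) -> dict[str, float]:
        out = {p: price / self.chips_per_platform for p, price in self.platform_price.items()}
        out["NG"] = 0.0
        return out


def scenario_cost(
    spec: ScenarioSpec,
    role_counts: dict[str, int] | None = None,
    cost_table: CostTable | None = None,
) -> float:
    """Total genotyping spend (EUR) over the last three generations."""
    counts = dict(DEFAULT_ROLE_COUNTS if role_counts is None else role_counts)
    table = (cost_table or CostTable()).per_animal
    total = 0.0
    for role in ROLES:
        platform = spec.platforms[role]
        n = counts[role]
        if role == "progeny":
            n = n * spec.progeny_split
        total += n * table[platform]
    return total
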