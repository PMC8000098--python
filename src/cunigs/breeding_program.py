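"""Maternal-line breeding scheme with gene-drop meiosis.

The program mirrors a small-nucleus rabbit line selected for litter size:

* generation 1: foundation from founder haplotypes (138 does, 77 sires);
* generations 2-6: random mating at constant size;
* generations 7-26: truncation selection on EBVs from a pedigree-BLUP
  callback — top 70 does and top 35 sires of each 150 F + 150 M cohort;
* generations 27-28 (genomic phase): all 150 does of the cohort serve as
  dams together with the top 35 sires; generation 27 is another
  150 F + 150 M cohort and generation 28 is the candidate cohort of
  1500 does + 1500 males (10 F + 10 M kits per dam).

Meiosis is a gene drop without interference: per chromosome the crossover
count is Poisson(length_cM / 100) with crossover positions uniform on the
cM map, and no new mutation.  True breeding values are computed at birth
from QTN dosages; every doe receives one phenotypic record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trait_architecture import TraitArchitecture, true_breeding_value

__all__ = [
    "SchemeConfig",
    "Individual",
    "Pedigree",
    "TrackedGenome",
    "GenomeStore",
    "meiosis",
    "mate",
    "run_program",
    "select_top",
]

UNKNOWN = 0


@dataclass
class SchemeConfig:
    base_does: int = 138
    base_sires: int = 77
    selected_does_per_gen: int = 70
    selected_sires_per_gen: int = 35
    cohort_females: int = 150
    cohort_males: int = 150
    blup_generations: int = 20
    genomic_generations: int = 2
    final_females: int = 1500
    final_males: int = 1500
    random_mating_generations: int = 5

    def __post_init__(self) -> None:
        if self.selected_does_per_gen > min(self.base_does, self.cohort_females):
            raise ValueError("cannot select more does than the cohort carries")
        if self.selected_sires_per_gen > min(self.base_sires, self.cohort_males):
            raise ValueError("cannot select more sires than the cohort carries")
        if self.final_females % self.cohort_females or self.final_males % self.cohort_females:
            raise ValueError("final cohort must split evenly over the dam cohort")

    @property
    def last_generation(self) -> int:
        # foundation (1) + random mating + BLUP + genomic phase
        return 1 + self.random_mating_generations + self.blup_generations + self.genomic_generations


@dataclass
class Individual:
    id: int
    sire_id: int
    dam_id: int
    sex: str  # "F" or "M"
    generation: int
    tbv: float
    phenotype: float | None


class Pedigree:
    """Topologically ordered individuals with per-generation cohort index."""

    def __init__(self) -> None:
        self.individuals: list[Individual] = []
        self.by_id: dict[int, Individual] = {}
        self.cohorts: dict[int, list[int]] = {}

    def add(self, ind: Individual) -> None:
        for pid in (ind.sire_id, ind.dam_id):
            if pid != UNKNOWN:
                parent = self.by_id.get(pid)
                if parent is None:
                    raise ValueError(f"parent {pid} of {ind.id} not in pedigree")
                if parent.generation >= ind.generation:
                    raise ValueError(
                        f"parent {pid} (gen {parent.generation}) not older than "
                        f"offspring {ind.id} (gen {ind.generation})"
                    )
        self.individuals.append(ind)
        self.by_id[ind.id] = ind
        self.cohorts.setdefault(ind.generation, []).append(ind.id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: int) -> bool:
        return iid in self.by_id

    def cohort(self, generation: int) -> list[int]:
        return self.cohorts.get(generation, [])

    def females(self, generation: int) -> list[int]:
        return [i for i in self.cohort(generation) if self.by_id[i].sex == "F"]

    def males(self, generation: int) -> list[int]:
        return [i for i in self.cohort(generation) if self.by_id[i].sex == "M"]

    def sires_of(self, generation: int) -> list[int]:
        """Distinct sires of the given cohort, in id order."""
        return sorted({self.by_id[i].sire_id for i in self.cohort(generation)} - {UNKNOWN})

    def dams_of(self, generation: int) -> list[int]:
        return sorted({self.by_id[i].dam_id for i in self.cohort(generation)} - {UNKNOWN})

    def subset_ids(self, generations: set[int]) -> list[int]:
        return [i.id for i in self.individuals if i.generation in generations]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "sire": [i.sire_id for i in self.individuals],
                "dam": [i.dam_id for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "generation": [i.generation for i in self.individuals],
                "tbv": [i.tbv for i in self.individuals],
                "phenotype": [i.phenotype for i in self.individuals],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path)
        ped = cls()
        for row in df.itertuples(index=False):
            phen = None if pd.isna(row.phenotype) else float(row.phenotype)
            ped.add(
                Individual(
                    id=int(row.id), sire_id=int(row.sire), dam_id=int(row.dam),
                    sex=str(row.sex), generation=int(row.generation),
                    tbv=float(row.tbv), phenotype=phen,
                )
            )
        return ped


@dataclass
class TrackedGenome:
    """Genetic map of the sites carried through the gene drop (markers + QTNs)."""

    cm_positions: list[np.ndarray]  # per chromosome, ascending
    qtn_cols: np.ndarray  # global tracked columns that are QTNs

    def __post_init__(self) -> None:
        sizes = [len(p) for p in self.cm_positions]
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        self.chrom_slices = [slice(int(bounds[i]), int(bounds[i + 1])) for i in range(len(sizes))]
        self.n_sites = int(bounds[-1])
        self.chrom_lengths_cm = [float(p[-1]) if len(p) else 0.0 for p in self.cm_positions]


class GenomeStore:
    """Gamete pairs per individual over the tracked sites."""

    def __init__(self, n_sites: int) -> None:
        self.n_sites = n_sites
        self._gametes: dict[int, np.ndarray] = {}

    def set(self, iid: int, gametes: np.ndarray) -> None:
        self._gametes[iid] = gametes

    def get(self, iid: int) -> np.ndarray:
        return self._gametes[iid]

    def __contains__(self, iid: int) -> bool:
        return iid in self._gametes

    def drop(self, ids) -> None:
        for iid in ids:
            self._gametes.pop(iid, None)

    def dosages(self, ids, cols: np.ndarray | None = None) -> np.ndarray:
        """(n_ids x n_cols) allele dosages in {0,1,2}."""
        out = np.empty((len(ids), self.n_sites if cols is None else len(cols)), dtype=np.int8)
        for k, iid in enumerate(ids):
            g = self._gametes[iid]
            s = g[0].astype(np.int8) + g[1]
            out[k] = s if cols is None else s[cols]
        return out


def _meiose_batch(
    stack: np.ndarray,  # (n, 2, n_sites) parental gamete pairs
    genome: TrackedGenome,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per parental pair; vectorised Poisson crossover gene drop."""
    n = stack.shape[0]
    out = np.empty((n, genome.n_sites), dtype=np.uint8)
    for sl, cm in zip(genome.chrom_slices, genome.cm_positions):
        n_sites = sl.stop - sl.start
        if n_sites == 0:
            continue
        length_cm = cm[-1] if n_sites else 0.0
        start = rng.integers(0, 2, size=n).astype(np.int8)
        if length_cm > 0:
            n_xo = rng.poisson(length_cm / 100.0, size=n)
            switches = np.zeros((n, n_sites), dtype=np.int8)
            total = int(n_xo.sum())
            if total:
                pos = rng.uniform(0.0, length_cm, size=total)
                site_idx = np.searchsorted(cm, pos)
                gamete_idx = np.repeat(np.arange(n), n_xo)
                keep = site_idx < n_sites
                np.add.at(switches, (gamete_idx[keep], site_idx[keep]), 1)
            active = (start[:, None] + np.cumsum(switches, axis=1)) & 1
        else:
            active = np.broadcast_to(start[:, None], (n, n_sites))
        picked = np.take_along_axis(stack[:, :, sl], active[:, None, :], axis=1)
        out[:, sl] = picked[:, 0, :]
    return out


def meiosis(parent_gametes: np.ndarray, genome: TrackedGenome, rng: np.random.Generator) -> np.ndarray:
    """Single gamete from one parent's gamete pair."""
    return _meiose_batch(parent_gametes[None, :, :], genome, rng)[0]


def mate(
    dam: Individual,
    sire: Individual,
    n_offspring: int,
    arch: TraitArchitecture,
    genome: TrackedGenome,
    store: GenomeStore,
    pedigree: Pedigree,
    next_id: int,
    generation: int,
    rng: np.random.Generator,
) -> list[Individual]:
    """Produce a litter with an exact 1:1 sex ratio (females first; off-by-one if odd)."""
    if dam.sex != "F" or sire.sex != "M":
        raise ValueError("mate() requires a female dam and a male sire")
    n_f = (n_offspring + 1) // 2
    sexes = ["F"] * n_f + ["M"] * (n_offspring - n_f)
    dam_stack = np.broadcast_to(store.get(dam.id), (n_offspring, 2, genome.n_sites))
    sire_stack = np.broadcast_to(store.get(sire.id), (n_offspring, 2, genome.n_sites))
    mat = _meiose_batch(np.ascontiguousarray(dam_stack), genome, rng)
    pat = _meiose_batch(np.ascontiguousarray(sire_stack), genome, rng)
    offspring = []
    for k, sex in enumerate(sexes):
        gametes = np.stack([pat[k], mat[k]])
        dos = (gametes[0].astype(np.int8) + gametes[1])[genome.qtn_cols]
        tbv = float(true_breeding_value(dos, arch))
        phen = None
        if sex == "F":
            phen = arch.mu + tbv + rng.normal(0.0, np.sqrt(arch.residual_variance))
        ind = Individual(next_id + k, sire.id, dam.id, sex, generation, tbv, phen)
        pedigree.add(ind)
        store.set(ind.id, gametes)
        offspring.append(ind)
    return offspring


def select_top(ids, ebvs: dict[int, float], k: int) -> list[int]:
    """Top-k by EBV, ties broken by lower id."""
    if k > len(ids):
        raise ValueError(f"cannot select {k} from a cohort of {len(ids)}")
    return sorted(ids, key=lambda i: (-ebvs[i], i))[:k]


def _produce_cohort(
    dams: list[int],
    sires: list[int],
    n_f: int,
    n_m: int,
    arch: TraitArchitecture,
    genome: TrackedGenome,
    store: GenomeStore,
    ped: Pedigree,
    next_id: int,
    generation: int,
    rng: np.random.Generator,
) -> int:
    """Batch-produce a cohort: kits spread equally over dams, sires round-robin.

    Litters are interleaved F/M so the split is exactly n_f females + n_m males.
    """
    n_total = n_f + n_m
    n_dams = len(dams)
    base, extra = divmod(n_total, n_dams)
    litter_sizes = np.full(n_dams, base, dtype=int)
    if extra:
        litter_sizes[rng.choice(n_dams, size=extra, replace=False)] += 1
    sire_order = list(rng.permutation(sires))
    pairs: list[tuple[int, int]] = []
    for j, dam_id in enumerate(dams):
        sire_id = sire_order[j % len(sire_order)]
        pairs.extend([(dam_id, sire_id)] * int(litter_sizes[j]))
    dam_stack = np.stack([store.get(d) for d, _ in pairs])
    sire_stack = np.stack([store.get(s) for _, s in pairs])
    mat = _meiose_batch(dam_stack, genome, rng)
    pat = _meiose_batch(sire_stack, genome, rng)
    del dam_stack, sire_stack
    # per-litter 1:1 sexes (odd litters alternate the extra kit's sex), then
    # repair any global off-by-ones so the cohort is exactly n_f F + n_m M
    sex_list: list[str] = []
    litter_start: list[int] = []
    extra_f = True
    for s in litter_sizes:
        litter_start.append(len(sex_list))
        f = s // 2 + (1 if (s % 2 and extra_f) else 0)
        if s % 2:
            extra_f = not extra_f
        sex_list.extend(["F"] * f + ["M"] * (s - f))
    diff = sex_list.count("F") - n_f
    i = 0
    while diff != 0 and i < n_total:
        if diff > 0 and sex_list[i] == "F":
            sex_list[i] = "M"
            diff -= 1
        elif diff < 0 and sex_list[i] == "M":
            sex_list[i] = "F"
            diff += 1
        i += 1
    sexes = np.array(sex_list)
    dosages = (pat.astype(np.int8) + mat)[:, genome.qtn_cols]
    tbvs = true_breeding_value(dosages, arch)
    noise = rng.normal(0.0, np.sqrt(arch.residual_variance), size=n_total)
    for k in range(n_total):
        sex = str(sexes[k])
        phen = float(arch.mu + tbvs[k] + noise[k]) if sex == "F" else None
        ind = Individual(next_id + k, pairs[k][1], pairs[k][0], sex, generation, float(tbvs[k]), phen)
        ped.add(ind)
        store.set(ind.id, np.stack([pat[k], mat[k]]))
    return next_id + n_total


def run_program(
    founder_pairs: list[tuple[int, int]],
    founder_haplotypes: np.ndarray,
    genome: TrackedGenome,
    arch: TraitArchitecture,
    scheme: SchemeConfig,
    evaluator,
    seed: int,
    keep_gametes_from: int | None = None,
) -> tuple[Pedigree, GenomeStore, pd.DataFrame]:
    """Run the full scheme and return pedigree, gametes and per-generation summaries.

    ``evaluator(pedigree, generation)`` must return an EBV per animal of the
    given cohort; it drives every truncation-selection step.  With
    ``keep_gametes_from`` set, gamete vectors of generations that no longer
    contribute to future matings and predate that generation are released to
    bound memory; pedigree, TBVs and phenotypes are always retained.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ped = Pedigree()
    store = GenomeStore(genome.n_sites)
    n_founders = scheme.base_does + scheme.base_sires
    if len(founder_pairs) < n_founders:
        raise ValueError("not enough founder diploids for the foundation cohort")

    next_id = 1
    for k in range(n_founders):
        a, b = founder_pairs[k]
        gametes = np.stack([founder_haplotypes[a], founder_haplotypes[b]]).astype(np.uint8)
        dos = (gametes[0].astype(np.int8) + gametes[1])[genome.qtn_cols]
        tbv = float(true_breeding_value(dos, arch))
        sex = "F" if k < scheme.base_does else "M"
        phen = None
        if sex == "F":
            phen = arch.mu + tbv + rng.normal(0.0, np.sqrt(arch.residual_variance))
        ind = Individual(next_id, UNKNOWN, UNKNOWN, sex, 1, tbv, phen)
        ped.add(ind)
        store.set(next_id, gametes)
        next_id += 1

    def prune(done_generation: int) -> None:
        if keep_gametes_from is None:
            return
        stale = done_generation - 1
        if stale >= 1 and stale < keep_gametes_from:
            store.drop(ped.cohort(stale))

    gen = 1
    for _ in range(scheme.random_mating_generations):
        gen += 1
        dams = ped.females(gen - 1)
        sires = ped.males(gen - 1)
        next_id = _produce_cohort(
            dams, sires, scheme.base_does, scheme.base_sires,
            arch, genome, store, ped, next_id, gen, rng,
        )
        prune(gen)

    for _ in range(scheme.blup_generations):
        ebvs = evaluator(ped, gen)
        dams = select_top(ped.females(gen), ebvs, min(scheme.selected_does_per_gen, len(ped.females(gen))))
        sires = select_top(ped.males(gen), ebvs, min(scheme.selected_sires_per_gen, len(ped.males(gen))))
        gen += 1
        next_id = _produce_cohort(
            dams, sires, scheme.cohort_females, scheme.cohort_males,
            arch, genome, store, ped, next_id, gen, rng,
        )
        prune(gen)

    # Genomic phase: every doe of the cohort is a dam; sires still truncation-selected.
    for step in range(scheme.genomic_generations):
        ebvs = evaluator(ped, gen)
        dams = ped.females(gen)
        sires = select_top(ped.males(gen), ebvs, scheme.selected_sires_per_gen)
        last = step == scheme.genomic_generations - 1
        n_f = scheme.final_females if last else scheme.cohort_females
        n_m = scheme.final_males if last else scheme.cohort_males
        gen += 1
        next_id = _produce_cohort(
            dams, sires, n_f, n_m, arch, genome, store, ped, next_id, gen, rng,
        )
        prune(gen)

    summaries = []
    for g in sorted(ped.cohorts):
        tbvs = np.array([ped.by_id[i].tbv for i in ped.cohort(g)])
        summaries.append(
            {"generation": g, "n": len(tbvs), "mean_tbv": float(tbvs.mean()),
             "var_tbv": float(tbvs.var())}
        )
    return ped, store, pd.DataFrame(summaries)
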