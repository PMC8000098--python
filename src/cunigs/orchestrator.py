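"""End-to-end replicated experiment runs.

One replicate = founder genomes -> trait architecture -> breeding program
(pedigree-BLUP truncation selection) -> per-scenario genotype masking ->
imputation -> genetic evaluation (pedigree BLUP or ssGBLUP) -> endpoint
metrics.  All scenarios within a replicate share the identical pedigree,
true breeding values and phenotypes; only the genotyping strategy and the
evaluation differ, so accuracy differences between scenarios are purely
method effects.

Seeding: the root seed spawns one stream per (QTN model, replicate), which
spawns per-stage streams (founders, QTNs, effects, founder pairing,
program, masking).  The masking stream is shared by all scenarios of a
replicate so the half-cohort split of S3 and S3_A coincides.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genetic_evaluation as ge
from .breeding_program import Pedigree, GenomeStore, SchemeConfig, TrackedGenome, run_program
from .experiment_metrics import (
    ScenarioOutcome,
    gebv_accuracy,
    percent_correctly_selected,
    selection_response,
    summarize,
)
from .founder_genome import GenomeConfig, HaplotypePool, draw_diploid_founders, simulate_founders
from .genotyping_scenarios import (
    SCENARIO_IDS,
    MarkerPanel,
    apply_scenario,
    assign_roles,
    build_panels,
    scenario,
    scenario_cost,
)
from .imputation import genotype_yield, imputation_accuracy, impute_scenario
from .trait_architecture import (
    TraitArchitecture,
    founder_qtn_dosages,
    sample_effects,
    sample_qtns,
    scale_variances,
)

__all__ = ["ExperimentConfig", "validate_config", "load_config", "run_replicate", "run_experiment"]

log = logging.getLogger("cunigs")

QTN_MODELS = {"QTN_5": 5, "QTN_44": 44}

#: desk-scale genome: 20 chromosomes with the real map lengths and rates but
#: a reduced founder sample and tracked-site count, sized for a workstation
DESK_GENOME = dict(
    n_founder_haplotypes=600,
    n_candidate_sites=3500,
    burn_in_generations=100,
    effective_size_schedule=((0, 250), (60, 100)),
)

PAPER_GENOME = dict(
    n_founder_haplotypes=2000,
    n_candidate_sites=30000,
    burn_in_generations=400,
    effective_size_schedule=((0, 1000), (300, 150)),
)


@dataclass
class ExperimentConfig:
    scale: str = "desk"  # "desk" or "paper"
    genome: dict = field(default_factory=dict)  # GenomeConfig overrides
    scheme: dict = field(default_factory=dict)  # SchemeConfig overrides
    hd_per_chromosome: int = 1000
    md_fraction: float = 0.30
    ld_fraction: float = 0.003
    qtn_models: tuple[str, ...] = ("QTN_44",)
    scenarios: tuple[str, ...] = SCENARIO_IDS
    n_replicates: int = 4
    seed: int = 0
    out_dir: str = "results"
    eval_window_generations: int = 5
    selection_top_n: int | None = None  # defaults to the cohort doe count


def validate_config(config: ExperimentConfig | dict) -> ExperimentConfig:
    """Fill defaults, check cross-field consistency, report all errors at once."""
    if isinstance(config, dict):
        config = ExperimentConfig(**config)
    errors: list[str] = []
    if config.scale not in ("desk", "paper"):
        errors.append(f"scale must be 'desk' or 'paper', got {config.scale!r}")
    if not 0 < config.ld_fraction <= config.md_fraction <= 1:
        errors.append(
            f"panel nesting violated: need 0 < ld_fraction ({config.ld_fraction}) "
            f"<= md_fraction ({config.md_fraction}) <= 1"
        )
    unknown = set(config.qtn_models) - set(QTN_MODELS)
    if unknown:
        errors.append(f"unknown QTN models: {sorted(unknown)}")
    unknown = set(config.scenarios) - set(SCENARIO_IDS)
    if unknown:
        errors.append(f"unknown scenarios: {sorted(unknown)}")
    if config.n_replicates < 1:
        errors.append("n_replicates must be at least 1")
    if config.scale == "desk":
        if config.hd_per_chromosome > 2000:
            errors.append("desk preset caps hd_per_chromosome at 2000")
        if config.n_replicates > 8:
            errors.append("desk preset caps n_replicates at 8")
    elif config.n_replicates > 8:
        log.warning("paper-scale run with %d replicates will take a long time", config.n_replicates)
    try:
        _genome_config(config, seed=0)
    except (TypeError, ValueError) as exc:
        errors.append(f"genome: {exc}")
    try:
        _scheme_config(config)
    except (TypeError, ValueError) as exc:
        errors.append(f"scheme: {exc}")
    if errors:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(errors))
    return config


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("qtn_models", "scenarios"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return validate_config(raw)


def _genome_config(config: ExperimentConfig, seed: int) -> GenomeConfig:
    base = dict(DESK_GENOME if config.scale == "desk" else PAPER_GENOME)
    base.update(config.genome)
    sched = base.get("effective_size_schedule")
    if sched is not None:
        base["effective_size_schedule"] = tuple(tuple(e) for e in sched)
    return GenomeConfig(seed=seed, **base)


def _scheme_config(config: ExperimentConfig) -> SchemeConfig:
    return SchemeConfig(**config.scheme)


def _stage_seeds(ss: np.random.SeedSequence, n: int) -> list[int]:
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _prepare_replicate(
    config: ExperimentConfig, qtn_model: str, replicate: int
) -> tuple[Pedigree, GenomeStore, MarkerPanel, TraitArchitecture, SchemeConfig, int, np.ndarray]:
    """Founders, architecture, panels and the full breeding program."""
    scheme = _scheme_config(config)
    ss = np.random.SeedSequence((config.seed, sorted(QTN_MODELS).index(qtn_model), replicate))
    seeds = _stage_seeds(ss, 7)
    t0 = time.time()
    pool = simulate_founders(
        _genome_config(config, seed=seeds[0]),
        min_segregating_per_chromosome=config.hd_per_chromosome + QTN_MODELS[qtn_model],
    )
    log.info(
        "replicate %s/%d: founders done in %.1fs (segregating sites per chromosome: %d-%d)",
        qtn_model, replicate, time.time() - t0, min(pool.n_segregating()), max(pool.n_segregating()),
    )
    arch = sample_qtns(pool, QTN_MODELS[qtn_model], seeds[1])
    arch = sample_effects(arch, seeds[2])
    arch = scale_variances(arch, founder_qtn_dosages(pool, arch))

    n_chrom = len(pool.chromosomes)
    local_panel = build_panels(
        [np.arange(c.n_sites) for c in pool.chromosomes],
        config.hd_per_chromosome,
        arch.qtn_site_indices,
        seeds[3],
        md_fraction=config.md_fraction,
        ld_fraction=config.ld_fraction,
        col_offsets=[0] * n_chrom,
    )
    # restrict the gene drop to the sites that matter: HD panel + QTNs
    tracked_local = [
        np.union1d(local_panel.hd_by_chrom[c], arch.qtn_site_indices[c]) for c in range(n_chrom)
    ]
    offsets = np.concatenate([[0], np.cumsum([len(t) for t in tracked_local])])

    def to_global(c: int, local_idx: np.ndarray) -> np.ndarray:
        return np.searchsorted(tracked_local[c], local_idx) + offsets[c]

    panel = MarkerPanel(
        [to_global(c, local_panel.hd_by_chrom[c]) for c in range(n_chrom)],
        [to_global(c, local_panel.md_by_chrom[c]) for c in range(n_chrom)],
        [to_global(c, local_panel.ld_by_chrom[c]) for c in range(n_chrom)],
        md_fraction=config.md_fraction,
        ld_fraction=config.ld_fraction,
    )
    qtn_cols = np.concatenate([to_global(c, arch.qtn_site_indices[c]) for c in range(n_chrom)])
    genome = TrackedGenome(
        cm_positions=[pool.chromosomes[c].positions_cm[tracked_local[c]] for c in range(n_chrom)],
        qtn_cols=qtn_cols,
    )
    founder_haps = np.hstack(
        [pool.chromosomes[c].haplotypes[:, tracked_local[c]] for c in range(n_chrom)]
    )
    pairs = draw_diploid_founders(pool, scheme.base_does + scheme.base_sires, seeds[4])
    evaluator = ge.make_program_evaluator(
        arch.lambda_ratio, window_generations=config.eval_window_generations
    )
    t0 = time.time()
    ped, store, _ = run_program(
        pairs, founder_haps, genome, arch, scheme, evaluator, seeds[5],
        keep_gametes_from=scheme.last_generation - 2,
    )
    log.info("replicate %s/%d: breeding program done in %.1fs (%d animals)",
             qtn_model, replicate, time.time() - t0, len(ped))
    hd_cm = np.concatenate(genome.cm_positions)[panel.hd_sites]
    return ped, store, panel, arch, scheme, seeds[6], hd_cm


def _evaluation_frame(ped: Pedigree, scheme: SchemeConfig):
    """Pedigree / record layout shared by every scenario of a replicate."""
    last = scheme.last_generation
    gens = set(range(last - 5, last + 1))
    ids = [
        i for i in ped.subset_ids(gens)
        if not (ped.by_id[i].generation == last and ped.by_id[i].sex == "M")
    ]
    order, sire, dam = ge.pedigree_arrays(ped, ids)
    pos = {iid: k for k, iid in enumerate(order)}
    y, ridx = [], []
    for iid in order:
        ind = ped.by_id[iid]
        if ind.sex == "F" and ind.generation < last and ind.phenotype is not None:
            y.append(ind.phenotype)
            ridx.append(pos[iid])
    return order, sire, dam, pos, np.array(y), np.array(ridx)


def run_replicate(
    config: ExperimentConfig,
    qtn_model: str,
    replicate: int,
    scenarios: tuple[str, ...] | None = None,
) -> list[ScenarioOutcome]:
    """All scenario outcomes for one replicate of one QTN model."""
    scenarios = tuple(scenarios if scenarios is not None else config.scenarios)
    ped, store, panel, arch, scheme, mask_seed, hd_cm = _prepare_replicate(config, qtn_model, replicate)
    order, sire, dam, pos, y, ridx = _evaluation_frame(ped, scheme)
    lam = arch.lambda_ratio
    F = ge.inbreeding(sire, dam)
    a_inv = ge.a_inverse(sire, dam, F)
    a_full = ge.a_matrix(sire, dam)

    last = scheme.last_generation
    candidates = ped.females(last)
    tbv_of = {i: ped.by_id[i].tbv for i in candidates}
    top_n = config.selection_top_n or min(scheme.cohort_females, len(candidates))
    # cost bookkeeping follows the actual role cohort sizes of this pedigree
    role_counts = {r: len(m) for r, m in assign_roles(ped, last).items()}

    # pedigree-only baseline first: every genomic scenario reports its gain
    t0 = time.time()
    blup_out = ge.solve_mme(y, ridx, a_inv, lam, method="BLUP")
    blup_ebv = {iid: blup_out.ebv[pos[iid]] for iid in order}
    blup_acc = gebv_accuracy(
        np.array([blup_ebv[i] for i in candidates]), np.array([tbv_of[i] for i in candidates])
    )
    log.info("replicate %s/%d: BLUP evaluation in %.1fs (accuracy %.3f)",
             qtn_model, replicate, time.time() - t0, blup_acc)

    outcomes: list[ScenarioOutcome] = []
    for sid in scenarios:
        spec = scenario(sid)
        cost = scenario_cost(spec, role_counts)
        if sid == "BLUP":
            ebv_of = blup_ebv
            mean_ia = mean_yield = float("nan")
            acc = blup_acc
        else:
            t0 = time.time()
            gm = apply_scenario(spec, ped, panel, store, seed=mask_seed, candidate_generation=last)
            imp = impute_scenario(gm, ped, panel, spec, positions_cm=hd_cm)
            true_d = store.dosages(imp.ids, cols=panel.hd_sites)
            _, mean_ia, _, _ = imputation_accuracy(true_d, imp)
            _, mean_yield = genotype_yield(imp)

            geno_ids = [
                i for i in gm.ids
                if gm.roles[i] in ("grand_sires", "sires")
                or (
                    gm.roles[i] in ("grand_dams", "dams")
                    and spec.female_ancestor_genotypes_used_in_g
                    and gm.platform_of[i] == "HD"
                )
            ]
            gm_row = {iid: k for k, iid in enumerate(gm.ids)}
            rows = [gm.dosages[gm_row[i]].astype(np.float64) for i in geno_ids]
            geno_ids = geno_ids + imp.ids
            M = np.vstack(rows + [imp.dosages.astype(np.float64)])
            M_qc, kept_sites, kept_animals, _ = ge.qc_genotypes(M)
            geno_ids = [geno_ids[k] for k in kept_animals]
            g_idx = np.array([pos[i] for i in geno_ids])
            a22 = a_full[np.ix_(g_idx, g_idx)]
            G = ge.g_matrix(M_qc, a22=a22)
            h_inv = ge.h_inverse(a_inv, G, a22, g_idx)
            out = ge.solve_mme(y, ridx, h_inv, lam, method="ssGBLUP")
            ebv_of = {iid: out.ebv[pos[iid]] for iid in order}
            if spec.parent_average_for_ungenotyped:
                ng = [i for i in candidates if i not in set(imp.ids)]
                ebv_of.update(ge.parent_average_ebv(ped, ebv_of, ng))
            acc = gebv_accuracy(
                np.array([ebv_of[i] for i in candidates]), np.array([tbv_of[i] for i in candidates])
            )
            log.info("replicate %s/%d: %s in %.1fs (IA %.3f, accuracy %.3f)",
                     qtn_model, replicate, sid, time.time() - t0, mean_ia, acc)
        cand_ebv = {i: ebv_of[i] for i in candidates}
        outcomes.append(
            ScenarioOutcome(
                scenario_id=sid,
                replicate=replicate,
                qtn_model=qtn_model,
                mean_ia=mean_ia,
                mean_yield=mean_yield,
                gebv_accuracy=acc,
                accuracy_vs_blup=acc - blup_acc,
                selection_response=selection_response(candidates, cand_ebv, tbv_of, top_n),
                percent_correctly_selected=percent_correctly_selected(
                    candidates, cand_ebv, tbv_of, top_n
                ),
                cost_eur=cost,
            )
        )
    return outcomes


def run_experiment(config: ExperimentConfig | dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every (QTN model, replicate) cell and write outcome/summary tables.

    A replicate that fails in any stage is logged with the stage name and
    skipped; the remaining replicates continue.
    """
    config = validate_config(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[ScenarioOutcome] = []
    for qtn_model in config.qtn_models:
        for rep in range(config.n_replicates):
            try:
                rows.extend(run_replicate(config, qtn_model, rep))
            except Exception:
                log.exception("replicate %s/%d failed; continuing", qtn_model, rep)
    if not rows:
        raise RuntimeError("every replicate failed")
    from dataclasses import asdict

    outcomes = pd.DataFrame([asdict(o) for o in rows])
    summary = summarize(outcomes)
    outcomes.to_csv(out_dir / "outcomes.csv", index=False)
    summary.to_csv(out_dir / "summary.csv", index=False)
    costs = outcomes[["scenario_id", "cost_eur"]].drop_duplicates("scenario_id")
    costs.to_csv(out_dir / "costs.csv", index=False)
    return outcomes, summary
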