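"""Reference phasing, posterior haplotype tracking and imputation metrics."""

import numpy as np
import pytest

from cunigs.breeding_program import Individual, Pedigree
from cunigs.genotyping_scenarios import MISSING, GenotypeMatrix, apply_scenario, scenario
from cunigs.imputation import (
    NO_CALL,
    UNKNOWN,
    ImputationResult,
    PhasedSet,
    genotype_yield,
    imputation_accuracy,
    impute_individual,
    impute_scenario,
    impute_whole_genome,
    phase_reference,
)


def _mini_pedigree():
    ped = Pedigree()
    ped.add(Individual(1, 0, 0, "M", 1, 0.0, None))  # sire
    ped.add(Individual(2, 0, 0, "F", 1, 0.0, None))  # dam
    ped.add(Individual(3, 1, 2, "F", 2, 0.0, None))  # offspring
    return ped


def _gm(ids, dosages, platforms=None, roles=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    return GenotypeMatrix(
        ids=list(ids),
        sites=np.arange(dosages.shape[1]),
        dosages=dosages,
        roles=roles or {i: "dams" for i in ids},
        platform_of=platforms or {i: "HD" for i in ids},
    )


def test_homozygous_animal_fully_phased():
    ped = _mini_pedigree()
    gm = _gm([1], [[0, 2, 0, 2]])
    ps = phase_reference(gm, ped)
    np.testing.assert_array_equal(ps.haplotypes[1][0], [0, 1, 0, 1])
    np.testing.assert_array_equal(ps.haplotypes[1][1], [0, 1, 0, 1])
    assert ps.fraction_phased(1) == 1.0


def test_trio_heterozygote_phased_by_homozygous_parent():
    ped = _mini_pedigree()
    # site 0: sire 0/0, offspring het -> paternal 0, maternal 1
    # site 1: dam 2/2, offspring het -> maternal 1, paternal 0
    gm = _gm([1, 2, 3], [[0, 0], [1, 2], [1, 1]])
    ps = phase_reference(gm, ped)
    assert ps.haplotypes[3][0, 0] == 0 and ps.haplotypes[3][1, 0] == 1
    assert ps.haplotypes[3][1, 1] == 1 and ps.haplotypes[3][0, 1] == 0


def test_mendelian_conflict_drops_parent_with_warning():
    ped = _mini_pedigree()
    # opposite homozygotes everywhere: impossible parent-offspring pair
    gm = _gm([1, 3], [[0, 0, 0, 0], [2, 2, 2, 2]])
    with pytest.warns(UserWarning, match="Mendelian conflict"):
        ps = phase_reference(gm, ped)
    # offspring still phased (homozygous), parent info discarded
    assert ps.fraction_phased(3) == 1.0


def test_phased_assignments_match_gene_drop_truth(tiny_world):
    """At least 95% of phased alleles must equal the simulator's own gametes."""
    ped, store, panel = tiny_world["pedigree"], tiny_world["store"], tiny_world["panel"]
    last = tiny_world["scheme"].last_generation
    gm = apply_scenario(scenario("S1"), ped, store=store, panel=panel, seed=1,
                        candidate_generation=last)
    sizes = [len(h) for h in panel.hd_by_chrom]
    ancestors = [i for i in gm.ids if gm.roles[i] != "progeny"]
    ps = phase_reference(gm, ped, ancestors, hd_chrom_sizes=sizes)
    total = correct = 0
    for iid in ancestors:
        ind = ped.by_id[iid]
        if ind.sire_id == 0:
            continue
        truth = store.get(iid)[:, panel.hd_sites]  # row 0 paternal, row 1 maternal
        haps = ps.haplotypes[iid]
        known = haps != UNKNOWN
        total += known.sum()
        correct += (haps[known] == truth[known]).sum()
    assert total > 0
    assert correct / total >= 0.95


def test_impute_direct_inheritance_no_recombination():
    """LD-typed offspring of phased parents, zero-length map: exact recovery."""
    rng = np.random.default_rng(3)
    S = 60
    ped = _mini_pedigree()
    sire_h = rng.integers(0, 2, size=(2, S)).astype(np.int8)
    dam_h = rng.integers(0, 2, size=(2, S)).astype(np.int8)
    child_true = sire_h[0] + dam_h[1]  # transmits haplotype 0 / haplotype 1
    typed = np.zeros(S, dtype=bool)
    typed[::7] = True
    child_obs = np.where(typed, child_true, MISSING)
    gm = _gm(
        [1, 2, 3],
        [sire_h.sum(axis=0), dam_h.sum(axis=0), child_obs],
        platforms={1: "HD", 2: "HD", 3: "LD"},
    )
    ps = PhasedSet(
        haplotypes={1: sire_h.copy(), 2: dam_h.copy()},
        provenance={},
        n_sites=S,
    )
    from cunigs.genotyping_scenarios import MarkerPanel

    panel = MarkerPanel([np.arange(S)], [np.arange(S)], [np.arange(0, S, 7)])
    # a zero-recombination map: all sites at the same position
    dose = impute_individual(3, gm, ps, ped, panel, positions_cm=np.zeros(S))
    # where typed, pass-through; elsewhere posterior must lock onto the truth
    # unless both parental haplotypes are consistent with every typed site
    assert np.allclose(dose[typed], child_true[typed])
    agreement = np.mean(np.abs(dose - child_true) < 0.3)
    assert agreement > 0.9


def test_impute_unphased_parents_falls_back_to_frequencies():
    ped = _mini_pedigree()
    S = 10
    child_obs = np.full(S, MISSING, dtype=np.int8)
    gm = _gm([3], [child_obs], platforms={3: "NG"})
    from cunigs.genotyping_scenarios import MarkerPanel

    panel = MarkerPanel([np.arange(S)], [np.arange(S)], [np.arange(1)])
    freqs = np.linspace(0.1, 0.9, S).astype(np.float32)
    dose = impute_individual(3, gm, PhasedSet(n_sites=S), ped, panel, freqs=freqs)
    np.testing.assert_allclose(dose, 2 * freqs, atol=1e-5)


def test_impute_absent_animal_raises():
    ped = _mini_pedigree()
    gm = _gm([1], [[0, 1]])
    from cunigs.genotyping_scenarios import MarkerPanel

    panel = MarkerPanel([np.arange(2)], [np.arange(2)], [np.arange(1)])
    with pytest.raises(ValueError, match="absent"):
        impute_individual(99, gm, PhasedSet(n_sites=2), ped, panel, freqs=np.full(2, 0.5))


def test_pedigree_imputer_beats_frequency_fill(tiny_world):
    """Mean IA of the pedigree-aware imputer must dominate a 2p-fill baseline."""
    ped, store, panel = tiny_world["pedigree"], tiny_world["store"], tiny_world["panel"]
    hd_cm = tiny_world["hd_cm"]
    last = tiny_world["scheme"].last_generation
    spec = scenario("S2")
    gm = apply_scenario(spec, ped, panel, store, seed=5, candidate_generation=last)
    imp = impute_scenario(gm, ped, panel, spec, positions_cm=hd_cm)
    truth = store.dosages(imp.ids, cols=panel.hd_sites)
    _, mean_ia, _, _ = imputation_accuracy(truth, imp)

    ancestors = [i for i in gm.ids if gm.roles[i] != "progeny"]
    from cunigs.imputation import _reference_frequencies

    freqs = _reference_frequencies(gm, ancestors)
    base_dose = np.tile(2 * freqs, (len(imp.ids), 1)).astype(np.float32)
    typed = imp.typed_mask
    base_dose[typed] = imp.dosages[typed]
    baseline = ImputationResult(imp.ids, base_dose, imp.hard_calls, typed)
    _, mean_base, _, _ = imputation_accuracy(truth, baseline)
    assert mean_ia > mean_base


def test_whole_genome_midparent_contract():
    dose, callable_mask = impute_whole_genome(np.array([2, 1, 0]), np.array([2, 1, 2]))
    np.testing.assert_allclose(dose, [2.0, 1.0, 1.0])
    np.testing.assert_array_equal(callable_mask, [True, False, True])
    with pytest.raises(ValueError, match="missing"):
        impute_whole_genome(np.array([MISSING]), np.array([0]))


def test_whole_genome_full_sibs_identical(tiny_world):
    ped, store, panel = tiny_world["pedigree"], tiny_world["store"], tiny_world["panel"]
    hd_cm = tiny_world["hd_cm"]
    last = tiny_world["scheme"].last_generation
    spec = scenario("S3_A")
    gm = apply_scenario(spec, ped, panel, store, seed=6, candidate_generation=last)
    imp = impute_scenario(gm, ped, panel, spec, positions_cm=hd_cm)
    row = {iid: k for k, iid in enumerate(imp.ids)}
    ng = [i for i in imp.ids if gm.platform_of[i] == "NG"]
    by_litter = {}
    for i in ng:
        ind = ped.by_id[i]
        by_litter.setdefault((ind.sire_id, ind.dam_id), []).append(i)
    checked = 0
    for sibs in by_litter.values():
        for other in sibs[1:]:
            np.testing.assert_array_equal(imp.dosages[row[sibs[0]]], imp.dosages[row[other]])
            checked += 1
    assert checked > 0


def test_accuracy_trivial_and_degenerate_cases(rng):
    S = 10_000
    truth = rng.binomial(2, 0.4, size=(3, S)).astype(np.int8)
    typed = np.zeros((3, S), dtype=bool)
    typed[:, :100] = True
    perfect = truth.astype(np.float32)
    constant = np.full((3, S), 1.0, dtype=np.float32)
    noise = rng.uniform(0, 2, size=(3, S)).astype(np.float32)
    for dosages, expect in [(perfect, 1.0), (noise, 0.0)]:
        res = ImputationResult([1, 2, 3], dosages, np.zeros((3, S), np.int8), typed)
        r, mean, _, n_excl = imputation_accuracy(truth, res)
        assert n_excl == 0
        assert mean == pytest.approx(expect, abs=0.03)
    res = ImputationResult([1, 2, 3], constant, np.zeros((3, S), np.int8), typed)
    r, mean, _, n_excl = imputation_accuracy(truth, res)
    assert n_excl == 3 and np.isnan(r).all()
    full_typed = np.ones((3, S), dtype=bool)
    with pytest.raises(ValueError, match="untyped"):
        imputation_accuracy(truth, ImputationResult([1, 2, 3], perfect, np.zeros((3, S), np.int8), full_typed))


def test_genotype_yield_extremes():
    S = 20
    typed = np.zeros((2, S), dtype=bool)
    typed[:, :5] = True
    all_called = np.ones((2, S), dtype=np.int8)
    res = ImputationResult([1, 2], np.ones((2, S), np.float32), all_called, typed)
    per, mean = genotype_yield(res)
    assert mean == 1.0
    none_called = np.full((2, S), NO_CALL, dtype=np.int8)
    res = ImputationResult([1, 2], np.ones((2, S), np.float32), none_called, typed)
    per, mean = genotype_yield(res)
    assert mean == 0.0


def test_impute_scenario_deterministic(tiny_world):
    ped, store, panel = tiny_world["pedigree"], tiny_world["store"], tiny_world["panel"]
    hd_cm = tiny_world["hd_cm"]
    last = tiny_world["scheme"].last_generation
    spec = scenario("S6")
    gm = apply_scenario(spec, ped, panel, store, seed=8, candidate_generation=last)
    a = impute_scenario(gm, ped, panel, spec, positions_cm=hd_cm)
    b = impute_scenario(gm, ped, panel, spec, positions_cm=hd_cm)
    assert a.ids == b.ids
    np.testing.assert_array_equal(a.dosages, b.dosages)
    np.testing.assert_array_equal(a.hard_calls, b.hard_calls)


def test_imputed_exports(tmp_path, rng):
    S = 6
    truth = rng.binomial(2, 0.5, size=(2, S)).astype(np.int8)
    typed = np.zeros((2, S), dtype=bool)
    typed[:, 0] = True
    dosages = truth.astype(np.float32)
    dosages[0, 3] = 0.97
    from cunigs.imputation import _hard_calls, write_accuracy_table, write_imputed_vcf

    res = ImputationResult([5, 6], dosages, _hard_calls(dosages, 0.1), typed)
    vcf = tmp_path / "imp.vcf"
    write_imputed_vcf(res, np.arange(S), vcf)
    body = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
    assert len(body) == S and ":DS" not in body[0].split("\t")[8].replace("GT:DS", "")
    csv = tmp_path / "ia.csv"
    write_accuracy_table(res, truth, csv)
    rows = csv.read_text().splitlines()
    assert rows[0] == "id,accuracy,yield"
    assert rows[1].startswith("5,")
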