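"""Pedigree-based genotype imputation to the HD panel.

The imputer is a simplified hybrid of the long-range-phasing /
haplotype-library / pedigree-imputation pipeline used in livestock
genetics:

1. **Reference phasing** — animals genotyped at HD or MD are phased
   iteratively: homozygous sites are trivial; heterozygous sites are
   resolved by parental origin whenever a genotyped parent is homozygous;
   remaining heterozygotes are resolved by surrogate haplotypes (parents,
   grandparents, and the relevant parental haplotype of phased offspring)
   that share an identical-by-state stretch with the animal inside a
   chromosome window.

2. **Haplotype tracking** — which of the two parental haplotypes a
   low-density-typed animal inherited is tracked per chromosome by a
   two-state hidden-Markov chain over the animal's typed sites, one chain
   per parent: transition probabilities between adjacent typed sites follow
   the Haldane map function of their genetic distance, and emissions
   penalise haplotype alleles incompatible with the animal's homozygous
   genotypes.  The forward-backward state posterior is interpolated into
   the intervals between typed sites, and each untyped allele is imputed by
   its posterior expectation over the two parental haplotypes.  Haplotype
   alleles the phaser left unresolved, and sites of untyped parents,
   contribute the parent's expected allele dosage (its own imputed genotype
   over two) or, lacking any parental information, the reference allele
   frequency.  This returns genotype probabilities rather than forced
   haplotype calls, which is also what the accuracy metric is designed to
   score.

3. **Whole-genome imputation** — an entirely ungenotyped animal receives a
   verbatim copy of the imputed genome of its lowest-id genotyped full sib,
   emulating the sib-copying degeneracy of reference pedigree imputation
   software when asked for whole genomes: all ungenotyped full sibs of a
   litter carry identical vectors, which both depresses their individual
   accuracy (a sib's genome differs by Mendelian sampling) and plants
   duplicated rows in the genomic relationship matrix.  Lacking any
   genotyped full sib, the animal falls back to the mid-parent expected
   dosage (``impute_whole_genome``).

Fractional dosages in [0, 2] feed the genomic relationship matrix; hard
calls (within ``call_margin`` of an integer) exist only for the genotype
yield statistic.  Imputation accuracy is the per-individual Pearson
correlation between imputed and true dosages at untyped sites, averaged
over individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .breeding_program import Pedigree
from .genotyping_scenarios import MISSING, GenotypeMatrix, MarkerPanel, ScenarioSpec

__all__ = [
    "UNKNOWN",
    "NO_CALL",
    "PhasedSet",
    "ImputationResult",
    "phase_reference",
    "impute_individual",
    "impute_whole_genome",
    "impute_scenario",
    "imputation_accuracy",
    "genotype_yield",
]

UNKNOWN = -9
NO_CALL = -9

# provenance codes per phased site
PROV_UNRESOLVED = 0
PROV_HOMOZYGOTE = 1
PROV_PARENTAL = 2
PROV_SURROGATE = 3


@dataclass
class PhasedSet:
    """Phased haplotypes over the HD panel for the reference animals."""

    haplotypes: dict[int, np.ndarray] = field(default_factory=dict)  # (2, S) int8, UNKNOWN=-9
    provenance: dict[int, np.ndarray] = field(default_factory=dict)  # (S,) uint8
    n_sites: int = 0

    def __contains__(self, iid: int) -> bool:
        return iid in self.haplotypes

    def fraction_phased(self, iid: int) -> float:
        h = self.haplotypes[iid]
        return float((h != UNKNOWN).all(axis=0).mean())


def _check_mendelian(child: np.ndarray, parent: np.ndarray) -> float:
    """Fraction of co-typed sites with an opposite-homozygote conflict."""
    both = (child != MISSING) & (parent != MISSING)
    if not both.any():
        return 0.0
    c, p = child[both], parent[both]
    conflicts = ((c == 0) & (p == 2)) | ((c == 2) & (p == 0))
    return float(conflicts.mean())


def phase_reference(
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    reference_ids: list[int] | None = None,
    window: int = 50,
    conflict_threshold: float = 0.01,
    n_iterations: int = 3,
    min_surrogate_overlap: int = 6,
    hd_chrom_sizes: list[int] | None = None,
) -> PhasedSet:
    """Phase the HD/MD-genotyped reference animals.

    Parents whose genotypes conflict with the offspring at more than
    ``conflict_threshold`` of co-typed sites are warned about and ignored
    for phasing.  Haplotype 0 is paternal, haplotype 1 maternal.
    """
    S = gm.dosages.shape[1]
    row_of = {iid: k for k, iid in enumerate(gm.ids)}
    if reference_ids is None:
        reference_ids = [i for i in gm.ids if gm.platform_of.get(i) in ("HD", "MD")]
    reference_ids = [i for i in reference_ids if gm.platform_of.get(i) in ("HD", "MD")]
    # windows follow chromosome boundaries when sizes are given
    if hd_chrom_sizes is None:
        bounds = [(0, S)]
    else:
        offs = np.concatenate([[0], np.cumsum(hd_chrom_sizes)])
        bounds = [(int(offs[i]), int(offs[i + 1])) for i in range(len(hd_chrom_sizes))]

    ps = PhasedSet(n_sites=S)
    usable_parent: dict[tuple[int, int], bool] = {}

    def parent_row(iid: int, which: str) -> np.ndarray | None:
        ind = pedigree.by_id.get(iid)
        if ind is None:
            return None
        pid = ind.sire_id if which == "sire" else ind.dam_id
        if pid == 0 or pid not in row_of:
            return None
        key = (iid, pid)
        if key not in usable_parent:
            rate = _check_mendelian(gm.dosages[row_of[iid]], gm.dosages[row_of[pid]])
            if rate > conflict_threshold:
                warnings.warn(
                    f"Mendelian conflict rate {rate:.3f} between {iid} and parent {pid}; "
                    "parent treated as unknown for phasing"
                )
                usable_parent[key] = False
            else:
                usable_parent[key] = True
        return gm.dosages[row_of[pid]] if usable_parent[key] else None

    # pass 1: homozygote + parental phasing
    by_gen = sorted(reference_ids, key=lambda i: (pedigree.by_id[i].generation, i))
    for iid in by_gen:
        d = gm.dosages[row_of[iid]]
        haps = np.full((2, S), UNKNOWN, dtype=np.int8)
        prov = np.zeros(S, dtype=np.uint8)
        typed = d != MISSING
        hom = typed & (d != 1)
        haps[0, hom] = haps[1, hom] = (d[hom] // 2).astype(np.int8)
        prov[hom] = PROV_HOMOZYGOTE
        het = typed & (d == 1)
        # the conflict screen runs for every declared parent, heterozygous
        # sites or not, so impossible pairings are always reported
        sire_d = parent_row(iid, "sire")
        dam_d = parent_row(iid, "dam")
        if het.any():
            if sire_d is not None:
                inf = het & (sire_d != MISSING) & (sire_d != 1)
                haps[0, inf] = (sire_d[inf] // 2).astype(np.int8)
                haps[1, inf] = 1 - haps[0, inf]
                prov[inf] = PROV_PARENTAL
                het = het & ~inf
            if dam_d is not None:
                inf = het & (dam_d != MISSING) & (dam_d != 1)
                haps[1, inf] = (dam_d[inf] // 2).astype(np.int8)
                haps[0, inf] = 1 - haps[1, inf]
                prov[inf] = PROV_PARENTAL
        ps.haplotypes[iid] = haps
        ps.provenance[iid] = prov

    # surrogate pools: parents, grandparents, and phased offspring's
    # corresponding parental haplotype
    offspring_of: dict[int, list[tuple[int, int]]] = {}
    for iid in by_gen:
        ind = pedigree.by_id[iid]
        if ind.sire_id in ps.haplotypes:
            offspring_of.setdefault(ind.sire_id, []).append((iid, 0))
        if ind.dam_id in ps.haplotypes:
            offspring_of.setdefault(ind.dam_id, []).append((iid, 1))

    def surrogate_haps(iid: int) -> list[np.ndarray]:
        out = []
        ind = pedigree.by_id[iid]
        ancestors = []
        for pid in (ind.sire_id, ind.dam_id):
            p = pedigree.by_id.get(pid)
            if p is None:
                continue
            ancestors.append(pid)
            ancestors.extend([p.sire_id, p.dam_id])
        for aid in ancestors:
            if aid in ps.haplotypes:
                out.append(ps.haplotypes[aid][0])
                out.append(ps.haplotypes[aid][1])
        for oid, side in offspring_of.get(iid, [])[:20]:
            out.append(ps.haplotypes[oid][side])
        return out

    for _ in range(n_iterations):
        changed = 0
        for iid in by_gen:
            d = gm.dosages[row_of[iid]]
            haps = ps.haplotypes[iid]
            prov = ps.provenance[iid]
            unresolved = (d == 1) & (haps[0] == UNKNOWN)
            if not unresolved.any():
                continue
            pool = surrogate_haps(iid)
            if not pool:
                continue
            pool_m = np.stack(pool)  # (P, S)
            pool_known = pool_m != UNKNOWN
            for lo, hi in bounds:
                for start in range(lo, hi, window):
                    stop = min(start + window, hi)
                    seg = slice(start, stop)
                    un = np.flatnonzero(unresolved[seg]) + start
                    if un.size == 0:
                        continue
                    # only sites where the two haplotypes are known to differ
                    # can tell surrogates for one haplotype from the other
                    discriminating = (
                        (haps[0, seg] != UNKNOWN)
                        & (haps[1, seg] != UNKNOWN)
                        & (haps[0, seg] != haps[1, seg])
                    )
                    p_seg = pool_m[:, seg]
                    p_known = pool_known[:, seg]
                    informative = (p_known & discriminating).sum(axis=1)
                    for h in (0, 1):
                        target = haps[h, seg]
                        known = target != UNKNOWN
                        mismatch = (p_known & known & (p_seg != target)).any(axis=1)
                        use = (informative >= min_surrogate_overlap) & ~mismatch
                        if not use.any():
                            continue
                        sel = p_seg[use]
                        sel_known = p_known[use] & ~known
                        ones = (sel_known & (sel == 1)).sum(axis=0)
                        zeros = (sel_known & (sel == 0)).sum(axis=0)
                        for site in un:
                            j = site - start
                            if ones[j] == zeros[j]:
                                continue
                            allele = 1 if ones[j] > zeros[j] else 0
                            haps[h, site] = allele
                            haps[1 - h, site] = 1 - allele
                            prov[site] = PROV_SURROGATE
                            unresolved[site] = False
                            changed += 1
        if changed == 0:
            break

    # haplotype-library pass: within each window, haplotypes that are fully
    # resolved across the reference form a library; an unresolved haplotype
    # that is consistent with exactly one library segment (seen at least
    # twice) copies its remaining alleles from it
    for lo, hi in bounds:
        for start in range(lo, hi, window):
            stop = min(start + window, hi)
            seg = slice(start, stop)
            library: dict[bytes, int] = {}
            for iid in by_gen:
                for h in (0, 1):
                    s_seg = ps.haplotypes[iid][h, seg]
                    if (s_seg != UNKNOWN).all():
                        key = s_seg.tobytes()
                        library[key] = library.get(key, 0) + 1
            segments = [
                np.frombuffer(key, dtype=np.int8) for key, cnt in library.items() if cnt >= 2
            ]
            if not segments:
                continue
            lib = np.stack(segments)
            for iid in by_gen:
                d = gm.dosages[row_of[iid]]
                haps = ps.haplotypes[iid]
                prov = ps.provenance[iid]
                for h in (0, 1):
                    target = haps[h, seg]
                    unknown = target == UNKNOWN
                    if not unknown.any() or (~unknown).sum() < min_surrogate_overlap:
                        continue
                    known = ~unknown
                    consistent = (lib[:, known] == target[known]).all(axis=1)
                    if not consistent.any():
                        continue
                    cand = lib[consistent]
                    # fill only where every consistent library segment agrees
                    unanimous = (cand == cand[0]).all(axis=0)
                    idx = np.flatnonzero(unknown & unanimous) + start
                    typed_het = (d[idx] == 1)
                    take = idx[typed_het]
                    haps[h, take] = cand[0][take - start]
                    haps[1 - h, take] = 1 - cand[0][take - start]
                    prov[take] = PROV_SURROGATE
    return ps


def _haldane_switch_prob(d_cm: np.ndarray) -> np.ndarray:
    """Probability that the transmitted parental haplotype switches over d cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=np.float64) / 100.0))


def _forward_backward(
    d_typed: np.ndarray,  # (n, T) observed dosages at typed positions
    p0: np.ndarray,
    p1: np.ndarray,  # (n, T) parent haplotype alleles, UNKNOWN where unphased
    theta: np.ndarray,  # (T-1,) switch probabilities between adjacent typed sites
    emission_error: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward/backward messages of the two-state haplotype chain."""
    n, T = d_typed.shape

    def emit(p: np.ndarray) -> np.ndarray:
        # only the animal's homozygous sites identify the transmitted allele
        mismatch = ((d_typed == 0) & (p == 1)) | ((d_typed == 2) & (p == 0))
        match = ((d_typed == 0) & (p == 0)) | ((d_typed == 2) & (p == 1))
        e = np.full((n, T), 0.5, dtype=np.float32)
        e[match] = 1.0 - emission_error
        e[mismatch] = emission_error
        return e

    e = np.stack([emit(p0), emit(p1)], axis=-1)  # (n, T, 2)
    fwd = np.empty((n, T, 2), dtype=np.float32)
    bwd = np.empty((n, T, 2), dtype=np.float32)
    f = e[:, 0, :] * 0.5
    fwd[:, 0] = f / f.sum(axis=1, keepdims=True)
    for t in range(1, T):
        th = theta[t - 1]
        pred = fwd[:, t - 1] * (1 - th) + fwd[:, t - 1][:, ::-1] * th
        f = pred * e[:, t, :]
        fwd[:, t] = f / f.sum(axis=1, keepdims=True)
    b = np.full((n, 2), 0.5, dtype=np.float32)
    bwd[:, T - 1] = b
    for t in range(T - 2, -1, -1):
        th = theta[t]
        msg = bwd[:, t + 1] * e[:, t + 1, :]
        b = msg * (1 - th) + msg[:, ::-1] * th
        bwd[:, t] = b / b.sum(axis=1, keepdims=True)
    return fwd, bwd


def _posterior_expected_allele(
    d_obs: np.ndarray,  # (n, S) dosages with MISSING
    parent_haps: np.ndarray,  # (n, 2, S) int8, UNKNOWN where unphased
    fb_allele: np.ndarray,  # (n, S) expected allele where the haplotype is unresolved
    positions_cm: np.ndarray,  # (S,) map positions (per-chromosome concatenated)
    hd_chrom_sizes: list[int],
    emission_error: float,
    commit_states: bool = False,
) -> np.ndarray:
    """Posterior-expected transmitted allele per site, one hidden chain per chromosome.

    The chain state is which parental haplotype is being transmitted;
    switch probabilities follow the Haldane map function.  At each site the
    expected allele is ``gamma0 * a0 + gamma1 * a1`` with unresolved
    haplotype alleles replaced by the fallback expectation.
    """
    n, S = d_obs.shape
    out = np.empty((n, S), dtype=np.float32)
    offs = np.concatenate([[0], np.cumsum(hd_chrom_sizes)])
    typed_cols = d_obs[0] != MISSING  # callers batch animals with a common typing pattern
    for c in range(len(hd_chrom_sizes)):
        lo, hi = int(offs[c]), int(offs[c + 1])
        sl = slice(lo, hi)
        seg_len = hi - lo
        if seg_len == 0:
            continue
        cols = np.flatnonzero(typed_cols[sl]) + lo
        cm = positions_cm[sl]
        if cols.size == 0:
            gamma0 = np.full((n, seg_len), 0.5, dtype=np.float32)
        else:
            cm_typed = positions_cm[cols]
            theta = _haldane_switch_prob(np.diff(cm_typed)).astype(np.float32)
            fwd, bwd = _forward_backward(
                d_obs[:, cols], parent_haps[:, 0, cols], parent_haps[:, 1, cols],
                theta, emission_error,
            )
            # interpolate the state posterior into the gaps between typed sites
            right = np.searchsorted(cm_typed, cm, side="left")
            left = right - 1
            has_l = left >= 0
            has_r = right < cols.size
            th_l = np.where(has_l, _haldane_switch_prob(cm - cm_typed[np.clip(left, 0, None)]), 0.5).astype(np.float32)
            th_r = np.where(has_r, _haldane_switch_prob(cm_typed[np.clip(right, None, cols.size - 1)] - cm), 0.5).astype(np.float32)
            fl = fwd[:, np.clip(left, 0, None), :]
            br = bwd[:, np.clip(right, None, cols.size - 1), :]
            # message from the left anchor (its emission is inside fwd)
            Lm = np.where(
                has_l[None, :, None],
                fl * (1 - th_l)[None, :, None] + fl[:, :, ::-1] * th_l[None, :, None],
                0.5,
            )
            # message from the right anchor (emission at the anchor included)
            e_anchor = np.stack(
                [
                    _anchor_emission(d_obs, parent_haps[:, h, :], cols, emission_error)
                    for h in (0, 1)
                ],
                axis=-1,
            )  # (n, T, 2)
            br_e = br * e_anchor[:, np.clip(right, None, cols.size - 1), :]
            Rm = np.where(
                has_r[None, :, None],
                br_e * (1 - th_r)[None, :, None] + br_e[:, :, ::-1] * th_r[None, :, None],
                0.5,
            )
            g = Lm * Rm
            gamma0 = g[..., 0] / g.sum(axis=-1)
        if commit_states:
            # MAP-path commitment: reconstruct one specific haplotype mosaic
            # instead of hedging over the two parental origins
            gamma0 = (gamma0 >= 0.5).astype(np.float32)
        a0 = parent_haps[:, 0, sl].astype(np.float32)
        a1 = parent_haps[:, 1, sl].astype(np.float32)
        fb = fb_allele[:, sl]
        a0 = np.where(parent_haps[:, 0, sl] == UNKNOWN, fb, a0)
        a1 = np.where(parent_haps[:, 1, sl] == UNKNOWN, fb, a1)
        out[:, sl] = (gamma0 * a0 + (1.0 - gamma0) * a1).astype(np.float32)
    return out


def _anchor_emission(
    d_obs: np.ndarray, hap: np.ndarray, cols: np.ndarray, emission_error: float
) -> np.ndarray:
    d = d_obs[:, cols]
    p = hap[:, cols]
    mismatch = ((d == 0) & (p == 1)) | ((d == 2) & (p == 0))
    match = ((d == 0) & (p == 0)) | ((d == 2) & (p == 1))
    e = np.full(d.shape, 0.5, dtype=np.float32)
    e[match] = 1.0 - emission_error
    e[mismatch] = emission_error
    return e


def _impute_batch(
    ids: list[int],
    gm: GenotypeMatrix,
    phased: PhasedSet,
    pedigree: Pedigree,
    freqs: np.ndarray,
    hd_chrom_sizes: list[int],
    fallback: dict[int, np.ndarray],
    positions_cm: np.ndarray | None = None,
    emission_error: float = 0.01,
    commit: bool = False,
) -> np.ndarray:
    """Fractional imputed dosages for animals sharing one typing pattern.

    ``commit=True`` reconstructs committed genomes: MAP haplotype paths and
    integer genotype calls, the way a genotype file would be written.
    """
    row_of = {iid: k for k, iid in enumerate(gm.ids)}
    S = gm.dosages.shape[1]
    n = len(ids)
    if positions_cm is None:
        positions_cm = _uniform_positions(hd_chrom_sizes)
    d_obs = np.stack([gm.dosages[row_of[i]] for i in ids]).astype(np.int8)
    total = np.zeros((n, S), dtype=np.float32)
    blank = np.full((2, S), UNKNOWN, dtype=np.int8)
    for which in ("sire", "dam"):
        parent_ids = [
            getattr(pedigree.by_id[i], "sire_id" if which == "sire" else "dam_id") for i in ids
        ]
        haps = np.stack([phased.haplotypes.get(p, blank) for p in parent_ids])
        fb = np.tile(freqs.astype(np.float32), (n, 1))
        for k, pid in enumerate(parent_ids):
            if pid in fallback:
                fb[k] = fallback[pid] / 2.0
            elif pid in row_of:
                # an unphased but genotyped parent still pins its typed sites
                pd = gm.dosages[row_of[pid]]
                typed_p = pd != MISSING
                fb[k, typed_p] = pd[typed_p] / 2.0
        total += _posterior_expected_allele(
            d_obs, haps, fb, positions_cm, hd_chrom_sizes, emission_error,
            commit_states=commit,
        )
    typed = d_obs != MISSING
    total[typed] = d_obs[typed]
    total = np.clip(total, 0.0, 2.0)
    return np.rint(total).astype(np.float32) if commit else total


def _uniform_positions(hd_chrom_sizes: list[int], length_cm: float = 100.0) -> np.ndarray:
    """Fallback map: panel sites evenly spaced on ``length_cm`` per chromosome."""
    parts = [
        (np.arange(s) + 0.5) * (length_cm / s) if s else np.empty(0) for s in hd_chrom_sizes
    ]
    return np.concatenate(parts) if parts else np.empty(0)


def impute_individual(
    iid: int,
    gm: GenotypeMatrix,
    phased: PhasedSet,
    pedigree: Pedigree,
    panel: MarkerPanel,
    freqs: np.ndarray | None = None,
    fallback: dict[int, np.ndarray] | None = None,
    positions_cm: np.ndarray | None = None,
    emission_error: float = 0.01,
) -> np.ndarray:
    """Impute a single animal's dosages over the HD panel."""
    if iid not in pedigree:
        raise ValueError(f"animal {iid} absent from pedigree")
    sizes = [len(h) for h in panel.hd_by_chrom]
    if freqs is None:
        freqs = _reference_frequencies(gm)
    return _impute_batch(
        [iid], gm, phased, pedigree, freqs, sizes, fallback or {},
        positions_cm=positions_cm, emission_error=emission_error,
    )[0]


def impute_whole_genome(sire_dosage: np.ndarray, dam_dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-parent expected dosage; hard-callable only where both parents are homozygous."""
    for name, d in (("sire", sire_dosage), ("dam", dam_dosage)):
        if np.any(np.asarray(d) == MISSING):
            raise ValueError(f"{name} has missing genotypes; whole-genome imputation needs genotyped parents")
    dose = (np.asarray(sire_dosage, dtype=np.float32) + np.asarray(dam_dosage, dtype=np.float32)) / 2.0
    callable_mask = (np.asarray(sire_dosage) != 1) & (np.asarray(dam_dosage) != 1)
    return dose, callable_mask


def _reference_frequencies(gm: GenotypeMatrix, ids: list[int] | None = None) -> np.ndarray:
    rows = gm.dosages if ids is None else gm.dosages[[gm.ids.index(i) for i in ids]]
    typed = rows != MISSING
    with np.errstate(invalid="ignore"):
        p = np.where(typed, rows, 0).sum(axis=0) / np.maximum(typed.sum(axis=0), 1) / 2.0
    p[typed.sum(axis=0) == 0] = 0.5
    return p.astype(np.float32)


@dataclass
class ImputationResult:
    ids: list[int]
    dosages: np.ndarray  # (n, S) float32 in [0, 2]
    hard_calls: np.ndarray  # (n, S) int8, NO_CALL where ambiguous
    typed_mask: np.ndarray  # (n, S) bool: observed (not imputed) entries


def _hard_calls(dosages: np.ndarray, call_margin: float) -> np.ndarray:
    rounded = np.rint(dosages)
    ok = np.abs(dosages - rounded) <= call_margin
    out = np.where(ok, rounded, NO_CALL).astype(np.int8)
    return out


def impute_scenario(
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    panel: MarkerPanel,
    spec: ScenarioSpec,
    positions_cm: np.ndarray | None = None,
    window: int = 50,
    emission_error: float = 0.01,
    call_margin: float = 0.1,
    conflict_threshold: float = 0.01,
    n_phase_iterations: int = 3,
) -> ImputationResult:
    """Run the full imputation pipeline for one genotyping strategy.

    Non-HD ancestors are imputed first (in generation order) so that their
    fractional dosages can serve as fallbacks for their offspring; candidate
    does are imputed last.  In whole-genome mode the ungenotyped half of the
    candidates receives mid-parent vectors; otherwise ungenotyped candidates
    stay out of the result.
    """
    sizes = [len(h) for h in panel.hd_by_chrom]
    ancestors = [i for i in gm.ids if gm.roles[i] != "progeny"]
    candidates = [i for i in gm.ids if gm.roles[i] == "progeny"]
    ref_ids = [i for i in ancestors if gm.platform_of[i] in ("HD", "MD")]
    phased = phase_reference(
        gm, pedigree, ref_ids, window=window, conflict_threshold=conflict_threshold,
        n_iterations=n_phase_iterations, hd_chrom_sizes=sizes,
    )
    freqs = _reference_frequencies(gm, ancestors)
    fallback: dict[int, np.ndarray] = {}
    stepping = [i for i in ancestors if gm.platform_of[i] != "HD"]
    for gen in sorted({pedigree.by_id[i].generation for i in stepping}):
        group = [i for i in stepping if pedigree.by_id[i].generation == gen]
        for plat in ("MD", "LD", "NG"):
            batch = [i for i in group if gm.platform_of[i] == plat]
            if batch:
                dose = _impute_batch(
                    batch, gm, phased, pedigree, freqs, sizes, fallback,
                    positions_cm=positions_cm, emission_error=emission_error,
                )
                for k, iid in enumerate(batch):
                    fallback[iid] = dose[k]
    row_of = {iid: k for k, iid in enumerate(gm.ids)}
    typed_cand = [i for i in candidates if gm.platform_of[i] != "NG"]
    ng_cand = [i for i in candidates if gm.platform_of[i] == "NG"]
    out_ids: list[int] = []
    blocks: list[np.ndarray] = []
    if typed_cand:
        blocks.append(
            _impute_batch(
                typed_cand, gm, phased, pedigree, freqs, sizes, fallback,
                positions_cm=positions_cm, emission_error=emission_error,
            )
        )
        out_ids.extend(typed_cand)
    if ng_cand and spec.whole_genome_for_ungenotyped:
        sibs_of: dict[tuple[int, int], int] = {}
        for iid in typed_cand:
            ind = pedigree.by_id[iid]
            key = (ind.sire_id, ind.dam_id)
            if key not in sibs_of or iid < sibs_of[key]:
                sibs_of[key] = iid
        # the copied genomes are the sibs' committed reconstructions: one
        # specific haplotype mosaic per sib, written as integer calls
        donors = sorted(set(sibs_of.values()))
        committed = {}
        if donors:
            dose = _impute_batch(
                donors, gm, phased, pedigree, freqs, sizes, fallback,
                positions_cm=positions_cm, emission_error=emission_error, commit=True,
            )
            committed = {iid: dose[k] for k, iid in enumerate(donors)}
        wg = np.empty((len(ng_cand), gm.dosages.shape[1]), dtype=np.float32)
        for k, iid in enumerate(ng_cand):
            ind = pedigree.by_id[iid]
            sib = sibs_of.get((ind.sire_id, ind.dam_id))
            if sib is not None:
                wg[k] = committed[sib]
            else:
                sire_d = gm.dosages[row_of[ind.sire_id]]
                dam_d = gm.dosages[row_of[ind.dam_id]]
                wg[k], _ = impute_whole_genome(sire_d, dam_d)
        blocks.append(wg)
        out_ids.extend(ng_cand)
    dosages = np.vstack(blocks) if blocks else np.zeros((0, gm.dosages.shape[1]), dtype=np.float32)
    typed_mask = np.stack(
        [gm.dosages[row_of[i]] != MISSING for i in out_ids]
    ) if out_ids else np.zeros((0, gm.dosages.shape[1]), dtype=bool)
    return ImputationResult(
        ids=out_ids,
        dosages=dosages,
        hard_calls=_hard_calls(dosages, call_margin),
        typed_mask=typed_mask,
    )


def imputation_accuracy(
    true_dosages: np.ndarray, result: ImputationResult
) -> tuple[np.ndarray, float, float, int]:
    """Per-individual Pearson r at untyped sites, plus mean, SD and the
    count of individuals excluded for zero variance."""
    if result.typed_mask.all():
        raise ValueError("no untyped sites: imputation accuracy undefined")
    n = len(result.ids)
    r = np.full(n, np.nan)
    for k in range(n):
        un = ~result.typed_mask[k]
        x = result.dosages[k, un].astype(np.float64)
        y = true_dosages[k, un].astype(np.float64)
        if x.std() == 0 or y.std() == 0:
            continue
        r[k] = float(np.corrcoef(x, y)[0, 1])
    valid = ~np.isnan(r)
    mean = float(r[valid].mean()) if valid.any() else float("nan")
    sd = float(r[valid].std()) if valid.any() else float("nan")
    return r, mean, sd, int((~valid).sum())


def write_imputed_vcf(result: ImputationResult, sites: np.ndarray, path) -> None:
    """VCF export of imputed genotypes with a DS (dosage) FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=cunigs-imputation\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Hard call">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"A{iid}" for iid in result.ids) + "\n"
        )
        gt = {0: "0/0", 1: "0/1", 2: "1/1", NO_CALL: "./."}
        for j, site in enumerate(sites):
            calls = "\t".join(
                f"{gt[int(result.hard_calls[k, j])]}:{result.dosages[k, j]:.3f}"
                for k in range(len(result.ids))
            )
            fh.write(f"chr1\t{int(site) + 1}\tsite{int(site)}\tA\tC\t.\tPASS\t.\tGT:DS\t{calls}\n")


def write_accuracy_table(result: ImputationResult, true_dosages: np.ndarray, path) -> None:
    """Per-individual imputation accuracy and yield as CSV."""
    r, _, _, _ = imputation_accuracy(true_dosages, result)
    per_yield, _ = genotype_yield(result)
    with open(path, "w") as fh:
        fh.write("id,accuracy,yield\n")
        for k, iid in enumerate(result.ids):
            fh.write(f"{iid},{r[k]:.6f},{per_yield[k]:.6f}\n")


def genotype_yield(result: ImputationResult) -> tuple[np.ndarray, float]:
    """Fraction of untyped sites receiving a hard call, per individual and mean."""
    untyped = ~result.typed_mask
    called = (result.hard_calls != NO_CALL) & untyped
    denom = untyped.sum(axis=1)
    per_ind = np.where(denom > 0, called.sum(axis=1) / np.maximum(denom, 1), np.nan)
    valid = ~np.isnan(per_ind)
    return per_ind, float(per_ind[valid].mean()) if valid.any() else float("nan")
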