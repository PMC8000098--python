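"""Pedigree BLUP and single-step GBLUP for the animal model.

The model is ``y = 1*mu + Z*a + e`` with ``a ~ N(0, K*sigma2_a)`` where K is
the pedigree relationship matrix A (BLUP) or the combined pedigree-genomic
matrix H (ssGBLUP), and ``e ~ N(0, I*sigma2_e)``.  The mixed-model equations
are solved with the true simulation variance components (no REML step), so
``lambda = sigma2_e / sigma2_a``.

``A^-1`` uses Henderson's rules with inbreeding: the Mendelian-sampling
variance of animal i is ``d_i = 1/2 - (F_s + F_d)/4`` (with the usual
unknown-parent adjustments), and F comes from a memoised kinship recursion
(Meuwissen-Luo equivalent).  G follows VanRaden's first method,
``G0 = Z Z' / (2 * sum p_j (1 - p_j))`` on frequency-centred dosages, blended
``0.95 G0 + 0.05 A22`` for invertibility.  H^-1 adds the genotyped-block
correction ``G^-1 - A22^-1`` onto ``A^-1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .breeding_program import Pedigree

__all__ = [
    "VarianceComponents",
    "EvaluationOutput",
    "pedigree_arrays",
    "inbreeding",
    "a_inverse",
    "a_matrix",
    "g_matrix",
    "qc_genotypes",
    "h_inverse",
    "solve_mme",
    "parent_average_ebv",
    "make_program_evaluator",
]

NO_PARENT = -1


@dataclass
class VarianceComponents:
    sigma2_a: float = 0.675
    sigma2_e: float = 5.2985  # 0.675 * (1 - 0.113) / 0.113

    @property
    def lambda_ratio(self) -> float:
        return self.sigma2_e / self.sigma2_a


@dataclass
class EvaluationOutput:
    mu_hat: float
    ebv: dict[int, float]
    method: str  # "BLUP" or "ssGBLUP"


def pedigree_arrays(
    pedigree: Pedigree, ids: list[int] | None = None
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Topologically ordered id list with parent index arrays (-1 = unknown).

    Parents outside ``ids`` are treated as unknown (pedigree truncation).
    """
    if ids is None:
        ids = [ind.id for ind in pedigree.individuals]
    ids = sorted(ids, key=lambda i: (pedigree.by_id[i].generation, i))
    pos = {iid: k for k, iid in enumerate(ids)}
    sire = np.full(len(ids), NO_PARENT, dtype=np.int64)
    dam = np.full(len(ids), NO_PARENT, dtype=np.int64)
    for k, iid in enumerate(ids):
        ind = pedigree.by_id[iid]
        sire[k] = pos.get(ind.sire_id, NO_PARENT)
        dam[k] = pos.get(ind.dam_id, NO_PARENT)
    return ids, sire, dam


def inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients by memoised kinship recursion.

    Requires topological order (parents precede offspring); raises on cycles.
    """
    n = len(sire)
    if np.any(sire >= np.arange(n)) or np.any(dam >= np.arange(n)):
        raise ValueError("pedigree not topologically ordered (possible cycle)")
    F = np.zeros(n)
    memo: dict[tuple[int, int], float] = {}

    def kinship(i: int, j: int) -> float:
        if i == NO_PARENT or j == NO_PARENT:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        hit = memo.get(key)
        if hit is not None:
            return hit
        if i == j:
            val = 0.5 * (1.0 + F[i])
        else:
            val = 0.5 * (kinship(i, int(sire[j])) + kinship(i, int(dam[j])))
        memo[key] = val
        return val

    for k in range(n):
        F[k] = kinship(int(sire[k]), int(dam[k]))
    return F


def a_inverse(sire: np.ndarray, dam: np.ndarray, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with parental inbreeding."""
    n = len(sire)
    if F is None:
        F = inbreeding(sire, dam)
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = int(sire[i]), int(dam[i])
        known = [p for p in (s, d) if p != NO_PARENT]
        if len(known) == 2:
            d_i = 0.5 - 0.25 * (F[s] + F[d])
        elif len(known) == 1:
            d_i = 0.75 - 0.25 * F[known[0]]
        else:
            d_i = 1.0
        alpha = 1.0 / d_i
        rows.append(i), cols.append(i), vals.append(alpha)
        for p in known:
            rows += [i, p]
            cols += [p, i]
            vals += [-alpha / 2.0, -alpha / 2.0]
            for q in known:
                rows.append(p), cols.append(q), vals.append(alpha / 4.0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def a_matrix(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense tabular A (used for the genotyped block A22)."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = int(sire[i]), int(dam[i])
        a_sd = A[s, d] if (s != NO_PARENT and d != NO_PARENT) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        row = np.zeros(i)
        if s != NO_PARENT:
            row += 0.5 * A[s, :i]
        if d != NO_PARENT:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def g_matrix(
    dosages: np.ndarray,
    freqs: np.ndarray | None = None,
    a22: np.ndarray | None = None,
    blend_weight: float = 0.95,
) -> np.ndarray:
    """VanRaden genomic relationship matrix, optionally blended with A22.

    ``freqs`` defaults to the observed allele frequencies of the genotyped
    set.  Fractional (imputed) dosages are allowed; missing values are not.
    """
    M = np.asarray(dosages, dtype=np.float64)
    if np.any(M < 0):
        raise ValueError("dosage matrix must be complete (impute or QC first)")
    if freqs is None:
        freqs = M.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(freqs * (1.0 - freqs)))
    if denom <= 0:
        raise ValueError("sum of p(1-p) is zero: no segregating markers")
    Z = M - 2.0 * freqs
    G0 = (Z @ Z.T) / denom
    if a22 is None:
        return G0
    return blend_weight * G0 + (1.0 - blend_weight) * a22


def qc_genotypes(
    dosages: np.ndarray,
    maf_min: float = 0.05,
    site_call_rate_min: float = 0.90,
    animal_call_rate_min: float = 0.90,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Marker/animal quality control (reference-software default thresholds).

    Negative entries are treated as missing.  Returns the filtered matrix,
    the kept site and animal index arrays, and an exclusion report.
    """
    D = np.asarray(dosages, dtype=np.float64)
    missing = D < 0
    site_cr = 1.0 - missing.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(missing, 0.0, D).sum(axis=0) / np.maximum((~missing).sum(axis=0), 1) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep_sites = (maf >= maf_min) & (site_cr >= site_call_rate_min)
    animal_cr = 1.0 - missing[:, keep_sites].mean(axis=1) if keep_sites.any() else np.zeros(D.shape[0])
    keep_animals = animal_cr >= animal_call_rate_min
    report = {
        "n_sites_in": D.shape[1],
        "n_sites_removed_maf": int((maf < maf_min).sum()),
        "n_sites_removed_call_rate": int(((site_cr < site_call_rate_min) & (maf >= maf_min)).sum()),
        "n_animals_removed": int((~keep_animals).sum()),
    }
    if not keep_sites.any() or not keep_animals.any():
        raise ValueError(f"quality control removed everything: {report}")
    out = D[np.ix_(keep_animals, keep_sites)]
    return out, np.flatnonzero(keep_sites), np.flatnonzero(keep_animals), report


def h_inverse(
    a_inv: sp.spmatrix,
    G: np.ndarray,
    a22: np.ndarray,
    genotyped_idx: np.ndarray,
) -> np.ndarray:
    """Dense H^-1: A^-1 plus the genotyped-block correction G^-1 - A22^-1."""
    H = np.asarray(a_inv.todense(), dtype=np.float64)
    g_idx = np.asarray(genotyped_idx, dtype=np.int64)
    if g_idx.size == 0:
        return H
    try:
        c, low = sla.cho_factor(G)
        G_inv = sla.cho_solve((c, low), np.eye(G.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "G is singular; increase the A22 blending weight before inversion"
        ) from exc
    c, low = sla.cho_factor(a22)
    a22_inv = sla.cho_solve((c, low), np.eye(a22.shape[0]))
    H[np.ix_(g_idx, g_idx)] += G_inv - a22_inv
    return H


def solve_mme(
    y: np.ndarray,
    record_idx: np.ndarray,
    k_inv,
    lam: float,
    method: str = "BLUP",
    dense_threshold: int = 6000,
    cg_tol: float = 1e-10,
) -> EvaluationOutput:
    """Solve the single-trait animal-model mixed-model equations.

    ``record_idx`` maps each record to its animal's index in ``k_inv``.
    Uses a direct symmetric solve up to ``dense_threshold`` equations and
    preconditioned conjugate gradients above it.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    y = np.asarray(y, dtype=np.float64)
    record_idx = np.asarray(record_idx, dtype=np.int64)
    n = k_inv.shape[0]
    ztz = np.bincount(record_idx, minlength=n).astype(np.float64)
    zty = np.bincount(record_idx, weights=y, minlength=n)
    n_rec = float(len(y))
    if n_rec == 0:
        raise ValueError("no phenotypic records")

    if n + 1 <= dense_threshold:
        K = k_inv.toarray() if sp.issparse(k_inv) else np.asarray(k_inv, dtype=np.float64)
        lhs = np.empty((n + 1, n + 1))
        lhs[0, 0] = n_rec
        lhs[0, 1:] = ztz
        lhs[1:, 0] = ztz
        lhs[1:, 1:] = np.diag(ztz) + lam * K
        rhs = np.concatenate([[y.sum()], zty])
        try:
            sol = sla.solve(lhs, rhs, assume_a="sym")
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("mixed-model equations are singular") from exc
    else:
        Ksp = sp.csr_matrix(k_inv)
        top = sp.hstack([sp.csr_matrix([[n_rec]]), sp.csr_matrix(ztz[None, :])])
        bottom = sp.hstack([sp.csr_matrix(ztz[:, None]), sp.diags(ztz) + lam * Ksp])
        lhs = sp.vstack([top, bottom]).tocsr()
        rhs = np.concatenate([[y.sum()], zty])
        diag = lhs.diagonal()
        diag[diag == 0] = 1.0
        precond = sp.diags(1.0 / diag)
        sol, info = spla.cg(lhs, rhs, rtol=cg_tol, maxiter=20000, M=precond)
        if info != 0:
            raise RuntimeError(f"conjugate-gradient solver did not converge (info={info})")
    return EvaluationOutput(mu_hat=float(sol[0]), ebv=dict(enumerate(sol[1:])), method=method)


def parent_average_ebv(pedigree: Pedigree, ebvs: dict[int, float], ids: list[int]) -> dict[int, float]:
    """Mid-parent EBVs for unevaluated (e.g. ungenotyped) candidates."""
    out = {}
    for iid in ids:
        ind = pedigree.by_id[iid]
        if ind.sire_id not in ebvs or ind.dam_id not in ebvs:
            raise ValueError(f"animal {iid}: a parent has no EBV")
        out[iid] = 0.5 * (ebvs[ind.sire_id] + ebvs[ind.dam_id])
    return out


def write_ebv_csv(path, ids: list[int], output: EvaluationOutput, scenario_id: str = "") -> None:
    """EBV table: id, method, scenario, ebv (ids in k_inv order)."""
    with open(path, "w") as fh:
        fh.write("id,method,scenario,ebv\n")
        for k, iid in enumerate(ids):
            fh.write(f"{iid},{output.method},{scenario_id},{output.ebv[k]:.8g}\n")


def write_coordinate_matrix(path, matrix) -> None:
    """Dump a (sparse or dense) matrix as 'i j value' text for inspection."""
    m = sp.coo_matrix(matrix)
    with open(path, "w") as fh:
        for i, j, v in zip(m.row, m.col, m.data):
            fh.write(f"{i} {j} {v:.10g}\n")


def make_program_evaluator(lam: float, window_generations: int = 5):
    """Pedigree-BLUP callback for within-program truncation selection.

    Evaluates the cohort of ``generation`` from the records of does in the
    ``window_generations`` most recent generations, excluding the candidate
    cohort's own records (litter size cannot be observed before selection).
    """

    def evaluator(pedigree: Pedigree, generation: int) -> dict[int, float]:
        gens = set(range(max(1, generation - window_generations + 1), generation + 1))
        ids, sire, dam = pedigree_arrays(pedigree, pedigree.subset_ids(gens))
        pos = {iid: k for k, iid in enumerate(ids)}
        y, ridx = [], []
        for iid in ids:
            ind = pedigree.by_id[iid]
            if ind.phenotype is not None and ind.generation < generation:
                y.append(ind.phenotype)
                ridx.append(pos[iid])
        if not y:
            # nothing informative yet: rank on nothing (all zero EBVs)
            return {iid: 0.0 for iid in ids}
        k_inv = a_inverse(sire, dam)
        out = solve_mme(np.array(y), np.array(ridx), k_inv, lam)
        return {iid: out.ebv[k] for k, iid in enumerate(ids)}

    return evaluator
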