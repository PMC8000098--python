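"""A-inverse, G, H-inverse and mixed-model equations against dense oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from cunigs.genetic_evaluation import (
    NO_PARENT,
    VarianceComponents,
    a_inverse,
    a_matrix,
    g_matrix,
    h_inverse,
    inbreeding,
    parent_average_ebv,
    pedigree_arrays,
    qc_genotypes,
    solve_mme,
)


def _random_pedigree(n, rng, p_known=0.8):
    """Random topologically ordered pedigree with optional unknown parents."""
    sire = np.full(n, NO_PARENT, dtype=np.int64)
    dam = np.full(n, NO_PARENT, dtype=np.int64)
    for i in range(2, n):
        if rng.random() < p_known:
            sire[i], dam[i] = sorted(rng.choice(i, size=2, replace=False))
    return sire, dam


def _tabular_a_oracle(sire, dam):
    """Independent tabular relationship-matrix recursion (plain loops)."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if d >= 0:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return A


def test_inbreeding_textbook_values():
    # founders, then full sibs, then their inbred offspring
    sire = np.array([NO_PARENT, NO_PARENT, 0, 0, 2])
    dam = np.array([NO_PARENT, NO_PARENT, 1, 1, 3])
    F = inbreeding(sire, dam)
    np.testing.assert_allclose(F[:4], 0.0)
    assert F[4] == pytest.approx(0.25)


def test_inbreeding_matches_tabular_oracle(rng):
    sire, dam = _random_pedigree(40, rng)
    F = inbreeding(sire, dam)
    A = _tabular_a_oracle(sire, dam)
    np.testing.assert_allclose(F, np.diag(A) - 1.0, atol=1e-10)


def test_inbreeding_rejects_unordered_pedigree():
    with pytest.raises(ValueError, match="topologically"):
        inbreeding(np.array([1, NO_PARENT]), np.array([NO_PARENT, NO_PARENT]))


def test_a_inverse_single_founder_and_trio():
    ainv = a_inverse(np.array([NO_PARENT]), np.array([NO_PARENT]))
    np.testing.assert_allclose(ainv.toarray(), [[1.0]])
    sire = np.array([NO_PARENT, NO_PARENT, 0])
    dam = np.array([NO_PARENT, NO_PARENT, 1])
    expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
    np.testing.assert_allclose(a_inverse(sire, dam).toarray(), expected)


def test_a_inverse_inverts_tabular_a(rng):
    sire, dam = _random_pedigree(40, rng)
    A = _tabular_a_oracle(sire, dam)
    ainv = a_inverse(sire, dam).toarray()
    np.testing.assert_allclose(ainv @ A, np.eye(40), atol=1e-8)


def test_a_matrix_agrees_with_oracle(rng):
    sire, dam = _random_pedigree(30, rng)
    np.testing.assert_allclose(a_matrix(sire, dam), _tabular_a_oracle(sire, dam), atol=1e-12)


def test_g_matrix_duplicate_rows_and_loop_oracle(rng):
    M = rng.binomial(2, 0.4, size=(5, 20)).astype(float)
    M[1] = M[0]
    G = g_matrix(M)
    assert G[0, 0] == pytest.approx(G[1, 1])
    assert G[0, 1] == pytest.approx(G[0, 0])
    # brute-force double loop
    p = M.mean(axis=0) / 2
    denom = 2 * np.sum(p * (1 - p))
    Z = M - 2 * p
    expected = np.array(
        [[sum(Z[i, k] * Z[j, k] for k in range(20)) / denom for j in range(5)] for i in range(5)]
    )
    np.testing.assert_allclose(G, expected, atol=1e-10)


def test_g_matrix_degenerate_inputs():
    with pytest.raises(ValueError, match="segregating"):
        g_matrix(np.zeros((3, 4)))
    with pytest.raises(ValueError, match="complete"):
        g_matrix(np.array([[0.0, -1.0], [1.0, 2.0]]))


def test_qc_hand_countable_fixture(rng):
    n_animals, n_sites = 20, 10
    M = rng.binomial(2, 0.5, size=(n_animals, n_sites)).astype(float)
    # three sites pushed below MAF 0.05
    for s in (2, 5, 7):
        M[:, s] = 0.0
        M[0, s] = 1.0  # MAF = 1/40 = 0.025
    # one animal loses 2 of the 7 surviving sites -> call rate 5/7 < 0.9
    M[3, [0, 1]] = -1.0
    out, kept_sites, kept_animals, report = qc_genotypes(M)
    assert report["n_sites_removed_maf"] == 3
    assert report["n_animals_removed"] == 1
    assert 3 not in kept_animals
    assert set(kept_sites) == {0, 1, 3, 4, 6, 8, 9}
    assert out.shape == (19, 7)
    # a clean matrix passes untouched
    clean = rng.binomial(2, 0.5, size=(10, 6)).astype(float)
    out2, ks, ka, rep2 = qc_genotypes(clean)
    assert out2.shape == clean.shape and rep2["n_animals_removed"] == 0


def test_h_inverse_trivial_cases(rng):
    sire, dam = _random_pedigree(12, rng)
    ainv = a_inverse(sire, dam)
    # no genotyped animals
    H = h_inverse(ainv, np.empty((0, 0)), np.empty((0, 0)), np.array([], dtype=int))
    np.testing.assert_allclose(H, ainv.toarray())
    # G == A22: correction cancels exactly
    A = a_matrix(sire, dam)
    idx = np.array([5, 8, 11])
    a22 = A[np.ix_(idx, idx)]
    H = h_inverse(ainv, a22.copy(), a22, idx)
    np.testing.assert_allclose(H, ainv.toarray(), atol=1e-10)


def _dense_h_oracle(A, G, idx):
    """Partitioned-matrix identity for H (independent of h_inverse)."""
    n = A.shape[0]
    rest = np.setdiff1d(np.arange(n), idx)
    order = np.concatenate([rest, idx])
    Ao = A[np.ix_(order, order)]
    n1 = len(rest)
    A11, A12, A22 = Ao[:n1, :n1], Ao[:n1, n1:], Ao[n1:, n1:]
    A22i = np.linalg.inv(A22)
    H11 = A11 + A12 @ A22i @ (G - A22) @ A22i @ A12.T
    H12 = A12 @ A22i @ G
    Ho = np.block([[H11, H12], [H12.T, G]])
    H = np.empty_like(Ho)
    H[np.ix_(order, order)] = Ho
    return H


def test_h_inverse_mme_matches_dense_h_oracle(rng):
    """8 animals, 3 genotyped: identical solutions from H^-1 and explicit H."""
    sire = np.array([NO_PARENT, NO_PARENT, NO_PARENT, 0, 0, 2, 2, 4])
    dam = np.array([NO_PARENT, NO_PARENT, NO_PARENT, 1, 1, 3, 3, 5])
    A = a_matrix(sire, dam)
    idx = np.array([5, 6, 7])
    M = rng.binomial(2, 0.45, size=(3, 40)).astype(float)
    a22 = A[np.ix_(idx, idx)]
    G = g_matrix(M, a22=a22)
    ainv = a_inverse(sire, dam)
    Hinv = h_inverse(ainv, G, a22, idx)
    H = _dense_h_oracle(A, G, idx)
    y = rng.normal(10, 2, size=4)
    ridx = np.array([3, 4, 5, 6])
    lam = 2.0
    out1 = solve_mme(y, ridx, Hinv, lam)
    out2 = solve_mme(y, ridx, np.linalg.inv(H), lam)
    assert out1.mu_hat == pytest.approx(out2.mu_hat, abs=1e-6)
    for k in range(8):
        assert out1.ebv[k] == pytest.approx(out2.ebv[k], abs=1e-6)


def test_h_inverse_singular_g_raises(rng):
    sire, dam = _random_pedigree(6, rng)
    ainv = a_inverse(sire, dam)
    A = a_matrix(sire, dam)
    idx = np.array([3, 4, 5])
    G = np.ones((3, 3))  # rank 1: singular
    with pytest.raises(ValueError, match="singular"):
        h_inverse(ainv, G, A[np.ix_(idx, idx)], idx)


def test_solve_mme_dense_oracle_and_limits(rng):
    sire = np.array([NO_PARENT, NO_PARENT, 0, 0, 2, 2])
    dam = np.array([NO_PARENT, NO_PARENT, 1, 1, 3, 3])
    ainv = a_inverse(sire, dam)
    y = np.array([8.0, 11.0, 9.5])
    ridx = np.array([2, 3, 4])
    lam = 3.0
    out = solve_mme(y, ridx, ainv, lam)
    # independent dense assembly of the MME
    n = 6
    Z = np.zeros((3, n))
    Z[np.arange(3), ridx] = 1
    X = np.ones((3, 1))
    lhs = np.block(
        [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * ainv.toarray()]]
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    assert out.mu_hat == pytest.approx(sol[0], abs=1e-8)
    np.testing.assert_allclose([out.ebv[k] for k in range(n)], sol[1:], atol=1e-8)
    # information flows to record-free relatives
    assert out.ebv[5] != 0.0
    # infinite-shrinkage limit
    out_inf = solve_mme(y, ridx, ainv, 1e8)
    assert out_inf.mu_hat == pytest.approx(y.mean(), abs=1e-4)
    assert max(abs(v) for v in out_inf.ebv.values()) < 1e-4


def test_solve_mme_cg_matches_dense(rng):
    sire, dam = _random_pedigree(50, rng)
    ainv = a_inverse(sire, dam)
    ridx = rng.choice(50, size=30, replace=False)
    y = rng.normal(10, 2, size=30)
    dense = solve_mme(y, ridx, ainv, 4.0)
    iterative = solve_mme(y, ridx, ainv, 4.0, dense_threshold=10)
    assert dense.mu_hat == pytest.approx(iterative.mu_hat, abs=1e-6)
    for k in range(50):
        assert dense.ebv[k] == pytest.approx(iterative.ebv[k], abs=1e-6)


def test_solve_mme_input_guards(rng):
    ainv = a_inverse(np.array([NO_PARENT]), np.array([NO_PARENT]))
    with pytest.raises(ValueError, match="lambda"):
        solve_mme(np.array([1.0]), np.array([0]), ainv, 0.0)
    with pytest.raises(ValueError, match="records"):
        solve_mme(np.array([]), np.array([], dtype=int), ainv, 1.0)


def test_ssgblup_reduces_to_blup_without_genotypes(rng):
    sire, dam = _random_pedigree(25, rng)
    ainv = a_inverse(sire, dam)
    Hinv = h_inverse(ainv, np.empty((0, 0)), np.empty((0, 0)), np.array([], dtype=int))
    y = rng.normal(10, 1, size=12)
    ridx = rng.choice(25, size=12, replace=False)
    blup = solve_mme(y, ridx, ainv, 7.85)
    ss = solve_mme(y, ridx, Hinv, 7.85)
    for k in range(25):
        assert blup.ebv[k] == pytest.approx(ss.ebv[k], abs=1e-12)


def test_parent_average_ebv(tiny_world):
    ped = tiny_world["pedigree"]
    last = tiny_world["scheme"].last_generation
    kid = ped.cohort(last)[0]
    ind = ped.by_id[kid]
    ebvs = {ind.sire_id: 0.4, ind.dam_id: 0.2}
    assert parent_average_ebv(ped, ebvs, [kid])[kid] == pytest.approx(0.3)
    with pytest.raises(ValueError, match="no EBV"):
        parent_average_ebv(ped, {}, [kid])


def test_variance_components_lambda():
    vc = VarianceComponents()
    assert vc.lambda_ratio == pytest.approx((1 - 0.113) / 0.113, rel=1e-3)


def test_evaluation_exports(tmp_path, rng):
    from cunigs.genetic_evaluation import write_coordinate_matrix, write_ebv_csv

    sire = np.array([NO_PARENT, NO_PARENT, 0])
    dam = np.array([NO_PARENT, NO_PARENT, 1])
    ainv = a_inverse(sire, dam)
    out = solve_mme(np.array([9.0, 11.0]), np.array([0, 1]), ainv, 2.0)
    path = tmp_path / "ebv.csv"
    write_ebv_csv(path, [101, 102, 103], out, "S6")
    lines = path.read_text().splitlines()
    assert lines[0] == "id,method,scenario,ebv" and len(lines) == 4
    assert lines[1].startswith("101,BLUP,S6,")
    coord = tmp_path / "ainv.txt"
    write_coordinate_matrix(coord, ainv)
    i, j, v = lines_first = coord.read_text().split()[:3]
    assert float(v) != 0
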