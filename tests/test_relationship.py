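"""Relationship matrix: recursion, inverse, probabilities, gene dropping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apisim.pedigree import (
    IDENTIFIED_DPQ, OPEN_GROUP, PS_GROUP, QUEEN, WORKER_GROUP, MateEntry,
    Pedigree, PedigreeEntity,
)
from apisim.relationship import (
    EXACT_PER_MATING, GROUP_LEVEL, build_factor, gene_drop_check,
    shared_father_probs,
)
from apisim.scenarios import SCENARIOS, build_estimation


def sibling_pedigree() -> Pedigree:
    """Unrelated dam x unrelated identified DPQ; worker group; two daughters."""
    ped = Pedigree()
    ped.add(PedigreeEntity(1, QUEEN))
    ped.add(PedigreeEntity(2, QUEEN))
    ped.add(MateEntry(3, IDENTIFIED_DPQ, member_queen_id=2, S=1, D=8))
    ped.add(PedigreeEntity(4, WORKER_GROUP, dam_id=1, sire_entry_id=3))
    ped.add(PedigreeEntity(5, QUEEN, dam_id=1, sire_entry_id=3, birth_year=1))
    ped.add(PedigreeEntity(6, QUEEN, dam_id=1, sire_entry_id=3, birth_year=1))
    ped.validate()
    return ped


def test_shared_father_probs_examples():
    assert shared_father_probs(1, 8) == (0.125, 1.0)
    p_dr, p_dpq = shared_father_probs(3, 8)
    assert p_dr == pytest.approx(1 / 8)
    assert p_dpq == pytest.approx(1 / 8 + (7 / 8) / 3)
    with pytest.raises(ValueError):
        shared_father_probs(0, 8)
    with pytest.raises(ValueError):
        shared_father_probs(3, 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(S=st.integers(1, 500), D=st.integers(1, 500))
def test_shared_father_probs_properties(S, D):
    p_dr, p_dpq = shared_father_probs(S, D)
    assert 0 < p_dr <= 1 and 0 < p_dpq <= 1
    assert p_dpq >= p_dr
    assert (p_dpq == 1.0) == (S == 1 or D == 1)
    # monotone: more sisters or more drones never increase sharing
    assert shared_father_probs(S + 1, D)[1] <= p_dpq
    assert shared_father_probs(S, D + 1)[1] <= p_dpq + 1e-15


def test_worker_group_residual_formula():
    fac = build_factor(sibling_pedigree(), GROUP_LEVEL)
    wg = fac.node_of[4]
    assert fac.d[wg] == pytest.approx((2 - 1) / 32)        # 0.03125
    assert fac.adiag[wg] == pytest.approx(0.25 + 0.25 + 1 / 32)  # 0.53125


def test_same_mating_siblings_group_vs_exact():
    ped = sibling_pedigree()
    fg = build_factor(ped, GROUP_LEVEL)
    fe = build_factor(ped, EXACT_PER_MATING)
    assert fg.a(5, 6) == pytest.approx(0.5)
    assert fe.a(5, 6) == pytest.approx(0.53125)
    # the two modes differ by at most 1/(2D) on any entry
    for i in (1, 2, 4, 5, 6):
        for j in (1, 2, 4, 5, 6):
            assert abs(fg.a(i, j) - fe.a(i, j)) <= 0.5 / 8 + 1e-12


def test_open_group_self_relationship():
    ped = Pedigree()
    ped.add(MateEntry(1, OPEN_GROUP, S=100, D=8))
    fac = build_factor(ped)
    assert fac.adiag[0] == pytest.approx(0.01)
    assert np.allclose(fac.ainverse().toarray(), [[100.0]])


def test_inbreeding_from_open_group_mating():
    """A daughter of (queen x open group) has F = a(dam, group)/2 = 0."""
    ped = Pedigree()
    ped.add(PedigreeEntity(1, QUEEN))
    ped.add(MateEntry(2, OPEN_GROUP, S=100, D=8))
    ped.add(PedigreeEntity(3, QUEEN, dam_id=1, sire_entry_id=2))
    ped.add(PedigreeEntity(4, QUEEN, dam_id=3, sire_entry_id=2, birth_year=2))
    fac = build_factor(ped)
    assert fac.F[3] == 0.0
    # granddaughter via the same open group: F = a(3, group)/2 = 1/(4S)
    assert fac.F[4] == pytest.approx(0.5 * 0.5 * 0.01)
    assert np.all(fac.d[:len(ped.rows)] > 0)


def test_founder_trio_inverse_matches_dense_oracle():
    ped = Pedigree()
    ped.add(PedigreeEntity(1, QUEEN))
    ped.add(PedigreeEntity(2, QUEEN))
    ped.add(MateEntry(3, IDENTIFIED_DPQ, member_queen_id=2, S=1, D=8))
    ped.add(PedigreeEntity(4, QUEEN, dam_id=1, sire_entry_id=3))
    fac = build_factor(ped)
    A = fac.dense_A()
    assert np.allclose(fac.ainverse().toarray(), np.linalg.inv(A))


def test_single_founder_inverse():
    ped = Pedigree()
    ped.add(PedigreeEntity(1, QUEEN))
    fac = build_factor(ped)
    assert np.allclose(fac.ainverse().toarray(), [[1.0]])


def test_monotonicity_in_s_and_d():
    """Sibling relationship is non-increasing in S and D (exact mode)."""
    def sib_a(S, D):
        ped = Pedigree()
        ped.add(PedigreeEntity(1, QUEEN))
        ped.add(PedigreeEntity(2, QUEEN))
        ped.add(MateEntry(3, OPEN_GROUP, S=10, D=D))
        if S == 1:
            ped.add(PedigreeEntity(4, QUEEN, dam_id=2, sire_entry_id=3))
            ped.add(MateEntry(5, IDENTIFIED_DPQ, member_queen_id=4, S=1, D=D))
        else:
            ped.add(MateEntry(5, PS_GROUP, dpq_dam_id=2, dpq_dam_mate_id=3,
                              S=S, D=D))
        ped.add(PedigreeEntity(6, QUEEN, dam_id=1, sire_entry_id=5))
        ped.add(PedigreeEntity(7, QUEEN, dam_id=1, sire_entry_id=5))
        return build_factor(ped, EXACT_PER_MATING).a(6, 7)

    for D in (2, 8, 32):
        vals = [sib_a(S, D) for S in (1, 2, 3, 6)]
        assert np.all(np.diff(vals) < 0)
    for S in (1, 3):
        vals = [sib_a(S, D) for D in (1, 2, 8, 64)]
        assert np.all(np.diff(vals) < 0)


def test_psd_on_simulated_pedigree(toy_sim):
    est = build_estimation(toy_sim, SCENARIOS["set1_ss_psp"], 0)
    fac = build_factor(est.pedigree)
    A = fac.dense_A()
    np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))  # raises if not PSD
    assert np.all(fac.d > 0)
    # queens: a_ii = 1 + F in [1, 2]
    for qid, F in fac.F.items():
        assert 0.0 <= F < 1.0
        assert fac.adiag[fac.node_of[qid]] == pytest.approx(1.0 + F)


def test_full_replicate_inverse_probe(small_sim):
    """A @ (A^-1 x) = x on a full replicate system (matvec probes)."""
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla
    est = build_estimation(small_sim, SCENARIOS["set1_ss_ssp"], 5)
    fac = build_factor(est.pedigree)
    Ainv = fac.ainverse().tocsc()
    n = fac.n_nodes
    # A via the factor: A = (I-B)^-1 D (I-B)^-T
    rows, cols, vals = [], [], []
    for i in range(n):
        for k in range(2):
            p = fac.parents[i, k]
            if p >= 0:
                rows.append(i)
                cols.append(int(p))
                vals.append(fac.bcoef[i, k])
    ImB = sp.eye(n, format="csc") - sp.csc_matrix((vals, (rows, cols)),
                                                  shape=(n, n))
    lu = spla.splu(ImB, permc_spec="NATURAL")
    rng = np.random.default_rng(0)
    X = rng.standard_normal((n, 8))
    AX = lu.solve(fac.d[:, None] * lu.solve(X, trans="T"))
    err = np.abs(Ainv @ AX - X).max()
    assert err < 1e-6


def test_gene_drop_validates_exact_mode(oracle_pedigree):
    df = gene_drop_check(oracle_pedigree, 20_000, 123, mode=EXACT_PER_MATING)
    assert np.isfinite(df.abs_dev_se).all()
    assert df.abs_dev_se.max() < 3.0


def test_gene_drop_founder_pair_unrelated(oracle_pedigree):
    df = gene_drop_check(oracle_pedigree, 5_000, 7, pairs=[(1, 2)])
    assert df.empirical.iloc[0] == 0.0
    assert df.analytic.iloc[0] == 0.0


def test_gene_drop_single_sire_forced_sharing():
    """With one DPQ (S=1) two daughters share a father DPQ with certainty."""
    assert shared_father_probs(1, 8)[1] == 1.0
    ped = sibling_pedigree()
    df = gene_drop_check(ped, 20_000, 11, pairs=[(5, 6)],
                         mode=EXACT_PER_MATING)
    assert df.abs_dev_se.iloc[0] < 3.0
    assert df.analytic.iloc[0] == pytest.approx(0.53125)
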