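"""Mixed-model assembly and AI-REML behaviour."""

import numpy as np
import pandas as pd
import pytest

from apisim.pedigree import (
    BASE_OPEN, OPEN_GROUP, QUEEN, WORKER_GROUP, MateEntry, Pedigree,
    PedigreeEntity,
)
from apisim.relationship import build_factor
from apisim.reml import (
    REMLOptions, ai_reml, assemble_mme, build_model, reml_loglik,
)
from apisim.scenarios import SCENARIOS, EstimationData, build_estimation


def one_record_model():
    """Founder queen open-mated to a 100-member group, one colony record."""
    ped = Pedigree()
    ped.add(PedigreeEntity(1, QUEEN))
    ped.add(MateEntry(2, OPEN_GROUP, S=100, D=8))
    ped.add(PedigreeEntity(3, WORKER_GROUP, dam_id=1, sire_entry_id=2))
    ped.validate()
    rec = pd.DataFrame({
        "colony_id": [3], "queen_id": [1], "worker_group_id": [3],
        "mate_entry_id": [2], "year": [0], "open_group_label": [BASE_OPEN],
        "phenotype": [1.0]})
    est = EstimationData(scenario=None, pedigree=ped, records=rec, est_id={},
                         true_id={}, fixed_group=False, random_group=False)
    return est, build_factor(ped)


def test_assemble_mme_hand_computed():
    """The one-record system matches entries assembled by hand."""
    est, factor = one_record_model()
    spec = build_model(est, factor)
    theta = np.array([1.0, 0.0, 1.0, 1.0])
    C, rhs, r = assemble_mme(spec, theta)
    # worker Mendelian residual of the colony: d = (2 - 0.01)/32
    d = (2 - 0.01) / 32
    assert r[0] == pytest.approx(1.0 + d)
    # order: u_w(queen, group), u_q(queen, group), year mean
    lam = 1.0 / (1.0 + d)
    Ainv = np.diag([1.0, 100.0])
    row_w = np.array([0.5, 0.5])
    expect = np.zeros((5, 5))
    expect[:2, :2] = lam * np.outer(row_w, row_w) + Ainv
    expect[2:4, 2:4] = lam * np.outer([1, 0], [1, 0]) + Ainv
    expect[:2, 2:4] = lam * np.outer(row_w, [1, 0])
    expect[2:4, :2] = expect[:2, 2:4].T
    expect[4, 4] = lam
    expect[4, :2] = expect[:2, 4] = lam * row_w
    expect[4, 2:4] = expect[2:4, 4] = lam * np.array([1, 0])
    assert np.allclose(C.toarray(), expect)
    assert np.allclose(rhs, lam * np.array([0.5, 0.5, 1, 0, 1]))


def test_blup_of_zero_phenotypes_is_zero():
    est, factor = one_record_model()
    est.records.loc[:, "phenotype"] = 0.0
    spec = build_model(est, factor)
    C, rhs, _ = assemble_mme(spec, np.array([1.0, 0.0, 1.0, 1.0]))
    sol = np.linalg.solve(C.toarray(), rhs)
    assert np.allclose(sol, 0.0)


def test_record_permutation_invariance(identified_toy_model):
    est, factor, spec = identified_toy_model
    rl = reml_loglik(spec, (8.0, 1.0, 9.0, 28.0))
    shuffled = EstimationData(
        scenario=est.scenario, pedigree=est.pedigree,
        records=est.records.sample(frac=1.0, random_state=3).reset_index(drop=True),
        est_id=est.est_id, true_id=est.true_id,
        fixed_group=est.fixed_group, random_group=est.random_group)
    spec2 = build_model(shuffled, factor)
    assert reml_loglik(spec2, (8.0, 1.0, 9.0, 28.0)) == pytest.approx(rl, abs=1e-8)
    # estimates agree up to the optimizer's own localization precision
    r1 = ai_reml(spec)
    r2 = ai_reml(spec2)
    for k in r1.estimates:
        assert r1.estimates[k] == pytest.approx(r2.estimates[k], abs=5e-4)


def test_sparse_absorbed_likelihood_matches_dense(toy_model,
                                                  dense_restricted_loglik):
    """Absorbing worker groups leaves the restricted likelihood unchanged."""
    est, factor, spec = toy_model
    dense_rl = dense_restricted_loglik(est, factor)
    for theta in [(5, 0, 5, 35), (10, 1, 9, 28), (12, -3, 7, 31)]:
        assert reml_loglik(spec, theta) == pytest.approx(dense_rl(theta),
                                                         abs=1e-6)


def test_likelihood_never_decreases(toy_model):
    _, _, spec = toy_model
    res = ai_reml(spec)
    rls = [rl for _, rl in res.history]
    assert all(b >= a - 1e-8 * (1 + abs(a)) for a, b in zip(rls, rls[1:]))
    assert res.converged


def test_residual_only_reduction(toy_model):
    """With G0 pinned to ~0 the REML residual variance is the OLS one.

    The restricted likelihood as a function of var_e alone, with the genetic
    covariance floored at a negligible value, is maximized at the usual
    unbiased residual variance of the year-means model.
    """
    est, factor, spec = toy_model
    rec = est.records
    y = rec.phenotype.to_numpy(float)
    resid = y - rec.groupby("year").phenotype.transform("mean").to_numpy()
    p = rec.year.nunique()
    ols = float(resid @ resid) / (len(y) - p)
    eps = 1e-8
    ves = np.linspace(0.75 * ols, 1.3 * ols, 41)
    rls = [reml_loglik(spec, (eps, 0.0, eps, ve)) for ve in ves]
    best = ves[int(np.argmax(rls))]
    assert best == pytest.approx(ols, rel=0.02)


def test_clamped_correlation_and_boundary_flagging():
    """A degenerate tiny dataset drives the fit to the boundary: the
    correlation estimate stays clamped inside [-1, 1]."""
    from apisim.simulate import GeneticParameterSet, SchemeConfig, run_replicate
    sim = run_replicate(GeneticParameterSet.preset(1),
                        SchemeConfig(n_families=2, n_bq_per_dam=6,
                                     n_dpq_per_dam=4, n_years=2), 7)
    est = build_estimation(sim, SCENARIOS["set1_ss_ssp"], 7)
    res = ai_reml(build_model(est, build_factor(est.pedigree)))
    assert -1.0 <= res.r_wq <= 1.0


def test_zero_variance_response_rejected(toy_model):
    est, factor, _ = toy_model
    flat = EstimationData(
        scenario=est.scenario, pedigree=est.pedigree,
        records=est.records.assign(phenotype=5.0), est_id=est.est_id,
        true_id=est.true_id, fixed_group=False, random_group=False)
    with pytest.raises(ValueError, match="zero-variance"):
        ai_reml(build_model(flat, factor))


def test_ebv_table_covers_unphenotyped_queens(default_fit, default_sim):
    """Queens without their own record still get finite EBVs via relatives."""
    est, factor, result = default_fit
    ebv = result.ebv()
    assert len(ebv) == len(default_sim.queens)
    assert np.isfinite(ebv.ebv_w).all() and np.isfinite(ebv.ebv_q).all()
    recorded = set(est.records.queen_id)
    dead = ebv[~ebv.id.isin(recorded)]
    assert len(dead) > 0
    # regressed from relatives, not just set to zero
    assert np.abs(dead.ebv_w).max() > 0


def test_predicted_se_scales_with_nucleus_size(default_fit, recovery_battery):
    """Predicted SEs shrink like 1/sqrt(N) from 12 to 24 families."""
    _, _, result24 = default_fit
    se24 = result24.predicted_se["var_w"]
    se12 = np.mean([s.predicted_se["var_w"] for s in recovery_battery
                    if s.converged])
    assert 1.1 < se12 / se24 < 1.8  # ideal ratio sqrt(2) ~ 1.41


def test_within_replicate_error_comovement(comovement_battery):
    """Worker- and queen-variance errors tend to move together within a
    replicate (both under- or both over-estimated) at the full 24-family
    scale, where replicate-level genetic sampling is the shared driver."""
    conv = [s for s in comovement_battery if s.converged]
    ew = np.array([s.rel_err["var_w"] for s in conv])
    eq = np.array([s.rel_err["var_q"] for s in conv])
    assert np.corrcoef(ew, eq)[0, 1] > 0


def test_predicted_se_matches_realized_spread(recovery_battery):
    """AI-based predicted SEs agree with the across-replicate spread."""
    conv = [s for s in recovery_battery if s.converged]
    pred = np.mean([s.predicted_se["var_w"] for s in conv])
    realized = np.std([s.estimates["var_w"] for s in conv])
    assert 0.5 < pred / realized < 2.0
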