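"""Shared fixtures: simulations, replicate batteries and oracles.

Expensive objects (full-scale replicates, replicate batteries) are built
once per session and shared across tests.  All randomness is seeded, so
the whole suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from apisim.pedigree import (
    IDENTIFIED_DPQ, OPEN_GROUP, PS_GROUP, QUEEN, WORKER_GROUP, MateEntry,
    Pedigree, PedigreeEntity,
)
from apisim.relationship import build_factor
from apisim.reml import ai_reml, build_model
from apisim.scenarios import SCENARIOS, build_estimation
from apisim.simulate import GeneticParameterSet, SchemeConfig, run_replicate
from apisim.metrics import run_one

PARAMS1 = GeneticParameterSet.preset(1)

# toy breeding scheme: 2 families, 2 years, 64 colonies
TOY_SCHEME = dict(n_families=2, n_bq_per_dam=6, n_dpq_per_dam=4, n_years=2)
TOY_SEED = 12  # yields an interior REML optimum (all components positive)


@pytest.fixture(scope="session")
def default_sim():
    """One replicate of the default 24-family, 10-year breeding scheme."""
    return run_replicate(PARAMS1, SchemeConfig(), 1)


@pytest.fixture(scope="session")
def default_fit(default_sim):
    """Correctly specified single-sire analysis of the default replicate."""
    est = build_estimation(default_sim, SCENARIOS["set1_ss_ssp"], 1)
    factor = build_factor(est.pedigree)
    result = ai_reml(build_model(est, factor))
    return est, factor, result


@pytest.fixture(scope="session")
def small_sim():
    """A 12-family replicate (half-size nucleus)."""
    return run_replicate(PARAMS1, SchemeConfig(n_families=12), 5)


@pytest.fixture(scope="session")
def small_sim_ps():
    """A 12-family replicate under pseudo-sire controlled mating."""
    return run_replicate(PARAMS1, SchemeConfig(n_families=12,
                                               controlled_style="PS"), 5)


@pytest.fixture(scope="session")
def toy_sim():
    return run_replicate(PARAMS1, SchemeConfig(**TOY_SCHEME), TOY_SEED)


@pytest.fixture(scope="session")
def toy_model(toy_sim):
    est = build_estimation(toy_sim, SCENARIOS["set1_ss_ssp"], TOY_SEED)
    factor = build_factor(est.pedigree)
    return est, factor, build_model(est, factor)


# a slightly richer toy (117 colonies) whose restricted likelihood has a
# well-identified interior maximum: the 64-colony toy above lies on a flat
# ridge (nearly singular information), which makes parameter-level optimizer
# comparisons ill-posed there
ORACLE_TOY_SCHEME = dict(n_families=3, n_bq_per_dam=6, n_dpq_per_dam=4,
                         n_years=3)
ORACLE_TOY_SEED = 6


@pytest.fixture(scope="session")
def identified_toy_model():
    sim = run_replicate(PARAMS1, SchemeConfig(**ORACLE_TOY_SCHEME),
                        ORACLE_TOY_SEED)
    est = build_estimation(sim, SCENARIOS["set1_ss_ssp"], ORACLE_TOY_SEED)
    factor = build_factor(est.pedigree)
    return est, factor, build_model(est, factor)


@pytest.fixture(scope="session")
def oracle_pedigree():
    """Three-generation toy pedigree with S=3/D=8 and S=1/D=8 matings.

    Two founder queens; one open-mating group; a pseudo-sire group of three
    sisters; an identified DPQ used as a single sire; daughters, a
    granddaughter pair and worker groups on both mating types.
    """
    ped = Pedigree()
    ped.add(PedigreeEntity(1, QUEEN))
    ped.add(PedigreeEntity(2, QUEEN))
    ped.add(MateEntry(3, OPEN_GROUP, S=5, D=8))
    ped.add(MateEntry(4, PS_GROUP, dpq_dam_id=2, dpq_dam_mate_id=3, S=3, D=8))
    ped.add(PedigreeEntity(5, QUEEN, dam_id=1, sire_entry_id=4, birth_year=1))
    ped.add(PedigreeEntity(6, QUEEN, dam_id=1, sire_entry_id=4, birth_year=1))
    ped.add(PedigreeEntity(7, WORKER_GROUP, dam_id=1, sire_entry_id=4))
    ped.add(PedigreeEntity(8, QUEEN, dam_id=2, sire_entry_id=3, birth_year=1))
    ped.add(MateEntry(9, IDENTIFIED_DPQ, member_queen_id=8, S=1, D=8))
    ped.add(PedigreeEntity(10, QUEEN, dam_id=5, sire_entry_id=9, birth_year=2))
    ped.add(PedigreeEntity(11, QUEEN, dam_id=5, sire_entry_id=9, birth_year=2))
    ped.add(PedigreeEntity(12, WORKER_GROUP, dam_id=5, sire_entry_id=9))
    ped.add(PedigreeEntity(13, QUEEN, dam_id=6, sire_entry_id=9, birth_year=2))
    ped.add(PedigreeEntity(14, WORKER_GROUP, dam_id=6, sire_entry_id=9))
    ped.validate()
    return ped


@pytest.fixture(scope="session")
def dense_restricted_loglik():
    """Independent dense restricted log-likelihood with explicit worker groups.

    Builds V = Zw (g11 A) Zw' + ... + ve I directly from the densified
    relationship matrix, with worker-group effects explicit (no absorption),
    and evaluates the textbook restricted likelihood by dense linear algebra.
    """

    def make(est, factor):
        A = factor.dense_A()
        rec = est.records
        n_all = factor.n_nodes
        nr = len(rec)
        wg = np.array([factor.node_of[w] for w in rec.worker_group_id])
        qn = np.array([factor.node_of[q] for q in rec.queen_id])
        Zw = np.zeros((nr, n_all))
        Zw[np.arange(nr), wg] = 1.0
        Zq = np.zeros((nr, n_all))
        Zq[np.arange(nr), qn] = 1.0
        years = sorted(rec.year.unique())
        X = np.zeros((nr, len(years)))
        for k, t in enumerate(years):
            X[:, k] = (rec.year == t).astype(float)
        y = rec.phenotype.to_numpy(float)
        ZwA = Zw @ A
        ZqA = Zq @ A
        Vw = ZwA @ Zw.T
        Vq = ZqA @ Zq.T
        Vc = ZwA @ Zq.T

        def rl(theta):
            g11, g12, g22, ve = theta
            if ve <= 0:
                return -np.inf
            G0 = np.array([[g11, g12], [g12, g22]])
            if np.linalg.eigvalsh(G0).min() <= 0:
                return -np.inf
            V = g11 * Vw + g12 * (Vc + Vc.T) + g22 * Vq + ve * np.eye(nr)
            try:
                Vi = np.linalg.inv(V)
            except np.linalg.LinAlgError:
                return -np.inf
            XVX = X.T @ Vi @ X
            b = np.linalg.solve(XVX, X.T @ Vi @ y)
            ypy = (y - X @ b) @ Vi @ y
            s1, l1 = np.linalg.slogdet(V)
            s2, l2 = np.linalg.slogdet(XVX)
            if s1 <= 0 or s2 <= 0:
                return -np.inf
            return -0.5 * (l1 + l2 + ypy
                           + (nr - X.shape[1]) * np.log(2 * np.pi))

        return rl

    return make


# ---------------------------------------------------------------------------
# replicate batteries (the heavy acceptance fixtures)
# ---------------------------------------------------------------------------

RECOVERY_N_REP = 20
RECOVERY_SEED = 2000

SCALED_N_REP = 8
SCALED_SEED = 7000
SCALED_FAMILIES = 12


@pytest.fixture(scope="session")
def comovement_battery():
    """Eight replicates of the correct SS analysis at the full 24-family
    scale (error co-movement is a full-scale property: the common
    replicate-level genetic sampling dominates only for larger nuclei)."""
    return [run_one("set1_ss_ssp", 3000 + r) for r in range(8)]


@pytest.fixture(scope="session")
def recovery_battery():
    """20 replicates of the correctly specified SS analysis, 12 families."""
    return [run_one("set1_ss_ssp", RECOVERY_SEED + r,
                    scheme_overrides={"n_families": 12})
            for r in range(RECOVERY_N_REP)]


def _scaled_one(r: int) -> dict:
    """One replicate of every scenario checked in the scaled reproduction.

    The three simulations (SS, PS, Set II) are shared across the estimation
    scenarios that re-analyse them, exactly as the estimation step only
    re-encodes the sire side.
    """
    seed = SCALED_SEED + r
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    fam = {"n_families": SCALED_FAMILIES}
    sims = {
        "ss": run_replicate(PARAMS1, SCENARIOS["set1_ss_ssp"].scheme(**fam),
                            rngs[0]),
        "ps": run_replicate(PARAMS1, SCENARIOS["set1_ps_psp"].scheme(**fam),
                            rngs[1]),
        "set2": run_replicate(PARAMS1, SCENARIOS["set2_nopheno"].scheme(**fam),
                              rngs[2]),
    }
    plan = {
        "set1_ss_ssp": "ss", "set1_ss_dummydam": "ss", "set1_ss_psp": "ss",
        "set1_ps_psp": "ps", "set1_ps_dummydam": "ps",
        "set2_nopheno": "set2", "set2_twopsp": "set2",
        "set2_fixedgroup": "set2", "set2_randgroup": "set2",
    }
    return {name: run_one(name, seed, sim=sims[src])
            for name, src in plan.items()}


@pytest.fixture(scope="session")
def scaled_battery():
    """Scaled-down reproduction battery: 12 families, 8 replicates.

    Returns a dict mapping scenario name to the list of replicate
    summaries.
    """
    per_rep = [_scaled_one(r) for r in range(SCALED_N_REP)]
    out: dict[str, list] = {}
    for rep in per_rep:
        for name, summary in rep.items():
            out.setdefault(name, []).append(summary)
    return out
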