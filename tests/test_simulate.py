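"""Breeding-program simulator: inheritance, mating, selection, counts."""

import numpy as np
import pytest

from apisim.pedigree import BASE_OPEN, CONTROLLED, SUBPOP_A, SUBPOP_B
from apisim.simulate import (
    PS, SS, TWO_SUBPOPS, GeneticParameterSet, KinshipTracker, SchemeConfig,
    controlled_drone_sources, draw_base_drone_bv, inherit_drone,
    inherit_queen, make_founders, make_worker_group, run_replicate,
)

PARAMS1 = GeneticParameterSet.preset(1)
G0 = PARAMS1.G0


def test_parameter_set_presets():
    for sid, (vw, vq) in {1: (10, 10), 2: (20, 10), 3: (10, 10),
                          4: (20, 10)}.items():
        p = GeneticParameterSet.preset(sid)
        assert (p.var_w, p.var_q, p.var_e) == (vw, vq, 30.0)
    assert GeneticParameterSet.preset(3).r_wq == pytest.approx(-0.5)
    assert GeneticParameterSet.preset(4).r_wq == pytest.approx(-0.5)


def test_non_psd_g0_rejected():
    with pytest.raises(ValueError, match="positive semi-definite"):
        GeneticParameterSet(var_w=1.0, var_q=1.0, cov_wq=2.0).validate()


def test_scheme_record_arithmetic():
    s = SchemeConfig()
    assert s.n_founders == 432
    assert s.n_bq_phenotyped == 18 and s.n_dpq_phenotyped == 15
    assert s.n_selected_dpq_dams == 16
    assert s.expected_records() == 8352
    assert SchemeConfig(n_families=12).expected_records() == 4176


def test_founders_degenerate_and_sampling():
    rng = np.random.default_rng(0)
    zero = GeneticParameterSet(var_w=0, var_q=0, cov_wq=0)
    q, d = make_founders(zero, SchemeConfig(), rng, n=50)
    assert np.all(q == 0) and np.all(d == 0)
    # 10 000 founders: sample variance of the worker trait within 3 SE of 10
    q, _ = make_founders(PARAMS1, SchemeConfig(), rng, n=10_000)
    se = PARAMS1.var_w * np.sqrt(2.0 / 10_000)
    assert abs(q[:, 0].var(ddof=1) - 10.0) < 3 * se
    assert abs(q.mean()) < 0.2


def test_inherit_queen_decomposition():
    rng = np.random.default_rng(1)
    a_dam = np.array([2.0, -1.0])
    g = np.array([0.5, 0.25])
    # no genetic variance: offspring is exactly dam/2 + drone
    zero = np.zeros((2, 2))
    assert np.allclose(inherit_queen(a_dam, 0.0, g, zero, rng),
                       0.5 * a_dam + g)
    # fully inbred dam: no Mendelian sampling on the dam gamete
    assert np.allclose(inherit_queen(a_dam, 1.0, g, G0, rng),
                       0.5 * a_dam + g)
    # base dam x base drone: unconditional Var(w) = 10 (1/4 + 1/4 + 1/2)
    n = 100_000
    rng = np.random.default_rng(2)
    dams = rng.standard_normal(n) * np.sqrt(10.0)
    drones = draw_base_drone_bv(G0, rng, n)
    psi = rng.standard_normal((n, 2)) @ np.linalg.cholesky(0.25 * G0).T
    w = 0.5 * dams + psi[:, 0] + drones[:, 0]
    se = 10.0 * np.sqrt(2.0 / n)
    assert abs(w.var(ddof=1) - 10.0) < 3 * se


def test_inherit_drone_halved_variance():
    rng = np.random.default_rng(3)
    # Mendelian term only: Var = G0/4 per component
    g = inherit_drone(np.zeros(2), 0.0, G0, rng, n=100_000)
    se = 2.5 * np.sqrt(2.0 / 100_000)
    assert abs(g[:, 0].var(ddof=1) - 2.5) < 3 * se
    # fully inbred dam: deterministic half the dam value
    g = inherit_drone(np.array([4.0, 2.0]), 1.0, G0, rng, n=5)
    assert np.allclose(g, [[2.0, 1.0]] * 5)
    # base drones have Var(w) = var_w / 2
    d = draw_base_drone_bv(G0, np.random.default_rng(4), 100_000)
    se = 5.0 * np.sqrt(2.0 / 100_000)
    assert abs(d[:, 0].var(ddof=1) - 5.0) < 3 * se


def test_worker_group_value():
    assert np.allclose(make_worker_group(np.zeros(2), np.zeros((8, 2))), 0.0)
    queen = np.array([2.0, 0.0])
    drones = np.tile([1.0, 0.0], (8, 1))
    assert np.allclose(make_worker_group(queen, drones), [2.0, 0.0])
    with pytest.raises(ValueError, match="8 drones"):
        make_worker_group(queen, drones[:5])
    # variance of the drone mean: (1/8) * var_w/2 = 0.625 at var_w = 10
    rng = np.random.default_rng(5)
    vals = np.array([make_worker_group(
        np.zeros(2), draw_base_drone_bv(G0, rng, 8))[0]
        for _ in range(20_000)])
    se = 0.625 * np.sqrt(2.0 / 20_000)
    assert abs(vals.var(ddof=1) - 0.625) < 3 * se


def test_controlled_drone_sources():
    rng = np.random.default_rng(6)
    # SS: a single sister supplies all drones
    assert len(set(controlled_drone_sources(SS, 3, 8, rng))) == 1
    # PS: each sister's expected share is 1/3
    draws = np.concatenate([controlled_drone_sources(PS, 3, 8, rng)
                            for _ in range(2000)])
    share = np.bincount(draws, minlength=3) / len(draws)
    se = np.sqrt((1 / 3) * (2 / 3) / len(draws))
    assert np.all(np.abs(share - 1 / 3) < 3 * se)
    with pytest.raises(ValueError, match="empty"):
        controlled_drone_sources(SS, 0, 8, rng)


def test_replicate_counts_default(default_sim):
    assert len(default_sim.records) == 8352
    assert len(default_sim.queens) == 10_992


def test_replicate_counts_rescaled(small_sim):
    assert len(small_sim.records) == 4176
    assert len(small_sim.queens) == 5496
    # 8 groups per year, each used in exactly 36 matings
    from collections import Counter
    used = Counter(m.group_id for m in small_sim.matings.values()
                   if m.group_id >= 0)
    assert set(used.values()) == {36}
    assert len(used) == 8 * 8  # cohorts 3..10 use groups of years 1..8


def test_degenerate_zero_variance_replicate():
    p = GeneticParameterSet(var_w=0, var_q=0, cov_wq=0, var_e=0, var_year=0)
    sim = run_replicate(p, SchemeConfig(n_families=2, n_bq_per_dam=6,
                                        n_dpq_per_dam=4, n_years=2), 0)
    assert np.allclose(sim.records.phenotype, 0.0)


def test_selection_drives_positive_trend(small_sim):
    means = small_sim.cohort_bv_means()
    x = means.index.to_numpy(float)
    for trait in ("w", "q"):
        slope = np.polyfit(x, means[trait], 1)[0]
        assert slope > 0


def test_uninformative_phenotypes_give_no_trend():
    """With overwhelming residual noise, selection is effectively random."""
    p = GeneticParameterSet(var_w=10, var_q=10, cov_wq=0, var_e=1e8,
                            var_year=10)
    slopes = []
    for seed in range(3):
        sim = run_replicate(p, SchemeConfig(n_families=12, n_years=6), seed)
        m = sim.cohort_bv_means()
        slopes.append(np.polyfit(m.index.to_numpy(float), m["w"], 1)[0])
    # genetic SD is ~3.2; a real trend under selection is ~0.5/year
    assert abs(np.mean(slopes)) < 0.25


def test_bitwise_determinism():
    s = SchemeConfig(n_families=4, n_years=3)
    a = run_replicate(PARAMS1, s, 99)
    b = run_replicate(PARAMS1, s, 99)
    assert a.queens.equals(b.queens)
    assert a.colonies.equals(b.colonies)
    assert np.array_equal(a.year_effects, b.year_effects)


def test_two_subpop_allocation_balanced():
    sim = run_replicate(PARAMS1, SchemeConfig(n_families=12, n_years=4,
                                              open_structure=TWO_SUBPOPS), 8)
    col = sim.colonies
    dpq = col[col.role == "DPQ"]
    for t, grp in dpq.groupby("byear"):
        fams = sim.queens.set_index("id").loc[grp.queen, "family"]
        by_label = {}
        for lab in (SUBPOP_A, SUBPOP_B):
            by_label[lab] = set(fams[grp.label.to_numpy() == lab])
        # balanced halves of the maternal families, disjoint
        assert len(by_label[SUBPOP_A]) == len(by_label[SUBPOP_B]) == 6
        assert not (by_label[SUBPOP_A] & by_label[SUBPOP_B])
    # BQ colonies of the open years stay on the base population
    bq = col[(col.role != "DPQ") & (col.byear <= 2)]
    assert set(bq.label) == {BASE_OPEN}
    assert set(col[(col.byear >= 3) & (col.role == "BQ")].label) <= {CONTROLLED}


def test_subpopulation_shift_magnitude():
    """The queen-trait gap between drone subpopulations is one sigma_Q."""
    alpha = PARAMS1.alpha_vector()
    assert alpha[1] == pytest.approx(np.sqrt(10.0) / 2, abs=1e-12)
    rng = np.random.default_rng(11)
    a = draw_base_drone_bv(G0, rng, 40_000, mean=-alpha)
    b = draw_base_drone_bv(G0, rng, 40_000, mean=+alpha)
    gap = b[:, 1].mean() - a[:, 1].mean()
    assert abs(gap - np.sqrt(10.0)) < 3 * np.sqrt(2 * 5.0 / 40_000)


def test_kinship_tracker_hand_values():
    kin = KinshipTracker()
    # founder dam (1), base drone (2), two daughters sharing that father
    kin.add_drone(2, 0)
    kin.add_queen(3, 1, 2)
    kin.add_queen(4, 1, 2)
    assert kin.F(3) == 0.0
    # full sisters with the same father drone: f = 3/8 (a = 3/4)
    assert kin.f(3, 4) == pytest.approx(0.375)
    # distinct drones of a non-inbred queen: f(d, d') = 1/2
    kin.add_drone(5, 3)
    kin.add_drone(6, 3)
    assert kin.f(5, 6) == pytest.approx(0.5)
    # mother x son mating: the drone is a gamete of queen 3, so the
    # daughter's F = f(3, son) = (1 + F_3)/2 = 1/2
    kin.add_queen(7, 3, 6)
    assert kin.F(7) == pytest.approx(0.5)


def test_generation_interval_by_construction(small_sim):
    """Dams reproduce at age 1; DPQs supply drones at age 2.

    A queen's dam is one year older than her; the dam was mated (in her own
    birth year) to DPQs two years her senior — the 1-year dam path and
    2-year sire path of the scheme.
    """
    q = small_sim.queens.set_index("id")
    late = q[(q.byear >= 4) & (q.father_dpq > 0)]
    dam_year = q.loc[late.dam, "byear"].to_numpy()
    dpq_year = q.loc[late.father_dpq, "byear"].to_numpy()
    assert np.all(late.byear.to_numpy() - dam_year == 1)
    assert np.all(dam_year - dpq_year == 2)
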