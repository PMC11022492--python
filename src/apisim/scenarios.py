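"""Sire-modeling scenarios: re-encoding true matings for estimation.

The simulator knows exactly which drone-producing queen (DPQ) supplied the
drones of every controlled mating.  In practice breeders often record only
the *dam* of the DPQ(s), so the genetic evaluation has to assume how the
DPQs were used.  This module re-encodes the true matings of one replicate
under a scenario's (possibly deliberately wrong) assumptions and emits the
estimation pedigree and performance file.

Controlled-mating sire models (Set I):

* ``C_SSP`` — a single identified DPQ per mating: the true DPQ under SS
  simulation, or one of the three sisters chosen at random under PS
  simulation;
* ``C_DUMMY_DAM`` — one dummy DPQ (a pedigree daughter of the true DPQ dam)
  shared by all matings that used drones of that dam's sister group;
* ``C_DUMMY_Q`` — a fresh dummy DPQ for every single mating;
* ``C_PSP`` — a pseudo-sire group of S = 3 unidentified sister DPQs shared
  by all matings of the group.

Open-mating models (Set II; controlled matings encoded as ``C_SSP``):

* ``O_SINGLE`` — one open-mating pseudo-sire group of 100 unknown,
  unrelated, non-inbred DPQs for every open mating (also the Set I model);
* ``O_NOPHENO`` — like ``O_SINGLE`` but DPQ colony records are excluded
  from the performance file;
* ``O_TWOPSP`` — one open group for base/initial queens plus one distinct
  open group per drone subpopulation for DPQ matings;
* ``O_FIXEDGROUP`` / ``O_RANDGROUP`` — one open group for all open matings,
  with the drone subpopulation entering the evaluation model as a
  non-genetic fixed or random effect with three levels (base drones and the
  two subpopulations); controlled colonies carry no level.

Dam links are never altered: only the sire side of the pedigree changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import (
    BASE_OPEN, CONTROLLED, DUMMY_DPQ, IDENTIFIED_DPQ, OPEN_GROUP, PS_GROUP,
    QUEEN, SUBPOP_A, SUBPOP_B, WORKER_GROUP, ColonyRecord, MateEntry,
    Pedigree, PedigreeEntity, records_to_frame,
)
from .simulate import (
    HOMOGENEOUS, PS, ROLE_DPQ, SS, TWO_SUBPOPS, GeneticParameterSet,
    SchemeConfig, SimResult,
)

C_SSP = "C_SSP"
C_DUMMY_DAM = "C_DUMMY_DAM"
C_DUMMY_Q = "C_DUMMY_Q"
C_PSP = "C_PSP"

O_SINGLE = "O_SINGLE"
O_NOPHENO = "O_NOPHENO"
O_TWOPSP = "O_TWOPSP"
O_FIXEDGROUP = "O_FIXEDGROUP"
O_RANDGROUP = "O_RANDGROUP"

_CONTROLLED_MODES = (C_SSP, C_DUMMY_DAM, C_DUMMY_Q, C_PSP)
_OPEN_MODES = (O_SINGLE, O_NOPHENO, O_TWOPSP, O_FIXEDGROUP, O_RANDGROUP)


@dataclass
class ScenarioSpec:
    """One simulation x estimation scenario."""

    name: str
    set_id: int                    # 1 or 2
    sim_controlled: str = SS       # SS | PS
    estim_controlled: str = C_SSP
    estim_open: str = O_SINGLE
    open_group_size: int = 100
    params_set_id: int = 1

    def __post_init__(self) -> None:
        if self.estim_controlled not in _CONTROLLED_MODES:
            raise ValueError(f"unknown controlled sire model {self.estim_controlled}")
        if self.estim_open not in _OPEN_MODES:
            raise ValueError(f"unknown open sire model {self.estim_open}")
        if self.set_id == 2 and (self.sim_controlled != SS
                                 or self.estim_controlled != C_SSP):
            raise ValueError("Set II fixes SS simulation and C_SSP estimation")

    @property
    def open_structure(self) -> str:
        return TWO_SUBPOPS if self.set_id == 2 else HOMOGENEOUS

    def scheme(self, **overrides) -> SchemeConfig:
        return SchemeConfig(controlled_style=self.sim_controlled,
                            open_structure=self.open_structure, **overrides)

    def params(self) -> GeneticParameterSet:
        return GeneticParameterSet.preset(self.params_set_id)


def _set1(sim: str, estim: str) -> ScenarioSpec:
    tag = {C_SSP: "ssp", C_DUMMY_DAM: "dummydam", C_DUMMY_Q: "dummyq",
           C_PSP: "psp"}[estim]
    return ScenarioSpec(name=f"set1_{sim.lower()}_{tag}", set_id=1,
                        sim_controlled=sim, estim_controlled=estim)


def _set2(estim: str) -> ScenarioSpec:
    tag = {O_NOPHENO: "nopheno", O_TWOPSP: "twopsp",
           O_FIXEDGROUP: "fixedgroup", O_RANDGROUP: "randgroup",
           O_SINGLE: "singlepsp"}[estim]
    return ScenarioSpec(name=f"set2_{tag}", set_id=2, estim_open=estim)


SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s for s in (
        [_set1(sim, estim) for sim in (SS, PS) for estim in _CONTROLLED_MODES]
        + [_set2(estim) for estim in (O_NOPHENO, O_TWOPSP, O_FIXEDGROUP,
                                      O_RANDGROUP)]
    )
}


@dataclass
class EstimationData:
    """Estimation pedigree + performance records for one scenario."""

    scenario: ScenarioSpec | None
    pedigree: Pedigree
    records: pd.DataFrame          # performance-file columns
    est_id: dict[int, int]         # true queen id -> estimation entity id
    true_id: dict[int, int]        # estimation entity id -> true queen id
    fixed_group: bool
    random_group: bool

    @classmethod
    def from_files(cls, pedigree_path, performance_path,
                   fixed_group: bool = False, random_group: bool = False
                   ) -> "EstimationData":
        """Load an estimation dataset from pedigree/performance TSV files."""
        from .pedigree import read_pedigree, read_performance
        ped = read_pedigree(pedigree_path)
        rec = read_performance(performance_path)
        return cls(scenario=None, pedigree=ped, records=rec, est_id={},
                   true_id={}, fixed_group=fixed_group,
                   random_group=random_group)


def build_estimation(sim: SimResult, scenario: ScenarioSpec,
                     rng: np.random.Generator | int = 0) -> EstimationData:
    """Re-encode one replicate's truth under a scenario's assumptions."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if scenario.sim_controlled != sim.scheme.controlled_style:
        raise ValueError("scenario simulation style does not match the replicate")

    ped = Pedigree()
    counter = [0]

    def nid() -> int:
        counter[0] += 1
        return counter[0]

    est_id: dict[int, int] = {}
    own_mate: dict[int, int] = {}      # true queen id -> estimation mate id

    # open-mating pseudo-sire entries
    S_open = scenario.open_group_size
    og_base = ped.add(MateEntry(nid(), OPEN_GROUP, S=S_open,
                                D=sim.scheme.n_drones)).id
    if scenario.estim_open == O_TWOPSP:
        og_sub = {SUBPOP_A: ped.add(MateEntry(nid(), OPEN_GROUP, S=S_open,
                                              D=sim.scheme.n_drones)).id,
                  SUBPOP_B: ped.add(MateEntry(nid(), OPEN_GROUP, S=S_open,
                                              D=sim.scheme.n_drones)).id}
    else:
        og_sub = {}

    queens = sim.queens
    colonies = sim.colonies.reset_index(drop=True)
    drop_dpq_records = scenario.estim_open == O_NOPHENO

    group_entry: dict[int, int] = {}   # true group id -> shared mate entry id

    def controlled_mate_entry(qid: int) -> int:
        """Estimation mate entry for the controlled mating of queen qid."""
        m = sim.matings[qid]
        g = sim.groups[m.group_id]
        mode = scenario.estim_controlled
        if mode == C_SSP:
            if scenario.sim_controlled == SS:
                member = m.chosen_dpq
            else:
                member = int(g.members[rng.integers(len(g.members))])
            return ped.add(MateEntry(nid(), IDENTIFIED_DPQ,
                                     member_queen_id=est_id[member], S=1,
                                     D=sim.scheme.n_drones)).id
        if mode == C_DUMMY_Q:
            return ped.add(MateEntry(nid(), DUMMY_DPQ,
                                     dpq_dam_id=est_id[g.dam],
                                     dpq_dam_mate_id=own_mate[g.dam], S=1,
                                     D=sim.scheme.n_drones)).id
        # one shared entry per sister group (C_DUMMY_DAM, C_PSP)
        if m.group_id not in group_entry:
            if mode == C_DUMMY_DAM:
                e = MateEntry(nid(), DUMMY_DPQ, dpq_dam_id=est_id[g.dam],
                              dpq_dam_mate_id=own_mate[g.dam], S=1,
                              D=sim.scheme.n_drones)
            else:
                e = MateEntry(nid(), PS_GROUP, dpq_dam_id=est_id[g.dam],
                              dpq_dam_mate_id=own_mate[g.dam],
                              S=len(g.members), D=sim.scheme.n_drones)
            group_entry[m.group_id] = ped.add(e).id
        return group_entry[m.group_id]

    def open_mate_entry(qid: int) -> int:
        label = sim.matings[qid].label
        if scenario.estim_open == O_TWOPSP and label in og_sub:
            return og_sub[label]
        return og_base

    records: list[ColonyRecord] = []
    for t in sorted(queens.byear.unique()):
        cohort = queens[queens.byear == t]
        # queen entities (dam link is never altered by any scenario)
        for row in cohort.itertuples(index=False):
            dam_est = est_id.get(row.dam, 0)
            sire_est = own_mate.get(row.dam, 0)
            q = ped.add(PedigreeEntity(nid(), QUEEN, dam_id=dam_est,
                                       sire_entry_id=sire_est, birth_year=t))
            est_id[row.id] = q.id
        # mate entries for this cohort's matings
        for row in cohort.itertuples(index=False):
            m = sim.matings[row.id]
            if m.label == CONTROLLED:
                own_mate[row.id] = controlled_mate_entry(row.id)
            else:
                own_mate[row.id] = open_mate_entry(row.id)
        # worker groups + records for phenotyped colonies
        cset = colonies[(colonies.byear == t) & colonies.survived]
        for c in cset.itertuples(index=False):
            if drop_dpq_records and c.role == ROLE_DPQ:
                continue
            wg = ped.add(PedigreeEntity(nid(), WORKER_GROUP,
                                        dam_id=est_id[c.queen],
                                        sire_entry_id=own_mate[c.queen],
                                        birth_year=t))
            records.append(ColonyRecord(
                colony_id=wg.id, queen_id=est_id[c.queen],
                worker_group_id=wg.id, mate_entry_id=own_mate[c.queen],
                year=t, open_group_label=c.label, phenotype=float(c.phenotype)))

    ped.validate()
    rec = records_to_frame(records)
    return EstimationData(
        scenario=scenario, pedigree=ped, records=rec, est_id=est_id,
        true_id={v: k for k, v in est_id.items()},
        fixed_group=scenario.estim_open == O_FIXEDGROUP,
        random_group=scenario.estim_open == O_RANDGROUP)


def encode_controlled(sim: SimResult, mode: str,
                      rng: np.random.Generator | int = 0) -> EstimationData:
    """Encode a Set I scenario (controlled-mating sire model ``mode``)."""
    spec = _set1(sim.scheme.controlled_style, mode)
    return build_estimation(sim, spec, rng)


def encode_open(sim: SimResult, mode: str,
                rng: np.random.Generator | int = 0) -> EstimationData:
    """Encode a Set II scenario (open-mating model ``mode``)."""
    spec = _set2(mode)
    return build_estimation(sim, spec, rng)
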