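"""Stochastic simulation of a closed honeybee breeding program.

The simulator implements an infinitesimal model for two correlated genetic
effects per queen: a worker effect (expressed by her workers in a colony
phenotype) and a queen effect (expressed by the queen herself).  Queens are
diploid; drones are haploid and carry a single maternal gamete, so base
drones are drawn with a halved (co)variance matrix and a drone's breeding
value is ``g = a_dam/2 + phi`` with Mendelian term
``phi ~ N(0, (1 - F_dam)/4 * G0)``.

The breeding scheme (one replicate):

* year 0 — ``18 * n_families`` unrelated, non-inbred founder breeding queens
  (BQs), each open-mated to 8 unrelated base drones; all founder colonies are
  phenotyped and the best ``n_families`` queens are selected as dams;
* each year t >= 1 — every selected dam produces 24 BQ and 20 drone-producing
  queen (DPQ) daughters.  Daughters are mated at birth: BQ cohorts of years
  1-2 are open-mated (no DPQs are available yet), cohorts of year >= 3 are
  controlled-mated to sister-DPQ groups selected two years earlier; DPQs are
  always open-mated.  A winter mortality event kills exactly 25% of colonies
  within each maternal family (18 BQ and 15 DPQ colonies are phenotyped per
  dam).  One BQ per maternal family is selected on her own colony phenotype
  (within-family selection); two-thirds of the dams are selected on the mean
  phenotype of their DPQ daughters (across-family selection) and 3 surviving
  DPQs per selected dam form the sister groups used two years later.

The resulting generation interval is 1.5 years (1 year on the dam path,
2 years on the sire path).  Controlled mating is either single-sire (SS; one
DPQ of the three sisters supplies all 8 drones) or pseudo-sire (PS; each of
the 8 drones comes from a sister drawn uniformly with replacement).  Open
mating draws 8 unrelated drones, either from one homogeneous base population
or — for DPQs under the two-subpopulation structure — from one of two drone
subpopulations with mean breeding values shifted by ``-alpha`` and
``+alpha``.

Colony phenotypes follow ``y = year_t + a_W(worker group) + a_Q(queen) + e``
with a common random year effect and i.i.d. residuals.  Worker-group values
are the infinite-worker-group limit ``a_W = a_queen/2 + mean(8 drones)``
(the 8 drones contribute equally; no worker-side Mendelian residual).

True inbreeding coefficients are computed on demand from the realized
genealogy (including the identity of every father drone) by a memoized
coancestry recursion; they scale the Mendelian sampling variance.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# mating styles / labels shared with the pedigree module
from .pedigree import BASE_OPEN, CONTROLLED, SUBPOP_A, SUBPOP_B

SS = "SS"
PS = "PS"
OPEN = "OPEN"
HOMOGENEOUS = "HOMOGENEOUS"
TWO_SUBPOPS = "TWO_SUBPOPS"

ROLE_FOUNDER = "FOUNDER"
ROLE_BQ = "BQ"
ROLE_DPQ = "DPQ"


@dataclass
class GeneticParameterSet:
    """True genetic parameters of the base population.

    ``alpha`` is the per-trait mean shift of the two open-mating drone
    subpopulations (drone means are ``-alpha`` and ``+alpha``).  The default
    (``None``) scales alpha to half a genetic standard deviation per trait,
    so the two subpopulations differ by exactly one genetic SD of queen
    effects on the queen trait.
    """

    var_w: float = 10.0
    var_q: float = 10.0
    cov_wq: float = 0.0
    var_e: float = 30.0
    var_year: float = 10.0
    alpha: tuple[float, float] | None = None

    @property
    def G0(self) -> np.ndarray:
        return np.array([[self.var_w, self.cov_wq], [self.cov_wq, self.var_q]])

    @property
    def r_wq(self) -> float:
        denom = np.sqrt(self.var_w * self.var_q)
        return 0.0 if denom == 0 else self.cov_wq / denom

    def alpha_vector(self) -> np.ndarray:
        if self.alpha is not None:
            return np.asarray(self.alpha, dtype=float)
        return 0.5 * np.sqrt(np.array([self.var_w, self.var_q]))

    def validate(self) -> None:
        ev = np.linalg.eigvalsh(self.G0)
        if ev.min() < -1e-9 * max(1.0, ev.max()):
            raise ValueError("G0 is not positive semi-definite")
        if self.var_e < 0 or self.var_year < 0:
            raise ValueError("negative residual or year variance")

    @classmethod
    def preset(cls, set_id: int) -> "GeneticParameterSet":
        """The four canonical parameter sets (residual variance 30 in all)."""
        table = {
            1: (10.0, 10.0, 0.0),
            2: (20.0, 10.0, 0.0),
            3: (10.0, 10.0, -5.0),
            4: (20.0, 10.0, -0.5 * np.sqrt(200.0)),
        }
        vw, vq, cov = table[set_id]
        return cls(var_w=vw, var_q=vq, cov_wq=cov, var_e=30.0)


@dataclass
class SchemeConfig:
    """Breeding-scheme configuration (defaults: the 24-family nucleus)."""

    n_families: int = 24
    n_bq_per_dam: int = 24
    n_dpq_per_dam: int = 20
    survival: float = 0.75
    dpq_dam_selected_fraction: float = 2.0 / 3.0
    n_dpq_per_group: int = 3
    n_drones: int = 8
    n_years: int = 10
    controlled_style: str = SS
    open_structure: str = HOMOGENEOUS

    @property
    def n_founders(self) -> int:
        # 18 founder queens per maternal family slot (432 at 24 families)
        return 18 * self.n_families

    @property
    def n_bq_phenotyped(self) -> int:
        return round(self.survival * self.n_bq_per_dam)

    @property
    def n_dpq_phenotyped(self) -> int:
        return round(self.survival * self.n_dpq_per_dam)

    @property
    def n_selected_dpq_dams(self) -> int:
        return round(self.dpq_dam_selected_fraction * self.n_families)

    def validate(self) -> None:
        if self.n_families < 2 or self.n_years < 1:
            raise ValueError("infeasible scheme counts")
        if self.n_selected_dpq_dams < 1 or self.n_dpq_per_group < 1:
            raise ValueError("infeasible scheme counts")
        if self.n_bq_phenotyped < 1 or self.n_dpq_phenotyped < self.n_dpq_per_group:
            raise ValueError("infeasible scheme counts")
        if self.controlled_style not in (SS, PS):
            raise ValueError(f"unknown controlled mating style {self.controlled_style}")
        if self.open_structure not in (HOMOGENEOUS, TWO_SUBPOPS):
            raise ValueError(f"unknown open-mating structure {self.open_structure}")

    def expected_records(self) -> int:
        per_year = self.n_families * (self.n_bq_phenotyped + self.n_dpq_phenotyped)
        return self.n_founders + self.n_years * per_year


# ---------------------------------------------------------------------------
# elementary inheritance operations
# ---------------------------------------------------------------------------

def _chol_psd(G0: np.ndarray) -> np.ndarray:
    # Cholesky-like factor tolerant of semi-definite G0
    w, v = np.linalg.eigh(G0)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def draw_base_queen_bv(G0: np.ndarray, rng: np.random.Generator,
                       n: int = 1) -> np.ndarray:
    """Breeding values of unrelated non-inbred base queens, N(0, G0)."""
    return rng.standard_normal((n, 2)) @ _chol_psd(G0).T


def draw_base_drone_bv(G0: np.ndarray, rng: np.random.Generator, n: int = 1,
                       mean: np.ndarray | None = None) -> np.ndarray:
    """Haploid base drones: N(mean, G0/2) — halved covariance for haploidy."""
    g = rng.standard_normal((n, 2)) @ _chol_psd(0.5 * G0).T
    if mean is not None:
        g = g + np.asarray(mean, dtype=float)
    return g


def inherit_queen(a_dam: np.ndarray, F_dam: float, g_father: np.ndarray,
                  G0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Daughter queen: ``a = a_dam/2 + psi + g_father``.

    The dam gamete carries Mendelian term ``psi ~ N(0, (1 - F_dam)/4 G0)``;
    the father drone contributes his full haploid value.  At ``F_dam = 0``
    the unconditional variance totals ``G0`` (1/4 + 1/4 + 1/2).
    """
    psi = rng.standard_normal(2) @ _chol_psd(0.25 * (1.0 - F_dam) * G0).T
    return 0.5 * np.asarray(a_dam) + psi + np.asarray(g_father)


def inherit_drone(a_dam: np.ndarray, F_dam: float, G0: np.ndarray,
                  rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Drones of a queen: ``g = a_dam/2 + phi``, ``phi ~ N(0, (1-F)/4 G0)``."""
    phi = rng.standard_normal((n, 2)) @ _chol_psd(0.25 * (1.0 - F_dam) * G0).T
    return 0.5 * np.asarray(a_dam) + phi


def make_worker_group(a_queen: np.ndarray, drones: np.ndarray,
                      n_drones: int = 8) -> np.ndarray:
    """Worker-group value ``a_W = a_queen/2 + mean(drones)``.

    The D drones contribute equally; in the infinite-worker-group limit no
    worker-side Mendelian residual remains.
    """
    drones = np.atleast_2d(drones)
    if drones.shape[0] != n_drones:
        raise ValueError(f"expected {n_drones} drones, got {drones.shape[0]}")
    return 0.5 * np.asarray(a_queen) + drones.mean(axis=0)


def controlled_drone_sources(style: str, n_dpq: int, n_drones: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Member index (0..n_dpq-1) supplying each of the D drones of one mating.

    SS: one sister chosen uniformly supplies all drones; PS: each drone's
    sister is drawn uniformly with replacement.
    """
    if n_dpq < 1:
        raise ValueError("empty DPQ group")
    if style == SS:
        return np.full(n_drones, rng.integers(n_dpq))
    if style == PS:
        return rng.integers(n_dpq, size=n_drones)
    raise ValueError(f"unknown controlled mating style {style}")


# ---------------------------------------------------------------------------
# genealogy bookkeeping (true kinship / inbreeding)
# ---------------------------------------------------------------------------

class KinshipTracker:
    """Memoized coancestry over the realized genealogy.

    Individuals are queens (diploid) and drones (haploid gametes of their
    dam); both share one id space ordered by creation time.  ``f(x, y)`` is
    the probability that random alleles drawn from x and y are identical by
    descent; for a queen ``f(x, x) = (1 + F_x)/2`` and for a drone
    ``f(d, d) = 1``.  A queen's inbreeding coefficient is the coancestry of
    her dam and her (actual) father drone.
    """

    def __init__(self) -> None:
        self.queen_parents: dict[int, tuple[int, int]] = {}  # qid -> (dam, father drone)
        self.drone_dam: dict[int, int] = {}  # drone id -> dam qid (0 = base)
        self._f: dict[tuple[int, int], float] = {}
        self._F: dict[int, float] = {}

    def add_queen(self, qid: int, dam: int, father_drone: int) -> None:
        self.queen_parents[qid] = (dam, father_drone)

    def add_drone(self, did: int, dam: int) -> None:
        self.drone_dam[did] = dam

    def is_drone(self, xid: int) -> bool:
        return xid in self.drone_dam

    def F(self, qid: int) -> float:
        got = self._F.get(qid)
        if got is not None:
            return got
        dam, father = self.queen_parents.get(qid, (0, 0))
        val = 0.0 if dam == 0 else self.f(dam, father)
        self._F[qid] = val
        return val

    def f(self, x: int, y: int) -> float:
        if x == 0 or y == 0:
            return 0.0
        if x == y:
            return 1.0 if self.is_drone(x) else 0.5 * (1.0 + self.F(x))
        key = (x, y) if x > y else (y, x)
        got = self._f.get(key)
        if got is not None:
            return got
        a, b = key  # a is the younger individual: expand its parents
        if self.is_drone(a):
            dam = self.drone_dam[a]
            val = self.f(dam, b) if dam else 0.0
        else:
            dam, father = self.queen_parents.get(a, (0, 0))
            if dam == 0:
                val = 0.0
            else:
                val = 0.5 * self.f(dam, b) + 0.5 * self.f(father, b)
        self._f[key] = val
        return val


# ---------------------------------------------------------------------------
# replicate containers
# ---------------------------------------------------------------------------

@dataclass
class Mating:
    """One realized mating: style, group used and the 8 drones."""

    style: str                 # SS | PS | OPEN
    label: str                 # CONTROLLED | BASE_OPEN | SUBPOP_A | SUBPOP_B
    group_id: int = -1         # index into SimResult.groups
    chosen_dpq: int = 0        # SS only: the DPQ that supplied the drones
    drone_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    drone_src: np.ndarray = field(default_factory=lambda: np.empty(0, int))  # DPQ id per drone, 0 = base
    drone_bv: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


@dataclass
class DpqGroup:
    """A selected group of sister DPQs used for controlled mating."""

    group_id: int
    year: int                  # birth year of the members
    dam: int                   # queen id of the DPQ dam
    members: tuple[int, ...]   # queen ids of the sister DPQs


@dataclass
class SimResult:
    """Ground truth of one replicate."""

    params: GeneticParameterSet
    scheme: SchemeConfig
    queens: pd.DataFrame       # id, dam, byear, role, family, w, q, father_drone, father_dpq
    colonies: pd.DataFrame     # queen, byear, role, label, survived, phenotype, wg_w, wg_q
    matings: dict[int, Mating]
    groups: list[DpqGroup]
    year_effects: np.ndarray
    kinship: KinshipTracker
    selected_dams: list[list[int]]   # per year, the dams producing next cohort

    @property
    def records(self) -> pd.DataFrame:
        return self.colonies[self.colonies.survived].reset_index(drop=True)

    def cohort_bv_means(self, role: str = ROLE_BQ) -> pd.DataFrame:
        """Mean true breeding values of all candidates per birth year."""
        q = self.queens
        sub = q[q.role.isin([ROLE_FOUNDER, ROLE_BQ])] if role == ROLE_BQ else q[q.role == role]
        return sub.groupby("byear")[["w", "q"]].mean()


# ---------------------------------------------------------------------------
# the replicate driver
# ---------------------------------------------------------------------------

class _Sim:
    def __init__(self, params: GeneticParameterSet, scheme: SchemeConfig,
                 rng: np.random.Generator) -> None:
        params.validate()
        scheme.validate()
        self.p = params
        self.s = scheme
        self.rng = rng
        self.G0 = params.G0
        self.kin = KinshipTracker()
        self._next_id = 1
        self.bv: dict[int, np.ndarray] = {}      # queen id -> (w, q)
        self.queen_rows: list[tuple] = []
        self.colony_rows: list[tuple] = []
        self.matings: dict[int, Mating] = {}
        self.groups: list[DpqGroup] = []
        self.year_effects = np.zeros(scheme.n_years + 1)
        self.selected_dams: list[list[int]] = []

    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    # -- mating helpers -------------------------------------------------

    def _open_drones(self, mean: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        D = self.s.n_drones
        bv = draw_base_drone_bv(self.G0, self.rng, D, mean)
        ids = np.array([self.new_id() for _ in range(D)])
        for d in ids:
            self.kin.add_drone(int(d), 0)
        return ids, np.zeros(D, dtype=int), bv

    def _controlled_drones(self, group: DpqGroup, style: str
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        D = self.s.n_drones
        src_idx = controlled_drone_sources(style, len(group.members), D, self.rng)
        members = np.asarray(group.members)
        src = members[src_idx]
        bv = np.empty((D, 2))
        ids = np.empty(D, dtype=int)
        for j, dpq in enumerate(src):
            dpq = int(dpq)
            bv[j] = inherit_drone(self.bv[dpq], self.kin.F(dpq), self.G0, self.rng)[0]
            ids[j] = self.new_id()
            self.kin.add_drone(int(ids[j]), dpq)
        chosen = int(src[0]) if style == SS else 0
        return ids, src, bv, chosen

    def _mate_and_form_colony(self, qid: int, role: str, byear: int,
                              group: DpqGroup | None, subpop: str | None) -> None:
        """Mate queen ``qid`` and create her (not yet phenotyped) colony."""
        if group is not None:
            ids, src, bv, chosen = self._controlled_drones(group, self.s.controlled_style)
            m = Mating(style=self.s.controlled_style, label=CONTROLLED,
                       group_id=group.group_id, chosen_dpq=chosen,
                       drone_ids=ids, drone_src=src, drone_bv=bv)
        else:
            alpha = self.p.alpha_vector()
            if subpop == SUBPOP_A:
                mean, label = -alpha, SUBPOP_A
            elif subpop == SUBPOP_B:
                mean, label = +alpha, SUBPOP_B
            else:
                mean, label = None, BASE_OPEN
            ids, src, bv = self._open_drones(mean)
            m = Mating(style=OPEN, label=label, drone_ids=ids, drone_src=src,
                       drone_bv=bv)
        self.matings[qid] = m
        wg = make_worker_group(self.bv[qid], m.drone_bv, self.s.n_drones)
        self.colony_rows.append((qid, byear, role, m.label, False, np.nan,
                                 wg[0], wg[1]))

    def _phenotype_cohort(self, colony_idx: list[int], year: int) -> None:
        """Apply the year effect and residual to surviving colonies."""
        u = self.year_effects[year]
        for i in colony_idx:
            row = list(self.colony_rows[i])
            qid = row[0]
            y = u + row[6] + self.bv[qid][1] + self.rng.normal(0.0, np.sqrt(self.p.var_e))
            row[4] = True
            row[5] = y
            self.colony_rows[i] = tuple(row)

    def _offspring(self, dam: int, n: int, role: str, byear: int) -> list[int]:
        """Produce ``n`` daughters of ``dam``; father drawn among her 8 mates."""
        m = self.matings[dam]
        F_dam = self.kin.F(dam)
        a_dam = self.bv[dam]
        slots = self.rng.integers(self.s.n_drones, size=n)
        psi = self.rng.standard_normal((n, 2)) @ _chol_psd(
            0.25 * (1.0 - F_dam) * self.G0).T
        out = []
        for j in range(n):
            qid = self.new_id()
            slot = int(slots[j])
            self.bv[qid] = 0.5 * a_dam + psi[j] + m.drone_bv[slot]
            fd = int(m.drone_ids[slot])
            self.kin.add_queen(qid, dam, fd)
            self.queen_rows.append((qid, dam, byear, role, dam,
                                    self.bv[qid][0], self.bv[qid][1],
                                    fd, int(m.drone_src[slot])))
            out.append(qid)
        return out

    # -- selection helpers ----------------------------------------------

    def _argmax_random_ties(self, values: np.ndarray) -> int:
        jitter = self.rng.random(len(values))
        return int(np.lexsort((jitter, values))[-1])

    def _top_k_random_ties(self, values: np.ndarray, k: int) -> np.ndarray:
        jitter = self.rng.random(len(values))
        return np.lexsort((jitter, values))[::-1][:k]

    # -- main loop -------------------------------------------------------

    def run(self) -> SimResult:
        s, p, rng = self.s, self.p, self.rng
        self.year_effects = rng.normal(0.0, np.sqrt(p.var_year), s.n_years + 1)

        # year 0: founders, open-mated, all phenotyped
        founders = []
        base_bv = draw_base_queen_bv(self.G0, rng, s.n_founders)
        for i in range(s.n_founders):
            qid = self.new_id()
            self.bv[qid] = base_bv[i]
            self.queen_rows.append((qid, 0, 0, ROLE_FOUNDER, 0,
                                    base_bv[i][0], base_bv[i][1], 0, 0))
            founders.append(qid)
        idx0 = []
        for qid in founders:
            self._mate_and_form_colony(qid, ROLE_FOUNDER, 0, None, None)
            idx0.append(len(self.colony_rows) - 1)
        self._phenotype_cohort(idx0, 0)
        phenos = np.array([self.colony_rows[i][5] for i in idx0])
        dams = [founders[int(i)] for i in self._top_k_random_ties(phenos, s.n_families)]
        self.selected_dams.append(dams)

        groups_by_year: dict[int, list[DpqGroup]] = {}

        for t in range(1, s.n_years + 1):
            use_groups = groups_by_year.get(t - 2) if t >= 3 else None
            new_bq_idx: dict[int, list[int]] = {}
            new_dpq_idx: dict[int, list[int]] = {}
            bq_ids: dict[int, list[int]] = {}
            dpq_ids: dict[int, list[int]] = {}

            # subpopulation allocation of this year's DPQ sister groups
            # (balanced halves, random assignment of maternal families)
            if s.open_structure == TWO_SUBPOPS:
                half = len(dams) // 2
                perm = rng.permutation(len(dams))
                subpop_of_family = {}
                for pos, fam in enumerate(perm):
                    subpop_of_family[dams[int(fam)]] = (
                        SUBPOP_A if pos < half else SUBPOP_B)
            else:
                subpop_of_family = {d: None for d in dams}

            # produce and mate all offspring; round-robin group assignment
            # balanced across the cohort of controlled matings
            mating_counter = 0
            for dam in dams:
                bq = self._offspring(dam, s.n_bq_per_dam, ROLE_BQ, t)
                dpq = self._offspring(dam, s.n_dpq_per_dam, ROLE_DPQ, t)
                bq_ids[dam], dpq_ids[dam] = bq, dpq
                new_bq_idx[dam], new_dpq_idx[dam] = [], []
                for qid in bq:
                    if use_groups is not None:
                        g = use_groups[mating_counter % len(use_groups)]
                        mating_counter += 1
                        self._mate_and_form_colony(qid, ROLE_BQ, t, g, None)
                    else:
                        self._mate_and_form_colony(qid, ROLE_BQ, t, None, None)
                    new_bq_idx[dam].append(len(self.colony_rows) - 1)
                for qid in dpq:
                    self._mate_and_form_colony(qid, ROLE_DPQ, t, None,
                                               subpop_of_family[dam])
                    new_dpq_idx[dam].append(len(self.colony_rows) - 1)

            # winter mortality: exactly 25% of colonies die per family
            survivors: list[int] = []
            surv_bq: dict[int, list[int]] = {}
            surv_dpq: dict[int, list[int]] = {}
            for dam in dams:
                keep_b = rng.choice(len(new_bq_idx[dam]), s.n_bq_phenotyped,
                                    replace=False)
                keep_d = rng.choice(len(new_dpq_idx[dam]), s.n_dpq_phenotyped,
                                    replace=False)
                surv_bq[dam] = [new_bq_idx[dam][int(i)] for i in sorted(keep_b)]
                surv_dpq[dam] = [new_dpq_idx[dam][int(i)] for i in sorted(keep_d)]
                survivors += surv_bq[dam] + surv_dpq[dam]
            self._phenotype_cohort(survivors, t)

            # within-family selection of the replacement BQ
            next_dams = []
            for dam in dams:
                ph = np.array([self.colony_rows[i][5] for i in surv_bq[dam]])
                best = surv_bq[dam][self._argmax_random_ties(ph)]
                next_dams.append(self.colony_rows[best][0])

            # across-family selection of DPQ dams on mean DPQ-colony phenotype
            fam_means = np.array([
                np.mean([self.colony_rows[i][5] for i in surv_dpq[dam]])
                for dam in dams])
            sel = self._top_k_random_ties(fam_means, s.n_selected_dpq_dams)
            year_groups = []
            for fam in sel:
                dam = dams[int(fam)]
                cand = [self.colony_rows[i][0] for i in surv_dpq[dam]]
                chosen = rng.choice(len(cand), s.n_dpq_per_group, replace=False)
                gid = len(self.groups)
                g = DpqGroup(group_id=gid, year=t, dam=dam,
                             members=tuple(cand[int(i)] for i in sorted(chosen)))
                self.groups.append(g)
                year_groups.append(g)
            groups_by_year[t] = year_groups

            logger.info(
                "year %d: %d queens born, %d colonies phenotyped, "
                "%d DPQ groups formed", t,
                len(dams) * (s.n_bq_per_dam + s.n_dpq_per_dam),
                len(survivors), len(year_groups))
            dams = next_dams
            self.selected_dams.append(dams)

        queens = pd.DataFrame(self.queen_rows, columns=[
            "id", "dam", "byear", "role", "family", "w", "q",
            "father_drone", "father_dpq"])
        colonies = pd.DataFrame(self.colony_rows, columns=[
            "queen", "byear", "role", "label", "survived", "phenotype",
            "wg_w", "wg_q"])
        return SimResult(params=self.p, scheme=self.s, queens=queens,
                         colonies=colonies, matings=self.matings,
                         groups=self.groups, year_effects=self.year_effects,
                         kinship=self.kin, selected_dams=self.selected_dams)


def run_replicate(params: GeneticParameterSet, scheme: SchemeConfig,
                  rng: np.random.Generator | int) -> SimResult:
    """Simulate one replicate of the breeding program.

    All randomness flows from ``rng``; passing the same seed reproduces the
    replicate bit-for-bit.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sys.setrecursionlimit(100000)
    return _Sim(params, scheme, rng).run()


def make_founders(params: GeneticParameterSet, scheme: SchemeConfig,
                  rng: np.random.Generator, n: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Founder queen breeding values and their base-drone mates.

    Returns ``(queens, drones)`` with shapes ``(n, 2)`` and ``(n, D, 2)``;
    queens are N(0, G0), drones N(0, G0/2).  Mainly a testing surface; the
    replicate driver applies the same draws internally.
    """
    params.validate()
    n = scheme.n_founders if n is None else n
    queens = draw_base_queen_bv(params.G0, rng, n)
    drones = draw_base_drone_bv(params.G0, rng, n * scheme.n_drones)
    return queens, drones.reshape(n, scheme.n_drones, 2)
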