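"""Honeybee-specific additive relationship matrix and its sparse inverse.

The pedigree mixes diploid queens, "sire" entries that may represent groups
of drone-producing queens (DPQs), and worker groups.  All relationships are
expressed on the usual additive scale ``a_ij = 2 f_ij`` (twice the
coancestry, with coancestry defined by drawing one random allele from each
entity's allele distribution).  Group entries average over their members:
an open-mating pseudo-sire of S unknown, unrelated, non-inbred queens has
self-relationship ``1/S``.

Every non-founder entity regresses on (at most) two parent entities with
coefficients 1/2 and a residual variance ``d_i``, so ``A = T D T'`` with
``T`` unit lower triangular and ``A^{-1} = (I-B)' D^{-1} (I-B)`` assembles
directly from the factor (never by numerical inversion).

Two modes are provided:

* ``group_level`` (default, the production path): mate entries are shared
  across matings exactly as they appear in the pedigree.  The drone-sampling
  variance of one mating is absorbed into the worker-group residual
  ``d_W = (2 - a_MM) / (4 D)``; covariances between same-mating siblings
  omit the O(1/D) same-drone excess.
* ``exact_per_mating``: a latent sire node is inserted for every realized
  mating, representing the pool of D drones actually used.  Its diagonal
  ``a_LL = a_src + (2 - a_src)/D`` carries the probability 1/D that two
  independent father draws hit the same drone, which makes the plain
  1/2-1/2 recursion exact for all pairs, including same-mating siblings and
  queen/worker-group pairs of one colony.  Worker groups then have zero
  residual (a deterministic average of queen and drone pool), so this mode
  yields an exact but singular A, used for verification rather than for
  estimation.

A gene-dropping Monte-Carlo oracle (:func:`gene_drop_check`) verifies the
analytic recursion by simulating unique founder alleles through the same
allocation model and estimating ``a_ij`` as twice the probability of
identity by descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import (
    DUMMY_DPQ, IDENTIFIED_DPQ, OPEN_GROUP, PS_GROUP, QUEEN, UNKNOWN,
    MateEntry, Pedigree, PedigreeEntity,
)

GROUP_LEVEL = "group_level"
EXACT_PER_MATING = "exact_per_mating"

# node kinds inside the factor
_K_QUEEN = 0
_K_GROUP = 1       # PS_GROUP / OPEN_GROUP
_K_WORKER = 2
_K_LATENT = 3


def shared_father_probs(S: int, D: int) -> tuple[float, float]:
    """Probabilities that two offspring of one mating share a father.

    With D drones drawn uniformly with replacement from S sister-DPQs, two
    offspring have the same father drone with ``p_dr = 1/D`` and the same
    father DPQ with ``p_dpq = 1/D + (1 - 1/D)/S`` (exactly 1 when S = 1,
    the corrected single-sire behaviour).
    """
    if S < 1 or D < 1:
        raise ValueError("S and D must be >= 1")
    p_dr = 1.0 / D
    return p_dr, p_dr + (1.0 - p_dr) / S


@dataclass
class RelationshipFactor:
    """Recursion coefficients and residual variances defining A."""

    mode: str
    ids: list[int]                         # entity id per node (0 = latent)
    node_of: dict[int, int]                # entity id -> node index
    parents: np.ndarray                    # (n, 2) int, -1 = none
    bcoef: np.ndarray                      # (n, 2) float
    d: np.ndarray                          # residual variances
    adiag: np.ndarray                      # self-relationships a_ii
    kind: np.ndarray                       # node kinds
    F: dict[int, float]                    # queen id -> inbreeding coefficient
    _pair: dict[tuple[int, int], float] = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    # -- pairwise relationships ----------------------------------------

    def a_nodes(self, i: int, j: int) -> float:
        """Relationship between two nodes (iterative memoized recursion)."""
        if i == j:
            return float(self.adiag[i])
        key = (i, j) if i > j else (j, i)
        memo = self._pair
        got = memo.get(key)
        if got is not None:
            return got
        parents, bcoef, adiag = self.parents, self.bcoef, self.adiag
        stack = [key]
        while stack:
            x, y = stack[-1]
            if (x, y) in memo:
                stack.pop()
                continue
            val = 0.0
            ready = True
            for k in range(2):
                p = parents[x, k]
                if p < 0:
                    continue
                if p == y:
                    val += bcoef[x, k] * adiag[y]
                elif p < y:
                    sub = memo.get((y, p))
                    if sub is None:
                        stack.append((y, p))
                        ready = False
                    else:
                        val += bcoef[x, k] * sub
                else:
                    sub = memo.get((p, y))
                    if sub is None:
                        stack.append((p, y))
                        ready = False
                    else:
                        val += bcoef[x, k] * sub
            if ready:
                memo[(x, y)] = val
                stack.pop()
        return memo[key]

    def a(self, id_i: int, id_j: int) -> float:
        return self.a_nodes(self.node_of[id_i], self.node_of[id_j])

    def inbreeding(self) -> dict[int, float]:
        return dict(self.F)

    # -- matrices -------------------------------------------------------

    def dense_A(self, max_nodes: int = 4000) -> np.ndarray:
        """Densified A (tabular method); intended for small pedigrees."""
        n = self.n_nodes
        if n > max_nodes:
            raise ValueError(f"pedigree too large to densify ({n} nodes)")
        A = np.zeros((n, n))
        for i in range(n):
            row = np.zeros(i)
            for k in range(2):
                p = self.parents[i, k]
                if p >= 0:
                    row += self.bcoef[i, k] * A[p, :i]
            A[i, :i] = row
            A[:i, i] = row
            A[i, i] = self.adiag[i]
        return A

    def ainverse(self) -> sp.csc_matrix:
        """Sparse A^{-1} assembled from the factor; requires all d_i > 0."""
        bad = np.where(self.d <= 0)[0]
        if len(bad):
            raise ValueError(
                f"non-positive residual variance at node {bad[0]} "
                f"(entity id {self.ids[bad[0]]}); A is singular in this mode")
        n = self.n_nodes
        rows = np.empty(9 * n, np.int64)
        cols = np.empty(9 * n, np.int64)
        vals = np.empty(9 * n, float)
        k = 0
        for i in range(n):
            idx = [i]
            coef = [1.0]
            for m in range(2):
                p = self.parents[i, m]
                if p >= 0:
                    idx.append(int(p))
                    coef.append(-float(self.bcoef[i, m]))
            w = 1.0 / self.d[i]
            for a_i, a_c in zip(idx, coef):
                for b_i, b_c in zip(idx, coef):
                    rows[k] = a_i
                    cols[k] = b_i
                    vals[k] = w * a_c * b_c
                    k += 1
        return sp.csc_matrix((vals[:k], (rows[:k], cols[:k])), shape=(n, n))

    def logdet_A(self) -> float:
        return float(np.sum(np.log(self.d)))


def build_factor(ped: Pedigree, mode: str = GROUP_LEVEL) -> RelationshipFactor:
    """Single forward pass over a topologically ordered pedigree."""
    if mode not in (GROUP_LEVEL, EXACT_PER_MATING):
        raise ValueError(f"unknown mode {mode}")
    exact = mode == EXACT_PER_MATING

    # upper bound on node count: every row plus one latent node per row
    n_max = 2 * len(ped.rows) + 1
    ids: list[int] = []
    node_of: dict[int, int] = {}
    parents = np.full((n_max, 2), -1, np.int64)
    bcoef = np.zeros((n_max, 2))
    dvals = np.zeros(n_max)
    adiag = np.zeros(n_max)
    kinds = np.zeros(n_max, np.int64)
    F: dict[int, float] = {}
    latent: dict[tuple[int, int], int] = {}

    fac = RelationshipFactor(mode=mode, ids=ids, node_of=node_of,
                             parents=parents, bcoef=bcoef, d=dvals,
                             adiag=adiag, kind=kinds, F=F)

    def add_node(eid: int, pa: tuple[int, int], bc: tuple[float, float],
                 a_ii: float, d_i: float, kind: int) -> int:
        node = len(ids)
        ids.append(eid)
        if eid:
            node_of[eid] = node
        parents[node] = pa
        bcoef[node] = bc
        adiag[node] = a_ii
        dvals[node] = d_i
        kinds[node] = kind
        return node

    def latent_node(mother_id: int, mate_id: int) -> int:
        """Latent drone-pool node of one realized mating (exact mode)."""
        key = (mother_id, mate_id)
        node = latent.get(key)
        if node is not None:
            return node
        src = node_of[mate_id]
        D = ped.get(mate_id).D
        a_src = adiag[src]
        d_l = (2.0 - a_src) / D
        node = add_node(0, (src, -1), (1.0, 0.0), a_src + d_l, d_l, _K_LATENT)
        latent[key] = node
        return node

    def individual(eid: int, dam_id: int, sire_id: int) -> None:
        """A queen or dummy DPQ with (possibly unknown) parents."""
        if dam_id == UNKNOWN and sire_id == UNKNOWN:
            add_node(eid, (-1, -1), (0.0, 0.0), 1.0, 1.0, _K_QUEEN)
            F[eid] = 0.0
            return
        if dam_id != UNKNOWN and sire_id != UNKNOWN:
            dm = node_of[dam_id]
            sire = latent_node(dam_id, sire_id) if exact else node_of[sire_id]
            a_dm_m = fac.a_nodes(dm, sire)
            Fi = 0.5 * a_dm_m
            a_ii = 1.0 + Fi
            d_i = a_ii - 0.25 * (adiag[dm] + 2.0 * a_dm_m + adiag[sire])
            add_node(eid, (dm, sire), (0.5, 0.5), a_ii, d_i, _K_QUEEN)
            F[eid] = Fi
            return
        known = node_of[dam_id if dam_id != UNKNOWN else sire_id]
        add_node(eid, (known, -1), (0.5, 0.0), 1.0, 1.0 - 0.25 * adiag[known],
                 _K_QUEEN)
        F[eid] = 0.0

    for row in ped.rows:
        if isinstance(row, PedigreeEntity):
            if row.kind == QUEEN:
                individual(row.id, row.dam_id, row.sire_entry_id)
            else:  # worker group of one colony
                qn = node_of[row.dam_id]
                mate = ped.get(row.sire_entry_id)
                if exact:
                    mn = latent_node(row.dam_id, row.sire_entry_id)
                    quad = 0.25 * (adiag[qn] + 2.0 * fac.a_nodes(qn, mn)
                                   + adiag[mn])
                    add_node(row.id, (qn, mn), (0.5, 0.5), quad, 0.0, _K_WORKER)
                else:
                    mn = node_of[row.sire_entry_id]
                    a_mm = adiag[mn]
                    d_w = (2.0 - a_mm) / (4.0 * mate.D)
                    a_ww = 0.25 * (adiag[qn] + 2.0 * fac.a_nodes(qn, mn)
                                   + a_mm) + d_w
                    add_node(row.id, (qn, mn), (0.5, 0.5), a_ww, d_w, _K_WORKER)
        else:
            m: MateEntry = row
            if m.style == IDENTIFIED_DPQ:
                node_of[m.id] = node_of[m.member_queen_id]
            elif m.style == DUMMY_DPQ:
                individual(m.id, m.dpq_dam_id, m.dpq_dam_mate_id)
            elif m.style == OPEN_GROUP:
                add_node(m.id, (-1, -1), (0.0, 0.0), 1.0 / m.S, 1.0 / m.S,
                         _K_GROUP)
            elif m.style == PS_GROUP:
                # S unidentified sister daughters of (dpq_dam, her mate)
                dm = node_of[m.dpq_dam_id]
                mn = (latent_node(m.dpq_dam_id, m.dpq_dam_mate_id) if exact
                      else node_of[m.dpq_dam_mate_id])
                a_dm_m = fac.a_nodes(dm, mn)
                a_self = 1.0 + 0.5 * a_dm_m                  # member with itself
                a_between = 0.25 * (adiag[dm] + 2.0 * a_dm_m + adiag[mn])
                a_pp = a_self / m.S + (1.0 - 1.0 / m.S) * a_between
                d_p = a_pp - a_between
                add_node(m.id, (dm, mn), (0.5, 0.5), a_pp, d_p, _K_GROUP)
            else:
                raise ValueError(f"mate {m.id}: unknown style {m.style}")

    n = len(ids)
    fac.parents = parents[:n]
    fac.bcoef = bcoef[:n]
    fac.d = dvals[:n]
    fac.adiag = adiag[:n]
    fac.kind = kinds[:n]
    return fac


def invert_factor(factor: RelationshipFactor) -> sp.csc_matrix:
    """Sparse A^{-1}; alias of :meth:`RelationshipFactor.ainverse`."""
    return factor.ainverse()


# ---------------------------------------------------------------------------
# gene-dropping oracle
# ---------------------------------------------------------------------------

class _Support:
    """Allele distribution of an entity: haplotype arrays with weights."""

    def __init__(self, haps: list[np.ndarray], weights: list[float]) -> None:
        self.haps = haps
        self.weights = np.asarray(weights)


def _gamete(hap_a: np.ndarray, hap_b: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    pick = rng.integers(2, size=hap_a.shape[0]).astype(bool)
    return np.where(pick, hap_a, hap_b)


def gene_drop(ped: Pedigree, n_loci: int, rng: np.random.Generator | int
              ) -> dict[int, _Support]:
    """Drop unique founder alleles through the pedigree.

    Every locus is an independent realization of both Mendelian sampling and
    the mating allocation model (which member of a group supplies each of
    the D drones of a mating, which drone fathers each daughter), matching
    the expectations computed by the exact per-mating recursion.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = n_loci
    counter = [0]

    def fresh_hap() -> np.ndarray:
        counter[0] += 1
        return np.full(L, counter[0], np.int32)

    genomes: dict[int, tuple[np.ndarray, np.ndarray]] = {}  # individual -> 2 haps
    slots: dict[tuple[int, int], list[np.ndarray]] = {}     # mating -> drone haps
    members: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}  # group members
    support: dict[int, _Support] = {}

    def draw_drone(mate: MateEntry) -> np.ndarray:
        """One drone haplotype per locus from the mate entry's pool."""
        if mate.style in (IDENTIFIED_DPQ, DUMMY_DPQ):
            src = mate.member_queen_id if mate.style == IDENTIFIED_DPQ else mate.id
            h1, h2 = genomes[src]
            return _gamete(h1, h2, rng)
        mem = members[mate.id]
        pick = rng.integers(len(mem), size=L)
        out = np.empty(L, np.int32)
        for k, (h1, h2) in enumerate(mem):
            mask = pick == k
            nm = int(mask.sum())
            if nm:
                sel = rng.integers(2, size=nm).astype(bool)
                out[mask] = np.where(sel, h1[mask], h2[mask])
        return out

    def mating_slots(mother_id: int, mate: MateEntry) -> list[np.ndarray]:
        key = (mother_id, mate.id)
        if key not in slots:
            slots[key] = [draw_drone(mate) for _ in range(mate.D)]
        return slots[key]

    def offspring_genome(dam_id: int, sire_id: int
                         ) -> tuple[np.ndarray, np.ndarray]:
        dam1, dam2 = genomes[dam_id]
        mat = _gamete(dam1, dam2, rng)
        if sire_id == UNKNOWN:
            return mat, fresh_hap()
        mate = ped.get(sire_id)
        sl = mating_slots(dam_id, mate)
        which = rng.integers(mate.D, size=L)
        pat = np.choose(which, sl)
        return mat, pat

    for row in ped.rows:
        if isinstance(row, MateEntry):
            if row.style == OPEN_GROUP:
                members[row.id] = [(fresh_hap(), fresh_hap())
                                   for _ in range(row.S)]
                haps = [h for m in members[row.id] for h in m]
                support[row.id] = _Support(haps, [0.5 / row.S] * len(haps))
            elif row.style == PS_GROUP:
                mem = [offspring_genome(row.dpq_dam_id, row.dpq_dam_mate_id)
                       for _ in range(row.S)]
                members[row.id] = mem
                haps = [h for m in mem for h in m]
                support[row.id] = _Support(haps, [0.5 / row.S] * len(haps))
            elif row.style == DUMMY_DPQ:
                g = ((fresh_hap(), fresh_hap()) if row.dpq_dam_id == UNKNOWN
                     else offspring_genome(row.dpq_dam_id, row.dpq_dam_mate_id))
                genomes[row.id] = g
                support[row.id] = _Support(list(g), [0.5, 0.5])
            else:  # IDENTIFIED_DPQ shares its member queen's support
                support[row.id] = support[row.member_queen_id]
            continue
        if row.kind == QUEEN:
            g = ((fresh_hap(), fresh_hap()) if row.dam_id == UNKNOWN
                 else offspring_genome(row.dam_id, row.sire_entry_id))
            genomes[row.id] = g
            support[row.id] = _Support(list(g), [0.5, 0.5])
        else:  # worker group: half queen gametes, half own drone pool
            q1, q2 = genomes[row.dam_id]
            mate = ped.get(row.sire_entry_id)
            sl = mating_slots(row.dam_id, mate)
            haps = [q1, q2] + sl
            w = [0.25, 0.25] + [0.5 / mate.D] * mate.D
            support[row.id] = _Support(haps, w)
    return support


def empirical_a(support: dict[int, _Support], i: int, j: int
                ) -> tuple[float, float]:
    """Twice the mean IBD probability between two entities, with its SE.

    The per-locus IBD probability is a weighted mixture of indicator
    variables; the standard error is the empirical SD of that per-locus
    value across the (independent) loci.
    """
    si, sj = support[i], support[j]
    L = si.haps[0].shape[0]
    per_locus = np.zeros(L)
    for hi, wi in zip(si.haps, si.weights):
        for hj, wj in zip(sj.haps, sj.weights):
            per_locus += (wi * wj) * (hi == hj)
    est = 2.0 * float(per_locus.mean())
    se = 2.0 * float(per_locus.std(ddof=1)) / np.sqrt(L)
    return est, se


def gene_drop_check(ped: Pedigree, n_loci: int,
                    rng: np.random.Generator | int,
                    pairs: list[tuple[int, int]] | None = None,
                    mode: str = EXACT_PER_MATING) -> pd.DataFrame:
    """Compare analytic relationships with a gene-dropping estimate.

    Returns one row per entity pair with the analytic value, the
    Monte-Carlo estimate, its binomial standard error, and the absolute
    deviation expressed in standard errors.
    """
    factor = build_factor(ped, mode=mode)
    support = gene_drop(ped, n_loci, rng)
    entity_ids = [r.id for r in ped.rows
                  if not (isinstance(r, MateEntry) and r.style == IDENTIFIED_DPQ)]
    if pairs is None:
        pairs = [(i, j) for k, i in enumerate(entity_ids)
                 for j in entity_ids[k:]]
    rows = []
    for i, j in pairs:
        analytic = factor.a(i, j)
        emp, se = empirical_a(support, i, j)
        dev = abs(analytic - emp)
        # a deterministic mixture (e.g. a group entry with itself) has zero
        # per-locus variance; compare exactly there
        rows.append((i, j, analytic, emp, se,
                     dev / se if se > 1e-12 else (0.0 if dev < 1e-9 else np.inf)))
    return pd.DataFrame(rows, columns=["i", "j", "analytic", "empirical",
                                       "se", "abs_dev_se"])
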