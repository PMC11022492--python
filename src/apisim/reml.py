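"""AI-REML for the colony mixed model with queen and worker effects.

The evaluation model is ``y = Xb + Z_w a_w + Z_q a_q [+ Z_g g] + e`` with
fixed year effects (plus, optionally, fixed open-drone-group levels), two
correlated genetic effects per pedigree entity — a worker effect expressed
by the colony's worker group and a queen effect expressed by the queen —
with covariance ``G0 (x) A``, an optional i.i.d. random group effect, and
i.i.d. residuals.

Worker groups are terminal pedigree entities: the worker effect of colony
``c`` decomposes exactly as ``a_w(W_c) = (a_w(Q_c) + a_w(M_c))/2 + m_c``
where ``Q_c`` and ``M_c`` are the colony queen and her mate entry and
``m_c ~ N(0, d_c * var_w)`` is an independent worker Mendelian residual
(``d_c`` is the worker-group residual from the relationship factor).  The
mixed-model equations used here absorb ``m_c`` into a record-specific
residual variance ``r_c = var_e + var_w * d_c``, which halves the system
size without changing the restricted likelihood.

Estimation maximizes the exact restricted log-likelihood, evaluated through
a sparse factorization of the mixed-model coefficient matrix
(``-2 RL = log|R| + log|G| + log|C| + y'Py + const``), with Newton steps
built from the average-information matrix and a central finite-difference
score.  Updates that leave the parameter space are bent back (eigenvalue
flooring of the 2x2 genetic covariance); steps that fail to improve the
restricted likelihood fall back to damped (Levenberg) updates.  Predicted
standard errors come from the inverse average-information matrix at the
optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import BASE_OPEN, CONTROLLED, SUBPOP_A, SUBPOP_B
from .relationship import _K_WORKER, RelationshipFactor
from .scenarios import EstimationData

_GROUP_LEVELS = (BASE_OPEN, SUBPOP_A, SUBPOP_B)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class MixedModelSpec:
    """Design matrices and pedigree structure for one analysis."""

    y: np.ndarray                  # (n_rec,) phenotypes
    X: sp.csr_matrix               # fixed effects (full column rank)
    Zw: sp.csr_matrix              # worker-effect loadings onto nodes
    Zq: sp.csr_matrix              # queen-effect loadings onto nodes
    Ainv: sp.csc_matrix            # inverse relationship matrix (nodes)
    logdet_A: float
    d_resid: np.ndarray            # worker Mendelian residual d_c per record
    Zg: sp.csr_matrix | None = None  # random open-group levels
    fixed_names: list[str] = field(default_factory=list)
    node_ids: list[int] = field(default_factory=list)   # estimation entity ids
    node_byear: np.ndarray | None = None
    node_is_queen: np.ndarray | None = None

    # assembled once
    W: sp.csr_matrix = None
    Wt: sp.csr_matrix = None
    yty: float = 0.0

    @property
    def n_rec(self) -> int:
        return len(self.y)

    @property
    def n_nodes(self) -> int:
        return self.Ainv.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_glevels(self) -> int:
        return 0 if self.Zg is None else self.Zg.shape[1]

    @property
    def random_group(self) -> bool:
        return self.Zg is not None

    def finalize(self) -> "MixedModelSpec":
        blocks = [self.Zw, self.Zq, self.X]
        if self.Zg is not None:
            blocks.append(self.Zg)
        self.W = sp.hstack(blocks, format="csr")
        self.Wt = self.W.T.tocsr()
        self.yty = float(self.y @ self.y)
        return self


def _year_dummies(years: np.ndarray) -> tuple[sp.csr_matrix, list[str]]:
    levels = sorted(set(int(t) for t in years))
    cols = {t: k for k, t in enumerate(levels)}
    n = len(years)
    X = sp.csr_matrix((np.ones(n), (np.arange(n), [cols[int(t)] for t in years])),
                      shape=(n, len(levels)))
    return X, [f"year_{t}" for t in levels]


def _drop_dependent_columns(X: sp.csr_matrix, names: list[str]
                            ) -> tuple[sp.csr_matrix, list[str]]:
    G = (X.T @ X).toarray()
    # greedy Cholesky-style rank detection on the (small) Gram matrix
    keep: list[int] = []
    for j in range(G.shape[0]):
        sub = G[np.ix_(keep + [j], keep + [j])]
        if np.linalg.matrix_rank(sub, tol=1e-8 * max(1.0, G.max())) == len(keep) + 1:
            keep.append(j)
    if len(keep) < G.shape[0]:
        dropped = [names[j] for j in range(G.shape[0]) if j not in keep]
        warnings.warn(f"singular fixed block; dropping {dropped} to reference")
        X = X[:, keep].tocsr()
        names = [names[j] for j in keep]
    return X, names


def build_model(est: EstimationData, factor: RelationshipFactor
                ) -> MixedModelSpec:
    """Assemble the mixed-model specification for one scenario.

    Worker groups are absorbed: each record loads 1/2 on the worker effect
    of its colony queen and its mate entry and carries the worker-group
    residual ``d_c`` in its own residual variance.
    """
    rec = est.records
    n = len(rec)
    if n == 0:
        raise ValueError("no phenotyped records")

    # reduced node set: all factor nodes except worker groups
    keep = np.where(factor.kind != _K_WORKER)[0]
    red = {int(old): k for k, old in enumerate(keep)}
    node_ids = [factor.ids[int(old)] for old in keep]

    # reduced A^-1: worker groups are terminal, so simply skip their
    # contributions when assembling the factorized inverse
    rows, cols, vals = [], [], []
    logdet = 0.0
    for i in keep:
        i = int(i)
        idx = [red[i]]
        coef = [1.0]
        for k in range(2):
            p = factor.parents[i, k]
            if p >= 0:
                idx.append(red[int(p)])
                coef.append(-float(factor.bcoef[i, k]))
        di = float(factor.d[i])
        if di <= 0:
            raise ValueError(f"non-positive residual variance at entity {factor.ids[i]}")
        logdet += np.log(di)
        w = 1.0 / di
        for a, ac in zip(idx, coef):
            for b, bc in zip(idx, coef):
                rows.append(a)
                cols.append(b)
                vals.append(w * ac * bc)
    n_nodes = len(keep)
    Ainv = sp.csc_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes))

    qnode = np.array([red[factor.node_of[q]] for q in rec.queen_id])
    mnode = np.array([red[factor.node_of[m]] for m in rec.mate_entry_id])
    wnode = np.array([factor.node_of[w] for w in rec.worker_group_id])
    d_resid = factor.d[wnode].copy()

    r_idx = np.arange(n)
    Zw = sp.csr_matrix(
        (np.r_[np.full(n, 0.5), np.full(n, 0.5)],
         (np.r_[r_idx, r_idx], np.r_[qnode, mnode])), shape=(n, n_nodes))
    Zq = sp.csr_matrix((np.ones(n), (r_idx, qnode)), shape=(n, n_nodes))

    X, names = _year_dummies(rec.year.to_numpy())
    labels = rec.open_group_label.to_numpy()
    Zg = None
    if est.fixed_group:
        extra_cols = []
        extra_names = []
        for lab in _GROUP_LEVELS:
            ind = (labels == lab).astype(float)
            if ind.any():
                extra_cols.append(sp.csr_matrix(ind.reshape(-1, 1)))
                extra_names.append(f"group_{lab}")
        X = sp.hstack([X] + extra_cols, format="csr")
        names = names + extra_names
    elif est.random_group:
        lv = {lab: k for k, lab in enumerate(_GROUP_LEVELS)}
        rr, cc = [], []
        for i, lab in enumerate(labels):
            if lab != CONTROLLED:
                rr.append(i)
                cc.append(lv[lab])
        Zg = sp.csr_matrix((np.ones(len(rr)), (rr, cc)), shape=(n, 3))
    X, names = _drop_dependent_columns(X, names)

    byear = np.zeros(n_nodes)
    isq = np.zeros(n_nodes, bool)
    for k, old in enumerate(keep):
        eid = factor.ids[int(old)]
        if eid and eid in est.pedigree:
            row = est.pedigree.get(eid)
            byear[k] = getattr(row, "birth_year", 0)
            isq[k] = getattr(row, "kind", "") == "QUEEN"

    spec = MixedModelSpec(
        y=rec.phenotype.to_numpy(float), X=X, Zw=Zw, Zq=Zq, Ainv=Ainv,
        logdet_A=logdet, d_resid=d_resid, Zg=Zg, fixed_names=names,
        node_ids=node_ids, node_byear=byear, node_is_queen=isq)
    return spec.finalize()


# ---------------------------------------------------------------------------
# restricted likelihood machinery
# ---------------------------------------------------------------------------

def _theta_dict(theta: np.ndarray, random_group: bool) -> dict[str, float]:
    out = {"var_w": theta[0], "cov_wq": theta[1], "var_q": theta[2],
           "var_e": theta[3]}
    if random_group:
        out["var_g"] = theta[4]
    return out


def _bend(theta: np.ndarray, floor_frac: float = 1e-6) -> np.ndarray:
    """Project parameters into the admissible space.

    The 2x2 genetic covariance has its eigenvalues floored at a small
    fraction of its trace; variances are floored at small positive values.
    """
    th = theta.copy()
    G = np.array([[th[0], th[1]], [th[1], th[2]]])
    tr = max(G[0, 0] + G[1, 1], 1e-8)
    w, v = np.linalg.eigh(G)
    floor = floor_frac * tr
    if w[0] < floor:
        G = v @ np.diag(np.maximum(w, floor)) @ v.T
        th[0], th[1], th[2] = G[0, 0], G[0, 1], G[1, 1]
    th[3] = max(th[3], 1e-8)
    if len(th) > 4:
        th[4] = max(th[4], 1e-10)
    return th


def assemble_mme(spec: MixedModelSpec, theta: np.ndarray
                 ) -> tuple[sp.csc_matrix, np.ndarray, np.ndarray]:
    """Henderson mixed-model equations at parameters ``theta``.

    Returns the coefficient matrix, the right-hand side and the per-record
    residual variances ``r_c = var_e + var_w * d_c``.
    """
    g11, g12, g22, ve = theta[:4]
    r = ve + g11 * spec.d_resid
    G0 = np.array([[g11, g12], [g12, g22]])
    G0i = np.linalg.inv(G0)
    Rw = spec.Wt.multiply(1.0 / r)          # W' R^-1
    C = (Rw @ spec.W).tocsc()
    n = spec.n_nodes
    gblk = sp.bmat([[G0i[0, 0] * spec.Ainv, G0i[0, 1] * spec.Ainv],
                    [G0i[1, 0] * spec.Ainv, G0i[1, 1] * spec.Ainv]])
    pads = [gblk, sp.csc_matrix((spec.n_fixed, spec.n_fixed))]
    if spec.random_group:
        pads.append(sp.eye(spec.n_glevels) / theta[4])
    C = C + sp.block_diag(pads, format="csc")
    rhs = np.asarray(Rw @ spec.y).ravel()
    return C, rhs, r


@dataclass
class _Eval:
    rl: float
    sol: np.ndarray | None
    lu: object | None
    r: np.ndarray | None


def _restricted_loglik(spec: MixedModelSpec, theta: np.ndarray,
                       need_sol: bool = True) -> _Eval:
    g11, g12, g22, ve = theta[:4]
    G0 = np.array([[g11, g12], [g12, g22]])
    sign, logdet_G0 = np.linalg.slogdet(G0)
    if sign <= 0 or ve <= 0 or (spec.random_group and theta[4] <= 0):
        return _Eval(-np.inf, None, None, None)
    C, rhs, r = assemble_mme(spec, theta)
    try:
        lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A",
                       options=dict(SymmetricMode=True))
    except RuntimeError:
        # numerically singular system at extreme parameter values: treat the
        # point as inadmissible so the step is rejected or damped
        return _Eval(-np.inf, None, None, None)
    logdet_C = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    sol = lu.solve(rhs)
    yry = float(spec.y @ (spec.y / r))
    ypy = yry - float(sol @ rhs)
    logdet_R = float(np.sum(np.log(r)))
    logdet_G = (spec.n_nodes * logdet_G0 + 2.0 * spec.logdet_A
                + (spec.n_glevels * np.log(theta[4]) if spec.random_group else 0.0))
    m2rl = (logdet_R + logdet_G + logdet_C + ypy
            + (spec.n_rec - spec.n_fixed) * np.log(2.0 * np.pi))
    return _Eval(-0.5 * m2rl, sol if need_sol else None,
                 lu if need_sol else None, r)


def reml_loglik(spec: MixedModelSpec, theta) -> float:
    """Exact restricted log-likelihood (including constants)."""
    return _restricted_loglik(spec, np.asarray(theta, float), need_sol=False).rl


def _ai_matrix(spec: MixedModelSpec, theta: np.ndarray, ev: _Eval,
               Alu) -> np.ndarray:
    """Average-information matrix from data-based quantities (exact)."""
    r = ev.r
    resid = spec.y - np.asarray(spec.W @ ev.sol).ravel()
    Py = resid / r

    n = spec.n_nodes
    vw = np.asarray(spec.Zw.T @ Py).ravel()
    vq = np.asarray(spec.Zq.T @ Py).ravel()
    Aw = Alu.solve(vw)
    Aq = Alu.solve(vq)
    fs = [
        np.asarray(spec.Zw @ Aw).ravel() + spec.d_resid * Py,      # d/d var_w
        np.asarray(spec.Zw @ Aq + spec.Zq @ Aw).ravel(),           # d/d cov
        np.asarray(spec.Zq @ Aq).ravel(),                          # d/d var_q
        Py,                                                        # d/d var_e
    ]
    if spec.random_group:
        fs.append(np.asarray(spec.Zg @ (spec.Zg.T @ Py)).ravel())
    Pf = []
    for f in fs:
        rhs = np.asarray(spec.Wt @ (f / r)).ravel()
        solf = ev.lu.solve(rhs)
        Pf.append((f - np.asarray(spec.W @ solf).ravel()) / r)
    k = len(fs)
    AI = np.empty((k, k))
    for a in range(k):
        for b in range(a, k):
            AI[a, b] = AI[b, a] = 0.5 * float(fs[a] @ Pf[b])
    return AI


# ---------------------------------------------------------------------------
# the AI-REML driver
# ---------------------------------------------------------------------------

@dataclass
class REMLOptions:
    start: tuple[float, float, float, float] = (5.0, 0.0, 5.0, 35.0)
    start_group_var: float = 1.0
    tol: float = 1e-8
    max_iter: int = 200
    fd_rel: float = 1e-4
    # high-precision final localization of the optimum (Richardson-
    # extrapolated scores); None = automatic, on for small systems where the
    # extra factorizations are cheap
    polish: bool | None = None


@dataclass
class REMLResult:
    estimates: dict[str, float]
    r_wq: float
    converged: bool
    n_iter: int
    loglik: float
    predicted_se: dict[str, float]
    ai: np.ndarray
    sol: np.ndarray
    spec: MixedModelSpec
    history: list[tuple[int, float]]

    @property
    def theta(self) -> np.ndarray:
        keys = ["var_w", "cov_wq", "var_q", "var_e"]
        if "var_g" in self.estimates:
            keys.append("var_g")
        return np.array([self.estimates[k] for k in keys])

    def ebv(self) -> pd.DataFrame:
        """Worker- and queen-effect EBVs for every queen entity."""
        n = self.spec.n_nodes
        uw = self.sol[:n]
        uq = self.sol[n:2 * n]
        mask = self.spec.node_is_queen
        return pd.DataFrame({
            "id": np.asarray(self.spec.node_ids)[mask],
            "byear": self.spec.node_byear[mask].astype(int),
            "ebv_w": uw[mask],
            "ebv_q": uq[mask],
        })


def _fd_score(spec: MixedModelSpec, theta: np.ndarray, fd_rel: float,
              base_rl: float) -> np.ndarray:
    """Central finite-difference score, one-sided at inadmissible points."""
    grad = np.empty(len(theta))
    for k in range(len(theta)):
        h = fd_rel * max(abs(theta[k]), 0.05 * theta[3])
        tp = theta.copy()
        tp[k] += h
        tm = theta.copy()
        tm[k] -= h
        rp = _restricted_loglik(spec, _bend(tp), need_sol=False).rl
        rm = _restricted_loglik(spec, _bend(tm), need_sol=False).rl
        if np.isfinite(rp) and np.isfinite(rm):
            grad[k] = (rp - rm) / (2.0 * h)
        elif np.isfinite(rp):
            grad[k] = (rp - base_rl) / h
        elif np.isfinite(rm):
            grad[k] = (base_rl - rm) / h
        else:
            grad[k] = 0.0
    return grad


def _richardson_score(spec: MixedModelSpec, theta: np.ndarray) -> np.ndarray:
    """High-accuracy score: Richardson extrapolation of central differences.

    Combines step sizes h and h/2 to cancel the O(h^2) truncation term,
    leaving roundoff ~1e-9/h; used only for the final localization of the
    optimum, where the extra likelihood evaluations are affordable.
    """
    def central(h_scale):
        g = np.empty(len(theta))
        for k in range(len(theta)):
            h = h_scale * max(abs(theta[k]), 0.05 * theta[3])
            tp = theta.copy()
            tp[k] += h
            tm = theta.copy()
            tm[k] -= h
            rp = _restricted_loglik(spec, tp, need_sol=False).rl
            rm = _restricted_loglik(spec, tm, need_sol=False).rl
            if not (np.isfinite(rp) and np.isfinite(rm)):
                return None
            g[k] = (rp - rm) / (2.0 * h)
        return g

    g1 = central(2e-3)
    g2 = central(1e-3)
    if g1 is None or g2 is None:
        return None
    return (4.0 * g2 - g1) / 3.0


def ai_reml(spec: MixedModelSpec, options: REMLOptions | None = None
            ) -> REMLResult:
    """Maximize the restricted likelihood by AI-accelerated Newton steps.

    Convergence is declared when the largest relative parameter change of an
    accepted step falls below ``options.tol`` (or the restricted likelihood
    stops improving to numerical precision); otherwise the fit is flagged
    non-converged after ``max_iter`` iterations.
    """
    opt = options or REMLOptions()
    if np.std(spec.y) == 0:
        raise ValueError("zero-variance response")
    theta = np.array(list(opt.start) +
                     ([opt.start_group_var] if spec.random_group else []))
    theta = _bend(theta)
    if not np.all(np.isfinite(theta)):
        raise ValueError("invalid starting values")

    Alu = spla.splu(spec.Ainv.tocsc(), permc_spec="MMD_AT_PLUS_A",
                    options=dict(SymmetricMode=True))
    ev = _restricted_loglik(spec, theta)
    if not np.isfinite(ev.rl):
        raise ValueError("starting values outside the parameter space")
    history = [(0, ev.rl)]
    converged = False
    n_iter = 0
    stall = 0
    AI = np.eye(len(theta))

    for it in range(1, opt.max_iter + 1):
        n_iter = it
        grad = _fd_score(spec, theta, opt.fd_rel, ev.rl)
        AI = _ai_matrix(spec, theta, ev, Alu)

        accepted = False
        mu = 0.0
        scale = np.trace(AI) / len(theta)
        for attempt in range(8):
            try:
                step = np.linalg.solve(AI + mu * scale * np.eye(len(theta)), grad)
            except np.linalg.LinAlgError:
                mu = max(4.0 * mu, 1e-4)
                continue
            cand = _bend(theta + step)
            ev_new = _restricted_loglik(spec, cand)
            if np.isfinite(ev_new.rl) and ev_new.rl >= ev.rl - 1e-9 * (1 + abs(ev.rl)):
                accepted = True
                break
            mu = max(4.0 * mu, 1e-4)
        if not accepted:
            # no admissible uphill step: treat as stalled
            stall += 1
            if stall >= 2:
                break
            continue

        delta = np.max(np.abs(cand - theta) / np.maximum(np.abs(cand), 1e-2 * cand[3]))
        improve = ev_new.rl - ev.rl
        theta, ev = cand, ev_new
        history.append((it, ev.rl))
        if delta < opt.tol:
            converged = True
            break
        if improve < 1e-10 * (1 + abs(ev.rl)):
            stall += 1
            if stall >= 2:
                converged = True
                break
        else:
            stall = 0

    polish = opt.polish if opt.polish is not None else spec.n_rec <= 2000
    if polish and converged:
        for _ in range(6):
            grad = _richardson_score(spec, theta)
            if grad is None:
                break
            AI = _ai_matrix(spec, theta, ev, Alu)
            try:
                step = np.linalg.solve(AI + 1e-10 * np.eye(len(theta)), grad)
            except np.linalg.LinAlgError:
                break
            cand = _bend(theta + step)
            ev_new = _restricted_loglik(spec, cand)
            if not np.isfinite(ev_new.rl) or ev_new.rl < ev.rl - 1e-7 * (1 + abs(ev.rl)):
                break
            moved = np.max(np.abs(cand - theta))
            theta, ev = cand, ev_new
            history.append((n_iter, ev.rl))
            if moved < 1e-9 * max(1.0, theta[3]):
                break

    AI = _ai_matrix(spec, theta, ev, Alu)
    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(theta), np.nan)
    names = ["var_w", "cov_wq", "var_q", "var_e"] + (
        ["var_g"] if spec.random_group else [])
    estimates = dict(zip(names, theta))
    denom = np.sqrt(max(theta[0], 1e-12) * max(theta[2], 1e-12))
    r_wq = float(np.clip(theta[1] / denom, -1.0, 1.0))
    return REMLResult(
        estimates=estimates, r_wq=r_wq, converged=converged, n_iter=n_iter,
        loglik=ev.rl, predicted_se=dict(zip(names, se)), ai=AI, sol=ev.sol,
        spec=spec, history=history)


def fit_scenario(est: EstimationData, factor: RelationshipFactor,
                 options: REMLOptions | None = None) -> REMLResult:
    """Convenience wrapper: build the model and run AI-REML."""
    return ai_reml(build_model(est, factor), options)
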