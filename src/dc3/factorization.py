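"""Coupled non-negative matrix factorization of expression, accessibility and loops.

The core model jointly factorizes a gene x cell expression matrix E, an
enhancer x cell accessibility matrix O and a sparse gene x enhancer loop-count
matrix C by minimizing

    1/2 ||C - a D o (W1 L W2^T)||_F^2  +  mu1/2 ||E - W1 H1||_F^2
                                       +  mu2/2 ||O - W2 H2||_F^2

subject to column-simplex constraints on H1, H2 and the mixing weights L
(lambda), with D the 0/1 indicator of modeled loop pairs and ``a`` (alpha) a
global scale. The coupling term ties the two clusterings together through the
observed loops: within a subpopulation, loop strength is modeled as
proportional to the product of promoter expression and enhancer openness.

Optimization is by multiplicative updates. Because the H-column
renormalization and the lambda re-estimate are not themselves descent
operations (and the printed W2 rule drops alpha), every substep is verified
against the total objective and exponent-damped or rejected if it would
increase it; this makes the trajectory monotone by construction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .datatypes import LoopTable, SingleCellLoopMatrix

EPS = 1e-12

__all__ = [
    "FactorModel",
    "OptimizerTrace",
    "DC3",
    "objective",
    "update_step",
    "fit",
    "fit_setting",
    "als_initialize",
    "select_hyperparameters",
    "select_K",
    "assign_clusters",
    "HyperparameterSearchResult",
]


# ---------------------------------------------------------------------------
# model containers


@dataclass
class FactorModel:
    """Fitted factors and hyper-parameters of the coupled model.

    ``W1``: gene x K, ``H1``: K x n1, ``W2``: enhancer x K, ``H2``: K x n2,
    ``lam``: K mixing weights on the simplex, ``alpha``: coupling scale.
    Settings with single-cell loop input carry auxiliary ``W3`` (pair x K)
    and ``H3`` (K x n3). Bulk-input settings leave the corresponding H as
    None.
    """

    W1: np.ndarray | None
    H1: np.ndarray | None
    W2: np.ndarray | None
    H2: np.ndarray | None
    lam: np.ndarray
    alpha: float
    mu1: float
    mu2: float
    K: int
    setting: int = 2
    W3: np.ndarray | None = None
    H3: np.ndarray | None = None

    def validate(self) -> None:
        for H in (self.H1, self.H2, self.H3):
            if H is not None and not np.allclose(H.sum(axis=0), 1.0, atol=1e-8):
                raise ValueError("H columns must sum to 1")
        if not np.isclose(self.lam.sum(), 1.0, atol=1e-8):
            raise ValueError("lambda must lie on the simplex")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def copy(self) -> "FactorModel":
        return FactorModel(
            W1=None if self.W1 is None else self.W1.copy(),
            H1=None if self.H1 is None else self.H1.copy(),
            W2=None if self.W2 is None else self.W2.copy(),
            H2=None if self.H2 is None else self.H2.copy(),
            lam=self.lam.copy(),
            alpha=float(self.alpha),
            mu1=self.mu1,
            mu2=self.mu2,
            K=self.K,
            setting=self.setting,
            W3=None if self.W3 is None else self.W3.copy(),
            H3=None if self.H3 is None else self.H3.copy(),
        )


@dataclass
class OptimizerTrace:
    objective: list[float] = field(default_factory=list)
    relative_change: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    seed: int | None = None


# ---------------------------------------------------------------------------
# objective


def _coupling_matrix(W1, W2, lam, D):
    """D o (W1 L W2^T) -- the modeled loop matrix before the alpha scale."""
    return D * ((W1 * lam[None, :]) @ W2.T)


def _as_dense_loops(loops: LoopTable) -> tuple[np.ndarray, np.ndarray]:
    return loops.to_dense()


def objective(E, O, loops: LoopTable, model: FactorModel) -> float:
    """Total objective of the coupled problem (setting 2)."""
    C, D = _as_dense_loops(loops)
    return _objective_dense(
        np.asarray(E, float), np.asarray(O, float), C, D,
        model.W1, model.H1, model.W2, model.H2, model.lam, model.alpha,
        model.mu1, model.mu2,
    )


def _objective_dense(E, O, C, D, W1, H1, W2, H2, lam, alpha, mu1, mu2) -> float:
    M = _coupling_matrix(W1, W2, lam, D)
    val = 0.5 * float(np.sum((C - alpha * M) ** 2))
    val += 0.5 * mu1 * float(np.sum((E - W1 @ H1) ** 2))
    val += 0.5 * mu2 * float(np.sum((O - W2 @ H2) ** 2))
    return val


# ---------------------------------------------------------------------------
# verified multiplicative substeps


def _normalize_columns(H):
    s = H.sum(axis=0)
    out = H / np.maximum(s, EPS)[None, :]
    dead = s <= EPS  # e.g. an all-zero cell after dropout: keep on the simplex
    if np.any(dead):
        out[:, dead] = 1.0 / H.shape[0]
    return out


def _damped_multiplicative(current, ratio, obj_of, obj0, normalize=False):
    """Apply x <- x * ratio**gamma, halving gamma until the objective does
    not increase; returns (accepted array, new objective)."""
    tol = 1e-13 * max(obj0, 1.0)
    gamma = 1.0
    for _ in range(30):
        cand = current * np.power(ratio, gamma)
        if normalize:
            cand = _normalize_columns(cand)
        val = obj_of(cand)
        if np.isfinite(val) and val <= obj0 + tol:
            return cand, val
        gamma *= 0.5
    return current, obj0


def _alpha_closed_form(C, M, alpha_old):
    den = float(np.sum(M * M))
    if den <= 0.0:
        warnings.warn("coupling prediction identically zero; alpha update skipped")
        return alpha_old
    num = float(np.sum(M * C))
    if num <= 0.0:
        return alpha_old
    return num / den


def update_step(E, O, loops: LoopTable, model: FactorModel,
                symmetric_alpha: bool = True) -> FactorModel:
    """One full multiplicative update (W1, H1, W2, H2, renormalize, alpha,
    lambda), each substep verified against the total objective.

    The printed W2 rule omits alpha from the coupling gradient split;
    ``symmetric_alpha=True`` inserts alpha/alpha^2 symmetrically. A closing
    alpha refit keeps alpha at its closed form for the returned factors.
    """
    C, D = _as_dense_loops(loops)
    m = model.copy()
    E = np.asarray(E, float)
    O = np.asarray(O, float)
    _update_coupled_state(E, O, C, D, m, symmetric_alpha)
    return m


def _update_coupled_state(E, O, C, D, m: FactorModel, symmetric_alpha: bool) -> float:
    """In-place verified update of a setting-2 state; returns the objective."""
    mu1, mu2 = m.mu1, m.mu2

    def obj(W1=None, H1=None, W2=None, H2=None, lam_=None, alpha=None):
        return _objective_dense(
            E, O, C, D,
            m.W1 if W1 is None else W1,
            m.H1 if H1 is None else H1,
            m.W2 if W2 is None else W2,
            m.H2 if H2 is None else H2,
            m.lam if lam_ is None else lam_,
            m.alpha if alpha is None else alpha,
            mu1, mu2,
        )

    cur = obj()

    # W1 rule
    M = _coupling_matrix(m.W1, m.W2, m.lam, D)
    W2lam = m.W2 * m.lam[None, :]
    num = mu1 * (E @ m.H1.T) + m.alpha * (C @ W2lam)
    den = mu1 * (m.W1 @ (m.H1 @ m.H1.T)) + m.alpha ** 2 * (M @ W2lam)
    ratio = num / np.maximum(den, EPS)
    m.W1, cur = _damped_multiplicative(m.W1, ratio, lambda W: obj(W1=W), cur)

    # H1 rule + column renormalization
    num = m.W1.T @ E
    den = (m.W1.T @ m.W1) @ m.H1
    ratio = num / np.maximum(den, EPS)
    m.H1, cur = _damped_multiplicative(
        m.H1, ratio, lambda H: obj(H1=H), cur, normalize=True
    )

    # W2 rule (alpha omitted from the coupling split unless symmetric_alpha)
    M = _coupling_matrix(m.W1, m.W2, m.lam, D)
    W1lam = m.W1 * m.lam[None, :]
    a_num = m.alpha if symmetric_alpha else 1.0
    a_den = m.alpha ** 2 if symmetric_alpha else 1.0
    num = mu2 * (O @ m.H2.T) + a_num * (C.T @ W1lam)
    den = mu2 * (m.W2 @ (m.H2 @ m.H2.T)) + a_den * (M.T @ W1lam)
    ratio = num / np.maximum(den, EPS)
    m.W2, cur = _damped_multiplicative(m.W2, ratio, lambda W: obj(W2=W), cur)

    # H2 rule + column renormalization
    num = m.W2.T @ O
    den = (m.W2.T @ m.W2) @ m.H2
    ratio = num / np.maximum(den, EPS)
    m.H2, cur = _damped_multiplicative(
        m.H2, ratio, lambda H: obj(H2=H), cur, normalize=True
    )

    # alpha closed form
    M = _coupling_matrix(m.W1, m.W2, m.lam, D)
    m.alpha = _alpha_closed_form(C, M, m.alpha)
    cur = obj()

    # lambda: average assignment weight per cluster, damped toward the
    # current value if it would increase the objective
    lam_cand = (m.H1.sum(axis=1) + m.H2.sum(axis=1)) / (m.H1.shape[1] + m.H2.shape[1])
    tol = 1e-13 * max(cur, 1.0)
    gamma = 1.0
    for _ in range(30):
        cand = (1.0 - gamma) * m.lam + gamma * lam_cand
        val = obj(lam_=cand)
        if np.isfinite(val) and val <= cur + tol:
            m.lam, cur = cand, val
            break
        gamma *= 0.5

    # closing alpha refit so alpha matches its closed form for the new lambda
    M = _coupling_matrix(m.W1, m.W2, m.lam, D)
    m.alpha = _alpha_closed_form(C, M, m.alpha)
    return obj()


# ---------------------------------------------------------------------------
# initialization


def _projected_als(X, K, rng, n_iter=200, tol=1e-10):
    scale = np.sqrt(max(X.mean(), EPS) / K)
    W = (1.0 - rng.random((X.shape[0], K))) * scale
    H = (1.0 - rng.random((K, X.shape[1]))) * scale
    prev = np.inf
    for _ in range(n_iter):
        H = np.maximum(np.linalg.lstsq(W, X, rcond=None)[0], 0.0)
        W = np.maximum(np.linalg.lstsq(H.T, X.T, rcond=None)[0].T, 0.0)
        resid = float(np.sum((X - W @ H) ** 2))
        if np.isfinite(prev) and prev - resid <= tol * max(prev, 1.0):
            prev = resid
            break
        prev = resid
    return W, H, prev


def als_initialize(E, O, K, n_restarts: int = 50, seed=None, n_iter: int = 200):
    """Independent non-negativity-projected ALS factorizations of E and O.

    Runs ``n_restarts`` Monte-Carlo random starts for each matrix and returns
    the lowest-residual (W, H) pair of each: (W1, H1, W2, H2).
    """
    rng = np.random.default_rng(seed)
    out = []
    for X in (np.asarray(E, float), np.asarray(O, float)):
        best = None
        for _ in range(n_restarts):
            W, H, resid = _projected_als(X, K, rng, n_iter=n_iter)
            if best is None or resid < best[2]:
                best = (W, H, resid)
        out.extend(best[:2])
    return tuple(out)


def _align_columns_to_coupling(loops: LoopTable, W1, W2, H2):
    """Permute (W2, H2) columns so cluster k of the accessibility factor
    matches cluster k of the expression factor.

    Independent initializations fix an arbitrary column order per modality;
    multiplicative updates cannot swap columns later, so a mismatched order
    would strand the fit in a poor stationary point. The permutation
    maximizes, over the loop support, the summed Pearson correlation between
    observed counts and each candidate rank-one coupling component.
    """
    from scipy.optimize import linear_sum_assignment

    gi, ei = loops.gene_index, loops.enhancer_index
    c = loops.count
    if len(c) == 0 or np.std(c) == 0:
        return W2, H2
    K = W1.shape[1]
    score = np.zeros((K, K))
    cc = c - c.mean()
    for k in range(K):
        for l in range(K):
            pred = W1[gi, k] * W2[ei, l]
            sd = pred.std()
            if sd > 0:
                score[k, l] = float((cc * (pred - pred.mean())).sum()) / sd
    _, cols = linear_sum_assignment(-score)
    return W2[:, cols], H2[cols, :]


def _initial_model(E, O, loops, K, mu1, mu2, init, seed, n_restarts, als_iter):
    if isinstance(init, (tuple, list)):
        W1, H1, W2, H2 = (np.asarray(a, float).copy() for a in init)
    elif init == "als":
        W1, H1, W2, H2 = als_initialize(
            E, O, K, n_restarts=n_restarts, seed=seed, n_iter=als_iter
        )
    elif init == "random":
        rng = np.random.default_rng(seed)
        s1 = np.sqrt(max(np.mean(E), EPS) / K)
        s2 = np.sqrt(max(np.mean(O), EPS) / K)
        W1 = (1.0 - rng.random((E.shape[0], K))) * s1
        H1 = 1.0 - rng.random((K, E.shape[1]))
        W2 = (1.0 - rng.random((O.shape[0], K))) * s2
        H2 = 1.0 - rng.random((K, O.shape[1]))
    else:
        raise ValueError(f"unknown init {init!r}")
    W2, H2 = _align_columns_to_coupling(loops, W1, W2, H2)
    # keep multiplicative updates alive on exact zeros from the projection
    floor1 = 1e-10 * max(W1.max(), 1.0)
    floor2 = 1e-10 * max(W2.max(), 1.0)
    W1 = np.maximum(W1, floor1)
    W2 = np.maximum(W2, floor2)
    H1 = _normalize_columns(np.maximum(H1, 1e-10))
    H2 = _normalize_columns(np.maximum(H2, 1e-10))
    lam = np.full(K, 1.0 / K)
    C, D = loops.to_dense()
    M = _coupling_matrix(W1, W2, lam, D)
    alpha = _alpha_closed_form(C, M, 1.0)
    return FactorModel(W1, H1, W2, H2, lam, alpha, mu1, mu2, K)


def fit(E, O, loops: LoopTable, K: int, mu1: float, mu2: float,
        init="als", tol: float = 1e-4, max_iter: int = 300, seed=None,
        n_restarts: int = 10, als_iter: int = 100,
        symmetric_alpha: bool = True) -> tuple[FactorModel, OptimizerTrace]:
    """Fit the coupled model (setting 2) by verified multiplicative updates.

    Iterates until the relative change of the objective drops below ``tol``
    or ``max_iter`` is reached. ``init`` is "als", "random" or an explicit
    (W1, H1, W2, H2) tuple.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    E = np.asarray(E, float)
    O = np.asarray(O, float)
    C, D = loops.to_dense()
    model = _initial_model(E, O, loops, K, mu1, mu2, init, seed, n_restarts, als_iter)
    trace = OptimizerTrace(seed=seed)
    obj = _objective_dense(E, O, C, D, model.W1, model.H1, model.W2, model.H2,
                           model.lam, model.alpha, mu1, mu2)
    trace.objective.append(obj)
    for it in range(max_iter):
        obj_new = _update_coupled_state(E, O, C, D, model, symmetric_alpha)
        if not np.isfinite(obj_new):
            raise FloatingPointError("non-finite objective during optimization")
        rel = abs(obj - obj_new) / obj if obj > 0 else 0.0
        trace.objective.append(obj_new)
        trace.relative_change.append(rel)
        trace.n_iter = it + 1
        obj = obj_new
        if rel < tol:
            trace.converged = True
            break
    model.validate()
    return model, trace


# ---------------------------------------------------------------------------
# general input settings


def fit_setting(E_or_bulk, O_or_bulk, loops_or_scloops, setting: int, K: int,
                mu1: float = 1.0, mu2: float = 1.0, init="random",
                tol: float = 1e-4, max_iter: int = 300, seed=None,
                symmetric_alpha: bool = True,
                **fit_kwargs) -> tuple[FactorModel, OptimizerTrace]:
    """Fit the model under one of the four input combinations.

    1: scRNA + scATAC + single-cell loops (three NMF terms);
    2: scRNA + scATAC + bulk loops (the standard coupled model);
    3: scRNA + bulk ATAC vector + bulk loops;
    4: bulk RNA vector + scATAC + bulk loops.
    Bulk vector terms penalize the squared error between the bulk profile and
    the lambda-weighted mixture of W columns.
    """
    if setting == 2:
        return fit(E_or_bulk, O_or_bulk, loops_or_scloops, K, mu1, mu2,
                   init=init, tol=tol, max_iter=max_iter, seed=seed,
                   symmetric_alpha=symmetric_alpha, **fit_kwargs)
    if setting == 1:
        return _fit_setting1(E_or_bulk, O_or_bulk, loops_or_scloops, K,
                             mu1, mu2, tol, max_iter, seed)
    if setting == 3:
        return _fit_bulk_vector(
            np.asarray(E_or_bulk, float), np.asarray(O_or_bulk, float),
            loops_or_scloops, K, mu1, mu2, tol, max_iter, seed, bulk_side="atac",
        )
    if setting == 4:
        return _fit_bulk_vector(
            np.asarray(E_or_bulk, float), np.asarray(O_or_bulk, float),
            loops_or_scloops, K, mu1, mu2, tol, max_iter, seed, bulk_side="rna",
        )
    raise ValueError("setting must be one of 1, 2, 3, 4")


def _nmf_pair_update(X, W, H, weight, obj_of_W, obj_of_H, cur):
    num = weight * (X @ H.T)
    den = weight * (W @ (H @ H.T))
    ratio = num / np.maximum(den, EPS)
    W, cur = _damped_multiplicative(W, ratio, obj_of_W, cur)
    num = W.T @ X
    den = (W.T @ W) @ H
    ratio = num / np.maximum(den, EPS)
    H, cur = _damped_multiplicative(H, ratio, obj_of_H(W), cur, normalize=True)
    return W, H, cur


def _fit_setting1(E, O, sc_loops: SingleCellLoopMatrix, K, mu1, mu2,
                  tol, max_iter, seed):
    """Three simplex-constrained NMF terms (scRNA, scATAC, single-cell loops)."""
    E = np.asarray(E, float)
    O = np.asarray(O, float)
    Cs = np.asarray(sc_loops.values, float)
    rng = np.random.default_rng(seed)

    def rand_pair(X):
        s = np.sqrt(max(X.mean(), EPS) / K)
        W = (1.0 - rng.random((X.shape[0], K))) * s
        H = _normalize_columns(1.0 - rng.random((K, X.shape[1])))
        return W, H

    state = {}
    state["W1"], state["H1"] = rand_pair(E)
    state["W2"], state["H2"] = rand_pair(O)
    state["W3"], state["H3"] = rand_pair(Cs)
    terms = (("W3", "H3", Cs, 1.0), ("W1", "H1", E, mu1), ("W2", "H2", O, mu2))

    def total(**override):
        g = {**state, **override}
        return (0.5 * float(np.sum((Cs - g["W3"] @ g["H3"]) ** 2))
                + 0.5 * mu1 * float(np.sum((E - g["W1"] @ g["H1"]) ** 2))
                + 0.5 * mu2 * float(np.sum((O - g["W2"] @ g["H2"]) ** 2)))

    trace = OptimizerTrace(seed=seed)
    obj = total()
    trace.objective.append(obj)
    for it in range(max_iter):
        cur = obj
        for wk, hk, X, weight in terms:
            state[wk], state[hk], cur = _nmf_pair_update(
                X, state[wk], state[hk], weight,
                lambda W, wk=wk: total(**{wk: W}),
                lambda W, wk=wk, hk=hk: (lambda H: total(**{wk: W, hk: H})),
                cur)
        n_total = sum(state[h].shape[1] for h in ("H1", "H2", "H3"))
        lam = sum(state[h].sum(axis=1) for h in ("H1", "H2", "H3")) / n_total
        obj_new = total()
        rel = abs(obj - obj_new) / obj if obj > 0 else 0.0
        trace.objective.append(obj_new)
        trace.relative_change.append(rel)
        trace.n_iter = it + 1
        obj = obj_new
        if rel < tol:
            trace.converged = True
            break
    model = FactorModel(state["W1"], state["H1"], state["W2"], state["H2"],
                        lam, 1.0, mu1, mu2, K, setting=1,
                        W3=state["W3"], H3=state["H3"])
    model.validate()
    return model, trace


def _fit_bulk_vector(E_in, O_in, loops: LoopTable, K, mu1, mu2,
                     tol, max_iter, seed, bulk_side: str):
    """Coupled model with one bulk profile vector (setting 3 or 4).

    ``bulk_side='atac'``: E_in is gene x cell single-cell expression and O_in
    a length-n bulk accessibility vector; ``'rna'`` is the mirror case. The
    bulk term is ||v - W lam||^2; lambda receives a multiplicative update
    assembled from the coupling and bulk gradients (verified/damped).
    """
    C, D = loops.to_dense()
    rng = np.random.default_rng(seed)
    if bulk_side == "atac":
        E = E_in
        if O_in.ndim != 1:
            raise ValueError("setting 3 expects a 1-d bulk accessibility vector")
        v = O_in
        m_genes, n_enh = C.shape
        s1 = np.sqrt(max(E.mean(), EPS) / K)
        W1 = (1.0 - rng.random((m_genes, K))) * s1
        H1 = _normalize_columns(1.0 - rng.random((K, E.shape[1])))
        # warm-start the loop-only factor from the coupling itself
        W2 = np.maximum(C.T @ W1, EPS)
        W2 = W2 / max(W2.max(), EPS) * max(v.max(), 1.0)
        H2 = None
    elif bulk_side == "rna":
        O = O_in
        if E_in.ndim != 1:
            raise ValueError("setting 4 expects a 1-d bulk expression vector")
        v = E_in
        m_genes, n_enh = C.shape
        s2 = np.sqrt(max(O.mean(), EPS) / K)
        W2 = (1.0 - rng.random((n_enh, K))) * s2
        H2 = _normalize_columns(1.0 - rng.random((K, O.shape[1])))
        W1 = np.maximum(C @ W2, EPS)
        W1 = W1 / max(W1.max(), EPS) * max(v.max(), 1.0)
        H1 = None
    else:  # pragma: no cover
        raise ValueError(bulk_side)

    lam = np.full(K, 1.0 / K)
    alpha = _alpha_closed_form(C, _coupling_matrix(W1, W2, lam, D), 1.0)
    mu_sc = mu1 if bulk_side == "atac" else mu2
    mu_bulk = mu2 if bulk_side == "atac" else mu1

    def total(W1=None, H1=None, W2=None, H2=None, lam_=None, alpha_=None):
        W1_ = W1 if W1 is not None else state["W1"]
        W2_ = W2 if W2 is not None else state["W2"]
        lam__ = lam_ if lam_ is not None else state["lam"]
        a = alpha_ if alpha_ is not None else state["alpha"]
        M = _coupling_matrix(W1_, W2_, lam__, D)
        val = 0.5 * float(np.sum((C - a * M) ** 2))
        if bulk_side == "atac":
            H1_ = H1 if H1 is not None else state["H1"]
            val += 0.5 * mu_sc * float(np.sum((E - W1_ @ H1_) ** 2))
            val += 0.5 * mu_bulk * float(np.sum((v - W2_ @ lam__) ** 2))
        else:
            H2_ = H2 if H2 is not None else state["H2"]
            val += 0.5 * mu_sc * float(np.sum((O - W2_ @ H2_) ** 2))
            val += 0.5 * mu_bulk * float(np.sum((v - W1_ @ lam__) ** 2))
        return val

    state = {"W1": W1, "H1": H1, "W2": W2, "H2": H2, "lam": lam, "alpha": alpha}
    trace = OptimizerTrace(seed=seed)
    obj = total()
    trace.objective.append(obj)

    for it in range(max_iter):
        cur = total()
        a = state["alpha"]
        lam_v = state["lam"]
        M = _coupling_matrix(state["W1"], state["W2"], lam_v, D)
        # single-cell side: NMF + coupling split (symmetric in alpha)
        if bulk_side == "atac":
            W2lam = state["W2"] * lam_v[None, :]
            num = mu_sc * (E @ state["H1"].T) + a * (C @ W2lam)
            den = (mu_sc * (state["W1"] @ (state["H1"] @ state["H1"].T))
                   + a ** 2 * (M @ W2lam))
            ratio = num / np.maximum(den, EPS)
            state["W1"], cur = _damped_multiplicative(
                state["W1"], ratio, lambda W: total(W1=W), cur)
            num = state["W1"].T @ E
            den = (state["W1"].T @ state["W1"]) @ state["H1"]
            ratio = num / np.maximum(den, EPS)
            state["H1"], cur = _damped_multiplicative(
                state["H1"], ratio, lambda H: total(H1=H), cur, normalize=True)
            # bulk side factor: coupling + bulk mixture term
            M = _coupling_matrix(state["W1"], state["W2"], lam_v, D)
            W1lam = state["W1"] * lam_v[None, :]
            num = a * (C.T @ W1lam) + mu_bulk * np.outer(v, lam_v)
            den = (a ** 2 * (M.T @ W1lam)
                   + mu_bulk * np.outer(state["W2"] @ lam_v, lam_v))
            ratio = num / np.maximum(den, EPS)
            state["W2"], cur = _damped_multiplicative(
                state["W2"], ratio, lambda W: total(W2=W), cur)
        else:
            W1lam = state["W1"] * lam_v[None, :]
            num = mu_sc * (O @ state["H2"].T) + a * (C.T @ W1lam)
            den = (mu_sc * (state["W2"] @ (state["H2"] @ state["H2"].T))
                   + a ** 2 * (M.T @ W1lam))
            ratio = num / np.maximum(den, EPS)
            state["W2"], cur = _damped_multiplicative(
                state["W2"], ratio, lambda W: total(W2=W), cur)
            num = state["W2"].T @ O
            den = (state["W2"].T @ state["W2"]) @ state["H2"]
            ratio = num / np.maximum(den, EPS)
            state["H2"], cur = _damped_multiplicative(
                state["H2"], ratio, lambda H: total(H2=H), cur, normalize=True)
            M = _coupling_matrix(state["W1"], state["W2"], lam_v, D)
            W2lam = state["W2"] * lam_v[None, :]
            num = a * (C @ W2lam) + mu_bulk * np.outer(v, lam_v)
            den = (a ** 2 * (M @ W2lam)
                   + mu_bulk * np.outer(state["W1"] @ lam_v, lam_v))
            ratio = num / np.maximum(den, EPS)
            state["W1"], cur = _damped_multiplicative(
                state["W1"], ratio, lambda W: total(W1=W), cur)

        # lambda: multiplicative update from coupling + bulk terms
        M = _coupling_matrix(state["W1"], state["W2"], lam_v, D)
        DC = D * C
        num = a * np.einsum("ik,ij,jk->k", state["W1"], DC, state["W2"])
        den = a ** 2 * np.einsum("ik,ij,jk->k", state["W1"], M, state["W2"])
        Wb = state["W2"] if bulk_side == "atac" else state["W1"]
        num = num + mu_bulk * (v @ Wb)
        den = den + mu_bulk * ((Wb @ lam_v) @ Wb)
        ratio = num / np.maximum(den, EPS)
        tol_l = 1e-13 * max(cur, 1.0)
        gamma = 1.0
        for _ in range(30):
            cand = lam_v * np.power(ratio, gamma)
            cand = cand / max(cand.sum(), EPS)
            val = total(lam_=cand)
            if np.isfinite(val) and val <= cur + tol_l:
                state["lam"], cur = cand, val
                break
            gamma *= 0.5

        M = _coupling_matrix(state["W1"], state["W2"], state["lam"], D)
        state["alpha"] = _alpha_closed_form(C, M, state["alpha"])
        obj_new = total()
        rel = abs(obj - obj_new) / obj if obj > 0 else 0.0
        trace.objective.append(obj_new)
        trace.relative_change.append(rel)
        trace.n_iter = it + 1
        obj = obj_new
        if rel < tol:
            trace.converged = True
            break

    model = FactorModel(state["W1"], state["H1"], state["W2"], state["H2"],
                        state["lam"], state["alpha"], mu1, mu2, K,
                        setting=3 if bulk_side == "atac" else 4)
    model.validate()
    return model, trace


# ---------------------------------------------------------------------------
# model selection


@dataclass
class HyperparameterSearchResult:
    mu1: float
    mu2: float
    model: FactorModel
    trace: OptimizerTrace
    mu10: float
    mu20: float
    grid: list[dict]


def select_hyperparameters(E, O, loops: LoopTable, K: int,
                           grid_exponents: Sequence[int] = (0, 1, 2, 3, 4),
                           seed=None, n_restarts: int = 10, als_iter: int = 100,
                           max_iter: int = 200, tol: float = 1e-4,
                           top_fraction: float = 0.05) -> HyperparameterSearchResult:
    """Grid search mu1, mu2 over mu10*10^a x mu20*10^b.

    The base ratios mu10, mu20 equate the coupling residual with each NMF
    residual at the ALS initialization; the winning pair maximizes the summed
    subpopulation-specific subnetwork connectivity of the fitted model.
    """
    from .evaluation import subnetwork_connectivity

    E = np.asarray(E, float)
    O = np.asarray(O, float)
    C, D = loops.to_dense()
    init = als_initialize(E, O, K, n_restarts=n_restarts, seed=seed, n_iter=als_iter)
    W1, H1, W2, H2 = init
    H1n = _normalize_columns(np.maximum(H1, 1e-10))
    H2n = _normalize_columns(np.maximum(H2, 1e-10))
    lam = np.full(K, 1.0 / K)
    M = _coupling_matrix(np.maximum(W1, EPS), np.maximum(W2, EPS), lam, D)
    alpha = _alpha_closed_form(C, M, 1.0)
    coupling = float(np.sum((C - alpha * M) ** 2))
    res_E = float(np.sum((E - W1 @ H1) ** 2))
    res_O = float(np.sum((O - W2 @ H2) ** 2))
    if res_E <= 0:
        warnings.warn("zero expression residual at initialization; mu10 from coupling")
        mu10 = max(coupling, 1.0)
    else:
        mu10 = coupling / res_E
    if res_O <= 0:
        warnings.warn("zero accessibility residual at initialization; mu20 from coupling")
        mu20 = max(coupling, 1.0)
    else:
        mu20 = coupling / res_O

    grid = []
    best = None
    for a_exp, b_exp in itertools.product(grid_exponents, grid_exponents):
        mu1 = mu10 * 10.0 ** a_exp
        mu2 = mu20 * 10.0 ** b_exp
        model, trace = fit(E, O, loops, K, mu1, mu2,
                           init=(W1, H1n, W2, H2n), tol=tol, max_iter=max_iter)
        labels_rna = assign_clusters(model.H1)
        labels_atac = assign_clusters(model.H2)
        _, total = subnetwork_connectivity(
            E, O, labels_rna, labels_atac, model, loops, top_fraction=top_fraction
        )
        rec = {"mu1": mu1, "mu2": mu2, "exp1": a_exp, "exp2": b_exp,
               "connectivity": total}
        grid.append(rec)
        if best is None or total > best[0]:
            best = (total, mu1, mu2, model, trace)
    return HyperparameterSearchResult(
        mu1=best[1], mu2=best[2], model=best[3], trace=best[4],
        mu10=mu10, mu20=mu20, grid=grid,
    )


def select_K(E, O, loops: LoopTable, K_range: Sequence[int], n_runs: int = 10,
             mu1: float = 1.0, mu2: float = 1.0, seed=None,
             max_iter: int = 100, tol: float = 1e-4,
             min_drop: float = 0.01) -> int:
    """Consensus-clustering choice of the cluster number.

    For each K, fits from ``n_runs`` random starts, forms the co-clustering
    consensus over scRNA cells and computes the cophenetic correlation of the
    consensus dissimilarity; returns the K preceding the largest drop of the
    coefficient. Drops below ``min_drop`` count as no drop; if the
    coefficient never falls materially the smallest K is returned.
    """
    K_range = sorted(set(int(k) for k in K_range))
    if not all(2 <= k <= 10 for k in K_range):
        raise ValueError("K_range must lie in [2, 10]")
    ss = np.random.SeedSequence(seed)
    coph = {}
    for K in K_range:
        n1 = np.asarray(E).shape[1]
        consensus = np.zeros((n1, n1))
        for child in ss.spawn(n_runs):
            run_seed = int(child.generate_state(1)[0] % (2 ** 31))
            model, _ = fit(E, O, loops, K, mu1, mu2, init="random",
                           seed=run_seed, max_iter=max_iter, tol=tol)
            labels = assign_clusters(model.H1)
            consensus += (labels[:, None] == labels[None, :]).astype(float)
        consensus /= n_runs
        dist = squareform(1.0 - consensus, checks=False)
        if dist.size == 0 or np.allclose(dist.std(), 0.0):
            coph[K] = 1.0  # degenerate: identical assignments in every run
            continue
        Z = linkage(dist, method="average")
        c, _ = cophenet(Z, dist)
        coph[K] = float(c) if np.isfinite(c) else 1.0
    if len(K_range) == 1:
        return K_range[0]
    best_K, best_drop = K_range[0], -np.inf
    for k_lo, k_hi in zip(K_range[:-1], K_range[1:]):
        drop = coph[k_lo] - coph[k_hi]
        if drop > best_drop:
            best_K, best_drop = k_lo, drop
    if best_drop < min_drop:
        # coefficient never falls materially: smallest K is the stable choice
        return K_range[0]
    return best_K


def assign_clusters(H: np.ndarray) -> np.ndarray:
    """Hard labels (1..K) from a column-stochastic assignment matrix.

    Ties break toward the smallest cluster index.
    """
    return np.argmax(np.asarray(H), axis=0) + 1


# ---------------------------------------------------------------------------
# estimator


class DC3(BaseEstimator):
    """Coupled factorization of expression, accessibility and loop data.

    scikit-learn-style estimator around :func:`fit`/:func:`fit_setting`.

    Parameters
    ----------
    n_clusters : number of subpopulations K (>= 2).
    mu1, mu2 : NMF term weights; None derives each from the residual ratio of
        the coupling term to the corresponding NMF term at initialization.
    setting : input combination (1 sc/sc/sc-loops, 2 sc/sc/bulk loops,
        3 sc/bulk-ATAC/bulk loops, 4 bulk-RNA/sc/bulk loops).
    init : "als", "random", or an explicit (W1, H1, W2, H2) tuple (setting 2).
    symmetric_alpha : insert alpha symmetrically into the W2 update.

    Attributes (after fit)
    ----------------------
    W1_, H1_, W2_, H2_, W3_, H3_ : fitted factors (None where the setting has
        no such factor); lambda_ : mixing weights; alpha_ : coupling scale;
    labels_rna_, labels_atac_ : hard cluster labels per modality;
    trace_ : OptimizerTrace; n_iter_, converged_, objective_.
    """

    def __init__(self, n_clusters=2, mu1=None, mu2=None, setting=2,
                 tol=1e-4, max_iter=300, init="als", n_restarts=10,
                 als_iter=100, symmetric_alpha=True, random_state=None):
        self.n_clusters = n_clusters
        self.mu1 = mu1
        self.mu2 = mu2
        self.setting = setting
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.n_restarts = n_restarts
        self.als_iter = als_iter
        self.symmetric_alpha = symmetric_alpha
        self.random_state = random_state

    def _resolve_mus(self, E, O, loops):
        mu1, mu2 = self.mu1, self.mu2
        if mu1 is not None and mu2 is not None:
            return float(mu1), float(mu2)
        C, D = loops.to_dense()
        c2 = float(np.sum(C ** 2))
        if mu1 is None:
            eE = np.asarray(E, float)
            if eE.ndim == 1:
                eE = eE[:, None]
            mu1 = max(c2, 1.0) / max(float(np.sum(eE ** 2)), EPS)
        if mu2 is None:
            oO = np.asarray(O, float)
            if oO.ndim == 1:
                oO = oO[:, None]
            mu2 = max(c2, 1.0) / max(float(np.sum(oO ** 2)), EPS)
        return float(mu1), float(mu2)

    def fit(self, E, O, loops, y=None):
        """Fit on expression E, accessibility O and loop data.

        For setting 1 ``loops`` is a :class:`SingleCellLoopMatrix`; for
        settings 3/4 the bulk modality is a 1-d profile vector.
        """
        if self.setting in (2, 3, 4):
            mu1, mu2 = self._resolve_mus(E, O, loops)
        else:
            mu1 = 1.0 if self.mu1 is None else float(self.mu1)
            mu2 = 1.0 if self.mu2 is None else float(self.mu2)
        if self.setting == 2:
            model, trace = fit(
                E, O, loops, self.n_clusters, mu1, mu2, init=self.init,
                tol=self.tol, max_iter=self.max_iter, seed=self.random_state,
                n_restarts=self.n_restarts, als_iter=self.als_iter,
                symmetric_alpha=self.symmetric_alpha,
            )
        else:
            model, trace = fit_setting(
                E, O, loops, self.setting, self.n_clusters, mu1, mu2,
                init=self.init, tol=self.tol, max_iter=self.max_iter,
                seed=self.random_state, symmetric_alpha=self.symmetric_alpha,
            )
        self.model_ = model
        self.W1_, self.H1_ = model.W1, model.H1
        self.W2_, self.H2_ = model.W2, model.H2
        self.W3_, self.H3_ = model.W3, model.H3
        self.lambda_ = model.lam
        self.alpha_ = model.alpha
        self.mu1_, self.mu2_ = model.mu1, model.mu2
        self.trace_ = trace
        self.n_iter_ = trace.n_iter
        self.converged_ = trace.converged
        self.objective_ = trace.objective[-1]
        self.labels_rna_ = None if model.H1 is None else assign_clusters(model.H1)
        self.labels_atac_ = None if model.H2 is None else assign_clusters(model.H2)
        self.labels_hic_ = None if model.H3 is None else assign_clusters(model.H3)
        return self
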