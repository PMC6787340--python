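"""Subpopulation-specific expression, accessibility and loop profiles.

Given a fitted coupled model and hard cluster labels, profiles come from
(1) per-cluster means of the single-cell matrices, (2) the plug-in expression
p3_ijk = alpha * d_ij * lambda_k * p1_ik * p2_jk for the bulk loop modality,
or (3) a Poisson/multinomial MAP allocation of each observed loop count to
clusters, optimized by iterated conditional modes (ICM).

The MAP model: the observed count C_ij splits into latent per-cluster counts
C_ijk whose prior allocation follows a multinomial with probabilities
rho_ijk proportional to sqrt(O_ik * O_jk) (geometric mean of promoter and
enhancer openness), while cluster-level gene expression is Poisson with rate
beta * sum_q C_iqk, tying allocations of all loops of a gene together.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import comb, gammaln

from .datatypes import LoopTable

__all__ = [
    "SubpopulationProfiles",
    "cluster_mean_profiles",
    "plugin_loop_profiles",
    "compute_rho",
    "poisson_map_deconvolve",
    "PoissonMapResult",
]


@dataclass
class SubpopulationProfiles:
    """P1: gene x K expression, P2: enhancer x K accessibility,
    P3: loop-pair x K loop strength over the loop table's support."""

    P1: np.ndarray | None
    P2: np.ndarray | None
    P3: np.ndarray | None
    method: str
    loops: LoopTable | None = None


def cluster_mean_profiles(E, O, labels_rna, labels_atac, K: int | None = None
                          ) -> SubpopulationProfiles:
    """Per-cluster mean profiles of the single-cell matrices.

    An empty cluster in a modality yields a zero column with a warning.
    """
    E = np.asarray(E, float)
    O = np.asarray(O, float)
    labels_rna = np.asarray(labels_rna, int)
    labels_atac = np.asarray(labels_atac, int)
    if K is None:
        K = int(max(labels_rna.max(), labels_atac.max()))
    P1 = np.zeros((E.shape[0], K))
    P2 = np.zeros((O.shape[0], K))
    for k in range(1, K + 1):
        sel = labels_rna == k
        if sel.any():
            P1[:, k - 1] = E[:, sel].mean(axis=1)
        else:
            warnings.warn(f"cluster {k} empty in scRNA-seq; zero expression profile")
        sel = labels_atac == k
        if sel.any():
            P2[:, k - 1] = O[:, sel].mean(axis=1)
        else:
            warnings.warn(f"cluster {k} empty in scATAC-seq; zero accessibility profile")
    return SubpopulationProfiles(P1=P1, P2=P2, P3=None, method="cluster_mean")


def plugin_loop_profiles(P1, P2, lam, alpha, loops: LoopTable) -> np.ndarray:
    """Plug-in loop profiles p3_ijk = alpha * d_ij * lambda_k * p1_ik * p2_jk.

    Returns a pair x K array indexed like the loop table's entries.
    """
    P1 = np.asarray(P1, float)
    P2 = np.asarray(P2, float)
    lam = np.asarray(lam, float)
    g = loops.gene_index
    e = loops.enhancer_index
    d = loops.indicator
    return alpha * d[:, None] * lam[None, :] * P1[g, :] * P2[e, :]


def compute_rho(o_promoter, o_enhancer) -> np.ndarray:
    """Allocation probabilities rho_k proportional to sqrt(O_ik * O_jk)."""
    prod = np.sqrt(np.asarray(o_promoter, float) * np.asarray(o_enhancer, float))
    total = prod.sum()
    if total <= 0:
        raise ValueError("all openness products are zero; rho undefined")
    return prod / total


@dataclass
class PoissonMapResult:
    P3: np.ndarray            # pair x K integer allocations
    beta: float
    n_sweeps: int
    objective: list[float]    # joint log-posterior at the start/end of each sweep
    excluded_pairs: np.ndarray


def _pair_log_score(comp, rho_log, T_minus, E_i, beta, tau):
    """Log conditional score for one pair's composition: multinomial prior
    factor plus the gene's per-cluster Poisson expression likelihood with the
    smoothed rate beta * (T + tau)."""
    val = 0.0
    for k, c in enumerate(comp):
        val += c * rho_log[k] - gammaln(c + 1)
        T = T_minus[k] + c + tau
        val += -beta * T
        if E_i[k] > 0:
            val += E_i[k] * np.log(beta * T)
    return val


def _compositions(total, K):
    """All K-part non-negative integer compositions of ``total``."""
    for cuts in itertools.combinations(range(total + K - 1), K - 1):
        comp = []
        prev = -1
        for c in cuts:
            comp.append(c - prev - 1)
            prev = c
        comp.append(total + K - 2 - prev)
        yield tuple(comp)


def _best_composition(total, K, rho_log, T_minus, E_i, beta, enum_limit, tau):
    if comb(total + K - 1, K - 1) <= enum_limit:
        best, best_val = None, -np.inf
        for cmp_ in _compositions(int(total), K):
            v = _pair_log_score(cmp_, rho_log, T_minus, E_i, beta, tau)
            if v > best_val:
                best, best_val = cmp_, v
        return np.array(best, dtype=int)
    # greedy unit-transfer ascent from the rho-proportional rounding
    comp = _round_to_total(np.exp(rho_log) * total, int(total))
    cur = _pair_log_score(comp, rho_log, T_minus, E_i, beta, tau)
    improved = True
    while improved:
        improved = False
        for a in range(K):
            if comp[a] == 0:
                continue
            for b in range(K):
                if a == b:
                    continue
                comp[a] -= 1
                comp[b] += 1
                v = _pair_log_score(comp, rho_log, T_minus, E_i, beta, tau)
                if v > cur:
                    cur = v
                    improved = True
                else:
                    comp[a] += 1
                    comp[b] -= 1
    return np.asarray(comp, dtype=int)


def _round_to_total(x, total):
    base = np.floor(x).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(x - base))
        base[order[:rem]] += 1
    elif rem < 0:
        order = np.argsort(x - base)
        take = 0
        for i in order:
            while base[i] > 0 and take < -rem:
                base[i] -= 1
                take += 1
            if take >= -rem:
                break
    return base


def _joint_log_posterior(alloc, rho_log, T, E_by_cluster, genes, beta, tau):
    val = 0.0
    for p in range(alloc.shape[0]):
        val += float(np.sum(alloc[p] * rho_log[p]) - np.sum(gammaln(alloc[p] + 1)))
    for i in genes:
        for k in range(T.shape[1]):
            t = T[i, k] + tau
            val += -beta * t
            e = E_by_cluster[i, k]
            if e > 0:
                val += e * np.log(beta * t)
    return val


def poisson_map_deconvolve(loops: LoopTable, promoter_openness, enhancer_openness,
                           E_by_cluster, beta_init: float = 1.0,
                           max_sweeps: int = 20, enum_limit: float = 1e5,
                           update_beta: bool = True,
                           rate_smoothing: float = 1e-8) -> PoissonMapResult:
    """MAP allocation of each loop count across clusters by ICM.

    Parameters
    ----------
    loops : loop table with (near-)integer counts (rounded with a warning).
    promoter_openness : gene x K openness constants (cluster-mean promoter
        accessibility, or an expression proxy).
    enhancer_openness : enhancer x K openness constants.
    E_by_cluster : gene x K cluster-level expression observations.
    update_beta : re-estimate the expression rate scale each sweep by moment
        matching beta = sum(E) / sum(allocated counts).
    rate_smoothing : small constant tau added to the allocated totals inside
        the Poisson expression rate beta * (T + tau), keeping the posterior
        finite when a cluster holds no reads of an expressed gene.

    Each pair is visited in descending-count order; the conditional maximizer
    is found by exhaustive composition enumeration when the composition count
    is at most ``enum_limit``, otherwise by greedy unit transfers. Counts are
    conserved exactly: the allocation of pair (i,j) sums to C_ij.
    """
    Op = np.asarray(promoter_openness, float)
    Oe = np.asarray(enhancer_openness, float)
    Ec = np.asarray(E_by_cluster, float)
    K = Op.shape[1]
    counts = loops.count
    if not np.allclose(counts, np.rint(counts)):
        warnings.warn("non-integer loop counts rounded for the Poisson MAP model")
    counts = np.rint(counts).astype(int)
    n_pairs = loops.n_pairs

    rho = np.zeros((n_pairs, K))
    excluded = np.zeros(n_pairs, dtype=bool)
    for p in range(n_pairs):
        prod = np.sqrt(Op[loops.gene_index[p]] * Oe[loops.enhancer_index[p]])
        if prod.sum() <= 0:
            excluded[p] = True
            continue
        rho[p] = prod / prod.sum()
    if excluded.any():
        warnings.warn(f"{int(excluded.sum())} pairs with all-zero openness excluded")
    with np.errstate(divide="ignore"):
        rho_log = np.log(rho)

    alloc = np.zeros((n_pairs, K), dtype=int)
    for p in range(n_pairs):
        if excluded[p] or counts[p] == 0:
            continue
        alloc[p] = _round_to_total(rho[p] * counts[p], counts[p])

    # gene x K totals of allocated counts
    T = np.zeros((Op.shape[0], K), dtype=float)
    np.add.at(T, loops.gene_index, alloc)

    order = np.argsort(-counts, kind="stable")
    genes_used = np.unique(loops.gene_index)
    beta = float(beta_init)
    tau = float(rate_smoothing)
    objective = [
        _joint_log_posterior(alloc[~excluded], rho_log[~excluded],
                             T, Ec, genes_used, beta, tau)
    ]
    n_sweeps = 0
    for sweep in range(max_sweeps):
        changed = False
        for p in order:
            if excluded[p] or counts[p] == 0:
                continue
            i = loops.gene_index[p]
            T[i] -= alloc[p]
            new = _best_composition(counts[p], K, rho_log[p], T[i], Ec[i],
                                    beta, enum_limit, tau)
            if not np.array_equal(new, alloc[p]):
                changed = True
                alloc[p] = new
            T[i] += alloc[p]
        n_sweeps = sweep + 1
        objective.append(
            _joint_log_posterior(alloc[~excluded], rho_log[~excluded],
                                 T, Ec, genes_used, beta, tau)
        )
        if update_beta:
            total_alloc = float(T[genes_used].sum())
            if total_alloc > 0:
                beta = float(Ec[genes_used].sum()) / total_alloc
        if not changed:
            break
    return PoissonMapResult(P3=alloc.astype(float), beta=beta, n_sweeps=n_sweeps,
                            objective=objective, excluded_pairs=excluded)
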