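"""Scoring of deconvolution and clustering against ground truth.

Deconvolution is scored by the Pearson correlation between true and predicted
per-cluster loop (or expression/accessibility) profiles, after matching
predicted clusters to true clusters by maximum-PCC Hungarian assignment.
Clustering is scored by the minimum misclassification fraction over cluster
relabelings. The subnetwork-connectivity criterion used for hyper-parameter
selection sums predicted loop strength over the top subpopulation-specific
genes x enhancers of each cluster.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .datatypes import LoopTable

__all__ = [
    "deconvolution_pcc",
    "matched_profile_pcc",
    "clustering_error",
    "subnetwork_connectivity",
    "run_benchmark",
    "EvaluationReport",
]


def deconvolution_pcc(true_profile, predicted_profile) -> float:
    """Pearson correlation of two profile vectors (nan if either is flat)."""
    t = np.asarray(true_profile, float)
    p = np.asarray(predicted_profile, float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("profiles must be 1-d vectors of equal length")
    if len(t) < 3:
        raise ValueError("profiles must have length >= 3")
    if np.std(t) == 0 or np.std(p) == 0:
        warnings.warn("zero-variance profile; PCC undefined")
        return float("nan")
    return float(stats.pearsonr(t, p).statistic)


def _pcc_matrix(P_true, P_pred):
    Kt, Kp = P_true.shape[1], P_pred.shape[1]
    M = np.full((Kt, Kp), -1.0)
    for a in range(Kt):
        for b in range(Kp):
            if np.std(P_true[:, a]) == 0 or np.std(P_pred[:, b]) == 0:
                continue
            M[a, b] = stats.pearsonr(P_true[:, a], P_pred[:, b]).statistic
    return M


def matched_profile_pcc(P_true, P_pred):
    """Match predicted to true clusters by maximum-PCC assignment.

    Returns (per-cluster PCC array in true-cluster order, column permutation
    applied to the prediction).
    """
    P_true = np.asarray(P_true, float)
    P_pred = np.asarray(P_pred, float)
    M = _pcc_matrix(P_true, P_pred)
    rows, cols = linear_sum_assignment(-M)
    pccs = np.full(P_true.shape[1], np.nan)
    perm = np.arange(P_pred.shape[1])
    for a, b in zip(rows, cols):
        pccs[a] = M[a, b] if M[a, b] > -1.0 else np.nan
        perm[a] = b
    return pccs, perm


def concatenated_profile_pcc(P_true, P_pred) -> float:
    """PCC of the cluster-matched profiles stacked into one long vector."""
    pccs, perm = matched_profile_pcc(np.asarray(P_true), np.asarray(P_pred))
    P_pred = np.asarray(P_pred, float)[:, perm]
    return deconvolution_pcc(np.asarray(P_true, float).ravel(order="F"),
                             P_pred.ravel(order="F"))


def clustering_error(true_labels, predicted_labels) -> float:
    """Minimum misclassification fraction over cluster relabelings.

    Exhaustive over permutations for K <= 6, Hungarian assignment on the
    confusion matrix otherwise.
    """
    t = np.asarray(true_labels, int)
    p = np.asarray(predicted_labels, int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    K = int(max(t.max(), p.max()))
    if K <= 6:
        best = len(t)
        for perm in itertools.permutations(range(1, K + 1)):
            mapped = np.array(perm)[p - 1]
            best = min(best, int((mapped != t).sum()))
        return best / len(t)
    conf = np.zeros((K, K))
    for a, b in zip(t, p):
        conf[a - 1, b - 1] += 1
    rows, cols = linear_sum_assignment(-conf)
    return 1.0 - conf[rows, cols].sum() / len(t)


def _top_fraction_features(X, labels, k, top_fraction):
    """Indices of the top-fraction features by one-tailed Welch t (cluster k
    vs rest, alternative greater); ties broken by larger |t|."""
    sel = labels == k
    if sel.sum() < 2 or (~sel).sum() < 2:
        return None
    res = stats.ttest_ind(X[:, sel], X[:, ~sel], axis=1, equal_var=False,
                          alternative="greater")
    p = np.nan_to_num(res.pvalue, nan=1.0)
    tstat = np.nan_to_num(res.statistic, nan=0.0)
    n_top = int(np.ceil(top_fraction * X.shape[0]))
    order = np.lexsort((-np.abs(tstat), p))
    return order[:n_top]


def subnetwork_connectivity(E, O, labels_rna, labels_atac, model,
                            loops: LoopTable, top_fraction: float = 0.05):
    """Per-cluster connectivity of the subpopulation-specific subnetworks.

    For each cluster, the top-fraction subpopulation-specific genes and
    enhancers (one-tailed t-tests against the remaining cells) define a
    subnetwork; its connectivity sums the cluster's predicted loop strength
    A_ij = alpha * d_ij * lambda_k * w1_ik * w2_jk over selected pairs.
    Returns (K-vector, total).
    """
    E = np.asarray(E, float)
    O = np.asarray(O, float)
    labels_rna = np.asarray(labels_rna, int)
    labels_atac = np.asarray(labels_atac, int)
    K = model.K
    gi, ei = loops.gene_index, loops.enhancer_index
    d = loops.indicator
    conn = np.zeros(K)
    for k in range(1, K + 1):
        genes = _top_fraction_features(E, labels_rna, k, top_fraction)
        enhancers = _top_fraction_features(O, labels_atac, k, top_fraction)
        if genes is None:
            warnings.warn(f"cluster {k}: too few scRNA cells for the gene t-test")
        if enhancers is None:
            warnings.warn(f"cluster {k}: too few scATAC cells for the enhancer t-test")
        in_g = np.ones(len(gi), bool) if genes is None else np.isin(gi, genes)
        in_e = np.ones(len(ei), bool) if enhancers is None else np.isin(ei, enhancers)
        sel = in_g & in_e
        A = (model.alpha * d[sel] * model.lam[k - 1]
             * model.W1[gi[sel], k - 1] * model.W2[ei[sel], k - 1])
        conn[k - 1] = float(A.sum())
    return conn, float(conn.sum())


@dataclass
class EvaluationReport:
    """Per-run benchmark results plus seed bookkeeping."""

    table: pd.DataFrame
    seeds: list[int] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        agg = self.table.groupby(["dropout", "method"]).agg(
            mean_pcc=("pcc", "mean"), sd_pcc=("pcc", "std"),
            mean_error=("error", "mean"), sd_error=("error", "std"),
            n=("run", "count"),
        ).reset_index()
        one_run = agg["n"] == 1
        agg.loc[one_run, ["sd_pcc", "sd_error"]] = 0.0
        return agg


def _fit_method(method, E, O, loops, K, seed, max_iter, tol):
    from . import factorization as fz

    if method == "dc3":
        est = fz.DC3(n_clusters=K, setting=2, init="als", n_restarts=3,
                     als_iter=50, max_iter=max_iter, tol=tol, random_state=seed)
        est.fit(E, O, loops)
        return est
    if method == "coupled_nmf":
        # same optimizer with the loop coupling removed (empty support)
        empty = LoopTable(np.array([], int), np.array([], int), np.array([], float),
                          loops.gene_ids, loops.enhancer_ids)
        est = fz.DC3(n_clusters=K, mu1=1.0, mu2=1.0, setting=2, init="als",
                     n_restarts=3, als_iter=50, max_iter=max_iter, tol=tol,
                     random_state=seed)
        est.fit(E, O, empty)
        return est
    if method == "nmf":
        from sklearn.decomposition import NMF

        est = type("PlainNMF", (), {})()
        for X, name in ((E, "rna"), (O, "atac")):
            nmf = NMF(n_components=K, init="random", random_state=seed,
                      max_iter=max_iter * 2, tol=tol)
            Wx = nmf.fit_transform(np.asarray(X, float))
            H = nmf.components_
            setattr(est, f"labels_{name}_", np.argmax(H, axis=0) + 1)
        est.model_ = None
        return est
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(generator_params: dict, methods=("dc3", "coupled_nmf"),
                  n_runs: int = 50, dropout_grid=(0.0, 0.5, 0.8, 0.9),
                  seed=None, max_iter: int = 100, tol: float = 1e-4
                  ) -> EvaluationReport:
    """Benchmark harness over dropout rates, methods and restart seeds.

    One mixture is generated per harness seed; for each dropout rate the two
    single-cell matrices are thinned, and each method runs ``n_runs`` times
    from different initial values. Rows report the HiChIP-deconvolution PCC
    (plug-in profiles vs truth; DC3 only) and the RNA/ATAC-averaged
    clustering error.
    """
    from .deconvolution import cluster_mean_profiles, plugin_loop_profiles
    from .simulation import apply_dropout, generate_mixture

    ss = np.random.SeedSequence(seed)
    data_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    E, O, loops, _, truth = generate_mixture(seed=data_seed, **generator_params)
    K = len(truth.lam)
    rows = []
    seeds = []
    run_ss = ss.spawn(len(dropout_grid) * n_runs)
    idx = 0
    for rate in dropout_grid:
        for run in range(n_runs):
            child = run_ss[idx]
            idx += 1
            run_seed = int(child.generate_state(1)[0] % (2 ** 31))
            seeds.append(run_seed)
            Ed = apply_dropout(E, rate, seed=run_seed)
            Od = apply_dropout(O, rate, seed=run_seed + 1)
            for method in methods:
                est = _fit_method(method, Ed, Od, loops, K, run_seed, max_iter, tol)
                err = 0.5 * (clustering_error(truth.labels_rna, est.labels_rna_)
                             + clustering_error(truth.labels_atac, est.labels_atac_))
                pcc = pcc_concat = np.nan
                if method == "dc3":
                    prof = cluster_mean_profiles(Ed, Od, est.labels_rna_,
                                                 est.labels_atac_, K=K)
                    P3 = plugin_loop_profiles(prof.P1, prof.P2, est.lambda_,
                                              est.alpha_, loops)
                    pccs, _ = matched_profile_pcc(truth.loop_profile, P3)
                    pcc = float(np.nanmean(pccs))
                    pcc_concat = concatenated_profile_pcc(truth.loop_profile, P3)
                rows.append(dict(dropout=rate, method=method, run=run,
                                 pcc=pcc, pcc_concat=pcc_concat, error=err))
    return EvaluationReport(table=pd.DataFrame(rows), seeds=seeds)
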