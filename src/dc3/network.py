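"""Subpopulation-specific regulatory-network analysis.

Covers: ranking subpopulation-specific genes by combining expression and loop
evidence (one-tailed t-test + binomial test on rescaled loop counts, Fisher
combination), motif-enrichment scoring, key-regulator calling, TF-enhancer-
gene network construction, dense-subnetwork extraction by a bilinear
replicator iteration with a degree-preserving permutation null, surface-
marker selection and shared-GO-term filtering.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "subpopulation_specific_genes",
    "motif_enrichment_score",
    "differential_expression_pvalues",
    "key_regulators",
    "build_network",
    "DenseSubnetwork",
    "DenseSubnetworkExtractor",
    "dense_subnetwork",
    "partition_ucd",
    "switch_edges",
    "permutation_significance",
    "select_surface_markers",
    "filter_shared_go_terms",
]

SUPPORT_THRESHOLD = 1e-6


# ---------------------------------------------------------------------------
# subpopulation-specific genes


def subpopulation_specific_genes(E, labels, loop_profile, pair_gene_index,
                                 gene_ids=None, N: int = 10, top: int = 1000
                                 ) -> dict[int, pd.DataFrame]:
    """Rank genes per cluster by combined expression + loop evidence.

    Expression p-value: one-tailed Welch t-test (cells in the cluster vs the
    rest, alternative greater). Loop p-value: each interaction's per-cluster
    strengths are rescaled to a total of N; the rounded count in the cluster
    is tested against Binomial(N, 1/K) upper tail; a gene takes the most
    significant p over its interactions (1 if it has none). The two p-values
    are combined by Fisher's method (chi-square with 4 df) and the ``top``
    genes with smallest combined p are returned per cluster.
    """
    E = np.asarray(E, float)
    labels = np.asarray(labels, int)
    P3 = np.asarray(loop_profile, float)
    pair_gene_index = np.asarray(pair_gene_index, int)
    m = E.shape[0]
    K = P3.shape[1]
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(m)]

    out = {}
    for k in range(1, K + 1):
        sel = labels == k
        if sel.sum() < 2:
            warnings.warn(f"cluster {k} has < 2 cells; expression p-values set to 1")
            p_rna = np.ones(m)
        else:
            res = stats.ttest_ind(E[:, sel], E[:, ~sel], axis=1,
                                  equal_var=False, alternative="greater")
            p_rna = np.nan_to_num(res.pvalue, nan=1.0)

        p_hic = np.ones(m)
        totals = P3.sum(axis=1)
        ok = totals > 0
        n_k = np.rint(N * P3[ok, k - 1] / totals[ok]).astype(int)
        pair_p = stats.binom.sf(n_k - 1, N, 1.0 / K)
        for g, pv in zip(pair_gene_index[ok], pair_p):
            if pv < p_hic[g]:
                p_hic[g] = pv

        X = -2.0 * (np.log(np.maximum(p_rna, 1e-300))
                    + np.log(np.maximum(p_hic, 1e-300)))
        p_comb = stats.chi2.sf(X, df=4)
        df = pd.DataFrame({
            "gene_id": gene_ids, "p_rna": p_rna, "p_hic": p_hic,
            "fisher_x": X, "p_combined": p_comb,
        }).sort_values(["p_combined", "gene_id"], kind="stable").head(top)
        out[k] = df.reset_index(drop=True)
    return out


def motif_enrichment_score(p_value: float, fold_change: float) -> float:
    """Geometric mean of -log10(p) and the fold change."""
    p_value = float(p_value)
    fold_change = float(fold_change)
    if p_value <= 0 or p_value > 1:
        raise ValueError("p-value must lie in (0, 1]")
    if fold_change < 0:
        raise ValueError("fold change must be non-negative")
    return float(np.sqrt(-np.log10(p_value) * fold_change))


# ---------------------------------------------------------------------------
# key regulators


def differential_expression_pvalues(E, labels, feature_ids=None) -> pd.DataFrame:
    """Feature x cluster minimum BH-adjusted two-sided Welch t-test p-value
    against any other cluster (adjustment within each cluster pair)."""
    from statsmodels.stats.multitest import multipletests

    E = np.asarray(E, float)
    labels = np.asarray(labels, int)
    K = int(labels.max())
    m = E.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(m)]
    min_p = np.ones((m, K))
    for k, other in itertools.permutations(range(1, K + 1), 2):
        a, b = labels == k, labels == other
        if a.sum() < 2 or b.sum() < 2:
            continue
        res = stats.ttest_ind(E[:, a], E[:, b], axis=1, equal_var=False)
        p = np.nan_to_num(res.pvalue, nan=1.0)
        adj = multipletests(p, method="fdr_bh")[1]
        min_p[:, k - 1] = np.minimum(min_p[:, k - 1], adj)
    return pd.DataFrame(min_p, index=feature_ids,
                        columns=[f"cluster{k}" for k in range(1, K + 1)])


def key_regulators(fpkm_by_cluster: pd.DataFrame, motif_scores: pd.DataFrame,
                   diff_expr_p_adjusted: pd.DataFrame,
                   fpkm_min: float = 10.0, score_min: float = 2.0,
                   p_max: float = 0.01, top: int | None = None
                   ) -> dict[int, pd.DataFrame]:
    """Key TFs per cluster: FPKM > 10, motif score > 2 (both strict) and
    adjusted differential-expression p < 0.01 vs at least one other cluster.

    Importance = log2(FPKM) x expression specificity (max fold change vs the
    other clusters) x motif score; TFs are returned ranked by it. TFs missing
    from the motif table are excluded with a warning.
    """
    common = fpkm_by_cluster.index.intersection(motif_scores.index)
    missing = fpkm_by_cluster.index.difference(motif_scores.index)
    if len(missing):
        warnings.warn(f"{len(missing)} TFs absent from the motif table; excluded")
    fpkm = fpkm_by_cluster.loc[common]
    motif = motif_scores.loc[common]
    diffp = diff_expr_p_adjusted.loc[common]
    K = fpkm.shape[1]
    out = {}
    eps = 1e-12
    for k in range(K):
        keep = ((fpkm.iloc[:, k] > fpkm_min)
                & (motif.iloc[:, k] > score_min)
                & (diffp.iloc[:, k] < p_max))
        tfs = fpkm.index[keep]
        others = [j for j in range(K) if j != k]
        fc = fpkm.loc[tfs].iloc[:, k].to_numpy()[:, None] / np.maximum(
            fpkm.loc[tfs].iloc[:, others].to_numpy(), eps)
        specificity = fc.max(axis=1) if len(others) else np.ones(len(tfs))
        importance = (np.log2(np.maximum(fpkm.loc[tfs].iloc[:, k], eps))
                      * specificity * motif.loc[tfs].iloc[:, k])
        df = pd.DataFrame({
            "tf": tfs, "fpkm": fpkm.loc[tfs].iloc[:, k].to_numpy(),
            "motif_score": motif.loc[tfs].iloc[:, k].to_numpy(),
            "specificity": specificity,
            "importance": importance.to_numpy(),
        }).sort_values("importance", ascending=False, kind="stable")
        if top is not None:
            df = df.head(top)
        out[k + 1] = df.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# network construction


def build_network(key_tfs, loop_counts: pd.DataFrame, motif_matches: pd.DataFrame,
                  expr_correlations: pd.DataFrame, min_loop_count: float = 2.0):
    """Weighted directed TF -> target-gene network from TF-enhancer-gene triples.

    A triple (T, RE, G) forms when the enhancer-gene loop count is >= 2, T has
    a significant motif match on RE and T's expression correlates
    significantly with G; the edge weight W_TG sums motif_score x loop_count
    over triples. Nodes are restricted to the supplied key TFs.

    Parameters
    ----------
    loop_counts : columns (gene, enhancer, count).
    motif_matches : columns (tf, enhancer, motif_score, significant).
    expr_correlations : columns (tf, gene, r, significant).
    """
    import networkx as nx

    key = set(key_tfs)
    motifs = motif_matches[motif_matches["significant"].astype(bool)]
    corr = expr_correlations[expr_correlations["significant"].astype(bool)]
    corr_pairs = set(zip(corr["tf"], corr["gene"]))
    motif_by_enh: dict = {}
    for row in motifs.itertuples(index=False):
        motif_by_enh.setdefault(row.enhancer, []).append((row.tf, row.motif_score))

    G = nx.DiGraph()
    G.add_nodes_from(sorted(key))
    for row in loop_counts.itertuples(index=False):
        if row.count < min_loop_count:
            continue
        for tf, score in motif_by_enh.get(row.enhancer, ()):
            if tf not in key or row.gene not in key:
                continue
            if (tf, row.gene) not in corr_pairs:
                continue
            w = score * row.count
            if G.has_edge(tf, row.gene):
                G[tf][row.gene]["weight"] += w
            else:
                G.add_edge(tf, row.gene, weight=w)
    if G.number_of_edges() == 0:
        warnings.warn("no TF-enhancer-gene triples passed the filters; empty network")
    return G


# ---------------------------------------------------------------------------
# dense subnetwork


@dataclass
class DenseSubnetwork:
    x: np.ndarray
    y: np.ndarray
    nodes: list
    objective: float
    n_iter: int
    upstream: list
    core: list
    downstream: list
    p_value: float | None = None


def _as_adjacency(W):
    import networkx as nx

    if isinstance(W, nx.DiGraph):
        nodes = list(W.nodes)
        A = nx.to_numpy_array(W, nodelist=nodes, weight="weight")
        return A, nodes
    A = np.asarray(W, float)
    return A, list(range(A.shape[0]))


def dense_subnetwork(W, beta: float = 1.0, tol: float = 1e-12,
                     max_iter: int = 2000) -> DenseSubnetwork:
    """Extract the dense subnetwork maximizing sum_ij W_ij x_i y_j with
    simplex (beta = 1) constraints on the regulator weights x and target
    weights y.

    Solved by alternating replicator updates x <- x*(Wy)/(x'Wy),
    y <- y*(W'x)/(x'Wy) from the uniform start; both stay on the simplex at
    every step. Support = weights above 1e-6; the support is partitioned into
    upstream (x only), core (both) and downstream (y only) nodes.
    """
    if beta != 1.0:
        raise NotImplementedError("only the beta = 1 (L1 simplex) variant is supported")
    A, nodes = _as_adjacency(W)
    if A.size == 0 or np.all(A <= 0):
        raise ValueError("adjacency has no positive edge weight")
    if np.any(A < 0):
        raise ValueError("edge weights must be non-negative")
    n = A.shape[0]
    x = np.full(n, 1.0 / n)
    y = np.full(n, 1.0 / n)
    obj = float(x @ A @ y)
    it = 0
    for it in range(1, max_iter + 1):
        Ay = A @ y
        obj = float(x @ Ay)
        if obj <= 0:
            break
        x = x * Ay / obj
        Atx = A.T @ x
        obj = float(x @ A @ y)
        y = y * Atx / obj
        new_obj = float(x @ A @ y)
        if abs(new_obj - obj) <= tol * max(obj, 1.0) and it > 1:
            obj = new_obj
            break
        obj = new_obj
    up, core, down = _partition(x, y, nodes)
    return DenseSubnetwork(x=x, y=y, nodes=nodes, objective=obj, n_iter=it,
                           upstream=up, core=core, downstream=down)


def _partition(x, y, nodes, threshold=SUPPORT_THRESHOLD):
    up, core, down = [], [], []
    for i, node in enumerate(nodes):
        xi, yi = x[i] > threshold, y[i] > threshold
        if xi and yi:
            core.append(node)
        elif xi:
            up.append(node)
        elif yi:
            down.append(node)
    return up, core, down


def partition_ucd(subnet: DenseSubnetwork):
    """(upstream, core, downstream) node sets of an extracted subnetwork."""
    return _partition(subnet.x, subnet.y, subnet.nodes)


class DenseSubnetworkExtractor(BaseEstimator):
    """Estimator wrapper around :func:`dense_subnetwork`.

    ``fit(W)`` accepts a non-negative adjacency matrix or a networkx DiGraph;
    fitted attributes: ``x_``, ``y_``, ``objective_``, ``upstream_``,
    ``core_``, ``downstream_``, and ``p_value_`` when ``n_networks > 0``.
    """

    def __init__(self, beta=1.0, tol=1e-12, max_iter=2000,
                 n_networks=0, n_switches=1000, allow_self_loops=False,
                 random_state=None):
        self.beta = beta
        self.tol = tol
        self.max_iter = max_iter
        self.n_networks = n_networks
        self.n_switches = n_switches
        self.allow_self_loops = allow_self_loops
        self.random_state = random_state

    def fit(self, W, y=None):
        sub = dense_subnetwork(W, beta=self.beta, tol=self.tol,
                               max_iter=self.max_iter)
        if self.n_networks:
            sub.p_value = permutation_significance(
                W, sub, n_networks=self.n_networks, n_switches=self.n_switches,
                seed=self.random_state, allow_self_loops=self.allow_self_loops,
                tol=self.tol, max_iter=self.max_iter,
            )
        self.subnetwork_ = sub
        self.x_, self.y_ = sub.x, sub.y
        self.objective_ = sub.objective
        self.upstream_, self.core_, self.downstream_ = (
            sub.upstream, sub.core, sub.downstream)
        self.p_value_ = sub.p_value
        return self


# ---------------------------------------------------------------------------
# permutation null


def switch_edges(A: np.ndarray, n_switches: int, rng,
                 allow_self_loops: bool = False,
                 max_attempts_factor: int = 100) -> np.ndarray:
    """Degree-preserving randomization by edge switching.

    Repeatedly picks two edges (a->b), (c->d) and rewires them to (a->d),
    (c->b); a switch is rejected if it would create a duplicate edge or a
    disallowed self-loop. Weights travel with their source slot. Performs
    ``n_switches`` accepted switches (or gives up after
    ``max_attempts_factor * n_switches`` attempts).
    """
    A = np.asarray(A, float)
    src, dst = np.nonzero(A)
    weights = A[src, dst].copy()
    edges = {(int(a), int(b)) for a, b in zip(src, dst)}
    src, dst = list(map(int, src)), list(map(int, dst))
    n_edges = len(src)
    if n_edges < 2:
        return A.copy()
    accepted = 0
    attempts = 0
    limit = max_attempts_factor * n_switches
    while accepted < n_switches and attempts < limit:
        attempts += 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b = src[i], dst[i]
        c, d = src[j], dst[j]
        if b == d:
            continue
        if not allow_self_loops and (a == d or c == b):
            continue
        if (a, d) in edges or (c, b) in edges:
            continue
        edges.discard((a, b))
        edges.discard((c, d))
        edges.add((a, d))
        edges.add((c, b))
        dst[i], dst[j] = d, b
        accepted += 1
    out = np.zeros_like(A)
    for a, b, w in zip(src, dst, weights):
        out[a, b] = w
    return out


def permutation_significance(W, subnet: DenseSubnetwork, n_networks: int = 1000,
                             n_switches: int = 1000, seed=None,
                             allow_self_loops: bool = False,
                             tol: float = 1e-12, max_iter: int = 2000) -> float:
    """Add-one permutation p-value of the dense-subnetwork objective.

    Each null network is an edge-switched (degree-preserving) randomization
    of W; p = (#{null objective >= observed} + 1) / (n_networks + 1).
    """
    A, _ = _as_adjacency(W)
    if int(np.count_nonzero(A)) < 2:
        warnings.warn("network too small to switch; p-value reported as 1")
        return 1.0
    rng = np.random.default_rng(seed)
    observed = subnet.objective
    exceed = 0
    for _ in range(n_networks):
        null_A = switch_edges(A, n_switches, rng, allow_self_loops=allow_self_loops)
        null_obj = dense_subnetwork(null_A, tol=tol, max_iter=max_iter).objective
        if null_obj >= observed:
            exceed += 1
    return (exceed + 1) / (n_networks + 1)


# ---------------------------------------------------------------------------
# surface markers and GO filtering


def select_surface_markers(E_tpm, labels, target_cluster: int, candidates,
                           gene_ids, top: int = 20, high_tpm: float = 10.0,
                           low_tpm: float = 2.0) -> pd.DataFrame:
    """Rank candidate surface markers specific to one cluster.

    Candidates are ranked by a one-tailed t-test (target vs rest); the top
    ``top`` are kept and then required to have mean TPM > ``high_tpm`` in the
    target, mean TPM < ``low_tpm`` (strict) in every other cluster, and the
    highest mean in the target. Survivors are returned in rank order.
    """
    E_tpm = np.asarray(E_tpm, float)
    labels = np.asarray(labels, int)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    idx = np.array([gene_pos[c] for c in candidates if c in gene_pos], int)
    names = [c for c in candidates if c in gene_pos]
    K = int(labels.max())
    sel = labels == target_cluster
    res = stats.ttest_ind(E_tpm[idx][:, sel], E_tpm[idx][:, ~sel], axis=1,
                          equal_var=False, alternative="greater")
    p = np.nan_to_num(res.pvalue, nan=1.0)
    order = np.argsort(p, kind="stable")[:top]
    rows = []
    for rank, o in enumerate(order):
        gi = idx[o]
        target_mean = E_tpm[gi, sel].mean()
        other_means = [E_tpm[gi, labels == k].mean()
                       for k in range(1, K + 1) if k != target_cluster]
        if target_mean <= high_tpm:
            continue
        if any(mu >= low_tpm for mu in other_means):
            continue
        if other_means and target_mean <= max(other_means):
            continue
        rows.append(dict(marker=names[o], p_value=p[o], rank=rank + 1,
                         target_mean=target_mean,
                         max_other_mean=max(other_means) if other_means else 0.0))
    if not rows:
        warnings.warn("no surface marker survived the expression filters")
        return pd.DataFrame(columns=["marker", "p_value", "rank",
                                     "target_mean", "max_other_mean"])
    return pd.DataFrame(rows)


def filter_shared_go_terms(enrichment_tables: dict, score_threshold: float = 2.0
                           ) -> dict:
    """Keep per-cluster terms with score > threshold, dropping terms that are
    significant in every cluster.

    ``enrichment_tables`` maps cluster -> DataFrame with columns (term, score).
    """
    significant = {
        k: set(df.loc[df["score"] > score_threshold, "term"])
        for k, df in enrichment_tables.items()
    }
    shared = set.intersection(*significant.values()) if significant else set()
    return {k: sorted(terms - shared) for k, terms in significant.items()}
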