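"""Synthetic coupled multi-omic mixtures with known ground truth.

The generator emulates an in-silico mixture of K cell types measured by
three separate assays on disjoint cells: scRNA-seq (genes x n1 cells),
scATAC-seq (enhancers x n2 cells) and loops (either a bulk gene x enhancer
count table or a per-cell loop matrix obtained by thinning the bulk reads).
Cluster archetypes contain a ``separation`` fraction of cluster-exclusive
marker features; cells are Poisson samples around their cluster archetype;
bulk loop counts are Poisson around the coupling model
alpha * d_ij * sum_k lambda_k * w1_ik * w2_jk. Default cell numbers follow
the two-cell-line mixture layout: 146 scRNA cells, 746 scATAC cells and 200
single-cell loop cells, split evenly between the two clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import LoopTable, SingleCellLoopMatrix

__all__ = [
    "SyntheticTruth",
    "generate_mixture",
    "apply_dropout",
    "downsample_dropseq",
    "random_deconvolution_null",
    "permute_modality_control",
    "DEFAULT_CELLS",
    "DROPOUT_GRID",
]

DEFAULT_CELLS = (146, 746, 200)
DROPOUT_GRID = (0.0, 0.5, 0.8, 0.9)


@dataclass
class SyntheticTruth:
    labels_rna: np.ndarray
    labels_atac: np.ndarray
    labels_hic: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    lam: np.ndarray
    alpha: float
    loop_profile: np.ndarray  # pair x K true per-cluster loop strengths
    seed: int | None
    params: dict = field(default_factory=dict)


def _split_cells(n: int, lam: np.ndarray) -> np.ndarray:
    """Deterministic proportional allocation of n cells to clusters (1..K)."""
    K = len(lam)
    sizes = np.floor(lam * n).astype(int)
    order = np.argsort(-(lam * n - sizes))
    for i in range(n - sizes.sum()):
        sizes[order[i % K]] += 1
    return np.repeat(np.arange(1, K + 1), sizes)


def _archetypes(n_features, K, separation, low, high, background, rng):
    """Feature x K archetype matrix with a ``separation`` fraction of
    cluster-exclusive marker rows split evenly among clusters."""
    W = np.tile(rng.uniform(low, high, size=(n_features, 1)), (1, K))
    n_markers = int(round(separation * n_features))
    marker_rows = rng.choice(n_features, size=n_markers, replace=False)
    for idx, row in enumerate(marker_rows):
        k = idx % K
        W[row, :] = rng.uniform(0.0, background)
        W[row, k] = rng.uniform(high, 2 * high)
    return W


def generate_mixture(K: int = 2, m: int = 500, n: int = 1000,
                     cells=DEFAULT_CELLS, lam=None, separation: float = 0.5,
                     n_loops: int = 2000, mean_loop_count: float = 10.0,
                     noise: str = "poisson", seed=None):
    """Generate a coupled (E, O, loops, sc_loops, truth) dataset.

    Parameters
    ----------
    K, m, n : clusters, genes, enhancers.
    cells : (n1, n2, n3) cells for scRNA, scATAC and single-cell loops.
    lam : cluster proportions (default uniform).
    separation : fraction of cluster-exclusive marker features (0 = clusters
        indistinguishable).
    n_loops : number of gene-enhancer pairs carrying loops.
    mean_loop_count : target mean bulk count over pairs (sets alpha).
    noise : "poisson" for count noise, "none" for exact archetype/model values.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    rng = np.random.default_rng(seed)
    n1, n2, n3 = cells
    if min(n1, n2, n3) < K:
        raise ValueError("every modality needs at least K cells")
    lam = np.full(K, 1.0 / K) if lam is None else np.asarray(lam, float)
    lam = lam / lam.sum()

    W1 = _archetypes(m, K, separation, low=1.0, high=8.0, background=0.3, rng=rng)
    W2 = _archetypes(n, K, separation, low=1.0, high=8.0, background=0.3, rng=rng)

    labels_rna = _split_cells(n1, lam)
    labels_atac = _split_cells(n2, lam)
    labels_hic = _split_cells(n3, lam)

    if noise == "poisson":
        E = rng.poisson(W1[:, labels_rna - 1]).astype(float)
        O = rng.poisson(W2[:, labels_atac - 1]).astype(float)
    elif noise == "none":
        E = W1[:, labels_rna - 1].copy()
        O = W2[:, labels_atac - 1].copy()
    else:
        raise ValueError(f"unknown noise family {noise!r}")

    # loop support: distinct random gene-enhancer pairs
    n_loops = min(n_loops, m * n)
    flat = rng.choice(m * n, size=n_loops, replace=False)
    gi, ei = np.unravel_index(flat, (m, n))
    base = np.einsum("k,ik,ik->i", lam, W1[gi], W2[ei])  # sum_k lam w1 w2 per pair
    alpha = mean_loop_count / max(base.mean(), 1e-12)
    mean_counts = alpha * base
    if noise == "poisson":
        counts = rng.poisson(mean_counts).astype(float)
    else:
        counts = mean_counts.copy()
    loops = LoopTable(gene_index=gi, enhancer_index=ei, count=counts,
                      gene_ids=[f"gene{i}" for i in range(m)],
                      enhancer_ids=[f"enh{j}" for j in range(n)])
    loop_profile = alpha * lam[None, :] * W1[gi] * W2[ei]  # pair x K truth

    # single-cell loops: thin integer bulk reads into cells; each read picks a
    # cluster with probability proportional to its per-cluster intensity, then
    # a uniform cell within the cluster
    reads = np.rint(counts).astype(int)
    cell_weights = np.zeros((K, n3))
    for k in range(1, K + 1):
        sel = labels_hic == k
        cell_weights[k - 1, sel] = 1.0 / sel.sum()
    Cs = np.zeros((n_loops, n3))
    pk = lam[None, :] * W1[gi] * W2[ei]
    pk = pk / np.maximum(pk.sum(axis=1, keepdims=True), 1e-300)
    for p in range(n_loops):
        if reads[p] == 0:
            continue
        pvec = pk[p] @ cell_weights
        Cs[p] = rng.multinomial(reads[p], pvec)
    sc_loops = SingleCellLoopMatrix(
        values=Cs,
        pair_ids=loops.pair_ids(),
        cell_ids=[f"hic_cell{j}" for j in range(n3)],
    )

    truth = SyntheticTruth(
        labels_rna=labels_rna, labels_atac=labels_atac, labels_hic=labels_hic,
        W1=W1, W2=W2, lam=lam, alpha=alpha, loop_profile=loop_profile,
        seed=seed,
        params=dict(K=K, m=m, n=n, cells=tuple(cells), separation=separation,
                    n_loops=n_loops, mean_loop_count=mean_loop_count, noise=noise),
    )
    return E, O, loops, sc_loops, truth


def apply_dropout(M, rate: float, seed=None) -> np.ndarray:
    """Zero each entry independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("dropout rate must lie in [0, 1]")
    M = np.asarray(M, float)
    if rate == 0.0:
        return M.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(M.shape) >= rate
    return M * keep


def downsample_dropseq(P, seed=None, literal: bool = False) -> np.ndarray:
    """Emulate shallow droplet sequencing of a deep count matrix.

    Each entry is replaced by a Poisson draw with mean P/100, then zeroed by a
    Bernoulli dropout whose KEEP probability is 1 / (1 + (P/100)^(-0.1)) —
    dropout probability falls as expression rises. ``literal=True`` uses the
    alternative precedence 1 / (1 + P * 100^0.1).
    """
    P = np.asarray(P, float)
    rng = np.random.default_rng(seed)
    down = rng.poisson(P / 100.0).astype(float)
    with np.errstate(divide="ignore"):
        if literal:
            keep_p = 1.0 / (1.0 + P * 100.0 ** 0.1)
        else:
            keep_p = np.where(P > 0, 1.0 / (1.0 + (P / 100.0) ** -0.1), 0.0)
    keep = rng.random(P.shape) < keep_p
    return down * keep


def random_deconvolution_null(E, O, loops: LoopTable, model, truth: SyntheticTruth,
                              n_runs: int, seed=None) -> np.ndarray:
    """Null distribution of deconvolution PCC under random cell labels.

    Each run permutes the cell-to-cluster assignments of both single-cell
    modalities uniformly at random, recomputes cluster-mean profiles and the
    plug-in loop profiles, and scores them against the true per-cluster loop
    strengths (mean matched PCC). Returns the null sample (length n_runs).
    """
    from .deconvolution import cluster_mean_profiles, plugin_loop_profiles
    from .evaluation import matched_profile_pcc

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_runs):
        perm_rna = rng.permutation(truth.labels_rna)
        perm_atac = rng.permutation(truth.labels_atac)
        prof = cluster_mean_profiles(E, O, perm_rna, perm_atac, K=len(truth.lam))
        P3 = plugin_loop_profiles(prof.P1, prof.P2, model.lam, model.alpha, loops)
        pccs, _ = matched_profile_pcc(truth.loop_profile, P3)
        out.append(float(np.nanmean(pccs)))
    return np.asarray(out)


def permute_modality_control(E, O, loops: LoopTable, which: str, seed=None):
    """Negative control: permute one modality, keep the other two intact.

    ``which='rna'``/``'atac'`` permutes cell columns; ``'loops'`` shuffles the
    count-to-pair mapping.
    """
    rng = np.random.default_rng(seed)
    E = np.asarray(E, float)
    O = np.asarray(O, float)
    if which == "rna":
        return E[:, rng.permutation(E.shape[1])], O.copy(), loops
    if which == "atac":
        return E.copy(), O[:, rng.permutation(O.shape[1])], loops
    if which == "loops":
        perm = rng.permutation(loops.n_pairs)
        shuffled = LoopTable(
            gene_index=loops.gene_index.copy(),
            enhancer_index=loops.enhancer_index.copy(),
            count=loops.count[perm],
            gene_ids=list(loops.gene_ids),
            enhancer_ids=list(loops.enhancer_ids),
        )
        return E.copy(), O.copy(), shuffled
    raise ValueError("which must be one of 'rna', 'atac', 'loops'")
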