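"""Regulatory-network analysis: gene calling, key TFs, dense subnetworks."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import networkx as nx

from dc3.network import (
    DenseSubnetworkExtractor,
    build_network,
    dense_subnetwork,
    differential_expression_pvalues,
    filter_shared_go_terms,
    key_regulators,
    motif_enrichment_score,
    partition_ucd,
    permutation_significance,
    select_surface_markers,
    subpopulation_specific_genes,
    switch_edges,
)


# ---------------------------------------------------------------------------
# subpopulation-specific genes


def test_binomial_tail_closed_form():
    """All ten rescaled reads in one of two clusters: p = 2^-10."""
    rng = np.random.default_rng(0)
    E = rng.random((3, 12)) + 0.1
    labels = np.array([1, 2] * 6)
    P3 = np.array([[10.0, 0.0]])  # one pair on gene 0, all weight in cluster 1
    out = subpopulation_specific_genes(E, labels, P3, np.array([0]), N=10)
    assert out[1]["p_hic"][out[1]["gene_id"] == "gene0"].iloc[0] == \
        pytest.approx(2.0 ** -10)


def test_fisher_combination_identity_case():
    """p_rna = p_hic = 1 gives X = 0 and combined p = 1."""
    E = np.ones((2, 8))  # flat expression: t-test p = 1 (nan -> 1)
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    P3 = np.zeros((0, 2))
    out = subpopulation_specific_genes(E, labels, P3, np.array([], int))
    assert (out[1]["fisher_x"] == 0.0).all()
    assert (out[1]["p_combined"] == 1.0).all()


def test_ranking_matches_independent_chi2_oracle():
    """Fisher survival against an independent numerical integration of the
    chi-square(4) density; ordering equals brute-force sort of combined p."""
    rng = np.random.default_rng(1)
    m = 50
    E = rng.gamma(2.0, 2.0, (m, 20))
    E[:10, :10] += 5  # make the first 10 genes cluster-1 specific
    labels = np.array([1] * 10 + [2] * 10)
    n_pairs = 30
    gi = rng.integers(0, m, size=n_pairs)
    P3 = rng.random((n_pairs, 2)) * 10
    out = subpopulation_specific_genes(E, labels, P3, gi, N=10, top=1000)
    df = out[1]
    assert len(df) == m  # top-1000 request returns all 50
    assert df["p_combined"].is_monotonic_increasing
    for _, row in df.head(5).iterrows():
        x = row["fisher_x"]
        dens = lambda t: stats.chi2.pdf(t, 4)
        tail, _ = integrate.quad(dens, x, np.inf)
        assert row["p_combined"] == pytest.approx(tail, abs=1e-8)


# ---------------------------------------------------------------------------
# motif score


def test_motif_score_examples_and_validation():
    assert motif_enrichment_score(1.0, 50.0) == 0.0
    assert motif_enrichment_score(0.01, 2.0) == pytest.approx(2.0)
    assert motif_enrichment_score(0.1, 1.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        motif_enrichment_score(0.0, 1.0)
    with pytest.raises(ValueError):
        motif_enrichment_score(0.5, -1.0)


# ---------------------------------------------------------------------------
# key regulators


def test_key_regulators_strict_thresholds_and_ranking():
    tfs = ["tf1", "tf2", "tf3", "tf4", "tf5"]
    fpkm = pd.DataFrame({"c1": [50.0, 10.0, 40.0, 30.0, 12.0],
                         "c2": [5.0, 5.0, 4.0, 3.0, 11.0]}, index=tfs)
    motif = pd.DataFrame({"c1": [3.0, 4.0, 2.0, 2.5, 3.0],
                          "c2": [1.0, 1.0, 1.0, 1.0, 4.0]}, index=tfs)
    diffp = pd.DataFrame({"c1": [1e-4, 1e-4, 1e-4, 0.5, 1e-4],
                          "c2": [0.5, 0.5, 0.5, 0.5, 1e-4]}, index=tfs)
    out = key_regulators(fpkm, motif, diffp)
    sel = out[1]
    # tf2 fails FPKM > 10 (exactly 10), tf3 fails score > 2 (exactly 2),
    # tf4 fails the differential-expression cut
    assert sel["tf"].tolist() == ["tf1"] or "tf1" in sel["tf"].tolist()
    assert "tf2" not in sel["tf"].tolist()
    assert "tf3" not in sel["tf"].tolist()
    assert "tf4" not in sel["tf"].tolist()
    # hand-computed importance: log2(50) * (50/5) * 3
    imp = np.log2(50.0) * 10.0 * 3.0
    assert sel.loc[sel["tf"] == "tf1", "importance"].iloc[0] == \
        pytest.approx(imp)


def test_key_regulators_warns_on_missing_motif_tf():
    fpkm = pd.DataFrame({"c1": [50.0, 20.0]}, index=["a", "b"])
    motif = pd.DataFrame({"c1": [3.0]}, index=["a"])
    diffp = pd.DataFrame({"c1": [1e-4, 1e-4]}, index=["a", "b"])
    with pytest.warns(UserWarning, match="absent"):
        out = key_regulators(fpkm, motif, diffp)
    assert out[1]["tf"].tolist() == ["a"]


def test_differential_expression_pvalues_shape():
    rng = np.random.default_rng(2)
    E = rng.random((10, 18))
    E[:3, :6] += 4
    labels = np.array([1] * 6 + [2] * 6 + [3] * 6)
    out = differential_expression_pvalues(E, labels)
    assert out.shape == (10, 3)
    assert (out.to_numpy() <= 1.0).all()
    assert (out.iloc[:3, 0] < 0.05).all()


# ---------------------------------------------------------------------------
# network construction


def _toy_network_inputs():
    loops = pd.DataFrame({"gene": ["tfB", "tfB", "tfC"],
                          "enhancer": ["e1", "e2", "e1"],
                          "count": [2.0, 1.9, 5.0]})
    motifs = pd.DataFrame({"tf": ["tfA", "tfA", "tfC"],
                           "enhancer": ["e1", "e2", "e1"],
                           "motif_score": [3.0, 4.0, 2.0],
                           "significant": [True, True, True]})
    corr = pd.DataFrame({"tf": ["tfA", "tfA", "tfC"],
                         "gene": ["tfB", "tfC", "tfB"],
                         "r": [0.9, 0.8, 0.7],
                         "significant": [True, True, True]})
    return loops, motifs, corr


def test_build_network_thresholds_and_weights():
    loops, motifs, corr = _toy_network_inputs()
    G = build_network(["tfA", "tfB", "tfC"], loops, motifs, corr)
    # e2 loop (1.9) is below the >= 2 cutoff, so only e1 triples survive
    assert G["tfA"]["tfB"]["weight"] == pytest.approx(3.0 * 2.0)
    assert G["tfC"]["tfB"]["weight"] == pytest.approx(2.0 * 2.0)
    # tfC is also a target gene of e1, so tfA -> tfC forms via the 5-read loop
    assert G["tfA"]["tfC"]["weight"] == pytest.approx(3.0 * 5.0)
    assert not G.has_edge("tfC", "tfC")


def test_build_network_additive_over_triples():
    rng = np.random.default_rng(3)
    tfs = [f"tf{i}" for i in range(6)]
    rows = []
    for _ in range(10):
        rows.append((rng.choice(tfs), f"e{rng.integers(4)}",
                     float(rng.integers(2, 8))))
    loops = pd.DataFrame(rows, columns=["gene", "enhancer", "count"])
    motifs = pd.DataFrame(
        [(t, f"e{j}", float(rng.uniform(1, 5)), True)
         for t in tfs for j in range(4)],
        columns=["tf", "enhancer", "motif_score", "significant"])
    corr = pd.DataFrame([(a, b, 0.9, True) for a in tfs for b in tfs],
                        columns=["tf", "gene", "r", "significant"])
    full = build_network(tfs, loops, motifs, corr)
    part1 = build_network(tfs, loops.iloc[:5], motifs, corr)
    part2 = build_network(tfs, loops.iloc[5:], motifs, corr)
    for u, v, data in full.edges(data=True):
        w = 0.0
        if part1.has_edge(u, v):
            w += part1[u][v]["weight"]
        if part2.has_edge(u, v):
            w += part2[u][v]["weight"]
        assert data["weight"] == pytest.approx(w)


def test_build_network_empty_warns():
    loops, motifs, corr = _toy_network_inputs()
    with pytest.warns(UserWarning, match="empty network"):
        G = build_network(["tfZ"], loops, motifs, corr)
    assert G.number_of_edges() == 0


# ---------------------------------------------------------------------------
# dense subnetwork


def test_single_edge_concentrates_mass():
    W = np.zeros((5, 5))
    W[1, 3] = 4.0
    sub = dense_subnetwork(W)
    assert sub.x[1] == pytest.approx(1.0)
    assert sub.y[3] == pytest.approx(1.0)
    assert sub.objective == pytest.approx(4.0)
    assert sub.upstream == [1] and sub.downstream == [3] and sub.core == []


def test_planted_block_recovery():
    """A constant-weight complete block (self-loops included) is recovered
    as the support of both x and y on 20 random instances."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        n = 15
        block = set(map(int, rng.choice(n, size=4, replace=False)))
        W = rng.uniform(0, 0.5, (n, n))
        for a in block:
            for b in block:
                W[a, b] = 10.0
        sub = dense_subnetwork(W)
        assert set(np.flatnonzero(sub.x > 1e-6)) == block
        assert set(np.flatnonzero(sub.y > 1e-6)) == block
        assert set(sub.core) == block


def test_objective_non_decreasing_along_replicator_iterations():
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = int(rng.integers(4, 12))
        W = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
        if np.all(W <= 0):
            continue
        x = np.full(n, 1.0 / n)
        y = np.full(n, 1.0 / n)
        prev = x @ W @ y
        for _ in range(50):
            x = x * (W @ y) / (x @ W @ y)
            y = y * (W.T @ x) / (x @ W @ y)
            cur = x @ W @ y
            assert cur >= prev - 1e-12
            prev = cur


def test_objective_invariant_under_node_relabeling():
    rng = np.random.default_rng(6)
    W = rng.random((10, 10)) * (rng.random((10, 10)) < 0.4)
    W[2, 7] = 5.0
    perm = rng.permutation(10)
    Wp = W[np.ix_(perm, perm)]
    assert dense_subnetwork(W).objective == pytest.approx(
        dense_subnetwork(Wp).objective, rel=1e-8)


def test_partition_rules():
    sub = dense_subnetwork(np.array([[0.0, 3.0], [0.0, 0.0]]))
    up, core, down = partition_ucd(sub)
    assert up == [0] and down == [1] and core == []
    # membership rule: x > 0 and y = 0 -> upstream, both positive -> core
    sub.x = np.array([0.3, 0.0])
    sub.y = np.array([0.2, 0.9])
    up, core, down = partition_ucd(sub)
    assert core == [0] and down == [1]


def test_dense_subnetwork_validation():
    with pytest.raises(ValueError):
        dense_subnetwork(np.zeros((3, 3)))
    with pytest.raises(NotImplementedError):
        dense_subnetwork(np.ones((2, 2)), beta=2.0)


# ---------------------------------------------------------------------------
# permutation null


def test_switching_preserves_degree_sequences():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = 12
        W = (rng.random((n, n)) < 0.3) * rng.uniform(0.5, 2.0, (n, n))
        np.fill_diagonal(W, 0.0)
        null = switch_edges(W, 200, rng)
        np.testing.assert_array_equal((W > 0).sum(axis=0), (null > 0).sum(axis=0))
        np.testing.assert_array_equal((W > 0).sum(axis=1), (null > 0).sum(axis=1))
        # weights travel: the multiset of weights is conserved
        np.testing.assert_allclose(np.sort(W[W > 0]), np.sort(null[null > 0]))


def test_permutation_p_value_add_one_floor():
    rng = np.random.default_rng(8)
    n = 10
    W = (rng.random((n, n)) < 0.4) * rng.uniform(0.5, 1.0, (n, n))
    np.fill_diagonal(W, 0.0)
    sub = dense_subnetwork(W)
    sub.objective = 1e9  # observed exceeds every null by construction
    p = permutation_significance(W, sub, n_networks=1000, n_switches=50,
                                 seed=1, max_iter=200)
    assert p == pytest.approx(1.0 / 1001.0)


def test_permutation_p_value_small_network_reports_one():
    W = np.zeros((3, 3))
    W[0, 1] = 2.0
    sub = dense_subnetwork(W)
    with pytest.warns(UserWarning, match="too small"):
        assert permutation_significance(W, sub, n_networks=10) == 1.0


def test_extractor_estimator_interface():
    rng = np.random.default_rng(9)
    W = (rng.random((8, 8)) < 0.4) * rng.uniform(0.5, 2.0, (8, 8))
    np.fill_diagonal(W, 0.0)
    G = nx.DiGraph()
    for a, b in zip(*np.nonzero(W)):
        G.add_edge(f"n{a}", f"n{b}", weight=W[a, b])
    est = DenseSubnetworkExtractor(n_networks=20, n_switches=50,
                                   random_state=0, max_iter=300)
    est.fit(G)
    assert 0.0 < est.p_value_ <= 1.0
    assert est.objective_ > 0
    assert set(est.upstream_) | set(est.core_) | set(est.downstream_) <= set(G.nodes)


# ---------------------------------------------------------------------------
# surface markers and GO terms


def test_surface_marker_filters_strict():
    rng = np.random.default_rng(10)
    m = 30
    gene_ids = [f"g{i}" for i in range(m)]
    labels = np.array([1] * 8 + [2] * 8 + [3] * 8)
    E = rng.uniform(0.0, 1.0, (m, 24))
    E[0, labels == 2] = 50.0     # clean marker
    E[1, labels == 2] = 50.0     # fails: expressed at exactly 2.0 elsewhere
    E[1, labels == 1] = 2.0
    E[2, labels == 2] = 8.0      # fails the > 10 target expression cut
    out = select_surface_markers(E, labels, 2, gene_ids[:10], gene_ids)
    assert "g0" in out["marker"].tolist()
    assert "g1" not in out["marker"].tolist()
    assert "g2" not in out["marker"].tolist()
    # hand-filter oracle over the candidate list
    expected = []
    for g in gene_ids[:10]:
        i = gene_ids.index(g)
        tm = E[i, labels == 2].mean()
        others = [E[i, labels == k].mean() for k in (1, 3)]
        if tm > 10 and all(o < 2 for o in others) and tm > max(others):
            expected.append(g)
    assert sorted(out["marker"]) == sorted(expected)


def test_surface_marker_no_survivor_warns():
    E = np.ones((5, 9))
    labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
    with pytest.warns(UserWarning, match="no surface marker"):
        out = select_surface_markers(E, labels, 2, ["g0", "g1"],
                                     [f"g{i}" for i in range(5)])
    assert out.empty


def test_shared_go_terms_removed_everywhere():
    tables = {
        1: pd.DataFrame({"term": ["shared", "t1", "weak"],
                         "score": [5.0, 3.0, 1.0]}),
        2: pd.DataFrame({"term": ["shared", "t2"], "score": [4.0, 2.5]}),
        3: pd.DataFrame({"term": ["shared", "t3"], "score": [3.0, 6.0]}),
    }
    out = filter_shared_go_terms(tables, score_threshold=2.0)
    assert all("shared" not in v for v in out.values())
    assert out[1] == ["t1"] and out[2] == ["t2"] and out[3] == ["t3"]
    # set-algebra oracle on a 12-term fixture
    rng = np.random.default_rng(11)
    terms = [f"T{i}" for i in range(12)]
    tables = {k: pd.DataFrame({"term": terms,
                               "score": rng.uniform(0, 4, 12)})
              for k in (1, 2, 3)}
    out = filter_shared_go_terms(tables)
    sig = {k: {t for t, s in zip(terms, tables[k]["score"]) if s > 2}
           for k in tables}
    shared = sig[1] & sig[2] & sig[3]
    for k in tables:
        assert set(out[k]) == sig[k] - shared
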