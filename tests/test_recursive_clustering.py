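import itertools

import numpy as np
import pytest

import annealclust as ac
from annealclust.errors import ClusteringError
from conftest import barbell, random_graph, two_triangles


def test_two_triangles_split_along_components():
    a, b, ss = ac.bipartition(
        two_triangles(), range(6), gamma=0.5, sampler=ac.ExactSampler(), min_size=1
    )
    assert {tuple(a), tuple(b)} == {(0, 1, 2), (3, 4, 5)}


def test_k4_splits_two_plus_two():
    g = ac.SNNGraph(4, {(i, j): 1.0 for i in range(4) for j in range(i + 1, 4)})
    a, b, _ = ac.bipartition(g, range(4), gamma=5.0, sampler=ac.ExactSampler(), min_size=1)
    assert len(a) == 2 and len(b) == 2
    x = np.zeros(4, dtype=np.uint8)
    x[list(b)] = 1
    assert ac.cut_weight(g, x) == pytest.approx(4.0)


def test_bipartition_min_size_precondition():
    with pytest.raises(ClusteringError):
        ac.bipartition(two_triangles(), range(6), 0.5, ac.ExactSampler(), min_size=4)


def test_edgeless_subset_split_trivially():
    g = ac.SNNGraph(6, {(0, 1): 1.0})  # nodes 2..5 isolated
    a, b, ss = ac.bipartition(g, [2, 3, 4, 5], 0.5, ac.ExactSampler(), min_size=1)
    assert ss is None
    assert sorted(list(a) + list(b)) == [2, 3, 4, 5]
    assert len(a) == 2 and len(b) == 2


def test_confidence_closed_form():
    bqm = ac.build_mincut_bqm(ac.SNNGraph(2, {(0, 1): 1.0}), ac.MinCutParams(gamma=0.0))
    ss = ac.SampleSet(
        states=np.array([[0, 0], [0, 1]], dtype=np.uint8),
        energies=np.array([0.0, 2.0]),
        occurrences=np.array([5, 5]),
    )
    assert ac.stopping_confidence(ss, top_m=2, total_weight=1.0) == pytest.approx(1.0)


def test_confidence_zero_for_single_state():
    bqm = ac.build_mincut_bqm(ac.SNNGraph(2, {(0, 1): 1.0}), ac.MinCutParams(gamma=0.0))
    ss = ac.SampleSet.from_samples(np.array([[1, 1]] * 7, dtype=np.uint8), bqm)
    assert ac.stopping_confidence(ss, top_m=5) == 0.0


def test_confidence_low_on_clean_component_split():
    g = two_triangles()
    bqm = ac.build_mincut_bqm(g, ac.MinCutParams(gamma=0.5))
    ss = ac.exact_sample(bqm)
    conf = ac.stopping_confidence(ss, top_m=5, total_weight=g.total_weight())
    assert conf < 0.05


def test_three_cliques_recover_three_clusters():
    w = {}
    for base in (0, 8, 16):
        for i in range(8):
            for j in range(i + 1, 8):
                w[(base + i, base + j)] = 1.0
    g = ac.SNNGraph(24, w)
    cfg = ac.ClusterConfig(
        min_size=3, sampler=ac.SimulatedAnnealingSampler(sweeps=200), reads=100, seed=0
    )
    res = ac.recursive_cluster(g, cfg)
    assert res.n_clusters == 3
    for base in (0, 8, 16):
        assert len({int(res.labels[base + i]) for i in range(8)}) == 1


def test_min_size_stops_whole_graph():
    g = barbell()
    cfg = ac.ClusterConfig(min_size=6, sampler=ac.ExactSampler(), seed=0)
    res = ac.recursive_cluster(g, cfg)
    assert res.n_clusters == 1
    assert res.tree.stop_reason == "min_size"


def test_labels_partition_cells_and_match_leaves():
    g = barbell()
    cfg = ac.ClusterConfig(min_size=2, sampler=ac.ExactSampler(), seed=0)
    res = ac.recursive_cluster(g, cfg)
    leaves = res.tree.leaves()
    assert res.n_clusters == len(leaves)
    seen = sorted(i for leaf in leaves for i in leaf.node_ids)
    assert seen == list(range(10))
    assert (res.labels >= 0).all()


def test_recursion_deterministic_under_fixed_seed():
    g = random_graph(np.random.default_rng(21), 30, p=0.3)
    cfg = ac.ClusterConfig(
        min_size=3, sampler=ac.SimulatedAnnealingSampler(sweeps=200), reads=100, seed=4
    )
    a = ac.recursive_cluster(g, cfg)
    b = ac.recursive_cluster(g, cfg)
    assert (a.labels == b.labels).all()


def test_disconnected_components_never_merge():
    rng = np.random.default_rng(31)
    blocks = []
    w = {}
    offset = 0
    comp_of = {}
    for size in (7, 9, 6):
        for i in range(size):
            comp_of[offset + i] = len(blocks)
            for j in range(i + 1, size):
                if rng.random() < 0.7:
                    w[(offset + i, offset + j)] = float(rng.uniform(0.1, 1.0))
        blocks.append(size)
        offset += size
    g = ac.SNNGraph(offset, w)
    cfg = ac.ClusterConfig(min_size=2, sampler=ac.SimulatedAnnealingSampler(sweeps=100),
                           reads=50, seed=1)
    res = ac.recursive_cluster(g, cfg)
    for lab in range(res.n_clusters):
        members = np.flatnonzero(res.labels == lab)
        assert len({comp_of[int(i)] for i in members}) == 1


def test_exact_first_cut_is_optimal_over_admissible_states():
    rng = np.random.default_rng(77)
    g = random_graph(rng, 10, p=0.5)
    gamma = 0.4
    min_size = 2
    bqm = ac.build_mincut_bqm(g, ac.MinCutParams(gamma=gamma))
    best = None
    for bits in itertools.product((0, 1), repeat=10):
        x = np.array(bits, dtype=np.uint8)
        if min(x.sum(), 10 - x.sum()) < min_size:
            continue
        e = bqm.energy(x)
        if best is None or e < best[0]:
            best = (e, x)
    a, b, ss = ac.bipartition(g, range(10), gamma, ac.ExactSampler(), min_size=min_size)
    x = np.zeros(10, dtype=np.uint8)
    x[list(b)] = 1
    assert bqm.energy(x) == pytest.approx(best[0])


def test_tune_gamma_prefers_smallest_on_ties():
    g = two_triangles()
    gamma = ac.tune_gamma(g, [0.2, 0.5, 1.0], ac.ExactSampler(), min_size=1)
    assert gamma == pytest.approx(0.2)


def test_tune_gamma_rejects_degenerate_zero():
    g = ac.SNNGraph(3, {(0, 1): 1.0, (1, 2): 1.0})
    with pytest.raises(ClusteringError):
        ac.tune_gamma(g, [0.0], ac.ExactSampler(), min_size=1)


def test_tune_gamma_recovers_barbell_bridge():
    g = barbell()
    gamma = ac.tune_gamma(g, [0.01, 0.1, 1.0, 10.0], ac.ExactSampler(), min_size=1)
    bqm = ac.build_mincut_bqm(g, ac.MinCutParams(gamma=gamma))
    ss = ac.exact_sample(bqm)
    assert tuple(ac.canonicalize(ss.states[0])) == (0, 0, 0, 0, 0, 1, 1, 1, 1, 1)


def test_tree_json_serializes(tmp_path):
    g = barbell()
    res = ac.recursive_cluster(g, ac.ClusterConfig(min_size=2, sampler=ac.ExactSampler()))
    text = res.tree_json()
    assert "stop_reason" in text
    res.save_labels(tmp_path / "labels.tsv")
    lines = (tmp_path / "labels.tsv").read_text().strip().splitlines()
    assert len(lines) == 10
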