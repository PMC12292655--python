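"""Local DND score components, aggregation, candidates and trend statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dndnet.datamodel import DataModelError, DirectedNet, OmicsMatrix, SampleTable, SSNRecord
from dndnet.scoring import (
    LocalModule,
    local_module,
    local_score,
    local_score_undirected,
    sample_score,
    score_all,
    sed_in,
    select_candidates,
    spcc_in,
    spcc_out,
    stage_mean_scores,
    stage_trend_stats,
)
from dndnet.ssn import ReferenceStats, build_reference, build_ssn


def _ref_stats(means, sds, graph_edges):
    g = nx.DiGraph()
    g.add_edges_from(graph_edges)
    feats = sorted(set(means))
    return ReferenceStats(
        edges=pd.DataFrame({"source": [e[0] for e in graph_edges],
                            "target": [e[1] for e in graph_edges],
                            "pcc_ref": 0.5, "p_ref": 0.01, "retained": True}),
        feature_stats=pd.DataFrame({"ref_mean": pd.Series(means), "ref_sd": pd.Series(sds)}),
        n_ref=10,
        reference_samples=[f"r{i}" for i in range(10)],
        edge_alpha=0.05,
        retained_graph=g,
    )


def _ssn(sample_id, edges):
    df = pd.DataFrame(edges, columns=["source", "target", "spcc"])
    df["pcc_ref"] = 0.3
    df["z"] = 0.0
    df["p"] = 1.0
    df["significant"] = False
    return SSNRecord(sample_id, df[["source", "target", "pcc_ref", "spcc", "z", "p", "significant"]], 10)


def test_local_module_downstream_only():
    g = nx.DiGraph([("c", "a"), ("c", "b"), ("u", "c"), ("a", "d"), ("b", "c")])
    m = local_module("c", g)
    assert m.first_order == ["a", "b"]
    assert m.second_order == ["d"]  # c excluded even though b -> c
    assert "u" not in m.first_order  # upstream-only neighbor ignored


def test_sed_in_hand_mean():
    # center deviates 2 sd, single neighbor 1 sd -> mean 1.5
    ref = _ref_stats({"c": 0.0, "a": 0.0}, {"c": 1.0, "a": 2.0}, [("c", "a")])
    vals = pd.Series({"c": 2.0, "a": 2.0})  # a: |2-0|/2 = 1
    mod = LocalModule("c", ["a"], [])
    assert sed_in(mod, vals, ref) == pytest.approx(1.5)
    # at the reference means the deviation vanishes
    assert sed_in(mod, pd.Series({"c": 0.0, "a": 0.0}), ref) == 0.0


def test_spcc_in_and_out_hand_means():
    mod = LocalModule("c", ["a", "b"], ["d", "e", "f"])
    ssn = _ssn("s", [("c", "a", 0.4), ("c", "b", -0.2),
                     ("a", "d", 0.1), ("a", "e", 0.3), ("b", "f", 0.2)])
    assert spcc_in(mod, ssn.edges) == pytest.approx(0.3)  # mean(|0.4|, |-0.2|)
    assert spcc_out(mod, ssn.edges) == pytest.approx(0.2)  # mean(0.1, 0.3, 0.2)
    # single negative edge -> absolute value; empty boundary -> floor
    ssn2 = _ssn("s", [("c", "a", -0.5)])
    assert spcc_in(LocalModule("c", ["a"], []), ssn2.edges) == pytest.approx(0.5)
    assert spcc_out(LocalModule("c", ["a"], []), ssn2.edges, floor=1e-6) == 1e-6


def test_local_score_composition_and_no_downstream():
    ref = _ref_stats({"c": 0.0, "a": 0.0, "d": 0.0}, {"c": 1.0, "a": 1.0, "d": 1.0},
                     [("c", "a"), ("a", "d")])
    ssn = _ssn("s", [("c", "a", 0.3), ("a", "d", 0.2)])
    vals = pd.Series({"c": 2.0, "a": 1.0, "d": 0.0})
    # sed = mean(2,1) = 1.5; spcc_in = 0.3; spcc_out = 0.2 -> 1.5*0.3/0.2 = 2.25
    assert local_score("c", ssn, ref, vals, floor=1e-6) == pytest.approx(2.25)
    assert local_score("d", ssn, ref, vals, floor=1e-6) == 0.0  # no out-neighbors


def test_local_score_matches_adjacency_power_oracle():
    """Module enumeration agrees with a brute-force oracle that finds first-
    and second-order downstream nodes from powers of the adjacency matrix."""
    rng = np.random.default_rng(8)
    nodes = list("abcdef")
    for _ in range(20):
        adj = (rng.random((6, 6)) < 0.35).astype(int)
        np.fill_diagonal(adj, 0)
        g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
        g = nx.relabel_nodes(g, dict(enumerate(nodes)))
        edges = list(g.edges)
        if not edges:
            continue
        means = {n: 0.0 for n in nodes}
        sds = {n: 1.0 for n in nodes}
        ref = _ref_stats(means, sds, edges)
        ssn = _ssn("s", [(u, v, float(rng.normal(0, 0.3))) for u, v in edges])
        vals = pd.Series(rng.normal(size=6), index=nodes)
        for ci, center in enumerate(nodes):
            # oracle: adjacency-power neighborhoods
            first = {nodes[j] for j in np.flatnonzero(adj[ci])}
            reach2 = set()
            for f in first:
                reach2 |= {nodes[j] for j in np.flatnonzero(adj[nodes.index(f)])}
            second = reach2 - first - {center}
            if not first:
                expected = 0.0
            else:
                e = ssn.edges
                ins = e[(e.source == center) & e.target.isin(first)]["spcc"].abs()
                outs = e[e.source.isin(first) & e.target.isin(second)]["spcc"].abs()
                s_ed = float(np.mean([abs(vals[n]) for n in [center, *sorted(first)]]))
                s_in = float(ins.mean()) if len(ins) else 0.0
                s_out = max(float(outs.mean()), 1e-6) if len(outs) else 1e-6
                expected = s_ed * s_in / s_out
            assert local_score(center, ssn, ref, vals, floor=1e-6) == pytest.approx(expected, rel=1e-12)


def test_score_monotone_in_each_dnb_condition():
    """Raising deviation or in-module perturbation, or lowering boundary
    perturbation, each increases Is with the other components held fixed."""
    ref = _ref_stats({"c": 0.0, "a": 0.0, "d": 0.0}, {"c": 1.0, "a": 1.0, "d": 1.0},
                     [("c", "a"), ("a", "d")])
    base_vals = pd.Series({"c": 1.0, "a": 1.0, "d": 0.0})
    base = local_score("c", _ssn("s", [("c", "a", 0.3), ("a", "d", 0.2)]), ref, base_vals)
    higher_dev = local_score("c", _ssn("s", [("c", "a", 0.3), ("a", "d", 0.2)]), ref,
                             pd.Series({"c": 3.0, "a": 1.0, "d": 0.0}))
    higher_in = local_score("c", _ssn("s", [("c", "a", 0.6), ("a", "d", 0.2)]), ref, base_vals)
    lower_out = local_score("c", _ssn("s", [("c", "a", 0.3), ("a", "d", 0.05)]), ref, base_vals)
    assert higher_dev > base and higher_in > base and lower_out > base


def test_reversing_upstream_edge_changes_module():
    """An incoming edge never contributes; flipping it downstream does."""
    ssn = _ssn("s", [("c", "a", 0.3), ("u", "c", 0.9)])
    ref_up = _ref_stats({"c": 0.0, "a": 0.0, "u": 0.0}, {"c": 1.0, "a": 1.0, "u": 1.0},
                        [("c", "a"), ("u", "c")])
    vals = pd.Series({"c": 1.0, "a": 1.0, "u": 5.0})
    s_up = local_score("c", ssn, ref_up, vals)
    ref_down = _ref_stats({"c": 0.0, "a": 0.0, "u": 0.0}, {"c": 1.0, "a": 1.0, "u": 1.0},
                          [("c", "a"), ("c", "u")])
    ssn_down = _ssn("s", [("c", "a", 0.3), ("c", "u", 0.9)])
    s_down = local_score("c", ssn_down, ref_down, vals)
    assert s_up != s_down
    # u (deviation 5) joins the module only in the downstream variant
    assert s_down > s_up


def _sim_cohort(seed=0):
    rng = np.random.default_rng(seed)
    feats = list("abcdef")
    n_ref, n_new = 15, 5
    sids = [f"s{i}" for i in range(n_ref + n_new)]
    data = pd.DataFrame(rng.normal(size=(6, n_ref + n_new)), index=feats, columns=sids)
    data.loc["b"] = 0.7 * data.loc["a"] + 0.3 * rng.normal(size=n_ref + n_new)
    data.loc["c"] = 0.7 * data.loc["b"] + 0.3 * rng.normal(size=n_ref + n_new)
    m = OmicsMatrix(data, pd.Series("mRNA", index=feats))
    meta = pd.DataFrame({"sample_id": sids, "subject_id": sids,
                         "stage": ["ref"] * n_ref + ["new"] * n_new})
    return m, SampleTable(meta, ["ref", "new"])


def test_directed_score_equals_undirected_on_symmetrized_network():
    """Limit equivalence: duplicating every edge in both directions makes the
    downstream-restricted score coincide with the classic undirected l-DNB."""
    m, s = _sim_cohort(21)
    sym_edges = [("a", "b"), ("b", "a"), ("b", "c"), ("c", "b"), ("a", "d"), ("d", "a")]
    net = DirectedNet.from_edges(sym_edges)
    ref = build_reference(m, s, net, edge_alpha=1.0)  # keep all edges
    recs = build_ssn(m, s, ref, ssn_alpha=0.05)
    for rec in recs[:6]:
        vals = m.data[rec.sample_id]
        for center in "abcd":
            d = local_score(center, rec, ref, vals, floor=1e-6)
            u = local_score_undirected(center, rec, ref, vals, floor=1e-6)
            assert d == pytest.approx(u, abs=1e-9)


def test_sample_score_mean_and_pooling_identity():
    scores = pd.Series([0.0, 2.0, 4.0])
    assert sample_score(scores) == pytest.approx(2.0)
    assert sample_score(pd.Series([3.0, 3.0])) == 3.0
    # pooled mean = count-weighted mean of two kind-specific means
    mrna, mirna = pd.Series([1.0, 2.0, 3.0]), pd.Series([5.0])
    pooled = sample_score(pd.concat([mrna, mirna]))
    weighted = (mrna.mean() * 3 + mirna.mean() * 1) / 4
    assert pooled == pytest.approx(weighted)
    with pytest.raises(DataModelError):
        sample_score(pd.Series(dtype=float))


def test_select_candidates_rules():
    sm = pd.DataFrame(
        {"s1": [0.1, 2.0, 0.1, 0.2], "s2": [0.5, 1.0, 0.2, 0.1], "s3": [2.0, 0.5, 0.3, 0.15]},
        index=["up_top", "down", "up_small", "wiggle"],
    )
    cands = select_candidates(sm, ["s1", "s2", "s3"], top_fraction=0.25)
    assert cands == ["up_top"]  # monotone and in the top quartile
    assert "down" not in cands  # decreasing trajectory
    with pytest.raises(DataModelError):
        select_candidates(sm[["s1"]], ["s1"])


def test_stage_trend_uptrend_and_flat():
    rows, scores = [], []
    for i in range(5):
        for j, st in enumerate(["a", "b", "c"]):
            rows.append({"sample_id": f"p{i}{st}", "subject_id": f"p{i}", "stage": st})
            scores.append({"sample_id": f"p{i}{st}", "dnd_score": float(j + 1)})
    samples = SampleTable(pd.DataFrame(rows), ["a", "b", "c"])
    res = stage_trend_stats(pd.DataFrame(scores), samples)
    assert res.uptrend_subjects == 5 and res.n_complete_subjects == 5
    flat = pd.DataFrame(scores).assign(dnd_score=1.0)
    res2 = stage_trend_stats(flat, samples)
    assert res2.uptrend_subjects == 0


def test_adjusted_icc_near_zero_for_subject_free_noise():
    """Residuals with no subject component: mean adjusted ICC ~ 0 over
    repeated simulations at 20 subjects."""
    rng = np.random.default_rng(31)
    rows = []
    for i in range(20):
        for st in ["a", "b", "c"]:
            rows.append({"sample_id": f"p{i}{st}", "subject_id": f"p{i}", "stage": st})
    samples = SampleTable(pd.DataFrame(rows), ["a", "b", "c"])
    iccs = []
    for _ in range(200):
        scores = pd.DataFrame({
            "sample_id": [r["sample_id"] for r in rows],
            "dnd_score": rng.normal(size=len(rows)),
        })
        iccs.append(stage_trend_stats(scores, samples).adjusted_icc)
    assert abs(float(np.mean(iccs))) < 0.05


def test_stage_means_equal_arithmetic_mean():
    per = pd.DataFrame({
        "feature_id": ["f"] * 4, "sample_id": list("wxyz"),
        "stage": ["a", "a", "b", "b"], "score": [1.0, 3.0, 2.0, 6.0],
    })
    sm = stage_mean_scores(per, ["a", "b"])
    assert sm.loc["f", "a"] == 2.0 and sm.loc["f", "b"] == 4.0
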