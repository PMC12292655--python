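"""Minimum feedback vertex set on a small regulatory motif.

Two feedback loops share the hub TF: TF -> A -> TF and TF -> B -> TF,
plus a downstream cascade.  Removing the hub alone breaks every loop, so
the minimum FVS is {TF}; the heuristic solver agrees here.
"""

from dndnet import DirectedNet, fvs_exact, fvs_heuristic, rank_drivers

net = DirectedNet.from_edges([
    ("TF", "A"), ("A", "TF"),
    ("TF", "B"), ("B", "TF"),
    ("TF", "C"), ("C", "D"), ("D", "E"),
])

exact = fvs_exact(net)
heur = fvs_heuristic(net)
print(f"exact FVS:     {exact.fvs_nodes} (residual acyclic: {exact.residual_acyclic})")
print(f"heuristic FVS: {heur.fvs_nodes} (guaranteed valid, not guaranteed minimum)")
print(f"drivers ranked by out-degree: {rank_drivers(exact, net)}")
# A DAG needs no removals at all:
dag = DirectedNet.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
print(f"FVS of a DAG: {fvs_exact(dag).fvs_nodes}")
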