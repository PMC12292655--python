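"""Generate a synthetic three-stage skin-lesion study and run the full
Dynamic Network Driver analysis on it.

The generator plants a driver module: a hub transcription factor
(gene_001) whose targets destabilize and co-fluctuate more as stages
progress while decoupling from the rest of the network.  The pipeline
should rediscover it: the planted center ends up in the driver list,
ranked first by background out-degree.
"""

from dndnet import RunConfig, SimConfig, make_network, run_dnd, simulate_expression

cfg = SimConfig(seed=42)
net = make_network(cfg)
matrix, samples = simulate_expression(net, cfg)
print(f"simulated {len(matrix.feature_ids)} features "
      f"({(matrix.feature_kind == 'miRNA').sum()} miRNA) x {len(matrix.sample_ids)} samples, "
      f"background network with {net.n_edges} directed edges")

result = run_dnd(matrix, samples, net,
                 RunConfig(skip_outliers=True, skip_filter=True, n_perm=199))

print(f"reference edges retained at alpha=0.05: "
      f"{int(result.reference.edges['retained'].sum())} / {len(result.reference.edges)}")
p = result.permanova
print(f"PERMANOVA across stages: F = {p.pseudo_F:.2f}, R2 = {100 * p.R2:.1f}%, p = {p.p:.3g}")
print(f"DND candidates ({len(result.score_table.candidates)}): "
      f"{', '.join(result.score_table.candidates)}")
print(f"drivers (FVS, ranked by out-degree): {result.drivers}")
print(f"subjects with strictly rising DND score: "
      f"{result.trend.uptrend_subjects}/{result.trend.n_complete_subjects}")
print(f"planted center gene_001 recovered as top driver: "
      f"{bool(result.drivers and result.drivers[0] == cfg.center)}")
# The candidate list should be dominated by the planted module
# (gene_001..gene_009 and the repressor miRNAs); the driver list is the
# minimal node set breaking every feedback loop among candidates.
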