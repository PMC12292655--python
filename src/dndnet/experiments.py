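"""Reusable in-silico experiments: planted-driver recovery and null calibrations.

These are the package's validation workloads — each builds its own inputs
with the synthetic generator, runs the pipeline, and measures an outcome.
The recovery experiment runs the scoring path (reference network, SSNs,
DND scores, candidate selection, FVS) without the outlier/filter
preprocessing: the generator plants no technical outliers to remove, so
those stages are exercised and calibrated by their own dedicated
experiments instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pipeline import RunConfig, run_dnd
from .simulate import SimConfig, evaluate_recovery, make_network, simulate_expression


@dataclass
class RecoveryOutcome:
    auroc: float
    uptrend_fraction: float
    center_in_drivers: bool
    center_driver_rank: int | None
    n_candidates: int
    fvs_size: int


def recovery_run(sim_cfg: SimConfig, run_cfg: RunConfig | None = None) -> RecoveryOutcome:
    """One end-to-end planted-driver recovery run."""
    run_cfg = run_cfg or RunConfig(skip_outliers=True, skip_filter=True, n_perm=99)
    net = make_network(sim_cfg)
    matrix, samples = simulate_expression(net, sim_cfg)
    res = run_dnd(matrix, samples, net, run_cfg)
    rec = evaluate_recovery(res.score_table.stage_means, sim_cfg, res.drivers)
    n_complete = max(res.trend.n_complete_subjects, 1)
    return RecoveryOutcome(
        auroc=rec["auroc"],
        uptrend_fraction=res.trend.uptrend_subjects / n_complete,
        center_in_drivers=sim_cfg.center in res.drivers,
        center_driver_rank=rec["center_driver_rank"],
        n_candidates=len(res.score_table.candidates),
        fvs_size=len(res.fvs.fvs_nodes) if res.fvs else 0,
    )


def recovery_experiment(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Planted-driver recovery over ``n_seeds`` independent simulated
    cohorts; medians of AUROC and uptrend fraction, and the fraction of
    cohorts where the planted center tops the driver list."""
    outcomes = [recovery_run(SimConfig(seed=base_seed + i)) for i in range(n_seeds)]
    return {
        "median_auroc": float(np.median([o.auroc for o in outcomes])),
        "median_uptrend_fraction": float(np.median([o.uptrend_fraction for o in outcomes])),
        "center_ranked_first_fraction": float(
            np.mean([o.center_driver_rank == 1 for o in outcomes])
        ),
        "center_in_drivers_fraction": float(np.mean([o.center_in_drivers for o in outcomes])),
        "median_n_candidates": float(np.median([o.n_candidates for o in outcomes])),
        "median_fvs_size": float(np.median([o.fvs_size for o in outcomes])),
        "outcomes": outcomes,
    }


def null_candidate_run(seed: int = 0) -> int:
    """Candidate count under the no-progression null (flat sigma and rho):
    should stay near the false-positive expectation of the selection rule."""
    cfg = SimConfig(
        seed=seed,
        sigma_stage=(0.5, 0.5, 0.5),
        rho_out_stage=(0.3, 0.3, 0.3),
        module_shift_stage=(0.5, 0.5, 0.5),
        stage_shift_scale=0.0,
    )
    net = make_network(cfg, allow_flat=True)
    matrix, samples = simulate_expression(net, cfg, allow_flat=True)
    res = run_dnd(matrix, samples, net, RunConfig(skip_outliers=True, skip_filter=True, n_perm=9))
    return len(res.score_table.candidates)


def ssn_null_calibration(n_ref: int = 100, n_new: int = 400, n_edges: int = 60,
                         alpha: float = 0.05, seed: int = 0) -> float:
    """Significant-edge rate when evaluated samples come from the reference
    distribution itself; should approximate ``alpha``.

    Uses correlated Gaussian pairs (r = 0.5) so retained edges exist.
    """
    import pandas as pd

    from .datamodel import DirectedNet, OmicsMatrix, SampleTable
    from .ssn import build_reference, build_ssn

    rng = np.random.default_rng(seed)
    n_feat = 2 * n_edges
    cov_r = 0.5
    # features come in correlated pairs (2i, 2i+1)
    z = rng.standard_normal((n_feat, n_ref + n_new))
    for i in range(n_edges):
        z[2 * i + 1] = cov_r * z[2 * i] + np.sqrt(1 - cov_r**2) * z[2 * i + 1]
    feats = [f"f{i:03d}" for i in range(n_feat)]
    sids = [f"s{i:04d}" for i in range(n_ref + n_new)]
    matrix = OmicsMatrix(
        pd.DataFrame(z, index=feats, columns=sids),
        pd.Series("mRNA", index=feats),
    )
    meta = pd.DataFrame({
        "sample_id": sids,
        "subject_id": sids,
        "stage": ["ref"] * n_ref + ["new"] * n_new,
    })
    samples = SampleTable(meta, ["ref", "new"])
    net = DirectedNet.from_edges([(feats[2 * i], feats[2 * i + 1]) for i in range(n_edges)])
    ref = build_reference(matrix, samples, net, edge_alpha=0.05)
    records = build_ssn(matrix, samples, ref, ssn_alpha=alpha, include_reference_samples=False)
    sig = np.concatenate([r.edges["significant"].to_numpy() for r in records])
    return float(sig.mean())
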