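"""End-to-end orchestration: preprocess → reference → SSN → score → select
→ control, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import control, preprocess, scoring, ssn as ssn_mod
from .datamodel import (
    DirectedNet,
    OmicsMatrix,
    SampleTable,
    load_expression,
    load_network,
    load_samples,
    load_whitelist,
    write_outputs,
)

logger = logging.getLogger(__name__)

KNOWN_KEYS = {
    "expression", "kind_map", "metadata", "network", "whitelist", "stage_order",
    "confidence", "outlier_policy", "mahalanobis_k", "n_perm", "seed",
    "pcc_alpha", "anova_alpha", "edge_alpha", "ssn_alpha", "floor",
    "top_fraction", "require_monotone", "fvs_mode", "fvs_budget",
    "min_reference", "skip_outliers", "skip_filter", "out_dir",
}


@dataclass
class RunConfig:
    """All pipeline parameters with defaults; unknown keys are rejected."""

    expression: str = ""
    kind_map: str = ""
    metadata: str = ""
    network: str = ""
    whitelist: str | None = None
    stage_order: list[str] = field(default_factory=list)
    confidence: float = 0.95
    outlier_policy: str = "union"
    mahalanobis_k: int | None = None
    n_perm: int = 999
    seed: int = 17
    pcc_alpha: float = 0.05
    anova_alpha: float = 0.05
    edge_alpha: float = 0.05
    ssn_alpha: float = 0.05
    floor: float | None = None  # None: per-sample median |sPCC|
    top_fraction: float = 0.10
    require_monotone: bool = True
    fvs_mode: str = "auto"
    fvs_budget: int = 20
    min_reference: int = 5
    skip_outliers: bool = False
    skip_filter: bool = False
    out_dir: str = "dnd_out"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    samples_retained: SampleTable
    outliers: preprocess.OutlierReport | None
    permanova: preprocess.PermanovaResult | None
    filter_result: preprocess.FeatureFilterResult | None
    reference: ssn_mod.ReferenceStats
    ssn_records: list
    score_table: scoring.ScoreTable
    trend: scoring.TrendStats
    fvs: control.FvsResult | None
    drivers: list[str]
    degree_p: float | None


def run_dnd(
    matrix: OmicsMatrix,
    samples: SampleTable,
    net: DirectedNet,
    cfg: RunConfig | None = None,
    whitelist: set[str] | None = None,
) -> PipelineResult:
    """Run the full DND analysis in memory and return every stage product."""
    cfg = cfg or RunConfig()
    samples.validate_against(matrix)

    # --- preprocess
    outliers = None
    if not cfg.skip_outliers:
        outliers = preprocess.outlier_report(
            matrix, samples, cfg.confidence, cfg.mahalanobis_k, cfg.outlier_policy
        )
        if outliers.excluded_subjects:
            logger.info("excluding subjects: %s", outliers.excluded_subjects)
            samples = preprocess.exclude_subjects(outliers, samples)
    matrix = matrix.subset_samples(samples.sample_ids)

    perm = None
    stage_counts = samples.table["stage"].value_counts()
    if (stage_counts >= 2).sum() >= 2:
        perm = preprocess.permanova(
            matrix, samples.table.set_index("sample_id").loc[matrix.sample_ids, "stage"].to_numpy(),
            n_perm=cfg.n_perm, seed=cfg.seed,
        )

    filt = None
    if not cfg.skip_filter:
        filt = preprocess.feature_filter(
            matrix, samples, whitelist, cfg.pcc_alpha, cfg.anova_alpha
        )
        selected = filt.selected
        if selected:
            matrix = matrix.subset_features(selected)
        else:
            logger.warning("feature filter selected nothing; keeping all features")

    # --- reference network and SSNs
    ref = ssn_mod.build_reference(matrix, samples, net, cfg.edge_alpha, cfg.min_reference)
    records = ssn_mod.build_ssn(matrix, samples, ref, cfg.ssn_alpha)

    # --- scoring
    per_sample = scoring.score_all(records, ref, matrix.data, samples, cfg.floor)
    stage_means = scoring.stage_mean_scores(per_sample, samples.stage_order)
    candidates = scoring.select_candidates(
        stage_means, samples.stage_order, cfg.top_fraction, cfg.require_monotone
    )
    sample_scores = (
        per_sample.groupby(["sample_id", "stage"], as_index=False)["score"]
        .mean()
        .rename(columns={"score": "dnd_score"})
    )
    sample_scores = sample_scores.merge(
        samples.table[["sample_id", "subject_id"]], on="sample_id"
    )
    trend = scoring.stage_trend_stats(sample_scores, samples)

    # --- control
    fvs = None
    drivers: list[str] = []
    degree_p = None
    if candidates:
        try:
            sub = control.induced_subgraph(net, candidates)
            fvs = control.fvs_auto(sub, cfg.fvs_mode, cfg.fvs_budget)
            drivers = control.rank_drivers(fvs, net)
        except Exception as exc:  # empty intersection etc.
            logger.warning("FVS stage skipped: %s", exc)
        final_stage = samples.stage_order[-1]
        final_ids = set(samples.samples_in_stage(final_stage))
        final_records = [r for r in records if r.sample_id in final_ids]
        non_cand = [f for f in matrix.feature_ids if f not in set(candidates)]
        if final_records and non_cand:
            _, _, degree_p = control.degree_comparison(candidates, final_records, matrix.feature_ids)

    per_feature = pd.DataFrame({"feature_id": stage_means.index})
    per_feature["candidate"] = per_feature["feature_id"].isin(candidates)
    per_feature["driver"] = per_feature["feature_id"].isin(drivers)
    per_feature["out_degree"] = [net.out_degree(f) for f in per_feature["feature_id"]]

    score_table = scoring.ScoreTable(
        per_sample=per_sample,
        stage_means=stage_means,
        per_feature=per_feature,
        sample_scores=sample_scores,
        candidates=candidates,
        drivers=drivers,
    )
    return PipelineResult(
        samples_retained=samples,
        outliers=outliers,
        permanova=perm,
        filter_result=filt,
        reference=ref,
        ssn_records=records,
        score_table=score_table,
        trend=trend,
        fvs=fvs,
        drivers=drivers,
        degree_p=degree_p,
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(cfg: RunConfig) -> dict:
    """File-based run: load inputs, execute, write outputs and a manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = load_expression(cfg.expression, cfg.kind_map)
    samples = load_samples(cfg.metadata, cfg.stage_order, cfg.min_reference)
    net = load_network(cfg.network)
    wl = load_whitelist(cfg.whitelist) if cfg.whitelist else None

    result = run_dnd(matrix, samples, net, cfg, wl)
    paths = write_outputs(result.score_table, result.ssn_records, out)

    if result.permanova:
        pd.DataFrame([{
            "pseudo_F": result.permanova.pseudo_F, "R2": result.permanova.R2,
            "p": result.permanova.p, "n_perm": result.permanova.n_perm,
        }]).to_csv(out / "permanova.tsv", sep="\t", index=False, float_format="%.6g")
    if result.outliers is not None:
        result.outliers.per_sample.to_csv(out / "outliers.tsv", sep="\t", index=False, float_format="%.6g")
    result.trend.paired_t.to_csv(out / "trend_tests.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "input_checksums": {
            k: _checksum(Path(p))
            for k, p in [("expression", cfg.expression), ("kind_map", cfg.kind_map),
                         ("metadata", cfg.metadata), ("network", cfg.network)]
            if p
        },
        "n_samples_retained": len(result.samples_retained.sample_ids),
        "n_candidates": len(result.score_table.candidates),
        "n_drivers": len(result.drivers),
        "uptrend_subjects": result.trend.uptrend_subjects,
        "n_complete_subjects": result.trend.n_complete_subjects,
        "adjusted_icc": result.trend.adjusted_icc,
        "fvs_size": len(result.fvs.fvs_nodes) if result.fvs else 0,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def report(out_dir: str | Path) -> str:
    """Human-readable summary recomputed purely from written outputs."""
    out = Path(out_dir)
    required = ["manifest.json", "candidates.txt", "drivers.txt"]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        return "incomplete run; missing: " + ", ".join(missing)
    manifest = json.loads((out / "manifest.json").read_text())
    candidates = [l for l in (out / "candidates.txt").read_text().splitlines()[1:] if l]
    drivers = [l for l in (out / "drivers.txt").read_text().splitlines()[1:] if l]
    lines = [
        f"samples retained: {manifest['n_samples_retained']}",
        f"candidates: {len(candidates)}",
        f"uptrend subjects: {manifest['uptrend_subjects']}/{manifest['n_complete_subjects']}",
        f"adjusted ICC: {manifest['adjusted_icc']:.3f}",
        f"FVS size: {manifest['fvs_size']}",
    ]
    perm_path = out / "permanova.tsv"
    if perm_path.exists():
        perm = pd.read_csv(perm_path, sep="\t")
        lines.insert(1, (
            f"PERMANOVA: F = {perm['pseudo_F'][0]:.3g}, "
            f"R2 = {100 * perm['R2'][0]:.3g}%, p = {perm['p'][0]:.3g}"
        ))
    if drivers:
        lines.append("top drivers by out-degree: " + ", ".join(drivers[:10]))
    else:
        lines.append("no drivers (empty candidate set or acyclic subnetwork)")
    return "\n".join(lines)
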