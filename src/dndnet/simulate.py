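"""Synthetic three-stage multi-omics study with a planted driver module.

The generator emulates the study design the pipeline targets: subjects
sampled once per ordered stage (a pseudo-temporal progression), a directed
background network of TF-like mRNA hubs and miRNA->mRNA repression edges,
and a planted driver module wired so the center sits on feedback loops.

Expression follows a latent-factor model chosen because the tipping-point
(DNB) signature is a statement about second moments: module nodes load on
a shared severity factor whose standard deviation grows with stage
(variance and intra-module correlation rise), while the factor leaks into
the module's downstream boundary with a coupling that *shrinks* with stage
(boundary correlation falls).  The severity factor is subject-anchored
with a small per-sample jitter, reflecting repeated measures: a subject's
lesion severity is largely a property of the subject, so within-subject
trajectories rise monotonically for most — not all — subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DataModelError, DirectedNet, OmicsMatrix, SampleTable

logger = logging.getLogger(__name__)

STAGES = ["photo_protected", "peri_lesion", "lesion"]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    sigma_stage is the SD of the module latent factor per stage (rising ⇒
    growing module fluctuation); rho_out_stage the latent-to-boundary
    coupling (falling ⇒ boundary decorrelation); noise_sd the baseline
    per-feature noise; subject_jitter the within-subject share of severity
    not explained by the subject's own level (small ⇒ consistent
    trajectories).
    """

    n_mrna: int = 90
    n_mirna: int = 10
    n_subjects: int = 20
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sigma_stage: tuple[float, ...] = (0.5, 1.5, 3.0)
    rho_out_stage: tuple[float, ...] = (0.6, 0.3, 0.1)
    noise_sd: float = 0.3
    subject_jitter: float = 0.3
    #: additive mean level of module genes per stage (repressor miRNAs get
    #: the negative of 0.8x this): progression raises the level, not just
    #: the fluctuation, as for a driver whose expression climbs stage by
    #: stage.  The default tracks sigma_stage so that per subject the
    #: module deviation is sigma_t*(z+1) — level and fluctuation grow
    #: together and the deviation magnitude rises with stage for every
    #: severity draw z.
    module_shift_stage: tuple[float, ...] = (0.5, 1.5, 3.0)
    #: fraction of non-module mRNAs that are generically stage-responsive
    #: (random sign), giving the cohort the stage-wise differential
    #: expression that PERMANOVA and the ANOVA filter act on
    stage_shift_fraction: float = 0.3
    stage_shift_scale: float = 0.5
    n_module_targets: int = 8
    n_feedback_targets: int = 3
    n_mirna_repressors: int = 2
    targets_per_module_gene: int = 3
    hub_fraction: float = 0.2
    mean_hub_out_degree: float = 4.0
    mean_mirna_out_degree: float = 3.0
    replicates: int = 1
    seed: int = 0

    def validate(self, allow_flat: bool = False) -> None:
        if self.n_mrna < 20 or self.n_mirna < 2:
            raise DataModelError("need n_mrna >= 20 and n_mirna >= 2")
        if len(self.sigma_stage) != len(self.stages) or len(self.rho_out_stage) != len(self.stages):
            raise DataModelError("per-stage parameter lengths must match stages")
        if len(self.module_shift_stage) != len(self.stages):
            raise DataModelError("module_shift_stage length must match stages")
        if not allow_flat:
            if not all(b > a for a, b in zip(self.sigma_stage, self.sigma_stage[1:])):
                raise DataModelError("sigma_stage must increase strictly along stages")
            if not all(b < a for a, b in zip(self.rho_out_stage, self.rho_out_stage[1:])):
                raise DataModelError("rho_out_stage must decrease strictly along stages")
            if not all(b >= a for a, b in zip(self.module_shift_stage, self.module_shift_stage[1:])):
                raise DataModelError("module_shift_stage must be non-decreasing")
        if self.n_module_targets < 3:
            raise DataModelError("planted center needs out-degree >= 3")
        if self.n_module_targets + self.targets_per_module_gene * self.n_module_targets >= self.n_mrna - 1:
            raise DataModelError("module wiring does not fit in n_mrna")

    @property
    def mrna_ids(self) -> list[str]:
        return [f"gene_{i:03d}" for i in range(1, self.n_mrna + 1)]

    @property
    def mirna_ids(self) -> list[str]:
        return [f"mir_{i:03d}" for i in range(1, self.n_mirna + 1)]

    @property
    def center(self) -> str:
        return self.mrna_ids[0]

    def module_targets(self, rng: np.random.Generator | None = None) -> list[str]:
        # deterministic: targets are the mRNAs right after the center
        return self.mrna_ids[1 : 1 + self.n_module_targets]

    @property
    def module_nodes(self) -> list[str]:
        return [self.center] + self.module_targets()

    @property
    def mirna_repressors(self) -> list[str]:
        return self.mirna_ids[: self.n_mirna_repressors]


def make_network(cfg: SimConfig, allow_flat: bool = False) -> DirectedNet:
    """Random directed background network with the planted driver wiring.

    TF-like mRNA hubs get geometric out-degrees; miRNAs regulate only
    mRNAs (in-degree 0).  The planted center is wired to its module
    targets, each target onward to boundary genes (guaranteeing a
    second-order shell), and a subset of targets back to the center so
    every feedback loop through the module passes the center.  The center
    is made the highest-out-degree node by construction.
    """
    cfg.validate(allow_flat=allow_flat)
    rng = np.random.default_rng(cfg.seed)
    mrna, mirna = cfg.mrna_ids, cfg.mirna_ids
    center = cfg.center
    targets = cfg.module_targets()
    module = set([center] + targets)
    edges: set[tuple[str, str]] = set()

    # background TF hubs among non-module mRNAs
    pool = [g for g in mrna if g not in module]
    n_hubs = max(1, int(cfg.hub_fraction * len(pool)))
    hubs = list(rng.choice(pool, size=n_hubs, replace=False))
    for h in hubs:
        k = rng.geometric(1.0 / cfg.mean_hub_out_degree)
        tgts = rng.choice([g for g in mrna if g != h], size=min(k, len(mrna) - 1), replace=False)
        for t in tgts:
            edges.add((h, str(t)))

    # miRNA -> mRNA only
    for m in mirna:
        k = rng.geometric(1.0 / cfg.mean_mirna_out_degree)
        tgts = rng.choice(mrna, size=min(k, len(mrna)), replace=False)
        for t in tgts:
            edges.add((m, str(t)))
    for m in cfg.mirna_repressors:  # repressors hit module genes incl. the center
        for t in [center] + targets[:2]:
            edges.add((m, t))

    # planted module wiring
    for t in targets:
        edges.add((center, t))
    boundary_pool = [g for g in mrna if g not in module]
    boundary = list(rng.choice(boundary_pool, size=cfg.targets_per_module_gene * len(targets), replace=False))
    for i, t in enumerate(targets):
        for j in range(cfg.targets_per_module_gene):
            edges.add((t, boundary[i * cfg.targets_per_module_gene + j]))
    for t in targets[: cfg.n_feedback_targets]:  # feedback loops through the center only
        edges.add((t, center))

    # make the center the top out-degree node
    out_deg: dict[str, int] = {}
    for u, _ in edges:
        out_deg[u] = out_deg.get(u, 0) + 1
    max_other = max((d for u, d in out_deg.items() if u != center), default=0)
    extra_needed = max(0, max_other + 2 - out_deg.get(center, 0))
    if extra_needed:
        extra_pool = [g for g in mrna if g != center and (center, g) not in edges]
        for t in list(rng.choice(extra_pool, size=min(extra_needed, len(extra_pool)), replace=False)):
            edges.add((center, str(t)))

    net = DirectedNet.from_edges(sorted(edges), nodes=mrna + mirna)
    assert set(net.out_neighbors(center)) >= set(targets)
    return net


def simulate_expression(
    net: DirectedNet, cfg: SimConfig, allow_flat: bool = False
) -> tuple[OmicsMatrix, SampleTable]:
    """One sample per subject per stage (times ``replicates``) from the
    latent-factor model, finally standardized per feature against the
    reference stage."""
    cfg.validate(allow_flat=allow_flat)
    rng = np.random.default_rng(cfg.seed + 1)
    features = cfg.mrna_ids + cfg.mirna_ids
    fidx = {f: i for i, f in enumerate(features)}
    center, targets = cfg.center, cfg.module_targets()
    module = [center] + targets
    repressors = [m for m in cfg.mirna_repressors if center in net.out_neighbors(m) or set(net.out_neighbors(m)) & set(module)]

    # boundary = downstream of module targets, outside the module
    boundary: set[str] = set()
    for t in targets:
        boundary |= net.out_neighbors(t)
    boundary -= set(module)

    loadings = {center: 1.0}
    for t in targets:
        loadings[t] = float(rng.uniform(0.8, 1.2))
    for m in repressors:
        loadings[m] = -0.8

    # generically stage-responsive features outside the module (random sign)
    non_module = [g for g in cfg.mrna_ids if g not in set(module)]
    n_shift = int(cfg.stage_shift_fraction * len(non_module))
    shifted = list(rng.choice(non_module, size=n_shift, replace=False))
    shift_sign = {g: float(rng.choice([-1.0, 1.0])) for g in shifted}
    shift_mag = {g: float(rng.uniform(0.5, 1.5)) * cfg.stage_shift_scale for g in shifted}

    j = cfg.subject_jitter
    norm = np.sqrt(1 + j**2)
    # severity is a non-negative subject trait (half-normal): subjects
    # progress by different amounts, none in the reverse direction
    u_subj = np.abs(rng.standard_normal(cfg.n_subjects))

    cols, rows_meta = [], []
    data = np.zeros((len(features), cfg.n_subjects * len(cfg.stages) * cfg.replicates))
    col = 0
    for s_i in range(cfg.n_subjects):
        subj = f"subj_{s_i + 1:02d}"
        for st_i, stage in enumerate(cfg.stages):
            sigma = cfg.sigma_stage[st_i]
            rho = cfg.rho_out_stage[st_i]
            shift = cfg.module_shift_stage[st_i]
            for rep in range(cfg.replicates):
                z_unit = (u_subj[s_i] + j * rng.standard_normal()) / norm  # unit-variance severity
                f = sigma * z_unit
                x = rng.normal(0.0, cfg.noise_sd, size=len(features))
                for node, lam in loadings.items():
                    # loading applies to the severity level and its fluctuation
                    # alike: positive-loading genes climb, repressors fall
                    x[fidx[node]] += lam * (f + shift)
                for b in boundary:
                    x[fidx[b]] += rho * z_unit
                for g in shifted:
                    x[fidx[g]] += shift_sign[g] * shift_mag[g] * st_i
                sid = f"{subj}_{stage}" + (f"_r{rep + 1}" if cfg.replicates > 1 else "")
                data[:, col] = x
                cols.append(sid)
                level = sigma * (z_unit + 1)  # severity level driving the phenotypes
                rows_meta.append({
                    "sample_id": sid, "subject_id": subj, "stage": stage,
                    "spot_size": float(2.0 * level + rng.normal(0, 0.5)),
                    "melanin_index": float(10.0 + 3.0 * level + rng.normal(0, 1.0)),
                })
                col += 1

    df = pd.DataFrame(data, index=features, columns=cols)
    meta = pd.DataFrame(rows_meta)
    ref_ids = meta.loc[meta["stage"] == cfg.stages[0], "sample_id"]
    ref = df.loc[:, ref_ids]
    df = df.sub(ref.mean(axis=1), axis=0).div(ref.std(axis=1, ddof=1), axis=0)

    kind = pd.Series(
        ["mRNA"] * cfg.n_mrna + ["miRNA"] * cfg.n_mirna, index=features, name="kind"
    )
    matrix = OmicsMatrix(df, kind)
    table = SampleTable(meta, list(cfg.stages))
    return matrix, table


def evaluate_recovery(
    stage_means: pd.DataFrame,
    cfg: SimConfig,
    drivers: list[str] | None = None,
) -> dict:
    """Recovery metrics of the planted module.

    AUROC of the final-stage mean local score for planted-module
    membership; rank of the planted center among all features by that
    score; rank of the center in the driver list (None if absent).
    """
    from sklearn.metrics import roc_auc_score

    final_col = stage_means.columns[-1]
    score = stage_means[final_col].dropna()
    truth = score.index.isin(cfg.module_nodes).astype(int)
    if truth.sum() == 0 or truth.sum() == len(score):
        raise DataModelError("planted module absent from scored features")
    auroc = float(roc_auc_score(truth, score.to_numpy()))
    ranks = score.rank(ascending=False, method="min")
    center_rank = int(ranks.get(cfg.center, len(score)))
    driver_rank = None
    if drivers is not None and cfg.center in drivers:
        driver_rank = drivers.index(cfg.center) + 1
    return {
        "auroc": auroc,
        "center_score_rank": center_rank,
        "center_driver_rank": driver_rank,
    }
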