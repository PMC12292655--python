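"""Directed local DNB (DND) scoring and candidate selection.

Each feature x is scored per sample on its *downstream* local module: x
plus its out-neighbors in the retained reference network (first order), and
their out-neighbors (second order).  The score

    Is(x) = sED_in * sPCC_in / sPCC_out

combines the three DNB conditions: sED_in is the mean absolute z-deviation
(vs reference mean/sd) of the center and first-order nodes; sPCC_in the
mean |sPCC| on center->first-order edges; sPCC_out the mean |sPCC| on
first-to-second-order boundary edges (floored at a small constant when no
boundary edge exists).  A feature whose module variance rises, whose
intra-module correlation strengthens, and whose boundary decorrelates —
the tipping-point signature — scores high.  Candidates are features whose
stage-mean score rises strictly along the stage order and ends in the top
fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataModelError, SampleTable, SSNRecord
from .ssn import ReferenceStats

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 1e-6


@dataclass
class LocalModule:
    """Downstream local module of a center node."""

    center: str
    first_order: list[str]
    second_order: list[str]

    def __post_init__(self) -> None:
        assert self.center not in self.first_order
        inner = set(self.first_order) | {self.center}
        assert not inner & set(self.second_order)


def local_module(center: str, graph: nx.DiGraph) -> LocalModule:
    """First- and second-order downstream neighborhoods of ``center``.

    ``graph`` is the retained reference network (directed).  Second order
    excludes the center and first-order nodes.
    """
    if center not in graph:
        return LocalModule(center, [], [])
    first = sorted(set(graph.successors(center)) - {center})
    second: set[str] = set()
    for u in first:
        second |= set(graph.successors(u))
    second -= set(first) | {center}
    return LocalModule(center, first, sorted(second))


def sed_in(module: LocalModule, sample_values: pd.Series, ref: ReferenceStats) -> float:
    """Mean |value - ref_mean| / ref_sd over the center and first-order nodes."""
    nodes = [module.center] + module.first_order
    stats_ = ref.feature_stats.loc[nodes]
    if (stats_["ref_sd"] <= 0).any():
        raise DataModelError("sed_in needs positive reference sd for all module nodes")
    dev = (sample_values.loc[nodes] - stats_["ref_mean"]).abs() / stats_["ref_sd"]
    return float(dev.mean())


def spcc_in(module: LocalModule, ssn_edges: pd.DataFrame) -> float:
    """Mean |sPCC| over center -> first-order edges present in the SSN."""
    sel = ssn_edges[
        (ssn_edges["source"] == module.center) & ssn_edges["target"].isin(module.first_order)
    ]
    if sel.empty:
        logger.debug("no center->first-order SSN edges for %s; spcc_in = 0", module.center)
        return 0.0
    return float(sel["spcc"].abs().mean())


def spcc_out(module: LocalModule, ssn_edges: pd.DataFrame, floor: float = DEFAULT_FLOOR) -> float:
    """Mean |sPCC| over first-to-second-order boundary edges, floored."""
    sel = ssn_edges[
        ssn_edges["source"].isin(module.first_order) & ssn_edges["target"].isin(module.second_order)
    ]
    if sel.empty:
        return floor
    return max(float(sel["spcc"].abs().mean()), floor)


def local_score(
    center: str,
    ssn: SSNRecord,
    ref: ReferenceStats,
    sample_values: pd.Series,
    floor: float = DEFAULT_FLOOR,
    graph: nx.DiGraph | None = None,
) -> float:
    """Is(x) = sED_in * sPCC_in / sPCC_out for one center and one sample.

    A center with no downstream neighbors in the retained network scores 0
    — it cannot drive anything by construction.
    """
    g = ref.retained_graph if graph is None else graph
    module = local_module(center, g)
    if not module.first_order:
        return 0.0
    s_ed = sed_in(module, sample_values, ref)
    s_in = spcc_in(module, ssn.edges)
    s_out = spcc_out(module, ssn.edges, floor)
    return s_ed * s_in / s_out


@dataclass
class ScoreTable:
    """Per-(feature, sample) local scores plus aggregates and flags."""

    per_sample: pd.DataFrame  # feature_id, sample_id, stage, sed_in, spcc_in, spcc_out, score
    stage_means: pd.DataFrame  # index feature_id, one column per stage
    per_feature: pd.DataFrame  # feature_id, candidate, driver, out_degree
    sample_scores: pd.DataFrame = field(default_factory=pd.DataFrame)  # sample_id, subject_id, stage, dnd_score
    candidates: list[str] = field(default_factory=list)
    drivers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.per_sample):
            assert (self.per_sample["score"] >= 0).all(), "Is must be >= 0"


def score_all(
    ssn_records: list[SSNRecord],
    ref: ReferenceStats,
    matrix_data: pd.DataFrame,
    samples: SampleTable,
    floor: float | None = None,
) -> pd.DataFrame:
    """Local scores of every network feature in every sample (long format).

    Centers are the nodes of the retained reference network; features with
    no downstream neighbors score 0 throughout.  ``floor`` replaces an
    empty or vanishing boundary term; the default (None) uses the median
    |sPCC| of the sample's SSN, i.e. an absent boundary counts as
    null-level decorrelation, keeping scores comparable across features.
    A fixed tiny floor would rank every boundary-less module above every
    genuine one.
    """
    g = ref.retained_graph
    centers = sorted(g.nodes)
    modules = {c: local_module(c, g) for c in centers}
    stage_of = dict(zip(samples.table["sample_id"], samples.table["stage"]))

    # index SSN edge tables once per sample for vectorized lookups
    rows = []
    for rec in ssn_records:
        e = rec.edges
        abs_spcc = e["spcc"].abs().to_numpy()
        if floor is None:
            sample_floor = float(np.median(abs_spcc)) if len(abs_spcc) else DEFAULT_FLOOR
            sample_floor = max(sample_floor, DEFAULT_FLOOR)
        else:
            sample_floor = floor
        by_source: dict[str, list[int]] = {}
        for i, s in enumerate(e["source"]):
            by_source.setdefault(s, []).append(i)
        tgt = e["target"].to_numpy()
        vals = matrix_data[rec.sample_id]
        zdev = ((vals - ref.feature_stats["ref_mean"]) / ref.feature_stats["ref_sd"]).abs()
        for c in centers:
            m = modules[c]
            if not m.first_order:
                rows.append((c, rec.sample_id, stage_of.get(rec.sample_id), 0.0, 0.0, 0.0, 0.0))
                continue
            s_ed = float(zdev.loc[[c] + m.first_order].mean())
            first = set(m.first_order)
            second = set(m.second_order)
            idx_c = by_source.get(c, [])
            in_vals = [abs_spcc[i] for i in idx_c if tgt[i] in first]
            s_in = float(np.mean(in_vals)) if in_vals else 0.0
            out_vals = [
                abs_spcc[i]
                for u in m.first_order
                for i in by_source.get(u, [])
                if tgt[i] in second
            ]
            s_out = max(float(np.mean(out_vals)), sample_floor) if out_vals else sample_floor
            rows.append((c, rec.sample_id, stage_of.get(rec.sample_id), s_ed, s_in, s_out, s_ed * s_in / s_out))
    return pd.DataFrame(
        rows, columns=["feature_id", "sample_id", "stage", "sed_in", "spcc_in", "spcc_out", "score"]
    )


def sample_score(local_scores: pd.Series, top_k: int | None = None) -> float:
    """DND score of one sample: mean of its per-feature local scores
    (mRNA and miRNA pooled), optionally restricted to the top-k scores."""
    if local_scores.empty:
        raise DataModelError("sample_score needs >= 1 scored feature")
    if top_k is not None:
        local_scores = local_scores.nlargest(top_k)
    return float(local_scores.mean())


def stage_mean_scores(per_sample: pd.DataFrame, stage_order: list[str]) -> pd.DataFrame:
    """Per-feature arithmetic mean of per-sample scores within each stage."""
    pivot = per_sample.pivot_table(index="feature_id", columns="stage", values="score", aggfunc="mean")
    return pivot.reindex(columns=[s for s in stage_order if s in pivot.columns])


def select_candidates(
    stage_means: pd.DataFrame,
    stage_order: list[str],
    top_fraction: float = 0.10,
    require_monotone: bool = True,
) -> list[str]:
    """DND candidates: stage-mean score strictly increasing along the stage
    order and final-stage mean within the top ``top_fraction`` of features."""
    cols = [s for s in stage_order if s in stage_means.columns]
    if len(cols) < 2:
        raise DataModelError("candidate selection needs >= 2 stages with scores")
    sm = stage_means[cols].dropna()
    monotone = pd.Series(True, index=sm.index)
    if require_monotone:
        for a, b in zip(cols[:-1], cols[1:]):
            monotone &= sm[b] > sm[a]
    final = sm[cols[-1]]
    cutoff = final.quantile(1 - top_fraction)
    top = final >= cutoff
    return sorted(sm.index[monotone & top])


@dataclass
class TrendStats:
    paired_t: pd.DataFrame  # stage_a, stage_b, t, p, n_subjects
    uptrend_subjects: int
    n_complete_subjects: int
    adjusted_icc: float


def stage_trend_stats(
    sample_scores: pd.DataFrame, samples: SampleTable
) -> TrendStats:
    """Subject-level trend statistics of the per-sample DND score.

    ``sample_scores`` needs columns sample_id, dnd_score.  Per adjacent
    stage pair a paired t-test is run on subject-matched mean scores; the
    uptrend count is the number of subjects (complete in all stages) whose
    per-stage means increase strictly; the adjusted ICC is the
    between-subject variance fraction of the residuals after removing stage
    means — near zero when stage, not subject identity, drives the score.
    """
    merged = sample_scores.drop(columns=["subject_id", "stage"], errors="ignore").merge(
        samples.table[["sample_id", "subject_id", "stage"]], on="sample_id"
    )
    per = merged.groupby(["subject_id", "stage"])["dnd_score"].mean().unstack("stage")
    stages = [s for s in samples.stage_order if s in per.columns]
    per = per[stages]

    t_rows = []
    for a, b in zip(stages[:-1], stages[1:]):
        pair = per[[a, b]].dropna()
        if len(pair) < 3:
            logger.warning("paired t-test %s vs %s skipped: < 3 complete subjects", a, b)
            t_rows.append({"stage_a": a, "stage_b": b, "t": np.nan, "p": np.nan, "n_subjects": len(pair)})
            continue
        t, p = stats.ttest_rel(pair[b], pair[a])
        t_rows.append({"stage_a": a, "stage_b": b, "t": float(t), "p": float(p), "n_subjects": len(pair)})

    complete = per.dropna()
    up = int((complete.diff(axis=1).iloc[:, 1:] > 0).all(axis=1).sum()) if len(stages) > 1 else 0

    # adjusted ICC: one-way between-subject variance fraction on residuals
    resid = merged.copy()
    resid["r"] = resid["dnd_score"] - resid.groupby("stage")["dnd_score"].transform("mean")
    groups = [g["r"].to_numpy() for _, g in resid.groupby("subject_id") if len(g) > 0]
    icc = _icc_oneway(groups)
    return TrendStats(pd.DataFrame(t_rows), up, len(complete), icc)


def _icc_oneway(groups: list[np.ndarray]) -> float:
    """ICC(1) from a one-way random-effects ANOVA with unequal group sizes
    (k0 correction for the expected mean squares)."""
    groups = [g for g in groups if len(g) > 0]
    a = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    n_total = ns.sum()
    if a < 2 or n_total <= a:
        return float("nan")
    grand = np.concatenate(groups).mean()
    ssb = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (a - 1)
    msw = ssw / (n_total - a)
    k0 = (n_total - (ns**2).sum() / n_total) / (a - 1)
    if msw == 0:
        return 1.0
    return float((msb - msw) / (msb + (k0 - 1) * msw))


# ---------------------------------------------------------------------------
# oracles kept alongside the implementation for cross-checking


def local_score_undirected(
    center: str,
    ssn: SSNRecord,
    ref: ReferenceStats,
    sample_values: pd.Series,
    floor: float = DEFAULT_FLOOR,
) -> float:
    """Classic (undirected) local DNB score: the module is the center plus
    *all* network neighbors, and boundary edges run between first- and
    second-order nodes regardless of direction.  On a fully symmetrized
    digraph this coincides with the directed score."""
    g = ref.retained_graph.to_undirected()
    if center not in g:
        return 0.0
    first = sorted(set(g.neighbors(center)) - {center})
    if not first:
        return 0.0
    second: set[str] = set()
    for u in first:
        second |= set(g.neighbors(u))
    second -= set(first) | {center}
    stats_ = ref.feature_stats.loc[[center] + first]
    dev = (sample_values.loc[[center] + first] - stats_["ref_mean"]).abs() / stats_["ref_sd"]
    s_ed = float(dev.mean())
    e = ssn.edges
    und = e.assign(
        a=e[["source", "target"]].min(axis=1),
        b=e[["source", "target"]].max(axis=1),
        abs_spcc=e["spcc"].abs(),
    )
    und = und.groupby(["a", "b"], as_index=False)["abs_spcc"].mean()
    in_mask = ((und["a"] == center) & und["b"].isin(first)) | (
        (und["b"] == center) & und["a"].isin(first)
    )
    s_in = float(und.loc[in_mask, "abs_spcc"].mean()) if in_mask.any() else 0.0
    firsts, seconds = set(first), second
    out_mask = (und["a"].isin(firsts) & und["b"].isin(seconds)) | (
        und["b"].isin(firsts) & und["a"].isin(seconds)
    )
    s_out = max(float(und.loc[out_mask, "abs_spcc"].mean()), floor) if out_mask.any() else floor
    return s_ed * s_in / s_out
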