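"""Reference network and single-sample network (SSN) construction.

The reference network is the background network with each edge weighted by
the Pearson correlation of its endpoints over the reference-stage samples;
edges whose correlation is significant (t-test on r) are retained.  The SSN
of a sample quantifies, per retained edge, how much that sample perturbs
the reference correlation:

    sPCC(x, y) = PCC_{n+1}(x, y) - PCC_n(x, y)

where PCC_{n+1} adds the sample to the n reference samples.  Under the
null that the sample comes from the reference distribution, the
perturbation statistic

    z = sPCC / ((1 - PCC_n^2) / (n - 1))

is approximately standard normal, giving a per-edge two-sided p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataModelError, DirectedNet, OmicsMatrix, SampleTable, SSNRecord

logger = logging.getLogger(__name__)


def pearson(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DataModelError("pearson needs equal-length vectors, n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise DataModelError("pearson undefined for a constant vector")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p for H0: rho = 0 via t = r*sqrt((n-2)/(1-r^2))."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def spcc(ref_x, ref_y, new_x: float, new_y: float) -> float:
    """Correlation perturbation of one edge by one added sample."""
    r_n = pearson(ref_x, ref_y)
    r_n1 = pearson(np.append(ref_x, new_x), np.append(ref_y, new_y))
    return r_n1 - r_n


def ssn_edge_test(spcc_value: float, pcc_ref: float, n_ref: int) -> tuple[float, float]:
    """Perturbation z-statistic and two-sided normal p for one SSN edge."""
    if abs(pcc_ref) >= 1.0:
        raise DataModelError("degenerate edge: |pcc_ref| = 1")
    z = spcc_value / ((1 - pcc_ref**2) / (n_ref - 1))
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


@dataclass
class ReferenceStats:
    """Reference-cohort statistics on the background network.

    ``edges`` rows cover every background edge with both endpoints measured;
    ``retained`` marks edges significant at ``edge_alpha``.  ``feature_stats``
    holds per-feature reference mean and sd (used by the deviation term of
    the DND score).
    """

    edges: pd.DataFrame  # source, target, pcc_ref, p_ref, retained
    feature_stats: pd.DataFrame  # index feature_id: ref_mean, ref_sd
    n_ref: int
    reference_samples: list[str]
    edge_alpha: float
    retained_graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def retained_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["retained"]]


def build_reference(
    matrix: OmicsMatrix,
    samples: SampleTable,
    net: DirectedNet,
    edge_alpha: float = 0.05,
    min_ref: int = 5,
) -> ReferenceStats:
    """Compute reference correlations for every measurable background edge.

    Background edges with an endpoint missing from the matrix, or with a
    constant endpoint over reference samples, are skipped with a log entry.
    """
    ref_ids = samples.reference_samples
    if len(ref_ids) < min_ref:
        raise DataModelError(f"only {len(ref_ids)} reference samples; need >= {min_ref}")
    ref = matrix.data.loc[:, ref_ids]
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    n = len(ref_ids)

    measured = set(matrix.feature_ids)
    rows = []
    n_skipped = 0
    for u, v in net.edges:
        if u == v:
            continue
        if u not in measured or v not in measured:
            n_skipped += 1
            continue
        if sd[u] == 0 or sd[v] == 0:
            logger.warning("edge %s->%s skipped: constant endpoint in reference", u, v)
            continue
        r = pearson(ref.loc[u].to_numpy(), ref.loc[v].to_numpy())
        p = pearson_p(r, n)
        rows.append({"source": u, "target": v, "pcc_ref": r, "p_ref": p, "retained": p <= edge_alpha})
    if n_skipped:
        logger.info("%d background edges skipped (endpoint not measured)", n_skipped)
    edges = pd.DataFrame(rows, columns=["source", "target", "pcc_ref", "p_ref", "retained"])
    g = nx.DiGraph()
    g.add_nodes_from(sorted(measured & set(net.graph.nodes)))
    for _, row in edges[edges["retained"]].iterrows():
        g.add_edge(row["source"], row["target"], pcc_ref=row["pcc_ref"])
    feature_stats = pd.DataFrame({"ref_mean": mean, "ref_sd": sd})
    return ReferenceStats(edges, feature_stats, n, list(ref_ids), edge_alpha, g)


def _edge_sums(ref_vals: np.ndarray, si: np.ndarray, ti: np.ndarray):
    """Per-edge sufficient statistics over the reference columns."""
    s1 = ref_vals.sum(axis=1)
    s2 = (ref_vals**2).sum(axis=1)
    sxy = (ref_vals[si] * ref_vals[ti]).sum(axis=1)
    return s1, s2, sxy


def _pcc_from_sums(n, sx, sy, sxx, syy, sxy):
    num = n * sxy - sx * sy
    den = np.sqrt(np.maximum(n * sxx - sx**2, 0.0) * np.maximum(n * syy - sy**2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.clip(r, -1.0, 1.0)


def build_ssn(
    matrix: OmicsMatrix,
    samples: SampleTable,
    ref: ReferenceStats,
    ssn_alpha: float = 0.05,
    leave_self_out: bool = True,
    include_reference_samples: bool = True,
) -> list[SSNRecord]:
    """Build the SSN of every sample over the retained reference edges.

    For a non-reference sample d, sPCC compares the correlation over the
    reference cohort with and without d appended.  A reference-stage sample
    would perturb its own reference, so it is scored against the
    leave-self-out reference (n-1 samples); adding it back recovers exactly
    the full-cohort correlation, keeping the statistic well defined.
    The retained edge set (topology) always comes from the full reference.
    """
    edges = ref.retained_edges.reset_index(drop=True)
    feats = matrix.feature_ids
    fidx = {f: i for i, f in enumerate(feats)}
    si = edges["source"].map(fidx).to_numpy(dtype=int)
    ti = edges["target"].map(fidx).to_numpy(dtype=int)
    ref_vals = matrix.data.loc[:, ref.reference_samples].to_numpy(dtype=float)
    n = ref.n_ref
    s1, s2, sxy = _edge_sums(ref_vals, si, ti)
    pcc_full = _pcc_from_sums(n, s1[si], s1[ti], s2[si], s2[ti], sxy)

    ref_pos = {sid: j for j, sid in enumerate(ref.reference_samples)}
    records: list[SSNRecord] = []
    for sid in samples.sample_ids:
        v = matrix.data[sid].to_numpy(dtype=float)
        vx, vy = v[si], v[ti]
        if sid in ref_pos:
            if not include_reference_samples:
                continue
            if not leave_self_out:
                logger.warning("sample %s is in the reference set; scoring without leave-self-out", sid)
            j = ref_pos[sid]
            col = ref_vals[:, j]
            s1_o = s1 - col
            s2_o = s2 - col**2
            sxy_o = sxy - col[si] * col[ti]
            pcc_n = _pcc_from_sums(n - 1, s1_o[si], s1_o[ti], s2_o[si], s2_o[ti], sxy_o)
            pcc_n1 = pcc_full  # leave-one-out plus the sample = full cohort
            n_eff = n - 1
        else:
            pcc_n = pcc_full
            s1_1 = s1[si] + vx, s1[ti] + vy
            s2_1 = s2[si] + vx**2, s2[ti] + vy**2
            pcc_n1 = _pcc_from_sums(n + 1, s1_1[0], s1_1[1], s2_1[0], s2_1[1], sxy + vx * vy)
            n_eff = n
        sp = pcc_n1 - pcc_n
        denom = (1 - pcc_n**2) / (n_eff - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(denom > 0, sp / denom, 0.0)
        p = 2 * stats.norm.sf(np.abs(z))
        rec = pd.DataFrame(
            {
                "source": edges["source"],
                "target": edges["target"],
                "pcc_ref": pcc_n,
                "spcc": sp,
                "z": z,
                "p": p,
                "significant": p <= ssn_alpha,
            }
        )
        records.append(SSNRecord(sample_id=sid, edges=rec, n_ref=n_eff))
    return records
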