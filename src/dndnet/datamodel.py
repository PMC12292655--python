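"""Core data containers and TSV I/O for the DND pipeline.

All pipeline stages exchange four containers: an expression matrix
(:class:`OmicsMatrix`), sample annotations (:class:`SampleTable`), the
directed background regulatory network (:class:`DirectedNet`) and the
per-sample perturbation network (:class:`SSNRecord`).  Everything is read
and written as plain tab-delimited text so that runs are diffable and
byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("mRNA", "miRNA")

#: float formatting used for every written table — 6 significant digits,
#: fixed so that re-runs produce byte-identical outputs.
FLOAT_FMT = "%.6g"


class DataModelError(ValueError):
    """Raised on invalid inputs (duplicate ids, missing values, ...)."""


@dataclass
class OmicsMatrix:
    """Normalized expression values (features x samples), mRNA and miRNA pooled.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id with sample ids as columns.
    feature_kind:
        Series mapping each feature id to ``"mRNA"`` or ``"miRNA"``.
    """

    data: pd.DataFrame
    feature_kind: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate feature ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate sample ids: {dups}")
        if self.data.isna().any().any():
            raise DataModelError("expression matrix contains missing values")
        self.feature_kind = self.feature_kind.reindex(self.data.index)
        if self.feature_kind.isna().any():
            missing = self.feature_kind.index[self.feature_kind.isna()].tolist()
            raise DataModelError(f"features without a kind assignment: {missing}")
        bad = set(self.feature_kind.unique()) - set(FEATURE_KINDS)
        if bad:
            raise DataModelError(f"unknown feature kinds: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[:, list(sample_ids)], self.feature_kind)

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        keep = [f for f in feature_ids if f in self.data.index]
        return OmicsMatrix(self.data.loc[keep], self.feature_kind.loc[keep])

    def drop_zero_variance(self) -> "OmicsMatrix":
        """Drop features that are constant across all samples (logged)."""
        sd = self.data.std(axis=1, ddof=1)
        dropped = self.data.index[(sd == 0) | sd.isna()].tolist()
        if dropped:
            logger.warning("dropping %d zero-variance features: %s", len(dropped), dropped)
            keep = self.data.index.difference(dropped, sort=False)
            return OmicsMatrix(self.data.loc[keep], self.feature_kind.loc[keep])
        return self


@dataclass
class SampleTable:
    """Sample annotations: subject, ordinal stage, optional phenotypes.

    ``stage_order`` declares the pseudo-temporal ordering (e.g. photo-protected
    < peri-lesion < lesion); the first entry is the reference stage used to
    build the reference correlation network.
    """

    table: pd.DataFrame  # columns: sample_id, subject_id, stage, [phenotypes...]
    stage_order: list[str]
    min_reference: int = 5

    REQUIRED = ("sample_id", "subject_id", "stage")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise DataModelError(f"sample table missing required column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise DataModelError("duplicate sample ids in sample table")
        extra = set(self.table["stage"]) - set(self.stage_order)
        if extra:
            raise DataModelError(f"stage labels outside declared order: {sorted(extra)}")
        present = [s for s in self.stage_order if (self.table["stage"] == s).any()]
        if len(present) < 2:
            raise DataModelError("fewer than 2 stages present")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def reference_stage(self) -> str:
        return self.stage_order[0]

    def samples_in_stage(self, stage: str) -> list[str]:
        return self.table.loc[self.table["stage"] == stage, "sample_id"].tolist()

    @property
    def reference_samples(self) -> list[str]:
        return self.samples_in_stage(self.reference_stage)

    @property
    def phenotype_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.REQUIRED]

    def validate_against(self, matrix: OmicsMatrix) -> None:
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise DataModelError(f"samples absent from expression matrix: {sorted(missing)}")
        if len(self.reference_samples) < self.min_reference:
            raise DataModelError(
                f"reference stage {self.reference_stage!r} has "
                f"{len(self.reference_samples)} samples; need >= {self.min_reference}"
            )

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        keep = set(sample_ids)
        sub = self.table[self.table["sample_id"].isin(keep)].copy()
        return SampleTable(sub, self.stage_order, self.min_reference)


@dataclass
class DirectedNet:
    """Directed background regulatory graph (TF→target, miRNA→mRNA edges)."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], nodes: Iterable[str] = ()) -> "DirectedNet":
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for e in edges:
            src, tgt = e[0], e[1]
            tag = e[2] if len(e) > 2 else ""
            g.add_edge(src, tgt, tag=tag)
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def self_loops(self) -> list[str]:
        return sorted(u for u, v in nx.selfloop_edges(self.graph))

    def out_neighbors(self, node: str) -> set[str]:
        return set(self.graph.successors(node)) if node in self.graph else set()

    def in_neighbors(self, node: str) -> set[str]:
        return set(self.graph.predecessors(node)) if node in self.graph else set()

    def out_degree(self, node: str) -> int:
        return self.graph.out_degree(node) if node in self.graph else 0

    def subgraph(self, nodes: Iterable[str]) -> "DirectedNet":
        return DirectedNet(self.graph.subgraph(nodes).copy())


@dataclass
class SSNRecord:
    """One sample's single-sample perturbation network.

    ``edges`` columns: source, target, pcc_ref, spcc, z, p, significant.
    """

    sample_id: str
    edges: pd.DataFrame
    n_ref: int

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) and ((e["pcc_ref"].abs() > 1 + 1e-12).any() or (e["spcc"].abs() > 2 + 1e-12).any()):
            raise DataModelError("pcc_ref outside [-1,1] or spcc outside [-2,2]")

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]


# ---------------------------------------------------------------------------
# loaders


def load_expression(
    path: str | Path,
    kind_map_path: str | Path,
    samples_as_rows: bool = False,
    zscale: bool = False,
) -> OmicsMatrix:
    """Load a tab-delimited expression matrix plus a feature-kind map.

    The matrix has feature ids in the first column and sample ids in the
    header (``samples_as_rows=True`` transposes).  The kind map is a
    two-column TSV ``feature_id<TAB>kind`` with kind in {mRNA, miRNA}.
    Zero-variance features are dropped with a warning; duplicate ids and
    missing values are hard errors.  ``zscale`` optionally z-scores each
    feature across all samples (the orientation of upstream normalisation
    of mRNA vs miRNA panels is otherwise taken as given).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    kinds = pd.read_csv(kind_map_path, sep="\t", header=None, names=["feature_id", "kind"])
    kind_series = pd.Series(
        kinds["kind"].values, index=kinds["feature_id"].astype(str), name="kind"
    )
    if kind_series.index.duplicated().any():
        raise DataModelError("duplicate feature ids in kind map")
    m = OmicsMatrix(df, kind_series).drop_zero_variance()
    if zscale:
        z = m.data.sub(m.data.mean(axis=1), axis=0).div(m.data.std(axis=1, ddof=1), axis=0)
        m = OmicsMatrix(z, m.feature_kind)
    return m


def load_samples(path: str | Path, stage_order: Sequence[str], min_reference: int = 5) -> SampleTable:
    """Load sample metadata (sample_id, subject_id, stage, phenotype columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return SampleTable(df, list(stage_order), min_reference)


def load_network(path: str | Path) -> DirectedNet:
    """Load a directed edge list (source<TAB>target[<TAB>tag], header optional).

    Duplicate directed edges are collapsed (count logged); self-loops are
    kept but reported.  A line with fewer than two fields is an error that
    names the offending line number.
    """
    edges: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("source", "src", "from"):
                continue
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise DataModelError(f"malformed network line {lineno}: {line!r}")
            tag = parts[2] if len(parts) > 2 else ""
            edges.append((parts[0].strip(), parts[1].strip(), tag))
    seen: dict[tuple[str, str], str] = {}
    n_dup = 0
    for src, tgt, tag in edges:
        if (src, tgt) in seen:
            n_dup += 1
        else:
            seen[(src, tgt)] = tag
    if n_dup:
        logger.warning("deduplicated %d duplicate directed edges", n_dup)
    net = DirectedNet.from_edges([(s, t, tag) for (s, t), tag in seen.items()])
    if net.self_loops:
        logger.warning("network contains self-loops on: %s", net.self_loops)
    return net


def load_whitelist(path: str | Path) -> set[str]:
    """Load a feature whitelist, one id per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# writers


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: FLOAT_FMT % v if pd.notna(v) else "NA")
    return out


def write_expression(matrix: OmicsMatrix, path: str | Path, kind_map_path: str | Path | None = None) -> None:
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="feature_id")
    if kind_map_path is not None:
        matrix.feature_kind.to_csv(kind_map_path, sep="\t", header=False)


def write_samples(samples: SampleTable, path: str | Path) -> None:
    _fmt(samples.table).to_csv(path, sep="\t", index=False)


def write_network(net: DirectedNet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\ttag\n")
        for u, v in net.edges:
            tag = net.graph.edges[u, v].get("tag", "")
            fh.write(f"{u}\t{v}\t{tag}\n")


def write_outputs(score_table, ssn_records: Sequence[SSNRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write the pipeline products: long score table, per-sample SSNs,
    candidate and driver lists.  Row order is (feature id, sample id) so
    re-runs on identical inputs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    long = score_table.per_sample.sort_values(["feature_id", "sample_id"]).reset_index(drop=True)
    paths["scores"] = out / "scores.tsv"
    _fmt(long).to_csv(paths["scores"], sep="\t", index=False)

    stage = score_table.stage_means.sort_index()
    paths["stage_means"] = out / "stage_means.tsv"
    stage_out = stage.copy()
    stage_out.insert(0, "feature_id", stage_out.index)
    _fmt(stage_out).to_csv(paths["stage_means"], sep="\t", index=False)

    feats = score_table.per_feature.sort_values("feature_id").reset_index(drop=True)
    paths["features"] = out / "features.tsv"
    _fmt(feats).to_csv(paths["features"], sep="\t", index=False)

    paths["candidates"] = out / "candidates.txt"
    with open(paths["candidates"], "w") as fh:
        fh.write("feature_id\n")
        for f in sorted(score_table.candidates):
            fh.write(f + "\n")

    paths["drivers"] = out / "drivers.txt"
    with open(paths["drivers"], "w") as fh:
        fh.write("feature_id\n")
        for f in score_table.drivers:  # already ranked
            fh.write(f + "\n")

    ssn_dir = out / "ssn"
    ssn_dir.mkdir(exist_ok=True)
    for rec in sorted(ssn_records, key=lambda r: r.sample_id):
        edges = rec.edges.sort_values(["source", "target"]).reset_index(drop=True)
        p = ssn_dir / f"{rec.sample_id}.tsv"
        _fmt(edges).to_csv(p, sep="\t", index=False)
        paths[f"ssn/{rec.sample_id}"] = p
    return paths
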