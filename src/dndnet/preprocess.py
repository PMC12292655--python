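"""Cohort QC and feature filtering.

Outlier handling follows a two-detector design: per-stage 95% confidence
ellipses in (PC1, PC2) space, and pooled Mahalanobis distances in a
k-dimensional PC space; any subject owning a flagged sample is removed
wholesale (policy configurable).  Group separation along the stage axis is
quantified with PERMANOVA on Euclidean distances.  Dimensionality is
reduced with a three-part filter: phenotype correlation, an external
whitelist (e.g. tissue-specific databases), and stage ANOVA — a feature is
kept if any part selects it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

from .datamodel import DataModelError, OmicsMatrix, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class OutlierReport:
    """Per-sample outlier flags and the subjects they condemn."""

    per_sample: pd.DataFrame  # sample_id, subject_id, stage, pc1..pck, mahalanobis_d2, ellipse_flag, mahalanobis_flag
    excluded_subjects: list[str]
    confidence: float
    k: int


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    exhaustive: bool


@dataclass
class FeatureFilterResult:
    table: pd.DataFrame  # feature_id, in_pheno_set, in_whitelist_set, in_anova_set, selected

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "feature_id"].tolist()


def pca_scores(matrix: OmicsMatrix, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the feature-standardized matrix via SVD.

    Samples are observations; features are z-scored first.  Component signs
    follow the convention that the largest-magnitude loading is positive,
    so repeated runs agree.  Returns (scores, explained variance ratio).
    """
    x = matrix.values.T  # samples x features
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise DataModelError("zero-variance feature passed to PCA")
    xz = (x - mu) / sd
    u, s, vt = np.linalg.svd(xz, full_matrices=False)
    k = min(n_components, len(s))
    # fix signs: largest-magnitude loading per component positive
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    evr = (s**2) / (s**2).sum()
    cols = [f"pc{j + 1}" for j in range(k)]
    return pd.DataFrame(scores, index=matrix.sample_ids, columns=cols), evr[:k]


def pca_ellipse_flags(
    matrix: OmicsMatrix, samples: SampleTable, confidence: float = 0.95
) -> pd.DataFrame:
    """Flag samples outside their own stage's (PC1, PC2) confidence ellipse.

    The ellipse is the chi-square(2) contour of the per-stage mean and
    covariance of the first two PC scores: a sample is flagged when its
    squared Mahalanobis distance to its stage centroid exceeds the
    chi-square quantile at ``confidence``.
    """
    if not 0 < confidence < 1:
        raise DataModelError("confidence must be in (0,1)")
    scores, _ = pca_scores(matrix, n_components=2)
    thr = stats.chi2.ppf(confidence, df=2)
    rows = []
    for stage in samples.stage_order:
        sids = samples.samples_in_stage(stage)
        if not sids:
            continue
        if len(sids) < 3:
            raise DataModelError(f"stage {stage!r} has < 3 samples; ellipse undefined")
        pts = scores.loc[sids, ["pc1", "pc2"]].to_numpy()
        mu = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        cov_inv = np.linalg.pinv(cov)
        d2 = np.einsum("ij,jk,ik->i", pts - mu, cov_inv, pts - mu)
        for sid, dd in zip(sids, d2):
            rows.append({"sample_id": sid, "stage": stage, "ellipse_d2": dd, "ellipse_flag": dd > thr})
    out = pd.DataFrame(rows).set_index("sample_id").loc[samples.sample_ids].reset_index()
    return pd.concat([scores.loc[samples.sample_ids].reset_index(drop=True), out], axis=1)


def mahalanobis_flags(
    pc_scores: pd.DataFrame, confidence: float = 0.95, k: int | None = None
) -> pd.DataFrame:
    """Flag samples whose pooled Mahalanobis d^2 in k-dim PC space exceeds
    the chi-square(k) quantile at ``confidence``."""
    cols = [c for c in pc_scores.columns if c.startswith("pc")]
    if k is None:
        k = len(cols)
    if k > len(cols):
        raise DataModelError(f"k={k} exceeds available components ({len(cols)})")
    pts = pc_scores[cols[:k]].to_numpy()
    mu = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov) < k or np.linalg.det(cov) <= 0:
        raise DataModelError("singular covariance in PC space; reduce k")
    cov_inv = np.linalg.inv(cov)
    d2 = np.einsum("ij,jk,ik->i", pts - mu, cov_inv, pts - mu)
    thr = stats.chi2.ppf(confidence, df=k)
    return pd.DataFrame(
        {"sample_id": pc_scores.index, "mahalanobis_d2": d2, "mahalanobis_flag": d2 > thr}
    ).reset_index(drop=True)


def default_k(evr: np.ndarray, target: float = 0.90, cap: int = 10) -> int:
    """Number of components explaining ``target`` variance, capped."""
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, target) + 1)
    return max(1, min(k, cap, len(evr)))


def outlier_report(
    matrix: OmicsMatrix,
    samples: SampleTable,
    confidence: float = 0.95,
    k: int | None = None,
    policy: str = "union",
) -> OutlierReport:
    """Run both outlier detectors and apply the subject-exclusion policy.

    ``policy`` in {union, intersection, ellipse-only, mahalanobis-only}
    decides which flags condemn a subject; all samples of a condemned
    subject are excluded.
    """
    n_pc = min(10, len(samples.sample_ids) - 1, len(matrix.feature_ids))
    scores, evr = pca_scores(matrix, n_components=n_pc)
    if k is None:
        k = default_k(evr)
    ell = pca_ellipse_flags(matrix, samples, confidence)
    mah = mahalanobis_flags(scores, confidence, k)
    per = ell.merge(mah, on="sample_id").merge(
        samples.table[["sample_id", "subject_id"]], on="sample_id"
    )
    if policy == "union":
        per["flagged"] = per["ellipse_flag"] | per["mahalanobis_flag"]
    elif policy == "intersection":
        per["flagged"] = per["ellipse_flag"] & per["mahalanobis_flag"]
    elif policy == "ellipse-only":
        per["flagged"] = per["ellipse_flag"]
    elif policy == "mahalanobis-only":
        per["flagged"] = per["mahalanobis_flag"]
    else:
        raise DataModelError(f"unknown outlier policy {policy!r}")
    excluded = sorted(per.loc[per["flagged"], "subject_id"].unique())
    return OutlierReport(per_sample=per, excluded_subjects=excluded, confidence=confidence, k=k)


def exclude_subjects(report: OutlierReport, samples: SampleTable) -> SampleTable:
    """Remove every sample belonging to a flagged subject."""
    keep = samples.table.loc[
        ~samples.table["subject_id"].isin(report.excluded_subjects), "sample_id"
    ]
    if keep.empty:
        raise DataModelError("outlier exclusion removed every sample")
    sub = samples.subset(keep)
    present = {s for s in sub.stage_order if sub.samples_in_stage(s)}
    if len(present) < 2:
        raise DataModelError("outlier exclusion left fewer than 2 populated stages")
    return sub


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from a squared-distance matrix and group labels.

    SS_total = sum_{i<j} d2_ij / n; SS_within = sum over groups of the
    analogous within-group quantity; F = (SS_between/(a-1)) / (SS_within/(n-a)).
    """
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ng = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    a = len(groups)
    ss_between = ss_total - ss_within
    if ss_within <= 0:  # perfect within-group agreement
        f = math.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _n_distinct_labelings(labels: np.ndarray) -> int:
    n = len(labels)
    counts = pd.Series(labels).value_counts()
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova(
    matrix_or_points,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """PERMANOVA on Euclidean distances with a permutation null.

    Accepts an :class:`OmicsMatrix` (samples are the observations) or a
    plain (n_samples x n_dims) array.  When the number of distinct label
    arrangements is <= ``n_perm`` the null is enumerated exhaustively
    (p = count/total over all arrangements, observed included); otherwise
    ``n_perm`` random shuffles are drawn and the add-one estimator
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) is used.
    """
    if isinstance(matrix_or_points, OmicsMatrix):
        pts = matrix_or_points.values.T
    else:
        pts = np.asarray(matrix_or_points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
    labels = np.asarray(groups)
    if len(labels) != pts.shape[0]:
        raise DataModelError("group labels do not match number of samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DataModelError("PERMANOVA needs >= 2 groups")
    if counts.min() < 2:
        raise DataModelError("every group needs >= 2 samples")
    d2 = squareform(pdist(pts, metric="euclidean") ** 2)
    f_obs, r2 = _permanova_f(d2, labels)

    n_total = _n_distinct_labelings(labels)
    if n_total <= n_perm:
        count = 0
        for perm in multiset_permutations(list(labels)):
            f_p, _ = _permanova_f(d2, np.asarray(perm))
            if f_p >= f_obs - 1e-12:
                count += 1
        p = count / n_total
        return PermanovaResult(f_obs, r2, p, n_total, True)
    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        f_p, _ = _permanova_f(d2, lab)
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, False)


def permanova_centroid_f(pts: np.ndarray, labels: np.ndarray) -> float:
    """Centroid-based pseudo-F on raw Euclidean coordinates.

    Independent formulation used as an internal cross-check: for Euclidean
    data the distance-matrix sums of squares equal explicit deviations
    from group centroids.
    """
    pts = np.asarray(pts, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = np.asarray(labels)
    grand = pts.mean(axis=0)
    ss_total = ((pts - grand) ** 2).sum()
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        sub = pts[labels == g]
        ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
    a, n = len(groups), len(labels)
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


# ---------------------------------------------------------------------------
# three-part feature filter


def feature_filter(
    matrix: OmicsMatrix,
    samples: SampleTable,
    whitelist: set[str] | None = None,
    pcc_alpha: float = 0.05,
    anova_alpha: float = 0.05,
    bh_correct: bool = False,
) -> FeatureFilterResult:
    """Three-part feature filter; a feature is selected by the union.

    Part 1: Pearson correlation of each feature with any phenotype column
    (t-test on r, p < pcc_alpha).  Part 2: membership in an external
    whitelist.  Part 3: one-way ANOVA of expression across stages
    (p < anova_alpha).  ``bh_correct`` applies Benjamini-Hochberg within
    parts 1 and 3 before thresholding.
    """
    whitelist = whitelist or set()
    feats = matrix.feature_ids
    x = matrix.data.loc[:, samples.sample_ids].to_numpy()

    # part 1 — phenotype correlation
    pheno_cols = samples.phenotype_columns
    in_pheno = np.zeros(len(feats), dtype=bool)
    if pheno_cols:
        pvals = np.ones((len(feats), len(pheno_cols)))
        for j, col in enumerate(pheno_cols):
            y = pd.to_numeric(samples.table[col], errors="coerce").to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 3:
                continue
            yv = y[ok]
            xv = x[:, ok]
            if np.std(yv) == 0:
                continue
            xc = xv - xv.mean(axis=1, keepdims=True)
            yc = yv - yv.mean()
            denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, (xc * yc).sum(axis=1) / denom, 0.0)
            n = ok.sum()
            r = np.clip(r, -0.9999999999, 0.9999999999)
            t = r * np.sqrt((n - 2) / (1 - r**2))
            pvals[:, j] = 2 * stats.t.sf(np.abs(t), df=n - 2)
        if bh_correct:
            flat = pvals.ravel()
            flat = multipletests(flat, method="fdr_bh")[1]
            pvals = flat.reshape(pvals.shape)
        in_pheno = (pvals < pcc_alpha).any(axis=1)
    else:
        logger.warning("no phenotype columns; phenotype filter part skipped")

    # part 2 — whitelist
    in_wl = np.array([f in whitelist for f in feats])

    # part 3 — stage ANOVA
    stage_groups = [
        matrix.data.loc[:, samples.samples_in_stage(s)].to_numpy()
        for s in samples.stage_order
        if len(samples.samples_in_stage(s)) >= 2
    ]
    if len(stage_groups) >= 2:
        f_stat, p_anova = stats.f_oneway(*[g.T for g in stage_groups])
        p_anova = np.nan_to_num(p_anova, nan=1.0)
        if bh_correct:
            p_anova = multipletests(p_anova, method="fdr_bh")[1]
        in_anova = p_anova < anova_alpha
    else:
        in_anova = np.zeros(len(feats), dtype=bool)

    table = pd.DataFrame(
        {
            "feature_id": feats,
            "in_pheno_set": in_pheno,
            "in_whitelist_set": in_wl,
            "in_anova_set": in_anova,
        }
    )
    table["selected"] = table[["in_pheno_set", "in_whitelist_set", "in_anova_set"]].any(axis=1)
    return FeatureFilterResult(table)
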