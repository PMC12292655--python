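"""Outlier detection, PERMANOVA and the three-part feature filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dndnet.datamodel import DataModelError, OmicsMatrix, SampleTable
from dndnet.preprocess import (
    exclude_subjects,
    feature_filter,
    mahalanobis_flags,
    outlier_report,
    pca_ellipse_flags,
    pca_scores,
    permanova,
    permanova_centroid_f,
)


def _cohort(n_per_stage=10, n_feat=20, seed=0, stages=("ctrl", "peri", "lesion")):
    rng = np.random.default_rng(seed)
    sids, rows = [], []
    for st in stages:
        for i in range(n_per_stage):
            sid = f"{st}_{i}"
            sids.append(sid)
            rows.append({"sample_id": sid, "subject_id": f"p{i}", "stage": st})
    feats = [f"g{i}" for i in range(n_feat)]
    data = pd.DataFrame(rng.normal(size=(n_feat, len(sids))), index=feats, columns=sids)
    m = OmicsMatrix(data, pd.Series("mRNA", index=feats))
    s = SampleTable(pd.DataFrame(rows), list(stages), min_reference=3)
    return m, s


# ---------------------------------------------------------------- outliers


def test_sample_at_stage_centroid_never_flagged():
    m, s = _cohort()
    rep = pca_ellipse_flags(m, s, 0.95)
    # construct a pseudo-sample at the centroid: the closest real sample to
    # the centroid must have d2 below the threshold whenever any sample is inside
    for stage in s.stage_order:
        sub = rep[rep["stage"] == stage]
        assert not sub.loc[sub["ellipse_d2"].idxmin(), "ellipse_flag"]


def test_ellipse_flag_rate_matches_chi2_coverage():
    # large multivariate-normal null: flagged fraction ~ 5% (+-2 binomial SE)
    m, s = _cohort(n_per_stage=500, n_feat=10, seed=1)
    rep = pca_ellipse_flags(m, s, 0.95)
    rate = rep["ellipse_flag"].mean()
    se = np.sqrt(0.05 * 0.95 / 1500)
    assert abs(rate - 0.05) < 2 * se + 0.005


def test_gross_outlier_flagged():
    m, s = _cohort(seed=2)
    data = m.data.copy()
    data.iloc[:, 0] += 50.0  # displace one sample far along every feature
    m2 = OmicsMatrix(data, m.feature_kind)
    rep = pca_ellipse_flags(m2, s, 0.95)
    assert rep.loc[rep["sample_id"] == m2.sample_ids[0], "ellipse_flag"].item()


def test_mahalanobis_closed_form_identity_cov():
    # identity covariance, k=2: a point at (3, 0) has d2 = 9 > chi2_2(0.95) = 5.991
    rng = np.random.default_rng(3)
    pts = rng.standard_normal((4000, 2))
    pts = (pts - pts.mean(0)) / pts.std(0, ddof=1)
    pts[0] = [3.0, 0.0]
    scores = pd.DataFrame(pts, columns=["pc1", "pc2"],
                          index=[f"s{i}" for i in range(len(pts))])
    rep = mahalanobis_flags(scores, 0.95, k=2)
    d2 = rep.loc[0, "mahalanobis_d2"]
    assert d2 == pytest.approx(9.0, rel=0.05)
    assert rep.loc[0, "mahalanobis_flag"]
    assert stats.chi2.ppf(0.95, 2) == pytest.approx(5.991, abs=1e-3)


def test_mahalanobis_singular_covariance_errors():
    scores = pd.DataFrame({"pc1": [1.0, 1.0, 1.0], "pc2": [2.0, 2.0, 2.0]},
                          index=["a", "b", "c"])
    with pytest.raises(DataModelError, match="singular"):
        mahalanobis_flags(scores, 0.95, k=2)


def test_exclude_subjects_removes_whole_subject():
    m, s = _cohort()
    rep = outlier_report(m, s, confidence=0.95)
    if not rep.excluded_subjects:  # force a flag
        data = m.data.copy()
        data.iloc[:, 0] += 100.0
        rep = outlier_report(OmicsMatrix(data, m.feature_kind), s, confidence=0.95)
    kept = exclude_subjects(rep, s)
    for subj in rep.excluded_subjects:
        assert subj not in set(kept.table["subject_id"])
    # no flags => identity
    rep.excluded_subjects = []
    assert exclude_subjects(rep, s).sample_ids == s.sample_ids


def test_pca_sign_convention_is_deterministic():
    m, _ = _cohort(seed=5)
    s1, _ = pca_scores(m, 3)
    s2, _ = pca_scores(m, 3)
    pd.testing.assert_frame_equal(s1, s2)


# ---------------------------------------------------------------- PERMANOVA


def test_permanova_exhaustive_toy_p_one_third():
    # 1-D [0,0,1,1] with groups AABB: only AABB and BBAA reach the maximal F
    res = permanova(np.array([0.0, 0.0, 1.0, 1.0]), ["A", "A", "B", "B"], n_perm=999)
    assert res.exhaustive and res.n_perm == 6
    assert res.p == pytest.approx(1 / 3)


def test_permanova_identical_groups_r2_zero():
    pts = np.array([[0.0], [1.0], [0.0], [1.0]])
    res = permanova(pts, ["A", "A", "B", "B"], n_perm=999)
    assert res.R2 == pytest.approx(0.0, abs=1e-12)


def test_permanova_matches_centroid_formulation():
    # distance-matrix pseudo-F equals explicit centroid sums of squares
    rng = np.random.default_rng(7)
    for _ in range(5):
        pts = rng.normal(size=(10, 3))
        labels = np.array(["A"] * 4 + ["B"] * 3 + ["C"] * 3)
        res = permanova(pts, labels, n_perm=9, seed=0)
        assert res.pseudo_F == pytest.approx(permanova_centroid_f(pts, labels), rel=1e-9)


def test_permanova_matches_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import permanova as sk_permanova
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(12, 4))
    labels = ["A"] * 6 + ["B"] * 6
    dm = skbio.DistanceMatrix(
        np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)),
        ids=[str(i) for i in range(12)],
    )
    expected = sk_permanova(dm, grouping=labels, permutations=99)
    res = permanova(pts, labels, n_perm=99, seed=0)
    assert res.pseudo_F == pytest.approx(float(expected["test statistic"]), rel=1e-9)


def test_permanova_null_p_uniform():
    # under exchangeable groups the permutation p-value is ~U(0,1)
    rng = np.random.default_rng(13)
    pvals = []
    for _ in range(300):
        pts = rng.normal(size=(12, 2))
        labels = np.array(["A"] * 6 + ["B"] * 6)
        pvals.append(permanova(pts, labels, n_perm=99,
                               seed=int(rng.integers(2**31))).p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_permanova_group_of_one_errors():
    with pytest.raises(DataModelError):
        permanova(np.array([0.0, 1.0, 2.0]), ["A", "B", "B"], n_perm=9)


# ---------------------------------------------------------------- filter


def test_feature_equal_to_phenotype_in_part1():
    m, s = _cohort(n_per_stage=8)
    pheno = m.data.loc["g0"].to_numpy()
    tab = s.table.copy()
    tab["spot"] = pheno
    s2 = SampleTable(tab, s.stage_order, min_reference=3)
    res = feature_filter(m, s2, whitelist=set())
    row = res.table.set_index("feature_id").loc["g0"]
    assert row["in_pheno_set"] and row["selected"]


def test_null_feature_anova_exclusion_rate():
    # identical stage means: exclusion from the ANOVA set with prob ~ 1 - alpha
    m, s = _cohort(n_per_stage=40, n_feat=400, seed=17)
    res = feature_filter(m, s, whitelist=set(), anova_alpha=0.05)
    rate = res.table["in_anova_set"].mean()
    se = np.sqrt(0.05 * 0.95 / 400)
    assert abs(rate - 0.05) < 3 * se + 0.01


def test_empty_whitelist_no_phenotype_selected_equals_anova():
    m, s = _cohort(n_per_stage=6)
    res = feature_filter(m, s, whitelist=set())
    assert (res.table["selected"] == res.table["in_anova_set"]).all()


def test_filter_monotone_in_whitelist():
    m, s = _cohort(n_per_stage=6, seed=19)
    small = feature_filter(m, s, whitelist={"g0"})
    big = feature_filter(m, s, whitelist={"g0", "g1", "g2"})
    assert set(small.selected) <= set(big.selected)
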