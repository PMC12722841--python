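"""ROI aggregation and group-level statistics for regional qT1.

The statistical battery of a small case-control qT1 study:

* per-ROI mean qT1 extraction over valid voxels,
* case-control general linear model (OLS of regional qT1 on a group
  indicator adjusting for age and sex), with Cohen's d derived from the
  group t-statistic,
* within-patient covariate sensitivity (age, sex, antipsychotic dose),
* Benjamini-Hochberg FDR applied separately per hemisphere family,
* inter-protocol Pearson correlation per ROI, and
* hemisphere-level summaries of across-subject SD.

Sex is coded as an indicator for female (column ``sex_F``), so a negative
sex coefficient reads "females lower". All tests are two-sided; times are
ms throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .t1fit import T1Map

logger = logging.getLogger(__name__)

__all__ = [
    "extract_roi_means",
    "fit_group_glm",
    "group_analysis",
    "cohens_d_from_t",
    "cohens_d_se",
    "bh_fdr",
    "interprotocol_correlation",
    "hemisphere_sd_summary",
    "covariate_analysis",
]

ROI_TABLE_COLUMNS = [
    "subject_id", "roi_id", "roi_name", "hemisphere", "protocol",
    "mean_qt1", "voxel_count",
]


def extract_roi_means(
    t1map: T1Map,
    labels: np.ndarray,
    roi_catalog: dict[int, tuple[str, str]],
    subject_id: str,
    protocol: str | None = None,
) -> pd.DataFrame:
    """Per-ROI arithmetic mean of valid T1 voxels for one subject.

    ROIs whose every voxel is invalid are omitted (with a warning) rather
    than emitted as NaN rows, so downstream models never see them.
    """
    if labels.shape != t1map.t1.shape:
        raise ValueError("label volume grid does not match the T1 map")
    present = set(np.unique(labels)) - {0}
    missing = present - set(roi_catalog)
    if missing:
        raise ValueError(f"label ids missing from catalog: {sorted(missing)}")
    protocol = protocol or t1map.protocol
    rows = []
    for rid in sorted(present):
        sel = (labels == rid) & t1map.valid
        n = int(sel.sum())
        if n == 0:
            logger.warning(
                "ROI %d (%s) has no valid voxels for %s; omitted",
                rid, roi_catalog[rid][0], subject_id,
            )
            continue
        name, hemi = roi_catalog[rid]
        rows.append((subject_id, rid, name, hemi, protocol, float(t1map.t1[sel].mean()), n))
    return pd.DataFrame(rows, columns=ROI_TABLE_COLUMNS)


def cohens_d_from_t(t_stat: float, n1: int, n2: int) -> float:
    """Standardized mean difference from a two-group (adjusted) t-statistic:
    d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 subjects per group")
    return float(t_stat) * np.sqrt(1.0 / n1 + 1.0 / n2)


def cohens_d_se(d: float, n1: int, n2: int) -> float:
    """Approximate standard error of Cohen's d:
    SE = sqrt((n1+n2)/(n1*n2) + d^2 / (2 (n1+n2)))."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 subjects per group")
    return float(np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))))


def _design(cov: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Build the design matrix and fail loudly on rank deficiency, naming
    the offending column (e.g. a single-sex sample)."""
    X = sm.add_constant(cov[columns], has_constant="add")
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        for col in columns:
            if np.ptp(cov[col].to_numpy(dtype=float)) == 0:
                raise ValueError(f"design matrix is rank deficient: column '{col}' is constant")
            rest = [c for c in X.columns if c != col]
            if np.linalg.matrix_rank(X[rest].to_numpy(dtype=float)) == np.linalg.matrix_rank(arr):
                raise ValueError(f"design matrix is rank deficient: column '{col}' is collinear")
        raise ValueError("design matrix is rank deficient")
    return X


def _prep_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    cov = covariates.copy()
    cov["group_ssd"] = (cov["group"] == "SSD").astype(float)
    cov["sex_F"] = (cov["sex"] == "F").astype(float)
    return cov


def fit_group_glm(table: pd.DataFrame, covariates: pd.DataFrame, roi_id: int) -> dict:
    """Case-control GLM for one ROI: OLS of mean qT1 on group (SSD = 1),
    age, and sex (female = 1); returns the group contrast with its SE,
    t on n - 4 df, two-sided p, and Cohen's d with its SE.
    """
    sub = table[table["roi_id"] == roi_id].merge(
        _prep_covariates(covariates), on="subject_id", validate="one_to_one"
    )
    n_ssd = int((sub["group"] == "SSD").sum())
    n_hc = int((sub["group"] == "HC").sum())
    if n_ssd < 2 or n_hc < 2:
        raise ValueError(f"ROI {roi_id}: both groups need >=2 subjects")
    X = _design(sub, ["group_ssd", "age", "sex_F"])
    fit = sm.OLS(sub["mean_qt1"].to_numpy(), X).fit()
    t = float(fit.tvalues["group_ssd"])
    d = cohens_d_from_t(t, n_ssd, n_hc)
    raw_diff = float(
        sub.loc[sub["group"] == "SSD", "mean_qt1"].mean()
        - sub.loc[sub["group"] == "HC", "mean_qt1"].mean()
    )
    row = {
        "roi_id": roi_id,
        "roi_name": sub["roi_name"].iloc[0],
        "hemisphere": sub["hemisphere"].iloc[0],
        "group_coef": float(fit.params["group_ssd"]),
        "coef_se": float(fit.bse["group_ssd"]),
        "t_stat": t,
        "p_raw": float(fit.pvalues["group_ssd"]),
        "raw_diff": raw_diff,
        "cohens_d": d,
        "d_se": cohens_d_se(d, n_ssd, n_hc),
        "n_ssd": n_ssd,
        "n_hc": n_hc,
    }
    return row


def group_analysis(table: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Run the case-control GLM over every ROI in ``table`` and apply
    hemisphere-wise BH-FDR to the group p-values."""
    rows = [fit_group_glm(table, covariates, rid) for rid in sorted(table["roi_id"].unique())]
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy(), groups=out["hemisphere"].to_numpy())
    return out


def bh_fdr(p_values, groups=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, computed independently
    within each family given by ``groups`` (e.g. hemisphere)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    if groups is None:
        groups = np.zeros(p.shape, dtype=int)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = groups == g
        out[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return out


def interprotocol_correlation(
    table_a: pd.DataFrame, table_b: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Across-subject correlation of regional qT1 between two protocols.

    For each ROI present in both tables, correlate the paired subject
    values (Pearson by default, Spearman optionally), with hemisphere-wise
    BH-FDR on the two-sided p-values.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    merged = table_a.merge(
        table_b, on=["subject_id", "roi_id", "roi_name", "hemisphere"],
        suffixes=("_a", "_b"), validate="one_to_one",
    )
    rows = []
    for rid, grp in merged.groupby("roi_id"):
        if len(grp) < 3:
            raise ValueError(f"ROI {rid}: need >=3 paired subjects, got {len(grp)}")
        x = grp["mean_qt1_a"].to_numpy()
        y = grp["mean_qt1_b"].to_numpy()
        if method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            r, p = stats.spearmanr(x, y)
        rows.append((rid, grp["roi_name"].iloc[0], grp["hemisphere"].iloc[0],
                     float(r), float(p), len(grp)))
    out = pd.DataFrame(rows, columns=["roi_id", "roi_name", "hemisphere", "r", "p_raw", "n"])
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy(), groups=out["hemisphere"].to_numpy())
    return out


def hemisphere_sd_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean across-subject SD per (protocol, hemisphere).

    For each ROI the sample SD of mean qT1 across subjects is computed,
    then averaged over the ROIs of each hemisphere — the hemisphere-level
    variability summary used to compare protocol precision.
    """
    counts = table.groupby(["protocol", "roi_id"])["subject_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need >=2 subjects per ROI for an SD summary")
    per_roi = (
        table.groupby(["protocol", "hemisphere", "roi_id"])["mean_qt1"]
        .std(ddof=1)
        .reset_index(name="sd")
    )
    return (
        per_roi.groupby(["protocol", "hemisphere"])["sd"]
        .mean()
        .reset_index(name="mean_roi_sd")
    )


def covariate_analysis(table: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Covariate sensitivity within the patient (SSD) group.

    Per ROI, OLS of mean qT1 on age, sex (female = 1) and CPZe jointly;
    each covariate's coefficient is therefore tested while accounting for
    the other two. BH-FDR is applied per covariate within each hemisphere.
    """
    cov = _prep_covariates(covariates)
    cov = cov[cov["group"] == "SSD"]
    if cov["cpze"].isna().any():
        missing = cov.loc[cov["cpze"].isna(), "subject_id"].tolist()
        raise ValueError(f"CPZe missing for SSD subjects: {missing}")
    ssd_table = table[table["subject_id"].isin(cov["subject_id"])]
    rows = []
    for rid, grp in ssd_table.groupby("roi_id"):
        sub = grp.merge(cov, on="subject_id", validate="one_to_one")
        X = _design(sub, ["age", "sex_F", "cpze"])
        fit = sm.OLS(sub["mean_qt1"].to_numpy(), X).fit()
        for term, label in (("age", "age"), ("sex_F", "sex"), ("cpze", "cpze")):
            rows.append({
                "roi_id": rid,
                "roi_name": sub["roi_name"].iloc[0],
                "hemisphere": sub["hemisphere"].iloc[0],
                "covariate": label,
                "coef": float(fit.params[term]),
                "se": float(fit.bse[term]),
                "p_raw": float(fit.pvalues[term]),
                "n": len(sub),
            })
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for cov_name in out["covariate"].unique():
        sel = out["covariate"] == cov_name
        out.loc[sel, "p_fdr"] = bh_fdr(
            out.loc[sel, "p_raw"].to_numpy(), groups=out.loc[sel, "hemisphere"].to_numpy()
        )
    return out
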