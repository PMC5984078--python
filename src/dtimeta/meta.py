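"""Random-effects inverse-variance meta-analysis of per-site records.

Pools one estimate per site (Cohen's d or a regression beta) with weights
``w* = 1/(se^2 + tau^2)``.  The between-site variance ``tau^2`` is estimated
by restricted maximum likelihood (default) or the DerSimonian–Laird moment
estimator::

    w   = 1/se^2                     (fixed-effect weights)
    Q   = sum w * (y - y_FE)^2       (Cochran heterogeneity)
    DL: tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))

Heterogeneity is summarized as ``I^2 = max(0, 100*(Q-(k-1))/Q)`` (0 for a
single study).  p-values are two-sided normal on z = pooled/se; a
Knapp–Hartung small-sample adjustment (t reference, scaled s.e.) is available
but off by default.  Cross-ROI secondary analyses — the paired per-sex
effect-vector comparison, the effect-size vs sqrt(voxel-count) correlation
and site-attribute subgroup pooling — live here too, as they operate on the
pooled per-ROI tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .registry import ROI_REGISTRY, VOXEL_COUNTS

_Z975 = sps.norm.ppf(0.975)


@dataclass
class MetaResult:
    """Pooled random-effects result for one ROI x metric x model."""

    pooled: float
    se: float
    z: float
    p: float
    tau2: float
    Q: float
    I2: float
    k: int
    ci_low: float
    ci_high: float
    method: str = "reml"
    roi: str | None = None
    metric: str | None = None
    model_id: str | None = None
    significant: bool | None = None


@dataclass
class ComparisonResult:
    """A scalar two-sample/paired comparison over per-ROI effect vectors."""

    description: str
    statistic: float
    df: int
    p: float
    n: int


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m (e.g. 0.05/25 = 0.002)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def dersimonian_laird_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """DerSimonian–Laird tau^2 and Cochran Q from estimates y, variances v."""
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    k = len(y)
    if k <= 1:
        return 0.0, Q
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    return float(tau2), Q


def reml_tau2(y: np.ndarray, v: np.ndarray, tol: float = 1e-10) -> float:
    """Restricted-maximum-likelihood tau^2 (bounded scalar maximization)."""
    k = len(y)
    if k <= 1:
        return 0.0

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        mu = np.sum(wi * y) / np.sum(wi)
        return 0.5 * (
            np.sum(np.log(v + tau2))
            + np.log(np.sum(wi))
            + np.sum(wi * (y - mu) ** 2)
        )

    upper = max(1e-6, 10.0 * (float(np.var(y)) + float(np.max(v))))
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, upper), method="bounded",
        options={"xatol": tol},
    )
    tau2 = float(res.x)
    # accept the boundary when it is at least as good
    if neg_restricted_ll(0.0) <= res.fun:
        tau2 = 0.0
    return tau2


def random_effects_meta(
    estimates,
    ses,
    method: str = "reml",
    knapp_hartung: bool = False,
) -> MetaResult:
    """Pool (estimate, se) records across sites under a random-effects model.

    ``method`` selects the tau^2 estimator: ``"dl"`` (closed-form
    DerSimonian–Laird) or ``"reml"`` (iterated restricted likelihood, default).
    k = 1 degenerates to the single study with tau^2 = Q = I^2 = 0.
    """
    y = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    if y.size == 0:
        raise ValueError("cannot meta-analyze zero records")
    if y.shape != se.shape:
        raise ValueError("estimates and ses must have equal length")
    bad = np.where(~(se > 0))[0]
    if bad.size:
        raise ValueError(f"non-positive standard error in records {bad.tolist()}")
    k = y.size
    v = se**2
    if k == 1:
        pooled, se_pooled = float(y[0]), float(se[0])
        tau2, Q = 0.0, 0.0
    else:
        tau2_dl, Q = dersimonian_laird_tau2(y, v)
        if method == "dl":
            tau2 = tau2_dl
        elif method == "reml":
            tau2 = reml_tau2(y, v)
        else:
            raise ValueError(f"unknown tau^2 method {method!r}")
        w_star = 1.0 / (v + tau2)
        pooled = float(np.sum(w_star * y) / np.sum(w_star))
        se_pooled = float(np.sum(w_star) ** -0.5)
    I2 = 0.0 if k <= 1 or Q <= 0 else max(0.0, 100.0 * (Q - (k - 1)) / Q)
    if knapp_hartung and k > 1:
        w_star = 1.0 / (v + tau2)
        q = float(np.sum(w_star * (y - pooled) ** 2) / (k - 1))
        se_pooled = float(np.sqrt(max(q, 0.0)) * se_pooled) if q > 0 else se_pooled
        z = pooled / se_pooled
        p = float(2.0 * sps.t.sf(abs(z), k - 1))
        half = float(sps.t.ppf(0.975, k - 1) * se_pooled)
    else:
        z = pooled / se_pooled
        p = float(2.0 * sps.norm.sf(abs(z)))
        half = float(_Z975 * se_pooled)
    return MetaResult(
        pooled=pooled, se=se_pooled, z=float(z), p=p, tau2=float(tau2),
        Q=float(Q), I2=float(I2), k=int(k),
        ci_low=pooled - half, ci_high=pooled + half, method=method,
    )


def meta_table(
    site_records: pd.DataFrame,
    model_id: str,
    method: str = "reml",
    alpha: float = 0.05,
    m: int = 25,
    knapp_hartung: bool = False,
    min_k: int = 1,
) -> pd.DataFrame:
    """Pool one model family's site records into a per-ROI report table.

    Output mirrors the published report shape: one row per ROI with pooled
    estimate, s.e., z, p, CI, tau^2, Q, I^2, number of contributing sites,
    total sample sizes, skeleton voxel count and a significance flag at the
    Bonferroni threshold alpha/m.  Rows sort by |estimate| descending, ties
    broken by ROI name.
    """
    recs = site_records[site_records["model_id"] == model_id]
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    for roi, grp in recs.groupby("roi"):
        if len(grp) < min_k:
            continue
        res = random_effects_meta(
            grp["estimate"], grp["se"], method=method, knapp_hartung=knapp_hartung
        )
        rows.append(
            dict(
                roi=roi, model_id=model_id,
                metric=grp["metric"].iloc[0],
                estimate=res.pooled, se=res.se, z=res.z, p=res.p,
                ci_low=res.ci_low, ci_high=res.ci_high,
                tau2=res.tau2, Q=res.Q, I2=res.I2, k=res.k,
                n1_total=int(grp["n1"].sum()),
                n2_total=int(np.nansum(grp["n2"])) if grp["n2"].notna().any() else 0,
                n_voxels=VOXEL_COUNTS.get(roi, np.nan),
                significant=res.p < threshold,
            )
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    # |estimate| descending, stable tie-break on ROI name
    table = table.sort_values(
        ["estimate", "roi"],
        key=lambda s: -s.abs() if s.name == "estimate" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def forest_data(
    site_records: pd.DataFrame, model_id: str, roi: str, method: str = "reml"
) -> pd.DataFrame:
    """Per-site forest-plot rows (site, d, ci, weight) for one ROI x model."""
    grp = site_records[
        (site_records["model_id"] == model_id) & (site_records["roi"] == roi)
    ]
    if grp.empty:
        raise ValueError(f"no records for model {model_id!r}, roi {roi!r}")
    res = random_effects_meta(grp["estimate"], grp["se"], method=method)
    w = 1.0 / (grp["se"] ** 2 + res.tau2)
    out = pd.DataFrame(
        {
            "site_id": grp["site_id"].to_numpy(),
            "estimate": grp["estimate"].to_numpy(),
            "ci_low": (grp["estimate"] - _Z975 * grp["se"]).to_numpy(),
            "ci_high": (grp["estimate"] + _Z975 * grp["se"]).to_numpy(),
            "weight": (w / w.sum()).to_numpy(),
        }
    )
    pooled_row = pd.DataFrame(
        {
            "site_id": ["POOLED"], "estimate": [res.pooled],
            "ci_low": [res.ci_low], "ci_high": [res.ci_high], "weight": [1.0],
        }
    )
    return pd.concat([out, pooled_row], ignore_index=True)


def compare_effect_vectors(d_group_a, d_group_b, description: str = "paired effect comparison") -> ComparisonResult:
    """Paired t-test on per-ROI effect-size differences (A minus B)."""
    a = np.asarray(d_group_a, float)
    b = np.asarray(d_group_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if np.allclose(diff, 0.0):
            return ComparisonResult(description, 0.0, a.size - 1, 1.0, a.size)
        raise ValueError("zero-variance nonzero differences; statistic undefined")
    t = diff.mean() / (sd / np.sqrt(a.size))
    df = a.size - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return ComparisonResult(description, float(t), df, p, a.size)


@dataclass
class CorrelationResult:
    """Effect-size vs sqrt(voxel-count) correlation, absolute and signed."""

    r_abs: float
    p_abs: float
    r_signed: float
    p_signed: float
    n: int


def effectsize_voxelcount_correlation(d_per_roi, n_voxels_per_roi) -> CorrelationResult:
    """Pearson correlation between effect size and sqrt(ROI voxel count)."""
    d = np.asarray(d_per_roi, float)
    nv = np.asarray(n_voxels_per_roi, float)
    if d.size < 3 or d.size != nv.size:
        raise ValueError("need >= 3 paired ROIs")
    root_n = np.sqrt(nv)
    if np.isclose(np.var(root_n), 0) or np.isclose(np.var(d), 0):
        raise ValueError("constant input; correlation undefined")
    r_abs, p_abs = sps.pearsonr(np.abs(d), root_n)
    r_sgn, p_sgn = sps.pearsonr(d, root_n)
    return CorrelationResult(float(r_abs), float(p_abs), float(r_sgn), float(p_sgn), d.size)


def group_meta_compare(
    site_records: pd.DataFrame,
    site_groups: dict,
    model_id: str,
    roi: str,
    method: str = "reml",
) -> dict:
    """Pool one ROI's records separately per site group and test the gap.

    ``site_groups`` maps site_id -> group label (e.g. high/low gradient
    directions).  Groups with fewer than 2 contributing sites are skipped
    with a warning.  Returns per-group :class:`MetaResult` plus a normal
    z-test on the difference between the two pooled estimates.
    """
    recs = site_records[
        (site_records["model_id"] == model_id) & (site_records["roi"] == roi)
    ].copy()
    recs["group"] = recs["site_id"].map(site_groups)
    results: dict = {"groups": {}, "difference": None}
    for label, grp in recs.groupby("group"):
        if len(grp) < 2:
            warnings.warn(f"group {label!r} has k={len(grp)} < 2; skipped", stacklevel=2)
            continue
        results["groups"][label] = random_effects_meta(
            grp["estimate"], grp["se"], method=method
        )
    labels = sorted(results["groups"])
    if len(labels) == 2:
        r1, r2 = (results["groups"][label] for label in labels)
        diff = r1.pooled - r2.pooled
        se = np.sqrt(r1.se**2 + r2.se**2)
        z = diff / se
        results["difference"] = ComparisonResult(
            f"{labels[0]} minus {labels[1]} ({model_id}/{roi})",
            float(z), 1, float(2.0 * sps.norm.sf(abs(z))), r1.k + r2.k,
        )
    return results


def meta_moderators(
    site_records: pd.DataFrame,
    model_id: str,
    method: str = "reml",
    alpha: float = 0.05,
    m: int = 25,
) -> pd.DataFrame:
    """Pool moderator regression betas per ROI (report-table shape)."""
    return meta_table(site_records, model_id, method=method, alpha=alpha, m=m)
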