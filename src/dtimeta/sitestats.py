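"""Per-site stage: covariate-adjusted group contrasts and moderator models.

Each site fits, on its own subjects only, ordinary least-squares models of an
ROI outcome on diagnosis plus the standard covariate set {age, sex, age*sex,
age^2, age^2*sex} (age mean-centered within site before squaring, to tame the
age/age^2 collinearity).  The diagnosis t statistic is converted to Cohen's d
(patients minus controls; negative = lower in patients) with the
Hedges–Olkin large-sample conversion::

    d    = t * (n1 + n2) / (sqrt(n1 * n2) * sqrt(df))
    se_d = sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2 - 2)))

Moderator regressions (age at onset, illness duration — with and without age,
duration as percent of lifetime, CPZ dose, symptom scales) run within
patients; subgroup contrasts (smoking, medication class) reuse the group-model
machinery with the subgroup indicator in place of diagnosis.  A site x model
cell is excluded whenever either group has fewer than ``MIN_PER_GROUP = 10``
complete-case subjects.

The module emits one flat interchange table per site (columns ``site_id, roi,
metric, model_id, estimate, se, stat, df, n1, n2``) — the "standardized
output" uploaded to the central meta-analysis stage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .registry import METRICS, MODERATORS, ROI_REGISTRY

log = logging.getLogger("dtimeta.sitestats")

MIN_PER_GROUP = 10

GLOBAL_COVARIATES = {
    "average_fa": "FA_AverageFA",
    "core_fa": "FA_core",
    "periphery_fa": "FA_periphery",
}

INTERACTIONS = ("dx_by_age", "dx_by_sex")

SITE_TABLE_COLUMNS = (
    "site_id", "roi", "metric", "model_id",
    "estimate", "se", "stat", "df", "n1", "n2",
)


class InsufficientGroupError(ValueError):
    """A required subject group fell below the inclusion cutoff."""


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate structure of one group model.

    The base set {age, sex, age*sex, age^2, age^2*sex} is included by
    default; ``sex_terms=False`` drops the sex columns for sex-stratified
    fits (where sex is constant).  ``global_covariate`` optionally adds one
    whole-skeleton FA summary and ``interaction`` one diagnosis interaction
    term.
    """

    model_id: str = "casecontrol"
    global_covariate: str | None = None
    interaction: str | None = None
    sex_terms: bool = True

    def __post_init__(self) -> None:
        if self.global_covariate is not None and self.global_covariate not in GLOBAL_COVARIATES:
            raise ValueError(f"unknown global covariate {self.global_covariate!r}")
        if self.interaction is not None and self.interaction not in INTERACTIONS:
            raise ValueError(f"unknown interaction {self.interaction!r}")
        if self.interaction == "dx_by_sex" and not self.sex_terms:
            raise ValueError("dx_by_sex interaction requires sex terms in the model")


@dataclass
class FitResult:
    """One fitted group model: diagnosis t plus the full coefficient table."""

    t_diag: float
    df_resid: int
    n_patients: int
    n_controls: int
    params: pd.DataFrame  # index: term; columns: coef, se, t
    interaction_term: str | None = None


def _base_terms(df: pd.DataFrame) -> pd.DataFrame:
    """Standard covariate columns, age centered within the supplied rows."""
    age_c = df["age"] - df["age"].mean()
    male = (df["sex"] == "M").astype(float)
    return pd.DataFrame(
        {
            "age_c": age_c,
            "male": male,
            "age_c_x_male": age_c * male,
            "age_c2": age_c**2,
            "age_c2_x_male": age_c**2 * male,
        },
        index=df.index,
    )


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(np.asarray(X, float))
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        _, r = np.linalg.qr(np.asarray(X, float))
        diag = np.abs(np.diag(r))
        bad = [c for c, v in zip(X.columns, diag) if v < 1e-10 * diag.max()]
        raise ValueError(f"rank-deficient design; collinear terms: {bad or list(X.columns)}")


def _design(
    df: pd.DataFrame,
    spec: CovariateSpec,
    indicator: pd.Series,
) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "dx": indicator.astype(float)}, index=df.index)
    base = _base_terms(df)
    if not spec.sex_terms:
        base = base[["age_c", "age_c2"]]
    X = pd.concat([X, base], axis=1)
    if spec.global_covariate:
        X[spec.global_covariate] = df[GLOBAL_COVARIATES[spec.global_covariate]]
    if spec.interaction == "dx_by_age":
        X["dx_x_age_c"] = X["dx"] * X["age_c"]
    elif spec.interaction == "dx_by_sex":
        X["dx_x_male"] = X["dx"] * X["male"]
    return X


def fit_group_model(
    site_df: pd.DataFrame,
    roi: str,
    metric: str,
    spec: CovariateSpec | None = None,
    group_col: str = "diagnosis",
    exposed_level: str = "patient",
    min_per_group: int = MIN_PER_GROUP,
) -> FitResult:
    """OLS of one ROI outcome on a group indicator plus covariates.

    Listwise-deletes rows with missing outcome or covariates, enforces the
    per-group inclusion cutoff, and returns the indicator coefficient's t
    statistic with the residual degrees of freedom and the full coefficient
    table.  Raises :class:`InsufficientGroupError` below the cutoff and
    ``ValueError`` for a rank-deficient design (naming the collinear terms).
    """
    spec = spec or CovariateSpec()
    outcome = f"{metric}_{roi}"
    needed = [outcome, "age", "sex", group_col]
    if spec.global_covariate:
        needed.append(GLOBAL_COVARIATES[spec.global_covariate])
    df = site_df.dropna(subset=[c for c in needed if c in site_df.columns])
    if outcome not in df.columns:
        raise KeyError(f"outcome column {outcome!r} not found")
    indicator = (df[group_col] == exposed_level).astype(float)
    n1 = int(indicator.sum())
    n2 = int(len(df) - n1)
    if n1 < min_per_group or n2 < min_per_group:
        raise InsufficientGroupError(
            f"{roi}/{metric}/{spec.model_id}: group sizes ({n1} {exposed_level}, "
            f"{n2} other) below cutoff {min_per_group}"
        )
    X = _design(df, spec, indicator)
    _check_rank(X)
    res = sm.OLS(np.asarray(df[outcome], float), np.asarray(X, float)).fit()
    params = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "t": res.tvalues},
        index=X.columns,
    )
    interaction_term = None
    if spec.interaction == "dx_by_age":
        interaction_term = "dx_x_age_c"
    elif spec.interaction == "dx_by_sex":
        interaction_term = "dx_x_male"
    return FitResult(
        t_diag=float(params.loc["dx", "t"]),
        df_resid=int(res.df_resid),
        n_patients=n1,
        n_controls=n2,
        params=params,
        interaction_term=interaction_term,
    )


def cohens_d_from_t(t: float, n1: int, n2: int, df: float) -> tuple[float, float]:
    """Convert an adjusted-model t statistic to Cohen's d and its s.e."""
    if not np.isfinite(t):
        raise ValueError("t statistic must be finite")
    if n1 < 2 or n2 < 2 or df <= 0:
        raise ValueError("need n1, n2 >= 2 and df > 0")
    d = t * (n1 + n2) / (np.sqrt(n1 * n2) * np.sqrt(df))
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2 - 2)))
    return float(d), float(se)


def site_effect_sizes(
    site_df: pd.DataFrame,
    metric: str = "FA",
    spec: CovariateSpec | None = None,
    rois=ROI_REGISTRY,
    group_col: str = "diagnosis",
    exposed_level: str = "patient",
    min_per_group: int = MIN_PER_GROUP,
) -> pd.DataFrame:
    """Vectorized effect-size table for every ROI at one site.

    Exact OLS (identical to :func:`fit_group_model` per ROI, tested to 1e-10)
    solved once for all outcome columns sharing the covariate rows.  Returns
    an interchange-schema frame; empty (with a logged reason) when the site
    fails the inclusion cutoff.
    """
    spec = spec or CovariateSpec()
    site_id = site_df["site_id"].iloc[0] if len(site_df) else "?"
    needed = ["age", "sex", group_col]
    if spec.global_covariate:
        needed.append(GLOBAL_COVARIATES[spec.global_covariate])
    df = site_df.dropna(subset=needed)
    indicator = (df[group_col] == exposed_level).astype(float)
    n1_all = int(indicator.sum())
    n2_all = int(len(df) - n1_all)
    if n1_all < min_per_group or n2_all < min_per_group:
        log.info(
            "site %s excluded for model %s: %d exposed / %d reference below cutoff %d",
            site_id, spec.model_id, n1_all, n2_all, min_per_group,
        )
        return pd.DataFrame(columns=list(SITE_TABLE_COLUMNS))
    X = _design(df, spec, indicator)
    _check_rank(X)
    Xa = np.asarray(X, float)
    xtx_inv = np.linalg.inv(Xa.T @ Xa)
    dx_idx = list(X.columns).index("dx")
    p = Xa.shape[1]

    rows = []
    outcome_cols = [f"{metric}_{r}" for r in rois]
    Y = df[outcome_cols].to_numpy(float)
    complete = ~np.isnan(Y).any(axis=0)
    for j, roi in enumerate(rois):
        if complete[j]:
            y = Y[:, j]
            Xj, xtx_inv_j, nj = Xa, xtx_inv, len(df)
            ind_j = indicator
        else:
            mask = ~np.isnan(Y[:, j])
            y = Y[mask, j]
            Xj = Xa[mask]
            ind_j = indicator[mask]
            nj = int(mask.sum())
            if int(ind_j.sum()) < min_per_group or nj - int(ind_j.sum()) < min_per_group:
                log.info("site %s roi %s excluded: below cutoff after deletion", site_id, roi)
                continue
            xtx_inv_j = np.linalg.inv(Xj.T @ Xj)
        beta = xtx_inv_j @ (Xj.T @ y)
        resid = y - Xj @ beta
        dof = nj - p
        if dof <= 0:
            continue
        sigma2 = float(resid @ resid) / dof
        se_b = np.sqrt(sigma2 * xtx_inv_j[dx_idx, dx_idx])
        t = beta[dx_idx] / se_b
        n1 = int(ind_j.sum())
        n2 = nj - n1
        d, se_d = cohens_d_from_t(t, n1, n2, dof)
        rows.append(
            dict(
                site_id=site_id, roi=roi, metric=metric, model_id=spec.model_id,
                estimate=d, se=se_d, stat=float(t), df=dof, n1=n1, n2=n2,
            )
        )
    return pd.DataFrame(rows, columns=list(SITE_TABLE_COLUMNS))


def interaction_records(
    site_df: pd.DataFrame,
    interaction: str,
    metric: str = "FA",
    rois=ROI_REGISTRY,
    min_per_group: int = MIN_PER_GROUP,
) -> pd.DataFrame:
    """Diagnosis-interaction coefficients (beta, se, z) per ROI at one site."""
    spec = CovariateSpec(model_id=f"interaction_{interaction}", interaction=interaction)
    site_id = site_df["site_id"].iloc[0] if len(site_df) else "?"
    rows = []
    for roi in rois:
        try:
            fit = fit_group_model(site_df, roi, metric, spec, min_per_group=min_per_group)
        except InsufficientGroupError as exc:
            log.info("site %s: %s", site_id, exc)
            break  # group sizes identical across ROIs for complete outcomes
        term = fit.params.loc[fit.interaction_term]
        rows.append(
            dict(
                site_id=site_id, roi=roi, metric=metric, model_id=spec.model_id,
                estimate=float(term["coef"]), se=float(term["se"]),
                stat=float(term["coef"] / term["se"]), df=fit.df_resid,
                n1=fit.n_patients, n2=fit.n_controls,
            )
        )
    return pd.DataFrame(rows, columns=list(SITE_TABLE_COLUMNS))


def moderator_regression(
    patients_df: pd.DataFrame,
    roi: str,
    metric: str,
    moderator: str,
    include_age: bool = True,
    min_n: int = MIN_PER_GROUP,
) -> dict:
    """OLS of one ROI outcome on a clinical moderator within patients.

    Covariates: sex, plus the age terms unless ``include_age=False`` (used for
    illness duration, which is collinear with age).  ``duration_pct`` is
    computed on the fly as duration/age.  Returns one interchange-schema row
    with estimate=beta, se, stat=z (beta/se).
    """
    df = patients_df.copy()
    if moderator == "duration_pct" and "duration_pct" not in df.columns:
        df["duration_pct"] = df["duration_years"] / df["age"]
    if moderator not in df.columns:
        raise KeyError(f"unknown moderator {moderator!r}")
    outcome = f"{metric}_{roi}"
    df = df.dropna(subset=[outcome, moderator, "age", "sex"])
    if len(df) < min_n:
        raise InsufficientGroupError(
            f"{roi}/{metric}/{moderator}: {len(df)} patients below cutoff {min_n}"
        )
    mod = df[moderator].astype(float)
    if np.isclose(mod.var(ddof=0), 0.0):
        raise ValueError(f"moderator {moderator!r} is constant")
    X = pd.DataFrame({"const": 1.0, "moderator": mod}, index=df.index)
    base = _base_terms(df)
    X["male"] = base["male"]
    if include_age:
        for c in ("age_c", "age_c_x_male", "age_c2", "age_c2_x_male"):
            X[c] = base[c]
    _check_rank(X)
    res = sm.OLS(np.asarray(df[outcome], float), np.asarray(X, float)).fit()
    beta = float(res.params[1])
    se = float(res.bse[1])
    model_id = f"mod_{moderator}" + ("" if include_age else "_noage")
    return dict(
        site_id=df["site_id"].iloc[0], roi=roi, metric=metric, model_id=model_id,
        estimate=beta, se=se, stat=beta / se, df=int(res.df_resid),
        n1=len(df), n2=np.nan,
    )


def subgroup_effects(
    patients_df: pd.DataFrame,
    grouping: str,
    metric: str = "FA",
    rois=ROI_REGISTRY,
    min_per_group: int = MIN_PER_GROUP,
) -> pd.DataFrame:
    """Cohen's d contrasts between patient subgroups (smoking / medication).

    ``grouping='smoking'`` contrasts smokers vs nonsmokers; the sign is
    exposed-minus-reference with smokers exposed, so lower FA in smokers
    yields d < 0.  ``grouping='medication'``
    runs all pairwise contrasts between medication classes; any contrast with
    a subgroup under the cutoff is skipped with a logged reason, mirroring the
    omission of underpowered antipsychotic contrasts.
    """
    rows = []
    if grouping == "smoking":
        df = patients_df.dropna(subset=["smoker"]).copy()
        df["subgroup"] = np.where(df["smoker"] > 0.5, "smoker", "nonsmoker")
        contrasts = [("smoker", "nonsmoker")]
    elif grouping == "medication":
        df = patients_df[patients_df["med_class"].astype(str) != ""].copy()
        df["subgroup"] = df["med_class"].astype(str)
        classes = sorted(df["subgroup"].unique())
        contrasts = list(itertools.combinations(classes, 2))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    for exposed, reference in contrasts:
        sub = df[df["subgroup"].isin([exposed, reference])]
        model_id = f"subgroup_{grouping}_{exposed}_vs_{reference}"
        spec = CovariateSpec(model_id=model_id)
        out = site_effect_sizes(
            sub, metric=metric, spec=spec, rois=rois,
            group_col="subgroup", exposed_level=exposed,
            min_per_group=min_per_group,
        )
        rows.append(out)
    if not rows:
        return pd.DataFrame(columns=list(SITE_TABLE_COLUMNS))
    return pd.concat(rows, ignore_index=True)


@dataclass
class VarianceComparison:
    """Two-group dispersion comparison for one outcome."""

    sd_exposed: float
    sd_reference: float
    statistic: float
    p: float
    method: str


def variance_comparison(
    values_patients, values_controls, method: str = "f"
) -> VarianceComparison:
    """Compare dispersions between patients and controls.

    ``method='f'`` (default): two-sided variance-ratio F test.
    ``method='levene'``: Brown–Forsythe/Levene test on absolute deviations.
    Both report the two sample s.d.s.  The underlying published comparison is
    described only loosely; both variants are labelled, neither claimed exact.
    """
    x = np.asarray(values_patients, float)
    y = np.asarray(values_controls, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    s1, s2 = x.std(ddof=1), y.std(ddof=1)
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError("zero variance in one of the samples")
    if method == "f":
        F = s1**2 / s2**2
        df1, df2 = len(x) - 1, len(y) - 1
        cdf = sps.f.cdf(F, df1, df2)
        p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
        return VarianceComparison(float(s1), float(s2), float(F), p, "f")
    if method == "levene":
        stat, p = sps.levene(x, y, center="median")
        return VarianceComparison(float(s1), float(s2), float(stat), float(p), "levene")
    raise ValueError(f"unknown method {method!r}")


# -- site-level driver ---------------------------------------------------

DEFAULT_FAMILIES = ("casecontrol", "global_adjusted", "interactions", "moderators", "subgroups")

_MODERATOR_MODELS: list[tuple[str, bool]] = [
    ("age_at_onset", True),
    ("duration_years", True),
    ("duration_years", False),
    ("duration_pct", True),
    ("cpz", True),
    ("panss_total", True),
    ("panss_pos", True),
    ("panss_neg", True),
    ("sans_total", True),
    ("saps_total", True),
]


def run_site(
    site_df: pd.DataFrame,
    families=DEFAULT_FAMILIES,
    metrics=METRICS,
    rois=ROI_REGISTRY,
    min_per_group: int = MIN_PER_GROUP,
) -> pd.DataFrame:
    """Run the requested model families at one site; returns the site table."""
    out = []
    patients = site_df[site_df["diagnosis"] == "patient"]
    for family in families:
        if family == "casecontrol":
            for metric in metrics:
                out.append(
                    site_effect_sizes(
                        site_df, metric=metric, rois=rois,
                        spec=CovariateSpec(model_id=f"casecontrol_{metric}"),
                        min_per_group=min_per_group,
                    )
                )
        elif family == "global_adjusted":
            for cov in GLOBAL_COVARIATES:
                adj_rois = [r for r in rois if r != "AverageFA"] if cov == "average_fa" else rois
                out.append(
                    site_effect_sizes(
                        site_df, metric="FA", rois=adj_rois,
                        spec=CovariateSpec(
                            model_id=f"casecontrol_FA_adj_{cov}", global_covariate=cov
                        ),
                        min_per_group=min_per_group,
                    )
                )
        elif family == "interactions":
            for interaction in INTERACTIONS:
                out.append(
                    interaction_records(site_df, interaction, rois=rois, min_per_group=min_per_group)
                )
        elif family == "moderators":
            rows = []
            for moderator, include_age in _MODERATOR_MODELS:
                for roi in rois:
                    try:
                        rows.append(
                            moderator_regression(
                                patients, roi, "FA", moderator,
                                include_age=include_age, min_n=min_per_group,
                            )
                        )
                    except (InsufficientGroupError, ValueError) as exc:
                        log.info("moderator model skipped: %s", exc)
                        break  # missingness is site-level: no point iterating ROIs
            out.append(pd.DataFrame(rows, columns=list(SITE_TABLE_COLUMNS)))
        elif family == "subgroups":
            for grouping in ("smoking", "medication"):
                out.append(
                    subgroup_effects(patients, grouping, rois=rois, min_per_group=min_per_group)
                )
        else:
            raise ValueError(f"unknown model family {family!r}")
    out = [f for f in out if not f.empty]
    if not out:
        return pd.DataFrame(columns=list(SITE_TABLE_COLUMNS))
    return pd.concat(out, ignore_index=True)
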