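"""Per-site stage: d-from-t conversion, adjusted group models, moderator and
subgroup machinery, inclusion cutoffs and the dispersion comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from dtimeta import GeneratorConfig, generate_multisite
from dtimeta.registry import ROI_REGISTRY
from dtimeta.sitestats import (
    CovariateSpec,
    InsufficientGroupError,
    cohens_d_from_t,
    fit_group_model,
    interaction_records,
    moderator_regression,
    site_effect_sizes,
    subgroup_effects,
    variance_comparison,
)
from dtimeta.synthetic import ClinicalParams

FULL_AVAILABILITY = {
    k: 1.0 for k in ("onset", "cpz", "panss", "sans", "saps", "smoker", "med_class")
}


# -- d-from-t conversion -------------------------------------------------


@pytest.mark.parametrize(
    "t, n1, n2, df, d_exp, se_exp",
    [
        # zero effect: d = 0, se = sqrt((n1+n2)/(n1*n2))
        (0.0, 50, 50, 96, 0.0, 0.2),
        (0.0, 30, 70, 96, 0.0, np.sqrt(100 / 2100)),
        # direct evaluation: d = 2*100/(50*sqrt(96)), se from the two-term formula
        (2.0, 50, 50, 96, 0.4082482904638631, 0.2021146707590877),
    ],
)
def test_cohens_d_from_t_closed_form(t, n1, n2, df, d_exp, se_exp):
    d, se = cohens_d_from_t(t, n1, n2, df)
    assert d == pytest.approx(d_exp, abs=1e-12)
    assert se == pytest.approx(se_exp, abs=1e-12)


def test_cohens_d_shrinks_by_sqrt2_when_groups_double():
    d1, _ = cohens_d_from_t(2.0, 50, 50, 96)
    d2, _ = cohens_d_from_t(2.0, 100, 100, 196)
    assert d1 / d2 == pytest.approx(np.sqrt(2), rel=0.02)


def test_cohens_d_rejects_nonfinite_and_tiny_groups():
    with pytest.raises(ValueError):
        cohens_d_from_t(np.nan, 50, 50, 96)
    with pytest.raises(ValueError):
        cohens_d_from_t(1.0, 1, 50, 47)


def test_conversion_vs_classical_pooled_sd_d(rng):
    """On a two-group model with no covariates the conversion equals the
    classical pooled-s.d. Cohen's d times exactly sqrt((n1+n2)/df)
    (brute-force oracle on random small samples, 1e-10).

    The factor (= sqrt((n1+n2)/(n1+n2-2)) here, ~1+1/n) is a property of the
    consortium d-from-t convention, which divides by sqrt(df) rather than
    sqrt(n1+n2); the two agree asymptotically.
    """
    for _ in range(20):
        n1, n2 = rng.integers(5, 40, 2)
        x = rng.normal(0.3, 1.1, n1)
        y = rng.normal(0.0, 1.1, n2)
        pooled_sd = np.sqrt(
            ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        )
        d_classic = (x.mean() - y.mean()) / pooled_sd
        X = np.column_stack([np.ones(n1 + n2), np.r_[np.ones(n1), np.zeros(n2)]])
        res = sm.OLS(np.r_[x, y], X).fit()
        d, _ = cohens_d_from_t(res.tvalues[1], int(n1), int(n2), res.df_resid)
        factor = np.sqrt((n1 + n2) / res.df_resid)
        assert d == pytest.approx(d_classic * factor, abs=1e-10)


# -- group models --------------------------------------------------------


def test_vectorized_path_matches_statsmodels(small_study):
    site = small_study.subjects.query("site_id == 'site01'")
    table = site_effect_sizes(site).set_index("roi")
    for roi in ("AverageFA", "ACR", "PLIC"):
        fit = fit_group_model(site, roi, "FA")
        d, se = cohens_d_from_t(fit.t_diag, fit.n_patients, fit.n_controls, fit.df_resid)
        assert table.loc[roi, "estimate"] == pytest.approx(d, abs=1e-10)
        assert table.loc[roi, "se"] == pytest.approx(se, abs=1e-10)
        assert table.loc[roi, "stat"] == pytest.approx(fit.t_diag, abs=1e-10)


def test_effect_recovery_with_covariates_present():
    """An injected -0.4 sigma shift is recovered by the adjusted model
    (averaged over ROIs and two seeds to tame shared-noise MC error)."""
    means = []
    for seed in (23, 24):
        cfg = GeneratorConfig(
            n_sites=1, n_controls=5000, n_patients=5000,
            true_d={r: -0.4 for r in ROI_REGISTRY},
            tau_between_site=0.0, metrics=("FA",), seed=seed,
        )
        recs = site_effect_sizes(generate_multisite(cfg).subjects)
        means.append(recs["estimate"].mean())
    assert np.mean(means) == pytest.approx(-0.40, abs=0.03)


def test_minimum_group_cutoff_excludes_site(small_study):
    site = small_study.subjects.query("site_id == 'site01'")
    tiny = pd.concat(
        [site[site["diagnosis"] == "control"],
         site[site["diagnosis"] == "patient"].head(9)]
    )
    with pytest.raises(InsufficientGroupError):
        fit_group_model(tiny, "ACR", "FA")
    assert site_effect_sizes(tiny).empty


def test_listwise_deletion_leaves_estimates_unchanged(small_study):
    site = small_study.subjects.query("site_id == 'site01'").copy()
    base = site_effect_sizes(site)
    broken = site.head(7).copy()
    broken["age"] = np.nan
    padded = pd.concat([site, broken], ignore_index=True)
    again = site_effect_sizes(padded)
    pd.testing.assert_frame_equal(base, again)


def test_rank_deficient_design_names_terms(small_study):
    site = small_study.subjects.query("site_id == 'site01'").copy()
    site["sex"] = "M"  # male indicator collinear with the intercept
    with pytest.raises(ValueError, match="collinear"):
        fit_group_model(site, "ACR", "FA")


def test_interaction_recovery():
    """An injected diagnosis-by-age slope appears as the interaction beta."""
    slope = -4e-4
    cfg = GeneratorConfig(
        n_sites=1, n_controls=4000, n_patients=4000, dx_age_slope=slope,
        tau_between_site=0.0, metrics=("FA",), seed=31,
    )
    recs = interaction_records(
        generate_multisite(cfg).subjects, "dx_by_age", rois=("AverageFA", "ACR")
    ).set_index("roi")
    est = recs.loc["AverageFA"]
    assert est["estimate"] == pytest.approx(slope, abs=3 * est["se"])


# -- moderator regressions ----------------------------------------------


def test_duration_pct_computed_as_lifetime_fraction(small_study):
    """duration_pct is duration/age (40 y with 10 ill -> 0.25) and feeds the
    same regression as an explicitly precomputed column."""
    patients = small_study.subjects.query("diagnosis == 'patient'").copy()
    explicit = patients.assign(
        duration_pct=patients["duration_years"] / patients["age"]
    )
    assert explicit.loc[explicit["age"].round() == 40, "duration_pct"].between(0, 1).all()
    row = pd.Series({"age": 40.0, "duration_years": 10.0})
    assert row["duration_years"] / row["age"] == pytest.approx(0.25)
    implicit = moderator_regression(patients, "ACR", "FA", "duration_pct")
    recomputed = moderator_regression(explicit, "ACR", "FA", "duration_pct")
    assert implicit["estimate"] == pytest.approx(recomputed["estimate"], abs=1e-12)


def test_constant_moderator_rejected(small_study):
    patients = small_study.subjects.query("diagnosis == 'patient'").copy()
    patients["cpz"] = 300.0
    with pytest.raises(ValueError, match="constant"):
        moderator_regression(patients, "ACR", "FA", "cpz")


def test_insufficient_patients_excluded(small_study):
    patients = small_study.subjects.query("diagnosis == 'patient'").head(9)
    with pytest.raises(InsufficientGroupError):
        moderator_regression(patients, "ACR", "FA", "duration_years")


def test_null_moderator_z_is_standard_normal():
    """Site-level z statistics are N(0,1) under the generator's null
    (Kolmogorov–Smirnov over 500 single-site replicates)."""
    zs = []
    cfg0 = GeneratorConfig(
        n_sites=1, n_controls=10, n_patients=100,
        tau_between_site=0.0, metrics=("FA",),
        clinical=ClinicalParams(availability=dict(FULL_AVAILABILITY)),
        true_d={r: 0.0 for r in ROI_REGISTRY}, d_core=0.0, d_periphery=0.0,
    )
    for seed in range(500):
        subjects = generate_multisite(cfg0.replace(seed=seed)).subjects
        patients = subjects.query("diagnosis == 'patient'")
        rec = moderator_regression(patients, "AverageFA", "FA", "cpz")
        zs.append(rec["stat"])
    _, p = sps.kstest(np.asarray(zs), "norm")
    assert p > 0.01


# -- subgroups -----------------------------------------------------------


def test_smoking_deficit_recovered():
    cfg = GeneratorConfig(
        n_sites=1, n_controls=50, n_patients=6000, smoker_d=-0.2,
        clinical=ClinicalParams(availability=dict(FULL_AVAILABILITY)),
        tau_between_site=0.0, metrics=("FA",), seed=41,
    )
    patients = generate_multisite(cfg).subjects.query("diagnosis == 'patient'")
    recs = subgroup_effects(patients, "smoking").set_index("roi")
    assert recs.loc["AverageFA", "estimate"] == pytest.approx(-0.2, abs=0.06)


def test_identical_subgroups_give_null_d(small_study):
    patients = small_study.subjects.query("diagnosis == 'patient'")
    recs = subgroup_effects(patients, "smoking")
    assert recs["estimate"].abs().mean() < 0.2  # no injected deficit


def test_underpowered_medication_contrast_skipped():
    """Contrasts with a subgroup under the 10-subject cutoff are omitted,
    so rare medication classes never yield records."""
    cfg = GeneratorConfig(
        n_sites=1, n_controls=50, n_patients=120,
        clinical=ClinicalParams(
            availability=dict(FULL_AVAILABILITY),
            med_fractions={"atypical": 0.90, "typical": 0.04, "both": 0.03, "none": 0.03},
        ),
        metrics=("FA",), seed=43,
    )
    patients = generate_multisite(cfg).subjects.query("diagnosis == 'patient'")
    recs = subgroup_effects(patients, "medication")
    kept = set(recs["model_id"].unique())
    counts = patients["med_class"].value_counts()
    for model_id in kept:
        a, b = model_id.removeprefix("subgroup_medication_").split("_vs_")
        assert counts[a] >= 10 and counts[b] >= 10
    # rare classes (expected ~4 subjects each) never produce a contrast
    rare = {c for c in ("typical", "both", "none") if counts.get(c, 0) < 10}
    assert rare, "fixture should contain at least one underpowered class"
    assert not any(c in m.removeprefix("subgroup_medication_").split("_vs_")
                   for m in kept for c in rare)


# -- dispersion comparison ----------------------------------------------


def test_variance_comparison_identical_samples(rng):
    x = rng.normal(0, 1, 200)
    res = variance_comparison(x, x.copy())
    assert res.statistic == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)


def test_variance_comparison_recovers_group_sds():
    cfg = GeneratorConfig(
        n_sites=1, n_controls=2000, n_patients=2000,
        tau_between_site=0.0, metrics=("FA",), seed=47,
    )
    df = generate_multisite(cfg).subjects
    res = variance_comparison(
        df.query("diagnosis == 'patient'")["FA_AverageFA"],
        df.query("diagnosis == 'control'")["FA_AverageFA"],
    )
    assert res.sd_exposed == pytest.approx(0.0176, abs=5e-4)
    assert res.sd_reference == pytest.approx(0.0194, abs=5e-4)


def test_variance_comparison_detects_doubled_sd(rng):
    """sigma ratio 2 at n=500/group is detected at alpha=0.05 in >99% of
    replicates (power simulation oracle)."""
    hits = 0
    for _ in range(100):
        x = rng.normal(0, 2.0, 500)
        y = rng.normal(0, 1.0, 500)
        if variance_comparison(x, y).p < 0.05:
            hits += 1
    assert hits >= 99


def test_variance_comparison_edge_cases(rng):
    with pytest.raises(ValueError):
        variance_comparison([1.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="zero variance"):
        variance_comparison([1.0, 1.0, 1.0], rng.normal(size=10))
    res = variance_comparison(rng.normal(size=50), rng.normal(size=50), method="levene")
    assert 0.0 <= res.p <= 1.0


def test_covariate_spec_validation():
    with pytest.raises(ValueError, match="global covariate"):
        CovariateSpec(global_covariate="banana")
    with pytest.raises(ValueError, match="interaction"):
        CovariateSpec(interaction="dx_by_banana")
    with pytest.raises(ValueError, match="sex terms"):
        CovariateSpec(interaction="dx_by_sex", sex_terms=False)
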