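"""Calibrated multi-site subject-level simulator for ROI DTI measures.

Emulates a coordinated multi-cohort case-control DTI study: 29 sites of
heterogeneous size, site-level intercept shifts, a standardized diagnosis
effect per ROI with between-site heterogeneity on the d scale, nonlinear
age/sex structure, and clinical moderators (age at onset, illness duration,
antipsychotic dose, symptom scales, smoking, medication class) with
configurable site-level availability.

Generative model for one subject's value on measure *r* (FA scale)::

    y_r = mu_r + b_site + dx * delta_r + f(age, sex) + extras + eps_r

where ``delta_r = (true_d[r] + u_site) * sigma_pool`` is the injected group
shift, ``f`` is a quadratic age trend with sex interactions, ``extras``
collects optional moderator-linked and interaction terms, and the residuals
``eps`` are compound-symmetric across measures (correlation ``rho_roi``).

The residual standard deviation per group is *solved*, not set: given target
marginal s.d.s of whole-skeleton FA (defaults 0.0194 controls / 0.0176
patients), the variance contributed by the deterministic covariate structure
is measured by an internal fixed-seed Monte-Carlo quadrature and subtracted,
so the printed dispersions are reproduced as sample statistics rather than
merely labelled.  Configurations whose covariate effects exceed the target
variance are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import registry
from .registry import AVERAGE_FA, METRICS, ROI_REGISTRY
from .skeleton import AtlasLabels, SkeletonVolume

# internal quadrature settings for the variance solve (independent of the
# user's seed so that calibration is a function of the config alone)
_MC_SEED = 0x5EED
_MC_N = 200_000

# residual-s.d. solves keyed by configuration (seed excluded)
_SD_CACHE: dict[str, dict] = {}

#: plausible control-group FA means per registry measure (skeleton-mean scale)
DEFAULT_ROI_MEANS: dict[str, float] = {
    AVERAGE_FA: 0.450,
    "ACR": 0.460, "ALIC": 0.540, "BCC": 0.630, "CGC": 0.520, "CGH": 0.450,
    "CST": 0.600, "EC": 0.430, "FX": 0.450, "FXST": 0.500, "GCC": 0.650,
    "IFO": 0.470, "PCR": 0.480, "PLIC": 0.620, "PTR": 0.560, "RLIC": 0.550,
    "SCC": 0.710, "SCR": 0.490, "SFO": 0.500, "SLF": 0.480, "SS": 0.520,
    "UNC": 0.450, "CC": 0.660, "CR": 0.475, "IC": 0.580,
    "core": 0.520, "periphery": 0.410,
}


@dataclass(frozen=True)
class AgeEffect:
    """Quadratic age trend with sex interactions on the FA scale.

    ``f(age, male) = linear*c + quad*c^2 + male*(sex + linear_sex*c + quad_sex*c^2)``
    with ``c = age - center`` (years).  Defaults give a gentle age-related FA
    decline (~0.005 FA over 25 years) and a small male offset, well inside
    the target marginal variance.
    """

    linear: float = -2.0e-4
    quad: float = -1.5e-6
    sex: float = 2.0e-3
    linear_sex: float = -5.0e-5
    quad_sex: float = -5.0e-7
    center: float = 40.0

    def evaluate(self, age: np.ndarray, male: np.ndarray) -> np.ndarray:
        c = np.asarray(age, float) - self.center
        m = np.asarray(male, float)
        return (
            self.linear * c
            + self.quad * c**2
            + m * (self.sex + self.linear_sex * c + self.quad_sex * c**2)
        )


@dataclass(frozen=True)
class ClinicalParams:
    """Distributional parameters for patient clinical moderators.

    Means follow the consortium-level descriptives (onset 23 y, duration 14 y,
    CPZ 371.23 mg-eq, PANSS total 55.90, SANS 16.72, SAPS 13.70); dispersion
    and shape are modelling choices.  Age at onset is a lower-truncated normal
    whose location is solved so the *truncated* mean equals ``onset_mean``;
    patient age is onset + duration (gamma), making onset/duration/age exactly
    consistent and duration collinear with age by construction.
    ``availability`` gives the fraction of sites that recorded each moderator
    family (site-level missingness, mirroring per-analysis cohort counts).
    """

    onset_mean: float = 23.0
    onset_sd: float = 5.0
    onset_min: float = 13.0
    duration_mean: float = 14.0
    duration_shape: float = 2.0
    cpz_mean: float = 371.23
    cpz_shape: float = 4.0
    panss_total: tuple[float, float] = (55.90, 15.0)
    panss_pos: tuple[float, float] = (14.5, 5.0)
    panss_neg: tuple[float, float] = (15.5, 6.0)
    sans_total: tuple[float, float] = (16.72, 8.0)
    saps_total: tuple[float, float] = (13.70, 8.0)
    smoking_frac: float = 0.5
    med_fractions: dict = field(
        default_factory=lambda: {
            "atypical": 0.71, "typical": 0.06, "both": 0.10, "none": 0.13
        }
    )
    availability: dict = field(
        default_factory=lambda: {
            "onset": 0.69, "cpz": 0.34, "panss": 0.34, "sans": 0.31,
            "saps": 0.31, "smoker": 0.21, "med_class": 0.34,
        }
    )

    def onset_location(self) -> float:
        """Location of the truncated normal such that E[onset] == onset_mean."""
        sd, lo, target = self.onset_sd, self.onset_min, self.onset_mean

        def trunc_mean(mu):
            a = (lo - mu) / sd
            return stats.truncnorm(a, np.inf, loc=mu, scale=sd).mean() - target

        return optimize.brentq(trunc_mean, target - 4 * sd, target + sd)


@dataclass(frozen=True)
class MetricParams:
    """Scale and effect parameters for one diffusivity metric (MD/AD/RD)."""

    mean: float
    sd_control: float
    sd_patient: float
    d: dict | float  # per-ROI map or scalar applied to every measure
    age_slope: float = 0.0  # metric units per year

    def d_for(self, roi: str) -> float:
        if isinstance(self.d, dict):
            return float(self.d.get(roi, 0.0))
        return float(self.d)


def _default_metric_params() -> dict[str, MetricParams]:
    # stylized diffusivity effects: MD and RD elevated in patients across
    # ROIs, AD essentially null except the fornix (units mm^2/s)
    return {
        "MD": MetricParams(7.3e-4, 2.2e-5, 2.2e-5, 0.18, age_slope=2.0e-7),
        "RD": MetricParams(5.5e-4, 2.5e-5, 2.5e-5, 0.22, age_slope=2.5e-7),
        "AD": MetricParams(1.1e-3, 2.5e-5, 2.5e-5, {"FX": 0.15}, age_slope=5.0e-8),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the multi-site simulator."""

    n_sites: int = 29
    n_controls: int | tuple[int, int] = (20, 250)
    n_patients: int | tuple[int, int] = (20, 250)
    true_d: dict = field(default_factory=lambda: dict(registry.REFERENCE_D))
    d_core: float = -0.35
    d_periphery: float = -0.45
    tau_between_site: float = 0.05
    site_location_sd: float = 0.01
    site_scale_sd: float = 0.0
    roi_means: dict = field(default_factory=lambda: dict(DEFAULT_ROI_MEANS))
    marginal_sd_control: float = 0.0194
    marginal_sd_patient: float = 0.0176
    age_range: tuple[float, float] = (18.0, 80.0)
    age_mean: float = 36.0
    age_sd: float = 12.0
    pct_male_controls: float = 0.534
    pct_male_patients: float = 0.67
    age_effect: AgeEffect = field(default_factory=AgeEffect)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    moderator_slopes: dict = field(default_factory=dict)
    dx_age_slope: float = 0.0  # extra FA/year slope in patients (age-by-dx)
    sex_d_shift: float = 0.0  # extra d for female patients (sex-dependent effect)
    smoker_d: float = 0.0  # standardized FA shift for smoking patients
    rho_roi: float = 0.5
    metric_params: dict = field(default_factory=_default_metric_params)
    metrics: tuple[str, ...] = METRICS
    seed: int = 0

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        errors = []
        if self.n_sites <= 0:
            errors.append("n_sites must be > 0")
        for name, n in (("n_controls", self.n_controls), ("n_patients", self.n_patients)):
            lo, hi = (n, n) if isinstance(n, int) else n
            if lo <= 0 or hi < lo:
                errors.append(f"{name} must be positive (got {n})")
        for name, s in (
            ("tau_between_site", self.tau_between_site),
            ("site_location_sd", self.site_location_sd),
            ("site_scale_sd", self.site_scale_sd),
            ("marginal_sd_control", self.marginal_sd_control),
            ("marginal_sd_patient", self.marginal_sd_patient),
        ):
            if s < 0:
                errors.append(f"{name} must be >= 0")
        for name, p in (
            ("pct_male_controls", self.pct_male_controls),
            ("pct_male_patients", self.pct_male_patients),
            ("smoking fraction", self.clinical.smoking_frac),
        ):
            if not 0.0 <= p <= 1.0:
                errors.append(f"{name} must lie in [0, 1]")
        med_sum = sum(self.clinical.med_fractions.values())
        if abs(med_sum - 1.0) > 1e-6:
            errors.append(f"medication fractions sum to {med_sum}, expected 1")
        if not 0.0 <= self.rho_roi < 1.0:
            errors.append("rho_roi must lie in [0, 1)")
        missing = [r for r in ROI_REGISTRY if not np.isfinite(self.true_d.get(r, np.nan))]
        if missing:
            errors.append(f"true_d missing/non-finite for: {missing}")
        if errors:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(errors))
        # variance feasibility (raises if covariate effects exceed target)
        self.residual_sds()

    # -- variance calibration -------------------------------------------
    def _draw_covariates(self, group: str, rng: np.random.Generator, n: int):
        """Draw (age, male) plus patient clinical moderators."""
        lo, hi = self.age_range
        if group == "control":
            a = (lo - self.age_mean) / self.age_sd
            b = (hi - self.age_mean) / self.age_sd
            age = stats.truncnorm.rvs(
                a, b, loc=self.age_mean, scale=self.age_sd, size=n, random_state=rng
            )
            male = (rng.random(n) < self.pct_male_controls).astype(float)
            return age, male, {}
        cl = self.clinical
        a0 = (cl.onset_min - cl.onset_mean) / cl.onset_sd
        onset = stats.truncnorm.rvs(
            a0, np.inf, loc=self._onset_loc, scale=cl.onset_sd, size=n, random_state=rng
        )
        duration = rng.gamma(cl.duration_shape, cl.duration_mean / cl.duration_shape, n)
        age = onset + duration
        male = (rng.random(n) < self.pct_male_patients).astype(float)
        clinical = {"age_at_onset": onset, "duration_years": duration}
        clinical["cpz"] = rng.gamma(cl.cpz_shape, cl.cpz_mean / cl.cpz_shape, n)
        for name, (m, s) in (
            ("panss_total", cl.panss_total), ("panss_pos", cl.panss_pos),
            ("panss_neg", cl.panss_neg), ("sans_total", cl.sans_total),
            ("saps_total", cl.saps_total),
        ):
            clinical[name] = np.clip(rng.normal(m, s, n), 0.0, None)
        clinical["duration_pct"] = duration / age
        return age, male, clinical

    def _moderator_effect(self, clinical: dict) -> np.ndarray:
        """Deterministic FA contribution of configured moderator slopes."""
        if not self.moderator_slopes or not clinical:
            return 0.0
        total = 0.0
        for mod, slope in self.moderator_slopes.items():
            vals = clinical[mod]
            total = total + slope * (vals - vals.mean())
        return total

    @property
    def _onset_loc(self) -> float:
        return self.clinical.onset_location()

    def covariate_variances(self) -> dict:
        """Variance decomposition of the deterministic covariate structure.

        Returns per group the variance explained by the age/sex model
        (``var_model``) and the total deterministic variance including
        moderator-linked and diagnosis-by-age terms (``var_total``), measured
        by a fixed-seed Monte-Carlo quadrature.
        """
        out = {}
        rng = np.random.default_rng(_MC_SEED)
        for group in ("control", "patient"):
            age, male, clinical = self._draw_covariates(group, rng, _MC_N)
            f = self.age_effect.evaluate(age, male)
            extra = 0.0
            if group == "patient":
                extra = self._moderator_effect(clinical)
                if self.dx_age_slope:
                    extra = extra + self.dx_age_slope * (age - self.age_effect.center)
            total = f + extra
            out[group] = {
                "var_model": float(np.var(f)),
                "var_total": float(np.var(total)),
            }
        return out

    def residual_sds(self) -> dict:
        """Solve generator residual s.d. and analysis-scale pooled s.d.

        ``resid`` is what the simulator draws; ``analysis`` approximates the
        residual s.d. the per-site covariate model will see (target variance
        minus model-explainable variance); ``sigma_pool`` standardizes the
        injected diagnosis shifts.  Cached per configuration (seed excluded):
        the solve depends only on the deterministic structure.
        """
        key_dict = config_to_dict(self)
        key_dict.pop("seed", None)
        key = repr(key_dict)
        if key in _SD_CACHE:
            return _SD_CACHE[key]
        cv = self.covariate_variances()
        targets = {
            "control": self.marginal_sd_control,
            "patient": self.marginal_sd_patient,
        }
        out = {}
        for group, tgt in targets.items():
            resid_var = tgt**2 - cv[group]["var_total"]
            if resid_var <= 0:
                raise ValueError(
                    f"covariate-effect variance {cv[group]['var_total']:.3g} exceeds "
                    f"target marginal variance {tgt**2:.3g} for {group}s"
                )
            out[group] = {
                "resid": float(np.sqrt(resid_var)),
                "analysis": float(np.sqrt(tgt**2 - cv[group]["var_model"])),
            }
        out["sigma_pool"] = float(
            np.sqrt((out["control"]["analysis"] ** 2 + out["patient"]["analysis"] ** 2) / 2)
        )
        _SD_CACHE[key] = out
        return out


@dataclass
class SimulatedStudy:
    """One simulated multi-site study: subject table + site attribute table."""

    subjects: pd.DataFrame
    sites: pd.DataFrame
    config: GeneratorConfig


def _fa_columns(config: GeneratorConfig) -> list[str]:
    return list(ROI_REGISTRY) + ["core", "periphery"]


def _correlated_noise(rng, n, m, rho) -> np.ndarray:
    """n x m unit-variance noise, compound-symmetric across columns."""
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, m))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own


def generate_multisite(config: GeneratorConfig) -> SimulatedStudy:
    """Simulate the full multi-site subject-level dataset.

    Deterministic for a fixed ``config.seed``.  Returns a
    :class:`SimulatedStudy` whose ``subjects`` table has one row per subject
    with demographics, clinical moderators (missing outside recording sites
    and for all controls) and ``<metric>_<roi>`` outcome columns, and whose
    ``sites`` table carries per-site attributes (group sizes, gradient
    directions).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sds = config.residual_sds()
    sigma_pool = sds["sigma_pool"]
    cl = config.clinical
    fa_cols = _fa_columns(config)
    d_fa = np.array(
        [config.true_d[r] for r in ROI_REGISTRY] + [config.d_core, config.d_periphery]
    )
    mu_fa = np.array([config.roi_means[r] for r in fa_cols])
    fa_sd = {"control": sds["control"]["resid"], "patient": sds["patient"]["resid"]}

    site_rows, frames = [], []
    for s in range(config.n_sites):
        site_id = f"site{s + 1:02d}"
        n_c = _draw_count(rng, config.n_controls)
        n_p = _draw_count(rng, config.n_patients)
        u_site = rng.normal(0.0, config.tau_between_site)
        loc_shift = rng.normal(0.0, config.site_location_sd)
        scale = 1.0 + (rng.normal(0.0, config.site_scale_sd) if config.site_scale_sd else 0.0)
        n_directions = int(rng.choice([12, 15, 20, 25, 30, 32, 60, 64]))
        has = {k: bool(rng.random() < v) for k, v in cl.availability.items()}

        group_frames = []
        for group, n in (("control", n_c), ("patient", n_p)):
            age, male, clinical = config._draw_covariates(group, rng, n)
            f = config.age_effect.evaluate(age, male)
            dx = 1.0 if group == "patient" else 0.0
            extra = np.zeros(n)
            smoker = med_class = None
            if group == "patient":
                extra = extra + config._moderator_effect(clinical)
                if config.dx_age_slope:
                    extra = extra + config.dx_age_slope * (age - config.age_effect.center)
                if config.sex_d_shift:
                    extra = extra + config.sex_d_shift * sigma_pool * (1.0 - male)
                smoker = (rng.random(n) < cl.smoking_frac).astype(float)
                if config.smoker_d:
                    extra = extra + config.smoker_d * sigma_pool * smoker
                classes = list(cl.med_fractions)
                med_class = rng.choice(
                    classes, size=n, p=[cl.med_fractions[c] for c in classes]
                )

            data = {
                "site_id": site_id,
                "subject_id": [f"{site_id}-{group[0]}{i:04d}" for i in range(n)],
                "diagnosis": group,
                "sex": np.where(male > 0.5, "M", "F"),
                "age": age,
            }
            # clinical columns: NaN for controls and at non-recording sites
            for col in (
                "age_at_onset", "duration_years", "cpz", "panss_total",
                "panss_pos", "panss_neg", "sans_total", "saps_total", "smoker",
            ):
                data[col] = np.full(n, np.nan)
            data["med_class"] = np.full(n, "", dtype=object)
            if group == "patient":
                if has["onset"]:
                    data["age_at_onset"] = clinical["age_at_onset"]
                    data["duration_years"] = clinical["duration_years"]
                if has["med_class"]:
                    data["med_class"] = med_class
                if has["cpz"]:
                    medicated = med_class != "none"
                    cpz = np.where(medicated, clinical["cpz"], np.nan)
                    data["cpz"] = cpz
                if has["panss"]:
                    for c in ("panss_total", "panss_pos", "panss_neg"):
                        data[c] = clinical[c]
                if has["sans"]:
                    data["sans_total"] = clinical["sans_total"]
                if has["saps"]:
                    data["saps_total"] = clinical["saps_total"]
                if has["smoker"]:
                    data["smoker"] = smoker

            # FA block (compound-symmetric residuals across measures)
            eps = _correlated_noise(rng, n, len(fa_cols), config.rho_roi)
            vals = (
                mu_fa[None, :]
                + loc_shift
                + dx * (d_fa + u_site)[None, :] * sigma_pool
                + (f + extra)[:, None]
                + scale * fa_sd[group] * eps
            )
            for j, roi in enumerate(fa_cols):
                data[f"FA_{roi}"] = vals[:, j]

            # diffusivity metrics
            for metric in config.metrics:
                if metric == "FA":
                    continue
                mp = config.metric_params[metric]
                sd_g = mp.sd_control if group == "control" else mp.sd_patient
                d_m = np.array([mp.d_for(r) for r in ROI_REGISTRY])
                eps_m = _correlated_noise(rng, n, len(ROI_REGISTRY), config.rho_roi)
                shift = loc_shift * sd_g / max(fa_sd["control"], 1e-12)
                vals_m = (
                    mp.mean
                    + shift
                    + dx * (d_m + u_site)[None, :] * sd_g
                    + (mp.age_slope * (age - config.age_effect.center))[:, None]
                    + scale * sd_g * eps_m
                )
                for j, roi in enumerate(ROI_REGISTRY):
                    data[f"{metric}_{roi}"] = vals_m[:, j]

            group_frames.append(pd.DataFrame(data))

        frames.append(pd.concat(group_frames, ignore_index=True))
        site_rows.append(
            {
                "site_id": site_id,
                "n_controls": n_c,
                "n_patients": n_p,
                "n_directions": n_directions,
                "direction_group": "high" if n_directions > 30 else "low",
                **{f"has_{k}": v for k, v in has.items()},
            }
        )

    subjects = pd.concat(frames, ignore_index=True)
    sites = pd.DataFrame(site_rows)
    return SimulatedStudy(subjects=subjects, sites=sites, config=config)


def _draw_count(rng, n) -> int:
    if isinstance(n, int):
        return n
    lo, hi = n
    return int(rng.integers(lo, hi + 1))


# -- skeleton fixture generator -----------------------------------------


def generate_skeleton_subject(
    n_voxels: int,
    atlas: AtlasLabels,
    subject_mean: float = 0.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    label_means: dict | None = None,
) -> SkeletonVolume:
    """Voxelwise skeleton volume with per-ROI means plus i.i.d. noise.

    ``label_means`` maps atomic ROI (or PERIPHERY) to its mean value; defaults
    to the bundled control FA means.  ``subject_mean`` is an additive global
    offset.  Reproducible under ``seed``.
    """
    if n_voxels <= 0:
        raise ValueError("n_voxels must be positive")
    if atlas.n_voxels != n_voxels:
        raise ValueError("atlas length must equal n_voxels")
    means = dict(DEFAULT_ROI_MEANS) if label_means is None else dict(label_means)
    means.setdefault(registry.PERIPHERY, means.get("periphery", 0.41))
    rng = np.random.default_rng(seed)
    base = np.array([means[atlas.atomic_of(lab)] for lab in atlas.labels])
    values = base + subject_mean + (rng.normal(0.0, noise_sd, n_voxels) if noise_sd else 0.0)
    return SkeletonVolume(values=values, metric="FA")


# -- persistence ---------------------------------------------------------


def _tuples_to_lists(obj):
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    if isinstance(obj, list):
        return [_tuples_to_lists(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["metric_params"] = {
        k: dataclasses.asdict(v) for k, v in config.metric_params.items()
    }
    return _tuples_to_lists(d)


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write per-site subject CSVs, the site table and a YAML config sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for site_id, df in study.subjects.groupby("site_id", sort=True):
        df.to_csv(out / f"subjects_{site_id}.csv", index=False, float_format="%.17g")
    study.sites.to_csv(out / "sites.csv", index=False)
    with open(out / "generator_config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(study.config), fh, sort_keys=True)


def read_study(indir) -> SimulatedStudy:
    from pathlib import Path

    ind = Path(indir)
    frames = [
        pd.read_csv(p, dtype={"med_class": "string"}, float_precision="round_trip")
        for p in sorted(ind.glob("subjects_site*.csv"))
    ]
    if not frames:
        raise FileNotFoundError(f"no subjects_site*.csv under {ind}")
    subjects = pd.concat(frames, ignore_index=True)
    subjects["med_class"] = subjects["med_class"].fillna("").astype(object)
    sites = pd.read_csv(ind / "sites.csv")
    with open(ind / "generator_config.yaml") as fh:
        raw = yaml.safe_load(fh)
    config = _config_from_dict(raw)
    return SimulatedStudy(subjects=subjects, sites=sites, config=config)


def _config_from_dict(raw: dict) -> GeneratorConfig:
    raw = dict(raw)
    raw["age_effect"] = AgeEffect(**raw["age_effect"])
    clinical = dict(raw["clinical"])
    for key in ("panss_total", "panss_pos", "panss_neg", "sans_total", "saps_total"):
        if isinstance(clinical.get(key), list):
            clinical[key] = tuple(clinical[key])
    raw["clinical"] = ClinicalParams(**clinical)
    raw["metric_params"] = {
        k: MetricParams(**v) for k, v in raw["metric_params"].items()
    }
    for key in ("n_controls", "n_patients", "age_range", "metrics"):
        if isinstance(raw.get(key), list):
            raw[key] = tuple(raw[key])
    return GeneratorConfig(**raw)
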