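"""Synthetic baseline cohort generator.

Produces cohorts whose tables mimic the marginal distributions and
cross-domain associations of the study sample, so that every pipeline
stage is exercisable without the (non-public) subject data:

* age from a truncated normal on [50, 70]; gender Bernoulli(1/2);
* raw clinical fields drawn so the implied risk-flag marginals match the
  printed prevalences (hypertension 30.3%, dyslipidemia 27.5%, ...);
* a latent-factor battery model: each raw subtest is an affine rescaling
  of ``g_i + sigma_i * eps``, where ``g_i`` is general cognition and
  ``sigma_i`` a subject-specific inconsistency scale (log-normal, shifted
  upward by combined risk) — this gives the across-test variability V_i a
  recoverable ground truth;
* TIV with a gender gap, tissue fractions with age slopes, temporal
  cortical thickness reduced in high-risk subjects;
* white-matter lesions: negative-binomial counts and log-normal volumes
  increasing with age and cardiovascular score, allocated over the three
  location classes;
* an amyloid-PET global cortical index for a subset, with about 8.6%
  above the 1.45 positivity cut and independent of age and cognition.

The latent-scale constants (``mu_sigma``, ``tau``, ``risk_inconsistency``
and the age loading on log lesion volume) were calibrated once by
simulation at n = 100,000 against the targets V_i mean 0.89 / SD 0.40,
partial corr(risk, V_i | age, gender) = 0.21 and corr(age, WML fraction)
= 0.39, then frozen here.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = [
    "EffectConfig",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_cohort",
]

# raw battery columns rescaled to these cohort means/SDs (TMT B is derived
# from TMT A plus the B-A difference and is listed without a target)
RAW_BATTERY_STATS = {
    "mmse": (29.2, 1.0),
    "mattis": (142.3, 2.8),
    "corsi_direct": (5.3, 0.9),
    "corsi_inverse": (4.7, 0.9),
    "digit_direct": (6.0, 1.1),
    "digit_inverse": (4.7, 1.1),
    "grober_buschke_total_recall": (46.6, 1.4),
    "dms_immediate": (96.9, 3.7),
    "rey_immediate": (35.0, 1.4),
    "rey_3min": (20.5, 7.4),
    "stroop_interference_time": (53.8, 11.8),
    "bref": (17.1, 1.3),
    "phonematic_fluency": (23.9, 6.7),
    "semantic_fluency": (39.0, 9.1),
    "do80": (79.8, 0.7),
}
#: raw columns where a larger value means worse performance
LOWER_IS_BETTER_RAW = ("stroop_interference_time",)

_TMT_A_MEAN, _TMT_A_SD = 31.9, 9.8
_TMT_DIFF_MEAN, _TMT_DIFF_SD = 40.4, 20.0

_LESION_CLASS_PROBS = np.array([0.5, 0.3, 0.2])  # periventricular, juxtacortical, deep
#: per-lesion size multipliers making the expected class volume shares
#: match the printed class means (83.8% / 10.3% / 5.9% of the total)
_LESION_SIZE_WEIGHTS = np.array([1.676, 0.343, 0.295])
_LESION_CLASSES = ("periventricular", "juxtacortical", "deep_white")

_THICKNESS_REGIONS = {
    # region -> (mean mm, SD mm)
    "medial_temporal": (2.90, 0.15),
    "parahippocampal": (2.70, 0.18),
    "entorhinal": (3.30, 0.25),
}


@dataclass
class EffectConfig:
    """Standardized cross-domain effect loadings; all zero in a null cohort.

    Loadings are on standardized scales: correlations for the linear
    volume models, a log-scale loading for lesion volume, SD units for the
    TIV gender gap, and a log-sigma shift per SD of combined risk for the
    risk -> inconsistency path.
    """

    age_wm: float = -0.41  # age slope on WM fraction (target r)
    vi_wm: float = -0.35  # latent-inconsistency slope on WM fraction
    age_gm: float = -0.22  # age slope on cortical GM fraction
    gender_gm: float = 0.15  # female offset on GM fraction (SD units)
    age_thickness: float = -0.22
    age_hippocampus: float = -0.17
    gender_hippocampus: float = 0.30  # female offset after TIV correction
    tiv_gender_gap_sd: float = 1.078  # male - female TIV gap in within-gender SDs
    age_wml: float = 0.556  # age loading on log lesion volume (calibrated)
    cardio_wml: float = 0.31  # cardiovascular-score loading on log lesion volume
    cognitive_wml: float = 0.21
    risk_inconsistency: float = 0.094  # log-sigma shift per SD of combined risk
    risk_thickness: tuple = (-0.30, -0.20, -0.24, -0.22, -0.12, -0.10)
    # order: medial_temporal L/R, parahippocampal L/R, entorhinal L/R

    def nulled(self) -> "EffectConfig":
        return EffectConfig(
            **{
                f: (0.0 if not isinstance(getattr(self, f), tuple) else (0.0,) * 6)
                for f in self.__dataclass_fields__
            }
        )


@dataclass
class GeneratorConfig:
    """All marginal targets and latent-model parameters of the generator."""

    n_subjects: int = 142
    effects: EffectConfig = field(default_factory=EffectConfig)

    # clinical marginals
    age_low: float = 50.0
    age_high: float = 70.0
    age_mean: float = 60.0
    age_parent_sd: float = 15.0  # parent SD before truncation (see docs)
    p_female: float = 0.5
    flag_probs: dict = field(
        default_factory=lambda: {
            "diabetes": 0.059,
            "hypertension": 0.303,
            "dyslipidemia": 0.275,
            "smoking": 0.056,
            "obesity": 0.113,
            "depression_risk": 0.063,
            "low_education": 0.169,
        }
    )
    p_apoe4: tuple = (0.771, 0.222, 0.007)  # 0 / 1 / 2 epsilon-4 copies

    # battery latent scales (calibrated; see module docstring)
    mu_sigma: float = 1.346
    tau: float = 0.372

    # volumetrics marginals
    tiv_mean: float = 1.45e6  # mm^3
    tiv_within_sd: float = 1.15e5
    gm_frac_mean: float = 0.4781
    gm_frac_sd: float = 0.0204
    wm_frac_mean: float = 0.3559
    wm_frac_sd: float = 0.0276
    hippo_left_frac_mean: float = 0.00285
    hippo_right_frac_mean: float = 0.00275
    hippo_frac_sd: float = 0.00028
    mean_thickness: float = 2.45
    mean_thickness_sd: float = 0.10

    # white-matter lesions
    lesion_count_mean: float = 10.6
    lesion_count_sd: float = 7.1
    wml_frac_mean: float = 8.72e-4
    wml_frac_cv: float = 1.38  # coefficient of variation of the total fraction
    lesion_size_dispersion: float = 0.8  # log-SD of raw per-lesion sizes

    # amyloid PET
    pet_fraction: float = 81.0 / 142.0
    amyloid_positive_rate: float = 0.086
    gci_negative_mean: float = 1.24
    gci_negative_sd: float = 0.085
    gci_positive_excess_mean: float = 0.12
    gci_positive_excess_sd: float = 0.08

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise ConfigurationError("n_subjects must be >= 10")
        for name, p in self.flag_probs.items():
            if not 0 <= p < 1:
                raise ConfigurationError(f"flag probability {name}={p} outside [0, 1)")
        e = self.effects
        for label, total in {
            "wm": e.age_wm**2 + e.vi_wm**2,
            "gm": e.age_gm**2 + e.gender_gm**2,
            "wml": e.age_wml**2 + e.cardio_wml**2 + e.cognitive_wml**2,
            "hippocampus": e.age_hippocampus**2 + e.gender_hippocampus**2,
        }.items():
            if total >= 1:
                raise ConfigurationError(
                    f"effect loadings for {label} imply variance > 1 (non-PSD structure)"
                )
        for r in e.risk_thickness:
            if e.age_thickness**2 + r**2 >= 1:
                raise ConfigurationError("thickness loadings imply variance > 1")

    def nulled(self) -> "GeneratorConfig":
        """Copy with every cross-domain effect set to zero."""
        return replace(self, effects=self.effects.nulled())

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticCohort:
    """Generated analysis tables plus the latent ground truth."""

    clinical: pd.DataFrame
    battery: pd.DataFrame
    volumes: pd.DataFrame
    lesions: pd.DataFrame
    pet: pd.DataFrame
    ground_truth: pd.DataFrame
    config: GeneratorConfig
    seed: int

    def save(self, outdir) -> None:
        """Write the five analysis CSVs, the ground truth and a config echo."""
        import os

        os.makedirs(outdir, exist_ok=True)
        for name in ("clinical", "battery", "volumes", "lesions", "pet", "ground_truth"):
            getattr(self, name).to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
        self.config.to_yaml(os.path.join(outdir, "generator_config.yaml"))


def _truncnorm_std_age(cfg: GeneratorConfig, rng: np.random.Generator, n: int):
    a = (cfg.age_low - cfg.age_mean) / cfg.age_parent_sd
    b = (cfg.age_high - cfg.age_mean) / cfg.age_parent_sd
    dist = sps.truncnorm(a, b, loc=cfg.age_mean, scale=cfg.age_parent_sd)
    age = dist.rvs(size=n, random_state=rng)
    mean, var = dist.stats(moments="mv")
    return age, (age - float(mean)) / float(np.sqrt(var))


def _std_score(score: np.ndarray, probs) -> np.ndarray:
    """Standardize a sum-of-Bernoulli score with its theoretical moments."""
    probs = np.asarray(probs, dtype=float)
    mu = probs.sum()
    sd = float(np.sqrt((probs * (1 - probs)).sum()))
    return (score - mu) / sd


def _clinical_table(cfg: GeneratorConfig, rng: np.random.Generator):
    n = cfg.n_subjects
    ids = [f"S{i:05d}" for i in range(1, n + 1)]
    age, age_std = _truncnorm_std_age(cfg, rng, n)
    female = rng.random(n) < cfg.p_female
    fp = cfg.flag_probs
    flags = {k: rng.random(n) < fp[k] for k in fp}

    # diabetes mechanisms: elevated glycemia, self-report, drug (>= 1 holds)
    glycemia = np.clip(rng.normal(0.95, 0.12, n), 0.6, 1.259)
    d = flags["diabetes"]
    mech_gly = d & (rng.random(n) < 0.6)
    sr_diab = d & (rng.random(n) < 0.5)
    drug_diab = d & (rng.random(n) < 0.5)
    none = d & ~(mech_gly | sr_diab | drug_diab)
    mech_gly |= none
    glycemia[mech_gly] = 1.27 + np.abs(rng.normal(0.12, 0.10, mech_gly.sum()))

    # hypertension: blood-pressure measurement, self-report, drug
    sbp = np.clip(rng.normal(122, 8, n), 100, 139.4)
    dbp = np.clip(sbp - 45 + rng.normal(0, 5, n), 60, None)
    h = flags["hypertension"]
    mech_bp = h & (rng.random(n) < 0.7)
    sr_ht = h & (rng.random(n) < 0.4)
    drug_ht = h & (rng.random(n) < 0.5)
    none = h & ~(mech_bp | sr_ht | drug_ht)
    mech_bp |= none
    systolic = rng.random(n) < 0.75  # elevated systolic (vs diastolic-only)
    idx = mech_bp & systolic
    sbp[idx] = 140 + np.abs(rng.normal(8, 6, idx.sum()))
    dbp[idx] = np.clip(sbp[idx] - 55 + rng.normal(0, 6, idx.sum()), 70, None)
    idx = mech_bp & ~systolic
    sbp[idx] = np.clip(rng.normal(133, 4, idx.sum()), 110, 139.4)
    dbp[idx] = 90 + np.abs(rng.normal(4, 3, idx.sum()))
    dbp = np.minimum(dbp, sbp - 5)

    # dyslipidemia: cholesterol above 2.5 mmol/L, self-report, drug
    chol = np.clip(rng.normal(2.05, 0.25, n), 1.2, 2.5)
    dl = flags["dyslipidemia"]
    mech_chol = dl & (rng.random(n) < 0.6)
    sr_dl = dl & (rng.random(n) < 0.5)
    drug_dl = dl & (rng.random(n) < 0.4)
    none = dl & ~(mech_chol | sr_dl | drug_dl)
    mech_chol |= none
    chol[mech_chol] = 2.51 + np.abs(rng.normal(0.35, 0.25, mech_chol.sum()))

    bmi = np.clip(rng.normal(24.3, 2.8, n), 17, 29.9)
    ob = flags["obesity"]
    bmi[ob] = 30.1 + np.abs(rng.normal(2.0, 2.0, ob.sum()))

    gds = np.minimum(rng.poisson(3.0, n), 9).astype(float)
    dep = flags["depression_risk"]
    gds[dep] = 10 + rng.poisson(2.5, dep.sum())

    apoe4 = rng.choice([0, 1, 2], size=n, p=np.asarray(cfg.p_apoe4) / sum(cfg.p_apoe4))

    clinical = pd.DataFrame(
        {
            "subject_id": ids,
            "age": age,
            "gender": np.where(female, "female", "male"),
            "sbp": sbp,
            "dbp": dbp,
            "glycemia": glycemia,
            "cholesterol": chol,
            "bmi": bmi,
            "active_smoker": flags["smoking"],
            "self_reported_diabetes": sr_diab,
            "antidiabetic_drug": drug_diab,
            "self_reported_hypertension": sr_ht,
            "antihypertensive_drug": drug_ht,
            "self_reported_hypercholesterolemia": sr_dl,
            "lipid_lowering_drug": drug_dl,
            "gds": gds,
            "high_education": ~flags["low_education"],
            "apoe_e4_copies": apoe4,
        }
    )
    latent = {
        "ids": ids,
        "age_std": age_std,
        "female": female.astype(float),
        "flags": flags,
    }
    return clinical, latent


def _battery_table(cfg: GeneratorConfig, rng: np.random.Generator, latent: dict):
    n = cfg.n_subjects
    fp = cfg.flag_probs
    cardio = sum(latent["flags"][k] for k in ("diabetes", "hypertension", "dyslipidemia", "smoking", "obesity"))
    cognitive = latent["flags"]["depression_risk"].astype(int) + latent["flags"]["low_education"].astype(int)
    combined = cardio + cognitive
    c_std = _std_score(combined, list(fp.values()))
    latent["cardio_std"] = _std_score(
        cardio, [fp[k] for k in ("diabetes", "hypertension", "dyslipidemia", "smoking", "obesity")]
    )
    latent["cognitive_std"] = _std_score(cognitive, [fp["depression_risk"], fp["low_education"]])
    latent["combined_std"] = c_std
    latent["combined"] = np.asarray(combined, dtype=int)

    g = rng.normal(size=n)
    u = rng.normal(size=n)
    log_sigma = cfg.mu_sigma + cfg.tau * u + cfg.effects.risk_inconsistency * c_std
    sigma = np.exp(log_sigma)
    latent["g"] = g
    latent["sigma"] = sigma
    v_exp = cfg.tau**2 + cfg.effects.risk_inconsistency**2
    s_bar = float(np.sqrt(1 + np.exp(2 * cfg.mu_sigma + 2 * v_exp)))  # theoretical SD of g + sigma*eps

    cols = {"subject_id": latent["ids"]}
    for name, (mean, sd) in RAW_BATTERY_STATS.items():
        x = (g + sigma * rng.normal(size=n)) / s_bar
        if name in LOWER_IS_BETTER_RAW:
            raw = mean - sd * x
        else:
            raw = mean + sd * x
        if name.endswith("_time"):
            raw = np.clip(raw, 1.0, None)
        cols[name] = raw
    # TMT: A is its own timed task; B is A plus an executive-cost difference
    x_tmt = (g + sigma * rng.normal(size=n)) / s_bar
    tmt_a = np.clip(_TMT_A_MEAN + _TMT_A_SD * rng.normal(size=n), 5.0, None)
    diff = np.clip(_TMT_DIFF_MEAN - _TMT_DIFF_SD * x_tmt, 0.5, None)
    cols["tmt_a_time"] = tmt_a
    cols["tmt_b_time"] = tmt_a + diff
    return pd.DataFrame(cols)


def _volumes_table(cfg: GeneratorConfig, rng: np.random.Generator, latent: dict):
    n = cfg.n_subjects
    e = cfg.effects
    a = latent["age_std"]
    f_std = latent["female"] * 2 - 1  # +1 female, -1 male
    c_std = latent["combined_std"]
    # standardized latent log-inconsistency (drives the V_i -> volume paths)
    q = np.log(latent["sigma"]) - np.log(latent["sigma"]).mean()
    qsd = q.std()
    q = q / qsd if qsd > 0 else np.zeros(n)

    def blend(*loadings_and_vars):
        total = sum(l**2 for l, _ in loadings_and_vars)
        rest = np.sqrt(max(0.0, 1 - total))
        return sum(l * v for l, v in loadings_and_vars) + rest * rng.normal(size=n)

    tiv = cfg.tiv_mean + cfg.tiv_within_sd * (
        -0.5 * e.tiv_gender_gap_sd * f_std + rng.normal(size=n)
    )
    wm_frac = cfg.wm_frac_mean + cfg.wm_frac_sd * blend((e.age_wm, a), (e.vi_wm, q))
    gm_frac = cfg.gm_frac_mean + cfg.gm_frac_sd * blend((e.age_gm, a), (e.gender_gm, f_std))
    csf_frac = 1.0 - gm_frac - wm_frac
    hip_l = cfg.hippo_left_frac_mean + cfg.hippo_frac_sd * blend(
        (e.age_hippocampus, a), (e.gender_hippocampus, f_std)
    )
    hip_r = cfg.hippo_right_frac_mean + cfg.hippo_frac_sd * blend(
        (0.8 * e.age_hippocampus, a), (0.5 * e.gender_hippocampus, f_std)
    )

    cols = {
        "subject_id": latent["ids"],
        "tiv": tiv,
        "gm_volume": gm_frac * tiv,
        "wm_volume": wm_frac * tiv,
        "csf_volume": csf_frac * tiv,
        "hippocampus_left": hip_l * tiv,
        "hippocampus_right": hip_r * tiv,
    }
    region_keys = []
    for region, (mu, sd) in _THICKNESS_REGIONS.items():
        region_keys += [f"{region}_thickness_l", f"{region}_thickness_r"]
    for j, key in enumerate(region_keys):
        region = key.rsplit("_thickness", 1)[0]
        mu, sd = _THICKNESS_REGIONS[region]
        cols[key] = mu + sd * blend((e.age_thickness, a), (e.risk_thickness[j], c_std))
    for side in ("l", "r"):
        cols[f"mean_thickness_{side}"] = cfg.mean_thickness + cfg.mean_thickness_sd * blend(
            (e.age_thickness, a)
        )
    latent["tiv"] = tiv
    return pd.DataFrame(cols)


def _lesion_table(cfg: GeneratorConfig, rng: np.random.Generator, latent: dict):
    n = cfg.n_subjects
    e = cfg.effects
    a = latent["age_std"]
    s = float(np.sqrt(np.log(1 + cfg.wml_frac_cv**2)))
    loadings = np.array([e.age_wml, e.cardio_wml, e.cognitive_wml])
    rest = np.sqrt(max(0.0, 1 - (loadings**2).sum()))
    z = (
        e.age_wml * a
        + e.cardio_wml * latent["cardio_std"]
        + e.cognitive_wml * latent["cognitive_std"]
        + rest * rng.normal(size=n)
    )
    total_frac = cfg.wml_frac_mean * np.exp(s * z - s**2 / 2)

    var = cfg.lesion_count_sd**2
    r_nb = cfg.lesion_count_mean**2 / max(var - cfg.lesion_count_mean, 1e-9)
    p_nb = r_nb / (r_nb + cfg.lesion_count_mean)
    counts = rng.negative_binomial(r_nb, p_nb, size=n)

    rows = []
    fazekas_latent = 0.6 * z + 0.8 * rng.normal(size=n)
    for i in range(n):
        c = int(counts[i])
        if c == 0:
            continue
        classes = rng.choice(3, size=c, p=_LESION_CLASS_PROBS)
        raw = _LESION_SIZE_WEIGHTS[classes] * rng.lognormal(0.0, cfg.lesion_size_dispersion, c)
        vols = raw * (total_frac[i] * latent["tiv"][i] / raw.sum())
        for j in range(c):
            rows.append(
                {
                    "subject_id": latent["ids"][i],
                    "lesion_id": f"{latent['ids'][i]}_L{j + 1:03d}",
                    "lesion_class": _LESION_CLASSES[classes[j]],
                    "volume": vols[j],
                }
            )
    lesions = pd.DataFrame(rows, columns=["subject_id", "lesion_id", "lesion_class", "volume"])
    # Fazekas visual rating: ordinal cut of a latent correlated with lesion load
    cuts = np.quantile(fazekas_latent, [0.35, 0.65, 0.83])
    latent["fazekas"] = np.digitize(fazekas_latent, cuts)
    return lesions


def _pet_table(cfg: GeneratorConfig, rng: np.random.Generator, latent: dict):
    n = cfg.n_subjects
    n_pet = int(round(cfg.pet_fraction * n))
    idx = np.sort(rng.choice(n, size=n_pet, replace=False))
    positive = rng.random(n_pet) < cfg.amyloid_positive_rate
    gci = np.clip(
        rng.normal(cfg.gci_negative_mean, cfg.gci_negative_sd, n_pet), 0.9, 1.449
    )
    gci[positive] = 1.45 + np.abs(
        rng.normal(cfg.gci_positive_excess_mean, cfg.gci_positive_excess_sd, positive.sum())
    ) + 1e-6
    return pd.DataFrame(
        {"subject_id": [latent["ids"][i] for i in idx], "gci": gci}
    )


def generate_cohort(
    config: Optional[GeneratorConfig] = None, seed: int = 0, n_subjects: Optional[int] = None
) -> SyntheticCohort:
    """Generate one synthetic cohort; reproducible given ``seed``.

    A single seed expands into independent per-table substreams, so adding
    a table never perturbs the existing ones.
    """
    cfg = config or GeneratorConfig()
    if n_subjects is not None:
        cfg = replace(cfg, n_subjects=n_subjects)
    cfg.validate()
    streams = np.random.SeedSequence(seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in streams]

    clinical, latent = _clinical_table(cfg, rngs[0])
    battery = _battery_table(cfg, rngs[1], latent)
    volumes = _volumes_table(cfg, rngs[2], latent)
    lesions = _lesion_table(cfg, rngs[3], latent)
    volumes["fazekas"] = latent["fazekas"]
    pet = _pet_table(cfg, rngs[4], latent)

    ground_truth = pd.DataFrame(
        {
            "subject_id": latent["ids"],
            "g": latent["g"],
            "sigma": latent["sigma"],
            "combined_risk": latent["combined"],
            "age_std": latent["age_std"],
            "female": latent["female"],
        }
    )
    return SyntheticCohort(
        clinical=clinical,
        battery=battery,
        volumes=volumes,
        lesions=lesions,
        pet=pet,
        ground_truth=ground_truth,
        config=cfg,
        seed=seed,
    )


def generate_null_cohort(
    config: Optional[GeneratorConfig] = None, seed: int = 0, n_subjects: Optional[int] = None
) -> SyntheticCohort:
    """Cohort with every cross-domain effect at zero (type-I-error testing)."""
    cfg = (config or GeneratorConfig()).nulled()
    return generate_cohort(cfg, seed=seed, n_subjects=n_subjects)
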