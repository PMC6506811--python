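"""Synthetic paired clinical-metabolomics cohorts.

Generates a two-samples-per-subject cohort (e.g. two tissue types dissected
from each patient) whose log2 abundances follow the random-intercept model

    y_ij = beta_0j + u_ij + sum_k beta_jk x_ik + e_ij

with per-subject random intercepts and homoscedastic residual noise. The
default covariate marginals reproduce a 59-patient colorectal-carcinoma
cohort: age 62.92 +- 13.71 y, BMI 27.14 +- 4.38 kg/m^2, 16/59 female,
tumor stages I-IV at (9, 23, 16, 11)/59, tumor location colon/rectum at
(26, 33)/59.

Subject intercepts are drawn independently per subject-feature pair; any
cross-feature correlation of subject effects present in real cohorts is not
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CovariateInfo, FixedEffectSpec, MetabolomicsDataset

__all__ = ["CohortConfig", "generate_cohort", "null_cohort",
           "default_fixed_effect_spec", "CLASS_LEVELS"]

CLASS_LEVELS = ("A", "B")
SEX_LEVELS = ("male", "female")
STAGE_LEVELS = ("I", "II", "III", "IV")
LOCATION_LEVELS = ("colon", "rectum")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults are the reference cohort's marginals."""

    n_subjects: int = 59
    age_mean: float = 62.92          # years
    age_sd: float = 13.71
    bmi_mean: float = 27.14          # kg/m^2
    bmi_sd: float = 4.38
    p_female: float = 16 / 59
    stage_probs: tuple[float, ...] = (9 / 59, 23 / 59, 16 / 59, 11 / 59)
    location_probs: tuple[float, ...] = (26 / 59, 33 / 59)
    n_features: int = 100
    frac_discriminative: float = 0.3
    effect_size_range: tuple[float, float] = (0.5, 2.0)  # log2 units, random sign
    covariate_effect_sds: dict = field(default_factory=lambda: {
        "age": 0.01, "bmi": 0.02, "sex": 0.2, "location": 0.2, "stage": 0.3})
    sigma_u: float = 2.0             # subject SD, log2 units
    sigma_e: float = 1.0             # residual SD, log2 units
    baseline_mean: float = 20.0      # intercept distribution, log2 units
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 2:
            problems.append("n_subjects must be >= 2")
        if self.n_features < 1:
            problems.append("n_features must be >= 1")
        for name in ("age_sd", "bmi_sd", "sigma_u", "sigma_e", "baseline_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not 0.0 <= self.p_female <= 1.0:
            problems.append("p_female must lie in [0, 1]")
        if not 0.0 <= self.frac_discriminative <= 1.0:
            problems.append("frac_discriminative must lie in [0, 1]")
        for name, probs, want in (("stage_probs", self.stage_probs, 4),
                                  ("location_probs", self.location_probs, 2)):
            if len(probs) != want:
                problems.append(f"{name} must have {want} entries")
            elif any(p < 0 or p > 1 for p in probs):
                problems.append(f"{name} entries must lie in [0, 1]")
            elif abs(sum(probs) - 1.0) > 1e-12:
                problems.append(f"{name} must sum to 1")
        lo, hi = self.effect_size_range
        if lo < 0 or hi < lo:
            problems.append("effect_size_range must be 0 <= low <= high")
        for k, v in self.covariate_effect_sds.items():
            if v < 0:
                problems.append(f"covariate_effect_sds[{k!r}] must be >= 0")
        if problems:
            raise ValueError("invalid CohortConfig: " + "; ".join(problems))


def default_fixed_effect_spec() -> FixedEffectSpec:
    """The full fixed-effect formula used for the generated cohorts."""
    return FixedEffectSpec(("class", "age", "bmi", "sex", "location", "stage"))


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None):
    """Draw one paired cohort; returns (dataset, truth record).

    The truth record holds every drawn parameter: ``coefficients`` is a
    feature x design-column frame matching the column naming of the design
    builder, ``u`` the subject x feature random intercepts,
    ``discriminative`` the set of features given a nonzero class effect.
    Fully reproducible from the seed.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    S, F = config.n_subjects, config.n_features

    subjects = [f"subj{(i + 1):04d}" for i in range(S)]
    age = rng.normal(config.age_mean, config.age_sd, S)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, S)
    sex = np.where(rng.random(S) < config.p_female, "female", "male")
    stage = rng.choice(STAGE_LEVELS, size=S, p=config.stage_probs)
    location = rng.choice(LOCATION_LEVELS, size=S, p=config.location_probs)

    # per-feature coefficients
    beta0 = rng.normal(config.baseline_mean, config.baseline_sd, F)
    n_disc = int(round(config.frac_discriminative * F))
    disc_idx = rng.choice(F, size=n_disc, replace=False)
    lo, hi = config.effect_size_range
    class_eff = np.zeros(F)
    class_eff[disc_idx] = (rng.uniform(lo, hi, n_disc)
                           * rng.choice([-1.0, 1.0], n_disc))
    sds = config.covariate_effect_sds
    b_age = rng.normal(0, sds.get("age", 0.0), F)
    b_bmi = rng.normal(0, sds.get("bmi", 0.0), F)
    b_sex = rng.normal(0, sds.get("sex", 0.0), F)
    b_loc = rng.normal(0, sds.get("location", 0.0), F)
    b_stage = rng.normal(0, sds.get("stage", 0.0), (3, F))  # II, III, IV

    u = rng.normal(0, config.sigma_u, (S, F))

    # two samples per subject, classes A then B
    sample_ids, subj_col, class_col = [], [], []
    for i, s in enumerate(subjects):
        for c in CLASS_LEVELS:
            sample_ids.append(f"{s}_{c}")
            subj_col.append(s)
            class_col.append(c)
    n = 2 * S
    subj_idx = np.repeat(np.arange(S), 2)
    is_b = np.array([c == "B" for c in class_col], dtype=float)

    sex_ind = (sex == "female").astype(float)[subj_idx]
    loc_ind = (location == "rectum").astype(float)[subj_idx]
    stage_ind = np.stack([(stage == lev).astype(float)[subj_idx]
                          for lev in STAGE_LEVELS[1:]])  # 3 x n

    lin = (beta0[None, :]
           + np.outer(is_b, class_eff)
           + np.outer(age[subj_idx], b_age)
           + np.outer(bmi[subj_idx], b_bmi)
           + np.outer(sex_ind, b_sex)
           + np.outer(loc_ind, b_loc)
           + np.tensordot(stage_ind.T, b_stage, axes=1))
    y = lin + u[subj_idx, :] + rng.normal(0, config.sigma_e, (n, F))

    feature_ids = [f"met{(j + 1):04d}" for j in range(F)]
    abundances = pd.DataFrame(y, index=pd.Index(sample_ids, name="sample_id"),
                              columns=feature_ids)
    covariates = pd.DataFrame({
        "age": age[subj_idx], "bmi": bmi[subj_idx],
        "sex": np.asarray(sex)[subj_idx],
        "location": np.asarray(location)[subj_idx],
        "stage": np.asarray(stage)[subj_idx],
    }, index=abundances.index)
    dataset = MetabolomicsDataset(
        abundances=abundances,
        subject=pd.Series(subj_col, index=abundances.index, name="subject"),
        class_label=pd.Series(class_col, index=abundances.index, name="class"),
        class_levels=CLASS_LEVELS,
        covariates=covariates,
        covariate_info={
            "age": CovariateInfo("age", "numeric"),
            "bmi": CovariateInfo("bmi", "numeric"),
            "sex": CovariateInfo("sex", "categorical", SEX_LEVELS),
            "location": CovariateInfo("location", "categorical",
                                      LOCATION_LEVELS),
            "stage": CovariateInfo("stage", "categorical", STAGE_LEVELS),
        })

    coef = pd.DataFrame({
        "(Intercept)": beta0, "class[B]": class_eff,
        "age": b_age, "bmi": b_bmi, "sex[female]": b_sex,
        "location[rectum]": b_loc,
        "stage[II]": b_stage[0], "stage[III]": b_stage[1],
        "stage[IV]": b_stage[2],
    }, index=pd.Index(feature_ids, name="feature"))
    truth = {
        "coefficients": coef,
        "discriminative": [feature_ids[j] for j in sorted(disc_idx)],
        "u": pd.DataFrame(u, index=subjects, columns=feature_ids),
        "sigma_u": config.sigma_u, "sigma_e": config.sigma_e,
        "config": config,
    }
    return dataset, truth


def null_cohort(config: CohortConfig | None = None, seed: int | None = None):
    """A cohort with the class effect forced to zero for every feature."""
    import dataclasses
    config = config or CohortConfig()
    config = dataclasses.replace(config, frac_discriminative=0.0)
    return generate_cohort(config, seed)
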