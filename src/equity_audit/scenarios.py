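"""Named synthetic-study scenarios used by the validation suite.

Each function returns a :class:`~equity_audit.synthetic_data.GeneratorConfig`
describing one study condition under which the estimators are exercised:

* ``study_population`` — the full audit-round emulation (submitted cohort
  size, under-18 records and missing follow-ups, so the exclusion pipeline
  has work to do).
* ``analysis_cohort`` — an already-filtered cohort (no exclusions trigger).
* ``direct_effect`` — one ethnicity category carries a direct latent harm
  chosen to give a true direct ATT of about +0.3 change units.
* ``uptake_mediation`` — the youngest age band takes up the two effective
  treatments less often but carries no direct effect: the score-only
  adjusted contrast is biased away from zero while the fully adjusted one
  is null (the audit's 18-24 pattern).  Physical-health interventions are
  rare here so full matching stays near-exact.
* ``null_effects`` — nothing affects the outcome; used for type-I-error
  calibration.  Uses mid-range initial scores and wide latent cutpoints so
  boundary clipping never binds and every fitted coefficient is truly null.
* ``regression_recovery`` — known coefficients including one negative
  demographic-by-treatment interaction, again clipping-free, so ordinal
  probit estimates are directly comparable to the generating values.
* ``interaction_power`` — the default outcome family with one injected
  interaction, for detection-power checks at audit scale.
"""

from __future__ import annotations

from .data_model import AgeGroup, Ethnicity, Gender
from .synthetic_data import GeneratorConfig

__all__ = [
    "study_population",
    "analysis_cohort",
    "direct_effect",
    "DIRECT_EFFECT_LEVEL",
    "uptake_mediation",
    "MEDIATION_LEVEL",
    "null_effects",
    "regression_recovery",
    "RECOVERY_TRUE_COEF",
    "interaction_power",
    "POWER_INTERACTION",
]

#: Wide latent thresholds (spacing 3): with mid-range initial scores the
#: candidate change stays within -1..+1 and the score bounds never clip.
WIDE_CUTPOINTS = (-10.5, -7.5, -4.5, -1.5, 1.5, 4.5, 7.5, 10.5)
MID_SCORE_PROBS = (0.0, 0.25, 0.50, 0.25, 0.0)

DIRECT_EFFECT_LEVEL = f"ethnicity:{Ethnicity.BLACK.value}"
MEDIATION_LEVEL = f"age_group:{AgeGroup.A18_24.value}"
POWER_INTERACTION = ("CBTp", f"gender:{Gender.MALE.value}")

#: Low uptake intercepts for the screened physical-health interventions in
#: the mediation scenario (offered only to at-risk subsets).
_RARE_PHYSICAL = {
    "Smoking": -2.2,
    "Alcohol": -2.5,
    "SubstanceMisuse": -2.3,
    "WeightGain": -2.2,
    "Hypertension": -2.8,
    "Diabetes": -2.9,
    "Dyslipidaemia": -3.0,
}


def study_population(n: int = 10557, seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(n=n, seed=seed)


def analysis_cohort(n: int = 6813, seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(n=n, seed=seed, under18_fraction=0.0,
                           missing_initial_rate=0.0, missing_followup_rate=0.0)


def direct_effect(n: int = 6813, seed: int = 0, gamma: float = 0.35) -> GeneratorConfig:
    """Direct latent harm on one ethnicity category (true direct ATT ~ +0.3)."""
    return analysis_cohort(n, seed).replace(
        gamma_demographic={DIRECT_EFFECT_LEVEL: gamma})


def uptake_mediation(n: int = 6813, seed: int = 0) -> GeneratorConfig:
    """Lower uptake of an effective treatment in the 18-24 band, zero direct effect.

    The mediated path runs through CBTp alone: the youngest band's uptake
    drops from ~40% to ~8% of a treatment with a strong latent benefit.
    Untreated pool support is wide (60% of non-members decline or are not
    offered CBTp), so full-mode matching finds near-exact counterparts and
    the adjusted contrast is null, while the score-only contrast inherits
    the whole mediated harm.
    """
    cfg = analysis_cohort(n, seed)
    intercepts = dict(cfg.uptake_intercepts)
    intercepts.update(_RARE_PHYSICAL)
    gamma_t = dict(cfg.gamma_treatment)
    gamma_t.update({"CBTp": -0.60})
    return cfg.replace(
        uptake_intercepts=intercepts,
        gamma_treatment=gamma_t,
        uptake_demo_effects={"CBTp": {MEDIATION_LEVEL: -2.0}},
        gamma_demographic={},
    )


def null_effects(n: int = 2000, seed: int = 0) -> GeneratorConfig:
    """No effects anywhere; clipping-free so every coefficient is truly null."""
    return analysis_cohort(n, seed).replace(
        initial_score_probs=MID_SCORE_PROBS,
        cutpoints=WIDE_CUTPOINTS,
        gamma0=0.0,
        gamma_score=0.0,
        gamma_treatment={},
        gamma_demographic={},
        gamma_interaction={},
    )


#: Generating coefficients of the recovery scenario, keyed by the design
#: column names that build_design produces under default reference levels.
RECOVERY_TRUE_COEF = {
    "initial_score": -0.15,
    "CBTp": -0.25,
    "Antipsychotic": -0.30,
    "SupportedEmployment": -0.20,
    f"gender[{Gender.MALE.value}]": 0.15,
    f"ethnicity[{Ethnicity.BLACK.value}]": 0.20,
    f"gender[{Gender.MALE.value}] x CBTp": -0.40,
}


def regression_recovery(n: int = 5000, seed: int = 0) -> GeneratorConfig:
    """Known coefficients, clipping-free: ordinal probit recovery is well-posed."""
    return analysis_cohort(n, seed).replace(
        initial_score_probs=MID_SCORE_PROBS,
        cutpoints=WIDE_CUTPOINTS,
        gamma0=0.0,
        gamma_score=-0.15,
        gamma_treatment={"CBTp": -0.25, "Antipsychotic": -0.30, "SupportedEmployment": -0.20},
        gamma_demographic={f"gender:{Gender.MALE.value}": 0.15,
                           f"ethnicity:{Ethnicity.BLACK.value}": 0.20},
        gamma_interaction={"CBTp": {f"gender:{Gender.MALE.value}": -0.40}},
    )


def interaction_power(n: int = 6813, seed: int = 0, gamma: float = -0.40) -> GeneratorConfig:
    """Default outcome family plus one injected interaction for power checks."""
    treatment, level = POWER_INTERACTION
    return analysis_cohort(n, seed).replace(
        gamma_interaction={treatment: {level: gamma}})
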