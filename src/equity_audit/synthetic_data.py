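"""Synthetic EIP-audit cohorts with known ground-truth effects.

The generator emulates the structure of the national audit's patient-level
table: demographic marginals, demographic-dependent treatment uptake, and an
ordinal 0-4 symptom score at two assessments.  Outcome change is produced by
a latent-index model,

    y* = g0 + g_s * s0 + sum_t g_t T_t + sum_d g_d x_d
         + sum_{d,t} g_{d,t} x_d T_t + eps,      eps ~ N(0, 1),

cut at fixed thresholds into a candidate change in {-4..+4} and then clipped
so the follow-up score s0 + delta stays inside 0-4.  Because the analysis
fits the same latent-probit family, parameter recovery is a well-posed test;
the clipping step is the one deliberate misspecification (scores are bounded
in real data too).

Uptake of treatment t is Bernoulli(logistic(a_t + sum_d b_{t,d} x_d)), which
provides the selection-bias channel: with b != 0 and g_d = 0 a demographic
group's unadjusted outcome contrast is biased away from zero while its true
direct effect is zero.

Demographic levels are addressed throughout by ``"variable:level"`` keys,
e.g. ``"ethnicity:Black or Black British"`` or ``"age_group:18-24"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    DEFAULT_TREATMENTS,
    AgeGroup,
    CohortTable,
    Ethnicity,
    Gender,
    UptakeStatus,
)

__all__ = ["GeneratorConfig", "TruthTable", "generate_cohort", "compute_truth"]

#: Latent thresholds mapping y* to integer candidate change -4..+4.
DEFAULT_CUTPOINTS: tuple[float, ...] = (-3.5, -2.5, -1.5, -0.5, 0.5, 1.5, 2.5, 3.5)

#: Audit-round demographic marginals (filtered-cohort shares; the small
#: non-binary, refused and unknown shares are plausible fill-ins since only
#: suppressed counts exist for them).
DEFAULT_GENDER_PROBS: dict[str, float] = {
    Gender.FEMALE.value: 0.3887,
    Gender.MALE.value: 0.6063,
    Gender.NON_BINARY_OTHER.value: 0.005,
}
DEFAULT_ETHNICITY_PROBS: dict[str, float] = {
    Ethnicity.ASIAN.value: 0.1315,
    Ethnicity.BLACK.value: 0.1331,
    Ethnicity.MIXED.value: 0.0385,
    Ethnicity.WHITE.value: 0.6417,
    Ethnicity.OTHER.value: 0.0308,
    Ethnicity.REFUSED.value: 0.0100,
    Ethnicity.UNKNOWN.value: 0.0144,
}
#: Chosen to give a cohort mean age near 30 (audit: mean 30, range 18-67).
DEFAULT_AGE_GROUP_PROBS: dict[str, float] = {
    AgeGroup.A18_24.value: 0.37,
    AgeGroup.A25_34.value: 0.35,
    AgeGroup.A35_44.value: 0.16,
    AgeGroup.A45_54.value: 0.08,
    AgeGroup.A55_69.value: 0.04,
}
_AGE_BIN_RANGES = {
    AgeGroup.A18_24.value: (18, 24),
    AgeGroup.A25_34.value: (25, 34),
    AgeGroup.A35_44.value: (35, 44),
    AgeGroup.A45_54.value: (45, 54),
    AgeGroup.A55_69.value: (55, 69),
}

DEFAULT_INITIAL_SCORE_PROBS: tuple[float, ...] = (0.04, 0.10, 0.22, 0.36, 0.28)

#: Per-treatment uptake intercepts (log-odds); moderate for the core
#: psychological/pharmacological treatments, low for screened physical-health
#: interventions which are only offered to at-risk subsets.
DEFAULT_UPTAKE_INTERCEPTS: dict[str, float] = {
    "CBTp": -0.4,
    "FamilyIntervention": -1.0,
    "Antipsychotic": 1.8,
    "Clozapine": -2.5,
    "SupportedEmployment": -1.2,
    "CarerIntervention": -1.1,
    "Smoking": -1.4,
    "Alcohol": -1.6,
    "SubstanceMisuse": -1.3,
    "WeightGain": -1.0,
    "Hypertension": -2.2,
    "Diabetes": -2.3,
    "Dyslipidaemia": -2.4,
}

DEFAULT_NONUPTAKE_PROBS: dict[str, float] = {
    UptakeStatus.NOT_OFFERED.value: 0.50,
    UptakeStatus.REFUSED.value: 0.25,
    UptakeStatus.NOT_ELIGIBLE.value: 0.15,
    UptakeStatus.WAITING.value: 0.10,
}

#: Latent outcome coefficients: strong dependence on initial score (higher
#: initial severity leaves more room to improve) and modest benefits for the
#: main treatments, so that every group improves on average, as in the audit.
DEFAULT_GAMMA_TREATMENT: dict[str, float] = {
    "CBTp": -0.12,
    "FamilyIntervention": -0.08,
    "Antipsychotic": -0.20,
    "Clozapine": -0.05,
    "SupportedEmployment": -0.13,
    "CarerIntervention": -0.04,
    "WeightGain": -0.05,
}


class ConfigError(ValueError):
    """Degenerate or inconsistent generator configuration."""


def _check_probs(name: str, probs: Mapping[str, float] | Sequence[float]) -> None:
    vals = list(probs.values()) if isinstance(probs, Mapping) else list(probs)
    if len(vals) == 0:
        raise ConfigError(f"{name}: empty category set")
    if min(vals) < 0:
        raise ConfigError(f"{name}: negative probability")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {sum(vals)}, not 1")


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Noise sd is fixed at 1 (probit identification).  ``uptake_demo_effects``
    and the three ``gamma_*`` maps are keyed as described in the module
    docstring; anything not listed is zero.
    """

    n: int = 10557
    seed: int = 0
    gender_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENDER_PROBS))
    ethnicity_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ETHNICITY_PROBS))
    age_group_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_GROUP_PROBS))
    initial_score_probs: tuple[float, ...] = DEFAULT_INITIAL_SCORE_PROBS
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    uptake_intercepts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UPTAKE_INTERCEPTS))
    #: treatment -> {"variable:level" -> log-odds shift}
    uptake_demo_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    nonuptake_status_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NONUPTAKE_PROBS))
    gamma0: float = 0.2
    gamma_score: float = -0.35
    gamma_treatment: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMA_TREATMENT))
    #: "variable:level" -> latent shift
    gamma_demographic: dict[str, float] = field(default_factory=dict)
    #: treatment -> {"variable:level" -> latent interaction}
    gamma_interaction: dict[str, dict[str, float]] = field(default_factory=dict)
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    noise: str = "normal"  # "logistic" available for misspecification checks
    under18_fraction: float = 0.03
    missing_initial_rate: float = 0.05
    missing_followup_rate: float = 0.30

    def validate(self) -> None:
        if self.n <= 0:
            raise ConfigError("n must be positive")
        _check_probs("gender_probs", self.gender_probs)
        _check_probs("ethnicity_probs", self.ethnicity_probs)
        _check_probs("age_group_probs", self.age_group_probs)
        _check_probs("initial_score_probs", self.initial_score_probs)
        _check_probs("nonuptake_status_probs", self.nonuptake_status_probs)
        if len(self.initial_score_probs) != 5:
            raise ConfigError("initial_score_probs must have 5 entries (scores 0-4)")
        if len(self.treatments) == 0:
            raise ConfigError("empty treatment set")
        if len(self.cutpoints) != 8 or np.any(np.diff(self.cutpoints) <= 0):
            raise ConfigError("cutpoints must be 8 strictly increasing thresholds")
        if self.noise not in ("normal", "logistic"):
            raise ConfigError(f"unknown noise family {self.noise!r}")
        for t in self.uptake_intercepts:
            if t not in self.treatments:
                raise ConfigError(f"uptake intercept for unknown treatment {t!r}")
        for rate in (self.under18_fraction, self.missing_initial_rate, self.missing_followup_rate):
            if not 0 <= rate < 1:
                raise ConfigError("rates must be in [0, 1)")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path_or_stream) -> "GeneratorConfig":
        if hasattr(path_or_stream, "read"):
            d = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                d = yaml.safe_load(fh)
        d = d or {}
        for key in ("initial_score_probs", "treatments", "cutpoints"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground-truth estimands of a generator config, by Monte-Carlo oracle.

    ``att_demographic`` holds, per ``"variable:level"`` key, the direct ATT of
    category membership on outcome change: mean over members of the change
    with the level's latent (and interaction) contributions present minus the
    change with them removed, holding every other covariate, the realised
    treatment uptake and the latent noise draw fixed (common random numbers).
    ``att_treatment`` is the analogous effect of each treatment among its
    takers.  ``interaction`` copies the latent interaction coefficients (the
    truth for the regression moderator analysis).
    """

    att_demographic: dict[str, float]
    att_demographic_se: dict[str, float]
    att_treatment: dict[str, float]
    att_treatment_se: dict[str, float]
    interaction: dict[str, dict[str, float]]
    oracle_n: int
    oracle_seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("demographic", k, v, self.att_demographic_se[k])
                for k, v in self.att_demographic.items()]
        rows += [("treatment", k, v, self.att_treatment_se[k])
                 for k, v in self.att_treatment.items()]
        return pd.DataFrame(rows, columns=["kind", "name", "att", "mc_se"])


def _level_keys(config: GeneratorConfig) -> dict[str, list[str]]:
    return {
        "gender": list(config.gender_probs),
        "ethnicity": list(config.ethnicity_probs),
        "age_group": list(config.age_group_probs),
    }


def _membership(variable: str, level: str, demo: dict[str, np.ndarray]) -> np.ndarray:
    return demo[variable] == level


def _draw_categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    # canonical (sorted) label order: draws depend on the config's content,
    # not on dict insertion order, so YAML round-trips stay byte-identical
    labels = np.array(sorted(probs.keys()), dtype=object)
    p = np.array([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


def _latent_to_delta(latent: np.ndarray, s0: np.ndarray, cutpoints: Sequence[float]) -> np.ndarray:
    """Cut the latent index into a candidate change and clip into range."""
    candidate = np.digitize(latent, np.asarray(cutpoints)) - 4  # -4..+4
    followup = np.clip(s0 + candidate, 0, 4)
    return followup - s0


class _SimState:
    """Covariates, uptake and noise for one simulated cohort (pre-outcome)."""

    def __init__(self, config: GeneratorConfig, n: int, rng: np.random.Generator):
        self.demo = {
            "gender": _draw_categorical(rng, config.gender_probs, n),
            "ethnicity": _draw_categorical(rng, config.ethnicity_probs, n),
            "age_group": _draw_categorical(rng, config.age_group_probs, n),
        }
        self.s0 = rng.choice(5, size=n, p=np.asarray(config.initial_score_probs))
        # uptake: Bernoulli(logistic(a_t + sum shifts)), one uniform per unit
        self.uptake = {}
        for t in config.treatments:
            eta = np.full(n, config.uptake_intercepts.get(t, 0.0))
            for key, shift in sorted(config.uptake_demo_effects.get(t, {}).items()):
                var, level = key.split(":", 1)
                eta = eta + shift * _membership(var, level, self.demo)
            p = 1.0 / (1.0 + np.exp(-eta))
            self.uptake[t] = (rng.random(n) < p).astype(np.int8)
        if config.noise == "normal":
            self.eps = rng.standard_normal(n)
        else:
            # logistic noise rescaled to unit variance (misspecification switch)
            self.eps = rng.logistic(0.0, np.sqrt(3.0) / np.pi, n)

    def latent(self, config: GeneratorConfig, drop_level: str | None = None) -> np.ndarray:
        """Latent index; optionally with one level's direct+interaction terms removed."""
        y = config.gamma0 + config.gamma_score * self.s0 + self.eps
        for t in config.treatments:
            g = config.gamma_treatment.get(t, 0.0)
            y = y + g * self.uptake[t]
        for key, g in sorted(config.gamma_demographic.items()):
            if key == drop_level:
                continue
            var, level = key.split(":", 1)
            y = y + g * _membership(var, level, self.demo)
        for t, terms in sorted(config.gamma_interaction.items()):
            for key, g in sorted(terms.items()):
                if key == drop_level:
                    continue
                var, level = key.split(":", 1)
                y = y + g * (_membership(var, level, self.demo) & (self.uptake[t] == 1))
        return y

    def delta(self, config: GeneratorConfig, drop_level: str | None = None) -> np.ndarray:
        return _latent_to_delta(self.latent(config, drop_level), self.s0, config.cutpoints)


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> CohortTable:
    """Draw one synthetic cohort; byte-identical given the same config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n
    state = _SimState(config, n, rng)

    # ages: under-18 records exist only to exercise the exclusion pipeline
    under18 = rng.random(n) < config.under18_fraction
    age = np.empty(n, dtype=np.int64)
    age[under18] = rng.integers(16, 18, size=int(under18.sum()))
    adult = ~under18
    for level, (lo, hi) in _AGE_BIN_RANGES.items():
        in_bin = adult & (state.demo["age_group"] == level)
        age[in_bin] = rng.integers(lo, hi + 1, size=int(in_bin.sum()))

    delta = state.delta(config)
    followup = np.clip(state.s0 + delta, 0, 4)

    status_labels = np.array(sorted(config.nonuptake_status_probs.keys()), dtype=object)
    status_p = np.array([config.nonuptake_status_probs[k] for k in status_labels], dtype=float)
    status_p = status_p / status_p.sum()

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "age": age,
            "gender": state.demo["gender"],
            "ethnicity": state.demo["ethnicity"],
            "honos6_initial": pd.array(state.s0, dtype="Int64"),
            "honos6_followup": pd.array(followup, dtype="Int64"),
        }
    )
    for t in config.treatments:
        taken = state.uptake[t] == 1
        col = np.empty(n, dtype=object)
        col[taken] = UptakeStatus.TAKEN_UP.value
        n_not = int((~taken).sum())
        col[~taken] = rng.choice(status_labels, size=n_not, p=status_p)
        df[f"uptake_{t}"] = col

    if config.missing_initial_rate > 0:
        miss = rng.random(n) < config.missing_initial_rate
        df.loc[miss, "honos6_initial"] = pd.NA
    if config.missing_followup_rate > 0:
        miss = rng.random(n) < config.missing_followup_rate
        df.loc[miss, "honos6_followup"] = pd.NA

    return CohortTable(df, tuple(config.treatments))


def compute_truth(config: GeneratorConfig, oracle_n: int = 100_000,
                  oracle_seed: int = 20_240_101) -> TruthTable:
    """Brute-force Monte-Carlo evaluation of every ground-truth estimand.

    Simulates ``oracle_n`` analysis-ready units (no missingness, adults only)
    and toggles one demographic level or one treatment at a time under common
    random numbers; see :class:`TruthTable` for the estimand definitions.
    """
    config.validate()
    rng = np.random.default_rng(oracle_seed)
    state = _SimState(config, oracle_n, rng)
    base = state.delta(config)

    att_d: dict[str, float] = {}
    att_d_se: dict[str, float] = {}
    interaction_keys = {k for terms in config.gamma_interaction.values() for k in terms}
    for variable, levels in _level_keys(config).items():
        for level in levels:
            key = f"{variable}:{level}"
            members = _membership(variable, level, state.demo)
            if not members.any():
                continue
            if key in config.gamma_demographic or key in interaction_keys:
                contrast = (base - state.delta(config, drop_level=key))[members]
            else:  # level has no direct or interaction term: exactly zero
                contrast = np.zeros(int(members.sum()))
            att_d[key] = float(contrast.mean())
            att_d_se[key] = float(contrast.std(ddof=1) / np.sqrt(len(contrast))) if len(contrast) > 1 else 0.0

    att_t: dict[str, float] = {}
    att_t_se: dict[str, float] = {}
    for t in config.treatments:
        takers = state.uptake[t] == 1
        if not takers.any():
            att_t[t] = 0.0
            att_t_se[t] = 0.0
            continue
        saved = state.uptake[t]
        state.uptake[t] = np.zeros_like(saved)
        off = state.delta(config)
        state.uptake[t] = saved
        contrast = (base - off)[takers]
        att_t[t] = float(contrast.mean())
        att_t_se[t] = float(contrast.std(ddof=1) / np.sqrt(len(contrast))) if len(contrast) > 1 else 0.0

    return TruthTable(
        att_demographic=att_d,
        att_demographic_se=att_d_se,
        att_treatment=att_t,
        att_treatment_se=att_t_se,
        interaction={t: dict(v) for t, v in config.gamma_interaction.items()},
        oracle_n=oracle_n,
        oracle_seed=oracle_seed,
    )
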