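"""Unadjusted outcome-change summaries by demographic group and treatment take-up.

For each category the summary reports the group size, mean initial and
follow-up HoNOS item 6 scores, the mean outcome change (negative change =
symptom improvement) and a seeded percentile-bootstrap 95% confidence
interval of the mean change.  Groups are resampled independently; a
whole-cohort resampling mode is available for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SUPPRESSION_THRESHOLD, CohortTable, UptakeStatus

logger = logging.getLogger("equity_audit")

__all__ = ["GroupSummary", "bootstrap_ci", "group_outcomes", "summaries_frame"]

CATEGORY_TYPES = ("gender", "age_group", "ethnicity", "treatment")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean_initial: float
    mean_followup: float
    mean_change: float
    ci_low: float
    ci_high: float


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95,
                 seed=None) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``values``.

    Resamples with replacement at the observed sample size; reproducible for
    a given seed (which may be an int, a Generator or a SeedSequence).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if x.size == 1 or np.ptp(x) == 0:
        return (float(x[0]), float(x[0]))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))


def _grouping(cohort: CohortTable, category_type: str, treatment: str | None) -> pd.Series:
    if category_type in ("gender", "ethnicity", "age_group"):
        return cohort.demographic_series(category_type)
    if category_type == "treatment":
        if treatment is None:
            raise ValueError("treatment grouping requires a treatment name")
        if treatment not in cohort.treatments:
            raise ValueError(f"unknown treatment {treatment!r}")
        return cohort.df[f"uptake_{treatment}"]
    raise ValueError(f"unknown category_type {category_type!r}; one of {CATEGORY_TYPES}")


def group_outcomes(cohort: CohortTable, category_type: str, treatment: str | None = None,
                   n_boot: int = 1000, level: float = 0.95, seed=None,
                   resample: str = "within_group",
                   suppress_threshold: int = SUPPRESSION_THRESHOLD) -> list[GroupSummary]:
    """Outcome-change summary per category of one grouping variable.

    For ``category_type="treatment"`` the categories are the fine uptake
    statuses of ``treatment`` (taken up / refused / waiting / not offered /
    not eligible / unknown), not the binary encoding.  Categories with fewer
    than ``suppress_threshold`` members are suppressed (logged, not reported).

    ``resample`` chooses the bootstrap scheme: ``"within_group"`` (default)
    resamples each group independently; ``"cohort"`` resamples the whole
    cohort and regroups inside every resample.
    """
    if resample not in ("within_group", "cohort"):
        raise ValueError(f"unknown resample mode {resample!r}")
    groups = _grouping(cohort, category_type, treatment)
    delta = cohort.outcome_change().to_numpy()
    initial = cohort.df["honos6_initial"].astype(float).to_numpy()
    followup = cohort.df["honos6_followup"].astype(float).to_numpy()

    if category_type == "treatment":
        order = [s.value for s in UptakeStatus]
        levels = [v for v in order if (groups == v).any()]
    else:
        levels = sorted(pd.unique(groups))

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    child_seeds = ss.spawn(len(levels))
    garr = groups.to_numpy()

    cohort_boot: dict[str, tuple[float, float]] = {}
    if resample == "cohort":
        rng = np.random.default_rng(ss.spawn(1)[0])
        alpha = (1.0 - level) / 2.0
        acc: dict[str, list[float]] = {str(lev): [] for lev in levels}
        for _ in range(n_boot):
            idx = rng.integers(0, delta.size, delta.size)
            g, d = garr[idx], delta[idx]
            for lev in levels:
                m = g == lev
                if m.any():
                    acc[str(lev)].append(d[m].mean())
        for lev, means in acc.items():
            lo, hi = np.quantile(np.asarray(means), [alpha, 1.0 - alpha])
            cohort_boot[lev] = (float(lo), float(hi))

    out: list[GroupSummary] = []
    for lev, child in zip(levels, child_seeds):
        mask = garr == lev
        n = int(mask.sum())
        if n < suppress_threshold:
            logger.info("suppressed %s=%r summary (n=%d < %d)",
                        category_type, lev, n, suppress_threshold)
            continue
        d = delta[mask]
        if resample == "cohort":
            lo, hi = cohort_boot[str(lev)]
        else:
            lo, hi = bootstrap_ci(d, n_boot=n_boot, level=level,
                                  seed=np.random.default_rng(child))
        out.append(GroupSummary(
            group=str(lev), n=n,
            mean_initial=float(initial[mask].mean()),
            mean_followup=float(followup[mask].mean()),
            mean_change=float(d.mean()),
            ci_low=lo, ci_high=hi,
        ))
    return out


def summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Tabular (CSV-ready) form of a list of group summaries."""
    return pd.DataFrame(
        [(s.group, s.n, s.mean_initial, s.mean_followup, s.mean_change, s.ci_low, s.ci_high)
         for s in summaries],
        columns=["group", "n", "mean_initial", "mean_followup", "mean_change", "ci_low", "ci_high"],
    )
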