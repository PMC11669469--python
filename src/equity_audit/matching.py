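"""Moderation effects of demographic categories via 1-nearest-neighbour matching.

Each member of an inspected demographic category (the *target* group) is
matched, with replacement, to its nearest non-member (the *pool*).  The
moderation effect is the mean outcome change of the group minus the mean
outcome change of the matched comparison set, in HoNOS item 6 change units;
positive values mean less improvement (worse outcomes) for the group.  This
is the average effect of category membership on the members (an ATT); an ATE
mode matching in both directions is available.

Two adjustment modes mirror the audit analysis:

* ``initial_score`` — match on the initial assessment score alone;
* ``full`` — match on initial score, every binary treatment-uptake variable
  and every encoded demographic variable except the variable being inspected
  (the whole variable is excluded, not just the inspected level).

Covariates are one-hot/binary plus the integer initial score, and the
default distance sums coordinate-wise absolute differences — Hamming
distance on the binary block, with each point of initial-score difference
costing as much as one binary mismatch.  (Down-weighting the score makes
score mismatches cheap, and because outcome change depends strongly on the
initial score that induces measurable matching bias.)  With such coarse
covariates many pool units
are exactly equidistant, so the moderation estimator breaks ties uniformly
at random (seeded); the raw :func:`match_nearest` primitive instead uses the
deterministic lowest-index rule.  Confidence intervals re-run the matching
inside every bootstrap resample of the cohort (pair-level resampling is
available as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .data_model import SUPPRESSION_THRESHOLD, CohortTable, DEMOGRAPHIC_VARIABLES

logger = logging.getLogger("equity_audit")

__all__ = [
    "MatchSpec",
    "MatchResult",
    "EffectEstimate",
    "matching_covariates",
    "match_nearest",
    "moderation_effect",
    "moderation_table",
    "effects_frame",
    "NearestNeighborMatcher",
    "ModerationEffect",
]

_METRIC_TO_CDIST = {"hamming": "cityblock", "euclidean": "euclidean"}
#: Hamming-style distances on this encoding are integer multiples of 1, so a
#: jitter below that gap breaks exact ties without reordering distinct ones.
_JITTER = {"hamming": 0.01, "euclidean": 1e-9}

MODES = ("initial_score", "full")


@dataclass(frozen=True)
class MatchSpec:
    """Which category is inspected and how the comparison set is adjusted."""

    variable: str
    level: str
    mode: str = "full"
    metric: str = "hamming"

    def __post_init__(self) -> None:
        if self.variable not in DEMOGRAPHIC_VARIABLES:
            raise ValueError(f"variable must be one of {DEMOGRAPHIC_VARIABLES}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.metric not in _METRIC_TO_CDIST:
            raise ValueError(f"metric must be one of {tuple(_METRIC_TO_CDIST)}")


@dataclass
class MatchResult:
    """One pool match per target; pool units may be reused (resampling)."""

    target_index: np.ndarray
    pool_index: np.ndarray
    distance: np.ndarray

    @property
    def pairs(self) -> list[tuple[int, int, float]]:
        return list(zip(self.target_index.tolist(), self.pool_index.tolist(),
                        self.distance.tolist()))

    @property
    def multiplicity(self) -> dict[int, int]:
        """How often each pool unit was used as a match."""
        idx, counts = np.unique(self.pool_index, return_counts=True)
        return dict(zip(idx.tolist(), counts.tolist()))


@dataclass
class EffectEstimate:
    variable: str
    level: str
    mode: str
    n_group: int
    n_pool: int
    effect: float
    ci_low: float
    ci_high: float
    suppressed: bool = False


def matching_covariates(cohort: CohortTable, mode: str,
                        inspected_variable: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Covariate matrix for matching, plus column names.

    ``initial_score`` mode: the integer initial score alone.  ``full`` mode:
    initial score, binary uptake per treatment, and a full one-hot encoding
    of each demographic variable other than ``inspected_variable``; under
    the city-block/Hamming distance one point of score difference then costs
    as much as one binary mismatch.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    score = cohort.df["honos6_initial"].astype(float).to_numpy()
    cols = [score]
    names = ["initial_score"]
    if mode == "full":
        if inspected_variable is None:
            raise ValueError("full mode requires the inspected variable")
        upt = cohort.uptake_binary()
        for t in cohort.treatments:
            cols.append(upt[t].to_numpy(dtype=float))
            names.append(f"uptake[{t}]")
        for var in DEMOGRAPHIC_VARIABLES:
            if var == inspected_variable:
                continue
            series = cohort.demographic_series(var)
            for lev in sorted(pd.unique(series)):
                cols.append((series == lev).to_numpy(dtype=float))
                names.append(f"{var}[{lev}]")
    X = np.column_stack(cols).astype(np.float32)
    return X, names


def _distance_matrix(targets: np.ndarray, pool: np.ndarray, metric: str,
                     dtype=np.float32) -> np.ndarray:
    return cdist(np.asarray(targets, dtype=np.float64),
                 np.asarray(pool, dtype=np.float64),
                 metric=_METRIC_TO_CDIST[metric]).astype(dtype)


def match_nearest(targets, pool, metric: str = "hamming",
                  target_ids=None, pool_ids=None,
                  tie_break: str = "lowest", rng=None) -> MatchResult:
    """Match each target to its nearest pool unit (with replacement).

    Ties are broken deterministically to the lowest pool index by default
    (``tie_break="random"`` breaks them uniformly at random, seeded through
    ``rng``).  If ``target_ids``/``pool_ids`` are given, a target is never
    matched to a pool entry carrying its own id (self-match exclusion for
    resampled data containing duplicates of the same record).
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    pool = np.atleast_2d(np.asarray(pool, dtype=float))
    if pool.shape[0] == 0:
        raise ValueError("pool is empty")
    if targets.shape[1] != pool.shape[1]:
        raise ValueError(
            f"covariate length mismatch: targets {targets.shape[1]}, pool {pool.shape[1]}")
    if metric not in _METRIC_TO_CDIST:
        raise ValueError(f"metric must be one of {tuple(_METRIC_TO_CDIST)}")
    if tie_break not in ("lowest", "random"):
        raise ValueError("tie_break must be 'lowest' or 'random'")

    D = _distance_matrix(targets, pool, metric, dtype=np.float64)
    if target_ids is not None and pool_ids is not None:
        t_ids = np.asarray(target_ids)
        p_ids = np.asarray(pool_ids)
        same = t_ids[:, None] == p_ids[None, :]
        if same.all(axis=1).any():
            raise ValueError("a target has no admissible pool unit (all self-matches)")
        D = np.where(same, np.inf, D)
    if tie_break == "random":
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        D = D + rng.random(D.shape, dtype=np.float32) * _JITTER[metric]
    m = D.argmin(axis=1)
    return MatchResult(
        target_index=np.arange(targets.shape[0]),
        pool_index=m,
        distance=D[np.arange(targets.shape[0]), m].astype(float),
    )


def _weighted_matched_contrast(D: np.ndarray, dg: np.ndarray, dp: np.ndarray,
                               wg: np.ndarray, wp: np.ndarray,
                               rng: np.random.Generator, jitter: float) -> float:
    """Group-vs-matched contrast within one (possibly resampled) data-set.

    ``wg``/``wp`` are resample multiplicities of the original group and pool
    units; zero-weight units are absent.  Ties break uniformly at random.
    ``D`` is either float32, or uint16 integer distances shifted left 8 bits
    so a sub-gap random byte breaks ties (fast path for Hamming distances).
    """
    rows = np.flatnonzero(wg > 0)
    cols = np.flatnonzero(wp > 0)
    sub = D[np.ix_(rows, cols)]
    if not (wg[rows] == 1).all():
        # every resampled copy of a target gets its own independent tie draw;
        # collapsing duplicates into one weighted draw would correlate their
        # matches and inflate the bootstrap variance
        sub = np.repeat(sub, wg[rows], axis=0)
    if sub.dtype == np.uint16:
        sub += rng.integers(0, 256, sub.shape, dtype=np.uint16)
    else:
        sub += rng.random(sub.shape, dtype=np.float32) * jitter
    m = sub.argmin(axis=1)
    rep = np.repeat(rows, wg[rows])
    return float(dg[rep].mean() - dp[cols][m].mean())


def _score_only_contrast(sg: np.ndarray, sp: np.ndarray, dg: np.ndarray, dp: np.ndarray,
                         wg: np.ndarray, wp: np.ndarray,
                         rng: np.random.Generator) -> float:
    """Fast path for 1-D (initial-score-only) matching.

    Equivalent in distribution to the generic path: each target picks
    uniformly at random among the pool units at minimal score distance.
    """
    rows = np.flatnonzero(wg > 0)
    cols = np.flatnonzero(wp > 0)
    rep = np.repeat(rows, wg[rows])  # one entry per resampled target copy
    pool_scores = sp[cols]
    matched = np.empty(rep.size)
    for s in np.unique(sg[rep]):
        stratum = sg[rep] == s
        gaps = np.abs(pool_scores - s)
        cand = np.flatnonzero(gaps == gaps.min())
        pick = cand[rng.integers(0, cand.size, int(stratum.sum()))]
        matched[stratum] = dp[cols][pick]
    return float(dg[rep].mean() - matched.mean())


def moderation_effect(cohort: CohortTable, spec: MatchSpec, n_boot: int = 1000,
                      seed=None, bootstrap: str = "rematch", estimand: str = "att",
                      level: float = 0.95,
                      suppress_threshold: int = SUPPRESSION_THRESHOLD) -> EffectEstimate:
    """Moderation effect of one demographic category with a bootstrap 95% CI.

    The point estimate matches on the full sample; ``bootstrap="rematch"``
    (default) resamples the cohort with replacement and re-runs the matching
    inside every resample, ``"pairs"`` resamples the matched pair differences
    of the point estimate.  ``estimand="ate"`` additionally matches
    non-members to members and weights the two directions by group size.
    """
    if bootstrap not in ("rematch", "pairs"):
        raise ValueError("bootstrap must be 'rematch' or 'pairs'")
    if estimand not in ("att", "ate"):
        raise ValueError("estimand must be 'att' or 'ate'")
    if bootstrap == "pairs" and estimand == "ate":
        raise ValueError("pairs bootstrap supports the att estimand only")

    groups = cohort.demographic_series(spec.variable)
    gmask = (groups == spec.level).to_numpy()
    n_g, n_p = int(gmask.sum()), int((~gmask).sum())
    if n_g == 0 or n_p == 0:
        logger.warning("moderation %s=%r suppressed: empty %s", spec.variable, spec.level,
                       "group" if n_g == 0 else "pool")
        return EffectEstimate(spec.variable, spec.level, spec.mode, n_g, n_p,
                              float("nan"), float("nan"), float("nan"), suppressed=True)
    if n_p < 5 * n_g:
        logger.warning("moderation %s=%r: pool (n=%d) smaller than 5x group (n=%d)",
                       spec.variable, spec.level, n_p, n_g)

    X, _ = matching_covariates(cohort, spec.mode,
                               inspected_variable=spec.variable if spec.mode == "full" else None)
    delta = cohort.outcome_change().to_numpy()
    if np.isnan(delta).any():
        raise ValueError("cohort has missing outcomes; apply exclusions first")
    dg, dp = delta[gmask], delta[~gmask]
    Xg, Xp = X[gmask], X[~gmask]
    rng = np.random.default_rng(seed)
    jitter = _JITTER[spec.metric]
    score_only = X.shape[1] == 1

    if score_only:
        sg, sp = Xg[:, 0], Xp[:, 0]
        D = DT = None
    else:
        D = _distance_matrix(Xg, Xp, spec.metric)
        if spec.metric == "hamming" and float(D.max(initial=0.0)) < 255:
            # exact integer distances: quantize so a random byte breaks ties
            D = (np.rint(D).astype(np.uint16)) << 8
        DT = D.T if estimand == "ate" else None

    ones_g = np.ones(n_g, dtype=np.int64)
    ones_p = np.ones(n_p, dtype=np.int64)

    def estimate(wg: np.ndarray, wp: np.ndarray) -> float:
        if score_only:
            att = _score_only_contrast(sg, sp, dg, dp, wg, wp, rng)
            if estimand == "att":
                return att
            atc = -_score_only_contrast(sp, sg, dp, dg, wp, wg, rng)
        else:
            att = _weighted_matched_contrast(D, dg, dp, wg, wp, rng, jitter)
            if estimand == "att":
                return att
            atc = -_weighted_matched_contrast(DT, dp, dg, wp, wg, rng, jitter)
        sg_, sp_ = float(wg.sum()), float(wp.sum())
        return (sg_ * att + sp_ * atc) / (sg_ + sp_)

    alpha = (1.0 - level) / 2.0
    n = n_g + n_p
    g_pos = np.flatnonzero(gmask)
    p_pos = np.flatnonzero(~gmask)
    if bootstrap == "rematch":
        point = estimate(ones_g, ones_p)
        effs = np.empty(n_boot)
        for b in range(n_boot):
            cnt = np.bincount(rng.integers(0, n, n), minlength=n)
            wg, wp = cnt[g_pos], cnt[p_pos]
            if wg.sum() == 0 or wp.sum() == 0:
                effs[b] = np.nan
                continue
            effs[b] = estimate(wg, wp)
        effs = effs[~np.isnan(effs)]
    else:
        # pairs mode: the CI resamples the point estimate's own matched pairs
        if score_only:
            match = match_nearest(Xg, Xp, metric=spec.metric, tie_break="random", rng=rng)
        else:
            jit = (rng.integers(0, 256, D.shape, dtype=np.uint16) if D.dtype == np.uint16
                   else rng.random(D.shape, dtype=np.float32) * jitter)
            match = MatchResult(np.arange(n_g), (D + jit).argmin(axis=1), np.empty(n_g))
        diffs = dg - dp[match.pool_index]
        point = float(diffs.mean())
        idx = rng.integers(0, n_g, size=(n_boot, n_g))
        effs = diffs[idx].mean(axis=1)
    lo, hi = np.quantile(effs, [alpha, 1.0 - alpha])

    return EffectEstimate(spec.variable, spec.level, spec.mode, n_g, n_p,
                          point, float(lo), float(hi),
                          suppressed=n_g < suppress_threshold)


def moderation_table(cohort: CohortTable, n_boot: int = 1000, seed=None,
                     modes: tuple[str, ...] = ("initial_score", "full"),
                     metric: str = "hamming", bootstrap: str = "rematch",
                     suppress_threshold: int = SUPPRESSION_THRESHOLD) -> list[EffectEstimate]:
    """One moderation effect per observed demographic level per mode.

    Levels with fewer than ``suppress_threshold`` members are reported as
    suppressed rows (no numbers), mirroring the low-count masking rule.
    Seeding is stable per (variable, level, mode) so single categories can be
    re-run in isolation with identical results.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    out: list[EffectEstimate] = []
    tasks = []
    for variable in DEMOGRAPHIC_VARIABLES:
        series = cohort.demographic_series(variable)
        for lev in sorted(pd.unique(series)):
            for mode in modes:
                tasks.append((variable, str(lev), mode))
    for (variable, lev, mode), child in zip(tasks, ss.spawn(len(tasks))):
        n_g = int((cohort.demographic_series(variable) == lev).sum())
        if n_g < suppress_threshold:
            logger.info("suppressed moderation row %s=%r (n=%d < %d)",
                        variable, lev, n_g, suppress_threshold)
            out.append(EffectEstimate(variable, lev, mode, n_g, cohort.n - n_g,
                                      float("nan"), float("nan"), float("nan"),
                                      suppressed=True))
            continue
        spec = MatchSpec(variable, lev, mode=mode, metric=metric)
        out.append(moderation_effect(cohort, spec, n_boot=n_boot,
                                     seed=np.random.default_rng(child),
                                     bootstrap=bootstrap,
                                     suppress_threshold=suppress_threshold))
    return out


def effects_frame(effects: list[EffectEstimate]) -> pd.DataFrame:
    """Moderation table as a CSV-ready frame."""
    return pd.DataFrame(
        [(e.variable, e.level, e.mode, e.n_group, e.effect, e.ci_low, e.ci_high, e.suppressed)
         for e in effects],
        columns=["variable", "level", "mode", "n", "effect", "ci_low", "ci_high", "suppressed"],
    )


class NearestNeighborMatcher(BaseEstimator):
    """sklearn-style wrapper over :func:`match_nearest`.

    ``fit`` stores the pool; ``match`` returns (pool_indices, distances) of
    the nearest pool unit per query row.
    """

    def __init__(self, metric: str = "hamming", tie_break: str = "lowest",
                 random_state=None):
        self.metric = metric
        self.tie_break = tie_break
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            raise ValueError("pool is empty")
        self.pool_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def match(self, X) -> tuple[np.ndarray, np.ndarray]:
        if not hasattr(self, "pool_"):
            raise ValueError("matcher is not fitted")
        res = match_nearest(X, self.pool_, metric=self.metric,
                            tie_break=self.tie_break,
                            rng=np.random.default_rng(self.random_state))
        return res.pool_index, res.distance


class ModerationEffect(BaseEstimator):
    """sklearn-style estimator of one category's moderation effect.

    Parameters mirror :func:`moderation_effect`; after ``fit(cohort)`` the
    attributes ``effect_``, ``ci_``, ``n_group_`` and ``suppressed_`` hold
    the estimate.
    """

    def __init__(self, variable: str = "ethnicity", level: str = "", mode: str = "full",
                 metric: str = "hamming", n_boot: int = 1000, bootstrap: str = "rematch",
                 estimand: str = "att", random_state=None):
        self.variable = variable
        self.level = level
        self.mode = mode
        self.metric = metric
        self.n_boot = n_boot
        self.bootstrap = bootstrap
        self.estimand = estimand
        self.random_state = random_state

    def fit(self, cohort: CohortTable, y=None):
        spec = MatchSpec(self.variable, self.level, mode=self.mode, metric=self.metric)
        est = moderation_effect(cohort, spec, n_boot=self.n_boot,
                                seed=self.random_state, bootstrap=self.bootstrap,
                                estimand=self.estimand)
        self.effect_ = est.effect
        self.ci_ = (est.ci_low, est.ci_high)
        self.n_group_ = est.n_group
        self.n_pool_ = est.n_pool
        self.suppressed_ = est.suppressed
        self.estimate_ = est
        return self
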