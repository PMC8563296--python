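"""Pre/post-merge dyadic convergence analysis.

When colonies are merged, the prediction is that microbiome similarity of
*introduced* pairs (bats from different source roosts) rises over time
while that of *same-roost* pairs falls as each bat mixes into the new
social unit. Each analyzed dyad pairs one bat's fixed pre-merge reference
sample against a partner bat's repeated samples, giving a similarity
time-series per dyad.

Inference is a fixed-effects interaction model
``similarity ~ time_scaled * dyad_type`` (introduced as the baseline
level, so the interaction is the same-roost slope minus the introduced
slope) with a permutation null built by shuffling the time values within
each dyad's own points — exchangeability that destroys any time trend
while preserving every dyad's similarity values and design share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .abundance import SampleRecord
from .dyad import SimilarityMatrix
from .mrqap import _batched_column_t, _count_as_extreme, _ols

__all__ = [
    "DyadSeries",
    "InteractionFit",
    "PermutationTestResult",
    "DirectionSummary",
    "BootstrapCI",
    "ConvergenceResult",
    "select_premerge_pairs",
    "fit_interaction_model",
    "permute_time_within_dyad",
    "per_dyad_directions",
    "bootstrap_mean_ci",
]

log = logging.getLogger(__name__)

DYAD_TYPES = ("same_roost", "introduced")


@dataclass(frozen=True)
class DyadSeries:
    """Similarity of one partner bat's repeated samples against another
    bat's fixed pre-merge reference sample, over time (days since the
    reference sample)."""

    dyad: tuple
    dyad_type: str
    reference_sample: str
    times: np.ndarray  # days, strictly increasing, >= 0
    sims: np.ndarray  # similarity in [0, 1]
    n_pre: int = 0
    n_post: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sims, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sims", s)
        if self.dyad_type not in DYAD_TYPES:
            raise ValueError(f"dyad_type must be one of {DYAD_TYPES}")
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError(f"dyad {self.dyad}: times/sims shape mismatch")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError(
                f"dyad {self.dyad}: times must be non-negative and strictly "
                f"increasing"
            )

    @property
    def n_points(self) -> int:
        return int(self.times.size)


# ---------------------------------------------------------------------------
# Pair selection
# ---------------------------------------------------------------------------

def select_premerge_pairs(
    samples: Sequence[SampleRecord], sim: SimilarityMatrix,
    reference_bats: Optional[Sequence[str]] = None,
) -> list[DyadSeries]:
    """Enumerate usable pre/post-merge dyads from sample metadata.

    For every ordered pair (A, B): A must have a pre-merge faecal sample
    (earliest used as the fixed reference if several; logged), and B must
    have at least one pre-merge and one post-merge faecal sample on or
    after the reference day. The dyad is ``same_roost`` iff A and B share
    an origin colony. Pairs failing the before/after requirement are
    excluded and logged.

    *reference_bats* optionally restricts which bats may serve as the
    fixed-reference side A (e.g. only bats sampled once soon after
    capture); by default every bat with a pre-merge sample qualifies.
    """
    known = set(sim.ids)
    faecal: dict[str, list[SampleRecord]] = {}
    for r in samples:
        if r.sample_type == "faecal" and r.sample_id in known:
            faecal.setdefault(r.bat_id, []).append(r)
    colony = {r.bat_id: r.colony for r in samples}

    allowed = None if reference_bats is None else {str(b) for b in reference_bats}
    refs: dict[str, SampleRecord] = {}
    for bat, recs in faecal.items():
        if allowed is not None and bat not in allowed:
            continue
        pre = [r for r in recs if r.phase == "pre_merge"]
        if not pre:
            continue
        pre.sort(key=lambda r: (r.day, r.sample_id))
        if len(pre) > 1:
            log.info("select_premerge_pairs: bat %s has %d pre-merge "
                     "samples; using earliest (%s, day %d)",
                     bat, len(pre), pre[0].sample_id, pre[0].day)
        refs[bat] = pre[0]

    partners = {
        bat for bat, recs in faecal.items()
        if any(r.phase == "pre_merge" for r in recs)
        and any(r.phase == "post_merge" for r in recs)
    }

    series: list[DyadSeries] = []
    for a in sorted(refs):
        ref = refs[a]
        for b in sorted(partners):
            if b == a:
                continue
            pts = sorted(
                (r for r in faecal[b] if r.day >= ref.day),
                key=lambda r: r.day,
            )
            n_pre = sum(r.phase == "pre_merge" for r in pts)
            n_post = sum(r.phase == "post_merge" for r in pts)
            if n_pre < 1 or n_post < 1:
                log.info("select_premerge_pairs: pair (%s, %s) excluded "
                         "(pre=%d, post=%d after reference day)",
                         a, b, n_pre, n_post)
                continue
            days = [r.day for r in pts]
            if len(set(days)) != len(days):
                raise ValueError(
                    f"bat {b!r} has multiple faecal samples on one day; "
                    f"cannot form a strictly increasing series"
                )
            series.append(DyadSeries(
                dyad=(a, b),
                dyad_type=("same_roost" if colony[a] == colony[b]
                           else "introduced"),
                reference_sample=ref.sample_id,
                times=np.array([r.day - ref.day for r in pts], dtype=float),
                sims=np.array([sim[ref.sample_id, r.sample_id] for r in pts]),
                n_pre=n_pre,
                n_post=n_post,
            ))
    return series


# ---------------------------------------------------------------------------
# Interaction model
# ---------------------------------------------------------------------------

@dataclass
class InteractionFit:
    """Least-squares fit of similarity ~ time_scaled * dyad_type."""

    coef: dict  # intercept, time, same_roost, interaction
    tstat: dict
    slopes: dict  # per-type time slopes from separate per-type fits
    time_center: float
    time_scale: float
    n_points: int
    n_dyads: int

    def to_dict(self) -> dict:
        return {
            "coef": self.coef, "tstat": self.tstat, "slopes": self.slopes,
            "time_center": self.time_center, "time_scale": self.time_scale,
            "n_points": self.n_points, "n_dyads": self.n_dyads,
        }


def _long_arrays(series: Sequence[DyadSeries]):
    times = np.concatenate([s.times for s in series])
    sims = np.concatenate([s.sims for s in series])
    group = np.concatenate([
        np.full(s.n_points, 1.0 if s.dyad_type == "same_roost" else 0.0)
        for s in series
    ])
    dyad_of = np.concatenate([
        np.full(s.n_points, d, dtype=int) for d, s in enumerate(series)
    ])
    return times, sims, group, dyad_of


def _scale_time(times: np.ndarray, scale_time: bool):
    if not scale_time:
        return times, 0.0, 1.0
    center = float(times.mean())
    sd = float(times.std(ddof=1)) if times.size > 1 else 0.0
    if sd == 0:
        raise ValueError("all points share one time; cannot scale time")
    return (times - center) / sd, center, sd


def _fit_from_arrays(ts: np.ndarray, sims: np.ndarray, group: np.ndarray):
    X = np.column_stack([np.ones_like(ts), ts, group, ts * group])
    beta, t = _ols(sims, X)
    return beta, t


def fit_interaction_model(series: Sequence[DyadSeries],
                          scale_time: bool = True) -> InteractionFit:
    """Pooled OLS of similarity on scaled time, dyad type and their
    interaction (introduced = baseline, so interaction = same-roost slope
    − introduced slope). Per-type slopes come from separate per-type fits
    of similarity ~ time_scaled, which coincide with the joint fit because
    the model is saturated in dyad type.
    """
    if not series:
        raise ValueError("no dyad series supplied")
    kinds = {s.dyad_type for s in series}
    if kinds != set(DYAD_TYPES):
        raise ValueError(
            f"both dyad types required; got only {sorted(kinds)}"
        )
    times, sims, group, _ = _long_arrays(series)
    ts, center, sd = _scale_time(times, scale_time)
    for g, label in ((0.0, "introduced"), (1.0, "same_roost")):
        tg = ts[group == g]
        if np.unique(tg).size < 2:
            raise ValueError(
                f"dyad type {label!r} has all points at a single time"
            )
    beta, t = _fit_from_arrays(ts, sims, group)
    names = ["intercept", "time", "same_roost", "interaction"]
    slopes = {}
    for g, label in ((0.0, "introduced"), (1.0, "same_roost")):
        sel = group == g
        Xg = np.column_stack([np.ones(sel.sum()), ts[sel]])
        bg, _ = _ols(sims[sel], Xg)
        slopes[label] = float(bg[1])
    return InteractionFit(
        coef=dict(zip(names, map(float, beta))),
        tstat=dict(zip(names, map(float, t))),
        slopes=slopes,
        time_center=center,
        time_scale=sd,
        n_points=len(sims),
        n_dyads=len(series),
    )


# ---------------------------------------------------------------------------
# Within-dyad time permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    statistic: float  # observed interaction t
    interaction: float  # observed interaction coefficient
    pvalue: float
    n_as_extreme: int
    n_permutations: int
    seed: Optional[int]
    sided: str
    n_dyads_used: int
    n_dyads_excluded: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def permute_time_within_dyad(
    series: Sequence[DyadSeries], n_permutations: int = 1000,
    seed: Optional[int] = None, sided: str = "two",
) -> PermutationTestResult:
    """Permutation p-value for the time × dyad-type interaction.

    The null is simulated by shuffling the time values among each dyad's
    own points, independently per dyad, and refitting the interaction
    model; the pivotal t of the interaction term is compared across
    permutations with the add-one rule. Dyads with a single point cannot
    be shuffled and are excluded with a warning.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    usable = [s for s in series if s.n_points >= 2]
    excluded = len(series) - len(usable)
    if excluded:
        log.warning("permute_time_within_dyad: excluded %d single-point "
                    "dyad(s)", excluded)
    fit = fit_interaction_model(usable)
    times, sims, group, dyad_of = _long_arrays(usable)
    # within-dyad shuffling preserves the global multiset of times, so the
    # scaling constants are permutation-invariant and applied once
    ts = (times - fit.time_center) / fit.time_scale

    rng = np.random.default_rng(seed)
    B = n_permutations
    npts = len(ts)
    perm_ts = np.empty((B, npts))
    for d in range(len(usable)):
        idx = np.flatnonzero(dyad_of == d)
        order = np.argsort(rng.random((B, idx.size)), axis=1)
        perm_ts[:, idx] = ts[idx][order]

    Z = np.empty((B, npts, 4))
    Z[:, :, 0] = 1.0
    Z[:, :, 1] = perm_ts
    Z[:, :, 2] = group
    Z[:, :, 3] = perm_ts * group
    t_perm = _batched_column_t(Z, sims, 3)
    t_obs = fit.tstat["interaction"]
    count = _count_as_extreme(t_perm, t_obs, sided)
    return PermutationTestResult(
        statistic=t_obs,
        interaction=fit.coef["interaction"],
        pvalue=(1 + count) / (1 + B),
        n_as_extreme=count,
        n_permutations=B,
        seed=seed,
        sided=sided,
        n_dyads_used=len(usable),
        n_dyads_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Per-dyad slope directions
# ---------------------------------------------------------------------------

@dataclass
class DirectionSummary:
    slopes: dict  # dyad -> least-squares slope of similarity on days
    consistent: dict  # dyad -> bool (matches the predicted direction)
    ties: list  # dyads with slope exactly 0 (counted inconsistent)
    fraction_consistent: float
    n_dyads: int

    def to_dict(self) -> dict:
        return {
            "slopes": {"|".join(k): v for k, v in self.slopes.items()},
            "consistent": {"|".join(k): v for k, v in self.consistent.items()},
            "ties": ["|".join(k) for k in self.ties],
            "fraction_consistent": self.fraction_consistent,
            "n_dyads": self.n_dyads,
        }


def per_dyad_directions(series: Sequence[DyadSeries]) -> DirectionSummary:
    """Per-dyad similarity-on-time slopes and agreement with the
    transmission prediction: positive for introduced pairs, negative for
    same-roost pairs. A slope of exactly 0 counts as inconsistent and is
    flagged as a tie (conservative)."""
    slopes, consistent, ties = {}, {}, []
    for s in series:
        if s.n_points < 2:
            raise ValueError(f"dyad {s.dyad}: need >= 2 points for a slope")
        X = np.column_stack([np.ones(s.n_points), s.times])
        beta, _ = _ols(s.sims, X)
        slope = float(beta[1])
        slopes[s.dyad] = slope
        if slope == 0.0:
            ties.append(s.dyad)
            consistent[s.dyad] = False
        elif s.dyad_type == "introduced":
            consistent[s.dyad] = slope > 0
        else:
            consistent[s.dyad] = slope < 0
    frac = sum(consistent.values()) / len(series)
    return DirectionSummary(
        slopes=slopes, consistent=consistent, ties=ties,
        fraction_consistent=float(frac), n_dyads=len(series),
    )


# ---------------------------------------------------------------------------
# Percentile bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapCI:
    mean: float
    lower: float
    upper: float
    n: int
    n_boot: int
    level: float
    seed: Optional[int]

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def bootstrap_mean_ci(values, n_boot: int = 5000,
                      seed: Optional[int] = None,
                      level: float = 0.95) -> BootstrapCI:
    """Percentile-bootstrap CI for the mean: resample the values with
    replacement *n_boot* times and take the (1±level)/2 percentiles of the
    bootstrap means. Treats the values as exchangeable units; for dyadic
    values sharing individuals this understates dependence (see report
    caveat)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        mean=float(v.mean()), lower=float(lo), upper=float(hi),
        n=int(v.size), n_boot=n_boot, level=level, seed=seed,
    )


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceResult:
    """Full convergence analysis: model fit, permutation test, per-dyad
    directions and bootstrap CIs of the per-type mean slopes."""

    fit: InteractionFit
    permutation: PermutationTestResult
    directions: DirectionSummary
    slope_ci: dict  # dyad_type -> BootstrapCI over per-dyad slopes
    n_series: int

    def to_dict(self) -> dict:
        return {
            "fit": self.fit.to_dict(),
            "permutation": self.permutation.to_dict(),
            "directions": self.directions.to_dict(),
            "slope_ci": {k: v.to_dict() for k, v in self.slope_ci.items()},
            "n_series": self.n_series,
            "caveat": (
                "bootstrap treats dyads as exchangeable; dyads sharing a "
                "bat are not independent"
            ),
        }


def analyze_convergence(
    series: Sequence[DyadSeries], n_permutations: int = 1000,
    n_boot: int = 5000, seed: Optional[int] = None, sided: str = "two",
) -> ConvergenceResult:
    """Run the full convergence analysis on a set of dyad series."""
    fit = fit_interaction_model(series)
    perm = permute_time_within_dyad(series, n_permutations=n_permutations,
                                    seed=seed, sided=sided)
    dirs = per_dyad_directions(series)
    slope_ci = {}
    for offset, kind in enumerate(DYAD_TYPES, start=1):
        vals = [dirs.slopes[s.dyad] for s in series if s.dyad_type == kind]
        if len(vals) >= 2:
            sub_seed = None if seed is None else (seed + offset) % (2**31)
            slope_ci[kind] = bootstrap_mean_ci(vals, n_boot=n_boot,
                                               seed=sub_seed)
    return ConvergenceResult(fit=fit, permutation=perm, directions=dirs,
                             slope_ci=slope_ci, n_series=len(series))
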