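"""Seeded simulator of a merged bat colony with contact-driven microbial
transmission.

The generator produces every input the analysis pipeline consumes —
roosting-cluster scans, timed oral-contact bouts, a presence log, a
taxon-by-sample abundance table and sample metadata — from an explicit
causal model, so each downstream stage can be tested against known ground
truth:

* Each source colony has its own Dirichlet base community; bats start as
  i.i.d. draws from their colony's distribution (origin roost structures
  the microbiome).
* A latent per-dyad co-clustering affinity (log-normal, boosted for
  same-roost pairs) drives the roosting-cluster partitions; oral-contact
  bouts arise *within clusters only*, at a rate scaled by a second,
  independent per-dyad contact affinity (grooming/food-sharing
  relationships beyond mere proximity). Bats interact every post-merge
  day, but only a subsample of hours is observed and logged, emulating a
  video-sampling design.
* Microbes move only through contact bouts: a dyad's total contact of
  ``d`` seconds in a day mixes both compositions toward their mean with
  weight ``m/2`` each, ``m = 1 − exp(−τ·d)`` (repeated short bouts
  compose approximately like one long bout; ``m → 1`` makes the pair
  identical). A daily multiplicative log-normal drift perturbs every bat.
* Scheduled faecal samples and one final gut sample per bat are
  multinomial draws of fixed depth from that day's latent composition.

Clustering therefore influences microbiomes only by creating contact
opportunity, which makes "contact predicts similarity controlling for
clustering" a recoverable ground truth, while the clustering network
retains its own predictive share because the observed bout log is a
noisy subsample of true exposure. Setting ``shared_base=True`` (with
``transmission_rate=0``) gives a negative-control colony in which social
assortment exists but no mechanism links behaviour to microbiome
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .abundance import AbundanceTable, SampleRecord
from .socialnet import ContactBout, GroupingObservation, PresenceLog

__all__ = [
    "SimulationConfig",
    "SocialLogs",
    "GroundTruth",
    "SimulatedColony",
    "generate_base_communities",
    "simulate_social_logs",
    "simulate_transmission",
    "sample_microbiomes",
    "simulate_colony",
]

# stream ids for independent, individually reproducible RNG streams
_STREAM_BASE = 1
_STREAM_AFFINITY = 2
_STREAM_SOCIAL = 3
_STREAM_TRANSMISSION = 4
_STREAM_SAMPLING = 5
_STREAM_CONTACT_AFFINITY = 6


@dataclass
class SimulationConfig:
    """Parameters of the merged-colony simulation (defaults are the
    package's standard study conditions; see docs/methods.md)."""

    n_colonies: int = 3
    bats_per_colony: int = 9
    n_taxa: int = 100
    # base communities: per-colony Dirichlet concentration vectors; built
    # from core/signature blocks when not supplied explicitly
    colony_base_concentration: Optional[list] = None
    core_alpha: float = 0.8
    signature_alpha: float = 6.0
    shared_base: bool = False  # all colonies share colony 0's concentration
    transmission_rate: float = 0.003  # tau, per contact-second
    drift_sd: float = 0.05  # daily log-normal compositional drift
    n_days: int = 120
    merge_day: int = 14
    n_hours: int = 240  # observed sample hours (post-merge)
    hours_per_day: int = 6
    n_periods: int = 480  # half-hour cluster scans (2 per observed hour)
    grouping_preference: float = 3.0  # same-roost co-clustering odds boost
    affinity_sd: float = 1.5  # log-SD of the latent co-clustering affinity
    contact_affinity_sd: float = 0.7  # log-SD of bout propensity given proximity
    contact_propensity: dict = field(
        default_factory=lambda: {"same_roost": 0.1, "introduced": 0.1}
    )  # bouts per co-clustered dyad per hour, before the affinity multiplier
    mean_bout_duration: float = 20.0  # seconds (exponential)
    min_bout_duration: float = 1.0  # seconds (clip)
    new_cluster_weight: float = 20.0  # partition model: weight of a new cluster
    sampling_schedule: Optional[dict] = None  # bat_id -> faecal days
    gut_day: Optional[int] = None  # final gut sample day (default n_days)
    sequencing_depth: int = 100000
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_colonies < 1 or self.bats_per_colony < 1 or self.n_taxa < 2:
            raise ValueError("need >=1 colony, >=1 bat/colony, >=2 taxa")
        for name in ("transmission_rate", "drift_sd", "grouping_preference",
                     "affinity_sd", "contact_affinity_sd", "mean_bout_duration", "core_alpha",
                     "signature_alpha", "new_cluster_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.transmission_rate <= 1:
            raise ValueError("transmission_rate must be in [0, 1]")
        if any(v < 0 for v in self.contact_propensity.values()):
            raise ValueError("contact propensities must be >= 0")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be > 0")
        if not 0 <= self.merge_day <= self.n_days:
            raise ValueError("merge_day must lie within the horizon")
        if self.n_hours % self.hours_per_day:
            raise ValueError("n_hours must be a multiple of hours_per_day")
        if self.n_periods % (self.n_hours // self.hours_per_day):
            raise ValueError("n_periods must spread evenly over observed days")
        for bat, days in (self.sampling_schedule or {}).items():
            bad = [d for d in days if not 0 <= d <= self.n_days]
            if bad:
                raise ValueError(f"schedule for {bat}: days {bad} outside "
                                 f"[0, {self.n_days}]")
        if self.gut_day is not None and not 0 <= self.gut_day <= self.n_days:
            raise ValueError("gut_day outside the horizon")

    # -- derived structure -------------------------------------------------
    # Bats interact for `hours_per_day` active hours on every post-merge
    # day; only `n_hours` of those hours (evenly spaced days) are observed
    # and appear in the logs. Transmission uses all active hours.
    @property
    def n_bats(self) -> int:
        return self.n_colonies * self.bats_per_colony

    @property
    def n_active_hours(self) -> int:
        return max(self.n_days - self.merge_day, 0) * self.hours_per_day

    def day_of_active_hour(self, hour_id: int) -> int:
        return self.merge_day + hour_id // self.hours_per_day

    def bat_ids(self) -> list[str]:
        return [
            f"{chr(65 + c)}{i + 1:02d}"
            for c in range(self.n_colonies)
            for i in range(self.bats_per_colony)
        ]

    def colony_of(self) -> dict:
        return {
            b: b[0] for b in self.bat_ids()
        }

    def observation_days(self) -> np.ndarray:
        """Days carrying observed hours, spread evenly post-merge."""
        n_obs_days = self.n_hours // self.hours_per_day
        return np.linspace(
            self.merge_day, self.n_days - 1, n_obs_days
        ).round().astype(int)

    def day_of_hour(self, hour_id: int) -> int:
        return int(self.observation_days()[hour_id // self.hours_per_day])

    def concentrations(self) -> np.ndarray:
        """(n_colonies, n_taxa) Dirichlet concentration matrix."""
        if self.colony_base_concentration is not None:
            conc = np.asarray(self.colony_base_concentration, dtype=float)
            if conc.shape != (self.n_colonies, self.n_taxa):
                raise ValueError("colony_base_concentration shape mismatch")
        else:
            block = self.n_taxa // (self.n_colonies + 1)
            conc = np.full((self.n_colonies, self.n_taxa), self.core_alpha)
            for c in range(self.n_colonies):
                start = block * (c + 1)
                conc[c, start:start + block] = self.signature_alpha
        if self.shared_base:
            conc = np.tile(conc[0], (self.n_colonies, 1))
        if (conc <= 0).any():
            raise ValueError("Dirichlet concentrations must be positive")
        return conc

    def effective_schedule(self) -> dict:
        """Faecal-sampling schedule; the default mirrors a 25-pair
        pre/post-merge design: 5 reference bats (colony A, sampled once
        pre-merge) and 5 partner bats (2 colony A + 3 colony B) sampled
        before and repeatedly after the merge."""
        if self.sampling_schedule is not None:
            return {str(k): sorted(int(d) for d in v)
                    for k, v in self.sampling_schedule.items()}
        bats = self.bat_ids()
        schedule: dict[str, list[int]] = {}
        if self.n_colonies >= 2 and self.bats_per_colony >= 7:
            colony_a = [b for b in bats if b.startswith("A")]
            colony_b = [b for b in bats if b.startswith("B")]
            pre, mid = max(self.merge_day - 14, 0), max(self.merge_day - 9, 1)
            later = np.linspace(self.merge_day + 10, self.n_days - 20, 3)
            partner_days = [mid] + [int(round(d)) for d in later]
            for b in colony_a[:5]:
                schedule[b] = [pre]
            for b in colony_a[5:7] + colony_b[:3]:
                schedule[b] = partner_days
        return schedule

    def effective_gut_day(self) -> int:
        return self.n_days if self.gut_day is None else self.gut_day

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=[int(self.seed), int(stream)])
        )


@dataclass
class SocialLogs:
    groupings: list
    bouts: list  # observed bouts only (hour ids relative to observed hours)
    presence: PresenceLog
    affinity: np.ndarray  # latent per-dyad affinity multiplier
    observation_days: np.ndarray
    true_bouts: list = field(default_factory=list)  # all active-hour bouts


@dataclass
class GroundTruth:
    contact_seconds: np.ndarray  # cumulative per-dyad contact (n, n)
    trajectories: np.ndarray  # (n_days + 1, n_bats, n_taxa)
    affinity: np.ndarray
    bat_ids: list
    colonies: dict
    expect_introduced_convergence: bool

    def summary(self) -> dict:
        return {
            "n_bats": len(self.bat_ids),
            "total_contact_seconds": float(self.contact_seconds.sum() / 2),
            "expect_introduced_convergence":
                self.expect_introduced_convergence,
        }


@dataclass
class SimulatedColony:
    config: SimulationConfig
    bat_ids: list
    colonies: dict
    logs: SocialLogs
    table: AbundanceTable
    samples: list
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Stage 1: base communities
# ---------------------------------------------------------------------------

def generate_base_communities(config: SimulationConfig) -> np.ndarray:
    """(n_bats, n_taxa) initial latent compositions: colony c's bats drawn
    i.i.d. from Dirichlet(concentration_c). Deterministic under the seed."""
    rng = config.rng(_STREAM_BASE)
    conc = config.concentrations()
    comps = np.empty((config.n_bats, config.n_taxa))
    for c in range(config.n_colonies):
        rows = slice(c * config.bats_per_colony, (c + 1) * config.bats_per_colony)
        comps[rows] = rng.dirichlet(conc[c], size=config.bats_per_colony)
    return comps


# ---------------------------------------------------------------------------
# Stage 2: social observation logs
# ---------------------------------------------------------------------------

def _latent_affinity(config: SimulationConfig, sd: float,
                     stream: int) -> np.ndarray:
    """Symmetric log-normal dyadic affinity multiplier (mean 1)."""
    rng = config.rng(stream)
    n = config.n_bats
    logs = rng.normal(0.0, sd, size=(n, n))
    logs = np.triu(logs, 1)
    logs = logs + logs.T
    a = np.exp(logs - sd**2 / 2)
    np.fill_diagonal(a, 0.0)
    return a


def _same_colony_matrix(config: SimulationConfig) -> np.ndarray:
    labels = np.repeat(np.arange(config.n_colonies), config.bats_per_colony)
    return (labels[:, None] == labels[None, :]).astype(float)


def _draw_partition(rng, n, grouping_weight, new_cluster_weight):
    """Sequential preference-weighted random partition: in random order,
    each bat joins an existing cluster with weight equal to its summed
    pairwise grouping weight to the members, or opens a new cluster with
    constant weight."""
    order = rng.permutation(n)
    clusters: list[list[int]] = []
    for b in order:
        weights = np.array(
            [grouping_weight[b, cl].sum() for cl in clusters]
            + [new_cluster_weight]
        )
        choice = rng.choice(len(weights), p=weights / weights.sum())
        if choice == len(clusters):
            clusters.append([int(b)])
        else:
            clusters[choice].append(int(b))
    return clusters


def simulate_social_logs(config: SimulationConfig) -> SocialLogs:
    """Cluster scans, contact bouts and a presence log.

    Every active hour is divided into scan windows (``n_periods /
    n_hours`` per hour, half-hourly by default). Each window draws a
    roosting partition with co-clustering odds proportional to dyadic
    affinity × ``grouping_preference`` for same-roost pairs. Oral-contact
    bouts arise *within clusters only*: per window, each co-clustered
    dyad draws a Poisson number of bouts at its class propensity, with
    exponential durations clipped at ``min_bout_duration``. Clustering is
    thus the sole source of contact opportunity.

    All active hours generate true bouts (``true_bouts``); the returned
    ``groupings``/``bouts``/``presence`` logs cover only the observed
    hours, emulating a video subsample of colony life.
    """
    rng = config.rng(_STREAM_SOCIAL)
    n = config.n_bats
    bats = config.bat_ids()
    same = _same_colony_matrix(config)
    affinity = _latent_affinity(config, config.affinity_sd, _STREAM_AFFINITY)
    contact_aff = _latent_affinity(config, config.contact_affinity_sd,
                                   _STREAM_CONTACT_AFFINITY)
    grouping_weight = affinity * np.where(
        same > 0, config.grouping_preference, 1.0
    )
    rate = contact_aff * np.where(
        same > 0,
        config.contact_propensity.get("same_roost", 0.0),
        config.contact_propensity.get("introduced", 0.0),
    )

    spw = max(config.n_periods // max(config.n_hours, 1), 1)  # scans/hour
    obs_days = config.observation_days()
    observed_day = sorted({int(d) for d in obs_days})
    obs_rank = {d: k for k, d in enumerate(observed_day)}

    groupings, true_bouts, bouts = [], [], []
    for hour in range(config.n_active_hours):
        day = config.day_of_active_hour(hour)
        observed = day in obs_rank
        hod = hour % config.hours_per_day
        obs_hour = (obs_rank[day] * config.hours_per_day + hod
                    if observed else None)
        for w in range(spw):
            clusters = _draw_partition(rng, n, grouping_weight,
                                       config.new_cluster_weight)
            if observed:
                period = obs_hour * spw + w
                groups = tuple(
                    frozenset(bats[i] for i in cl)
                    for cl in clusters if len(cl) >= 2
                )
                groupings.append(
                    GroupingObservation(period, frozenset(bats), groups)
                )
            for cl in clusters:
                if len(cl) < 2:
                    continue
                for a in range(len(cl)):
                    for b in range(a + 1, len(cl)):
                        i, j = cl[a], cl[b]
                        k = rng.poisson(rate[i, j] / spw)
                        for _ in range(k):
                            dur = max(
                                rng.exponential(config.mean_bout_duration),
                                config.min_bout_duration,
                            )
                            actor, receiver = (
                                (i, j) if rng.random() < 0.5 else (j, i)
                            )
                            bout = ContactBout(
                                actor=bats[actor], receiver=bats[receiver],
                                duration=float(dur), hour_id=hour,
                            )
                            true_bouts.append(bout)
                            if observed:
                                bouts.append(ContactBout(
                                    actor=bout.actor,
                                    receiver=bout.receiver,
                                    duration=bout.duration,
                                    hour_id=obs_hour,
                                ))
    n_obs_hours = len(observed_day) * config.hours_per_day
    presence = PresenceLog.all_present(bats, list(range(n_obs_hours)))
    return SocialLogs(
        groupings=groupings, bouts=bouts, presence=presence,
        affinity=affinity, observation_days=obs_days,
        true_bouts=true_bouts,
    )


# ---------------------------------------------------------------------------
# Stage 3: transmission dynamics
# ---------------------------------------------------------------------------

def simulate_transmission(
    config: SimulationConfig, logs: SocialLogs, base: np.ndarray
) -> np.ndarray:
    """Latent composition trajectories, shape (n_days + 1, n_bats, n_taxa).

    Per day, each contacting dyad's total bout duration d mixes both
    compositions toward their mean with weight m/2, m = 1 − exp(−τ·d)
    (so m → 1 makes the pair identical); then every bat's composition is
    perturbed by multiplicative log-normal drift and renormalized.
    Dyad update order within a day is randomized.
    """
    rng = config.rng(_STREAM_TRANSMISSION)
    n, T = base.shape
    tau = config.transmission_rate
    daily: dict[int, dict[tuple, float]] = {}
    ids = {b: i for i, b in enumerate(config.bat_ids())}
    for b in (logs.true_bouts or logs.bouts):
        # contacts take effect at the end of their day; day-0 contacts
        # (merge_day == 0) fold into the first update step
        day = max(config.day_of_active_hour(b.hour_id), 1)
        i, j = sorted((ids[b.actor], ids[b.receiver]))
        daily.setdefault(day, {})
        daily[day][(i, j)] = daily[day].get((i, j), 0.0) + b.duration

    traj = np.empty((config.n_days + 1, n, T))
    comp = base.copy()
    traj[0] = comp
    for day in range(1, config.n_days + 1):
        events = daily.get(day)
        if events and tau > 0:
            pairs = list(events.items())
            for k in rng.permutation(len(pairs)):
                (i, j), dur = pairs[k]
                m = 1.0 - np.exp(-tau * dur)
                w = m / 2.0
                pi = comp[i].copy()
                comp[i] = (1 - w) * pi + w * comp[j]
                comp[j] = (1 - w) * comp[j] + w * pi
        if config.drift_sd > 0:
            comp = comp * np.exp(
                rng.normal(0.0, config.drift_sd, size=comp.shape)
            )
            comp = comp / comp.sum(axis=1, keepdims=True)
        traj[day] = comp
    return traj


# ---------------------------------------------------------------------------
# Stage 4: sequencing-like sampling
# ---------------------------------------------------------------------------

def sample_microbiomes(
    config: SimulationConfig, trajectories: np.ndarray
) -> tuple[AbundanceTable, list]:
    """Multinomial draws of ``sequencing_depth`` reads from each scheduled
    latent composition: faecal samples per the schedule (phase set by
    ``merge_day``) plus one final gut sample per bat."""
    rng = config.rng(_STREAM_SAMPLING)
    bats = config.bat_ids()
    colony = config.colony_of()
    ids = {b: i for i, b in enumerate(bats)}
    schedule = config.effective_schedule()
    gut_day = config.effective_gut_day()

    taxa = [f"sp{t + 1:03d}" for t in range(config.n_taxa)]
    columns, records = [], []
    for bat in bats:
        for day in schedule.get(bat, []):
            counts = rng.multinomial(config.sequencing_depth,
                                     trajectories[day, ids[bat]])
            sid = f"{bat}_f{day:03d}"
            columns.append(counts)
            records.append(SampleRecord(
                sample_id=sid, bat_id=bat, colony=colony[bat], day=day,
                sample_type="faecal",
                phase="pre_merge" if day < config.merge_day else "post_merge",
            ))
    for bat in bats:
        counts = rng.multinomial(config.sequencing_depth,
                                 trajectories[gut_day, ids[bat]])
        columns.append(counts)
        records.append(SampleRecord(
            sample_id=f"{bat}_gut", bat_id=bat, colony=colony[bat],
            day=gut_day, sample_type="gut",
            phase="pre_merge" if gut_day < config.merge_day else "post_merge",
        ))
    values = np.column_stack(columns).astype(float)
    table = AbundanceTable(taxa, [r.sample_id for r in records], values, "raw")
    return table, records


# ---------------------------------------------------------------------------
# End to end
# ---------------------------------------------------------------------------

def simulate_colony(config: SimulationConfig) -> SimulatedColony:
    """Run all four stages and bundle the outputs with ground truth."""
    base = generate_base_communities(config)
    logs = simulate_social_logs(config)
    traj = simulate_transmission(config, logs, base)
    table, samples = sample_microbiomes(config, traj)

    n = config.n_bats
    ids = {b: i for i, b in enumerate(config.bat_ids())}
    contact = np.zeros((n, n))
    for b in (logs.true_bouts or logs.bouts):
        i, j = ids[b.actor], ids[b.receiver]
        contact[i, j] += b.duration
        contact[j, i] += b.duration
    truth = GroundTruth(
        contact_seconds=contact,
        trajectories=traj,
        affinity=logs.affinity,
        bat_ids=config.bat_ids(),
        colonies=config.colony_of(),
        expect_introduced_convergence=config.transmission_rate > 0,
    )
    return SimulatedColony(
        config=config, bat_ids=config.bat_ids(), colonies=config.colony_of(),
        logs=logs, table=table, samples=samples, ground_truth=truth,
    )
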