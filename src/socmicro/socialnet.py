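"""Social networks from roosting-cluster scans and oral-contact bouts.

Two undirected networks are built per colony: a clustering network from
half-hourly scans of contiguous roosting groups, weighted by the simple
ratio index (SRI), and an oral-contact network weighted by the mean total
bout duration per hour of dyadic co-presence. Contact rates are heavily
right-skewed, so they pass through the bounded transform
t(x) = 1 − 1/(1 + x) before matrices are z-scored over dyads for
regression (−1/(1+x) differs only by an additive constant, so the choice
is immaterial after standardization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dyad import DyadMatrix

__all__ = [
    "GroupingObservation",
    "ContactBout",
    "PresenceLog",
    "SocialNetwork",
    "simple_ratio_index",
    "filter_bouts",
    "contact_rate_network",
    "transform_contact",
    "standardize_network",
    "read_grouping_csv",
    "write_grouping_csv",
    "read_bouts_csv",
    "write_bouts_csv",
    "read_presence_csv",
    "write_presence_csv",
]

log = logging.getLogger(__name__)

NETWORK_KINDS = ("sri", "contact_rate", "transformed", "standardized")


@dataclass(frozen=True)
class GroupingObservation:
    """One half-hour scan: who was present and the partition into
    contiguous roosting clusters (disjoint subsets of ``present``)."""

    period_id: int
    present: frozenset
    groups: tuple

    def __post_init__(self):
        present = frozenset(str(b) for b in self.present)
        groups = tuple(frozenset(str(b) for b in g) for g in self.groups)
        object.__setattr__(self, "present", present)
        object.__setattr__(self, "groups", groups)
        seen: set = set()
        for g in groups:
            overlap = seen & g
            if overlap:
                raise ValueError(
                    f"period {self.period_id}: bats {sorted(overlap)} appear "
                    f"in more than one group"
                )
            seen |= g
            stray = g - present
            if stray:
                raise ValueError(
                    f"period {self.period_id}: bats {sorted(stray)} grouped "
                    f"but not listed as present"
                )


@dataclass(frozen=True)
class ContactBout:
    """One timed licking bout (mouth-to-body or mouth-to-mouth pooled)."""

    actor: str
    receiver: str
    duration: float
    hour_id: int

    def __post_init__(self):
        if self.actor == self.receiver:
            raise ValueError(f"bout at hour {self.hour_id}: actor == receiver")
        if not self.duration > 0:
            raise ValueError(
                f"bout {self.actor}->{self.receiver} at hour {self.hour_id}: "
                f"duration must be > 0, got {self.duration}"
            )


class PresenceLog:
    """Bat-by-hour boolean presence in the flight cage."""

    def __init__(self, bat_ids: Sequence[str], hour_ids: Sequence[int],
                 present: np.ndarray):
        self.bat_ids = [str(b) for b in bat_ids]
        self.hour_ids = [int(h) for h in hour_ids]
        self.present = np.asarray(present, dtype=bool)
        if self.present.shape != (len(self.bat_ids), len(self.hour_ids)):
            raise ValueError("presence matrix shape mismatch")
        self._brow = {b: i for i, b in enumerate(self.bat_ids)}
        self._hcol = {h: j for j, h in enumerate(self.hour_ids)}

    def is_present(self, bat: str, hour: int) -> bool:
        if str(bat) not in self._brow:
            raise KeyError(f"unknown bat {bat!r} in presence log")
        if int(hour) not in self._hcol:
            raise KeyError(f"hour {hour} not covered by presence log")
        return bool(self.present[self._brow[str(bat)], self._hcol[int(hour)]])

    def co_present_hours(self) -> np.ndarray:
        """Bat-by-bat count of hours both were present."""
        p = self.present.astype(np.int64)
        return p @ p.T

    @classmethod
    def all_present(cls, bat_ids: Sequence[str], hour_ids: Sequence[int]):
        return cls(bat_ids, hour_ids,
                   np.ones((len(bat_ids), len(hour_ids)), dtype=bool))


class SocialNetwork(DyadMatrix):
    """Symmetric bat-by-bat network; ``kind`` and ``provenance`` record the
    transform chain. Diagonal stored as NaN (undefined)."""

    def __init__(self, ids, values, kind: str, provenance=None, *, check=True):
        if kind not in NETWORK_KINDS:
            raise ValueError(f"unknown network kind {kind!r}")
        values = np.array(values, dtype=float)
        np.fill_diagonal(values, np.nan)
        self.kind = kind
        self.provenance = list(provenance) if provenance else [kind]
        super().__init__(ids, values, check=check)

    def _like(self, ids, values):
        return SocialNetwork(ids, values, self.kind, self.provenance)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def simple_ratio_index(
    observations: Sequence[GroupingObservation],
) -> SocialNetwork:
    """Clustering network weighted by the simple ratio index.

    SRI(A,B) = x / (x + y_AB + y_A + y_B) over scan periods, where x counts
    periods with A and B in the same roosting cluster, y_AB both present but
    in different clusters (or ungrouped), and y_A / y_B only one present.
    Pairs never co-present in any period get SRI 0 (with a logged warning).
    """
    if not observations:
        raise ValueError("need at least one grouping observation")
    bats = sorted(set().union(*(o.present for o in observations)))
    idx = {b: i for i, b in enumerate(bats)}
    n = len(bats)
    together = np.zeros((n, n))
    both_present = np.zeros((n, n))
    present_count = np.zeros(n)
    for obs in observations:
        p = np.zeros(n)
        p[[idx[b] for b in obs.present]] = 1.0
        present_count += p
        both_present += np.outer(p, p)
        for g in obs.groups:
            gi = [idx[b] for b in g]
            if len(gi) >= 2:
                gv = np.zeros(n)
                gv[gi] = 1.0
                together += np.outer(gv, gv)
    # denominator = periods where at least one of the pair was present
    denom = present_count[:, None] + present_count[None, :] - both_present
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(denom > 0, together / np.where(denom > 0, denom, 1), 0.0)
    iu, ju = np.triu_indices(n, k=1)
    never = both_present[iu, ju] == 0
    if never.any():
        pairs = [(bats[i], bats[j]) for i, j in
                 zip(iu[never][:10], ju[never][:10])]
        log.warning(
            "simple_ratio_index: %d pair(s) never co-present, edge set to 0 "
            "(first few: %s)", int(never.sum()), pairs,
        )
    return SocialNetwork(bats, sri, "sri")


def filter_bouts(
    bouts: Sequence[ContactBout], min_duration: float = 5.0
) -> list[ContactBout]:
    """Drop bouts shorter than *min_duration* seconds (boundary kept:
    a bout of exactly *min_duration* survives)."""
    kept = [b for b in bouts if b.duration >= min_duration]
    removed = len(bouts) - len(kept)
    if removed:
        log.info("filter_bouts: removed %d of %d bouts shorter than %gs",
                 removed, len(bouts), min_duration)
    return kept


def contact_rate_network(
    bouts: Sequence[ContactBout], presence: PresenceLog
) -> SocialNetwork:
    """Oral-contact rate: total dyadic bout duration (both directions)
    divided by the number of sample hours both bats were present.

    Dyads with zero co-present hours have an undefined rate, stored as NaN,
    listed in the network provenance, and excluded from downstream
    regressions by the dyad mask.
    """
    bats = presence.bat_ids
    idx = {b: i for i, b in enumerate(bats)}
    n = len(bats)
    total = np.zeros((n, n))
    for b in bouts:
        for who in (b.actor, b.receiver):
            if not presence.is_present(who, b.hour_id):
                raise ValueError(
                    f"bout {b.actor}->{b.receiver} at hour {b.hour_id}: "
                    f"{who!r} not present that hour"
                )
        i, j = idx[b.actor], idx[b.receiver]
        total[i, j] += b.duration
        total[j, i] += b.duration
    co = presence.co_present_hours().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(co > 0, total / np.where(co > 0, co, 1), np.nan)
    iu, ju = np.triu_indices(n, k=1)
    undefined = [
        (bats[i], bats[j]) for i, j in zip(iu, ju) if co[i, j] == 0
    ]
    if undefined:
        log.warning("contact_rate_network: %d dyad(s) with no co-present "
                    "hours are undefined (NaN)", len(undefined))
    prov = ["contact_rate"]
    if undefined:
        prov.append(f"undefined_dyads={undefined}")
    return SocialNetwork(bats, rate, "contact_rate", prov)


def transform_contact(net: SocialNetwork) -> SocialNetwork:
    """Skew-reducing bounded transform t(x) = 1 − 1/(1 + x), applied
    elementwise to non-negative rates; monotone, range [0, 1)."""
    vals = net.values
    neg = np.isfinite(vals) & (vals < 0)
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative rate at ({net.ids[i]!r}, {net.ids[j]!r}): {vals[i, j]}"
        )
    out = 1.0 - 1.0 / (1.0 + vals)
    return SocialNetwork(net.ids, out, "transformed",
                         net.provenance + ["transform:1-1/(1+x)"])


def standardize_network(net: SocialNetwork) -> SocialNetwork:
    """Z-score the off-diagonal dyads (mean 0, SD 1 over unique unordered
    dyads; population SD). NaN dyads are ignored and propagate unchanged."""
    vals = net.values.copy()
    dy = net.dyad_values()
    finite = dy[np.isfinite(dy)]
    if finite.size < 2:
        raise ValueError(f"network {net.kind!r}: fewer than 2 finite dyads")
    mu, sd = finite.mean(), finite.std(ddof=0)
    if sd == 0:
        raise ValueError(
            f"network {net.kind!r} (provenance {net.provenance}): constant "
            f"off-diagonal values, cannot standardize"
        )
    out = (vals - mu) / sd
    return SocialNetwork(net.ids, out, "standardized",
                         net.provenance + ["standardize:zscore"])


# ---------------------------------------------------------------------------
# CSV IO (long formats)
# ---------------------------------------------------------------------------

def read_grouping_csv(path) -> list[GroupingObservation]:
    """Long CSV with columns period_id, bat_id, group_id; an empty group_id
    means present but not in any cluster."""
    df = pd.read_csv(path, dtype={"period_id": int, "bat_id": str,
                                  "group_id": str})
    for c in ("period_id", "bat_id", "group_id"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    obs = []
    for period, sub in df.groupby("period_id", sort=True):
        present = frozenset(sub["bat_id"])
        if len(present) != len(sub):
            raise ValueError(f"{path}: duplicate bat rows in period {period}")
        groups = []
        grouped = sub[sub["group_id"].notna() & (sub["group_id"] != "")]
        for _, gsub in grouped.groupby("group_id"):
            groups.append(frozenset(gsub["bat_id"]))
        obs.append(GroupingObservation(int(period), present, tuple(groups)))
    return obs


def write_grouping_csv(observations: Iterable[GroupingObservation], path):
    rows = []
    for o in observations:
        membership = {}
        for gi, g in enumerate(o.groups):
            for b in g:
                membership[b] = f"g{gi}"
        for b in sorted(o.present):
            rows.append({"period_id": o.period_id, "bat_id": b,
                         "group_id": membership.get(b, "")})
    pd.DataFrame(rows, columns=["period_id", "bat_id", "group_id"]).to_csv(
        path, index=False
    )


def read_bouts_csv(path) -> list[ContactBout]:
    df = pd.read_csv(path, dtype={"hour_id": int, "actor": str,
                                  "receiver": str, "duration_s": float})
    for c in ("hour_id", "actor", "receiver", "duration_s"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return [
        ContactBout(actor=r.actor, receiver=r.receiver,
                    duration=float(r.duration_s), hour_id=int(r.hour_id))
        for r in df.itertuples()
    ]


def write_bouts_csv(bouts: Iterable[ContactBout], path):
    pd.DataFrame(
        [{"hour_id": b.hour_id, "actor": b.actor, "receiver": b.receiver,
          "duration_s": b.duration} for b in bouts],
        columns=["hour_id", "actor", "receiver", "duration_s"],
    ).to_csv(path, index=False)


def read_presence_csv(path) -> PresenceLog:
    df = pd.read_csv(path, dtype={"hour_id": int, "bat_id": str,
                                  "present": int})
    for c in ("hour_id", "bat_id", "present"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    wide = df.pivot_table(index="bat_id", columns="hour_id",
                          values="present", fill_value=0)
    return PresenceLog(list(wide.index.astype(str)),
                       list(wide.columns.astype(int)),
                       wide.to_numpy(dtype=bool))


def write_presence_csv(presence: PresenceLog, path):
    rows = [
        {"hour_id": h, "bat_id": b, "present": int(presence.present[i, j])}
        for i, b in enumerate(presence.bat_ids)
        for j, h in enumerate(presence.hour_ids)
    ]
    pd.DataFrame(rows, columns=["hour_id", "bat_id", "present"]).to_csv(
        path, index=False
    )
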