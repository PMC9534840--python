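"""Curation of focal-follow observation data into weighted ego-networks.

The raw material is scan-sampled behavioural observation: each *focal follow*
tracks one individual (the focal/ego) for a fixed window — nominally 10
minutes with 10 instantaneous scan points — and each scan records whom, if
anyone, the focal is grooming.  Curation applies the study's filtering rules:

* follows lasting 5 minutes or less (visibility losses) are discarded;
* grooming is binarised per follow: a partner groomed on any scan of a follow
  contributes exactly one interaction for that follow, however many scans it
  spanned (an alternative minute-weighted mode sums grooming minutes instead);
* per-dyad weights aggregate over all retained follows of the study period;
* egos that groomed fewer than five distinct partners are excluded from
  fitting, but grooming *received* by them still counts in others' networks.

The output is one directed :class:`EgoNetwork` per observed actor: the ego's
grooming weight toward each alter, with the per-ego extremes and degree the
downstream model needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    CrossGroupDyadError,
    ConfigError,
    ParseError,
    ReferentialIntegrityError,
)

__all__ = [
    "ObservationSet",
    "EgoNetwork",
    "parse_observations",
    "discard_short_follows",
    "binarize_grooming",
    "weight_grooming_minutes",
    "build_ego_networks",
    "filter_egos",
    "infer_group_assignments",
    "curate",
]

FOLLOW_COLUMNS = ["follow_id", "group_id", "focal_id", "date", "duration_minutes", "n_scans"]
EVENT_COLUMNS = ["follow_id", "scan_index", "behavior", "partner_id", "minutes"]


@dataclass
class ObservationSet:
    """Parsed focal follows plus the scan-level grooming events they contain.

    ``follows`` has columns follow_id, group_id, focal_id, date,
    duration_minutes, n_scans; ``events`` has follow_id, scan_index,
    actor_id (the focal, joined in at parse time), partner_id, minutes.
    ``n_ignored_events`` counts event rows of non-grooming behaviours that
    were present in the input but not consumed.
    """

    follows: pd.DataFrame
    events: pd.DataFrame
    n_ignored_events: int = 0

    @property
    def n_follows(self) -> int:
        return len(self.follows)

    @property
    def n_events(self) -> int:
        return len(self.events)


def _require_columns(df: pd.DataFrame, required, table: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{table}: missing column(s) {missing}", field=missing[0])


def parse_observations(follows_table, events_table) -> ObservationSet:
    """Read the follows and events tables and verify their integrity.

    Parameters are file paths (or buffers) of the two CSVs.  Event rows whose
    ``behavior`` is not ``"grooming"`` are dropped and counted.  Duplicate
    (follow_id, scan_index, partner_id) grooming rows are collapsed with a
    warning (multi-observer entry noise).  Raises :class:`ParseError` naming
    the offending row/field on malformed input and
    :class:`ReferentialIntegrityError` if an event references an unknown
    follow.
    """
    follows = pd.read_csv(follows_table, dtype=str, keep_default_na=False)
    _require_columns(follows, FOLLOW_COLUMNS, "follows")
    follows = follows[FOLLOW_COLUMNS].copy()

    for col, kind in [("duration_minutes", float), ("n_scans", int)]:
        converted = pd.to_numeric(follows[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"follows: non-numeric {col} {follows[col].iloc[row]!r}",
                row=row, field=col,
            )
        follows[col] = converted.astype(kind)
    if (follows["duration_minutes"] <= 0).any():
        row = int(np.flatnonzero((follows["duration_minutes"] <= 0).to_numpy())[0])
        raise ParseError("follows: duration_minutes must be > 0", row=row,
                         field="duration_minutes")
    dates = pd.to_datetime(follows["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna().to_numpy())[0])
        raise ParseError(f"follows: unparseable ISO date {follows['date'].iloc[row]!r}",
                         row=row, field="date")
    follows["date"] = dates
    dup = follows["follow_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ParseError("follows: duplicate follow_id", row=row, field="follow_id")

    events = pd.read_csv(events_table, dtype=str, keep_default_na=False)
    _require_columns(events, EVENT_COLUMNS, "events")
    events = events[EVENT_COLUMNS].copy()
    is_grooming = events["behavior"] == "grooming"
    n_ignored = int((~is_grooming).sum())
    events = events[is_grooming].drop(columns="behavior").reset_index(drop=True)

    scan = pd.to_numeric(events["scan_index"], errors="coerce")
    if scan.isna().any():
        row = int(np.flatnonzero(scan.isna().to_numpy())[0])
        raise ParseError(f"events: non-numeric scan_index "
                         f"{events['scan_index'].iloc[row]!r}", row=row,
                         field="scan_index")
    events["scan_index"] = scan.astype(int)
    events["minutes"] = pd.to_numeric(events["minutes"], errors="coerce")

    unknown = ~events["follow_id"].isin(follows["follow_id"])
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise ReferentialIntegrityError(
            f"events: follow_id {events['follow_id'].iloc[row]!r} not in follows",
            row=row, field="follow_id",
        )

    # join the focal as the acting individual and sanity-check scan indices
    meta = follows.set_index("follow_id")[["focal_id", "n_scans"]]
    events = events.join(meta, on="follow_id")
    events = events.rename(columns={"focal_id": "actor_id"})
    bad_scan = (events["scan_index"] < 1) | (events["scan_index"] > events["n_scans"])
    if bad_scan.any():
        row = int(np.flatnonzero(bad_scan.to_numpy())[0])
        raise ParseError("events: scan_index outside [1, n_scans] of its follow",
                         row=row, field="scan_index")
    self_groom = events["actor_id"] == events["partner_id"]
    if self_groom.any():
        row = int(np.flatnonzero(self_groom.to_numpy())[0])
        raise ParseError("events: focal recorded grooming itself", row=row,
                         field="partner_id")
    events = events.drop(columns="n_scans")

    dup = events.duplicated(subset=["follow_id", "scan_index", "partner_id"])
    if dup.any():
        warnings.warn(
            f"collapsed {int(dup.sum())} duplicate (follow, scan, partner) "
            "grooming rows", stacklevel=2,
        )
        events = events[~dup].reset_index(drop=True)

    return ObservationSet(follows=follows, events=events, n_ignored_events=n_ignored)


def discard_short_follows(obs: ObservationSet,
                          threshold_minutes: float = 5.0) -> ObservationSet:
    """Drop follows of duration <= threshold (default 5 min) and their events.

    The boundary is inclusive on the discard side: a 5-minute follow is
    removed, a 6-minute follow retained.  Idempotent.
    """
    keep = obs.follows["duration_minutes"] > threshold_minutes
    follows = obs.follows[keep].reset_index(drop=True)
    events = obs.events[obs.events["follow_id"].isin(follows["follow_id"])]
    return ObservationSet(follows=follows, events=events.reset_index(drop=True),
                          n_ignored_events=obs.n_ignored_events)


def filter_date_range(obs: ObservationSet, start=None, end=None) -> ObservationSet:
    """Optionally restrict the aggregation window; default keeps everything."""
    keep = pd.Series(True, index=obs.follows.index)
    if start is not None:
        keep &= obs.follows["date"] >= pd.Timestamp(start)
    if end is not None:
        keep &= obs.follows["date"] <= pd.Timestamp(end)
    follows = obs.follows[keep].reset_index(drop=True)
    events = obs.events[obs.events["follow_id"].isin(follows["follow_id"])]
    return ObservationSet(follows=follows, events=events.reset_index(drop=True),
                          n_ignored_events=obs.n_ignored_events)


def binarize_grooming(obs: ObservationSet) -> dict:
    """Per-dyad counts of follows with at least one grooming scan.

    A partner groomed on any number of scans within one follow contributes
    exactly 1 to the (ego, partner) count; counts aggregate over all retained
    follows.  Returns a mapping (ego_id, alter_id) -> int.
    """
    if obs.events.empty:
        return {}
    per_follow = obs.events.drop_duplicates(subset=["follow_id", "partner_id"])
    counts = per_follow.groupby(["actor_id", "partner_id"], sort=True).size()
    return {pair: int(n) for pair, n in counts.items()}


def weight_grooming_minutes(obs: ObservationSet) -> dict:
    """Per-dyad total grooming minutes (the alternative weighting mode).

    Each grooming row contributes its ``minutes`` value; when the minutes
    column is entirely absent each scored scan counts as one minute (follows
    are 10 min / 10 scans).  A partially filled minutes column is ambiguous
    and raises :class:`ConfigError`.
    """
    if obs.events.empty:
        return {}
    minutes = obs.events["minutes"]
    if minutes.isna().all():
        minutes = pd.Series(1.0, index=obs.events.index)
    elif minutes.isna().any():
        raise ConfigError(
            f"minutes mode selected but {int(minutes.isna().sum())} grooming "
            "rows lack a minutes value"
        )
    totals = minutes.groupby(
        [obs.events["actor_id"], obs.events["partner_id"]], sort=True
    ).sum()
    return {pair: float(m) for pair, m in totals.items()}


@dataclass
class EgoNetwork:
    """One ego's directed grooming weights toward its alters.

    ``weights`` maps alter_id -> s_i (> 0); ``L`` is the number of alters,
    ``s_max``/``s_min`` the extreme weights, ``n_follows`` the number of
    retained follows in which this ego was the focal.
    """

    ego_id: str
    group_id: str
    weights: dict = field(default_factory=dict)
    n_follows: int = 0

    def __post_init__(self):
        if self.ego_id in self.weights:
            raise ValueError(f"ego {self.ego_id!r} appears among its own alters")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all stored weights must be positive")

    @property
    def L(self) -> int:
        return len(self.weights)

    @property
    def s_max(self) -> float:
        return max(self.weights.values())

    @property
    def s_min(self) -> float:
        return min(self.weights.values())

    @property
    def alters(self):
        return sorted(self.weights)

    def weight_array(self) -> np.ndarray:
        """Weights in descending order (s_1 = s_max first)."""
        return np.sort(np.fromiter(self.weights.values(), dtype=float))[::-1]


def infer_group_assignments(obs: ObservationSet) -> dict:
    """Map every individual to its group using the follows it appears in.

    Focals take the group of their follows; partners that never act as focal
    inherit the group of the follows they were groomed in.  Conflicting
    assignments raise :class:`CrossGroupDyadError`.
    """
    groups: dict[str, str] = {}

    def assign(ind, grp):
        if ind in groups and groups[ind] != grp:
            raise CrossGroupDyadError(
                f"individual {ind!r} appears in groups {groups[ind]!r} and {grp!r}"
            )
        groups[ind] = grp

    for row in obs.follows.itertuples():
        assign(row.focal_id, row.group_id)
    follow_group = obs.follows.set_index("follow_id")["group_id"]
    for row in obs.events.itertuples():
        assign(row.partner_id, follow_group[row.follow_id])
    return groups


def build_ego_networks(dyad_weights: Mapping, group_assignments: Mapping,
                       n_follows: Mapping | None = None) -> list[EgoNetwork]:
    """Assemble one :class:`EgoNetwork` per acting individual.

    ``dyad_weights`` maps (ego_id, alter_id) -> weight; zero weights are
    dropped.  Every individual must be assigned to exactly one group and both
    ends of a dyad must share it (:class:`CrossGroupDyadError` otherwise).
    Individuals appearing only as partners get no network of their own.
    """
    per_ego: dict[str, dict] = {}
    for (ego, alter), w in dyad_weights.items():
        if w < 0:
            raise ValueError(f"negative weight for dyad ({ego!r}, {alter!r})")
        if w == 0:
            continue
        for ind in (ego, alter):
            if ind not in group_assignments:
                raise CrossGroupDyadError(f"individual {ind!r} has no group assignment")
        if group_assignments[ego] != group_assignments[alter]:
            raise CrossGroupDyadError(
                f"dyad ({ego!r}, {alter!r}) spans groups "
                f"{group_assignments[ego]!r} and {group_assignments[alter]!r}"
            )
        per_ego.setdefault(ego, {})[alter] = w
    n_follows = n_follows or {}
    return [
        EgoNetwork(ego_id=ego, group_id=group_assignments[ego],
                   weights=weights, n_follows=int(n_follows.get(ego, 0)))
        for ego, weights in sorted(per_ego.items())
    ]


def filter_egos(networks, min_partners: int = 5):
    """Split networks into (retained, excluded) by grooming out-degree.

    Egos that groomed fewer than ``min_partners`` distinct alters (default 5,
    the canonical innermost-circle size in primates) are excluded from
    fitting; exactly 5 partners is retained.  Exclusion never alters the
    retained networks — grooming received by excluded individuals stays in
    place.
    """
    retained = [n for n in networks if n.L >= min_partners]
    excluded = [n for n in networks if n.L < min_partners]
    return retained, excluded


def curate(follows_table, events_table, mode: str = "count",
           min_partners: int = 5, min_follow_minutes: float = 5.0,
           start=None, end=None):
    """Full curation pipeline: parse, filter follows, weight, build, filter egos.

    Returns ``(retained, excluded, log)`` where ``log`` is a dict of stage
    counts (follows before/after the short-follow discard, ignored behaviour
    rows, egos pre/post the partner filter).
    """
    obs = parse_observations(follows_table, events_table)
    n_raw = obs.n_follows
    obs = discard_short_follows(obs, threshold_minutes=min_follow_minutes)
    obs = filter_date_range(obs, start=start, end=end)
    if mode == "count":
        weights = binarize_grooming(obs)
    elif mode == "minutes":
        weights = weight_grooming_minutes(obs)
    else:
        raise ConfigError(f"unknown weighting mode {mode!r}; use 'count' or 'minutes'")
    groups = infer_group_assignments(obs)
    follows_per_ego = obs.follows.groupby("focal_id").size().to_dict()
    networks = build_ego_networks(weights, groups, n_follows=follows_per_ego)
    retained, excluded = filter_egos(networks, min_partners=min_partners)
    log = {
        "n_follows_raw": n_raw,
        "n_follows_retained": obs.n_follows,
        "n_follows_discarded": n_raw - obs.n_follows,
        "n_ignored_events": obs.n_ignored_events,
        "n_egos_pre_filter": len(networks),
        "n_egos_retained": len(retained),
        "n_egos_excluded": len(excluded),
        "mean_follows_per_ego": float(np.mean(list(follows_per_ego.values())))
        if follows_per_ego else 0.0,
    }
    return retained, excluded, log
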