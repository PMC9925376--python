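"""Treatment-episode reconstruction from pharmacy dispensation series.

A person's dispenses of one drug group are scanned left to right; whenever
the gap between consecutive dispense dates exceeds ``gap_days`` (default 122,
i.e. four months — Swedish dispenses cover at most three months' supply and
may be refilled after two thirds of that), a new episode starts.  Each
episode ends at its last dispense date plus the days of supply of that
dispense (its DDD count, rounded to whole days) capped at ``tail_cap_days``
(default 90).  The gap comparison is strict: a gap of exactly ``gap_days``
continues the episode.

Because treatment may have started before registry coverage, episodes
starting within ``gap_days`` of the coverage start are left-truncated and
must be discarded with :func:`filter_left_truncated`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import resources

__all__ = [
    "Episode",
    "build_episodes",
    "build_episode_table",
    "filter_left_truncated",
    "mg_to_ddd",
    "GAP_DAYS",
    "TAIL_CAP_DAYS",
]

GAP_DAYS = 122       # "4 months" at the 30.5 d/month registry convention
TAIL_CAP_DAYS = 90   # maximum days of supply credited to the final dispense


@dataclass(frozen=True)
class Episode:
    """One continuous exposure window for a person × drug group."""
    person_id: object
    drug_group: str | None
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    dispense_dates: tuple = field(default_factory=tuple)

    @property
    def n_dispenses(self) -> int:
        return len(self.dispense_dates)

    @property
    def duration_days(self) -> int:
        return int((self.end_date - self.start_date).days)


def _tail_days(n_ddd: float, tail_cap_days: int) -> int:
    return int(min(np.rint(n_ddd), tail_cap_days))


def build_episodes(dates, n_ddd, gap_days: int = GAP_DAYS,
                   tail_cap_days: int = TAIL_CAP_DAYS,
                   person_id=None, drug_group: str | None = None) -> list[Episode]:
    """Partition one person×group dispense series into treatment episodes.

    Parameters
    ----------
    dates
        Dispense dates (anything ``pd.to_datetime`` accepts), not necessarily
        sorted.
    n_ddd
        Dispensed quantity in DDD units, aligned with ``dates``; the DDD count
        of an episode's last dispense sets its end-date tail.

    Returns episodes in chronological order; every dispense belongs to
    exactly one episode and consecutive within-episode gaps are ≤ gap_days.
    """
    dates = pd.to_datetime(pd.Series(list(dates)))
    qty = np.asarray(list(n_ddd), dtype=float)
    if len(dates) != len(qty):
        raise ValueError("dates and n_ddd must be the same length")
    if len(dates) == 0:
        return []
    if (qty < 0).any():
        raise ValueError("negative dispensed quantity (n_ddd)")
    order = np.argsort(dates.to_numpy(), kind="stable")
    dates = dates.iloc[order].reset_index(drop=True)
    qty = qty[order]

    gaps = dates.diff().dt.days.to_numpy()
    new_ep = np.zeros(len(dates), dtype=bool)
    new_ep[0] = True
    new_ep[1:] = gaps[1:] > gap_days   # strict: a gap of exactly gap_days continues

    episodes = []
    starts = np.flatnonzero(new_ep)
    bounds = list(starts) + [len(dates)]
    for i in range(len(starts)):
        lo, hi = bounds[i], bounds[i + 1]
        ep_dates = tuple(dates.iloc[lo:hi])
        end = ep_dates[-1] + pd.Timedelta(days=_tail_days(qty[hi - 1], tail_cap_days))
        episodes.append(Episode(person_id, drug_group, ep_dates[0], end, ep_dates))
    return episodes


def build_episode_table(dispenses: pd.DataFrame,
                        drug_groups: dict[str, list[str]] | None = None,
                        gap_days: int = GAP_DAYS,
                        tail_cap_days: int = TAIL_CAP_DAYS) -> pd.DataFrame:
    """Vectorised cohort-scale episode construction.

    ``dispenses`` needs columns person_id, date, atc, n_ddd.  ATC codes are
    mapped onto drug groups (defaults from the shipped config); dispenses of
    codes outside every group are ignored.  Returns one row per episode with
    columns episode_id, person_id, drug_group, start_date, end_date,
    n_dispenses, dispense_dates (tuple) — equivalent to applying
    :func:`build_episodes` per person × group, but fast on large tables.
    """
    if drug_groups is None:
        drug_groups = resources.drug_groups()
    atc_to_group = {atc: grp for grp, atcs in drug_groups.items() for atc in atcs}

    df = dispenses.copy()
    if (df["n_ddd"] < 0).any():
        raise ValueError("negative dispensed quantity (n_ddd)")
    df["date"] = pd.to_datetime(df["date"])
    df["drug_group"] = df["atc"].map(atc_to_group)
    df = df.dropna(subset=["drug_group"])
    if df.empty:
        return pd.DataFrame(columns=[
            "episode_id", "person_id", "drug_group", "start_date", "end_date",
            "n_dispenses", "dispense_dates"])
    df = df.sort_values(["person_id", "drug_group", "date"], kind="stable")

    grp = df.groupby(["person_id", "drug_group"], sort=False)
    gap = grp["date"].diff().dt.days
    df["episode_id"] = (gap.isna() | (gap > gap_days)).cumsum()

    def _last_tail(s: pd.Series) -> int:
        return _tail_days(s.iloc[-1], tail_cap_days)

    agg = df.groupby("episode_id", sort=True).agg(
        person_id=("person_id", "first"),
        drug_group=("drug_group", "first"),
        start_date=("date", "first"),
        last_date=("date", "last"),
        n_dispenses=("date", "size"),
        tail=("n_ddd", _last_tail),
        dispense_dates=("date", lambda s: tuple(s)),
    ).reset_index()
    agg["end_date"] = agg["last_date"] + pd.to_timedelta(agg["tail"], unit="D")
    return agg[["episode_id", "person_id", "drug_group", "start_date",
                "end_date", "n_dispenses", "dispense_dates"]]


def filter_left_truncated(episodes: pd.DataFrame, earliest_valid_start) -> pd.DataFrame:
    """Drop potentially left-truncated episodes.

    An episode whose start lies within one refill gap of the start of registry
    coverage may be the continuation of an unobserved earlier treatment, so
    only episodes starting strictly after ``earliest_valid_start`` (coverage
    start + gap_days, e.g. 2005-10-31 for coverage from 2005-07-01) are kept.
    """
    if len(episodes) == 0:
        return episodes
    cutoff = pd.Timestamp(earliest_valid_start)
    return episodes[pd.to_datetime(episodes["start_date"]) > cutoff].reset_index(drop=True)


def mg_to_ddd(drug: str, total_mg: float, ddd_table: dict[str, float] | None = None) -> float:
    """Convert a dispensed milligram total into DDD units for one substance."""
    table = ddd_table if ddd_table is not None else resources.ddd_mg()
    try:
        ddd = table[drug.lower()]
    except KeyError:
        raise KeyError(f"no defined daily dose on record for {drug!r}") from None
    if total_mg < 0:
        raise ValueError("total_mg must be non-negative")
    return total_mg / ddd
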