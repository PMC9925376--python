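"""Derivation of the four analysis-ready outcome tables.

From reconstructed treatment episodes, inpatient admissions, deaths and the
full dispense history, this module builds one record per analysis unit for:

* **nonpersistence** — no refill within 4 months (122 days) of the first
  dispense of an episode (binary; persons who died within the window are
  excluded);
* **discontinuation** — time from episode start to the last day of treatment,
  censored at study end, death, or 365 days, whichever comes first;
* **switch** — time from a new-user index dispense (no antidepressant, ATC
  N06A, in the prior year) to the first dispense of a different N06A
  substance, censored at death, study end, or 365 days;
* **mania** — time from episode start to the first inpatient admission with a
  mania / mixed-episode diagnosis (ICD-10 F300–302, F308–309, F310–312,
  F316), censored at 91 days (3 months) or death.

Every record carries the covariates used downstream: sex, study wave, age at
treatment start, and the three co-medication flags (antidepressant
monotherapy, mood-stabilizer use, CYP2C19 inducer/inhibitor use).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import resources

__all__ = [
    "icd_mania_match",
    "parse_icd_codes",
    "covariate_flags",
    "nonpersistence_records",
    "discontinuation_records",
    "switch_records",
    "mania_records",
]

WINDOW_NONPERSISTENCE = 122
WINDOW_MANIA = 91          # "3 months" at 30.5 d/month
MAX_FOLLOWUP_DAYS = 365


def icd_mania_match(code: str, prefixes: frozenset[str] | None = None) -> bool:
    """True iff an ICD-10 code denotes a manic or mixed episode.

    Matching is on the first four characters, so sub-codes such as F3010
    match F301 while F313–F315 (remission / other bipolar codes outside the
    set) do not match.
    """
    if prefixes is None:
        prefixes = resources.mania_icd10_prefixes()
    return code[:4] in prefixes


def parse_icd_codes(joined: str) -> list[str]:
    """Split a semicolon-joined diagnosis field into individual codes."""
    if not isinstance(joined, str) or not joined:
        return []
    return [c.strip() for c in joined.split(";") if c.strip()]


# ---------------------------------------------------------------------------
# covariates


def _merge_offsets(episodes: pd.DataFrame, dispenses: pd.DataFrame) -> pd.DataFrame:
    """Episode × dispense pairs for the same person, with day offsets."""
    eps = episodes[["episode_id", "person_id", "start_date", "drug_group"]].copy()
    eps["start_date"] = pd.to_datetime(eps["start_date"])
    d = dispenses[["person_id", "date", "atc"]].copy()
    d["date"] = pd.to_datetime(d["date"])
    m = eps.merge(d, on="person_id", how="left")
    m["offset"] = (m["date"] - m["start_date"]).dt.days
    return m


def covariate_flags(episodes: pd.DataFrame, dispenses: pd.DataFrame,
                    drug_groups: dict[str, list[str]] | None = None,
                    n06a_window: int = 122,
                    ms_year_window: int = 365, ms_recent_window: int = 122,
                    inducer_window: int = 183) -> pd.DataFrame:
    """Per-episode co-medication flags computed from the full dispense history.

    * ``monotherapy_flag`` — no dispense of a *different* N06A substance in
      the ``n06a_window`` days up to and including the episode start;
    * ``mood_stabilizer_flag`` — for at least one of lithium / valproate /
      lamotrigine, ≥ 2 dispenses within the last year of which ≥ 1 within
      the last 4 months before start;
    * ``inducer_inhibitor_flag`` — any dispense of a CYP2C19 enzyme inducer
      or inhibitor within ``inducer_window`` days before start.
    """
    if drug_groups is None:
        drug_groups = resources.drug_groups()
    ms_set = resources.mood_stabilizer_atc()
    ind_set = resources.inducer_inhibitor_atc()

    m = _merge_offsets(episodes, dispenses)
    own = m["drug_group"].map({g: set(a) for g, a in drug_groups.items()})
    is_own = [a in s for a, s in zip(m["atc"].fillna(""), own)]
    m["is_other_n06a"] = m["atc"].fillna("").str.startswith("N06A") & ~np.asarray(is_own)

    in_n06a_win = m["is_other_n06a"] & m["offset"].between(-n06a_window, 0)
    other_n06a = in_n06a_win.groupby(m["episode_id"]).any()

    ms = m[m["atc"].isin(ms_set)].copy()
    if len(ms):
        ms["in_year"] = ms["offset"].between(-ms_year_window, 0)
        ms["recent"] = ms["offset"].between(-ms_recent_window, 0)
        per_drug = ms.groupby(["episode_id", "atc"]).agg(
            n_year=("in_year", "sum"), any_recent=("recent", "any"))
        ms_flag = ((per_drug["n_year"] >= 2) & per_drug["any_recent"]) \
            .groupby("episode_id").any()
    else:
        ms_flag = pd.Series(dtype=bool)

    in_ind_win = m["atc"].isin(ind_set) & m["offset"].between(-inducer_window, 0)
    ind_flag = in_ind_win.groupby(m["episode_id"]).any()

    out = pd.DataFrame(index=episodes["episode_id"])
    out["monotherapy_flag"] = ~other_n06a.reindex(out.index, fill_value=False)
    out["mood_stabilizer_flag"] = ms_flag.reindex(out.index, fill_value=False)
    out["inducer_inhibitor_flag"] = ind_flag.reindex(out.index, fill_value=False)
    return out.reset_index()


def _attach_person_covariates(records: pd.DataFrame, persons: pd.DataFrame,
                              phenotypes: pd.DataFrame | None) -> pd.DataFrame:
    p = persons[["person_id", "sex", "birth_year", "wave"]]
    out = records.merge(p, on="person_id", how="left")
    start = pd.to_datetime(out["start_date"])
    birth = pd.to_datetime(dict(year=out["birth_year"], month=1, day=1))
    out["age_at_start"] = (start - birth).dt.days / 365.25
    out = out.drop(columns=["birth_year"])
    if phenotypes is not None:
        cols = [c for c in ("person_id", "phenotype", "phenotype3",
                            "activity_score", "cyp2c_rank", "cyp2c_collapse3")
                if c in phenotypes.columns]
        out = out.merge(phenotypes[cols], on="person_id", how="left")
    return out


def _attach_flags(records: pd.DataFrame, episodes: pd.DataFrame,
                  dispenses: pd.DataFrame | None, flags: pd.DataFrame | None):
    if flags is None and dispenses is not None:
        flags = covariate_flags(episodes, dispenses)
    if flags is not None:
        records = records.merge(flags, on="episode_id", how="left")
    return records


def _death_offset(records: pd.DataFrame, persons: pd.DataFrame) -> pd.Series:
    death = persons.set_index("person_id")["death_date"]
    d = pd.to_datetime(records["person_id"].map(death))
    return (d - pd.to_datetime(records["start_date"])).dt.days


# ---------------------------------------------------------------------------
# outcome 1: early treatment non-persistence


def nonpersistence_records(episodes: pd.DataFrame, persons: pd.DataFrame,
                           window_days: int = WINDOW_NONPERSISTENCE,
                           phenotypes: pd.DataFrame | None = None,
                           dispenses: pd.DataFrame | None = None,
                           flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """One binary record per episode: no refill within ``window_days`` of the
    first dispense (event = 1).  The window is inclusive: a refill on day
    ``window_days`` exactly counts as persistence.  Episodes of persons who
    died within the window are excluded."""
    recs = episodes[["episode_id", "person_id", "drug_group",
                     "start_date", "dispense_dates"]].copy()

    def _refill_gap(dates) -> float:
        if len(dates) < 2:
            return np.inf
        return (pd.Timestamp(dates[1]) - pd.Timestamp(dates[0])).days

    gap = recs["dispense_dates"].map(_refill_gap)
    recs["event"] = (gap > window_days).astype(int)

    death_off = _death_offset(recs, persons)
    recs = recs[~(death_off <= window_days)].reset_index(drop=True)

    recs["outcome"] = "nonpersistence"
    recs = recs.drop(columns=["dispense_dates"])
    recs = _attach_flags(recs, episodes, dispenses, flags)
    return _attach_person_covariates(recs, persons, phenotypes)


# ---------------------------------------------------------------------------
# outcome 2: treatment discontinuation within 1 year


def discontinuation_records(episodes: pd.DataFrame, persons: pd.DataFrame,
                            study_end, max_days: int = MAX_FOLLOWUP_DAYS,
                            cap_days: int | None = None,
                            first_episode_only: bool = False,
                            phenotypes: pd.DataFrame | None = None,
                            dispenses: pd.DataFrame | None = None,
                            flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-episode survival record for treatment discontinuation.

    The event is the episode's last treatment day; censoring occurs at study
    end, death, or ``max_days`` after start, whichever comes first (ties
    count as censored).  ``cap_days`` restricts follow-up further (the
    60-day sensitivity variant); ``first_episode_only`` keeps each person's
    chronologically first episode per drug group."""
    eps = episodes.copy()
    eps["start_date"] = pd.to_datetime(eps["start_date"])
    eps["end_date"] = pd.to_datetime(eps["end_date"])
    study_end = pd.Timestamp(study_end)
    if (eps["start_date"] > study_end).any():
        raise ValueError("episode starts after study end")
    if first_episode_only:
        eps = eps.sort_values("start_date", kind="stable") \
                 .groupby(["person_id", "drug_group"], sort=False).head(1)

    recs = eps[["episode_id", "person_id", "drug_group", "start_date"]].copy()
    t_event = (eps["end_date"] - eps["start_date"]).dt.days
    censor = pd.concat([
        (study_end - eps["start_date"]).dt.days,
        _death_offset(recs, persons),
        pd.Series(float(max_days), index=eps.index),
    ], axis=1).min(axis=1)
    if cap_days is not None:
        censor = censor.clip(upper=cap_days)
    recs["event"] = (t_event.to_numpy() < censor.to_numpy()).astype(int)
    recs["time_days"] = np.minimum(t_event.to_numpy(), censor.to_numpy())
    recs["outcome"] = "discontinuation"
    recs = recs.reset_index(drop=True)
    recs = _attach_flags(recs, episodes, dispenses, flags)
    return _attach_person_covariates(recs, persons, phenotypes)


# ---------------------------------------------------------------------------
# outcome 3: switch to another antidepressant


def switch_records(dispenses: pd.DataFrame, persons: pd.DataFrame,
                   drug_group: str,
                   followup_start="2006-07-01", followup_end="2016-12-31",
                   washout_days: int = 365, max_days: int = MAX_FOLLOWUP_DAYS,
                   drug_groups: dict[str, list[str]] | None = None,
                   phenotypes: pd.DataFrame | None = None) -> pd.DataFrame:
    """New-user index dispenses of one study drug group and subsequent switches.

    An index event is a dispense of the group's substances inside the
    follow-up window with no N06A dispense in the preceding ``washout_days``
    (a same-day dispense of a different N06A substance makes the start
    ambiguous and excludes the index).  The event is the first later dispense
    of a *different* N06A substance within ``max_days``; censoring occurs at
    death, ``followup_end``, or ``max_days``."""
    if drug_groups is None:
        drug_groups = resources.drug_groups()
    group_atcs = set(drug_groups[drug_group])
    f_start, f_end = pd.Timestamp(followup_start), pd.Timestamp(followup_end)

    d = dispenses[dispenses["atc"].str.startswith("N06A")].copy()
    d["date"] = pd.to_datetime(d["date"])
    d = d.drop_duplicates(subset=["person_id", "date", "atc"])
    d = d.sort_values(["person_id", "date"], kind="stable")
    death = persons.set_index("person_id")["death_date"]

    rows = []
    for pid, g in d.groupby("person_id", sort=False):
        dates = g["date"].to_numpy()
        atcs = g["atc"].to_numpy()
        for i in range(len(g)):
            if atcs[i] not in group_atcs:
                continue
            d0 = dates[i]
            if d0 < f_start or d0 > f_end:
                continue
            prior = (dates < d0) & (dates >= d0 - np.timedelta64(washout_days, "D"))
            if prior.any():
                continue
            if ((dates == d0) & (atcs != atcs[i])).any():
                continue  # ambiguous same-day start of another antidepressant
            later = (dates > d0) & (dates <= d0 + np.timedelta64(max_days, "D")) \
                & (atcs != atcs[i])
            censor = float(min((f_end - pd.Timestamp(d0)).days, max_days))
            dd = death.get(pid)
            if pd.notna(dd):
                censor = min(censor, (pd.Timestamp(dd) - pd.Timestamp(d0)).days)
            if later.any():
                t = (dates[later][0] - d0) / np.timedelta64(1, "D")
                event, time = 1, float(t)
            else:
                event, time = 0, censor
            rows.append((pid, d0, event, time))

    recs = pd.DataFrame(rows, columns=["person_id", "start_date", "event", "time_days"])
    recs["drug_group"] = drug_group
    recs["outcome"] = "switch"
    recs["episode_id"] = np.arange(len(recs))
    return _attach_person_covariates(recs, persons, phenotypes)


# ---------------------------------------------------------------------------
# outcome 4: treatment-emergent mania


def mania_records(episodes: pd.DataFrame, admissions: pd.DataFrame,
                  persons: pd.DataFrame, window_days: int = WINDOW_MANIA,
                  use_discharge: bool = False,
                  phenotypes: pd.DataFrame | None = None,
                  dispenses: pd.DataFrame | None = None,
                  flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-episode survival record for inpatient mania within ``window_days``.

    The event is the first admission carrying any mania/mixed-episode
    diagnosis dated within ``window_days`` of the episode start (event time
    anchored at the admission date by default — admission marks onset —
    or the discharge date with ``use_discharge``).  Censoring occurs at
    ``window_days`` or death, whichever comes first."""
    prefixes = resources.mania_icd10_prefixes()
    adm = admissions.copy()
    codes = adm["icd10_codes"].map(parse_icd_codes)
    is_mania = codes.map(lambda cs: any(icd_mania_match(c, prefixes) for c in cs))
    adm = adm[is_mania.to_numpy(dtype=bool)] if len(adm) else adm
    date_col = "discharge_date" if use_discharge else "admission_date"

    recs = episodes[["episode_id", "person_id", "drug_group", "start_date"]].copy()
    recs["start_date"] = pd.to_datetime(recs["start_date"])

    if len(adm):
        a = adm[["person_id", date_col]].copy()
        a["event_date"] = pd.to_datetime(a[date_col])
        m = recs.merge(a[["person_id", "event_date"]], on="person_id", how="inner")
        m["off"] = (m["event_date"] - m["start_date"]).dt.days
        m = m[(m["off"] >= 0) & (m["off"] <= window_days)]
        first = m.groupby("episode_id")["off"].min()
    else:
        first = pd.Series(dtype=float)

    death_off = _death_offset(recs, persons)
    censor = pd.Series(float(window_days), index=recs.index)
    censor = pd.concat([censor, death_off], axis=1).min(axis=1)
    ev_time = recs["episode_id"].map(first)
    has_event = ev_time.notna() & (ev_time <= censor)
    recs["event"] = has_event.astype(int)
    recs["time_days"] = np.where(has_event, ev_time, censor)
    recs["outcome"] = "mania"
    recs = _attach_flags(recs, episodes, dispenses, flags)
    return _attach_person_covariates(recs, persons, phenotypes)
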