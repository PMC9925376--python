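"""Synthetic prescription-registry cohorts for end-to-end pipeline testing.

Real dispensation and inpatient registries are not redistributable, so this
module generates cohorts with the statistical structure the analysis
assumes: phased CYP2C19 haplotypes at realistic frequencies, per-person
refill streams of antidepressant dispenses with dropout, co-medication,
deaths, and rare inpatient mania admissions whose hazard during the first
91 days of a treatment episode follows a log-linear trend in the inverted
activity score:

    h(score) = baseline_mania_hazard * exp(true_log_hr_per_step * (score - 3))

with the EM score (3) as the anchor.  A low phenotype-independent background
admission rate is on by default so the specificity of the 91-day outcome
window is itself testable.

Determinism: one random generator per output table, each seeded from the
master seed, so regenerating one table never perturbs the others and the
same configuration always yields byte-identical CSVs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import resources
from .episodes import build_episode_table

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_persons",
    "simulate_dispense_histories",
    "simulate_mania_admissions",
    "simulate_registry",
    "write_tables",
]

_HAPLOTYPE_SNPS = {"*1": ("G", "C"), "*2": ("A", "C"), "*17": ("G", "T")}

#: substances the simulator can dispense beyond the study drugs
_OTHER_N06A = ("N06AX11", "N06AX16", "N06AX03")   # mirtazapine, venlafaxine, mianserin
_BACKGROUND_NONMANIA = ("F313", "F315", "F320", "F329")


@dataclass
class SimulationConfig:
    """Free parameters of the synthetic registry.

    Haplotype frequencies default to the common European functional alleles
    (*2 from rs4244285-A at MAF 0.147, *17 from rs12248560-T at MAF 0.19).
    Registry coverage, the refill economy (≤3 months' supply, repurchase
    after two thirds of it) and the covariate structure mirror the Swedish
    registry design the analysis targets; refill-interval and dropout
    parameters are free choices, not registry estimates.
    """
    n_subjects: int = 1000
    haplotype_freqs: dict = field(default_factory=lambda: {
        "*1": 0.663, "*2": 0.147, "*17": 0.190})
    p_tg_given_star1: float = 0.30
    study_start: str = "2005-07-01"
    study_end: str = "2016-12-31"
    #: per-subject per-year initiation probability, per drug group
    drug_initiation_rate: dict = field(default_factory=lambda: {
        "escitalopram_citalopram": 0.035,
        "sertraline": 0.027,
        "amitriptyline_clomipramine": 0.014})
    mean_dispense_ddd: float = 90.0
    sd_dispense_ddd: float = 15.0
    refill_interval_mean: float = 85.0
    refill_interval_sd: float = 20.0
    refill_dropout_prob: float = 0.15
    true_log_hr_per_step: float = 0.0
    baseline_mania_hazard: float = 1.66e-4   # events / person-day at score 3
    background_mania_rate: float = 0.002     # admissions / person-year, any time
    death_rate: float = 0.006                # deaths / person-year
    #: per-subject per-year initiation probability of co-medication streams
    comedication_rates: dict = field(default_factory=lambda: {
        "other_n06a": 0.05, "mood_stabilizer": 0.10, "inducer_inhibitor": 0.03})
    p_female: float = 0.62
    wave_probs: tuple = (1 / 3, 1 / 3, 1 / 3)
    emit_cyp2c_snps: bool = True
    seed: int = 0

    def validate(self) -> None:
        freq_sum = sum(self.haplotype_freqs.values())
        if abs(freq_sum - 1.0) > 1e-8 or min(self.haplotype_freqs.values()) < 0:
            raise ValueError(f"haplotype frequencies must be non-negative and sum to 1 "
                             f"(got sum {freq_sum})")
        for name in ("p_tg_given_star1", "refill_dropout_prob", "p_female"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.wave_probs) - 1.0) > 1e-8 or min(self.wave_probs) < 0:
            raise ValueError("wave probabilities must be non-negative and sum to 1")
        if pd.Timestamp(self.study_start) >= pd.Timestamp(self.study_end):
            raise ValueError("study_start must precede study_end")
        for name in ("baseline_mania_hazard", "background_mania_rate", "death_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for d in (self.drug_initiation_rate, self.comedication_rates):
            if any(r < 0 for r in d.values()):
                raise ValueError("initiation rates must be non-negative")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")

    @property
    def n_days(self) -> int:
        return int((pd.Timestamp(self.study_end) - pd.Timestamp(self.study_start)).days)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wave_probs"] = list(self.wave_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "wave_probs" in d:
            d["wave_probs"] = tuple(d["wave_probs"])
        return cls(**d)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    return {name: np.random.default_rng(ss)
            for name, ss in zip(("persons", "genotypes", "dispenses", "admissions"),
                                children)}


def _days_to_dates(days, start) -> pd.Series:
    return pd.Timestamp(start) + pd.to_timedelta(np.asarray(days, dtype=int), unit="D")


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(n: int, freqs: dict, seed_or_rng,
                       p_tg_given_star1: float = 0.30,
                       emit_cyp2c_snps: bool = True,
                       person_ids=None) -> pd.DataFrame:
    """Draw ``n`` phased genotypes as two independent haplotypes.

    ``freqs`` maps star-allele labels (*1, *2, *17) to haplotype
    frequencies summing to 1.  No emitted haplotype ever carries both the
    *2- and the *17-defining variant.  With ``emit_cyp2c_snps`` the two
    extra SNPs of the CYP2C:TG haplotype are emitted: a fraction
    ``p_tg_given_star1`` of *1 haplotypes carry the TG configuration.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    labels = list(freqs)
    probs = np.asarray([freqs[k] for k in labels], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8 or (probs < 0).any():
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    if n <= 0:
        raise ValueError("n must be positive")
    if person_ids is None:
        person_ids = [f"P{i:06d}" for i in range(n)]

    out = {"person_id": person_ids}
    for h in ("h1", "h2"):
        draw = rng.choice(len(labels), size=n, p=probs)
        stars = np.asarray(labels, dtype=object)[draw]
        out[f"{h}_rs4244285"] = np.where(stars == "*2", "A", "G")
        out[f"{h}_rs12248560"] = np.where(stars == "*17", "T", "C")
        if emit_cyp2c_snps:
            tg = (stars == "*1") & (rng.random(n) < p_tg_given_star1)
            out[f"{h}_rs2860840"] = np.where(tg, "T", "C")
            out[f"{h}_rs11188059"] = "G"
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# persons


def simulate_persons(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    ids = [f"P{i:06d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    # adults (>= 18) at study start
    start_year = pd.Timestamp(config.study_start).year
    birth_year = rng.integers(start_year - 80, start_year - 18, size=n, endpoint=True)
    wave = rng.choice([1, 2, 3], size=n, p=np.asarray(config.wave_probs))
    if config.death_rate > 0:
        death_day = rng.exponential(365.25 / config.death_rate, size=n)
    else:
        death_day = np.full(n, np.inf)
    alive = death_day > config.n_days
    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    death_date[~alive] = _days_to_dates(death_day[~alive], config.study_start)
    return pd.DataFrame({
        "person_id": ids, "sex": sex, "birth_year": birth_year,
        "death_date": death_date.to_numpy(), "wave": wave,
    })


# ---------------------------------------------------------------------------
# dispenses


def _stream_dates(rng: np.random.Generator, start: float, horizon: float,
                  config: SimulationConfig) -> np.ndarray:
    """One refill stream: first dispense at ``start``, refills at roughly the
    refill interval until a per-refill dropout event; truncated at horizon."""
    p = config.refill_dropout_prob
    # intervals are >= 1 day, so the horizon bounds the dispense count
    n_max = int(max(horizon - start, 0)) + 1
    if p >= 1.0:
        n = 1
    elif p <= 0.0:
        n = n_max
    else:
        n = min(int(rng.geometric(p)), n_max)
    if n > 1:
        iv = np.maximum(1, np.rint(rng.normal(
            config.refill_interval_mean, config.refill_interval_sd, n - 1)))
        days = start + np.concatenate(([0.0], np.cumsum(iv)))
    else:
        days = np.asarray([float(start)])
    return days[days <= horizon]


def _person_stream(rng, horizon: float, rate_per_year: float,
                   config: SimulationConfig) -> np.ndarray | None:
    """At most one initiation per person × drug: the per-year initiation rate
    sets the probability of ever initiating (1 − exp(−rate·years)); the first
    dispense date is uniform over the study window, and the stream is
    truncated at death/study end."""
    if rate_per_year <= 0:
        return None
    years = config.n_days / 365.25
    if rng.random() >= 1.0 - np.exp(-rate_per_year * years):
        return None
    start = rng.uniform(0, config.n_days)
    if start > horizon:
        return None  # initiation would fall after death
    return _stream_dates(rng, start, horizon, config)


def simulate_dispense_histories(persons: pd.DataFrame, config: SimulationConfig,
                                rng: np.random.Generator) -> pd.DataFrame:
    """Dispense streams for study drugs and co-medications.

    Each initiated person × drug stream is an ordered series: first dispense
    at the initiation time, refill intervals around ``refill_interval_mean``
    until dropout, quantities around ``mean_dispense_ddd``.  No dispense is
    ever dated after the person's death.
    """
    config.validate()
    d = resources.defaults()
    groups = resources.drug_groups()
    pools: list[tuple[str, float, tuple[str, ...]]] = []
    for grp, rate in config.drug_initiation_rate.items():
        pools.append((grp, rate, tuple(groups[grp])))
    comed_atcs = {
        "other_n06a": _OTHER_N06A,
        "mood_stabilizer": tuple(d["mood_stabilizer_atc"]),
        "inducer_inhibitor": tuple(d["inducer_atc"]) + tuple(d["inhibitor_atc"]),
    }
    for cls, rate in config.comedication_rates.items():
        pools.append((cls, rate, comed_atcs[cls]))

    start_ts = pd.Timestamp(config.study_start)
    n_days = config.n_days
    death_off = (pd.to_datetime(persons["death_date"]) - start_ts).dt.days.to_numpy()

    pid_col, day_col, atc_col, qty_col = [], [], [], []
    for pid, doff in zip(persons["person_id"].to_numpy(), death_off):
        horizon = n_days if np.isnan(doff) else min(n_days, doff)
        for _, rate, atcs in pools:
            dates = _person_stream(rng, horizon, rate, config)
            if dates is not None and len(dates):
                atc = atcs[rng.integers(len(atcs))]
                qty = np.maximum(1.0, rng.normal(
                    config.mean_dispense_ddd, config.sd_dispense_ddd, len(dates)))
                pid_col.extend([pid] * len(dates))
                day_col.extend(dates.astype(int).tolist())
                atc_col.extend([atc] * len(dates))
                qty_col.extend(np.round(qty, 1).tolist())

    out = pd.DataFrame({
        "person_id": pid_col,
        "date": _days_to_dates(day_col, config.study_start) if day_col else
        pd.Series(dtype="datetime64[ns]"),
        "atc": atc_col, "n_ddd": qty_col,
    })
    return out.sort_values(["person_id", "date", "atc"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# admissions


def simulate_mania_admissions(persons: pd.DataFrame, episodes: pd.DataFrame,
                              activity_scores: pd.Series | dict,
                              config: SimulationConfig,
                              rng: np.random.Generator,
                              window_days: int = 91) -> pd.DataFrame:
    """Inpatient mania admissions: treatment-emergent plus background.

    For each episode an exponential event time is drawn at the person's
    score-dependent hazard; events landing within the first ``window_days``
    of the episode (and before death) become admissions with a mania/mixed
    ICD-10 discharge code.  Background admissions (phenotype-independent,
    uniform over the study period, mania or non-mania bipolar codes) are
    generated at ``background_mania_rate``.
    """
    config.validate()
    mania_codes = sorted(resources.mania_icd10_prefixes())
    scores = pd.Series(activity_scores)
    start_ts = pd.Timestamp(config.study_start)

    rows = []  # (person_id, admission_day, discharge_day, codes)
    if len(episodes) and config.baseline_mania_hazard > 0:
        ep_pid = episodes["person_id"].to_numpy()
        ep_start = (pd.to_datetime(episodes["start_date"]) - start_ts).dt.days.to_numpy()
        sc = scores.reindex(ep_pid).to_numpy(dtype=float)
        hazard = config.baseline_mania_hazard * np.exp(
            config.true_log_hr_per_step * (sc - 3.0))
        t = rng.exponential(1.0 / hazard)
        death_off = (pd.to_datetime(persons.set_index("person_id")["death_date"])
                     - start_ts).dt.days
        d_off = pd.Series(ep_pid).map(death_off).to_numpy(dtype=float)
        limit = np.where(np.isnan(d_off), window_days,
                         np.minimum(window_days, d_off - ep_start))
        hit = t <= limit
        for pid, s0, ti in zip(ep_pid[hit], ep_start[hit], t[hit]):
            adm = int(s0 + np.ceil(ti))
            dis = adm + int(rng.integers(3, 28))
            code = mania_codes[rng.integers(len(mania_codes))]
            rows.append((pid, adm, dis, code))

    if config.background_mania_rate > 0:
        years = config.n_days / 365.25
        counts = rng.poisson(config.background_mania_rate * years,
                             size=len(persons))
        death_off = (pd.to_datetime(persons["death_date"]) - start_ts).dt.days.to_numpy()
        for pid, k, doff in zip(persons["person_id"], counts, death_off):
            horizon = config.n_days if np.isnan(doff) else min(config.n_days, doff)
            for _ in range(int(k)):
                adm = int(rng.integers(0, max(int(horizon), 1)))
                dis = adm + int(rng.integers(3, 28))
                if rng.random() < 0.5:
                    code = mania_codes[rng.integers(len(mania_codes))]
                else:
                    code = _BACKGROUND_NONMANIA[rng.integers(len(_BACKGROUND_NONMANIA))]
                rows.append((pid, adm, dis, code))

    if not rows:
        return pd.DataFrame(columns=["person_id", "admission_date",
                                     "discharge_date", "icd10_codes"])
    out = pd.DataFrame(rows, columns=["person_id", "adm", "dis", "icd10_codes"])
    out["admission_date"] = _days_to_dates(out.pop("adm"), config.study_start)
    out["discharge_date"] = _days_to_dates(out.pop("dis"), config.study_start)
    out = out[["person_id", "admission_date", "discharge_date", "icd10_codes"]]
    return out.sort_values(["person_id", "admission_date"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# orchestration


def simulate_registry(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Generate the four registry tables for one configuration.

    Episode construction (needed to place treatment-emergent events) uses
    the same gap/tail rules the analysis applies, so simulated event windows
    line up with reconstructed episodes.
    """
    from .phenotypes import classify_cohort

    config.validate()
    rngs = _rngs(config.seed)
    persons = simulate_persons(config, rngs["persons"])
    genotypes = simulate_genotypes(
        config.n_subjects, config.haplotype_freqs, rngs["genotypes"],
        p_tg_given_star1=config.p_tg_given_star1,
        emit_cyp2c_snps=config.emit_cyp2c_snps,
        person_ids=persons["person_id"].tolist())
    dispenses = simulate_dispense_histories(persons, config, rngs["dispenses"])
    episodes = build_episode_table(dispenses)
    phen = classify_cohort(genotypes)
    scores = phen.set_index("person_id")["activity_score"]
    admissions = simulate_mania_admissions(
        persons, episodes, scores, config, rngs["admissions"])
    return {"persons": persons, "genotypes": genotypes,
            "dispenses": dispenses, "admissions": admissions}


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, str]:
    """Serialize registry tables as headered UTF-8 CSVs with ISO-8601 dates."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        df = df.copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)
    return paths


def read_tables(in_dir) -> dict[str, pd.DataFrame]:
    """Read the four registry tables written by :func:`write_tables`."""
    in_dir = Path(in_dir)
    tables = {}
    for name in ("persons", "genotypes", "dispenses", "admissions"):
        path = in_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing registry table {path}")
        df = pd.read_csv(path)
        for col in ("date", "death_date", "admission_date", "discharge_date"):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        tables[name] = df
    return tables
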