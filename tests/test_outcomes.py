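"""Outcome derivations: ICD matching, refill windows, censoring, flags."""
import numpy as np
import pandas as pd
import pytest

from pgxreg import outcomes as oc
from conftest import make_persons

D0 = pd.Timestamp("2010-01-01")


def make_episodes(rows):
    """rows: (person_id, drug_group, start_offset, end_offset, dispense_offsets)."""
    recs = []
    for i, (pid, grp, s, e, disp) in enumerate(rows):
        recs.append({
            "episode_id": i, "person_id": pid, "drug_group": grp,
            "start_date": D0 + pd.Timedelta(days=s),
            "end_date": D0 + pd.Timedelta(days=e),
            "n_dispenses": len(disp),
            "dispense_dates": tuple(D0 + pd.Timedelta(days=o) for o in disp),
        })
    return pd.DataFrame(recs)


@pytest.mark.parametrize("code, expected", [
    ("F301", True),       # manic episode range
    ("F316", True),       # mixed episode
    ("F313", False),      # the set skips F313–F315
    ("F3010", True),      # longer codes match on the 4-character prefix
    ("F32", False),       # depressive episode
    ("Z032", False),
])
def test_icd_mania_match(code, expected):
    assert oc.icd_mania_match(code) is expected


def test_parse_icd_codes():
    assert oc.parse_icd_codes("F301; F320 ;") == ["F301", "F320"]
    assert oc.parse_icd_codes("") == []


class TestNonpersistence:
    def test_refill_inside_window_is_persistence(self):
        eps = make_episodes([("a", "sertraline", 0, 200, [0, 60, 150])])
        recs = oc.nonpersistence_records(eps, make_persons(["a"]))
        assert recs["event"].tolist() == [0]

    def test_single_dispense_is_event(self):
        eps = make_episodes([("a", "sertraline", 0, 90, [0])])
        recs = oc.nonpersistence_records(eps, make_persons(["a"]))
        assert recs["event"].tolist() == [1]

    def test_refill_on_boundary_day_counts(self):
        eps = make_episodes([("a", "sertraline", 0, 250, [0, 122])])
        recs = oc.nonpersistence_records(eps, make_persons(["a"]))
        assert recs["event"].tolist() == [0]

    def test_death_within_window_excluded(self):
        eps = make_episodes([("a", "sertraline", 0, 90, [0]),
                             ("b", "sertraline", 0, 90, [0])])
        persons = make_persons(["a", "b"],
                               death_dates=[D0 + pd.Timedelta(days=30), None])
        recs = oc.nonpersistence_records(eps, persons)
        assert recs["person_id"].tolist() == ["b"]

    def test_record_count_identity(self):
        """Records + death-excluded episodes = total episodes."""
        eps = make_episodes([("a", "sertraline", 0, 90, [0]),
                             ("b", "sertraline", 0, 90, [0]),
                             ("c", "sertraline", 0, 200, [0, 60])])
        persons = make_persons(["a", "b", "c"],
                               death_dates=[D0 + pd.Timedelta(days=100), None, None])
        recs = oc.nonpersistence_records(eps, persons)
        assert len(recs) + 1 == len(eps)


class TestDiscontinuation:
    STUDY_END = D0 + pd.Timedelta(days=4000)

    def test_treatment_end_before_censoring_is_event(self):
        eps = make_episodes([("a", "sertraline", 0, 130, [0, 100])])
        recs = oc.discontinuation_records(eps, make_persons(["a"]), self.STUDY_END)
        assert recs.loc[0, "event"] == 1 and recs.loc[0, "time_days"] == 130

    def test_administrative_cap_at_one_year(self):
        eps = make_episodes([("a", "sertraline", 0, 400, [0, 100, 200, 300])])
        recs = oc.discontinuation_records(eps, make_persons(["a"]), self.STUDY_END)
        assert recs.loc[0, "event"] == 0 and recs.loc[0, "time_days"] == 365

    def test_death_censors_before_treatment_end(self):
        eps = make_episodes([("a", "sertraline", 0, 130, [0, 100])])
        persons = make_persons(["a"], death_dates=[D0 + pd.Timedelta(days=100)])
        recs = oc.discontinuation_records(eps, persons, self.STUDY_END)
        assert recs.loc[0, "event"] == 0 and recs.loc[0, "time_days"] == 100

    def test_sixty_day_cap_variant(self):
        eps = make_episodes([("a", "sertraline", 0, 130, [0, 100])])
        recs = oc.discontinuation_records(eps, make_persons(["a"]),
                                          self.STUDY_END, cap_days=60)
        assert recs.loc[0, "event"] == 0 and recs.loc[0, "time_days"] == 60

    def test_first_episode_only_variant(self):
        eps = make_episodes([("a", "sertraline", 0, 130, [0, 100]),
                             ("a", "sertraline", 400, 500, [400])])
        recs = oc.discontinuation_records(eps, make_persons(["a"]), self.STUDY_END,
                                          first_episode_only=True)
        assert len(recs) == 1 and recs.loc[0, "time_days"] == 130

    def test_start_after_study_end_is_error(self):
        eps = make_episodes([("a", "sertraline", 0, 130, [0])])
        with pytest.raises(ValueError, match="study end"):
            oc.discontinuation_records(eps, make_persons(["a"]),
                                       D0 - pd.Timedelta(days=1))


def _dispense_frame(rows):
    """rows: (person_id, offset_days, atc)."""
    return pd.DataFrame({
        "person_id": [r[0] for r in rows],
        "date": [D0 + pd.Timedelta(days=r[1]) for r in rows],
        "atc": [r[2] for r in rows],
        "n_ddd": 90.0,
    })


class TestSwitch:
    F_END = (D0 + pd.Timedelta(days=3000)).strftime("%Y-%m-%d")

    def _records(self, rows, persons=None):
        persons = persons if persons is not None else make_persons(
            sorted({r[0] for r in rows}))
        return oc.switch_records(_dispense_frame(rows), persons, "sertraline",
                                 followup_start=D0.strftime("%Y-%m-%d"),
                                 followup_end=self.F_END)

    def test_new_substance_within_year_is_switch(self):
        recs = self._records([("a", 0, "N06AB06"), ("a", 200, "N06AX11")])
        assert recs["event"].tolist() == [1]
        assert recs["time_days"].tolist() == [200.0]

    def test_prior_antidepressant_breaks_washout(self):
        recs = self._records([("a", -100, "N06AB04"), ("a", 0, "N06AB06")])
        assert len(recs) == 0

    def test_same_substance_refills_are_not_switches(self):
        recs = self._records([("a", 0, "N06AB06"), ("a", 90, "N06AB06")])
        assert recs["event"].tolist() == [0]
        assert recs["time_days"].tolist() == [365.0]

    def test_same_day_other_antidepressant_excludes_index(self):
        recs = self._records([("a", 0, "N06AB06"), ("a", 0, "N06AX11")])
        assert len(recs) == 0

    def test_index_events_subset_of_episode_starts(self):
        rows = [("a", 0, "N06AB06"), ("a", 90, "N06AB06"), ("a", 600, "N06AB06")]
        from pgxreg.episodes import build_episode_table
        eps = build_episode_table(_dispense_frame(rows))
        recs = self._records(rows)
        starts = set(pd.to_datetime(eps["start_date"]))
        assert set(pd.to_datetime(recs["start_date"])) <= starts


def make_admissions(rows):
    """rows: (person_id, adm_offset, dis_offset, codes)."""
    return pd.DataFrame({
        "person_id": [r[0] for r in rows],
        "admission_date": [D0 + pd.Timedelta(days=r[1]) for r in rows],
        "discharge_date": [D0 + pd.Timedelta(days=r[2]) for r in rows],
        "icd10_codes": [r[3] for r in rows],
    })


class TestMania:
    def test_mania_admission_in_window_is_event(self):
        eps = make_episodes([("a", "sertraline", 0, 300, [0, 100])])
        adm = make_admissions([("a", 45, 60, "F301;Z032")])
        recs = oc.mania_records(eps, adm, make_persons(["a"]))
        assert recs.loc[0, "event"] == 1 and recs.loc[0, "time_days"] == 45

    def test_admission_outside_window_censored_at_91(self):
        eps = make_episodes([("a", "sertraline", 0, 300, [0, 100])])
        adm = make_admissions([("a", 120, 130, "F310")])
        recs = oc.mania_records(eps, adm, make_persons(["a"]))
        assert recs.loc[0, "event"] == 0 and recs.loc[0, "time_days"] == 91

    def test_non_mania_diagnosis_is_not_an_event(self):
        eps = make_episodes([("a", "sertraline", 0, 300, [0, 100])])
        adm = make_admissions([("a", 10, 20, "F320")])
        recs = oc.mania_records(eps, adm, make_persons(["a"]))
        assert recs.loc[0, "event"] == 0

    def test_death_censors_the_window(self):
        eps = make_episodes([("a", "sertraline", 0, 300, [0])])
        persons = make_persons(["a"], death_dates=[D0 + pd.Timedelta(days=40)])
        recs = oc.mania_records(eps, make_admissions([]), persons)
        assert recs.loc[0, "event"] == 0 and recs.loc[0, "time_days"] == 40

    def test_discharge_date_anchor_option(self):
        eps = make_episodes([("a", "sertraline", 0, 300, [0])])
        adm = make_admissions([("a", 45, 60, "F301")])
        recs = oc.mania_records(eps, adm, make_persons(["a"]), use_discharge=True)
        assert recs.loc[0, "time_days"] == 60

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(99)
        pids = [f"p{i}" for i in range(30)]
        eps = make_episodes([
            (rng.choice(pids), "sertraline", int(s), int(s) + 200, [int(s)])
            for s in rng.integers(0, 1000, 60)])
        codes = ["F301", "F310", "F320", "F313", "F316"]
        adm = make_admissions([
            (rng.choice(pids), int(a), int(a) + 10, str(rng.choice(codes)))
            for a in rng.integers(0, 1200, 80)])
        persons = make_persons(pids)
        recs = oc.mania_records(eps, adm, persons).set_index("episode_id")

        for _, e in eps.iterrows():
            hits = []
            for _, a in adm.iterrows():
                if a["person_id"] != e["person_id"]:
                    continue
                if not oc.icd_mania_match(a["icd10_codes"]):
                    continue
                off = (a["admission_date"] - e["start_date"]).days
                if 0 <= off <= 91:
                    hits.append(off)
            row = recs.loc[e["episode_id"]]
            if hits:
                assert row["event"] == 1 and row["time_days"] == min(hits)
            else:
                assert row["event"] == 0 and row["time_days"] == 91

    def test_followup_never_exceeds_cap(self, null_fixture):
        _, tables = null_fixture
        from pgxreg.episodes import build_episode_table
        eps = build_episode_table(tables["dispenses"])
        recs = oc.mania_records(eps, tables["admissions"], tables["persons"])
        assert (recs["time_days"] <= 91).all()
        assert (recs["time_days"] >= 0).all()


class TestCovariateFlags:
    def _flags(self, disp_rows, start=0):
        eps = make_episodes([("a", "sertraline", start, start + 200, [start])])
        return oc.covariate_flags(eps, _dispense_frame(disp_rows)).iloc[0]

    def test_other_antidepressant_breaks_monotherapy(self):
        f = self._flags([("a", -30, "N06AX11"), ("a", 0, "N06AB06")])
        assert not f["monotherapy_flag"]

    def test_own_drug_dispenses_keep_monotherapy(self):
        f = self._flags([("a", 0, "N06AB06"), ("a", -100, "N06AB06")])
        assert f["monotherapy_flag"]

    def test_mood_stabilizer_two_dispense_rule(self):
        f = self._flags([("a", -300, "N05AN01"), ("a", -60, "N05AN01"),
                         ("a", 0, "N06AB06")])
        assert f["mood_stabilizer_flag"]

    def test_single_old_lithium_dispense_insufficient(self):
        f = self._flags([("a", -300, "N05AN01"), ("a", 0, "N06AB06")])
        assert not f["mood_stabilizer_flag"]

    def test_two_old_dispenses_without_recent_insufficient(self):
        f = self._flags([("a", -300, "N05AN01"), ("a", -200, "N05AN01"),
                         ("a", 0, "N06AB06")])
        assert not f["mood_stabilizer_flag"]

    def test_inducer_within_six_months_flags(self):
        f = self._flags([("a", -100, "N03AF01"), ("a", 0, "N06AB06")])
        assert f["inducer_inhibitor_flag"]

    def test_inhibitor_outside_window_does_not_flag(self):
        f = self._flags([("a", -200, "A02BC01"), ("a", 0, "N06AB06")])
        assert not f["inducer_inhibitor_flag"]
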