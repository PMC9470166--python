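"""Microstructure feature extraction, intake, inclusion filter, correlations."""

import numpy as np
import pandas as pd
import pytest

from sipstruct.errors import ValidationError
from sipstruct.features import (
    FEATURE_NAMES,
    Densities,
    compute_intake,
    extract_features,
    feature_table,
    inclusion_filter,
    intake_microstructure_correlation,
)
from sipstruct.lickometer import BoutRecord

from conftest import make_session, simple_bout


def reference_features(session):
    """Independent single-pass reference over the bout list."""
    T = session.session_length_s
    bouts = sorted(session.bouts, key=lambda b: b.start)
    out = dict.fromkeys(FEATURE_NAMES, 0.0)
    out["latency_to_drink_s"] = T
    out["mean_inter_drink_interval_s"] = T
    out["max_inter_drink_interval_s"] = T
    total_licks = total_dur = 0.0
    idis = []
    for i, b in enumerate(bouts):
        total_licks += b.n_licks
        total_dur += b.lick_duration
        out["max_bout_length_s"] = max(out["max_bout_length_s"], b.span)
        out["max_licks_per_bout"] = max(out["max_licks_per_bout"], b.n_licks)
        out["max_lick_duration_per_bout_s"] = max(
            out["max_lick_duration_per_bout_s"], b.lick_duration
        )
        if b.start < 1800.0:
            out["licks_first_30min"] += b.n_licks
            out["lick_duration_first_30min_s"] += b.lick_duration
            out["bouts_first_30min"] += 1
        if i > 0:
            idis.append(b.start - bouts[i - 1].end)
    n = len(bouts)
    out["total_licks"] = total_licks
    out["total_lick_duration_s"] = total_dur
    out["total_bouts"] = n
    if n:
        out["mean_licks_per_bout"] = total_licks / n
        out["mean_lick_duration_per_bout_s"] = total_dur / n
        out["mean_bout_length_s"] = sum(b.span for b in bouts) / n
        out["latency_to_drink_s"] = bouts[0].start
    if idis:
        out["mean_inter_drink_interval_s"] = sum(idis) / len(idis)
        out["max_inter_drink_interval_s"] = max(idis)
    out["lick_rate_per_min"] = total_licks / (T / 60.0)
    out["bout_rate_per_min"] = n / (T / 60.0)
    out["front_loading_index"] = out["bouts_first_30min"] / max(n, 1)
    return out


class TestExtractFeatures:
    def test_registry_arity_and_order(self):
        fv = extract_features(make_session([simple_bout(60.0)]))
        assert tuple(fv.features.keys()) == FEATURE_NAMES
        assert len(fv.features) == 18

    def test_empty_session_imputation(self):
        fv = extract_features(make_session([], length_h=2.0)).features
        assert fv["total_licks"] == fv["total_bouts"] == fv["max_licks_per_bout"] == 0
        assert fv["latency_to_drink_s"] == 7200.0
        assert fv["mean_inter_drink_interval_s"] == 7200.0
        assert fv["max_inter_drink_interval_s"] == 7200.0
        assert fv["lick_rate_per_min"] == 0.0
        assert fv["front_loading_index"] == 0.0

    def test_hand_computed_three_bout_session(self):
        # bouts at 60 s, 400 s, 2000 s; 2 s span, 5 licks each, in a 2 h session
        bouts = [simple_bout(60.0), simple_bout(400.0), simple_bout(2000.0)]
        fv = extract_features(make_session(bouts)).features
        assert fv["total_bouts"] == 3
        assert fv["total_licks"] == 15
        assert fv["latency_to_drink_s"] == 60.0
        # end-to-start intervals: (400-62) and (2000-402)
        assert fv["mean_inter_drink_interval_s"] == pytest.approx(968.0)
        assert fv["max_inter_drink_interval_s"] == pytest.approx(1598.0)
        assert fv["bouts_first_30min"] == 2  # the 2000 s bout starts after 1800 s
        assert fv["front_loading_index"] == pytest.approx(2 / 3)

    def test_appending_a_bout_grows_counts(self):
        bouts = [simple_bout(60.0), simple_bout(400.0)]
        before = extract_features(make_session(bouts)).features
        after = extract_features(make_session(bouts + [simple_bout(900.0)])).features
        assert after["total_bouts"] == before["total_bouts"] + 1
        assert after["total_licks"] >= before["total_licks"]

    def test_agrees_with_reference_on_random_sessions(self, rng):
        for _ in range(300):
            n = int(rng.integers(0, 40))
            starts = np.sort(rng.uniform(0, 7000, n))
            bouts, prev_end = [], -10.0
            for s in starts:
                s = max(s, prev_end + 0.5)
                span = float(rng.uniform(2.0, 30.0))
                if s + span > 7200:
                    continue
                dur = float(rng.uniform(0.05, span))
                bouts.append(BoutRecord(s, s + span, int(rng.integers(1, 200)), dur))
                prev_end = s + span
            session = make_session(bouts)
            got = extract_features(session).features
            want = reference_features(session)
            for k in FEATURE_NAMES:
                assert got[k] == pytest.approx(want[k], abs=1e-9), k

    def test_maxima_dominate_means_and_early_window_collapse(self, rng):
        # all bouts before 1800 s: first-30-min features equal session totals
        bouts = [simple_bout(100.0 * i + 10, span=2.5, n_licks=int(rng.integers(1, 30)))
                 for i in range(15)]
        fv = extract_features(make_session(bouts)).features
        assert fv["licks_first_30min"] == fv["total_licks"]
        assert fv["bouts_first_30min"] == fv["total_bouts"]
        assert fv["front_loading_index"] == 1.0
        assert fv["max_bout_length_s"] >= fv["mean_bout_length_s"]
        assert fv["max_licks_per_bout"] >= fv["mean_licks_per_bout"]
        assert fv["max_lick_duration_per_bout_s"] >= fv["mean_lick_duration_per_bout_s"]


class TestIntake:
    def test_zero_consumption_zero_dose(self):
        s = make_session([], pre=45.0, post=45.0)
        assert compute_intake(s).dose_g_per_kg == 0.0

    def test_water_dose_arithmetic(self):
        s = make_session([], pre=46.0, post=45.0, body=25.0)
        assert compute_intake(s).dose_g_per_kg == pytest.approx(40.0)

    def test_alcohol_dose_from_solution_density(self):
        # 0.970 g at 0.970 g/ml -> 1.0 ml of 20% v/v -> 0.2 ml ethanol
        s = make_session([], pre=46.0, post=46.0 - 0.970, body=25.0, fluid="alcohol")
        rec = compute_intake(s, Densities(ethanol=0.789, alcohol_solution=0.970))
        assert rec.dose_g_per_kg == pytest.approx(1.0 * 0.2 * 0.789 / 0.025)
        assert rec.dose_g_per_kg == pytest.approx(6.312)

    def test_invalid_body_weight_rejected(self):
        s = make_session([], body=0.0)
        with pytest.raises(ValidationError):
            compute_intake(s)


class TestInclusionFilter:
    @staticmethod
    def frame(fluid, intakes):
        return pd.DataFrame(
            {"animal_id": [f"{fluid[0]}{i}" for i in range(len(intakes))],
             "fluid": fluid, "total_intake": intakes}
        )

    def test_identical_intakes_keep_everyone(self):
        inc, exc = inclusion_filter(self.frame("water", [50.0] * 6))
        assert len(inc) == 6 and not exc

    def test_single_low_drinker_excluded(self):
        # mirrors a cohort where one animal drank almost nothing
        inc, exc = inclusion_filter(self.frame("alcohol", [50, 52, 55, 58, 60, 1.28]))
        assert exc == {"a5"}
        assert len(inc) == 5

    def test_empty_input_empty_output(self):
        inc, exc = inclusion_filter(self.frame("water", []))
        assert inc == set() and exc == set()

    def test_small_group_kept_with_warning(self):
        with pytest.warns(UserWarning):
            inc, exc = inclusion_filter(self.frame("water", [1.0, 50.0, 55.0]))
        assert len(inc) == 3 and not exc


class TestCorrelation:
    def test_perfect_linear_relation(self, tiny_cohort):
        sessions, _ = tiny_cohort
        table = feature_table(sessions[:30])
        doses = 0.01 * table["total_licks"].to_numpy()
        out = intake_microstructure_correlation(table, doses)
        assert out.loc["total_licks", "r"] == pytest.approx(1.0)

    def test_generator_coupling_exceeds_point_nine(self, tiny_cohort):
        sessions, _ = tiny_cohort
        table = feature_table(sessions)
        table["dose"] = [compute_intake(s).dose_g_per_kg for s in sessions]
        for fluid, grp in table.groupby("fluid"):
            out = intake_microstructure_correlation(grp, grp["dose"])
            assert out.loc["total_licks", "r"] > 0.9, fluid

    def test_shuffled_doses_calibrate_to_null_band(self, tiny_cohort, rng):
        # destroying the pairing leaves r inside the 95% null band ~95% of
        # the time; assert the calibration over many permutations rather
        # than gambling on a single draw
        sessions, _ = tiny_cohort
        table = feature_table(sessions)
        doses = np.array([compute_intake(s).dose_g_per_kg for s in sessions])
        band = 1.96 / np.sqrt(len(table) - 3)
        x = table["total_licks"].to_numpy(dtype=float)
        rs = []
        for _ in range(200):
            sh = rng.permutation(doses)
            rs.append(np.corrcoef(x, sh)[0, 1])
        inside = np.mean(np.abs(rs) < band)
        assert inside >= 0.85
        assert abs(np.mean(rs)) < band / 3

    def test_zero_variance_reported_undefined(self, tiny_cohort):
        sessions, _ = tiny_cohort
        table = feature_table(sessions[:10])
        out = intake_microstructure_correlation(table, np.ones(10))
        assert not out.loc["total_licks", "defined"]
        assert np.isnan(out.loc["total_licks", "r"])
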