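"""Schedule-generation invariants and contingency coding."""

import numpy as np
import pandas as pd
import pytest

import painlearn as pl
from painlearn.task_design import (REVERSAL_TRIALS, ConstraintFailure,
                                   _segment_bounds, designed_reversal_trials)


def _segments(schedule):
    """(label, sub-frame) per post-conditioning phase segment."""
    df = schedule.trials
    cond_len = int(np.flatnonzero(
        (df["heat_level"] == "medium").to_numpy())[0])
    labels = ["original", "reversed", "original", "reversed"]
    out = []
    for k, (start, end) in enumerate(_segment_bounds(cond_len)):
        seg = df[(df["trial_global"] >= start)
                 & (df["trial_global"] <= end)]
        out.append((labels[k], seg))
    return out


@pytest.mark.parametrize("group", ["instructed", "uninstructed"])
@pytest.mark.parametrize("order_id", [1, 2, "random"])
def test_schedule_block_structure(group, order_id):
    """84 trials tiled as 7 blocks of 12, with contiguous phase segments."""
    s = pl.generate_trial_schedule(group, order_id, seed=3)
    assert s.n_trials == 84
    assert s.trials.groupby("block").size().tolist() == [12] * 7
    assert designed_reversal_trials(s) == list(REVERSAL_TRIALS)
    # the 4 phase segments tile all trials with no gaps or overlaps
    covered = sum(len(seg) for _, seg in _segments(s))
    cond_len = int(np.flatnonzero(
        (s.trials["heat_level"] == "medium").to_numpy())[0])
    assert covered + cond_len == 84


@pytest.mark.parametrize("low_count", [2, 3])
def test_conditioning_prefix(low_count):
    """3 high pairings and 2-3 low pairings precede any medium trial."""
    s = pl.generate_trial_schedule("instructed", 1, seed=0,
                                   conditioning_low_count=low_count)
    df = s.trials
    first_medium = int(np.flatnonzero(
        (df["heat_level"] == "medium").to_numpy())[0])
    cond = df.iloc[:first_medium]
    assert len(cond) == 3 + low_count
    assert ((cond["cue_role_original"] == "orig_high")
            & (cond["heat_level"] == "high")).sum() == 3
    assert ((cond["cue_role_original"] == "orig_low")
            & (cond["heat_level"] == "low")).sum() == low_count


@pytest.mark.parametrize("group,order_id",
                         [("instructed", 1), ("instructed", 2),
                          ("uninstructed", 1), ("uninstructed", "random")])
def test_no_condition_three_in_a_row(group, order_id):
    """No (cue, heat) condition repeats on three consecutive trials."""
    s = pl.generate_trial_schedule(group, order_id, seed=9)
    conds = list(zip(s.trials["cue_role_original"], s.trials["heat_level"]))
    for i in range(2, len(conds)):
        assert not (conds[i] == conds[i - 1] == conds[i - 2])


def test_exact_fifty_percent_reinforcement_per_cue_per_phase():
    """Within each test phase each cue is reinforced on exactly half of its
    presentations (even counts; default conditioning prefix)."""
    for order in (1, 2):
        s = pl.generate_trial_schedule("instructed", order, seed=0)
        for label, seg in _segments(s):
            for role in ("orig_high", "orig_low"):
                pres = seg[seg["cue_role_original"] == role]
                n_reinf = (pres["heat_level"] != "medium").sum()
                assert len(pres) % 2 == 0
                assert n_reinf * 2 == len(pres)


def test_reinforced_trials_follow_current_contingency():
    """Reinforced heat is the currently contingent level for the cue."""
    s = pl.generate_trial_schedule("uninstructed", 2, seed=0)
    for label, seg in _segments(s):
        reinf = seg[seg["heat_level"] != "medium"]
        for _, row in reinf.iterrows():
            if label == "original":
                expected = ("high" if row["cue_role_original"] == "orig_high"
                            else "low")
            else:
                expected = ("low" if row["cue_role_original"] == "orig_high"
                            else "high")
            assert row["heat_level"] == expected


def test_instruction_events_by_group(instructed_schedule,
                                     uninstructed_schedule):
    """3 instruction events at the reversals (instructed), 0 otherwise."""
    instr = instructed_schedule.trials
    assert instr["instruction_event"].sum() == 3
    assert (instr.loc[instr["instruction_event"], "trial_global"].tolist()
            == list(REVERSAL_TRIALS))
    assert uninstructed_schedule.trials["instruction_event"].sum() == 0


def test_groups_trial_identical_except_instruction(instructed_schedule,
                                                   uninstructed_schedule):
    a = instructed_schedule.trials.drop(columns="instruction_event")
    b = uninstructed_schedule.trials.drop(columns="instruction_event")
    pd.testing.assert_frame_equal(a, b)


def test_post_reversal_first_occurrence_is_medium():
    """After each reversal the next occurrence of each cue is medium."""
    s = pl.generate_trial_schedule("instructed", 1, seed=0)
    for label, seg in _segments(s)[1:]:
        seen = set()
        for role, heat in zip(seg["cue_role_original"], seg["heat_level"]):
            if role not in seen:
                seen.add(role)
                assert heat == "medium"


def test_timing_invariants(instructed_schedule):
    """Jitters sum to 14 s; trials are spaced 48 s apart within a block."""
    df = instructed_schedule.trials
    assert np.allclose(df["jitter1_s"] + df["jitter2_s"], 14.0)
    assert df["jitter1_s"].between(8, 10).all()
    assert df["jitter2_s"].between(4, 6).all()
    for _, block in df.groupby("block"):
        onsets = block.sort_values("trial_in_block")["onset_s"].to_numpy()
        assert np.allclose(np.diff(onsets), 48.0)


def test_determinism_byte_identical():
    """Same (group, order, seed) arguments give byte-identical schedules."""
    a = pl.generate_trial_schedule("instructed", 1, seed=5)
    b = pl.generate_trial_schedule("instructed", 1, seed=5)
    assert a.to_frame().to_csv(index=False) == b.to_frame().to_csv(index=False)
    c = pl.generate_trial_schedule("instructed", "random", seed=6)
    d = pl.generate_trial_schedule("instructed", "random", seed=7)
    assert not c.trials["heat_level"].equals(d.trials["heat_level"]) or \
        not np.allclose(c.trials["jitter1_s"], d.trials["jitter1_s"])


def test_counterbalance_swap_is_valid(instructed_schedule):
    """Swapping the physical cue letters leaves a valid schedule."""
    swapped = pl.swap_cue_labels(instructed_schedule)
    pl.validate_schedule(swapped)
    assert (swapped.trials["cue"]
            != instructed_schedule.trials["cue"]).all()
    pd.testing.assert_series_equal(
        swapped.trials["cue_role_original"],
        instructed_schedule.trials["cue_role_original"])


def test_contingency_coding_definitions(instructed_schedule):
    """Coding: +1 original-high; x_current flips sign in reversed phases."""
    codes = pl.encode_contingencies(instructed_schedule)
    df = instructed_schedule.trials.set_index("trial_global")
    for _, row in codes.iterrows():
        role = df.loc[row["trial_global"], "cue_role_original"]
        assert row["x_original"] == (1 if role == "orig_high" else -1)
        if row["phase_index"] % 2 == 0:
            assert row["x_current"] == row["x_original"]
        else:
            assert row["x_current"] == -row["x_original"]


def test_instructed_phase_flips_at_instructions(instructed_schedule):
    assert (pl.reversal_event_trials(instructed_schedule)
            == list(REVERSAL_TRIALS))


def test_uninstructed_phase_flips_at_first_incongruent_pairing(
        uninstructed_schedule):
    """Independent linear scan: the experienced phase increments exactly at
    the first reinforced pairing incongruent with the old contingency."""
    df = uninstructed_schedule.trials
    # oracle: walk the trials tracking the currently *experienced*
    # contingency; flip when a reinforced trial contradicts it
    contingency = {"orig_high": "high", "orig_low": "low"}
    expected_events = []
    for _, row in df.iterrows():
        heat = row["heat_level"]
        if heat == "medium":
            continue
        if contingency[row["cue_role_original"]] != heat:
            expected_events.append(int(row["trial_global"]))
            contingency = {r: ("high" if h == "low" else "low")
                           for r, h in contingency.items()}
    assert pl.reversal_event_trials(uninstructed_schedule) == expected_events
    # events trail the designed reversals
    for ev, designed in zip(expected_events, REVERSAL_TRIALS):
        assert ev > designed


def test_trials_csv_roundtrip(tmp_path, instructed_schedule):
    frame = instructed_schedule.to_frame()
    path = tmp_path / "trials.csv"
    pl.write_trials_csv(frame, path)
    back = pl.read_trials_csv(path)
    pd.testing.assert_frame_equal(back, frame.reset_index(drop=True),
                                  check_dtype=False)
    rebuilt = pl.schedule_from_frame(back)
    pl.validate_schedule(rebuilt)
    assert rebuilt.group == "instructed"


def test_invalid_inputs_raise():
    with pytest.raises(ValueError):
        pl.generate_trial_schedule("other", 1, seed=0)
    with pytest.raises(ValueError):
        pl.generate_trial_schedule("instructed", 3, seed=0)
    with pytest.raises(ValueError):
        pl.generate_trial_schedule("instructed", 1, seed=0,
                                   conditioning_low_count=4)


def test_validator_names_broken_invariant(instructed_schedule):
    truncated = instructed_schedule.trials.iloc[:-1]
    with pytest.raises(ConstraintFailure, match="84"):
        pl.validate_schedule(truncated.assign(group="instructed"))
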