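"""Trial-schedule generation for the pain reversal-learning task.

The task pairs two auditory cues with calibrated heat. A short conditioning
phase deterministically pairs the original high-pain cue with high heat (3
pairings) and the original low-pain cue with low heat (2-3 pairings). The
remainder of the task delivers medium heat on unreinforced test trials,
crossed with both cues, while intermittent reinforcement continues at a 50%
rate per cue. Contingencies reverse three times, halfway through blocks 2, 4,
and 6; instructed participants see a reversal instruction at those points,
uninstructed participants experience the reversal through incongruent
pairings.

The two pseudorandom orders used in the original study are not published;
``order_id`` 1 and 2 select stored canonical seeds so that the constraint
structure (not the literal sequences) is reproduced deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_BLOCKS = 7
TRIALS_PER_BLOCK = 12
N_TRIALS = N_BLOCKS * TRIALS_PER_BLOCK
#: 1-based global trial index of each reversal (trial 7 of blocks 2, 4, 6).
REVERSAL_TRIALS = (19, 43, 67)
#: reinforcement coding of heat outcomes.
OUTCOME_VALUE = {"low": 0.0, "medium": 0.5, "high": 1.0}
#: valid pain-rating range: 0 ("no sensation") to 8.5 ("too hot" box).
RATING_RANGE = (0.0, 8.5)
#: seconds; jitter1 + jitter2 = 14 within every trial.
TRIAL_DURATION_S = 48.0
CUE_DUR_S = 2.0
ANTICIPATION_S = 6.0
HEAT_DUR_S = 8.0
RATING_DUR_S = 8.0
JITTER_SUM_S = 14.0

#: canonical sequence seeds behind the two counterbalanced orders.
_ORDER_SEEDS = {1: 735301, 2: 735302}

GROUPS = ("instructed", "uninstructed")

TRIALS_CSV_COLUMNS = [
    "subject_id", "group", "order_id", "block", "trial_in_block",
    "trial_global", "cue", "cue_role_original", "heat_level", "outcome_value",
    "phase", "instruction_event", "is_first_in_block", "onset_s",
    "jitter1_s", "jitter2_s", "pain",
]


class ConstraintFailure(RuntimeError):
    """A schedule constraint could not be satisfied within bounded retries."""


@dataclass
class TrialSchedule:
    """One subject's generated task: 84 trials in 7 blocks of 12.

    ``trials`` holds one row per trial with cue identity, heat level,
    designed phase, instruction events, and timing. The designed ``phase``
    column alternates original/reversed over four segments delimited by
    :data:`REVERSAL_TRIALS`.
    """

    subject_id: str
    group: str
    order_id: object
    conditioning_low_count: int
    seed: int
    trials: pd.DataFrame = field(repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_frame(self, pain=None) -> pd.DataFrame:
        """Long-format table with the canonical trials-CSV columns."""
        df = self.trials.copy()
        df.insert(0, "subject_id", self.subject_id)
        df.insert(1, "group", self.group)
        df.insert(2, "order_id", str(self.order_id))
        if pain is None:
            df["pain"] = np.nan
        else:
            pain = np.asarray(pain, dtype=float)
            if pain.shape != (len(df),):
                raise ValueError("pain vector must align with the schedule")
            df["pain"] = pain
        return df[TRIALS_CSV_COLUMNS]


def _no_triple(roles, heats) -> bool:
    """True when no (cue, heat) condition repeats on 3 consecutive trials."""
    for i in range(2, len(roles)):
        if (roles[i] == roles[i - 1] == roles[i - 2]
                and heats[i] == heats[i - 1] == heats[i - 2]):
            return False
    return True


def _shuffle_conditioning(rng, low_count, max_tries=2000):
    trials = [("orig_high", "high")] * 3 + [("orig_low", "low")] * low_count
    for _ in range(max_tries):
        perm = [trials[i] for i in rng.permutation(len(trials))]
        roles = [t[0] for t in perm]
        heats = [t[1] for t in perm]
        if _no_triple(roles, heats):
            return perm
    raise ConstraintFailure(
        "conditioning prefix: no (cue, heat) pair on 3 consecutive trials")


def _cue_counts(n, rng):
    """Split ``n`` cue presentations between the two cues.

    Counts are kept even wherever possible so that the 50% reinforcement
    rate is exact per cue (even totals split as equal-even or even+/-2
    with the favored cue chosen at random; odd totals leave one odd count).
    """
    if n % 2 == 0:
        if n % 4 == 0:
            counts = [n // 2, n // 2]
        else:
            counts = [n // 2 + 1, n // 2 - 1]
    else:
        counts = [(n + 1) // 2, n // 2]
    if rng.random() < 0.5:
        counts = counts[::-1]
    return {"orig_high": counts[0], "orig_low": counts[1]}


def _reinforced_heat(role, phase_label):
    """Heat level delivered on a reinforced trial under the current phase."""
    if phase_label == "original":
        return "high" if role == "orig_high" else "low"
    return "low" if role == "orig_high" else "high"


def _shuffle_segment(rng, pool, prev_roles, prev_heats, first_must_be_medium,
                     opening_medium=False, max_tries=20000):
    """Permute a segment's trial pool under the ordering constraints.

    ``first_must_be_medium`` enforces that the first post-reversal
    occurrence of each cue is an unreinforced medium trial, so that the new
    contingency is tested before it is reinforced. ``opening_medium``
    requires the segment's very first trial to be medium (the first test
    segment must not extend the conditioning prefix).
    """
    for _ in range(max_tries):
        perm = [pool[i] for i in rng.permutation(len(pool))]
        roles = list(prev_roles) + [t[0] for t in perm]
        heats = list(prev_heats) + [t[1] for t in perm]
        if not _no_triple(roles, heats):
            continue
        if opening_medium and perm[0][1] != "medium":
            continue
        if first_must_be_medium:
            ok = True
            seen = set()
            for role, heat in perm:
                if role not in seen:
                    seen.add(role)
                    if heat != "medium":
                        ok = False
                        break
            if not ok:
                continue
        return perm
    name = ("post-reversal first occurrence of each cue must be medium"
            if first_must_be_medium
            else "no (cue, heat) pair on 3 consecutive trials")
    raise ConstraintFailure(f"segment constraint unsatisfied: {name}")


def _segment_bounds(conditioning_len):
    """(start, end) 1-based inclusive global bounds of the 4 test segments."""
    edges = [conditioning_len + 1, *REVERSAL_TRIALS, N_TRIALS + 1]
    return [(edges[i], edges[i + 1] - 1) for i in range(4)]


def generate_trial_schedule(group, order_id, seed=0, conditioning_low_count=3,
                            subject_id=None) -> TrialSchedule:
    """Generate one subject's constraint-satisfying trial schedule.

    Parameters
    ----------
    group : {"instructed", "uninstructed"}
        Instructed schedules carry instruction events at the three
        reversals; uninstructed schedules are trial-identical except that
        ``instruction_event`` is all false (a fixation cross replaced the
        instructions in the study).
    order_id : {1, 2, "random"}
        Orders 1 and 2 select stored canonical sequence seeds; ``"random"``
        derives the sequence from ``seed``.
    seed : int
        Seeds the jitter draws, and the trial sequence when
        ``order_id="random"``.
    conditioning_low_count : {2, 3}
        Number of low-cue/low-heat pairings in the conditioning prefix.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if conditioning_low_count not in (2, 3):
        raise ValueError("conditioning_low_count must be 2 or 3")
    if order_id in _ORDER_SEEDS:
        seq_seed = _ORDER_SEEDS[order_id]
    elif order_id == "random":
        seq_seed = int(seed)
    else:
        raise ValueError("order_id must be 1, 2, or 'random'")

    seq_rng = np.random.default_rng(
        [seq_seed, conditioning_low_count, 735300])
    cond = _shuffle_conditioning(seq_rng, conditioning_low_count)
    cond_len = len(cond)

    sequence = list(cond)
    labels = ["original", "reversed", "original", "reversed"]
    for k, (start, end) in enumerate(_segment_bounds(cond_len)):
        n = end - start + 1
        counts = _cue_counts(n, seq_rng)
        pool = []
        for role, c in counts.items():
            n_reinf = c // 2  # exactly 50% whenever the count is even
            heat = _reinforced_heat(role, labels[k])
            pool += [(role, heat)] * n_reinf
            pool += [(role, "medium")] * (c - n_reinf)
        prev = sequence[-2:]
        seg = _shuffle_segment(
            seq_rng, pool,
            [t[0] for t in prev], [t[1] for t in prev],
            first_must_be_medium=(k > 0), opening_medium=(k == 0))
        sequence += seg

    roles = [t[0] for t in sequence]
    heats = [t[1] for t in sequence]
    trial_global = np.arange(1, N_TRIALS + 1)
    phase_idx = np.searchsorted(np.asarray(REVERSAL_TRIALS), trial_global,
                                side="right")
    phase = np.where(phase_idx % 2 == 0, "original", "reversed")
    instruction = np.isin(trial_global, REVERSAL_TRIALS) & (
        group == "instructed")

    jit_rng = np.random.default_rng([int(seed), 735304])
    jitter1 = jit_rng.uniform(8.0, 10.0, size=N_TRIALS)
    jitter2 = JITTER_SUM_S - jitter1

    trial_in_block = (trial_global - 1) % TRIALS_PER_BLOCK + 1
    trials = pd.DataFrame({
        "block": (trial_global - 1) // TRIALS_PER_BLOCK + 1,
        "trial_in_block": trial_in_block,
        "trial_global": trial_global,
        "cue": np.where(np.asarray(roles) == "orig_high", "A", "B"),
        "cue_role_original": roles,
        "heat_level": heats,
        "outcome_value": [OUTCOME_VALUE[h] for h in heats],
        "phase": phase,
        "instruction_event": instruction,
        "is_first_in_block": trial_in_block == 1,
        "onset_s": (trial_in_block - 1) * TRIAL_DURATION_S,
        "cue_dur_s": CUE_DUR_S,
        "anticipation_s": ANTICIPATION_S,
        "heat_dur_s": HEAT_DUR_S,
        "jitter1_s": jitter1,
        "rating_dur_s": RATING_DUR_S,
        "jitter2_s": jitter2,
    })
    if subject_id is None:
        subject_id = f"sub-{group[:3]}-o{order_id}-s{seed}"
    schedule = TrialSchedule(
        subject_id=subject_id, group=group, order_id=order_id,
        conditioning_low_count=conditioning_low_count, seed=int(seed),
        trials=trials)
    validate_schedule(schedule)
    return schedule


def swap_cue_labels(schedule: TrialSchedule) -> TrialSchedule:
    """Exchange which physical cue (letter) carries each role.

    The role structure attached to trials is untouched, so the swapped
    schedule satisfies every invariant; only the letter-to-role assignment
    (the dimension counterbalanced across participants) changes.
    """
    trials = schedule.trials.copy()
    trials["cue"] = trials["cue"].map({"A": "B", "B": "A"})
    return TrialSchedule(
        subject_id=schedule.subject_id + "-swapped", group=schedule.group,
        order_id=schedule.order_id,
        conditioning_low_count=schedule.conditioning_low_count,
        seed=schedule.seed, trials=trials)


def validate_schedule(schedule) -> None:
    """Check every schedule invariant; raise ConstraintFailure naming the rule.

    Accepts a :class:`TrialSchedule` or a one-subject trials DataFrame.
    """
    if isinstance(schedule, TrialSchedule):
        df = schedule.trials
        group = schedule.group
    else:
        df = schedule
        group = df["group"].iloc[0] if "group" in df else None

    if len(df) != N_TRIALS:
        raise ConstraintFailure(
            f"schedule must have exactly {N_TRIALS} trials "
            f"(7 blocks x 12), got {len(df)}")
    blocks = df.groupby("block").size()
    if len(blocks) != N_BLOCKS or not (blocks == TRIALS_PER_BLOCK).all():
        raise ConstraintFailure("schedule must tile 7 blocks of 12 trials")

    roles = df["cue_role_original"].to_numpy()
    heats = df["heat_level"].to_numpy()
    medium_pos = np.flatnonzero(heats == "medium")
    if medium_pos.size == 0:
        raise ConstraintFailure("schedule has no medium test trials")
    cond = df.iloc[: medium_pos[0]]
    n_high = ((cond["cue_role_original"] == "orig_high")
              & (cond["heat_level"] == "high")).sum()
    n_low = ((cond["cue_role_original"] == "orig_low")
             & (cond["heat_level"] == "low")).sum()
    if n_high != 3 or n_low not in (2, 3) or n_high + n_low != len(cond):
        raise ConstraintFailure(
            "conditioning prefix must contain exactly 3 high pairings and "
            f"2-3 low pairings before any medium trial, got {n_high} high / "
            f"{n_low} low in {len(cond)} trials")

    if not _no_triple(list(roles), list(heats)):
        raise ConstraintFailure(
            "no (cue, heat_level) pair may occur on 3 consecutive trials")

    labels = ["original", "reversed", "original", "reversed"]
    for k, (start, end) in enumerate(_segment_bounds(len(cond))):
        seg = df[(df["trial_global"] >= start) & (df["trial_global"] <= end)]
        if not (seg["phase"] == labels[k]).all():
            raise ConstraintFailure(
                "phase segments must alternate original/reversed at the "
                "three reversal points")
        for role in ("orig_high", "orig_low"):
            pres = seg[seg["cue_role_original"] == role]
            n = len(pres)
            reinforced = (pres["heat_level"] != "medium").sum()
            wrong = pres[(pres["heat_level"] != "medium")
                         & (pres["heat_level"]
                            != _reinforced_heat(role, labels[k]))]
            if len(wrong):
                raise ConstraintFailure(
                    "reinforced trials must pair each cue with its "
                    "currently contingent heat level")
            if reinforced != n // 2:
                raise ConstraintFailure(
                    "within each post-conditioning phase exactly 50% of "
                    f"each cue's presentations are reinforced ({role}: "
                    f"{reinforced}/{n})")
        if k > 0:
            seen = set()
            for role, heat in zip(seg["cue_role_original"],
                                  seg["heat_level"]):
                if role not in seen:
                    seen.add(role)
                    if heat != "medium":
                        raise ConstraintFailure(
                            "after each reversal the next occurrence of "
                            "each cue must be a medium trial")

    n_instr = int(df["instruction_event"].sum())
    if group == "instructed":
        at = df.loc[df["instruction_event"], "trial_global"].tolist()
        if n_instr != 3 or at != list(REVERSAL_TRIALS):
            raise ConstraintFailure(
                "instructed schedules must carry exactly 3 instruction "
                f"events at trials {REVERSAL_TRIALS}")
    elif group == "uninstructed" and n_instr != 0:
        raise ConstraintFailure(
            "uninstructed schedules must carry no instruction events")

    jsum = df["jitter1_s"].to_numpy() + df["jitter2_s"].to_numpy()
    if not np.allclose(jsum, JITTER_SUM_S):
        raise ConstraintFailure("jitter1_s + jitter2_s must equal 14 s "
                                "on every trial")


def designed_reversal_trials(schedule) -> list[int]:
    """Global trial indices where the designed contingency changes."""
    df = schedule.trials if isinstance(schedule, TrialSchedule) else schedule
    phase = df["phase"].to_numpy()
    tg = df["trial_global"].to_numpy()
    flips = np.flatnonzero(phase[1:] != phase[:-1]) + 1
    return [int(tg[i]) for i in flips]


def reversal_event_trials(schedule) -> list[int]:
    """Trials at which the subject's expected values reverse.

    Instructed group: the instruction trials themselves. Uninstructed
    group: for each designed reversal, the first subsequent reinforced
    trial that is incongruent with the previous contingency (the first
    time the previous high-pain cue is paired with low heat, or vice
    versa).
    """
    df = schedule.trials if isinstance(schedule, TrialSchedule) else schedule
    group = (schedule.group if isinstance(schedule, TrialSchedule)
             else df["group"].iloc[0])
    boundaries = designed_reversal_trials(schedule)
    if len(boundaries) != 3:
        raise ConstraintFailure(
            "schedule lacks the three-reversal phase structure")
    if group == "instructed":
        return boundaries

    tg = df["trial_global"].to_numpy()
    roles = df["cue_role_original"].to_numpy()
    heats = df["heat_level"].to_numpy()
    phase = df["phase"].to_numpy()
    events = []
    for b in boundaries:
        i0 = int(np.flatnonzero(tg == b)[0])
        prev_label = phase[i0 - 1]
        found = None
        for i in range(i0, len(tg)):
            if heats[i] == "medium":
                continue
            if heats[i] != _reinforced_heat(roles[i], prev_label):
                found = int(tg[i])
                break
        if found is None:
            raise ConstraintFailure(
                "no incongruent reinforced pairing follows a designed "
                "reversal; schedule lacks reversal structure")
        events.append(found)
    return events


def encode_contingencies(schedule) -> pd.DataFrame:
    """Contingency codes for the medium-heat test trials.

    Returns one row per medium trial with ``x_original`` (+1 original-high
    cue, -1 original-low cue), ``x_current`` (+1 currently-high cue, -1
    currently-low cue, relative to instructed reversals in the instructed
    group and experienced reversals in the uninstructed group), and the
    experienced ``phase_index`` 0-3.
    """
    df = schedule.trials if isinstance(schedule, TrialSchedule) else schedule
    events = np.asarray(reversal_event_trials(schedule))
    tg = df["trial_global"].to_numpy()
    phase_index = np.searchsorted(events, tg, side="right")
    x_original = np.where(df["cue_role_original"] == "orig_high", 1, -1)
    x_current = np.where(phase_index % 2 == 0, x_original, -x_original)
    medium = (df["heat_level"] == "medium").to_numpy()
    out = pd.DataFrame({
        "trial_global": tg[medium],
        "x_current": x_current[medium],
        "x_original": x_original[medium],
        "phase_index": phase_index[medium],
    })
    return out


def write_trials_csv(frames, path) -> None:
    """Write one or more subjects' trial tables to the canonical CSV."""
    if isinstance(frames, pd.DataFrame):
        frames = [frames]
    df = pd.concat(frames, ignore_index=True)
    missing = [c for c in TRIALS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials table missing columns: {missing}")
    df[TRIALS_CSV_COLUMNS].to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    """Read a trials CSV back into a long-format DataFrame."""
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "order_id": str},
    )
    for col in ("instruction_event", "is_first_in_block"):
        df[col] = df[col].astype(bool)
    return df


def schedule_from_frame(df: pd.DataFrame) -> TrialSchedule:
    """Rebuild a TrialSchedule from one subject's rows of a trials table."""
    subjects = df["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError("schedule_from_frame expects a single subject")
    trials = df.sort_values("trial_global").reset_index(drop=True)
    medium_pos = np.flatnonzero(trials["heat_level"].to_numpy() == "medium")
    cond = trials.iloc[: medium_pos[0]] if medium_pos.size else trials
    low_count = int(((cond["cue_role_original"] == "orig_low")).sum())
    order = trials["order_id"].iloc[0]
    try:
        order = int(order)
    except (TypeError, ValueError):
        pass
    keep = [c for c in trials.columns
            if c not in ("subject_id", "group", "order_id", "pain")]
    return TrialSchedule(
        subject_id=str(subjects[0]), group=trials["group"].iloc[0],
        order_id=order, conditioning_low_count=low_count, seed=-1,
        trials=trials[keep])
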