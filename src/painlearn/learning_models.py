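"""Instructed Rescorla-Wagner learning models and forward simulation.

Expected value (EV) for each cue is bounded in [0, 1] and updates in
response to prediction errors on reinforced trials,

    EV <- EV + alpha * (r - EV),        r in {0 (low), 1 (high)},

while reversal events exchange the two cues' EVs by a fraction rho,

    EV'(a) = rho * EV(b) + (1 - rho) * EV(a)   (and symmetrically for b),

computed simultaneously from the pre-event values. rho = 1 is a full
exchange, rho = 0 leaves both EVs untouched. For instructed participants
the reversal events are the instruction displays; for uninstructed
participants they are the first incongruent reinforced pairings after each
designed reversal.

Four model variants are supported:

``irw_fixed_init``
    Instructed RW with group-determined initial values (instructed: 1 for
    the original high-pain cue, 0 for the low; uninstructed: 0.5 both) and
    free (alpha, rho).
``irw_free_init``
    As above but the initial value is free: v0 for the original high-pain
    cue, 1 - v0 for the other. Free (alpha, rho, v0).
``rw``
    Standard Rescorla-Wagner without a reversal parameter; free (alpha, v0).
``hybrid``
    A Pearce-Hall hybrid in which an associability term tracking smoothed
    |PE| scales the value step, with instructed exchange of EVs at reversal
    events; free (rho, eta, kappa), initial associability fixed at 1.

Medium-heat test trials record EV and a prediction error relative to the
medium outcome (r = 0.5) but by default do not drive updates: the medium
temperature is constant, so cue-based variation on those trials reads out
expected value rather than feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .task_design import TrialSchedule, reversal_event_trials

MODELS = ("irw_fixed_init", "irw_free_init", "rw", "hybrid")

#: free learning parameters per model, in canonical order.
FREE_PARAMS = {
    "irw_fixed_init": ("alpha", "rho"),
    "irw_free_init": ("alpha", "rho", "v0"),
    "rw": ("alpha", "v0"),
    "hybrid": ("rho", "eta", "kappa"),
}

#: all learning parameters live on the unit interval.
PARAM_BOUNDS = (0.0, 1.0)

DEFAULT_A0 = 1.0


class DomainError(ValueError):
    """An argument left its documented domain."""


@dataclass(frozen=True)
class LearningParams:
    """Learning-model parameters; only the model's free set is required."""

    model: str
    alpha: Optional[float] = None
    rho: Optional[float] = None
    v0: Optional[float] = None
    eta: Optional[float] = None
    kappa: Optional[float] = None
    a0: float = DEFAULT_A0

    def __post_init__(self):
        if self.model not in MODELS:
            raise DomainError(f"unknown model {self.model!r}")
        for name in FREE_PARAMS[self.model]:
            value = getattr(self, name)
            if value is None:
                raise DomainError(
                    f"model {self.model!r} requires parameter {name!r}")
            if not 0.0 <= value <= 1.0:
                raise DomainError(f"{name}={value} outside [0, 1]")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FREE_PARAMS[self.model]])

    @classmethod
    def from_free_values(cls, model: str, values) -> "LearningParams":
        return cls(model=model,
                   **dict(zip(FREE_PARAMS[model], map(float, values))))


def rw_update(ev: float, outcome: float, alpha: float) -> float:
    """One Rescorla-Wagner step: ev + alpha * (outcome - ev)."""
    for name, v in (("ev", ev), ("outcome", outcome), ("alpha", alpha)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name}={v} outside [0, 1]")
    return ev + alpha * (outcome - ev)


def instructed_exchange(ev_a: float, ev_b: float, rho: float):
    """Symmetric simultaneous exchange of two cues' expected values.

    Both outputs are computed from the pre-exchange values:
    ``(rho*ev_b + (1-rho)*ev_a, rho*ev_a + (1-rho)*ev_b)``.
    """
    for name, v in (("ev_a", ev_a), ("ev_b", ev_b), ("rho", rho)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name}={v} outside [0, 1]")
    return (rho * ev_b + (1.0 - rho) * ev_a,
            rho * ev_a + (1.0 - rho) * ev_b)


def hybrid_update(ev: float, assoc: float, outcome: float,
                  eta: float, kappa: float):
    """Pearce-Hall hybrid step.

    The value step is scaled by associability, ``ev + kappa*assoc*pe``
    (clipped to [0, 1]); associability is an exponentially smoothed
    unsigned prediction error, ``eta*|pe| + (1-eta)*assoc``.
    """
    for name, v in (("ev", ev), ("outcome", outcome),
                    ("eta", eta), ("kappa", kappa)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name}={v} outside [0, 1]")
    if assoc < 0:
        raise DomainError(f"assoc={assoc} must be non-negative")
    pe = outcome - ev
    new_ev = min(1.0, max(0.0, ev + kappa * assoc * pe))
    new_assoc = eta * abs(pe) + (1.0 - eta) * assoc
    return new_ev, new_assoc


@dataclass
class EVTrace:
    """Per-trial expected value, prediction error, and associability."""

    model: str
    ev_cue_a: np.ndarray
    ev_cue_b: np.ndarray
    ev_presented: np.ndarray
    pe: np.ndarray
    upe: np.ndarray
    assoc: Optional[np.ndarray] = None
    trial_global: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "trial_global": self.trial_global,
            "ev_cue_a": self.ev_cue_a,
            "ev_cue_b": self.ev_cue_b,
            "ev_presented": self.ev_presented,
            "pe": self.pe,
            "upe": self.upe,
        })
        if self.assoc is not None:
            df["assoc"] = self.assoc
        return df


@dataclass
class CompiledSchedule:
    """Plain-array view of a schedule for fast repeated simulation."""

    group: str
    is_high_cue: np.ndarray     # True where the original-high cue is shown
    outcome: np.ndarray         # reinforcement coding: 0 / 0.5 / 1
    is_medium: np.ndarray
    is_event: np.ndarray        # reversal (rho) events
    trial_global: np.ndarray
    is_first_in_block: np.ndarray

    def __post_init__(self):
        # plain-python copies: scalar indexing into numpy arrays dominates
        # the fitting loop's cost otherwise
        self.rows = list(zip(self.is_high_cue.tolist(),
                             self.outcome.tolist(),
                             self.is_medium.tolist(),
                             self.is_event.tolist()))


def compile_schedule(schedule) -> CompiledSchedule:
    """Precompute the arrays :func:`simulate_ev_trace` iterates over."""
    if isinstance(schedule, CompiledSchedule):
        return schedule
    df = schedule.trials if isinstance(schedule, TrialSchedule) else schedule
    group = (schedule.group if isinstance(schedule, TrialSchedule)
             else df["group"].iloc[0])
    events = reversal_event_trials(schedule)
    tg = df["trial_global"].to_numpy()
    return CompiledSchedule(
        group=group,
        is_high_cue=(df["cue_role_original"] == "orig_high").to_numpy(),
        outcome=df["outcome_value"].to_numpy(dtype=float),
        is_medium=(df["heat_level"] == "medium").to_numpy(),
        is_event=np.isin(tg, events),
        trial_global=tg,
        is_first_in_block=df["is_first_in_block"].to_numpy(dtype=bool),
    )


def initial_values(params: LearningParams, group: str):
    """Initial (EV_high_cue, EV_low_cue) under the model's init policy."""
    if params.model in ("irw_free_init", "rw"):
        return params.v0, 1.0 - params.v0
    if group == "instructed":
        return 1.0, 0.0
    return 0.5, 0.5


def simulate_ev_trace(schedule, params: LearningParams,
                      update_on_medium: bool = False) -> EVTrace:
    """Forward pass of a learning model over one schedule.

    At each reversal event the instructed exchange is applied before the
    trial's cue presentation (for rw, which has no rho, no exchange
    occurs). ``ev_presented`` is the presented cue's EV before the
    outcome; PE is outcome - EV with medium trials scored against
    r = 0.5. By default only reinforced (high/low) trials drive updates.
    """
    cs = compile_schedule(schedule)
    model = params.model
    ev_h, ev_l = initial_values(params, cs.group)
    rho = params.rho if model != "rw" else 0.0
    alpha = params.alpha if model != "hybrid" else None
    assoc_h = assoc_l = params.a0 if model == "hybrid" else None

    n = len(cs.outcome)
    ev_a = np.empty(n)
    ev_b = np.empty(n)
    ev_p = np.empty(n)
    pe = np.empty(n)
    assoc_tr = np.empty(n) if model == "hybrid" else None

    for t in range(n):
        if cs.is_event[t] and model != "rw":
            ev_h, ev_l = instructed_exchange(ev_h, ev_l, rho)
        high = cs.is_high_cue[t]
        ev_t = ev_h if high else ev_l
        outcome = cs.outcome[t]
        is_medium = cs.is_medium[t]
        r = 0.5 if is_medium else outcome
        ev_a[t], ev_b[t] = ev_h, ev_l
        ev_p[t] = ev_t
        pe[t] = r - ev_t
        if model == "hybrid":
            assoc_t = assoc_h if high else assoc_l
            assoc_tr[t] = assoc_t
            if update_on_medium or not is_medium:
                new_ev, new_assoc = hybrid_update(
                    ev_t, assoc_t, r, params.eta, params.kappa)
                if high:
                    ev_h, assoc_h = new_ev, new_assoc
                else:
                    ev_l, assoc_l = new_ev, new_assoc
        else:
            if update_on_medium or not is_medium:
                new_ev = ev_t + alpha * (r - ev_t)
                if high:
                    ev_h = new_ev
                else:
                    ev_l = new_ev

    return EVTrace(model=model, ev_cue_a=ev_a, ev_cue_b=ev_b,
                   ev_presented=ev_p, pe=pe, upe=np.abs(pe),
                   assoc=assoc_tr, trial_global=cs.trial_global)
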