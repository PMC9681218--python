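"""Ground-truth synthetic behavior and mediator signals.

The generator inverts the observation model the analysis assumes: each
subject's learning parameters are drawn from group-specific distributions,
an EV trace is simulated over a generated schedule, and pain is

    pain_t = beta0 + beta_temp * level_t + beta_ev * EV_t + N(0, noise_sd),

with heat levels coded by their calibrated target ratings (low 2, medium
5, high 8 on the 10-point scale). Instructed agents reverse expectations
by rho at instruction; uninstructed agents learn from reinforced pairings
with a higher learning rate — the qualitative group structure the task
manipulation is designed to induce.

Mediator signals follow the multilevel mediation forward model on medium
trials: per-subject (a_j, b_j) are drawn from a bivariate normal with a
configurable correlation, then m = d1 + a_j x + noise and
y = d2 + c' x + b_j m + noise. The recorded population truth is
mean_a * mean_b + cov(a, b).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .learning_models import LearningParams, simulate_ev_trace
from .task_design import TrialSchedule, generate_trial_schedule

#: heat levels coded as the target ratings of the pain calibration.
HEAT_TARGET = {"low": 2.0, "medium": 5.0, "high": 8.0}
RATING_MAX = 8.5  # VAS top plus the "too hot" box


@dataclass
class MediationSpec:
    """Population parameters of the mediation forward model."""

    mean_a: float = 0.5
    sd_a: float = 0.2
    mean_b: float = 0.5
    sd_b: float = 0.2
    corr_ab: float = 0.0
    c_prime: float = 0.2
    d1: float = 0.0
    d2: float = 5.0
    m_noise_sd: float = 1.0
    y_noise_sd: float = 1.0

    def __post_init__(self):
        if min(self.sd_a, self.sd_b, self.m_noise_sd, self.y_noise_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if not -1.0 <= self.corr_ab <= 1.0:
            raise ValueError("corr_ab must lie in [-1, 1]")

    @property
    def true_ab(self) -> float:
        """Population mediated effect: mean_a*mean_b + cov(a, b)."""
        return self.mean_a * self.mean_b + self.corr_ab * self.sd_a * self.sd_b


@dataclass
class GenerativeSpec:
    """Study-level generative conditions for synthetic cohorts.

    Defaults are the study conditions: 20 subjects per group, two
    counterbalanced orders, near-zero learning rates with large instructed
    reversals in the instructed group and feedback-driven learning without
    instructed reversals in the uninstructed group, pain noise of 0.5
    rating units.
    """

    n_subjects_per_group: int = 20
    model: str = "irw_fixed_init"
    alpha_range: dict = field(default_factory=lambda: {
        "instructed": (0.0, 0.0), "uninstructed": (0.1, 0.5)})
    rho_range: dict = field(default_factory=lambda: {
        "instructed": (0.7, 1.0), "uninstructed": (0.0, 0.4)})
    beta0: float = -2.0
    beta_temp: float = 1.0
    beta_ev: float = 2.0
    noise_sd: float = 0.5
    truncate_ratings: bool = True
    conditioning_low_count: int = 3
    mediation: MediationSpec = field(default_factory=MediationSpec)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for d in (self.alpha_range, self.rho_range):
            for lo, hi in d.values():
                if not (0.0 <= lo <= hi <= 1.0):
                    raise ValueError("parameter ranges must be ordered and "
                                     "within [0, 1]")

    def to_flat_dict(self) -> dict:
        flat = asdict(self)
        med = flat.pop("mediation")
        for key, value in med.items():
            flat[f"mediation_{key}"] = value
        for key in ("alpha_range", "rho_range"):
            rng = flat.pop(key)
            for grp, (lo, hi) in rng.items():
                flat[f"{key[:-6]}_{grp}_lo"] = lo
                flat[f"{key[:-6]}_{grp}_hi"] = hi
        return flat


def draw_subject_params(spec: GenerativeSpec, group: str,
                        rng: np.random.Generator) -> LearningParams:
    """Draw one subject's generative learning parameters."""
    alpha = rng.uniform(*spec.alpha_range[group])
    rho = rng.uniform(*spec.rho_range[group])
    if spec.model == "irw_fixed_init":
        return LearningParams(model="irw_fixed_init", alpha=alpha, rho=rho)
    if spec.model == "irw_free_init":
        return LearningParams(model="irw_free_init", alpha=alpha, rho=rho,
                              v0=rng.uniform())
    if spec.model == "rw":
        return LearningParams(model="rw", alpha=alpha, v0=rng.uniform())
    if spec.model == "hybrid":
        return LearningParams(model="hybrid", rho=rho, eta=rng.uniform(),
                              kappa=rng.uniform())
    raise ValueError(f"unknown generative model {spec.model!r}")


def generate_pain(schedule: TrialSchedule, spec: GenerativeSpec, seed: int,
                  params: Optional[LearningParams] = None):
    """Simulate one subject's pain ratings over a schedule.

    Returns ``(pain, truth)`` where ``truth`` records the drawn learning
    parameters and observation coefficients.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = draw_subject_params(spec, schedule.group, rng)
    trace = simulate_ev_trace(schedule, params)
    levels = schedule.trials["heat_level"].map(HEAT_TARGET).to_numpy()
    pain = (spec.beta0 + spec.beta_temp * levels
            + spec.beta_ev * trace.ev_presented
            + rng.normal(0.0, spec.noise_sd, size=len(levels)))
    if spec.truncate_ratings:
        pain = np.clip(pain, 0.0, RATING_MAX)
    truth = {"params": params, "beta0": spec.beta0,
             "beta_temp": spec.beta_temp, "beta_ev": spec.beta_ev,
             "noise_sd": spec.noise_sd}
    return pain, truth


def generate_cohort(spec: GenerativeSpec, seed: int = 0):
    """Generate a full two-group cohort of schedules and pain ratings.

    Orders 1 and 2 are counterbalanced across subjects within group.
    Returns ``(subjects, trials, truth)``: a list of (schedule, pain)
    pairs, the concatenated long-format trials table, and a per-subject
    truth table.
    """
    ss = np.random.SeedSequence([int(seed), 735310])
    subjects = []
    truth_rows = []
    frames = []
    i = 0
    for group in ("instructed", "uninstructed"):
        for j in range(spec.n_subjects_per_group):
            child = ss.spawn(1)[0]
            sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
            order = 1 if j % 2 == 0 else 2
            sid = f"sim-{group[:3]}{j:03d}"
            schedule = generate_trial_schedule(
                group, order, seed=sub_seed,
                conditioning_low_count=spec.conditioning_low_count,
                subject_id=sid)
            pain, truth = generate_pain(schedule, spec, sub_seed)
            subjects.append((schedule, pain))
            frames.append(schedule.to_frame(pain))
            params = truth["params"]
            truth_rows.append({
                "subject_id": sid, "group": group, "order_id": order,
                "alpha": params.alpha, "rho": params.rho, "v0": params.v0,
                "eta": params.eta, "kappa": params.kappa,
                "beta0": spec.beta0, "beta_temp": spec.beta_temp,
                "beta_ev": spec.beta_ev, "noise_sd": spec.noise_sd})
            i += 1
    trials = pd.concat(frames, ignore_index=True)
    return subjects, trials, pd.DataFrame(truth_rows)


def generate_mediators(schedule: TrialSchedule, spec: GenerativeSpec,
                       seed: int, region: str = "region_1",
                       ab_draw=None, baseline_pain=None):
    """Simulate one subject's mediator signal and medium-trial pain.

    ``ab_draw`` optionally fixes the subject's (a_j, b_j); otherwise they
    are drawn from the bivariate normal of ``spec.mediation``. With
    ``baseline_pain`` (a schedule-aligned pain vector, e.g. from
    :func:`generate_pain`), the mediated effect is overlaid on that
    baseline instead of the constant intercept d2, so one cohort can carry
    both the learning and the mediation structure. Returns
    ``(mediator_rows, pain, truth)``: a long mediator table for the
    subject's included medium trials, a schedule-aligned pain vector (NaN
    off the medium trials unless a baseline was given), and the subject
    truth.
    """
    from .mediation import _codes_for_subject

    ms = spec.mediation
    rng = np.random.default_rng(seed)
    if ab_draw is None:
        cov = np.array([
            [ms.sd_a ** 2, ms.corr_ab * ms.sd_a * ms.sd_b],
            [ms.corr_ab * ms.sd_a * ms.sd_b, ms.sd_b ** 2]])
        a_j, b_j = rng.multivariate_normal([ms.mean_a, ms.mean_b], cov)
    else:
        a_j, b_j = ab_draw

    df = schedule.trials
    if baseline_pain is None:
        pain = np.full(len(df), np.nan)
        probe = np.zeros(len(df))
    else:
        pain = np.asarray(baseline_pain, dtype=float).copy()
        probe = pain
    codes, _ = _codes_for_subject(schedule, probe)
    x = codes["x_current"].to_numpy(dtype=float)
    m = ms.d1 + a_j * x + rng.normal(0.0, ms.m_noise_sd, size=x.size)
    tg = codes["trial_global"].to_numpy()
    pos = np.searchsorted(df["trial_global"].to_numpy(), tg)
    base = ms.d2 if baseline_pain is None else pain[pos]
    y = (base + ms.c_prime * x + b_j * m
         + rng.normal(0.0, ms.y_noise_sd, size=x.size))
    if spec.truncate_ratings:
        y = np.clip(y, 0.0, RATING_MAX)
    pain[pos] = y
    rows = pd.DataFrame({
        "subject_id": schedule.subject_id, "trial_global": tg,
        "region": region, "response": m})
    truth = {"a": float(a_j), "b": float(b_j), "c_prime": ms.c_prime}
    return rows, pain, truth


def generate_mediation_cohort(spec: GenerativeSpec, seed: int = 0,
                              n_subjects: Optional[int] = None,
                              region: str = "region_1", subjects=None):
    """Generate a cohort for mediation analysis.

    With ``subjects`` (an existing list of (schedule, pain) pairs, e.g.
    from :func:`generate_cohort`) the mediated effect is overlaid on each
    subject's existing pain; otherwise fresh schedules are generated and
    pain comes from the mediation forward model alone. Returns
    ``(subjects, mediators, truth)`` where ``subjects`` is the list of
    (schedule, pain) pairs, ``mediators`` the long mediator table, and
    ``truth`` records the drawn subject paths and the population mediated
    effect.
    """
    overlay = subjects is not None
    if overlay:
        n_subjects = len(subjects)
    elif n_subjects is None:
        n_subjects = 2 * spec.n_subjects_per_group
    ss = np.random.SeedSequence([int(seed), 735311])
    states = ss.generate_state(2 * n_subjects) % (2 ** 31)
    out_subjects = []
    med_frames = []
    truth_rows = []
    for j in range(n_subjects):
        if overlay:
            schedule, baseline = subjects[j]
            sid = schedule.subject_id
        else:
            group = "instructed" if j % 2 == 0 else "uninstructed"
            order = 1 if (j // 2) % 2 == 0 else 2
            sid = f"med-{j:03d}"
            schedule = generate_trial_schedule(
                group, order, seed=int(states[2 * j]),
                conditioning_low_count=spec.conditioning_low_count,
                subject_id=sid)
            baseline = None
        rows, pain, truth = generate_mediators(
            schedule, spec, int(states[2 * j + 1]), region=region,
            baseline_pain=baseline)
        out_subjects.append((schedule, pain))
        med_frames.append(rows)
        truth_rows.append({"subject_id": sid, **truth})
    mediators = pd.concat(med_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["true_ab"] = spec.mediation.true_ab
    return out_subjects, mediators, truth


def recovery_experiment(spec: GenerativeSpec, n_replications: int = 1,
                        seed: int = 0, n_starts: int = 20) -> pd.DataFrame:
    """Generate -> fit -> summarize parameter recovery, one row per run.

    Each replication generates a fresh cohort, fits the generative model
    to every subject, and reports per-group recovered parameter means,
    the median absolute rho recovery error, and the between-group t-tests
    on recovered alpha and rho.
    """
    from .model_fitting import compare_groups, fit_subject

    ss = np.random.SeedSequence([int(seed), 735312])
    rep_seeds = ss.generate_state(2 * n_replications) % (2 ** 31)
    rows = []
    for r in range(n_replications):
        subjects, trials, truth = generate_cohort(
            spec, seed=int(rep_seeds[2 * r]))
        fit_seeds = np.random.SeedSequence(
            int(rep_seeds[2 * r + 1])).generate_state(
                len(subjects)) % (2 ** 31)
        fits = []
        for (schedule, pain), fseed in zip(subjects, fit_seeds):
            fit = fit_subject(schedule, pain, spec.model,
                              n_starts=n_starts, seed=int(fseed))
            fits.append({"subject_id": schedule.subject_id,
                         "group": schedule.group,
                         "alpha": fit.params.alpha, "rho": fit.params.rho})
        fits = pd.DataFrame(fits).merge(
            truth[["subject_id", "alpha", "rho"]], on="subject_id",
            suffixes=("_hat", "_true"))
        instructed = fits[fits["group"] == "instructed"]
        uninstructed = fits[fits["group"] == "uninstructed"]
        tests = compare_groups(instructed[["alpha_hat", "rho_hat"]],
                               uninstructed[["alpha_hat", "rho_hat"]])
        tests = tests.set_index("parameter")
        rows.append({
            "replication": r,
            "alpha_mean_instructed": instructed["alpha_hat"].mean(),
            "alpha_mean_uninstructed": uninstructed["alpha_hat"].mean(),
            "rho_mean_instructed": instructed["rho_hat"].mean(),
            "rho_mean_uninstructed": uninstructed["rho_hat"].mean(),
            "rho_median_abs_error":
                (fits["rho_hat"] - fits["rho_true"]).abs().median(),
            "alpha_bias": (fits["alpha_hat"] - fits["alpha_true"]).mean(),
            "rho_bias": (fits["rho_hat"] - fits["rho_true"]).mean(),
            "alpha_t": tests.loc["alpha_hat", "t"],
            "alpha_p": tests.loc["alpha_hat", "p"],
            "rho_t": tests.loc["rho_hat", "t"],
            "rho_p": tests.loc["rho_hat", "p"],
        })
    return pd.DataFrame(rows)
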