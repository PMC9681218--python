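"""Deviance fitting of learning models to medium-trial pain ratings.

Each candidate learning-parameter vector is scored by simulating its EV
trace over the subject's schedule and regressing pain on [1, EV] by
ordinary least squares over the included medium trials; the objective is
the residual sum of squares (deviance). The observation parameters
(intercept beta0 and EV slope beta1) are therefore profiled out exactly:
a Gaussian deviance with a linear observation model is conditionally
linear in the betas, so the inner OLS step is the standard exact
treatment.

Fitting uses 20 multi-start iterations by default, each drawing uniform
starting values within the [0, 1] bounds and running a bounded local
optimizer (L-BFGS-B); the global best across starts is returned.
Group-level fits share one learning-parameter vector across subjects
(summed per-subject OLS deviance) and are summarized through an iterative
leave-one-subject-out jack-knife, which is less sensitive to noise than
individual estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .learning_models import (FREE_PARAMS, CompiledSchedule, LearningParams,
                              compile_schedule, initial_values)

DEFAULT_N_STARTS = 20
_EPS = np.finfo(float).eps


class InsufficientDataError(ValueError):
    """Too few usable trials to fit the requested model."""


@dataclass(frozen=True)
class ObservationParams:
    """Linear observation model mapping EV to pain: beta0 + beta1 * EV."""

    beta0: float
    beta1: float


@dataclass
class FitResult:
    """Best fit of one learning model to one subject (or shared group)."""

    params: LearningParams
    obs: ObservationParams
    deviance: float
    n_trials: int
    aic: float
    n_starts: int
    converged_starts: int
    seed: int
    degenerate: bool = False

    def to_row(self, subject_id=None) -> dict:
        row = {"subject_id": subject_id, "model": self.params.model}
        for name in ("alpha", "rho", "v0", "eta", "kappa"):
            row[name] = getattr(self.params, name)
        row.update(beta0=self.obs.beta0, beta1=self.obs.beta1,
                   deviance=self.deviance, n_trials=self.n_trials,
                   aic=self.aic, degenerate_flag=self.degenerate)
        return row


@dataclass
class JackknifeResult:
    """Leave-one-out group estimates with jack-knife standard errors."""

    estimates: np.ndarray        # (n_subjects, n_free) leave-one-out fits
    mean: np.ndarray
    se: np.ndarray
    param_names: tuple
    group_label: Optional[str] = None

    def as_dict(self) -> dict:
        out = {}
        for j, name in enumerate(self.param_names):
            out[name] = float(self.mean[j])
            out[f"{name}_se"] = float(self.se[j])
        return out


def default_fit_mask(schedule, pain) -> np.ndarray:
    """Trials entering the deviance: medium heat, not first-in-block,
    with a recorded pain response."""
    cs = compile_schedule(schedule)
    pain = np.asarray(pain, dtype=float)
    return cs.is_medium & ~cs.is_first_in_block & np.isfinite(pain)


def _ols_rss(ev: np.ndarray, pain: np.ndarray):
    """Profile (beta0, beta1) by OLS of pain on [1, ev]; return betas, RSS.

    A constant EV trace is a rank-deficient design; the fit degenerates to
    the intercept-only model with beta1 = 0.
    """
    n = ev.size
    sx = ev.sum()
    sxx = ev @ ev
    det = n * sxx - sx * sx
    sy = pain.sum()
    if det <= 1e-12 * max(n * sxx, 1e-300):
        beta0 = sy / n
        resid = pain - beta0
        return beta0, 0.0, float(resid @ resid), True
    sxy = ev @ pain
    beta1 = (n * sxy - sx * sy) / det
    beta0 = (sy - beta1 * sx) / n
    resid = pain - beta0 - beta1 * ev
    return beta0, beta1, float(resid @ resid), False


def _simulate_ev_masked(cs: CompiledSchedule, params: LearningParams,
                        mask, update_on_medium: bool):
    """Presented-cue EV on masked trials (inlined forward pass, loop-hot)."""
    model = params.model
    ev_h, ev_l = initial_values(params, cs.group)
    rho = params.rho if model != "rw" else 0.0
    mask_l = mask.tolist() if isinstance(mask, np.ndarray) else mask
    out = []
    append = out.append
    if model == "hybrid":
        assoc_h = assoc_l = params.a0
        eta, kappa = params.eta, params.kappa
        for (high, outcome, is_medium, is_event), want in zip(cs.rows,
                                                              mask_l):
            if is_event:
                ev_h, ev_l = (rho * ev_l + (1 - rho) * ev_h,
                              rho * ev_h + (1 - rho) * ev_l)
            ev_t = ev_h if high else ev_l
            if want:
                append(ev_t)
            if update_on_medium or not is_medium:
                r = 0.5 if is_medium else outcome
                assoc_t = assoc_h if high else assoc_l
                pe = r - ev_t
                new_ev = min(1.0, max(0.0, ev_t + kappa * assoc_t * pe))
                new_assoc = eta * abs(pe) + (1 - eta) * assoc_t
                if high:
                    ev_h, assoc_h = new_ev, new_assoc
                else:
                    ev_l, assoc_l = new_ev, new_assoc
    else:
        alpha = params.alpha
        is_rw = model == "rw"
        for (high, outcome, is_medium, is_event), want in zip(cs.rows,
                                                              mask_l):
            if is_event and not is_rw:
                ev_h, ev_l = (rho * ev_l + (1 - rho) * ev_h,
                              rho * ev_h + (1 - rho) * ev_l)
            ev_t = ev_h if high else ev_l
            if want:
                append(ev_t)
            if update_on_medium or not is_medium:
                r = 0.5 if is_medium else outcome
                if high:
                    ev_h = ev_t + alpha * (r - ev_t)
                else:
                    ev_l = ev_t + alpha * (r - ev_t)
    return np.asarray(out)


def deviance_for_params(schedule, pain, params: LearningParams,
                        mask=None, update_on_medium: bool = False):
    """Deviance (RSS) of a candidate parameter vector, with profiled betas.

    Returns ``(deviance, ObservationParams, degenerate_flag)``.
    """
    cs = compile_schedule(schedule)
    pain = np.asarray(pain, dtype=float)
    if mask is None:
        mask = default_fit_mask(cs, pain)
    ev = _simulate_ev_masked(cs, params, mask, update_on_medium)
    beta0, beta1, rss, degenerate = _ols_rss(ev, pain[mask])
    return rss, ObservationParams(beta0, beta1), degenerate


def aic(deviance: float, n_trials: int, k_free: int) -> float:
    """Gaussian AIC: n * ln(RSS/n) + 2k, with k counting beta0 and beta1.

    RSS is floored at machine epsilon before the log so perfect fits stay
    finite; the shared noise-variance term is an equal constant across
    models at fixed n and is omitted.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if deviance < 0:
        raise ValueError("deviance must be non-negative")
    rss = max(float(deviance), _EPS)
    return n_trials * np.log(rss / n_trials) + 2.0 * k_free


def _check_usable(n_used, n_free):
    if n_used < n_free + 2:
        raise InsufficientDataError(
            f"{n_used} usable trials < {n_free} free parameters + 2")


def _multistart(objective, n_free, n_starts, seed, extra_starts=()):
    """Run the multi-start protocol; return (x, fval, converged_starts).

    Ties at equal deviance break toward the lexicographically smallest
    parameter vector (canonical order puts alpha before rho), which pins
    down flat regions that arise when beta1 is ~0.
    """
    rng = np.random.default_rng(seed)
    bounds = [(0.0, 1.0)] * n_free
    best_x, best_f = None, np.inf
    converged = 0
    starts = [np.asarray(s, dtype=float) for s in extra_starts]
    starts += [rng.uniform(0.0, 1.0, size=n_free) for _ in range(n_starts)]
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=bounds)
        if res.success:
            converged += 1
        cand_x = np.clip(res.x, 0.0, 1.0)
        cand_f = float(objective(cand_x))
        if (cand_f < best_f - 1e-12
                or (abs(cand_f - best_f) <= 1e-12
                    and best_x is not None
                    and tuple(cand_x) < tuple(best_x))):
            best_x, best_f = cand_x, cand_f
    return best_x, best_f, converged


def fit_subject(schedule, pain, model: str, mask=None,
                n_starts: int = DEFAULT_N_STARTS, seed: int = 0,
                update_on_medium: bool = False) -> FitResult:
    """Fit one learning model to one subject's pain ratings.

    The mask defaults to included medium trials (first-in-block and
    missing-response trials are omitted). Identical seeds give identical
    results.
    """
    cs = compile_schedule(schedule)
    pain = np.asarray(pain, dtype=float)
    if mask is None:
        mask = default_fit_mask(cs, pain)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(pain)
    names = FREE_PARAMS[model]
    _check_usable(int(mask.sum()), len(names))
    pain_m = pain[mask]
    mask_l = mask.tolist()

    def objective(x):
        params = LearningParams.from_free_values(
            model, np.clip(x, 0.0, 1.0))
        ev = _simulate_ev_masked(cs, params, mask_l, update_on_medium)
        return _ols_rss(ev, pain_m)[2]

    best_x, best_f, converged = _multistart(
        objective, len(names), n_starts, seed)
    params = LearningParams.from_free_values(model, best_x)
    rss, obs, degenerate = deviance_for_params(
        cs, pain, params, mask, update_on_medium)
    n_used = int(mask.sum())
    return FitResult(
        params=params, obs=obs, deviance=rss, n_trials=n_used,
        aic=aic(rss, n_used, len(names) + 2), n_starts=n_starts,
        converged_starts=converged, seed=int(seed), degenerate=degenerate)


def fit_group(subject_data: Sequence, model: str,
              n_starts: int = DEFAULT_N_STARTS, seed: int = 0,
              update_on_medium: bool = False) -> FitResult:
    """Fit one shared learning-parameter vector across subjects.

    ``subject_data`` is a sequence of ``(schedule, pain)`` pairs (or
    ``(schedule, pain, mask)``). The objective is the sum over subjects of
    each subject's own profiled-OLS deviance; betas remain per-subject.
    """
    if len(subject_data) < 2:
        raise InsufficientDataError("fit_group needs at least 2 subjects")
    names = FREE_PARAMS[model]
    compiled = []
    for item in subject_data:
        schedule, pain = item[0], np.asarray(item[1], dtype=float)
        cs = compile_schedule(schedule)
        mask = (default_fit_mask(cs, pain) if len(item) < 3
                else np.asarray(item[2], dtype=bool) & np.isfinite(pain))
        _check_usable(int(mask.sum()), len(names))
        compiled.append((cs, pain[mask], mask.tolist()))

    def objective(x):
        params = LearningParams.from_free_values(
            model, np.clip(x, 0.0, 1.0))
        total = 0.0
        for cs, pain_m, mask in compiled:
            ev = _simulate_ev_masked(cs, params, mask, update_on_medium)
            total += _ols_rss(ev, pain_m)[2]
        return total

    best_x, best_f, converged = _multistart(
        objective, len(names), n_starts, seed)
    params = LearningParams.from_free_values(model, best_x)
    n_used = sum(len(p) for _, p, _ in compiled)
    # group-level observation params: OLS pooled across subjects is not
    # meaningful (betas are per subject); report the mean of subject betas.
    betas = []
    for cs, pain_m, mask in compiled:
        ev = _simulate_ev_masked(cs, params, mask, update_on_medium)
        b0, b1, _, _ = _ols_rss(ev, pain_m)
        betas.append((b0, b1))
    b0m, b1m = np.mean(betas, axis=0)
    return FitResult(
        params=params, obs=ObservationParams(float(b0m), float(b1m)),
        deviance=best_f, n_trials=n_used,
        aic=aic(best_f, n_used, len(names) + 2), n_starts=n_starts,
        converged_starts=converged, seed=int(seed))


def jackknife_fit(group_data: Sequence, model: str,
                  n_starts: int = DEFAULT_N_STARTS, seed: int = 0,
                  group_label: Optional[str] = None,
                  update_on_medium: bool = False) -> JackknifeResult:
    """Iterative jack-knife group fit.

    For each subject i the group model is re-fit on the remaining n-1
    subjects, giving leave-one-out estimates theta_(i); the jack-knife SE
    is sqrt(((n-1)/n) * sum_i (theta_(i) - mean)^2).
    """
    n = len(group_data)
    if n < 3:
        raise InsufficientDataError("jackknife_fit needs at least 3 subjects")
    names = FREE_PARAMS[model]
    estimates = np.empty((n, len(names)))
    fold_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    for i in range(n):
        rest = [group_data[j] for j in range(n) if j != i]
        try:
            fit = fit_group(rest, model, n_starts=n_starts,
                            seed=int(fold_seeds[i]),
                            update_on_medium=update_on_medium)
        except Exception as exc:
            raise RuntimeError(f"jack-knife fold {i} failed: {exc}") from exc
        estimates[i] = fit.params.free_values()
    mean = estimates.mean(axis=0)
    se = np.sqrt((n - 1) / n * ((estimates - mean) ** 2).sum(axis=0))
    return JackknifeResult(estimates=estimates, mean=mean, se=se,
                           param_names=names, group_label=group_label)


def jackknife_se(estimates) -> np.ndarray:
    """Jack-knife SE from a list of leave-one-out estimates."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    if estimates.shape[0] == 1:
        estimates = estimates.T
    n = estimates.shape[0]
    mean = estimates.mean(axis=0)
    return np.sqrt((n - 1) / n * ((estimates - mean) ** 2).sum(axis=0))


def compare_groups(params_g1, params_g2) -> pd.DataFrame:
    """Two-sample t-tests per parameter between groups.

    ``params_g*`` are arrays (n_subjects, n_params) or dict-like columns.
    Pooled-variance t with df = n1 + n2 - 2 by default. Two groups with
    zero variance and equal means return t = 0, p = 1 by convention.
    """
    if isinstance(params_g1, pd.DataFrame):
        names = list(params_g1.columns)
        g1 = params_g1.to_numpy(dtype=float)
        g2 = params_g2[names].to_numpy(dtype=float)
    else:
        g1 = np.atleast_2d(np.asarray(params_g1, dtype=float))
        g2 = np.atleast_2d(np.asarray(params_g2, dtype=float))
        if g1.shape[0] == 1 and g1.shape[1] > 1 and g2.shape[0] == 1:
            g1, g2 = g1.T, g2.T
        names = [f"param_{j}" for j in range(g1.shape[1])]
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("need at least 2 values per group")
    rows = []
    for j, name in enumerate(names):
        x, y = g1[:, j], g2[:, j]
        if np.var(x) == 0 and np.var(y) == 0:
            if np.mean(x) == np.mean(y):
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(np.mean(x) - np.mean(y)), 0.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append({"parameter": name, "t": float(t),
                     "df": len(x) + len(y) - 2, "p": float(p),
                     "mean_g1": float(np.mean(x)),
                     "mean_g2": float(np.mean(y))})
    return pd.DataFrame(rows)


def fit_cohort(trials: pd.DataFrame, model: str,
               n_starts: int = DEFAULT_N_STARTS, seed: int = 0,
               update_on_medium: bool = False) -> pd.DataFrame:
    """Fit every subject in a long-format trials table; one row per subject."""
    from .task_design import schedule_from_frame
    rows = []
    subject_ids = trials["subject_id"].unique()
    seeds = np.random.SeedSequence(seed).generate_state(
        len(subject_ids)) % (2 ** 31)
    for sid, s in zip(subject_ids, seeds):
        sub = trials[trials["subject_id"] == sid]
        schedule = schedule_from_frame(sub)
        pain = sub.sort_values("trial_global")["pain"].to_numpy(dtype=float)
        fit = fit_subject(schedule, pain, model, n_starts=n_starts,
                          seed=int(s), update_on_medium=update_on_medium)
        row = fit.to_row(subject_id=sid)
        row["group"] = schedule.group
        rows.append(row)
    return pd.DataFrame(rows)
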