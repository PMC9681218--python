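"""Multilevel mediation of cue effects on trial-level pain.

Within each subject j, three OLS regressions estimate the mediation paths
for trial i:

    Y_ij = d0_j + c_j  X_ij + e0_ij                (total effect)
    M_ij = d1_j + a_j  X_ij + e1_ij                (path a)
    Y_ij = d2_j + c'_j X_ij + b_j M_ij + e2_ij     (paths b and c')

X is the cue contrast (+1 high-pain cue, -1 low-pain cue), M a trial-level
mediator signal (e.g. a brain region's response), Y the pain rating. Any
covariates are appended to all three designs. Within every subject the OLS
identity c = c' + a*b holds.

At the population level the mediated effect is the mean over subjects of
a_j * b_j, which decomposes exactly as mean(a)mean(b) + cov(a, b): subject
paths are treated as random effects, so mediation can be carried by the
between-subject covariance of the two paths even when either mean is
small. Significance is assessed by bootstrap resampling of subjects, and
moderated mediation (e.g. by group) by OLS of the subject-level paths on
the centered moderator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .task_design import TrialSchedule

DEFAULT_N_BOOT = 10_000
PATH_NAMES = ("a", "b", "c", "c_prime", "ab")


class DegenerateSubjectError(ValueError):
    """A subject's mediation design is rank deficient."""


@dataclass
class MediationDataset:
    """One subject's trial-level mediation variables."""

    subject_id: str
    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    covariates: Optional[np.ndarray] = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.x.size
        if self.m.size != n or self.y.size != n:
            raise ValueError("x, m, y must have equal lengths")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(
                np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != n:
                raise ValueError("covariates must align with trials")
        n_cov = 0 if self.covariates is None else self.covariates.shape[1]
        if n < n_cov + 3:
            raise DegenerateSubjectError(
                f"subject {self.subject_id}: {n} trials are too few for "
                f"{n_cov} covariates")


@dataclass(frozen=True)
class SubjectPaths:
    """OLS path coefficients for one subject."""

    a: float
    b: float
    c: float
    c_prime: float
    d0: float
    d1: float
    d2: float
    resid_var: tuple  # residual variances of Eqs (1)-(3)

    @property
    def ab(self) -> float:
        return self.a * self.b


@dataclass
class PathSummary:
    estimate: float
    boot_p: float
    ci_lo: float
    ci_hi: float


@dataclass
class MediationResult:
    """Population mediation summary over subjects."""

    paths: dict            # path name -> PathSummary
    ab_mean: float
    ab_decomposition: tuple  # (mean_a * mean_b, cov(a, b))
    subject_paths: pd.DataFrame
    moderation: Optional[pd.DataFrame]
    n_boot: int
    seed: int
    excluded_subjects: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_paths)


def _ols(X: np.ndarray, y: np.ndarray, label: str):
    """Least squares with an explicit rank check."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DegenerateSubjectError(f"rank-deficient design in {label}")
    beta, rss, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    return beta, float(resid @ resid) / dof


def fit_subject_paths(dataset: MediationDataset) -> SubjectPaths:
    """Three OLS regressions for one subject, covariates in every design."""
    x, m, y = dataset.x, dataset.m, dataset.y
    n = x.size
    ones = np.ones(n)
    cov = dataset.covariates
    cov_cols = [] if cov is None else [cov]

    X1 = np.column_stack([ones, x, *cov_cols])
    beta1, v0 = _ols(X1, y, f"total-effect model ({dataset.subject_id})")
    d0, c = float(beta1[0]), float(beta1[1])

    beta2, v1 = _ols(X1, m, f"path-a model ({dataset.subject_id})")
    d1, a = float(beta2[0]), float(beta2[1])

    X3 = np.column_stack([ones, x, m, *cov_cols])
    beta3, v2 = _ols(X3, y, f"path-b model ({dataset.subject_id})")
    d2, c_prime, b = float(beta3[0]), float(beta3[1]), float(beta3[2])

    return SubjectPaths(a=a, b=b, c=c, c_prime=c_prime,
                        d0=d0, d1=d1, d2=d2, resid_var=(v0, v1, v2))


def _bootstrap_p(boot_means: np.ndarray, n_boot: int) -> float:
    """Two-tailed percentile bootstrap p with floor 2/(n_boot+1)."""
    frac_le = np.mean(boot_means <= 0.0)
    frac_ge = np.mean(boot_means >= 0.0)
    p = 2.0 * min(frac_le, frac_ge)
    return float(min(1.0, max(p, 2.0 / (n_boot + 1))))


def mediate(datasets: Sequence[MediationDataset],
            n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
            moderator=None) -> MediationResult:
    """Population mediation across subjects with bootstrap significance.

    Subjects whose designs are rank deficient are excluded with a warning.
    The bootstrap resamples subjects (the exchangeable unit in the
    multilevel formulation) with replacement and recomputes path means;
    p-values are two-tailed percentile with floor 2/(n_boot+1). If a
    per-subject ``moderator`` vector is given, each subject-level path is
    regressed on the centered moderator by OLS (moderated mediation).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rows = []
    excluded = []
    kept_idx = []
    for i, ds in enumerate(datasets):
        try:
            p = fit_subject_paths(ds)
        except DegenerateSubjectError as exc:
            warnings.warn(f"excluding degenerate subject "
                          f"{ds.subject_id}: {exc}")
            excluded.append(ds.subject_id)
            continue
        kept_idx.append(i)
        rows.append({"subject_id": ds.subject_id, "a": p.a, "b": p.b,
                     "c": p.c, "c_prime": p.c_prime, "ab": p.ab})
    if len(rows) < 3:
        raise ValueError("mediation requires >= 3 non-degenerate subjects")
    table = pd.DataFrame(rows)
    n = len(table)

    path_vals = {name: table[name].to_numpy() for name in PATH_NAMES}
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    paths = {}
    for name, vals in path_vals.items():
        boot = vals[idx].mean(axis=1)
        paths[name] = PathSummary(
            estimate=float(vals.mean()),
            boot_p=_bootstrap_p(boot, n_boot),
            ci_lo=float(np.percentile(boot, 2.5)),
            ci_hi=float(np.percentile(boot, 97.5)))

    a_j, b_j = path_vals["a"], path_vals["b"]
    decomposition = (float(a_j.mean() * b_j.mean()),
                     float(np.cov(a_j, b_j, bias=True)[0, 1]))

    moderation = None
    if moderator is not None:
        mod = np.asarray(moderator, dtype=float)
        if mod.size != len(datasets):
            raise ValueError("moderator must have one value per subject")
        mod = mod[kept_idx]
        mod_c = mod - mod.mean()
        X = np.column_stack([np.ones(n), mod_c])
        mod_rows = []
        for name, vals in path_vals.items():
            beta, _, _, _ = np.linalg.lstsq(X, vals, rcond=None)
            resid = vals - X @ beta
            dof = n - 2
            s2 = float(resid @ resid) / dof
            se = np.sqrt(s2 / float(mod_c @ mod_c)) if mod_c @ mod_c > 0 \
                else np.inf
            t = beta[1] / se if np.isfinite(se) and se > 0 else 0.0
            p = 2 * stats.t.sf(abs(t), dof)
            mod_rows.append({"path": name, "slope": float(beta[1]),
                             "t": float(t), "p": float(p)})
        moderation = pd.DataFrame(mod_rows)

    return MediationResult(
        paths=paths, ab_mean=paths["ab"].estimate,
        ab_decomposition=decomposition, subject_paths=table,
        moderation=moderation, n_boot=n_boot, seed=int(seed),
        excluded_subjects=excluded)


def _codes_for_subject(schedule, pain):
    """Mask and contingency codes aligned to one subject's medium trials."""
    from .task_design import encode_contingencies
    df = schedule.trials if isinstance(schedule, TrialSchedule) else schedule
    codes = encode_contingencies(schedule)
    pain = np.asarray(pain, dtype=float)
    medium = (df["heat_level"] == "medium").to_numpy()
    first = df["is_first_in_block"].to_numpy(dtype=bool)
    tg = df["trial_global"].to_numpy()
    keep_tg = tg[medium & ~first & np.isfinite(pain)]
    codes = codes[codes["trial_global"].isin(keep_tg)]
    pain_map = dict(zip(tg, pain))
    y = np.array([pain_map[t] for t in codes["trial_global"]])
    return codes.reset_index(drop=True), y


def _mediator_lookup(mediators: pd.DataFrame):
    """Long mediator table -> {(subject, region): {trial: response}}."""
    required = {"subject_id", "trial_global", "region", "response"}
    missing = required - set(mediators.columns)
    if missing:
        raise ValueError(f"mediator table missing columns: {sorted(missing)}")
    regions = list(pd.unique(mediators["region"]))
    lut = {}
    for (sid, region), grp in mediators.groupby(["subject_id", "region"],
                                                sort=False):
        lut[(str(sid), region)] = dict(
            zip(grp["trial_global"], grp["response"]))
    return regions, lut


def _mediate_by_region(subjects, mediators, coding, n_boot, seed,
                       moderator, fdr_q):
    regions, lut = _mediator_lookup(mediators)
    results = {}
    mod_values = None
    if isinstance(moderator, str):
        if moderator != "group":
            raise ValueError("string moderator must be 'group'")
        mod_values = [1.0 if s[0].group == "instructed" else 0.0
                      for s in subjects]
    elif moderator is not None:
        mod_values = list(moderator)

    for region in regions:
        datasets = []
        for schedule, pain in subjects:
            sid = (schedule.subject_id if isinstance(schedule, TrialSchedule)
                   else schedule["subject_id"].iloc[0])
            codes, y = _codes_for_subject(schedule, pain)
            resp = lut.get((str(sid), region), {})
            m = np.array([resp.get(t, np.nan) for t in codes["trial_global"]])
            ok = np.isfinite(m)
            x = codes["x_current" if coding == "current"
                      else "x_original"].to_numpy(dtype=float)
            cov = (None if coding == "current"
                   else codes["x_current"].to_numpy(dtype=float)[ok, None])
            datasets.append(MediationDataset(
                subject_id=str(sid), x=x[ok], m=m[ok], y=y[ok],
                covariates=cov))
        results[region] = mediate(datasets, n_boot=n_boot, seed=seed,
                                  moderator=mod_values)

    rows = []
    for region, res in results.items():
        mod = (res.moderation.set_index("path")
               if res.moderation is not None else None)
        for name, summary in res.paths.items():
            rows.append({
                "region": region, "path": name,
                "estimate": summary.estimate, "boot_p": summary.boot_p,
                "ci_lo": summary.ci_lo, "ci_hi": summary.ci_hi,
                "moderator_slope": (float(mod.loc[name, "slope"])
                                    if mod is not None else np.nan),
                "moderator_p": (float(mod.loc[name, "p"])
                                if mod is not None else np.nan),
            })
    table = pd.DataFrame(rows)
    # BH FDR across regions, separately per path family
    table["fdr_q"] = np.nan
    table["fdr_significant"] = False
    for name in PATH_NAMES:
        sel = table["path"] == name
        if sel.sum() == 0:
            continue
        reject, q, _, _ = multipletests(table.loc[sel, "boot_p"],
                                        alpha=fdr_q, method="fdr_bh")
        table.loc[sel, "fdr_q"] = q
        table.loc[sel, "fdr_significant"] = reject
    return table, results


def mediate_current_contingencies(subjects, mediators,
                                  n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                                  moderator=None, fdr_q: float = 0.05):
    """Mediation of current cue contingencies (X = x_current).

    ``subjects`` is a sequence of ``(schedule, pain)`` pairs; ``mediators``
    a long table (subject_id, trial_global, region, response). Only
    included medium trials enter. Returns ``(table, results)``: a long
    per-region/per-path table with BH FDR across regions, and the full
    :class:`MediationResult` per region.
    """
    return _mediate_by_region(subjects, mediators, "current", n_boot, seed,
                              moderator, fdr_q)


def mediate_original_contingencies(subjects, mediators,
                                   n_boot: int = DEFAULT_N_BOOT,
                                   seed: int = 0, moderator=None,
                                   fdr_q: float = 0.05):
    """Mediation of original cue contingencies, controlling current ones.

    X = x_original with x_current appended as a covariate to all three
    path regressions. Subjects whose x_original and x_current are
    collinear (e.g. trials in only one phase) are excluded as degenerate.
    """
    return _mediate_by_region(subjects, mediators, "original", n_boot, seed,
                              moderator, fdr_q)
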