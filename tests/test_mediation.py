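"""Multilevel mediation: path regressions, identities, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import painlearn as pl
from painlearn.mediation import (DegenerateSubjectError, MediationDataset,
                                 fit_subject_paths, mediate)

TOY_X = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
TOY_M = np.array([2, 0, 2, 0, 2, 1, 1, 0], dtype=float)
TOY_Y = np.array([3, 1, 3, 1, 3, 2, 2, 1], dtype=float)


def _normal_equations(X, y):
    return np.linalg.inv(X.T @ X) @ X.T @ y


def test_toy_set_matches_normal_equations_oracle():
    """The printed toy set reproduces closed-form normal-equation OLS."""
    paths = fit_subject_paths(MediationDataset("t", TOY_X, TOY_M, TOY_Y))
    ones = np.ones_like(TOY_X)
    b1 = _normal_equations(np.column_stack([ones, TOY_X]), TOY_Y)
    b2 = _normal_equations(np.column_stack([ones, TOY_X]), TOY_M)
    b3 = _normal_equations(np.column_stack([ones, TOY_X, TOY_M]), TOY_Y)
    assert paths.c == pytest.approx(b1[1], abs=1e-10)
    assert paths.a == pytest.approx(b2[1], abs=1e-10)
    assert paths.c_prime == pytest.approx(b3[1], abs=1e-10)
    assert paths.b == pytest.approx(b3[2], abs=1e-10)
    assert paths.d0 == pytest.approx(b1[0], abs=1e-10)
    # within-subject identity
    assert abs(paths.c - (paths.c_prime + paths.a * paths.b)) < 1e-10


def test_location_invariance_of_paths():
    """Adding a constant to the mediator shifts intercepts only."""
    base = fit_subject_paths(MediationDataset("t", TOY_X, TOY_M, TOY_Y))
    shifted = fit_subject_paths(
        MediationDataset("t", TOY_X, TOY_M + 7.0, TOY_Y))
    for name in ("a", "b", "c", "c_prime"):
        assert getattr(base, name) == pytest.approx(
            getattr(shifted, name), abs=1e-10)
    assert shifted.d2 != pytest.approx(base.d2, abs=1e-6)


def test_null_path_a_is_small():
    """m independent of x at n=200: the estimated a stays near zero."""
    rng = np.random.default_rng(0)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        x = np.tile([1.0, -1.0], 100)
        m = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 200)
        paths = fit_subject_paths(MediationDataset("n", x, m, y))
        assert abs(paths.a) < 0.2


def test_rank_deficiency_raises():
    x = np.array([1.0, -1, 1, -1, 1, -1])
    with pytest.raises(DegenerateSubjectError):
        fit_subject_paths(MediationDataset("d", x, 2 * x, 3 * x))  # m == 2x
    with pytest.raises(DegenerateSubjectError):
        # covariate collinear with x (original vs current coding overlap)
        fit_subject_paths(MediationDataset(
            "d", x, x + np.arange(6) * 0.1, x * 2.0,
            covariates=x.copy()))
    with pytest.raises(DegenerateSubjectError):
        MediationDataset("d", x[:2], x[:2], x[:2])  # too few trials


def _exact_subject(sid, a_j, b_j, n=8):
    """Noise-free subject with exact paths a_j, b_j (e orthogonal to x)."""
    x = np.tile([1.0, -1.0], n // 2)
    e = np.repeat([1.0, -1.0], n // 2)  # orthogonal to x, zero mean
    m = a_j * x + e
    y = b_j * m
    return MediationDataset(sid, x, m, y)


def test_mediate_exact_paths_zero_covariance():
    """Identical subjects with a=2, b=3: ab_mean = 6, covariance 0."""
    datasets = [_exact_subject(f"s{i}", 2.0, 3.0) for i in range(4)]
    res = mediate(datasets, n_boot=500, seed=0)
    assert res.ab_mean == pytest.approx(6.0, abs=1e-10)
    prod, cov = res.ab_decomposition
    assert prod == pytest.approx(6.0, abs=1e-10)
    assert cov == pytest.approx(0.0, abs=1e-12)
    assert res.paths["a"].estimate == pytest.approx(2.0, abs=1e-10)
    assert res.paths["b"].estimate == pytest.approx(3.0, abs=1e-10)


def test_mediate_covariance_driven_effect():
    """Zero-mean, perfectly correlated subject paths: the mediated effect
    equals the covariance term of the decomposition."""
    z = np.array([-1.5, -0.5, 0.5, 1.5, -1.0, 1.0])
    z = (z - z.mean()) / z.std()  # exactly centered, unit population SD
    datasets = [_exact_subject(f"s{i}", zi, zi) for i, zi in enumerate(z)]
    res = mediate(datasets, n_boot=500, seed=0)
    prod, cov = res.ab_decomposition
    assert prod == pytest.approx(0.0, abs=1e-10)
    assert cov == pytest.approx(1.0, abs=1e-10)
    assert res.ab_mean == pytest.approx(prod + cov, abs=1e-10)


def test_decomposition_and_within_subject_identities():
    """mean(a_j b_j) = mean(a)mean(b) + cov(a,b) to 1e-10 and
    c = c' + a*b to 1e-8 for every subject, on noisy generated data."""
    spec = pl.GenerativeSpec(n_subjects_per_group=6)
    subjects, mediators, _ = pl.generate_mediation_cohort(spec, seed=3)
    _, results = pl.mediate_current_contingencies(
        subjects, mediators, n_boot=200, seed=0)
    res = results["region_1"]
    prod, cov = res.ab_decomposition
    assert abs(res.ab_mean - (prod + cov)) < 1e-10
    sp = res.subject_paths
    assert (sp["c"] - (sp["c_prime"] + sp["ab"])).abs().max() < 1e-8


def test_bootstrap_determinism_and_p_floor():
    datasets = [_exact_subject(f"s{i}", 2.0 + 0.1 * i, 3.0) for i in range(5)]
    a = mediate(datasets, n_boot=999, seed=42)
    b = mediate(datasets, n_boot=999, seed=42)
    for name in ("a", "b", "ab"):
        assert a.paths[name].boot_p == b.paths[name].boot_p
        assert a.paths[name].ci_lo == b.paths[name].ci_lo
    # all-positive effects bottom out at the bootstrap floor
    assert a.paths["ab"].boot_p == pytest.approx(2.0 / 1000.0)


def test_moderated_mediation_recovers_group_difference():
    """Subject paths that differ by group produce a moderation slope on
    path a near the group difference."""
    datasets = []
    moderator = []
    rng = np.random.default_rng(1)
    for i in range(16):
        grp = i % 2
        a_j = (2.0 if grp else 1.0) + rng.normal(0, 0.05)
        datasets.append(_exact_subject(f"s{i}", a_j, 1.0, n=16))
        moderator.append(float(grp))
    res = mediate(datasets, n_boot=500, seed=0, moderator=moderator)
    mod = res.moderation.set_index("path")
    assert mod.loc["a", "slope"] == pytest.approx(1.0, abs=0.1)
    assert mod.loc["a", "p"] < 1e-6


def test_current_coding_passthrough(instructed_schedule):
    """The x vector equals +1 exactly on current-high medium trials."""
    codes = pl.encode_contingencies(instructed_schedule)
    spec = pl.GenerativeSpec()
    rows, pain, _ = pl.generate_mediators(instructed_schedule, spec, seed=0)
    from painlearn.mediation import _codes_for_subject
    sub_codes, y = _codes_for_subject(instructed_schedule, pain)
    merged = sub_codes.merge(codes, on="trial_global",
                             suffixes=("", "_full"))
    assert (merged["x_current"] == merged["x_current_full"]).all()


def test_original_vs_current_discriminability(schedule_pool):
    """Mediators driven by the original contingency are detected by the
    original-coding analysis, not the current-coding one."""
    rng = np.random.default_rng(0)
    subjects, med_frames = [], []
    from painlearn.mediation import _codes_for_subject
    for i in range(12):
        schedule = schedule_pool[i % len(schedule_pool)]
        schedule = pl.generate_trial_schedule(
            schedule.group, schedule.order_id if schedule.order_id != 1
            else 1, seed=100 + i, subject_id=f"d{i}")
        df = schedule.trials
        pain0 = np.zeros(len(df))
        codes, _ = _codes_for_subject(schedule, pain0)
        x_orig = codes["x_original"].to_numpy(dtype=float)
        m = 1.0 * x_orig + rng.normal(0, 0.3, x_orig.size)
        y = 0.5 * m + rng.normal(0, 0.3, x_orig.size)
        pain = np.full(len(df), np.nan)
        pos = np.searchsorted(df["trial_global"].to_numpy(),
                              codes["trial_global"].to_numpy())
        pain[pos] = y + 5.0
        subjects.append((schedule, pain))
        med_frames.append(pd.DataFrame({
            "subject_id": schedule.subject_id,
            "trial_global": codes["trial_global"],
            "region": "r1", "response": m}))
    mediators = pd.concat(med_frames, ignore_index=True)
    orig_table, _ = pl.mediate_original_contingencies(
        subjects, mediators, n_boot=300, seed=1)
    cur_table, _ = pl.mediate_current_contingencies(
        subjects, mediators, n_boot=300, seed=1)
    a_orig = orig_table.set_index("path").loc["a", "estimate"]
    a_cur = cur_table.set_index("path").loc["a", "estimate"]
    assert a_orig == pytest.approx(1.0, abs=0.15)
    assert abs(a_cur) < 0.3


def test_single_phase_subject_flagged_degenerate(instructed_schedule):
    """A subject with medium trials in only one phase has x_original
    collinear with x_current and is excluded from original-coding
    mediation."""
    df = instructed_schedule.trials
    # mask away all reversed-phase trials by recording no pain there
    pain = np.full(84, 5.0)
    rng = np.random.default_rng(0)
    pain += rng.normal(0, 0.1, 84)
    pain[df["phase"].to_numpy() == "reversed"] = np.nan
    from painlearn.mediation import _codes_for_subject
    codes, y = _codes_for_subject(instructed_schedule, pain)
    assert (codes["x_current"] == codes["x_original"]).all()
    ds = MediationDataset(
        "one-phase", codes["x_original"].to_numpy(dtype=float),
        rng.normal(0, 1, len(codes)), y,
        covariates=codes["x_current"].to_numpy(dtype=float))
    with pytest.raises(DegenerateSubjectError):
        fit_subject_paths(ds)
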