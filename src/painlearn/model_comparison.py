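"""Model comparison: AIC summaries and random-effects Bayesian model selection.

Per-subject AIC values are converted to approximate log model evidence
(-AIC/2) and fed to the variational Dirichlet scheme for random-effects
Bayesian model selection, which estimates the population frequencies of
the candidate models. ``expected_prob`` (alpha_k / sum(alpha)) is the
expected frequency of each model; ``exceedance_prob`` is the posterior
probability that a model is the most frequent, estimated by Monte-Carlo
draws from the fitted Dirichlet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import psi

DEFAULT_PRIOR_ALPHA = 1.0
DEFAULT_N_MC = 1_000_000
MAX_ITER = 10_000
CONV_TOL = 1e-8


@dataclass
class BMSResult:
    """Random-effects BMS posterior over model frequencies."""

    alpha_dirichlet: np.ndarray
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray
    n_iterations: int
    converged: bool


def evidence_from_aic(aic_matrix) -> np.ndarray:
    """Approximate log model evidence from AIC: -AIC/2, row-centered.

    Each subject's row is shifted by its maximum log evidence for numerical
    stability; per-subject constants cancel in the BMS posterior, so the
    centering provably leaves the BMS output unchanged.
    """
    aic_matrix = np.asarray(aic_matrix, dtype=float)
    bad = ~np.isfinite(aic_matrix)
    if bad.any():
        cells = list(zip(*np.nonzero(bad)))
        raise ValueError(f"non-finite AIC entries at (subject, model) cells "
                         f"{cells[:20]}")
    log_ev = -aic_matrix / 2.0
    return log_ev - log_ev.max(axis=1, keepdims=True)


def bms_random_effects(log_evidence, prior_alpha: float = DEFAULT_PRIOR_ALPHA,
                       seed: int = 0, n_mc: int = DEFAULT_N_MC) -> BMSResult:
    """Variational Dirichlet random-effects model selection.

    Iterates the fixed-point updates

        u_nk = exp(L_nk + psi(alpha_k) - psi(sum alpha)),
        g_nk = u_nk / sum_k u_nk,
        alpha_k = prior_alpha + sum_n g_nk,

    until max |delta alpha| < 1e-8 (or 10,000 iterations, with a warning
    and ``converged=False``). Exceedance probabilities are estimated from
    ``n_mc`` seeded Dirichlet draws.
    """
    L = np.atleast_2d(np.asarray(log_evidence, dtype=float))
    n, k = L.shape
    if k < 2:
        raise ValueError("need at least 2 models")
    if prior_alpha <= 0:
        raise ValueError("prior_alpha must be positive")
    alpha = np.full(k, float(prior_alpha))
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        log_u = L + psi(alpha) - psi(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        g = u / u.sum(axis=1, keepdims=True)
        new_alpha = prior_alpha + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < CONV_TOL:
            alpha = new_alpha
            converged = True
            break
        alpha = new_alpha
    if not converged:
        warnings.warn("BMS variational iteration did not converge within "
                      f"{MAX_ITER} iterations", RuntimeWarning)
    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    counts = np.zeros(k)
    remaining = int(n_mc)
    while remaining > 0:  # chunked to bound memory
        m = min(remaining, 200_000)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    exceedance = counts / n_mc
    return BMSResult(alpha_dirichlet=alpha, expected_prob=expected,
                     exceedance_prob=exceedance, n_iterations=it,
                     converged=converged)


def model_selection_report(fit_tables: Sequence[pd.DataFrame],
                           seed: int = 0, prior_alpha: float =
                           DEFAULT_PRIOR_ALPHA,
                           n_mc: int = DEFAULT_N_MC) -> pd.DataFrame:
    """Rank fitted models by expected posterior probability.

    ``fit_tables`` holds one per-subject fit table per model (as produced
    by :func:`painlearn.model_fitting.fit_cohort`) with ``subject_id``,
    ``model``, and ``aic`` columns; all tables must cover the same
    subjects.
    """
    if len(fit_tables) == 0:
        raise ValueError("no fit tables given")
    ref_ids = list(fit_tables[0]["subject_id"])
    models = []
    aics = []
    for table in fit_tables:
        ids = list(table["subject_id"])
        missing = sorted(set(ref_ids).symmetric_difference(ids))
        if missing:
            raise ValueError(
                f"subject sets differ across models; mismatched: {missing}")
        indexed = table.set_index("subject_id").loc[ref_ids]
        models.append(str(indexed["model"].iloc[0]))
        aics.append(indexed["aic"].to_numpy(dtype=float))
    aic_matrix = np.column_stack(aics)
    mean_aic = aic_matrix.mean(axis=0)

    if len(fit_tables) == 1:
        return pd.DataFrame({
            "model": models, "mean_aic": mean_aic,
            "mean_delta_aic": [0.0], "dirichlet_alpha": [np.nan],
            "expected_prob": [1.0], "exceedance_prob": [1.0],
        })

    bms = bms_random_effects(evidence_from_aic(aic_matrix),
                             prior_alpha=prior_alpha, seed=seed, n_mc=n_mc)
    report = pd.DataFrame({
        "model": models,
        "mean_aic": mean_aic,
        "mean_delta_aic": mean_aic - mean_aic.min(),
        "dirichlet_alpha": bms.alpha_dirichlet,
        "expected_prob": bms.expected_prob,
        "exceedance_prob": bms.exceedance_prob,
    })
    return report.sort_values(
        "expected_prob", ascending=False).reset_index(drop=True)
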