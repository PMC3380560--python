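"""Results-level behavioral analyses of session collections.

These functions reproduce, on any cohort (synthetic or imported), the
standard battery of analyses for adaptive-block bandit behavior:

* experience-conditioned optimal-choice probabilities in the first vs.
  last 10 trials of each block (model-free evidence for a time-varying
  learning rate);
* blockwise re-estimated FQ learning rates and Bayesian effective learning
  rates in the same windows (model-based counterpart);
* per-trial regression of the effective learning rate on the chosen
  action's value mean and SD (does uncertainty, not value level, drive the
  learning rate?);
* cross-validated model-comparison tables and the distribution of the
  fitted uncertainty-bonus parameter phi.

Every function is a pure function of (sessions, fits): rerunning with the
same inputs reproduces identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import logging

import statsmodels.api as sm
from scipy import optimize, stats

from . import _kernels
from .fitting import CVResult, FitResult, trajectory_frame
from .task import Session

__all__ = [
    "EXPERIENCE_LABELS",
    "ConditionalChoiceTable",
    "conditional_optimal_choice",
    "compare_windows",
    "blockwise_fq_learning_rates",
    "blockwise_effective_learning_rates",
    "RegressionEntry",
    "learning_rate_regression",
    "regression_report",
    "model_comparison_report",
    "phi_distribution_report",
]

#: The four experience types: (optimal?, rewarded?) of one past trial.
EXPERIENCE_LABELS = ("Opt-Rew", "NonOpt-Rew", "Opt-NonRew", "NonOpt-NonRew")

#: Unconditional optimal-choice probability in the analysis window.
BASELINE_KEY = "Choice0"

WINDOW_LEN = 10

logger = logging.getLogger("bayesq")


def _experience(optimal: bool, reward: int) -> str:
    if optimal:
        return "Opt-Rew" if reward else "Opt-NonRew"
    return "NonOpt-Rew" if reward else "NonOpt-NonRew"


def _window_slice(n_block: int, window: str) -> tuple[int, int] | None:
    """Start/stop (block-local) of the first/last 10-trial window, or None
    if the block cannot hold two disjoint windows."""
    if n_block < 2 * WINDOW_LEN:
        return None
    if window == "first":
        return 0, WINDOW_LEN
    if window == "last":
        return n_block - WINDOW_LEN, n_block
    raise ValueError("window must be 'first' or 'last'")


@dataclass
class ConditionalChoiceTable:
    """Experience-conditioned optimal-choice probabilities for one window."""

    window: str
    depth: int
    pooled: pd.DataFrame  # columns: key, n, n_optimal, p, empty (flag)
    per_session: pd.DataFrame  # columns: session_id, key, n, n_optimal, p


def conditional_optimal_choice(
    sessions: list[Session], window: str = "first", depth: int = 1
) -> ConditionalChoiceTable:
    """P(optimal at t | experiences at t-1[, t-2]) in 10-trial block windows.

    Conditioning trials must lie inside the same block and the same window
    as the conditioned trial, so cross-block (and cross-window) histories
    never contaminate a cell.  Depth-2 keys are "second-last + last"
    experience pairs.  The table always includes the unconditional baseline
    ``Choice0``.  Cells with no observations are flagged, not dropped.
    """
    if depth not in (1, 2):
        raise ValueError("depth must be 1 or 2")
    if depth == 1:
        keys = [BASELINE_KEY] + list(EXPERIENCE_LABELS)
    else:
        keys = [BASELINE_KEY] + [f"{e2}|{e1}" for e2 in EXPERIENCE_LABELS for e1 in EXPERIENCE_LABELS]

    rows = []
    pooled = {k: [0, 0] for k in keys}  # key -> [n, n_optimal]
    for s in sessions:
        counts = {k: [0, 0] for k in keys}
        for block in s.blocks():
            sl = _window_slice(len(block), window)
            if sl is None:
                continue
            w = block[sl[0] : sl[1]]
            for i, t in enumerate(w):
                counts[BASELINE_KEY][0] += 1
                counts[BASELINE_KEY][1] += int(t.optimal)
                if i >= depth:
                    labels = [_experience(w[i - j].optimal, w[i - j].reward) for j in range(depth, 0, -1)]
                    key = labels[0] if depth == 1 else f"{labels[0]}|{labels[1]}"
                    counts[key][0] += 1
                    counts[key][1] += int(t.optimal)
        for k in keys:
            n, n_opt = counts[k]
            pooled[k][0] += n
            pooled[k][1] += n_opt
            rows.append(
                {
                    "session_id": s.session_id,
                    "key": k,
                    "n": n,
                    "n_optimal": n_opt,
                    "p": n_opt / n if n else np.nan,
                }
            )
    pooled_df = pd.DataFrame(
        [
            {
                "key": k,
                "n": n,
                "n_optimal": n_opt,
                "p": n_opt / n if n else np.nan,
                "empty": n == 0,
            }
            for k, (n, n_opt) in pooled.items()
        ]
    )
    return ConditionalChoiceTable(
        window=window, depth=depth, pooled=pooled_df, per_session=pd.DataFrame(rows)
    )


def compare_windows(sessions: list[Session], depth: int = 1) -> pd.DataFrame:
    """Per-cell first-vs-last window comparison of per-session conditional
    probabilities (Mann-Whitney U across sessions, as in the original
    analysis; sessions whose cell is empty are dropped from that test)."""
    first = conditional_optimal_choice(sessions, "first", depth).per_session
    last = conditional_optimal_choice(sessions, "last", depth).per_session
    rows = []
    for key in first["key"].unique():
        a = first.loc[(first["key"] == key) & (first["n"] > 0), "p"].to_numpy()
        b = last.loc[(last["key"] == key) & (last["n"] > 0), "p"].to_numpy()
        if a.size and b.size and (np.ptp(np.concatenate([a, b])) > 0):
            p_value = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            p_value = np.nan
        rows.append(
            {
                "key": key,
                "p_first": float(np.mean(a)) if a.size else np.nan,
                "p_last": float(np.mean(b)) if b.size else np.nan,
                "n_first": int(a.size),
                "n_last": int(b.size),
                "p_value": p_value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Blockwise learning rates
# ---------------------------------------------------------------------------

_BOUND_TOL = 1e-3


def _session_blocks(s: Session) -> list[tuple[int, int]]:
    """Session-level (start, stop) trial indices of each block, 0-based."""
    out = []
    start = 0
    for b in s.blocks():
        out.append((start, start + len(b)))
        start += len(b)
    return out


def blockwise_fq_learning_rates(
    sessions: list[Session], fq_fits: dict[str, FitResult]
) -> pd.DataFrame:
    """Re-estimate the FQ learning rate per block window.

    For every block of at least 20 trials, the tied learning/forgetting
    rate is re-optimized separately on the first 10 and last 10 trials,
    with all other parameters frozen at the session-level FQ fit.  The
    value trajectory enters each window propagated from trial 1 under the
    session-fit parameters; within the evaluated window, updates use the
    candidate rate.  Estimates pinned at the [0, 1] bounds are flagged.
    """
    rows = []
    for s in sessions:
        fit = fq_fits[s.session_id]
        if fit.variant != "FQ":
            raise ValueError(f"session-level fit for {s.session_id} must be FQ, got {fit.variant}")
        c = np.ascontiguousarray(s.choices, dtype=np.int64)
        r = np.ascontiguousarray(s.rewards, dtype=np.int64)
        p = fit.params
        for bi, (start, stop) in enumerate(_session_blocks(s)):
            if stop - start < 2 * WINDOW_LEN:
                logger.debug("%s: block %d too short (%d trials), excluded",
                             s.session_id, bi + 1, stop - start)
                continue
            est = {}
            flags = {}
            for name, (w0, w1) in {
                "first": (start, start + WINDOW_LEN),
                "last": (stop - WINDOW_LEN, stop),
            }.items():
                res = optimize.minimize_scalar(
                    lambda a: -float(
                        _kernels.fq_window_loglik(c, r, p.alpha1, p.k1, p.k2, p.beta, w0, w1, a)
                    ),
                    bounds=(0.0, 1.0),
                    method="bounded",
                    options={"xatol": 1e-6},
                )
                est[name] = float(res.x)
                flags[name] = bool(res.x < _BOUND_TOL or res.x > 1.0 - _BOUND_TOL)
            rows.append(
                {
                    "session_id": s.session_id,
                    "block": bi + 1,
                    "alpha_first": est["first"],
                    "alpha_last": est["last"],
                    "at_bound_first": flags["first"],
                    "at_bound_last": flags["last"],
                }
            )
    return pd.DataFrame(rows)


def blockwise_effective_learning_rates(
    sessions: list[Session], bq_fits: dict[str, FitResult]
) -> pd.DataFrame:
    """Mean effective learning rate in the first vs. last 10 trials of each
    block, under a single session-level Bayesian fit (no re-fitting: the
    trial-by-trial variation comes entirely from the evolving posterior)."""
    rows = []
    for s in sessions:
        fit = bq_fits[s.session_id]
        traj = fit.trajectory
        if traj is None:
            traj = trajectory_frame(s, fit.variant, fit.params)
        if "ealpha" not in traj:
            raise ValueError(f"fit for {s.session_id} is not a Bayesian variant")
        ealpha = traj["ealpha"].to_numpy()
        for bi, (start, stop) in enumerate(_session_blocks(s)):
            if stop - start < 2 * WINDOW_LEN:
                continue
            rows.append(
                {
                    "session_id": s.session_id,
                    "block": bi + 1,
                    "ealpha_first": float(np.mean(ealpha[start : start + WINDOW_LEN])),
                    "ealpha_last": float(np.mean(ealpha[stop - WINDOW_LEN : stop])),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Effective-learning-rate regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionEntry:
    """Per-session regression of ealpha(t) on the chosen action's mean/SD."""

    session_id: str
    coef_mean: float
    coef_sd: float
    p_mean: float
    p_sd: float
    sig_mean: bool
    sig_sd: bool
    corr_mean: float
    corr_sd: float
    n_trials: int
    degenerate: bool


def learning_rate_regression(
    fit: FitResult, session_id: str | None = None, alpha_level: float = 0.01
) -> RegressionEntry:
    """OLS of the per-trial effective learning rate on intercept + chosen
    mean + chosen SD, with coefficient t-tests at ``alpha_level``; also the
    plain correlations of ealpha with each regressor.  Exactly collinear or
    constant designs are flagged, never silently solved."""
    traj = fit.trajectory
    if traj is None or "ealpha" not in traj:
        raise ValueError("regression requires a Bayesian fit with a stored trajectory")
    y = traj["ealpha"].to_numpy()
    mu = traj["mu_chosen"].to_numpy()
    sd = traj["sd_chosen"].to_numpy()
    X = np.column_stack([mu, sd])
    degenerate = (
        np.ptp(mu) < 1e-12
        or np.ptp(sd) < 1e-12
        or np.linalg.matrix_rank(np.column_stack([np.ones_like(mu), X])) < 3
    )
    sid = session_id or "session"
    if degenerate:
        return RegressionEntry(sid, np.nan, np.nan, np.nan, np.nan, False, False,
                               np.nan, np.nan, int(y.size), True)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    corr_mean = float(stats.pearsonr(y, mu).statistic) if np.ptp(y) > 0 else np.nan
    corr_sd = float(stats.pearsonr(y, sd).statistic) if np.ptp(y) > 0 else np.nan
    return RegressionEntry(
        session_id=sid,
        coef_mean=float(res.params[1]),
        coef_sd=float(res.params[2]),
        p_mean=float(res.pvalues[1]),
        p_sd=float(res.pvalues[2]),
        sig_mean=bool(res.pvalues[1] < alpha_level),
        sig_sd=bool(res.pvalues[2] < alpha_level),
        corr_mean=corr_mean,
        corr_sd=corr_sd,
        n_trials=int(y.size),
        degenerate=False,
    )


def regression_report(
    fits: dict[str, FitResult], alpha_level: float = 0.01
) -> pd.DataFrame:
    """Run :func:`learning_rate_regression` over a cohort of per-session
    Bayesian fits; one row per session."""
    entries = [
        learning_rate_regression(fit, session_id=sid, alpha_level=alpha_level)
        for sid, fit in fits.items()
    ]
    return pd.DataFrame([e.__dict__ for e in entries])


# ---------------------------------------------------------------------------
# Model comparison and phi distribution
# ---------------------------------------------------------------------------

#: Default variant pairs compared head-to-head (best standard vs. best
#: Bayesian; the uncertainty bonus; Bayesian learning alone vs. FQ).
DEFAULT_PAIRS = (
    ("asymmetricBQ", "FQ"),
    ("asymmetricBQ", "asymmetricBQ_phi0"),
    ("asymmetricBQ_phi0", "FQ"),
)


def model_comparison_report(
    cv: CVResult, pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
) -> dict[str, pd.DataFrame]:
    """Summarize held-out normalized likelihoods across variants.

    Returns a ``summary`` table (mean +/- SE of held-out Z per variant) and
    a ``pairwise`` table of paired t-tests with per-session win counts
    (ties split evenly between the two models).  Pairs whose variants are
    absent from the CV result are skipped.
    """
    wide = cv.pivot()
    summary = pd.DataFrame(
        {
            "variant": wide.columns,
            "mean_Z": wide.mean(axis=0).to_numpy(),
            "se_Z": (wide.std(axis=0, ddof=1) / np.sqrt(len(wide))).to_numpy(),
            "n_sessions": len(wide),
        }
    ).sort_values("mean_Z", ascending=False).reset_index(drop=True)
    rows = []
    for a, b in pairs:
        if a not in wide.columns or b not in wide.columns:
            continue
        za, zb = wide[a].to_numpy(), wide[b].to_numpy()
        diff = za - zb
        if np.ptp(diff) > 0:
            t_res = stats.ttest_rel(za, zb)
            t_stat, p_value = float(t_res.statistic), float(t_res.pvalue)
        elif diff[0] == 0:  # identical score vectors: no paired variance, test undefined
            t_stat, p_value = np.nan, np.nan
        else:  # constant nonzero offset: difference is certain
            t_stat, p_value = math.copysign(math.inf, diff[0]), 0.0
        ties = int(np.sum(diff == 0))
        rows.append(
            {
                "variant_a": a,
                "variant_b": b,
                "mean_diff": float(np.mean(diff)),
                "t": t_stat,
                "p_value": p_value,
                "wins_a": int(np.sum(diff > 0)) + ties / 2,
                "wins_b": int(np.sum(diff < 0)) + ties / 2,
                "n": int(diff.size),
            }
        )
    return {"summary": summary, "pairwise": pd.DataFrame(rows)}


def phi_distribution_report(
    fits: dict[str, FitResult], test: str = "signed-rank", n_bins: int = 20
) -> dict:
    """Distribution of the fitted uncertainty-bonus parameter phi.

    Reports the per-session phi values, their median, a histogram, and a
    location test of phi against zero: ``signed-rank`` (Wilcoxon, default)
    or ``mann-whitney`` (the fitted values against a zero sample of equal
    size; provided for comparability with analyses that label the
    one-sample question a Mann-Whitney U-test).
    """
    if len(fits) < 2:
        raise ValueError("phi distribution requires at least two sessions")
    phis = np.array([fit.free["phi"] for fit in fits.values()])
    if test == "signed-rank":
        if np.all(phis == 0):
            p_value = np.nan
        else:
            p_value = float(stats.wilcoxon(phis, alternative="two-sided").pvalue)
    elif test == "mann-whitney":
        if np.ptp(phis) == 0 and phis[0] == 0:
            p_value = np.nan
        else:
            p_value = float(
                stats.mannwhitneyu(phis, np.zeros_like(phis), alternative="two-sided").pvalue
            )
    else:
        raise ValueError("test must be 'signed-rank' or 'mann-whitney'")
    counts, edges = np.histogram(phis, bins=n_bins)
    return {
        "phi": phis,
        "median": float(np.median(phis)),
        "p_value": p_value,
        "test": test,
        "hist_counts": counts,
        "hist_edges": edges,
    }
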