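"""Normalized-likelihood model fitting and 2-fold cross-validation.

Model fit is scored by the *normalized likelihood*

    Z = exp( (1/N) * sum_t log z(t) ),    z(t) = P(a(t) = L) if left else 1 - P(L),

the geometric mean of the per-trial choice likelihoods: a chance-level
predictor scores exactly 0.5, a perfect one 1.  Free parameters are chosen
to maximize Z by bounded multi-start derivative-free search (the surface
is mildly multimodal).  Model comparison uses 2-fold cross-validation:
sessions are split into two groups, each group's shared parameters are fit
on the other, and every session receives one held-out Z per variant — the
implicit complexity penalty that replaces AIC/BIC-style corrections.

Parameter bounds (fitting choices, wide relative to fitted values):
alpha in [0, 1], k1/k2 in [0, 2], beta in [0, 50], G in [0.01, 1000]
(searched on a log10 scale), k in [0, 5], phi in [-20, 20].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from . import models, _kernels
from .models import BQParams, QParams
from .task import Session

__all__ = [
    "FREE_PARAMS",
    "BOUNDS",
    "FitResult",
    "GroupFitResult",
    "CVResult",
    "make_params",
    "params_to_free",
    "mean_loglik",
    "normalized_likelihood",
    "trajectory_frame",
    "fit_session",
    "fit_group",
    "cross_validate",
]

logger = logging.getLogger("bayesq")

#: Probabilities are clamped to [P_CLIP, 1 - P_CLIP] before taking logs.
P_CLIP = _kernels.P_CLIP

#: Free parameters of each model variant, in vector order.
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "Q": ("alpha1", "k1", "beta"),
    "FQ": ("alpha1", "k1", "k2", "beta"),
    "dFQ": ("alpha1", "alpha2", "k1", "k2", "beta"),
    "originalBQ": ("G", "beta", "phi"),
    "asymmetricBQ": ("G", "beta", "phi"),
    "asymmetricBQ_phi0": ("G", "beta"),
    "generalizedBQ": ("G", "k", "beta", "phi"),
}

#: Search bounds on the natural scale.
BOUNDS: dict[str, tuple[float, float]] = {
    "alpha1": (0.0, 1.0),
    "alpha2": (0.0, 1.0),
    "k1": (0.0, 2.0),
    "k2": (0.0, 2.0),
    "beta": (0.0, 50.0),
    "G": (1e-2, 1e3),
    "k": (0.0, 5.0),
    "phi": (-20.0, 20.0),
}

#: Parameters searched on a log10 scale (span several orders of magnitude).
_LOG_SCALE = ("G",)


def make_params(variant: str, **free: float) -> QParams | BQParams:
    """Build a full, constraint-respecting parameter object from the
    variant's free parameters."""
    names = FREE_PARAMS.get(variant)
    if names is None:
        raise ValueError(f"unknown variant {variant!r}")
    if set(free) != set(names):
        raise ValueError(f"variant {variant} takes free parameters {names}; got {tuple(free)}")
    if variant == "Q":
        return QParams.original_q(free["alpha1"], free["k1"], free["beta"])
    if variant == "FQ":
        return QParams.fq(free["alpha1"], free["k1"], free["k2"], free["beta"])
    if variant == "dFQ":
        return QParams(**free)
    if variant == "originalBQ":
        return BQParams(G=free["G"], k=1.0, beta=free["beta"], phi=free["phi"])
    if variant == "asymmetricBQ":
        return BQParams(G=free["G"], k=0.0, beta=free["beta"], phi=free["phi"])
    if variant == "asymmetricBQ_phi0":
        return BQParams(G=free["G"], k=0.0, beta=free["beta"], phi=0.0)
    return BQParams(**free)  # generalizedBQ


def params_to_free(variant: str, params: QParams | BQParams) -> dict[str, float]:
    """Extract the variant's free-parameter dict from a parameter object."""
    models.resolve_params(variant, params)
    return {name: float(getattr(params, name)) for name in FREE_PARAMS[variant]}


def mean_loglik(choices: np.ndarray, rewards: np.ndarray, variant: str, params) -> float:
    """Mean per-trial log choice likelihood (log Z) under one model."""
    params = models.resolve_params(variant, params)
    c = np.ascontiguousarray(choices, dtype=np.int64)
    r = np.ascontiguousarray(rewards, dtype=np.int64)
    if variant in models.Q_VARIANTS:
        return float(
            _kernels.q_mean_loglik(c, r, params.alpha1, params.alpha2, params.k1, params.k2, params.beta)
        )
    return float(_kernels.bq_mean_loglik(c, r, params.G, params.k, params.beta, params.phi))


def normalized_likelihood(session: Session, variant: str, params) -> tuple[float, np.ndarray]:
    """Normalized likelihood Z and the per-trial likelihoods z(t)."""
    params = models.resolve_params(variant, params)
    c = np.ascontiguousarray(session.choices, dtype=np.int64)
    r = np.ascontiguousarray(session.rewards, dtype=np.int64)
    if c.size == 0:
        raise ValueError("empty session")
    if variant in models.Q_VARIANTS:
        p_left, _ = _kernels.q_forward(c, r, params.alpha1, params.alpha2, params.k1, params.k2, params.beta)
    else:
        p_left, _, _, _ = _kernels.bq_forward(c, r, params.G, params.k, params.beta, params.phi)
    z = np.where(c == models.LEFT, p_left, 1.0 - p_left)
    z = np.clip(z, P_CLIP, 1.0 - P_CLIP)
    Z = float(np.exp(np.mean(np.log(z))))
    return Z, z


def trajectory_frame(session: Session, variant: str, params) -> pd.DataFrame:
    """Per-trial trajectory as a DataFrame (p_left, z; for BQ also the
    post-prediction means/SDs per action and the chosen-action effective
    learning rate)."""
    params = models.resolve_params(variant, params)
    c = np.ascontiguousarray(session.choices, dtype=np.int64)
    r = np.ascontiguousarray(session.rewards, dtype=np.int64)
    cols: dict[str, np.ndarray] = {
        "trial": np.arange(1, c.size + 1),
        "block": np.asarray([t.block for t in session.trials]),
        "choice": c,
        "reward": r,
    }
    if variant in models.Q_VARIANTS:
        p_left, q = _kernels.q_forward(c, r, params.alpha1, params.alpha2, params.k1, params.k2, params.beta)
        cols["qL"], cols["qR"] = q[:, 0], q[:, 1]
    else:
        p_left, mu, sd, ealpha = _kernels.bq_forward(c, r, params.G, params.k, params.beta, params.phi)
        cols["muL"], cols["muR"] = mu[:, 0], mu[:, 1]
        cols["sdL"], cols["sdR"] = sd[:, 0], sd[:, 1]
        idx = np.arange(c.size)
        cols["mu_chosen"] = mu[idx, c]
        cols["sd_chosen"] = sd[idx, c]
        cols["ealpha"] = ealpha
    cols["p_left"] = p_left
    z = np.where(c == models.LEFT, p_left, 1.0 - p_left)
    cols["z"] = np.clip(z, P_CLIP, 1.0 - P_CLIP)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


def _internal_bounds(variant: str) -> list[tuple[float, float]]:
    out = []
    for name in FREE_PARAMS[variant]:
        lo, hi = BOUNDS[name]
        if name in _LOG_SCALE:
            out.append((math.log10(lo), math.log10(hi)))
        else:
            out.append((lo, hi))
    return out


def _vec_to_free(variant: str, vec: np.ndarray) -> dict[str, float]:
    free = {}
    for name, v in zip(FREE_PARAMS[variant], vec):
        free[name] = float(10.0 ** v) if name in _LOG_SCALE else float(v)
    return free


def _free_to_vec(variant: str, free: dict[str, float]) -> np.ndarray:
    return np.asarray(
        [math.log10(free[n]) if n in _LOG_SCALE else free[n] for n in FREE_PARAMS[variant]]
    )


@dataclass
class FitResult:
    """Maximum-normalized-likelihood fit of one variant to one session."""

    variant: str
    params: QParams | BQParams
    free: dict[str, float]
    Z: float
    loglik: float  # mean per-trial log-likelihood, log(Z)
    n_trials: int
    converged: bool
    n_starts: int
    seed: int
    trajectory: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class GroupFitResult:
    """One shared parameter vector fit to a session group (CV training side)."""

    variant: str
    params: QParams | BQParams
    free: dict[str, float]
    mean_loglik: float  # mean over sessions of log Z
    n_sessions: int
    converged: bool


def _multistart_minimize(objective, variant: str, n_starts: int, seed: int):
    """Best of ``n_starts`` bounded Powell runs from scrambled-Sobol starts
    plus the bound-box midpoint.  Deterministic given ``seed``."""
    bounds = _internal_bounds(variant)
    d = len(bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [0.5 * (lo + hi)]
    if n_starts > 1:
        sob = qmc.Sobol(d, scramble=True, seed=seed)
        m = max(1, math.ceil(math.log2(n_starts - 1)))
        starts.extend((lo + (hi - lo) * sob.random_base2(m))[: n_starts - 1])

    def clipped(vec):
        # Powell's line searches may probe marginally outside the box
        return objective(np.clip(vec, lo, hi))

    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(
            clipped,
            x0=np.asarray(x0, dtype=float),
            method="Powell",
            bounds=bounds,
            options={"xtol": 1e-5, "ftol": 1e-8, "maxiter": 500},
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("optimizer produced no result")
    best.x = np.clip(np.atleast_1d(best.x), lo, hi)
    logger.debug("%s: %d starts, best -loglik %.6f, success=%s",
                 variant, len(starts), best.fun, any_ok)
    return best, any_ok


def fit_session(
    session: Session,
    variant: str,
    n_starts: int = 10,
    seed: int = 0,
    with_trajectory: bool = True,
) -> FitResult:
    """Fit one variant to one session by maximizing the normalized likelihood."""
    c = np.ascontiguousarray(session.choices, dtype=np.int64)
    r = np.ascontiguousarray(session.rewards, dtype=np.int64)
    if c.size == 0:
        raise ValueError("empty session")

    def objective(vec):
        p = make_params(variant, **_vec_to_free(variant, vec))
        return -mean_loglik(c, r, variant, p)

    best, ok = _multistart_minimize(objective, variant, n_starts, seed)
    free = _vec_to_free(variant, np.atleast_1d(best.x))
    params = make_params(variant, **free)
    loglik = -float(best.fun)
    return FitResult(
        variant=variant,
        params=params,
        free=free,
        Z=float(np.exp(loglik)),
        loglik=loglik,
        n_trials=int(c.size),
        converged=ok,
        n_starts=n_starts,
        seed=seed,
        trajectory=trajectory_frame(session, variant, params) if with_trajectory else None,
    )


def fit_group(
    sessions: list[Session],
    variant: str,
    n_starts: int = 10,
    seed: int = 0,
) -> GroupFitResult:
    """Fit one shared parameter vector to a session group, maximizing the
    mean over sessions of log Z (each session weighted equally regardless
    of length)."""
    if not sessions:
        raise ValueError("fit_group requires at least one session")
    data = [
        (
            np.ascontiguousarray(s.choices, dtype=np.int64),
            np.ascontiguousarray(s.rewards, dtype=np.int64),
        )
        for s in sessions
    ]

    def objective(vec):
        p = make_params(variant, **_vec_to_free(variant, vec))
        return -float(np.mean([mean_loglik(c, r, variant, p) for c, r in data]))

    best, ok = _multistart_minimize(objective, variant, n_starts, seed)
    free = _vec_to_free(variant, np.atleast_1d(best.x))
    return GroupFitResult(
        variant=variant,
        params=make_params(variant, **free),
        free=free,
        mean_loglik=-float(best.fun),
        n_sessions=len(sessions),
        converged=ok,
    )


@dataclass
class CVResult:
    """Held-out normalized likelihoods from 2-fold cross-validation."""

    scores: pd.DataFrame  # columns: session_id, fold, variant, Z
    folds: dict[str, int]  # session_id -> validation fold (0 or 1)
    group_fits: dict[tuple[int, str], GroupFitResult]  # (training fold, variant)

    def pivot(self) -> pd.DataFrame:
        """Sessions x variants table of held-out Z."""
        return self.scores.pivot(index="session_id", columns="variant", values="Z")


def cross_validate(
    sessions: list[Session],
    variants: list[str],
    split_seed: int = 0,
    n_starts: int = 10,
    fit_seed: int = 0,
    stratify_by_rat: bool = False,
) -> CVResult:
    """2-fold cross-validated model comparison.

    Sessions are split into two equal groups at random (odd counts leave
    the folds differing by one; with ``stratify_by_rat`` the split is done
    within each rat's sessions).  Each fold's shared parameters are fit on
    the *other* fold, so every session is scored exactly once with
    out-of-sample parameters.
    """
    if len(sessions) < 2:
        raise ValueError("cross-validation requires at least two sessions")
    ids = [s.session_id for s in sessions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate session_id in cohort")
    rng = np.random.default_rng(split_seed)
    fold_of: dict[str, int] = {}
    if stratify_by_rat:
        by_rat: dict[str, list[Session]] = {}
        for s in sessions:
            by_rat.setdefault(s.rat_id, []).append(s)
        for group in by_rat.values():
            order = rng.permutation(len(group))
            for pos, idx in enumerate(order):
                fold_of[group[idx].session_id] = pos % 2
    else:
        order = rng.permutation(len(sessions))
        for pos, idx in enumerate(order):
            fold_of[sessions[idx].session_id] = 0 if pos < len(sessions) // 2 else 1

    fold_sessions = {f: [s for s in sessions if fold_of[s.session_id] == f] for f in (0, 1)}
    group_fits: dict[tuple[int, str], GroupFitResult] = {}
    rows = []
    for train_fold in (0, 1):
        val_fold = 1 - train_fold
        for variant in variants:
            gf = fit_group(fold_sessions[train_fold], variant, n_starts=n_starts, seed=fit_seed)
            group_fits[(train_fold, variant)] = gf
            for s in fold_sessions[val_fold]:
                Z, _ = normalized_likelihood(s, variant, gf.params)
                rows.append(
                    {"session_id": s.session_id, "fold": val_fold, "variant": variant, "Z": Z}
                )
    scores = pd.DataFrame(rows).sort_values(["variant", "session_id"]).reset_index(drop=True)
    return CVResult(scores=scores, folds=fold_of, group_fits=group_fits)
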