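"""Compiled forward-pass kernels.

These duplicate the stepwise model equations in :mod:`bayesq.models` as
tight scalar loops so that likelihood optimization over whole sessions is
fast.  Equality with the pure-Python reference implementation is asserted
in the test suite; any change here must keep the two paths bit-compatible.

Choices are encoded 0 = left, 1 = right; rewards 0/1.  ``G`` above
``G_INF_CUTOFF`` disables the prediction step (stationary-world limit).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

XY_MIN = 1e-6
G_INF_CUTOFF = 1e12
P_CLIP = 1e-10


@njit(cache=True)
def _predict_xy(x, y, G):
    # moment-matched push of Beta(x, y) through Beta(1+Gq', 1+G(1-q'))
    if G > G_INF_CUTOFF:
        return x, y
    s0 = x + y
    m = x / s0
    m2 = x * (x + 1.0) / (s0 * (s0 + 1.0))
    e1 = (1.0 + G * m) / (2.0 + G)
    e2 = (2.0 + 3.0 * G * m + G * G * m2) / ((2.0 + G) * (3.0 + G))
    v = e2 - e1 * e1
    s = e1 * (1.0 - e1) / v - 1.0
    xn = e1 * s
    yn = (1.0 - e1) * s
    if xn < XY_MIN:
        xn = XY_MIN
    if yn < XY_MIN:
        yn = XY_MIN
    return xn, yn


@njit(cache=True)
def _sigmoid(u):
    if u > 700.0:
        return 1.0
    if u < -700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-u))


@njit(cache=True)
def bq_forward(choices, rewards, G, k, beta, phi):
    """Bayesian-Q forward pass over an observed session.

    Returns (p_left, mu, sd, ealpha) where mu and sd are (n, 2) arrays of
    post-prediction-step moments and ealpha the chosen action's effective
    learning rate per trial.
    """
    n = choices.shape[0]
    p_left = np.empty(n)
    mu = np.empty((n, 2))
    sd = np.empty((n, 2))
    ealpha = np.empty(n)
    xL = 1.0
    yL = 1.0
    xR = 1.0
    yR = 1.0
    for t in range(n):
        xL, yL = _predict_xy(xL, yL, G)
        xR, yR = _predict_xy(xR, yR, G)
        sl = xL + yL
        mL = xL / sl
        sdL = math.sqrt(xL * yL / (sl * sl * (sl + 1.0)))
        sr = xR + yR
        mR = xR / sr
        sdR = math.sqrt(xR * yR / (sr * sr * (sr + 1.0)))
        p_left[t] = _sigmoid(beta * ((mL + phi * sdL) - (mR + phi * sdR)))
        mu[t, 0] = mL
        mu[t, 1] = mR
        sd[t, 0] = sdL
        sd[t, 1] = sdR
        if choices[t] == 0:
            if rewards[t] == 1:
                ealpha[t] = 1.0 / (sl + 1.0)
                xL += 1.0
            else:
                ealpha[t] = k / (sl + k)
                yL += k
        else:
            if rewards[t] == 1:
                ealpha[t] = 1.0 / (sr + 1.0)
                xR += 1.0
            else:
                ealpha[t] = k / (sr + k)
                yR += k
    return p_left, mu, sd, ealpha


@njit(cache=True)
def q_forward(choices, rewards, alpha1, alpha2, k1, k2, beta):
    """Standard-Q forward pass; returns (p_left, q) with q an (n, 2) array
    of pre-update action values."""
    n = choices.shape[0]
    p_left = np.empty(n)
    q = np.empty((n, 2))
    qL = 0.5
    qR = 0.5
    for t in range(n):
        p_left[t] = _sigmoid(beta * (qL - qR))
        q[t, 0] = qL
        q[t, 1] = qR
        target = k1 * rewards[t] - k2 * (1 - rewards[t])
        if choices[t] == 0:
            qL = (1.0 - alpha1) * qL + alpha1 * target
            qR = (1.0 - alpha2) * qR
        else:
            qR = (1.0 - alpha1) * qR + alpha1 * target
            qL = (1.0 - alpha2) * qL
    return p_left, q


@njit(cache=True)
def bq_mean_loglik(choices, rewards, G, k, beta, phi):
    """Mean per-trial log-likelihood of the observed choices under BQ."""
    n = choices.shape[0]
    total = 0.0
    xL = 1.0
    yL = 1.0
    xR = 1.0
    yR = 1.0
    for t in range(n):
        xL, yL = _predict_xy(xL, yL, G)
        xR, yR = _predict_xy(xR, yR, G)
        sl = xL + yL
        mL = xL / sl
        sdL = math.sqrt(xL * yL / (sl * sl * (sl + 1.0)))
        sr = xR + yR
        mR = xR / sr
        sdR = math.sqrt(xR * yR / (sr * sr * (sr + 1.0)))
        p = _sigmoid(beta * ((mL + phi * sdL) - (mR + phi * sdR)))
        z = p if choices[t] == 0 else 1.0 - p
        if z < P_CLIP:
            z = P_CLIP
        total += math.log(z)
        if choices[t] == 0:
            if rewards[t] == 1:
                xL += 1.0
            else:
                yL += k
        else:
            if rewards[t] == 1:
                xR += 1.0
            else:
                yR += k
    return total / n


@njit(cache=True)
def q_mean_loglik(choices, rewards, alpha1, alpha2, k1, k2, beta):
    """Mean per-trial log-likelihood of the observed choices under standard Q."""
    n = choices.shape[0]
    total = 0.0
    qL = 0.5
    qR = 0.5
    for t in range(n):
        p = _sigmoid(beta * (qL - qR))
        z = p if choices[t] == 0 else 1.0 - p
        if z < P_CLIP:
            z = P_CLIP
        total += math.log(z)
        target = k1 * rewards[t] - k2 * (1 - rewards[t])
        if choices[t] == 0:
            qL = (1.0 - alpha1) * qL + alpha1 * target
            qR = (1.0 - alpha2) * qR
        else:
            qR = (1.0 - alpha1) * qR + alpha1 * target
            qL = (1.0 - alpha2) * qL
    return total / n


@njit(cache=True)
def fq_window_loglik(choices, rewards, alpha_sess, k1, k2, beta, w0, w1, alpha_win):
    """Mean log-likelihood of FQ over trials [w0, w1) with a window-local rate.

    The value trajectory is propagated from trial 0 with the session-level
    tied rate ``alpha_sess``; inside the evaluated window both the learning
    and forgetting rate are replaced by the candidate ``alpha_win``.  Only
    the window's trials contribute to the returned likelihood.
    """
    n = choices.shape[0]
    total = 0.0
    qL = 0.5
    qR = 0.5
    for t in range(n):
        if t >= w1:
            break
        if t >= w0:
            p = _sigmoid(beta * (qL - qR))
            z = p if choices[t] == 0 else 1.0 - p
            if z < P_CLIP:
                z = P_CLIP
            total += math.log(z)
            a = alpha_win
        else:
            a = alpha_sess
        target = k1 * rewards[t] - k2 * (1 - rewards[t])
        if choices[t] == 0:
            qL = (1.0 - a) * qL + a * target
            qR = (1.0 - a) * qR
        else:
            qR = (1.0 - a) * qR + a * target
            qL = (1.0 - a) * qL
    return total / (w1 - w0)
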