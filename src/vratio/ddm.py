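"""Drift diffusion simulator with post-decisional evidence accumulation.

Decisions arise from a random-walk approximation of the diffusion process: at
each step of size ``tau`` the integrated evidence moves by
``v*tau + sigma*sqrt(tau)*N(0,1)`` until it crosses 0 or ``boundary_a``. After
the boundary crossing, evidence keeps accumulating -- unbounded -- for a
duration set by the trial's confidence RT, with drift ``v * v_ratio``; the
evidence level at the end of that window is what confidence is computed from.

Because the post-decision phase has no absorbing boundary and only its endpoint
is observed, the endpoint is drawn exactly in closed form (a Gaussian with mean
``m*v_post*tau`` and SD ``sigma*sqrt(m*tau)`` around the evidence at choice,
``m`` the number of whole steps in the window) instead of stepping through it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .params import DDMParams

__all__ = [
    "TrialRecord",
    "TrialDataset",
    "simulate_trial",
    "simulate_dataset",
    "simulate_decision_times",
    "analytic_accuracy",
    "analytic_mean_decision_time",
    "sample_pool_without_replacement",
    "MAX_DECISION_TIME",
]

#: Simulated decision time cap in seconds. Walks that have not been absorbed by
#: then are discarded and redrawn (counter reported on the dataset).
MAX_DECISION_TIME = 7.5

_BUF = 1 << 16


@njit(cache=True, fastmath=True)
def _walk_kernel(v_signed, vpost_signed, a, z, tau, sigma, post_dur, max_steps, seed):
    """Simulate n decision random walks plus closed-form post-decision endpoints.

    Returns (decision_steps, choice, evidence_at_choice, evidence_at_confidence,
    n_capped) where choice is +1 (upper) or -1 (lower) and evidence values are in
    accumulator coordinates (lower boundary at 0).
    """
    np.random.seed(seed)
    n = v_signed.shape[0]
    sq = sigma * math.sqrt(tau)
    steps = np.empty(n, np.int64)
    choice = np.empty(n, np.int8)
    e_choice = np.empty(n)
    e_conf = np.empty(n)
    n_capped = 0
    buf = np.random.standard_normal(_BUF)
    bi = 0
    for i in range(n):
        drift = v_signed[i] * tau
        while True:
            e = z * a
            k = 0
            while 0.0 < e < a and k < max_steps:
                if bi == _BUF:
                    buf = np.random.standard_normal(_BUF)
                    bi = 0
                e += drift + sq * buf[bi]
                bi += 1
                k += 1
            if 0.0 < e < a:
                n_capped += 1  # hit the cap unabsorbed: resample this trial
            else:
                break
        steps[i] = k
        choice[i] = 1 if e >= a else -1
        e_choice[i] = e
        m = int(post_dur[i] / tau)
        if bi == _BUF:
            buf = np.random.standard_normal(_BUF)
            bi = 0
        zn = buf[bi]
        bi += 1
        e_conf[i] = e + vpost_signed[i] * m * tau + sigma * math.sqrt(m * tau) * zn
    return steps, choice, e_choice, e_conf, n_capped


@njit(cache=True, fastmath=True)
def _walk_kernel_crn(v_signed, vpost_signed, a, z, tau, sigma, post_dur, max_steps,
                     noise, post_noise, offset0):
    """Decision walks driven by a frozen noise table (common random numbers).

    Trial ``i`` reads its innovations from ``noise`` starting at a fixed
    per-trial offset, so the same underlying increments are reused for every
    candidate parameter vector and the fitting objective becomes a
    deterministic, near-continuous function of the parameters. Walks still
    unabsorbed at ``max_steps`` are terminated in place (choice goes to the
    nearer boundary) rather than resampled: with frozen noise a capped walk
    would stay capped forever. ``noise`` length must be a power of two.
    """
    n = v_signed.shape[0]
    mask = noise.shape[0] - 1
    sq = sigma * math.sqrt(tau)
    steps = np.empty(n, np.int64)
    choice = np.empty(n, np.int8)
    e_choice = np.empty(n)
    e_conf = np.empty(n)
    n_capped = 0
    for i in range(n):
        j = (i * 2654435761 + offset0) & mask
        drift = v_signed[i] * tau
        e = z * a
        k = 0
        while 0.0 < e < a and k < max_steps:
            e += drift + sq * noise[j]
            j = (j + 1) & mask
            k += 1
        if 0.0 < e < a:
            n_capped += 1
            choice[i] = 1 if e >= 0.5 * a else -1
        else:
            choice[i] = 1 if e >= a else -1
        steps[i] = k
        e_choice[i] = e
        m = int(post_dur[i] / tau)
        e_conf[i] = e + vpost_signed[i] * m * tau + sigma * math.sqrt(m * tau) * post_noise[i]
    return steps, choice, e_choice, e_conf, n_capped


def _simulate_arrays_crn(params, stimulus_sign, post_dur, noise, post_noise, offset0):
    """CRN counterpart of :func:`_simulate_arrays` (same return contract)."""
    v_signed = stimulus_sign.astype(float) * params.drift_v
    vpost_signed = v_signed * params.v_ratio
    max_steps = int(round(MAX_DECISION_TIME / params.tau))
    steps, choice, e_choice, e_conf, n_capped = _walk_kernel_crn(
        v_signed, vpost_signed, params.boundary_a, params.start_z, params.tau,
        params.sigma, np.asarray(post_dur, dtype=float), max_steps,
        noise, post_noise, offset0,
    )
    upper = choice == 1
    e_choice_rel = np.where(upper, e_choice, params.boundary_a - e_choice)
    e_conf_rel = np.where(upper, e_conf, params.boundary_a - e_conf)
    decision_time = steps * params.tau
    return decision_time, choice.astype(np.int64), e_choice_rel, e_conf_rel, n_capped


@dataclass(frozen=True)
class TrialRecord:
    """A single simulated trial.

    ``evidence_at_choice`` and ``evidence_at_confidence`` are expressed relative
    to the chosen boundary (for lower-boundary choices the accumulator value is
    reflected, ``boundary_a - e``), so larger values always mean more integrated
    support for the choice that was made.
    """

    stimulus_sign: int
    choice: int
    accuracy: bool
    decision_time: float
    rt: float
    postdecision_duration: float
    evidence_at_choice: float
    evidence_at_confidence: float
    confidence_raw: float = math.nan
    confidence: float = math.nan
    confidence_rt: float = math.nan


#: Column order used by :class:`TrialDataset` frames.
TRIAL_COLUMNS = [
    "stimulus",
    "choice",
    "accuracy",
    "decision_time",
    "rt",
    "postdecision_duration",
    "evidence_at_choice",
    "evidence_at_confidence",
    "confidence_raw",
    "confidence",
    "confidence_rt",
]


@dataclass
class TrialDataset:
    """Ordered collection of trials, stored as a DataFrame, plus labels."""

    trials: pd.DataFrame
    subject: Optional[str] = None
    condition: Optional[str] = None
    n_capped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trials) == 0:
            raise ValueError("TrialDataset must contain at least one trial")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def accuracy(self) -> np.ndarray:
        return self.trials["accuracy"].to_numpy(dtype=bool)

    @property
    def rt(self) -> np.ndarray:
        return self.trials["rt"].to_numpy(dtype=float)

    @property
    def confidence(self) -> np.ndarray:
        return self.trials["confidence"].to_numpy(dtype=float)

    @property
    def confidence_rt(self) -> np.ndarray:
        return self.trials["confidence_rt"].to_numpy(dtype=float)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _simulate_arrays(
    params: DDMParams,
    stimulus_sign: np.ndarray,
    post_dur: np.ndarray,
    rng: np.random.Generator,
):
    """Run the walk kernel and return choice-relative evidence arrays."""
    v_signed = stimulus_sign.astype(float) * params.drift_v
    vpost_signed = v_signed * params.v_ratio
    max_steps = int(round(MAX_DECISION_TIME / params.tau))
    steps, choice, e_choice, e_conf, n_capped = _walk_kernel(
        v_signed,
        vpost_signed,
        params.boundary_a,
        params.start_z,
        params.tau,
        params.sigma,
        np.asarray(post_dur, dtype=float),
        max_steps,
        _kernel_seed(rng),
    )
    upper = choice == 1
    # evidence relative to the chosen boundary: reflect lower-boundary choices
    e_choice_rel = np.where(upper, e_choice, params.boundary_a - e_choice)
    e_conf_rel = np.where(upper, e_conf, params.boundary_a - e_conf)
    decision_time = steps * params.tau
    return decision_time, choice.astype(np.int64), e_choice_rel, e_conf_rel, n_capped


def simulate_trial(
    params: DDMParams,
    stimulus_sign: int,
    postdecision_duration: float,
    rng: np.random.Generator,
) -> TrialRecord:
    """Simulate one trial: decision random walk plus post-decision accumulation.

    Parameters
    ----------
    stimulus_sign : {-1, +1}
        Sign applied to the drift rate for this trial.
    postdecision_duration : float
        Time in seconds the evidence keeps accumulating after the choice
        (the trial's confidence RT).
    """
    if stimulus_sign not in (-1, 1):
        raise ValueError("stimulus_sign must be -1 or +1")
    if postdecision_duration < 0:
        raise ValueError("postdecision_duration must be >= 0")
    dt, choice, e_choice, e_conf, n_capped = _simulate_arrays(
        params,
        np.array([stimulus_sign]),
        np.array([postdecision_duration], dtype=float),
        rng,
    )
    return TrialRecord(
        stimulus_sign=stimulus_sign,
        choice=int(choice[0]),
        accuracy=bool(choice[0] == stimulus_sign),
        decision_time=float(dt[0]),
        rt=float(dt[0] + params.ter),
        postdecision_duration=float(postdecision_duration),
        evidence_at_choice=float(e_choice[0]),
        evidence_at_confidence=float(e_conf[0]),
        confidence_rt=float(postdecision_duration),
    )


def sample_pool_without_replacement(
    pool: Sequence[float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from ``pool`` without replacement, restarting the pool
    (with a fresh shuffle) each time it is exhausted.

    Guarantees every pool value is used ``floor(n/len(pool))`` or
    ``ceil(n/len(pool))`` times.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("confidence-RT pool must be non-empty")
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        take = min(pool.size, n - filled)
        out[filled : filled + take] = rng.permutation(pool)[:take]
        filled += take
    return out


def simulate_dataset(
    params: DDMParams,
    n_trials: int,
    confidence_rt_pool: Sequence[float],
    rng: np.random.Generator,
    scale_spec=None,
    subject: Optional[str] = None,
    condition: Optional[str] = None,
) -> TrialDataset:
    """Simulate a full dataset of trials.

    Half of the trials (rounding down) get ``stimulus_sign = -1`` so that both
    stimulus classes are represented. Post-decision accumulation durations are
    drawn from ``confidence_rt_pool`` without replacement, restarting the pool
    when exhausted. Confidence is mapped from the post-decisional evidence via
    the agent's ``conf_M``/``conf_SD`` (and ``center_pull_P``); if
    ``scale_spec`` is given the mapped values are discretized/clamped to it,
    otherwise raw mapped confidence is reported.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    pool = np.asarray(confidence_rt_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("confidence-RT pool must be non-empty")
    if np.any(pool < 0):
        raise ValueError("pool durations must be >= 0")

    n_minus = n_trials // 2
    stimulus = np.ones(n_trials, dtype=np.int64)
    stimulus[:n_minus] = -1
    stimulus = rng.permutation(stimulus)
    post_dur = sample_pool_without_replacement(pool, n_trials, rng)

    dt, choice, e_choice, e_conf, n_capped = _simulate_arrays(params, stimulus, post_dur, rng)

    from .confidence import confidence_from_evidence  # local import, no cycle at runtime

    raw, conf = confidence_from_evidence(
        e_conf, params.conf_M, params.conf_SD, scale_spec, params.center_pull_P
    )

    df = pd.DataFrame(
        {
            "stimulus": stimulus,
            "choice": choice,
            "accuracy": choice == stimulus,
            "decision_time": dt,
            "rt": dt + params.ter,
            "postdecision_duration": post_dur,
            "evidence_at_choice": e_choice,
            "evidence_at_confidence": e_conf,
            "confidence_raw": raw,
            "confidence": conf,
            "confidence_rt": post_dur,
        },
        columns=TRIAL_COLUMNS,
    )
    return TrialDataset(trials=df, subject=subject, condition=condition, n_capped=n_capped)


def simulate_decision_times(
    drift_v: float,
    boundary_a: float,
    n: int,
    rng: np.random.Generator,
    tau: float = 0.001,
    sigma: float = 1.0,
    start_z: float = 0.5,
) -> np.ndarray:
    """First-passage (decision) times only, no non-decision component.

    Used to build dummy confidence-RT pools.
    """
    params = DDMParams(drift_v=drift_v, boundary_a=boundary_a, ter=0.0, tau=tau,
                       sigma=sigma, start_z=start_z)
    stimulus = np.ones(n, dtype=np.int64)
    dt, _, _, _, _ = _simulate_arrays(params, stimulus, np.zeros(n), rng)
    return dt


def analytic_accuracy(params: DDMParams) -> float:
    """Closed-form probability that the walk is absorbed at the boundary the
    drift points to (two-boundary diffusion absorption probability).

    For start point ``z`` and drift ``v``:
    ``(1 - exp(-2 v z a / sigma^2)) / (1 - exp(-2 v a / sigma^2))``;
    at ``z = 0.5`` this reduces to ``1 / (1 + exp(-v a / sigma^2))``.
    The ``v -> 0`` limit is ``z`` (returned exactly).
    """
    v, a, z, s2 = params.drift_v, params.boundary_a, params.start_z, params.sigma**2
    if v == 0.0:
        return z
    av = abs(v)
    num = -math.expm1(-2.0 * av * z * a / s2)
    den = -math.expm1(-2.0 * av * a / s2)
    return num / den


def analytic_mean_decision_time(params: DDMParams) -> float:
    """Closed-form mean first-passage time of the unbiased-start diffusion.

    At ``z = 0.5``: ``(a / (2 v)) * tanh(v a / (2 sigma^2))``; the driftless
    limit is ``a^2 z (1 - z) / sigma^2``. Excludes non-decision time. Only the
    ``z = 0.5`` case is supported for non-zero drift.
    """
    v, a, z, s2 = abs(params.drift_v), params.boundary_a, params.start_z, params.sigma**2
    if v == 0.0:
        return a * a * z * (1.0 - z) / s2
    if z != 0.5:
        raise NotImplementedError("mean decision time oracle requires start_z = 0.5")
    return (a / (2.0 * v)) * math.tanh(v * a / (2.0 * s2))
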