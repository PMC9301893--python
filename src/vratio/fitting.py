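"""Quantile-based chi-square fitting of the diffusion model with post-decision
accumulation.

Six free parameters are estimated per subject: drift rate v (one per condition
when requested), boundary a, non-decision time Ter, v-ratio, and the two
confidence-mapping constants M and SD. The data enter through accuracy-
conditioned proportion vectors: RT (and confidence) quantile bins computed
separately for corrects and errors, each class keeping its probability mass.
The objective is the chi-square distance between observed and model-predicted
proportions, with predictions obtained by simulating the model; differential
evolution minimizes it. Common random numbers (a frozen simulation seed, frozen
stimulus sequence and frozen post-decision durations) make the objective a
deterministic function of the parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .confidence import ConfidenceScaleSpec, confidence_from_evidence, estimate_P_from_data
from .ddm import TrialDataset, _simulate_arrays_crn, sample_pool_without_replacement
from .params import DDMParams

__all__ = [
    "QuantileSummary",
    "FitConfig",
    "FitResult",
    "quantile_summary",
    "chisquare_distance",
    "predict_summary",
    "fit_ddm",
    "make_objective",
]

DEFAULT_EDGES = (0.1, 0.3, 0.5, 0.7, 0.9)

DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "drift_v": (0.0, 5.0),
    "boundary_a": (0.3, 5.0),
    "ter": (0.0, 1.0),
    "v_ratio": (-1.0, 3.0),
    "conf_M": (-20.0, 20.0),
    "conf_SD": (0.05, 20.0),
}


@dataclass(frozen=True)
class QuantileSummary:
    """Accuracy-conditioned proportion vectors over RT and confidence bins.

    For each accuracy class the RT axis is cut at the class-conditional
    quantiles (``edges``); bin masses are scaled by the class probability so
    that correct + error proportions sum to 1. Confidence is treated the same
    way for continuous scales, or as one bin per scale level for discrete
    scales. A class with fewer than ``min_class_count`` trials collapses to a
    single bin carrying its whole mass (``rt_edges`` = None for that class).
    """

    edges: Tuple[float, ...]
    rt_edges_correct: Optional[np.ndarray]
    rt_edges_error: Optional[np.ndarray]
    rt_props_correct: np.ndarray
    rt_props_error: np.ndarray
    conf_kind: str  # "levels" or "quantiles"
    conf_levels: Optional[np.ndarray]
    conf_edges_correct: Optional[np.ndarray]
    conf_edges_error: Optional[np.ndarray]
    conf_props_correct: np.ndarray
    conf_props_error: np.ndarray

    def prop_blocks(self) -> Tuple[np.ndarray, ...]:
        return (
            self.rt_props_correct,
            self.rt_props_error,
            self.conf_props_correct,
            self.conf_props_error,
        )


def _props_against_edges(x: np.ndarray, edges_vals: Optional[np.ndarray], n_total: int,
                         n_bins_if_collapsed: int = 1) -> np.ndarray:
    """Bin masses of ``x`` against fixed edge values, normalized by ``n_total``."""
    if edges_vals is None:
        return np.array([x.size / n_total])
    bins = np.searchsorted(edges_vals, x, side="left")
    counts = np.bincount(bins, minlength=edges_vals.size + 1).astype(float)
    return counts / n_total


def _class_summary(x: np.ndarray, edges: Sequence[float], n_total: int, min_class_count: int):
    """(edge values, props) for one accuracy class; collapsed if too few trials."""
    if x.size < min_class_count:
        return None, np.array([x.size / n_total])
    ev = np.quantile(x, edges)
    return ev, _props_against_edges(x, ev, n_total)


def quantile_summary(
    dataset: TrialDataset,
    spec: Optional[ConfidenceScaleSpec] = None,
    edges: Sequence[float] = DEFAULT_EDGES,
    min_class_count: int = 5,
) -> QuantileSummary:
    """Observed proportion vectors for a dataset (the fitting target)."""
    return summary_from_arrays(
        dataset.rt, dataset.accuracy, dataset.confidence, spec, edges, min_class_count
    )


def summary_from_arrays(
    rt: np.ndarray,
    accuracy: np.ndarray,
    confidence: np.ndarray,
    spec: Optional[ConfidenceScaleSpec],
    edges: Sequence[float] = DEFAULT_EDGES,
    min_class_count: int = 5,
) -> QuantileSummary:
    rt = np.asarray(rt, dtype=float)
    accuracy = np.asarray(accuracy, dtype=bool)
    confidence = np.asarray(confidence, dtype=float)
    n = rt.size
    if n == 0:
        raise ValueError("empty dataset")
    edges = tuple(edges)
    out: dict = {"edges": edges}

    for label, m in (("correct", accuracy), ("error", ~accuracy)):
        ev, props = _class_summary(rt[m], edges, n, min_class_count)
        out[f"rt_edges_{label}"] = ev
        out[f"rt_props_{label}"] = props

    if spec is not None and spec.kind == "discrete":
        levels = np.asarray(spec.levels, dtype=float)
        out.update(conf_kind="levels", conf_levels=levels,
                   conf_edges_correct=None, conf_edges_error=None)
        for label, m in (("correct", accuracy), ("error", ~accuracy)):
            idx = np.searchsorted(levels, confidence[m])
            counts = np.bincount(idx, minlength=levels.size).astype(float)
            out[f"conf_props_{label}"] = counts / n
    else:
        out.update(conf_kind="quantiles", conf_levels=None)
        for label, m in (("correct", accuracy), ("error", ~accuracy)):
            ev, props = _class_summary(confidence[m], edges, n, min_class_count)
            out[f"conf_edges_{label}"] = ev
            out[f"conf_props_{label}"] = props
    return QuantileSummary(**out)


def _predicted_from_arrays(
    rt: np.ndarray,
    accuracy: np.ndarray,
    confidence: np.ndarray,
    observed: QuantileSummary,
) -> QuantileSummary:
    """Predicted proportions of simulated trials within the observed bin edges."""
    n = rt.size
    out: dict = {"edges": observed.edges}
    for label, m in (("correct", accuracy), ("error", ~accuracy)):
        ev = getattr(observed, f"rt_edges_{label}")
        out[f"rt_edges_{label}"] = ev
        out[f"rt_props_{label}"] = _props_against_edges(rt[m], ev, n)
    out["conf_kind"] = observed.conf_kind
    out["conf_levels"] = observed.conf_levels
    if observed.conf_kind == "levels":
        levels = observed.conf_levels
        out.update(conf_edges_correct=None, conf_edges_error=None)
        for label, m in (("correct", accuracy), ("error", ~accuracy)):
            idx = np.searchsorted(levels, confidence[m])
            counts = np.bincount(idx, minlength=levels.size).astype(float)
            out[f"conf_props_{label}"] = counts / n
    else:
        for label, m in (("correct", accuracy), ("error", ~accuracy)):
            ev = getattr(observed, f"conf_edges_{label}")
            out[f"conf_edges_{label}"] = ev
            out[f"conf_props_{label}"] = _props_against_edges(confidence[m], ev, n)
    return QuantileSummary(**out)


def chisquare_distance(
    observed: QuantileSummary, predicted: QuantileSummary, denom_floor: float = 1e-4
) -> float:
    """Sum over all RT and confidence bins of (o - p)^2 / p, with the predicted
    denominator floored at ``denom_floor``."""
    total = 0.0
    for o, p in zip(observed.prop_blocks(), predicted.prop_blocks()):
        o = np.asarray(o, dtype=float)
        p = np.asarray(p, dtype=float)
        if o.shape != p.shape:
            raise ValueError("observed and predicted summaries have mismatched bin structure")
        total += float(np.sum((o - p) ** 2 / np.maximum(p, denom_floor)))
    return total


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the quantile-optimization fit.

    ``n_sim`` is the number of model trials simulated per objective evaluation
    (default ``max(10000, 10 * n_observed)``). ``population`` is the total
    differential-evolution population; the search stops after
    ``max_generations`` or once the best objective has improved by less than
    ``stall_tol`` for ``stall_generations`` consecutive generations.
    """

    bounds: Dict[str, Tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    edges: Tuple[float, ...] = DEFAULT_EDGES
    n_sim: Optional[int] = None
    population: int = 60
    max_generations: int = 250
    stall_generations: int = 25
    stall_tol: float = 1e-4
    min_class_count: int = 5
    denom_floor: float = 1e-4
    seed: int = 1
    mutation: Tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7

    def resolve_n_sim(self, n_obs: int) -> int:
        return self.n_sim if self.n_sim is not None else max(10000, 10 * n_obs)


@dataclass
class FitResult:
    params: DDMParams  # drift_v holds the first condition's drift
    drifts: Tuple[float, ...]
    v_ratio: float
    objective_value: float
    n_evaluations: int
    master_seed: int
    converged: bool
    center_pull_P: float
    info: dict = field(default_factory=dict)


#: Size (log2) of the frozen innovation table used by the fitting objective.
_NOISE_LOG2 = 22


def predict_summary(
    params: DDMParams,
    n_sim: int,
    confidence_rt_pool: Sequence[float],
    seed: int,
    spec: Optional[ConfidenceScaleSpec],
    observed: QuantileSummary,
) -> QuantileSummary:
    """Model-predicted proportions within the observed bin edges.

    With the same ``seed``, parameters and pool, the result is bit-identical
    across calls (the common-random-numbers contract the optimizer relies on).
    """
    rng = np.random.default_rng(seed)
    n_minus = n_sim // 2
    stimulus = np.ones(n_sim, dtype=np.int64)
    stimulus[:n_minus] = -1
    post_dur = sample_pool_without_replacement(np.asarray(confidence_rt_pool, float), n_sim, rng)
    noise = rng.standard_normal(1 << _NOISE_LOG2)
    post_noise = rng.standard_normal(n_sim)
    return _predict_crn(params, stimulus, post_dur, noise, post_noise, 0, spec, observed)


def _predict_crn(params, stimulus, post_dur, noise, post_noise, offset0, spec, observed):
    dt, choice, _, e_conf, _ = _simulate_arrays_crn(
        params, stimulus, post_dur, noise, post_noise, offset0
    )
    _, conf = confidence_from_evidence(e_conf, params.conf_M, params.conf_SD, spec,
                                       params.center_pull_P)
    rt = dt + params.ter
    acc = choice == stimulus
    return _predicted_from_arrays(rt, acc, conf, observed)


def make_objective(
    dataset: TrialDataset,
    spec: Optional[ConfidenceScaleSpec],
    config: FitConfig,
    condition_column: Optional[str] = None,
):
    """Build the deterministic chi-square objective for a dataset.

    Returns ``(objective, unpack, k_conditions, info)`` where ``objective``
    maps a parameter vector ``[v_1..v_k, a, ter, v_ratio, M, SD]`` to the
    summed chi-square distance and ``unpack`` maps it to per-condition
    :class:`DDMParams`.
    """
    df = dataset.trials
    if condition_column is not None and condition_column in df.columns:
        cond_values = list(dict.fromkeys(df[condition_column]))
    else:
        cond_values = [None]
    k = len(cond_values)

    P = estimate_P_from_data(dataset.confidence, spec) if spec is not None else 0.0

    rng_master = np.random.default_rng(config.seed)
    noise = rng_master.standard_normal(1 << _NOISE_LOG2)
    per_cond = []
    for cv in cond_values:
        sub = df if cv is None else df[df[condition_column] == cv]
        rt = sub["rt"].to_numpy(float)
        acc = sub["accuracy"].to_numpy(bool)
        conf = sub["confidence"].to_numpy(float)
        crt = sub["confidence_rt"].to_numpy(float)
        observed = summary_from_arrays(rt, acc, conf, spec, config.edges, config.min_class_count)
        n_sim = config.resolve_n_sim(len(sub))
        # frozen design: stimulus sequence, post-decision durations, innovations
        stimulus = np.ones(n_sim, dtype=np.int64)
        stimulus[: n_sim // 2] = -1
        # the pool is a multiset: sort before sampling so the frozen design
        # (and hence the objective) is invariant to trial order in the data
        post_dur = sample_pool_without_replacement(np.sort(crt), n_sim, rng_master)
        post_noise = rng_master.standard_normal(n_sim)
        offset0 = int(rng_master.integers(0, 1 << _NOISE_LOG2))
        per_cond.append((observed, stimulus, post_dur, post_noise, offset0, n_sim))

    def unpack(theta) -> Tuple[DDMParams, ...]:
        drifts = theta[:k]
        a, ter, vr, m, sd = theta[k : k + 5]
        return tuple(
            DDMParams(drift_v=float(v), boundary_a=float(a), ter=float(ter),
                      v_ratio=float(vr), conf_M=float(m), conf_SD=float(sd),
                      center_pull_P=P)
            for v in drifts
        )

    def objective(theta) -> float:
        total = 0.0
        for p, (observed, stimulus, post_dur, post_noise, offset0, _) in zip(
            unpack(theta), per_cond
        ):
            pred = _predict_crn(p, stimulus, post_dur, noise, post_noise, offset0,
                                spec, observed)
            total += chisquare_distance(observed, pred, config.denom_floor)
        return total

    info = {
        "n_conditions": k,
        "condition_values": cond_values,
        "center_pull_P": P,
        "n_sim": [pc[5] for pc in per_cond],
        "observed": [pc[0] for pc in per_cond],
    }
    return objective, unpack, k, info


def _heuristic_start(dataset: TrialDataset, bounds_list, k: int) -> np.ndarray:
    """Moment-based starting point (EZ-style closed forms for v, a, Ter)."""
    rt = dataset.rt
    acc = dataset.accuracy
    conf = dataset.confidence
    n = rt.size
    pc = min(max(acc.mean(), 0.5 + 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))
    vrt = max(np.var(rt[acc]) if acc.sum() > 2 else np.var(rt), 1e-4)
    mrt = float(np.mean(rt[acc])) if acc.sum() > 0 else float(np.mean(rt))
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / vrt
    v0 = abs(x) ** 0.25 if x > 0 else 1.0
    a0 = L / v0 if v0 > 0 else 1.0
    mdt = (a0 / (2 * v0)) * math.tanh(v0 * a0 / 2.0) if v0 > 0 else 0.3
    ter0 = max(mrt - mdt, 0.01)
    crt_mean = float(np.mean(dataset.confidence_rt))
    e_sd = math.sqrt(max(crt_mean, 1e-3))
    sd0 = max(e_sd / max(np.std(conf), 1e-3), 0.1)
    m0 = float(np.mean(conf)) * sd0 - a0
    theta0 = np.array([v0] * k + [a0, ter0, 0.6, m0, sd0])
    lo = np.array([b[0] for b in bounds_list])
    hi = np.array([b[1] for b in bounds_list])
    return np.clip(theta0, lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo))


def fit_ddm(
    dataset: TrialDataset,
    spec: Optional[ConfidenceScaleSpec] = None,
    config: Optional[FitConfig] = None,
    condition_column: Optional[str] = None,
) -> FitResult:
    """Estimate the model parameters for one subject by quantile optimization.

    The dataset is expected to have passed the RT exclusions (see
    :func:`vratio.io.apply_exclusions`). The center-pull fraction P is not free:
    it is fixed at the observed proportion of ratings at the scale midpoint.
    Start point z = 0.5 and noise sigma = 1 are fixed throughout.
    """
    config = config or FitConfig()
    objective, unpack, k, info = make_objective(dataset, spec, config, condition_column)

    bounds_list = (
        [tuple(config.bounds["drift_v"])] * k
        + [tuple(config.bounds[name]) for name in ("boundary_a", "ter", "v_ratio", "conf_M", "conf_SD")]
    )
    x0 = _heuristic_start(dataset, bounds_list, k)

    n_eval = 0

    def counted(theta):
        nonlocal n_eval
        n_eval += 1
        return objective(theta)

    state = {"best": np.inf, "stall": 0, "stagnated": False}

    def callback(xk, convergence=None):
        val = objective(xk)
        if state["best"] - val > config.stall_tol:
            state["stall"] = 0
        else:
            state["stall"] += 1
        state["best"] = min(state["best"], val)
        if state["stall"] >= config.stall_generations:
            state["stagnated"] = True
            return True
        return False

    dim = len(bounds_list)
    popsize = max(4, int(math.ceil(config.population / dim)))
    result = optimize.differential_evolution(
        counted,
        bounds=bounds_list,
        x0=x0,
        seed=config.seed,
        maxiter=config.max_generations,
        popsize=popsize,
        tol=0.0,
        atol=0.0,
        mutation=config.mutation,
        recombination=config.recombination,
        polish=False,
        init="latinhypercube",
        callback=callback,
        updating="immediate",
    )

    params_per_cond = unpack(result.x)
    p0 = params_per_cond[0]
    converged = bool(state["stagnated"] or result.success)
    info_out = {
        "condition_values": info["condition_values"],
        "n_sim": info["n_sim"],
        "de_message": str(result.message),
    }
    return FitResult(
        params=p0,
        drifts=tuple(float(p.drift_v) for p in params_per_cond),
        v_ratio=float(p0.v_ratio),
        objective_value=float(result.fun),
        n_evaluations=n_eval,
        master_seed=config.seed,
        converged=converged,
        center_pull_P=float(info["center_pull_P"]),
        info=info_out,
    )
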