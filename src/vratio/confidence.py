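"""Mapping post-decisional evidence onto an empirical confidence scale.

Raw confidence is a linear read-out of the evidence integrated after the
choice, ``raw = (evidence + M) / SD``. Observed rating scales then impose
discretization (rounding to the nearest scale level, out-of-range values
clamped to the endpoints) or, for continuous scales, clamping to the scale
range plus a "center pull": the fraction P of ratings closest to the scale
midpoint is relabeled as the midpoint, mimicking the attraction of verbal
labels placed there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "ConfidenceScaleSpec",
    "map_evidence_to_confidence",
    "discretize_confidence",
    "apply_center_pull",
    "estimate_P_from_data",
    "confidence_from_evidence",
]


@dataclass(frozen=True)
class ConfidenceScaleSpec:
    """Description of the confidence response scale.

    kind "discrete": ratings take one of `levels` (strictly increasing).
    kind "continuous": ratings lie in [lo, hi].
    `midpoint` is the scale's center value used by the center-pull relabeling.
    """

    kind: str
    levels: Optional[Tuple[float, ...]] = None
    lo: Optional[float] = None
    hi: Optional[float] = None
    midpoint: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "discrete":
            if not self.levels or len(self.levels) < 2:
                raise ValueError("discrete scale needs >= 2 levels")
            if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
                raise ValueError("levels must be strictly increasing")
        elif self.kind == "continuous":
            if self.lo is None or self.hi is None or not self.lo < self.midpoint < self.hi:
                raise ValueError("continuous scale needs lo < midpoint < hi")
        else:
            raise ValueError(f"unknown scale kind {self.kind!r}")

    @classmethod
    def six_point(cls) -> "ConfidenceScaleSpec":
        """The 1..6 button scale; midpoint 3.5 (between levels, hence unattainable)."""
        return cls(kind="discrete", levels=tuple(float(v) for v in range(1, 7)), midpoint=3.5)

    @classmethod
    def continuous(cls, lo: float, hi: float, midpoint: Optional[float] = None) -> "ConfidenceScaleSpec":
        if midpoint is None:
            midpoint = 0.5 * (lo + hi)
        return cls(kind="continuous", lo=lo, hi=hi, midpoint=midpoint)

    @property
    def n_levels(self) -> int:
        if self.kind != "discrete":
            raise ValueError("n_levels only defined for discrete scales")
        return len(self.levels)


def map_evidence_to_confidence(evidence, conf_M: float, conf_SD: float):
    """Linear evidence-to-confidence mapping ``(evidence + M) / SD``."""
    if conf_SD <= 0:
        raise ValueError("conf_SD must be > 0")
    return (np.asarray(evidence, dtype=float) + conf_M) / conf_SD


def discretize_confidence(raw, spec: ConfidenceScaleSpec) -> np.ndarray:
    """Round raw confidence to the nearest scale level, clamping beyond endpoints.

    Equidistant values (e.g. 3.5 on a 1..6 scale) round away from zero.
    """
    if spec.kind != "discrete":
        raise ValueError("discretize_confidence requires a discrete scale spec")
    raw = np.atleast_1d(np.asarray(raw, dtype=float))
    levels = np.asarray(spec.levels, dtype=float)
    hi_idx = np.searchsorted(levels, raw, side="left")
    hi_idx = np.clip(hi_idx, 0, len(levels) - 1)
    lo_idx = np.clip(hi_idx - 1, 0, len(levels) - 1)
    d_lo = np.abs(raw - levels[lo_idx])
    d_hi = np.abs(levels[hi_idx] - raw)
    # pick the nearer level; exact ties go to the level farther from zero
    pick_hi = (d_hi < d_lo) | ((d_hi == d_lo) & (np.abs(levels[hi_idx]) >= np.abs(levels[lo_idx])))
    out = np.where(pick_hi, levels[hi_idx], levels[lo_idx])
    out = np.clip(out, levels[0], levels[-1])
    return out


def apply_center_pull(raws, P: float, spec: ConfidenceScaleSpec) -> np.ndarray:
    """Relabel the floor(P*n) values closest to the scale midpoint as the midpoint.

    Order is preserved; ties in distance are broken by position (earlier trials
    first), deterministically.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    raws = np.asarray(raws, dtype=float).copy()
    k = int(np.floor(P * raws.size))
    if k == 0:
        return raws
    order = np.argsort(np.abs(raws - spec.midpoint), kind="stable")
    raws[order[:k]] = spec.midpoint
    return raws


def estimate_P_from_data(observed_confidence, spec: ConfidenceScaleSpec) -> float:
    """Proportion of observed ratings exactly at the scale midpoint.

    On discrete scales whose midpoint falls between levels this is 0 by
    construction.
    """
    obs = np.asarray(observed_confidence, dtype=float)
    if obs.size == 0:
        raise ValueError("need at least one observation")
    return float(np.mean(obs == spec.midpoint))


def confidence_from_evidence(
    evidence,
    conf_M: float,
    conf_SD: float,
    spec: Optional[ConfidenceScaleSpec],
    P: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Full pipeline from post-decisional evidence to reported confidence.

    Returns ``(raw, reported)``. With no scale spec the reported value is the
    raw linear mapping. Continuous scales clamp to [lo, hi] and then apply the
    center pull; discrete scales round and clamp to the levels (the center pull
    does not apply: the midpoint lies between levels).
    """
    raw = map_evidence_to_confidence(evidence, conf_M, conf_SD)
    if spec is None:
        return raw, raw.copy()
    if spec.kind == "continuous":
        reported = np.clip(raw, spec.lo, spec.hi)
        reported = apply_center_pull(reported, P, spec)
        return raw, reported
    return raw, discretize_confidence(raw, spec)
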