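"""Static (signal detection theoretic) measures of performance and metacognition.

Implements the standard meta-d' construction: given stimulus x response x
confidence counts, find the sensitivity a classical SDT observer would need in
order to produce the observed confidence (type-2) data, holding the type-1
criterion at its (relative) empirical location. M-ratio = meta-d'/d' is the
static measure of metacognitive efficiency that the dynamic v-ratio framework
is compared against. The unequal-variance generalization enters through the
ratio ``s = sd(S1)/sd(S2)`` of the two stimulus distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import norm

__all__ = [
    "SDTTable",
    "MetaDResult",
    "bin_confidence",
    "build_sdt_table",
    "fit_meta_d",
    "type2_auc",
]


@dataclass(frozen=True)
class SDTTable:
    """Stimulus x response x confidence counts.

    ``counts_s1``/``counts_s2`` have length ``2 * n_levels``, ordered from the
    highest-confidence "S1" response down to confidence 1, then confidence 1 up
    to the highest-confidence "S2" response.
    """

    n_levels: int
    counts_s1: np.ndarray
    counts_s2: np.ndarray

    def __post_init__(self) -> None:
        for c in (self.counts_s1, self.counts_s2):
            arr = np.asarray(c, dtype=float)
            if arr.shape != (2 * self.n_levels,):
                raise ValueError("count vectors must have length 2 * n_levels")
            if np.any(arr < 0):
                raise ValueError("counts must be >= 0")
            if arr.sum() <= 0:
                raise ValueError("each stimulus class needs at least one trial")

    def padded(self, pad: Optional[float] = None) -> "SDTTable":
        """Add a small constant to every cell (default 1/(2*n_levels)) so that
        empty cells do not send criteria to infinity."""
        if pad is None:
            pad = 1.0 / (2.0 * self.n_levels)
        return SDTTable(
            self.n_levels,
            np.asarray(self.counts_s1, dtype=float) + pad,
            np.asarray(self.counts_s2, dtype=float) + pad,
        )


@dataclass(frozen=True)
class MetaDResult:
    d_prime: float
    criterion_c: float
    meta_d_prime: float
    m_ratio: float
    s_ratio_used: float
    nll: float = math.nan
    converged: bool = True


def bin_confidence(values: Sequence[float], n_bins: int) -> np.ndarray:
    """Equal-count (quantile) confidence bins, labelled 1..n_bins.

    Rank-based and therefore invariant to strictly monotone transforms of the
    ratings. Degenerate inputs (fewer distinct values than bins) merge bin
    edges; all-identical input lands in bin 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if np.unique(values).size == 1:
        return np.ones(values.size, dtype=np.int64)
    labels = pd.qcut(values, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(labels, dtype=np.int64) + 1


def build_sdt_table(
    stimulus: Sequence[int],
    choice: Sequence[int],
    confidence_level: Sequence[int],
    n_levels: Optional[int] = None,
) -> SDTTable:
    """Tabulate trials into the 2 x (2*n_levels) SDT count layout.

    ``stimulus`` and ``choice`` are coded -1 (S1 / "S1" response) and +1.
    ``confidence_level`` holds ordinal labels; if ``n_levels`` is omitted it is
    the number of distinct labels and labels are used by rank.
    """
    stimulus = np.asarray(stimulus)
    choice = np.asarray(choice)
    conf = np.asarray(confidence_level)
    if not (set(np.unique(stimulus)) <= {-1, 1}) or not (set(np.unique(choice)) <= {-1, 1}):
        raise ValueError("stimulus and choice must be coded -1 / +1")
    if np.unique(stimulus).size < 2:
        raise ValueError("both stimulus classes are required")
    levels = np.unique(conf)
    if n_levels is None:
        n_levels = levels.size
    elif levels.size > n_levels:
        raise ValueError("more distinct confidence labels than n_levels")
    rank = np.searchsorted(levels, conf)  # 0 .. levels.size-1
    if levels.size < n_levels:
        # labels are assumed to be 1..n_levels with some unused; keep absolute position
        if np.all(np.isin(levels, np.arange(1, n_levels + 1))):
            rank = conf.astype(np.int64) - 1
    counts = {s: np.zeros(2 * n_levels) for s in (-1, 1)}
    for s in (-1, 1):
        m = stimulus == s
        for r, k in zip(choice[m], rank[m]):
            idx = (n_levels - 1 - k) if r == -1 else (n_levels + k)
            counts[s][idx] += 1
    return SDTTable(n_levels=n_levels, counts_s1=counts[-1], counts_s2=counts[1])


def _type1_stats(table: SDTTable, s: float):
    """Hit/false-alarm based d' and criterion with SD ratio ``s = sd(S1)/sd(S2)``."""
    k = table.n_levels
    n1 = table.counts_s1.sum()
    n2 = table.counts_s2.sum()
    far = table.counts_s1[k:].sum() / n1  # "S2" responses to S1
    hr = table.counts_s2[k:].sum() / n2  # "S2" responses to S2
    d1 = (1.0 / s) * norm.ppf(hr) - norm.ppf(far)
    c1 = (-1.0 / (1.0 + s)) * (norm.ppf(hr) + norm.ppf(far))
    return d1, c1


def _cell_probs(meta_d1: float, meta_c: float, gaps_lo, gaps_hi, s: float, k: int):
    """Cell probabilities (2 stimuli x 2k cells) for the meta-level observer."""
    mu = np.array([-meta_d1 / 2.0, meta_d1 / 2.0])
    sd = np.array([1.0, 1.0 / s])
    lo = meta_c - np.cumsum(gaps_lo)[::-1]  # ascending criteria below meta_c
    hi = meta_c + np.cumsum(gaps_hi)
    bounds = np.concatenate(([-np.inf], lo, [meta_c], hi, [np.inf]))
    z = (bounds[None, :] - mu[:, None]) / sd[:, None]
    cdf = norm.cdf(z)
    return np.diff(cdf, axis=1), norm.cdf((meta_c - mu) / sd)


def fit_meta_d(table: SDTTable, s_ratio: float = 1.0, pad: Optional[float] = None) -> MetaDResult:
    """Maximum-likelihood meta-d' with the type-1 criterion held at its relative
    location (``meta_c = meta_d' * c / d'``).

    Parameters
    ----------
    table : SDTTable
        Raw counts; cell padding (default 1/(2*n_levels) per cell) is applied
        internally before fitting.
    s_ratio : float
        Ratio sd(S1)/sd(S2) of the type-1 model; 1 recovers the equal-variance
        model. Supplying a measured ratio gives the unequal-variance adjustment.

    Returns a :class:`MetaDResult`. If d' <= 0, M-ratio is undefined and
    returned as NaN with ``converged=False``.
    """
    if s_ratio <= 0:
        raise ValueError("s_ratio must be > 0")
    k = table.n_levels
    pt = table.padded(pad)
    d1, c1 = _type1_stats(pt, s_ratio)
    scale = math.sqrt(2.0 / (1.0 + s_ratio**2)) * s_ratio
    if d1 <= 0:
        return MetaDResult(
            d_prime=scale * d1, criterion_c=c1, meta_d_prime=math.nan,
            m_ratio=math.nan, s_ratio_used=s_ratio, converged=False,
        )
    counts = np.vstack([pt.counts_s1, pt.counts_s2])
    c_over_d = c1 / d1
    n_gaps = k - 1

    def nll(x):
        meta_d1 = x[0]
        gaps_lo = np.exp(x[1 : 1 + n_gaps])
        gaps_hi = np.exp(x[1 + n_gaps :])
        cells, p_resp_s1 = _cell_probs(meta_d1, meta_d1 * c_over_d, gaps_lo, gaps_hi, s_ratio, k)
        denom = np.concatenate(
            [np.repeat(p_resp_s1[:, None], k, axis=1), np.repeat(1.0 - p_resp_s1[:, None], k, axis=1)],
            axis=1,
        )
        cond = np.clip(cells / np.clip(denom, 1e-300, None), 1e-300, None)
        return -np.sum(counts * np.log(cond))

    bounds = [(-10.0, 10.0)] + [(math.log(1e-4), math.log(10.0))] * (2 * n_gaps)
    best = None
    for md0 in (d1, 0.2, min(2.0 * d1, 9.0)):
        x0 = np.concatenate(([md0], np.full(2 * n_gaps, math.log(0.5))))
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    meta_d1 = float(best.x[0])
    return MetaDResult(
        d_prime=scale * d1,
        criterion_c=c1,
        meta_d_prime=scale * meta_d1,
        m_ratio=meta_d1 / d1,
        s_ratio_used=s_ratio,
        nll=float(best.fun),
        converged=bool(best.success),
    )


def type2_auc(accuracies: Sequence[bool], confidences: Sequence[float]) -> float:
    """Area under the type-II ROC: how well confidence separates correct from
    error trials. 0.5 is chance. Midrank (trapezoid) tie convention.
    """
    acc = np.asarray(accuracies, dtype=bool)
    conf = np.asarray(confidences, dtype=float)
    if acc.size != conf.size or acc.size == 0:
        raise ValueError("accuracies and confidences must be equal-length, non-empty")
    n1 = int(acc.sum())
    n0 = acc.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one correct and one error trial")
    u = stats.mannwhitneyu(conf[acc], conf[~acc], alternative="two-sided").statistic
    return float(u / (n1 * n0))
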