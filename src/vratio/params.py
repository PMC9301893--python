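"""Parameter containers for the diffusion model with post-decisional accumulation."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class DDMParams:
    """One agent's generative (or fitted) parameter set.

    Attributes
    ----------
    drift_v : float
        Mean rate of evidence accumulation, evidence units per second. Multiplied
        by the stimulus sign (+1/-1) on each trial.
    boundary_a : float
        Separation between the two absorbing boundaries (0 and ``boundary_a``).
        Indexes response caution.
    ter : float
        Non-decision time in seconds, added to the decision time to form the
        observable choice RT.
    v_ratio : float
        Ratio of post-decision drift rate to drift rate. The post-decision drift
        is ``stimulus_sign * drift_v * v_ratio``. This is the dynamic measure of
        metacognitive accuracy.
    conf_M, conf_SD : float
        Additive and multiplicative constants mapping post-decisional evidence
        onto the empirical confidence scale: ``raw = (evidence + conf_M) / conf_SD``.
    center_pull_P : float
        Fraction of trials whose raw confidence, being closest to the scale
        midpoint, is relabeled as the midpoint (verbal-label attraction).
    start_z : float
        Relative start point of the accumulator, as a fraction of ``boundary_a``.
        Fixed at 0.5 (no bias) throughout.
    sigma : float
        Within-trial noise scale per sqrt(second). Fixed at 1 (not identifiable
        jointly with ``boundary_a``).
    tau : float
        Integration step of the random-walk approximation, seconds.
    """

    drift_v: float
    boundary_a: float
    ter: float = 0.3
    v_ratio: float = 1.0
    conf_M: float = 0.0
    conf_SD: float = 1.0
    center_pull_P: float = 0.0
    start_z: float = 0.5
    sigma: float = 1.0
    tau: float = 0.001

    def __post_init__(self) -> None:
        if not self.boundary_a > 0:
            raise ValueError(f"boundary_a must be > 0, got {self.boundary_a}")
        if not 0.0 < self.start_z < 1.0:
            raise ValueError(f"start_z must lie in (0, 1), got {self.start_z}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.conf_SD > 0:
            raise ValueError(f"conf_SD must be > 0, got {self.conf_SD}")
        if self.ter < 0:
            raise ValueError(f"ter must be >= 0, got {self.ter}")
        if not 0.0 <= self.center_pull_P <= 1.0:
            raise ValueError(f"center_pull_P must lie in [0, 1], got {self.center_pull_P}")

    def with_(self, **kwargs) -> "DDMParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    @property
    def post_drift(self) -> float:
        """Post-decision drift rate (evidence units per second)."""
        return self.drift_v * self.v_ratio
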