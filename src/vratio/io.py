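"""Reading/writing trial tables and the standard RT exclusions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .confidence import ConfidenceScaleSpec
from .ddm import TrialDataset

__all__ = ["TrialTableSchema", "read_trials", "write_trials", "apply_exclusions"]

#: Internal canonical column names.
CANONICAL = ["subject", "condition", "stimulus", "choice", "accuracy", "rt",
             "confidence", "confidence_rt"]
REQUIRED = ["stimulus", "choice", "accuracy", "rt", "confidence", "confidence_rt"]


@dataclass(frozen=True)
class TrialTableSchema:
    """Column mapping from a delimited trial table onto the canonical names.

    ``columns`` maps canonical name -> column name in the file. ``rt_unit``
    may be "s" or "ms" (milliseconds are converted to seconds on read).
    """

    columns: Dict[str, str] = field(default_factory=lambda: {c: c for c in CANONICAL})
    rt_unit: str = "s"

    def __post_init__(self) -> None:
        if self.rt_unit not in ("s", "ms"):
            raise ValueError("rt_unit must be 's' or 'ms'")


def read_trials(
    path,
    schema: Optional[TrialTableSchema] = None,
    scale_spec: Optional[ConfidenceScaleSpec] = None,
    sep: Optional[str] = None,
) -> TrialDataset:
    """Read a delimited trial table into a validated :class:`TrialDataset`.

    Validation errors (missing columns, non-numeric fields, negative RTs,
    out-of-scale confidence, accuracy inconsistent with stimulus/choice)
    raise ``ValueError`` naming the offending rows (1-based, excluding header).
    """
    schema = schema or TrialTableSchema()
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")

    missing = [c for c in REQUIRED if schema.columns.get(c, c) not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing} in {path}")

    df = pd.DataFrame(index=raw.index)
    for canon in CANONICAL:
        src = schema.columns.get(canon, canon)
        if src in raw.columns:
            df[canon] = raw[src]

    errors = []
    for col in ["stimulus", "choice", "accuracy", "rt", "confidence", "confidence_rt"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] if df[col].dtype == object else []
        bad = list(df.index[coerced.isna()])
        for i in bad:
            errors.append(f"row {i + 1}: unparsable {col}={df.loc[i, col]!r}")
        df[col] = coerced
    if errors:
        raise ValueError("invalid trial table:\n" + "\n".join(errors))

    if schema.rt_unit == "ms":
        df["rt"] = df["rt"] / 1000.0
        df["confidence_rt"] = df["confidence_rt"] / 1000.0

    for i in df.index[df["rt"] <= 0]:
        errors.append(f"row {i + 1}: rt must be > 0, got {df.loc[i, 'rt']}")
    for i in df.index[~df["stimulus"].isin([-1, 1])]:
        errors.append(f"row {i + 1}: stimulus must be -1/+1")
    for i in df.index[~df["choice"].isin([-1, 1])]:
        errors.append(f"row {i + 1}: choice must be -1/+1")
    mism = df.index[(df["accuracy"] == 1) != (df["stimulus"] == df["choice"])]
    for i in mism:
        errors.append(f"row {i + 1}: accuracy inconsistent with stimulus and choice")
    if scale_spec is not None:
        if scale_spec.kind == "discrete":
            ok = df["confidence"].isin(scale_spec.levels)
        else:
            ok = df["confidence"].between(scale_spec.lo, scale_spec.hi)
        for i in df.index[~ok]:
            errors.append(f"row {i + 1}: confidence {df.loc[i, 'confidence']} outside scale")
    if errors:
        raise ValueError("invalid trial table:\n" + "\n".join(errors))

    df["accuracy"] = df["accuracy"].astype(bool)
    df["stimulus"] = df["stimulus"].astype(np.int64)
    df["choice"] = df["choice"].astype(np.int64)
    subject = str(df["subject"].iloc[0]) if "subject" in df.columns else None
    return TrialDataset(trials=df.reset_index(drop=True), subject=subject)


def write_trials(dataset: TrialDataset, path, sep: str = ",") -> None:
    """Write the schema columns of a dataset as delimited text (lossless
    round-trip with :func:`read_trials`)."""
    df = dataset.trials.copy()
    if "subject" not in df.columns and dataset.subject is not None:
        df.insert(0, "subject", dataset.subject)
    cols = [c for c in CANONICAL if c in df.columns]
    out = df[cols].copy()
    out["accuracy"] = out["accuracy"].astype(int)
    out.to_csv(path, sep=sep, index=False)


def apply_exclusions(
    dataset: TrialDataset,
    min_rt: float = 0.1,
    max_confidence_rt: float = 5.0,
) -> Tuple[TrialDataset, Dict[str, int]]:
    """Remove trials with choice RT faster than 100 ms or confidence RT slower
    than 5 s (boundary values retained). Returns the filtered dataset and a
    per-rule exclusion report. Idempotent.
    """
    df = dataset.trials
    fast = df["rt"] < min_rt
    slow = df["confidence_rt"] > max_confidence_rt
    report = {
        "n_input": len(df),
        "excluded_fast_rt": int(fast.sum()),
        "excluded_slow_confidence_rt": int(slow.sum()),
        "n_retained": int((~(fast | slow)).sum()),
    }
    if report["n_retained"] == 0:
        raise ValueError("no trials remain after exclusions")
    kept = df[~(fast | slow)].reset_index(drop=True)
    return (
        TrialDataset(trials=kept, subject=dataset.subject, condition=dataset.condition,
                     n_capped=dataset.n_capped, meta=dict(dataset.meta)),
        report,
    )
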