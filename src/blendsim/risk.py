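"""FMEA risk scoring for blending process parameters.

Failure mode and effects analysis (FMEA) ranks each (process parameter,
quality attribute) pair by a risk priority number

    RPN = severity (S) x probability of occurrence (P) x detectability (D),

with each score drawn from the odd five-point scale {1, 3, 5, 7, 9}.  RPN
therefore ranges from 1 to 729.  Risk levels follow fixed cut-offs (low
below 82, medium 82-245, high 246 and above) and a Pareto threshold
``max_rpn * (1 - confidence)`` separates parameters that need active
control from the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RiskEntry",
    "VALID_SCORES",
    "compute_rpn",
    "classify_risk",
    "pareto_threshold",
    "pareto_summary",
    "read_risk_register",
    "write_risk_register",
    "score_register",
]

VALID_SCORES = frozenset({1, 3, 5, 7, 9})

#: Risk-level cut-offs: RPN < 82 is low, 82..245 medium, >= 246 high.
LOW_MEDIUM_CUTOFF = 82
MEDIUM_HIGH_CUTOFF = 246


class ScoreError(ValueError):
    """A severity/occurrence/detectability score outside the allowed set."""


def _check_score(value: int, name: str, permissive: bool = False) -> int:
    value = int(value)
    if permissive:
        if not 1 <= value <= 9:
            raise ScoreError(f"{name} score {value} outside 1..9")
    elif value not in VALID_SCORES:
        raise ScoreError(
            f"{name} score {value} not in allowed set {sorted(VALID_SCORES)}"
        )
    return value


def compute_rpn(
    severity: int, occurrence: int, detectability: int, *, permissive: bool = False
) -> int:
    """Risk priority number S x P x D.

    Scores must lie in {1,3,5,7,9}; with ``permissive=True`` any integer
    1..9 is accepted.
    """
    s = _check_score(severity, "severity", permissive)
    p = _check_score(occurrence, "occurrence", permissive)
    d = _check_score(detectability, "detectability", permissive)
    return s * p * d


def classify_risk(rpn: int) -> str:
    """Classify an RPN as ``'low'``, ``'medium'`` or ``'high'``."""
    rpn = int(rpn)
    if not 1 <= rpn <= 729:
        raise ValueError(f"rpn {rpn} outside valid range 1..729")
    if rpn < LOW_MEDIUM_CUTOFF:
        return "low"
    if rpn < MEDIUM_HIGH_CUTOFF:
        return "medium"
    return "high"


def pareto_threshold(max_rpn: int = 729, confidence: float = 0.90) -> float:
    """Pareto cut line ``max_rpn * (1 - confidence)``.

    With the default 90% confidence on the 729 maximum the threshold is
    72.9; parameters whose RPN exceeds it are flagged for control.
    """
    if not 0.0 <= confidence <= 1.0:
        raise ValueError(f"confidence {confidence} outside [0, 1]")
    if max_rpn <= 0:
        raise ValueError(f"max_rpn must be positive, got {max_rpn}")
    return max_rpn * (1.0 - confidence)


@dataclass
class RiskEntry:
    """One scored (process parameter, quality attribute) row."""

    parameter: str
    attribute: str
    severity: int
    occurrence: int
    detectability: int
    justification: str = ""
    permissive: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.rpn = compute_rpn(
            self.severity, self.occurrence, self.detectability,
            permissive=self.permissive,
        )
        self.level = classify_risk(self.rpn)


def pareto_summary(
    entries: Sequence[RiskEntry], confidence: float = 0.90
) -> pd.DataFrame:
    """Pareto table of RPN shares per process parameter.

    Within each parameter, rows are sorted by RPN descending (ties keep
    input order — stable sort), with per-row percentage of the parameter's
    RPN total, the cumulative percentage, and an ``above_threshold`` flag
    against :func:`pareto_threshold`.
    """
    if len(entries) == 0:
        raise ValueError("pareto_summary requires at least one entry")
    threshold = pareto_threshold(confidence=confidence)
    rows = []
    for order, e in enumerate(entries):
        rows.append(
            dict(parameter=e.parameter, attribute=e.attribute, rpn=e.rpn,
                 level=e.level, _order=order)
        )
    df = pd.DataFrame(rows)
    out = []
    for param, grp in df.groupby("parameter", sort=False):
        grp = grp.sort_values(["rpn", "_order"], ascending=[False, True],
                              kind="stable")
        total = grp["rpn"].sum()
        grp = grp.assign(
            pct_of_parameter=100.0 * grp["rpn"] / total,
            cumulative_pct=100.0 * grp["rpn"].cumsum() / total,
            above_threshold=grp["rpn"] > threshold,
        )
        out.append(grp)
    result = pd.concat(out, ignore_index=True).drop(columns="_order")
    result.attrs["threshold"] = threshold
    return result


def read_risk_register(path, *, permissive: bool = False) -> list[RiskEntry]:
    """Read a CSV register with columns parameter, attribute, S, P, D[, justification]."""
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    entries = []
    for _, row in df.iterrows():
        entries.append(
            RiskEntry(
                parameter=str(row["parameter"]),
                attribute=str(row["attribute"]),
                severity=int(row["S"]),
                occurrence=int(row["P"]),
                detectability=int(row["D"]),
                justification=str(row.get("justification", "") or ""),
                permissive=permissive,
            )
        )
    return entries


def score_register(entries: Iterable[RiskEntry]) -> pd.DataFrame:
    """Tabulate entries with their computed RPN and risk level."""
    return pd.DataFrame(
        [
            dict(parameter=e.parameter, attribute=e.attribute, S=e.severity,
                 P=e.occurrence, D=e.detectability, rpn=e.rpn, level=e.level,
                 justification=e.justification)
            for e in entries
        ]
    )


def write_risk_register(entries: Iterable[RiskEntry], path) -> None:
    """Write the scored register (input columns plus rpn and level)."""
    score_register(entries).to_csv(path, index=False)
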