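"""MELD-family severity scores.

A MELD-type score is an affine function of the natural logarithms of three
biomarkers — serum creatinine (mg/dL), serum total bilirubin (mg/dL) and the
INR — after clamping each biomarker to score-specific bounds and, for
patients on biweekly dialysis, substituting a fixed creatinine value::

    score = intercept + c_crea * log(crea) + c_bili * log(bili) + c_inr * log(INR)

Three definitions ship as built-ins:

* ``UNOS-MELD`` — the original allocation score (creatinine capped at 4.0,
  lower limit 1.0 on all biomarkers, dialysis -> creatinine 4.0);
* ``ReMELD`` — the earlier Eurotransplant re-estimation;
* ``DynReMELD`` — the cross-section/IPCW re-estimation implemented by this
  package.

Scores are continuous; :func:`round_score` provides the allocation-style
integer display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ScoreDefinition",
    "apply_caps",
    "compute_score",
    "compute_score_frame",
    "builtin_definitions",
    "component_weights",
    "round_score",
    "UNOS_MELD",
    "REMELD",
    "DYNREMELD",
]

_BIOMARKERS = ("creatinine", "bilirubin", "inr")


@dataclass(frozen=True)
class ScoreDefinition:
    """Parametrization of a MELD-family score.

    Parameters
    ----------
    name : str
        Display label.
    intercept : float
        Score points at the reference point (all log terms zero).
    coef_crea, coef_bili, coef_inr : float
        Score points per natural-log unit of the (capped) biomarker.
    bounds : mapping
        ``{"creatinine": (lo, hi), "bilirubin": (lo, hi), "inr": (lo, hi)}``;
        ``hi`` may be ``inf`` for an uncapped biomarker.
    dialysis_creatinine : float or None
        Creatinine value substituted for patients on biweekly dialysis
        (applied *before* capping); ``None`` means no substitution.
    """

    name: str
    intercept: float
    coef_crea: float
    coef_bili: float
    coef_inr: float
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {b: (0.0, math.inf) for b in _BIOMARKERS}
    )
    dialysis_creatinine: float | None = None

    def __post_init__(self) -> None:
        for b in _BIOMARKERS:
            lo, hi = self.bounds[b]
            if not lo < hi:
                raise ValueError(f"{self.name}: bounds for {b} must satisfy lower < upper")
        for c in (self.intercept, self.coef_crea, self.coef_bili, self.coef_inr):
            if not math.isfinite(c):
                raise ValueError(f"{self.name}: coefficients must be finite")

    @property
    def coefficients(self) -> dict[str, float]:
        return {
            "creatinine": self.coef_crea,
            "bilirubin": self.coef_bili,
            "inr": self.coef_inr,
        }


def apply_caps(value, bounds):
    """Clamp a biomarker value (scalar or array) to ``bounds = (lower, upper)``."""
    lo, hi = bounds
    return np.clip(value, lo, hi)


def _capped_logs(definition, creatinine, bilirubin, inr, dialysis):
    crea = np.asarray(creatinine, dtype=float)
    if definition.dialysis_creatinine is not None:
        crea = np.where(np.asarray(dialysis, dtype=bool), definition.dialysis_creatinine, crea)
    vals = {
        "creatinine": apply_caps(crea, definition.bounds["creatinine"]),
        "bilirubin": apply_caps(np.asarray(bilirubin, dtype=float), definition.bounds["bilirubin"]),
        "inr": apply_caps(np.asarray(inr, dtype=float), definition.bounds["inr"]),
    }
    for b, v in vals.items():
        if np.any(v <= 0):
            raise ValueError(f"non-positive {b} after capping; malformed definition or input")
    return {b: np.log(v) for b, v in vals.items()}


def compute_score(definition, creatinine, bilirubin, inr, dialysis=False):
    """Continuous (unrounded) score for one report or arrays of reports.

    The dialysis substitution is applied first, then the caps, then the
    log-linear formula with natural logarithms.
    """
    logs = _capped_logs(definition, creatinine, bilirubin, inr, dialysis)
    score = (
        definition.intercept
        + definition.coef_crea * logs["creatinine"]
        + definition.coef_bili * logs["bilirubin"]
        + definition.coef_inr * logs["inr"]
    )
    if np.ndim(score) == 0:
        return float(score)
    return score


def compute_score_frame(definition, reports: pd.DataFrame):
    """Vectorized :func:`compute_score` over a reports-shaped DataFrame."""
    return compute_score(
        definition,
        reports["creatinine"].to_numpy(),
        reports["bilirubin"].to_numpy(),
        reports["inr"].to_numpy(),
        reports["dialysis"].to_numpy(),
    )


def round_score(score):
    """Allocation-style integer score: nearest integer, halves up."""
    return np.floor(np.asarray(score, dtype=float) + 0.5).astype(int)


UNOS_MELD = ScoreDefinition(
    name="UNOS-MELD",
    intercept=6.43,
    coef_crea=9.57,
    coef_bili=3.78,
    coef_inr=11.20,
    bounds={
        "creatinine": (1.0, 4.0),
        "bilirubin": (1.0, math.inf),
        "inr": (1.0, math.inf),
    },
    dialysis_creatinine=4.0,
)

REMELD = ScoreDefinition(
    name="ReMELD",
    intercept=8.422,
    coef_crea=7.728,
    coef_bili=3.446,
    coef_inr=10.597,
    bounds={
        "creatinine": (0.7, 2.5),
        "bilirubin": (0.3, 27.0),
        "inr": (0.1, 2.6),
    },
    dialysis_creatinine=2.5,
)

DYNREMELD = ScoreDefinition(
    name="DynReMELD",
    intercept=8.50,
    coef_crea=9.12,
    coef_bili=4.14,
    coef_inr=9.42,
    bounds={
        "creatinine": (0.8, 2.5),
        "bilirubin": (0.6, 55.0),
        "inr": (1.0, 3.0),
    },
    dialysis_creatinine=2.5,
)


def builtin_definitions() -> dict[str, ScoreDefinition]:
    """The three published score equations, keyed by name."""
    return {d.name: d for d in (UNOS_MELD, REMELD, DYNREMELD)}


def component_weights(definition, reports: pd.DataFrame) -> dict[str, float]:
    """Relative biomarker weights over a cohort (Sharma-style).

    ``weight_k = coef_k * sd(log capped biomarker_k) / sum_j coef_j * sd(...)``
    — the score increase for a one-SD increase in biomarker *k* relative to a
    one-SD increase in every biomarker.
    """
    if len(reports) < 2:
        raise ValueError("component_weights requires at least 2 reports")
    logs = _capped_logs(
        definition,
        reports["creatinine"].to_numpy(),
        reports["bilirubin"].to_numpy(),
        reports["inr"].to_numpy(),
        reports["dialysis"].to_numpy() if "dialysis" in reports else False,
    )
    contrib = {}
    for b in _BIOMARKERS:
        sd = float(np.std(logs[b], ddof=1))
        if sd == 0:
            raise ValueError(f"zero variance in log {b}; weights undefined")
        contrib[b] = definition.coefficients[b] * sd
    total = sum(contrib.values())
    return {b: v / total for b, v in contrib.items()}
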