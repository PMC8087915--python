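"""Lesion-level objective response classification from longest diameters.

Applies RECIST-1.0-style rules to the longitudinal longest diameter of a
single lesion, yielding one of four classes:

* IRES  (intrinsic resistance)  — diameter at the first evaluation within the
  evaluation window (default 8 weeks) grew by >= 20% over baseline;
* PR    (partial response)      — the diameter fell by >= 30% from baseline
  at some point, with no subsequent regrowth;
* SD    (stable disease)        — shrinkage < 30% and growth < 20% over the
  running nadir throughout;
* ARES  (acquired resistance)   — a PR or SD phase followed by a measurement
  >= 20% above the smallest diameter seen so far (the nadir).

All thresholds are ratios of diameters, so the classification is invariant
to rescaling; the >= 20% and >= 30% bounds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RESPONSE_CLASSES = ("IRES", "PR", "SD", "ARES")

GROWTH_FACTOR = 1.20  # >= 20% increase over reference
SHRINK_FACTOR = 0.70  # >= 30% decrease from baseline


@dataclass
class LesionSeries:
    """Ordered (week, longest diameter in mm) measurements for one lesion."""

    lesion_id: str
    weeks: np.ndarray
    diameters_mm: np.ndarray

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=float)
        self.diameters_mm = np.asarray(self.diameters_mm, dtype=float)
        if self.weeks.shape != self.diameters_mm.shape:
            raise ValueError("weeks and diameters must have the same length")
        if len(self.weeks) < 2:
            raise ValueError("need at least baseline plus one follow-up")
        if self.weeks[0] != 0:
            raise ValueError("series must start with a week-0 baseline")
        if (np.diff(self.weeks) <= 0).any():
            raise ValueError("weeks must be strictly increasing")
        if (self.diameters_mm <= 0).any():
            raise ValueError("diameters must be positive")

    @property
    def baseline_mm(self) -> float:
        return float(self.diameters_mm[0])


@dataclass
class ResponseCall:
    response: str  # one of RESPONSE_CLASSES
    decisive_week: float
    nadir_mm: float


def classify_lesion(series: LesionSeries, eval_week: float = 8.0) -> ResponseCall:
    """Classify one lesion's response from its diameter trajectory.

    Rules are applied sequentially: the intrinsic-resistance check uses only
    the first post-baseline measurement, provided it falls at or before
    ``eval_week``; afterwards any measurement >= 1.2x the running nadir
    (baseline included) marks acquired resistance, and otherwise the best
    response (>= 30% shrinkage -> PR, else SD) decides.
    """
    baseline = series.baseline_mm
    weeks = series.weeks
    diam = series.diameters_mm

    # (1) intrinsic resistance at the first evaluation
    if weeks[1] <= eval_week and diam[1] >= GROWTH_FACTOR * baseline:
        return ResponseCall("IRES", float(weeks[1]), baseline)

    # (2) scan for regrowth over the running nadir
    nadir = baseline
    nadir_week = 0.0
    for w, d in zip(weeks[1:], diam[1:]):
        if d >= GROWTH_FACTOR * nadir:
            return ResponseCall("ARES", float(w), float(nadir))
        if d < nadir:
            nadir, nadir_week = float(d), float(w)

    # (3) best response
    if nadir <= SHRINK_FACTOR * baseline:
        return ResponseCall("PR", nadir_week, nadir)
    return ResponseCall("SD", float(weeks[-1]), nadir)
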