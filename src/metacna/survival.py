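"""Genome-wide permutation log-rank scan of CNA events against PFS.

For every region in an event matrix, carriers are compared with non-carriers
on progression-free survival using the chi-square-form log-rank statistic
(O - E)^2 / V with the aggregated hypergeometric variance for tied event
times. Significance comes from permuting the (time, event) pairs jointly
across samples — preserving the marginal censoring pattern — and comparing
permuted statistics to the observed one. A single shared permutation stream
serves all regions by default, which makes the scan O(B * (samples +
regions)) at the price of positively coupled region p-values; independent
per-region streams are available by flag.

The module also provides the Kaplan-Meier product-limit estimator used for
two-group survival displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .recurrence import EventMatrix


@dataclass
class SurvivalData:
    """Right-censored survival times: months to progression or censoring."""

    time: np.ndarray
    event: np.ndarray  # 1 = progression observed, 0 = censored
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have the same length")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class ScanConfig:
    B: int = 1999
    seed: int = 0
    alpha_perm: float = 0.005
    min_group: int = 3
    shared_stream: bool = True

    def __post_init__(self) -> None:
        if self.B < 1.0 / self.alpha_perm - 1:
            raise ValueError(
                f"B={self.B} cannot resolve the reporting threshold "
                f"{self.alpha_perm} (need B >= {1 / self.alpha_perm - 1:.0f})"
            )


@dataclass
class KMEstimate:
    """Product-limit survival estimate with at-risk table."""

    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float | None  # smallest time with S <= 0.5; None if never reached

    def survival_at(self, t: float) -> float:
        """Right-continuous step function; S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _risk_tables(time: np.ndarray, event: np.ndarray):
    """Distinct event times with pooled death counts and at-risk indicators.

    Returns (event_times, D, R, d, n) where D[j, t] marks sample j dying at
    event time t, R[j, t] marks sample j at risk at t, and d, n are their
    column sums.
    """
    te = np.unique(time[event == 1])
    D = (time[:, None] == te[None, :]) & (event[:, None] == 1)
    R = time[:, None] >= te[None, :]
    return te, D, R, D.sum(axis=0).astype(float), R.sum(axis=0).astype(float)


def _logrank_chi2(
    Z: np.ndarray, D: np.ndarray, R: np.ndarray, d: np.ndarray, n: np.ndarray
) -> np.ndarray:
    """Vectorized log-rank chi-square for many groupings at once.

    Z is a (regions x samples) boolean carrier matrix; D, R, d, n come from
    :func:`_risk_tables`. Ties are handled by the aggregated hypergeometric
    variance; regions with zero total variance score 0.
    """
    Zf = Z.astype(float)
    d1 = Zf @ D  # observed carrier deaths per event time
    n1 = Zf @ R  # carriers at risk per event time
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d * n1 / n
        frac = n1 / n
        v = np.where(n > 1, d * (n - d) / (n - 1) * frac * (1.0 - frac), 0.0)
    U = (d1 - expected).sum(axis=1)
    V = np.nan_to_num(v, nan=0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, U * U / V, 0.0)
    return chi2


def logrank_statistic(group_a: SurvivalData, group_b: SurvivalData) -> float:
    """Two-group log-rank statistic in chi-square form.

    Symmetric under swapping the groups; 0 when the grouping carries no
    information (identical groups, or no between-group variance at any event
    time). Requires at least one observed event overall.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    time = np.concatenate([group_a.time, group_b.time])
    event = np.concatenate([group_a.event, group_b.event])
    if event.sum() == 0:
        raise ValueError("no events in either group")
    Z = np.zeros((1, len(time)), dtype=bool)
    Z[0, : len(group_a)] = True
    te, D, R, d, n = _risk_tables(time, event)
    return float(_logrank_chi2(Z, D, R, d, n)[0])


def permutation_scan(
    matrix: "EventMatrix",
    survival: SurvivalData,
    config: ScanConfig | None = None,
    direction: str = "gain",
) -> pd.DataFrame:
    """Per-region permutation log-rank p-values.

    (time, event) pairs are permuted jointly across samples B times and the
    log-rank statistic of each permutation is compared with the observed one:
    p_r = (1 + #{perm >= obs}) / (B + 1). Regions with fewer than
    ``min_group`` carriers or non-carriers are reported untested (p = NaN).
    """
    config = config or ScanConfig()
    if survival.sample_ids is not None and list(survival.sample_ids) != list(
        matrix.samples
    ):
        raise ValueError("sample sets of event matrix and survival data differ")
    if len(survival) != len(matrix.samples):
        raise ValueError("survival data length does not match event matrix")
    if survival.event.sum() == 0:
        raise ValueError("no observed events")
    Z = matrix.events(direction)
    n_r, n_s = Z.shape
    carriers = Z.sum(axis=1)
    tested = (carriers >= config.min_group) & (n_s - carriers >= config.min_group)
    te, D, R, d, n = _risk_tables(survival.time, survival.event)
    obs = _logrank_chi2(Z, D, R, d, n)
    rng = np.random.default_rng(config.seed)
    exceed = np.zeros(n_r, dtype=int)
    # tolerance so permutations reproducing the observed partition (or its
    # complement, equal up to rounding) count as ties
    obs_tol = obs - 1e-9 * (1.0 + obs)
    if config.shared_stream:
        for _ in range(config.B):
            perm = rng.permutation(n_s)
            null = _logrank_chi2(Z, D[perm], R[perm], d, n)
            exceed += null >= obs_tol
    else:
        for r in np.flatnonzero(tested):
            Zr = Z[r : r + 1]
            for _ in range(config.B):
                perm = rng.permutation(n_s)
                exceed[r] += _logrank_chi2(Zr, D[perm], R[perm], d, n)[0] >= obs_tol[r]
    p = (1.0 + exceed) / (config.B + 1.0)
    out = matrix.regions.copy()
    out["direction"] = direction
    out["n_carriers"] = carriers
    out["statistic"] = obs
    out["tested"] = tested
    out["p_perm"] = np.where(tested, p, np.nan)
    out["significant"] = tested & (p <= config.alpha_perm)
    return out


def km_estimate(group: SurvivalData) -> KMEstimate:
    """Kaplan-Meier product-limit estimate.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times; censored
    subjects leave the risk set after their censoring time. The median is the
    smallest event time with S <= 0.5, undefined (None) when never reached.
    """
    if len(group) == 0:
        raise ValueError("empty survival data")
    te, D, R, d, n = _risk_tables(group.time, group.event)
    surv = np.cumprod(1.0 - d / n)
    below = np.flatnonzero(surv <= 0.5)
    median = float(te[below[0]]) if below.size else None
    return KMEstimate(
        times=te, survival=surv, at_risk=n, n_events=d, median=median
    )
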