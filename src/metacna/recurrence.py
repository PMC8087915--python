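"""GISTIC-style recurrence scoring of copy-number events across a cohort.

Regions are scored by a G-score — per-region mean of event amplitudes across
samples, amplitude capped to bound extreme focal amplifications — and tested
against a permutation null that cyclically shifts each sample's
event-amplitude track across the region grid. The cyclic shift preserves each
sample's event burden and segment autocorrelation, giving a conservative null
for segmented data. Empirical p-values are Benjamini-Hochberg adjusted into a
Q-bound; gains and losses are scored in separate passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparisons import bh_adjust

GAIN_CALLS = frozenset({"gain", "high_gain"})
LOSS_CALLS = frozenset({"loss", "homozygous_loss"})


@dataclass
class EventMatrix:
    """Regions x samples binary gain/loss events with segment amplitudes.

    ``regions`` is the union breakpoint grid of all samples' segments: sorted,
    non-overlapping intervals such that every sample's segmentation is
    constant within each region. ``amplitude`` holds |mean_log2| of the
    covering segment where a gain or loss event is present, 0 elsewhere.
    """

    regions: pd.DataFrame  # chrom, start, end
    samples: list[str]
    gain: np.ndarray  # bool, regions x samples
    loss: np.ndarray
    amplitude: np.ndarray  # float >= 0, regions x samples

    def __post_init__(self) -> None:
        r, s = len(self.regions), len(self.samples)
        for name in ("gain", "loss", "amplitude"):
            arr = getattr(self, name)
            if arr.shape != (r, s):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(r, s)}")
        if (self.amplitude < 0).any():
            raise ValueError("amplitudes must be non-negative")

    def events(self, direction: str) -> np.ndarray:
        if direction == "gain":
            return self.gain
        if direction == "loss":
            return self.loss
        raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")

    def carrier_counts(self, direction: str) -> np.ndarray:
        return self.events(direction).sum(axis=1)

    def to_table(self) -> pd.DataFrame:
        """Long-format TSV-ready view: one row per (region, sample) event."""
        r_idx, s_idx = np.nonzero(self.gain | self.loss)
        reg = self.regions.iloc[r_idx].reset_index(drop=True)
        return pd.DataFrame(
            {
                "chrom": reg["chrom"],
                "start": reg["start"],
                "end": reg["end"],
                "sample_id": [self.samples[j] for j in s_idx],
                "event": np.where(self.gain[r_idx, s_idx], "gain", "loss"),
                "amplitude": self.amplitude[r_idx, s_idx],
            }
        )


def build_event_matrix(segmentations: dict[str, pd.DataFrame]) -> EventMatrix:
    """Project called per-sample segmentations onto the union breakpoint grid.

    Parameters
    ----------
    segmentations
        Mapping sample_id -> called segment table (``chrom, start, end,
        mean_log2, call``). Segments of each sample must tile each chromosome.
    """
    if not segmentations:
        raise ValueError("no segmentations supplied")
    samples = sorted(segmentations)
    # union breakpoint grid per chromosome
    grid_rows = []
    chroms: dict[str, set[int]] = {}
    for seg in segmentations.values():
        for chrom, sub in seg.groupby("chrom", sort=False):
            pts = chroms.setdefault(str(chrom), set())
            pts.update(int(v) for v in sub["start"])
            pts.update(int(v) for v in sub["end"])
    for chrom in sorted(chroms):
        cuts = sorted(chroms[chrom])
        for a, b in zip(cuts[:-1], cuts[1:]):
            grid_rows.append({"chrom": chrom, "start": a, "end": b})
    regions = pd.DataFrame(grid_rows)
    n_r, n_s = len(regions), len(samples)
    gain = np.zeros((n_r, n_s), dtype=bool)
    loss = np.zeros((n_r, n_s), dtype=bool)
    amp = np.zeros((n_r, n_s), dtype=float)
    mids = ((regions["start"] + regions["end"]) / 2.0).to_numpy()
    for j, sample in enumerate(samples):
        seg = segmentations[sample]
        if "call" not in seg.columns:
            raise ValueError(f"segmentation for {sample!r} has no 'call' column")
        for chrom, sub in seg.groupby("chrom", sort=False):
            in_chrom = (regions["chrom"] == chrom).to_numpy()
            if not in_chrom.any():
                continue
            sub = sub.sort_values("start")
            idx = np.searchsorted(sub["start"].to_numpy(), mids[in_chrom], side="right") - 1
            idx = np.clip(idx, 0, len(sub) - 1)
            calls = sub["call"].to_numpy()[idx]
            means = sub["mean_log2"].to_numpy()[idx]
            covered = (mids[in_chrom] >= sub["start"].to_numpy()[idx]) & (
                mids[in_chrom] < sub["end"].to_numpy()[idx]
            )
            rows = np.flatnonzero(in_chrom)
            g = np.isin(calls, list(GAIN_CALLS)) & covered
            l = np.isin(calls, list(LOSS_CALLS)) & covered
            gain[rows, j] = g
            loss[rows, j] = l
            amp[rows, j] = np.where(g | l, np.abs(means), 0.0)
    return EventMatrix(regions=regions, samples=samples, gain=gain, loss=loss, amplitude=amp)


def gscore(matrix: EventMatrix, direction: str, cap: float = 2.0) -> np.ndarray:
    """Per-region G-score: mean over samples of capped event amplitude.

    G_r = (1/N) * sum_s min(amplitude_rs, cap) * event_rs. Invariant to sample
    order and linear in amplitude below the cap.
    """
    if len(matrix.samples) == 0:
        raise ValueError("empty event matrix")
    ev = matrix.events(direction)
    return (np.minimum(matrix.amplitude, cap) * ev).mean(axis=1)


def recurrence_significance(
    matrix: EventMatrix,
    direction: str,
    B: int = 999,
    seed: int = 0,
    cap: float = 2.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """G-score significance against a within-sample cyclic-shift null.

    Each of the B permutations independently rotates every sample's capped
    event-amplitude track by a uniform offset along the region grid; the
    empirical p for region r is (1 + #{null G_r >= observed G_r}) / (B + 1),
    BH-adjusted into the Q-bound. A region is significant at q <= 0.05 by
    default.
    """
    if B < 99:
        raise ValueError("need at least 99 permutations")
    if 1.0 / (B + 1) > q_threshold:
        warnings.warn(
            f"minimum attainable p {1/(B+1):.4g} exceeds q threshold {q_threshold}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    M = np.minimum(matrix.amplitude, cap) * matrix.events(direction)
    n_r, n_s = M.shape
    obs = M.mean(axis=1)
    exceed = np.zeros(n_r, dtype=int)
    rows = np.arange(n_r)[:, None]
    cols = np.arange(n_s)[None, :]
    obs_tol = obs - 1e-9 * (1.0 + obs)  # count rounding-level ties as exceedances
    for _ in range(B):
        shifts = rng.integers(0, n_r, size=n_s)
        null = M[(rows - shifts[None, :]) % n_r, cols].mean(axis=1)
        exceed += null >= obs_tol
    p = (1.0 + exceed) / (B + 1.0)
    q = bh_adjust(p)
    out = matrix.regions.copy()
    out["direction"] = direction
    out["n_events"] = matrix.carrier_counts(direction)
    out["G"] = obs
    out["p"] = p
    out["q"] = q
    out["significant"] = q <= q_threshold
    return out


def extract_focal_peaks(
    scores: pd.DataFrame,
    max_span_bp: int = 10_000_000,
    g_cutoff: float | None = None,
) -> pd.DataFrame:
    """Merge contiguous significant regions into peaks; drop broad runs.

    Maximal runs of adjacent significant grid regions (same chromosome,
    touching coordinates) are merged into one peak. Runs spanning more than
    ``max_span_bp`` are considered broad (arm-scale) rather than focal and
    are excluded. ``g_cutoff``, when given, additionally restricts peaks to
    those whose maximum G-score is <= the cutoff; the filter is off by
    default because its direction is ambiguous in common usage.
    """
    sig = scores[scores["significant"]].sort_values(["chrom", "start"])
    peaks = []
    run: list[pd.Series] = []

    def flush() -> None:
        if not run:
            return
        span = run[-1]["end"] - run[0]["start"]
        peaks.append(
            {
                "chrom": run[0]["chrom"],
                "start": int(run[0]["start"]),
                "end": int(run[-1]["end"]),
                "direction": run[0]["direction"],
                "n_regions": len(run),
                "span_bp": int(span),
                "max_G": max(r["G"] for r in run),
                "min_q": min(r["q"] for r in run),
                "broad": bool(span > max_span_bp),
            }
        )

    for _, row in sig.iterrows():
        if run and (row["chrom"] != run[-1]["chrom"] or row["start"] != run[-1]["end"]):
            flush()
            run = []
        run.append(row)
    flush()
    cols = [
        "chrom", "start", "end", "direction",
        "n_regions", "span_bp", "max_G", "min_q", "broad",
    ]
    out = pd.DataFrame(peaks, columns=cols)
    out = out.loc[~out["broad"].astype(bool)].drop(columns="broad").reset_index(drop=True)
    if g_cutoff is not None:
        out = out.loc[out["max_G"] <= g_cutoff].reset_index(drop=True)
    return out
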