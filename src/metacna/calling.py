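"""Copy-number calling from matched tumor/normal exome coverage.

Converts per-target read counts into median-centered log2 coverage ratios
(pseudo-CGH), segments them into piecewise-constant copy-number levels with a
recursive change-point search, assigns five-level calls, and computes
per-sample quality metrics (DLRS, fraction of genome altered).

Coordinates are 0-based half-open throughout this module; SEG export
(``metacna.io``) converts to 1-based inclusive at the boundary. Sex
chromosomes are removed at ingestion: coverage ratios on chrX/chrY are
confounded by patient sex and are excluded from every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})

TARGET_COLUMNS = ["target_id", "chrom", "start", "end"]

CALL_LEVELS = ["homozygous_loss", "loss", "neutral", "gain", "high_gain"]


@dataclass(frozen=True)
class CallThresholds:
    """log2-ratio cut points for the five-level call.

    Calls are inclusive at their boundary: a segment mean exactly at the gain
    threshold is called a gain.
    """

    hom_loss: float = -1.0
    loss: float = -0.2
    gain: float = 0.2
    high_gain: float = 1.0

    def validate(self) -> None:
        if not (self.hom_loss < self.loss < 0 < self.gain < self.high_gain):
            raise ValueError(
                "call thresholds must satisfy hom_loss < loss < 0 < gain < high_gain; "
                f"got {self}"
            )


@dataclass
class RatioTrack:
    """Per-target log2 tumor/normal coverage ratios for one sample."""

    sample_id: str
    targets: pd.DataFrame  # TARGET_COLUMNS, sorted, sex chromosomes removed
    log2: np.ndarray
    reference_kind: str = "matched"  # matched | pooled

    def __post_init__(self) -> None:
        self.log2 = np.asarray(self.log2, dtype=float)
        if len(self.log2) != len(self.targets):
            raise ValueError("log2 length does not match target map")
        if not np.all(np.isfinite(self.log2)):
            raise ValueError("non-finite log2 ratios")


@dataclass
class QCReport:
    sample_id: str
    dlrs: float
    n_segments: int
    fraction_genome_altered: float


def drop_sex_chromosomes(table: pd.DataFrame) -> pd.DataFrame:
    """Remove chrX/chrY rows from a coverage or target table."""
    return table[~table["chrom"].isin(SEX_CHROMS)].reset_index(drop=True)


def _check_target_map(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TARGET_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"coverage table missing columns: {missing}")
    if (table["start"] >= table["end"]).any():
        raise ValueError("target intervals must satisfy start < end")
    return table


def _same_target_map(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if len(a) != len(b):
        return False
    return bool(
        (a["target_id"].to_numpy() == b["target_id"].to_numpy()).all()
        and (a["start"].to_numpy() == b["start"].to_numpy()).all()
        and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
    )


def compute_log2_ratio(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    pseudocount: float = 1.0,
    sample_id: str = "sample",
    reference_kind: str = "matched",
) -> RatioTrack:
    """Matched tumor/normal log2 coverage ratio, total-scaled and median-centered.

    Both profiles are scaled to equal totals before the ratio, so global
    ploidy (a constant multiple of every tumor count) is unidentifiable by
    construction; the median of the returned ratios is 0.

    Parameters
    ----------
    tumor, normal
        Coverage tables with columns ``target_id, chrom, start, end, count``
        on identical target maps. Sex chromosomes are dropped here.
    pseudocount
        Added to both scaled counts before the log ratio; guards zero counts
        without materially biasing deep targets.
    """
    tumor = drop_sex_chromosomes(_check_target_map(tumor))
    normal = drop_sex_chromosomes(_check_target_map(normal))
    if not _same_target_map(tumor, normal):
        raise ValueError("tumor and normal coverage are on different target maps")
    t = tumor["count"].to_numpy(dtype=float)
    n = normal["count"].to_numpy(dtype=float)
    if (t < 0).any() or (n < 0).any():
        raise ValueError("negative counts")
    if n.sum() == 0:
        raise ValueError("all-zero normal profile")
    total = (t.sum() + n.sum()) / 2.0
    t_scaled = t * total / t.sum() if t.sum() > 0 else t
    n_scaled = n * total / n.sum()
    r = np.log2((t_scaled + pseudocount) / (n_scaled + pseudocount))
    r = r - np.median(r)
    return RatioTrack(
        sample_id=sample_id,
        targets=tumor[TARGET_COLUMNS].reset_index(drop=True),
        log2=r,
        reference_kind=reference_kind,
    )


def build_pooled_reference(normals: list[pd.DataFrame]) -> pd.DataFrame:
    """Synthetic reference profile: per-target mean of total-scaled normals.

    Used in place of a matched normal when none is available for a patient.
    Requires at least two normal profiles on a common target map.
    """
    if len(normals) < 2:
        raise ValueError("pooled reference requires at least 2 normal profiles")
    normals = [drop_sex_chromosomes(_check_target_map(n)) for n in normals]
    base = normals[0]
    for other in normals[1:]:
        if not _same_target_map(base, other):
            raise ValueError("normal profiles are on different target maps")
    counts = np.stack([n["count"].to_numpy(dtype=float) for n in normals])
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero normal profile in pool")
    target_total = totals.mean()
    scaled = counts * (target_total / totals)[:, None]
    out = base[TARGET_COLUMNS].copy()
    out["count"] = scaled.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Segmentation: recursive binary change-point search with permutation test
# ---------------------------------------------------------------------------


def _best_split(x: np.ndarray, min_targets: int) -> tuple[int, int, float]:
    """Best two-boundary split of ``x`` by the pooled two-sample t statistic.

    Scores every contiguous window x[i:j) against its complement (the
    circular-binary-style statistic, so interior focal events are directly
    comparable with their flanks; a window touching either end reduces to a
    single cut). Windows and complements shorter than ``min_targets`` are not
    considered. Returns (i, j, |t|), or (-1, -1, 0.0) when no admissible
    split exists. Zero pooled variance with unequal means scores +inf so
    noiseless steps are recovered exactly.
    """
    n = len(x)
    if n < 2 * min_targets:
        return -1, -1, 0.0
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    total, total2 = cs[-1], cs2[-1]
    i = np.arange(0, n - min_targets + 1)[:, None]
    j = np.arange(min_targets, n + 1)[None, :]
    n1 = (j - i).astype(float)
    valid = (n1 >= min_targets) & (n - n1 >= min_targets)
    n1 = np.where(valid, n1, np.nan)
    n2 = n - n1
    s1 = cs[j] - cs[i]
    q1 = cs2[j] - cs2[i]
    m1 = s1 / n1
    m2 = (total - s1) / n2
    ss = (q1 - n1 * m1 * m1) + ((total2 - q1) - n2 * m2 * m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled_var = ss / (n - 2) if n > 2 else np.full_like(ss, np.nan)
        se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        t = np.abs(m1 - m2) / se
    diff = np.abs(m1 - m2)
    t = np.where(se <= 1e-12, np.where(diff > 1e-12, np.inf, 0.0), t)
    t = np.where(valid, np.nan_to_num(t, nan=0.0, posinf=np.inf), -1.0)
    flat = int(np.argmax(t))
    bi, bj = np.unravel_index(flat, t.shape)
    return int(i[bi, 0]), int(j[0, bj]), float(t[bi, bj])


def _split_significant(
    x: np.ndarray,
    stat: float,
    min_targets: int,
    alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation p-value of the best split against within-segment shuffles.

    Stops early once enough permutations have matched the observed statistic
    to rule significance out; the decision is identical to running all
    ``n_permutations``.
    """
    if stat == 0.0:
        return False
    # p = (1+exceed)/(B+1) < alpha fails as soon as exceed reaches this bound
    give_up = alpha * (n_permutations + 1) - 1
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(x)
        _, _, perm_stat = _best_split(perm, min_targets)
        if perm_stat >= stat:
            exceed += 1
            if exceed >= give_up:
                return False
    return (1 + exceed) / (n_permutations + 1) < alpha


def _segment_chromosome(
    x: np.ndarray,
    alpha_split: float,
    min_targets: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Recursive binary splitting; returns half-open target-index spans."""
    spans: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        i, j, stat = _best_split(seg, min_targets)
        if i >= 0 and _split_significant(
            seg, stat, min_targets, alpha_split, n_permutations, rng
        ):
            for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                if b > a:
                    recurse(a, b)
        else:
            spans.append((lo, hi))

    recurse(0, len(x))
    spans.sort()
    return spans


def _merge_spans(
    x: np.ndarray, spans: list[tuple[int, int]], merge_delta: float
) -> list[tuple[int, int]]:
    """Merge adjacent segments whose means differ by less than merge_delta."""
    merged = [spans[0]]
    for lo, hi in spans[1:]:
        plo, phi = merged[-1]
        if abs(x[plo:phi].mean() - x[lo:hi].mean()) < merge_delta:
            merged[-1] = (plo, hi)
        else:
            merged.append((lo, hi))
    return merged


def segment_ratios(
    track: RatioTrack,
    alpha_split: float = 0.01,
    min_targets: int = 3,
    merge_delta: float = 0.1,
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment a ratio track into piecewise-constant copy-number levels.

    Per chromosome, recursively places the cut maximizing the two-sample
    t statistic between flanks; a cut is retained when its within-segment
    permutation p-value is below ``alpha_split``. Adjacent segments whose
    means differ by less than ``merge_delta`` are then merged, so the output
    segments tile each chromosome.

    Returns a segment table with columns
    ``sample_id, chrom, start, end, n_targets, mean_log2``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    targets = track.targets
    for chrom in targets["chrom"].unique():
        mask = (targets["chrom"] == chrom).to_numpy()
        x = track.log2[mask]
        sub = targets[mask]
        spans = _segment_chromosome(x, alpha_split, min_targets, n_permutations, rng)
        if merge_delta > 0 and len(spans) > 1:
            spans = _merge_spans(x, spans, merge_delta)
        starts = sub["start"].to_numpy()
        chrom_end = int(sub["end"].iloc[-1])
        for lo, hi in spans:
            # segments tile the chromosome: each ends where the next begins
            rows.append(
                {
                    "sample_id": track.sample_id,
                    "chrom": chrom,
                    "start": int(starts[lo]),
                    "end": int(starts[hi]) if hi < len(starts) else chrom_end,
                    "n_targets": hi - lo,
                    "mean_log2": float(x[lo:hi].mean()),
                }
            )
    return pd.DataFrame(rows)


def call_segments(
    segments: pd.DataFrame, thresholds: CallThresholds | None = None
) -> pd.DataFrame:
    """Assign the five-level call to each segment by its mean log2 ratio."""
    thresholds = thresholds or CallThresholds()
    thresholds.validate()
    m = segments["mean_log2"].to_numpy()
    call = np.full(len(m), "neutral", dtype=object)
    call[m <= thresholds.loss] = "loss"
    call[m <= thresholds.hom_loss] = "homozygous_loss"
    call[m >= thresholds.gain] = "gain"
    call[m >= thresholds.high_gain] = "high_gain"
    out = segments.copy()
    out["call"] = call
    return out


def qc_metrics(track: RatioTrack, segments: pd.DataFrame) -> QCReport:
    """Per-sample noise and aberration-burden metrics.

    DLRS (derivative log-ratio spread, the robust variance quality score) is
    the median absolute difference of adjacent same-chromosome log2 ratios
    divided by sqrt(2); chromosomes with a single target contribute nothing.
    Fraction of genome altered is the non-neutral base-pair share of the
    segmented span (requires a ``call`` column).
    """
    if len(track.log2) == 0:
        raise ValueError("empty ratio track")
    diffs = []
    for chrom in track.targets["chrom"].unique():
        x = track.log2[(track.targets["chrom"] == chrom).to_numpy()]
        if len(x) >= 2:
            diffs.append(np.abs(np.diff(x)))
    dlrs = float(np.median(np.concatenate(diffs)) / np.sqrt(2.0)) if diffs else 0.0
    if "call" not in segments.columns:
        raise ValueError("segments must be called before QC (missing 'call' column)")
    span = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    altered = span[(segments["call"] != "neutral").to_numpy()].sum()
    fga = float(altered / span.sum()) if span.sum() > 0 else 0.0
    return QCReport(
        sample_id=track.sample_id,
        dlrs=dlrs,
        n_segments=len(segments),
        fraction_genome_altered=fga,
    )
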