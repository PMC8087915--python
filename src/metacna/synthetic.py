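"""Synthetic longitudinal metastasis cohorts with known ground truth.

Emulates the data shape of a pre-/post-treatment liver-metastasis exome
cohort — per-target tumor and matched-normal read counts, a clinical table
with progression-free survival, a gene-level RNA count matrix, and lesion
diameter trajectories — with planted focal copy-number regions whose carrier
frequency may differ between timepoints and which may carry survival-hazard
and expression-dosage effects. Truth labels are returned (and written) in a
separate structure, never embedded in the analysis inputs, so recovery tests
cannot leak.

The generative model is deliberately simple: negative-binomial per-target
depths (Poisson in the zero-dispersion limit), exponential progression times
with independent exponential censoring and multiplicative hazards for
carried regions, and negative-binomial expression with a multiplicative
dosage effect on genes inside carried regions. Defaults mirror a cohort of
97 pre-treatment and 43 post-treatment samples with a median
progression-free survival near 9.7 months.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .lesions import LesionSeries

TARGET_WIDTH_BP = 120
TARGET_SPACING_BP = 10_000


@dataclass(frozen=True)
class TruthRegion:
    """A planted focal CNA with its clinical and transcriptional effects."""

    chrom: str
    start: int
    end: int
    direction: str  # gain | loss
    log2_shift: float  # expected segment log2 ratio, e.g. +0.58 for one extra copy
    freq_pre: float  # carrier probability among pre-treatment samples
    freq_post: float
    hazard_ratio: float = 1.0  # multiplicative effect on progression hazard
    expr_dosage: float = 1.0  # multiplier on mean expression of covered genes

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain or loss, got {self.direction!r}")
        if self.start >= self.end:
            raise ValueError("region start must precede end")
        if self.direction == "gain" and self.log2_shift <= 0:
            raise ValueError("gain regions need a positive log2 shift")
        if self.direction == "loss" and self.log2_shift >= 0:
            raise ValueError("loss regions need a negative log2 shift")
        for f in (self.freq_pre, self.freq_post):
            if not 0.0 <= f <= 1.0:
                raise ValueError("carrier frequencies must lie in [0, 1]")
        if self.hazard_ratio <= 0 or self.expr_dosage <= 0:
            raise ValueError("hazard ratio and expression dosage must be positive")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.direction}"


@dataclass
class CohortConfig:
    n_pre: int = 97
    n_post: int = 43
    n_chrom: int = 4
    targets_per_chrom: int = 150
    mean_depth: float = 150.0
    depth_dispersion: float = 0.05
    truth_regions: list[TruthRegion] = field(default_factory=list)
    baseline_hazard: float = float(np.log(2) / 9.7)  # per month
    censor_rate: float = 0.02  # per month, independent of progression
    nb_dispersion: float = 0.1
    n_genes: int = 400
    gene_length_range: tuple[int, int] = (500, 5000)
    expr_base_mean: float = 200.0
    bevacizumab_rate: float = 0.70
    regimen_probs: tuple[float, float, float] = (0.68, 0.22, 0.10)  # ox, iri, other
    seed: int = 0

    def validate(self) -> None:
        if self.n_pre + self.n_post < 1:
            raise ValueError("empty cohort")
        if self.n_chrom < 1 or self.targets_per_chrom < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if self.depth_dispersion < 0 or self.nb_dispersion < 0:
            raise ValueError("dispersions must be non-negative")
        if self.baseline_hazard <= 0 or self.censor_rate < 0:
            raise ValueError("baseline hazard must be positive, censor rate >= 0")
        chrom_len = self.targets_per_chrom * TARGET_SPACING_BP
        by_chrom: dict[str, list[TruthRegion]] = {}
        for reg in self.truth_regions:
            if reg.end > chrom_len:
                raise ValueError(f"region {reg.name} exceeds chromosome length {chrom_len}")
            by_chrom.setdefault(reg.chrom, []).append(reg)
        for regs in by_chrom.values():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs[:-1], regs[1:]):
                if b.start < a.end:
                    raise ValueError(f"truth regions {a.name} and {b.name} overlap")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SyntheticCohort:
    """Bundle of generated inputs plus ground-truth labels (kept separate)."""

    targets: pd.DataFrame  # target_id, chrom, start, end
    tumor_counts: pd.DataFrame  # targets x samples
    normal_counts: pd.DataFrame
    clinical: pd.DataFrame
    genes: pd.DataFrame  # gene_id, chrom, start, end, length
    expression: pd.DataFrame  # genes x samples
    truth_regions: pd.DataFrame
    carriers: pd.DataFrame  # truth regions x samples, bool
    config: CohortConfig


def _build_target_map(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for c in range(1, config.n_chrom + 1):
        chrom = f"chr{c}"
        for i in range(config.targets_per_chrom):
            start = i * TARGET_SPACING_BP
            rows.append(
                {
                    "target_id": f"{chrom}_t{i:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + TARGET_WIDTH_BP,
                }
            )
    return pd.DataFrame(rows)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = m + dispersion * m^2; Poisson at 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from one seeded stream.

    The same config and seed always produce identical outputs. Carrier status
    is drawn per sample and region with the timepoint-specific frequency;
    tumor depth inside carried regions is scaled by 2**log2_shift; the
    progression hazard is the baseline rate times the product of carried
    hazard ratios; expression means of genes inside carried regions are
    scaled by the region's dosage multiplier.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    targets = _build_target_map(config)
    n_pre, n_post = config.n_pre, config.n_post
    samples = [f"PRE{i+1:03d}" for i in range(n_pre)] + [
        f"POST{i+1:03d}" for i in range(n_post)
    ]
    timepoint = np.array(["pre"] * n_pre + ["post"] * n_post)

    regions = config.truth_regions
    n_s = len(samples)
    carrier = np.zeros((len(regions), n_s), dtype=bool)
    for k, reg in enumerate(regions):
        freq = np.where(timepoint == "pre", reg.freq_pre, reg.freq_post)
        carrier[k] = rng.random(n_s) < freq

    # per-target multiplicative copy shift for each sample
    in_region = np.zeros((len(regions), len(targets)), dtype=bool)
    mid = ((targets["start"] + targets["end"]) / 2).to_numpy()
    for k, reg in enumerate(regions):
        in_region[k] = (
            (targets["chrom"] == reg.chrom).to_numpy()
            & (mid >= reg.start)
            & (mid < reg.end)
        )
    shift = np.array([r.log2_shift for r in regions], dtype=float)

    tumor = np.empty((len(targets), n_s), dtype=int)
    normal = np.empty_like(tumor)
    for j in range(n_s):
        mult = np.ones(len(targets))
        for k in range(len(regions)):
            if carrier[k, j]:
                mult[in_region[k]] *= 2.0 ** shift[k]
        tumor[:, j] = _nb_counts(rng, config.mean_depth * mult, config.depth_dispersion)
        normal[:, j] = _nb_counts(
            rng, np.full(len(targets), config.mean_depth), config.depth_dispersion
        )
    tumor_counts = pd.DataFrame(tumor, index=targets["target_id"], columns=samples)
    normal_counts = pd.DataFrame(normal, index=targets["target_id"], columns=samples)

    # survival: exponential with multiplicative hazards, independent censoring
    hr = np.array([r.hazard_ratio for r in regions], dtype=float)
    log_rate = np.log(config.baseline_hazard) + (
        carrier.T @ np.log(hr) if len(regions) else np.zeros(n_s)
    )
    t_prog = rng.exponential(1.0 / np.exp(log_rate))
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n_s)
    else:
        t_cens = np.full(n_s, np.inf)
    pfs = np.minimum(t_prog, t_cens)
    event = (t_prog <= t_cens).astype(int)
    pfs = np.maximum(pfs, 1e-3)

    regimen = rng.choice(
        ["oxaliplatin-based", "irinotecan-based", "other"],
        size=n_s,
        p=list(config.regimen_probs),
    )
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "patient_id": [f"P{i+1:03d}" for i in range(n_s)],
            "timepoint": timepoint,
            "pfs_months": np.round(pfs, 3),
            "progression": event,
            "bevacizumab": (rng.random(n_s) < config.bevacizumab_rate).astype(int),
            "regimen": regimen,
        }
    )

    # gene map and expression counts
    chrom_len = config.targets_per_chrom * TARGET_SPACING_BP
    g_chrom = rng.integers(1, config.n_chrom + 1, size=config.n_genes)
    g_len = rng.integers(*config.gene_length_range, size=config.n_genes)
    g_start = rng.integers(0, chrom_len - config.gene_length_range[1], size=config.n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i+1:05d}" for i in range(config.n_genes)],
            "chrom": [f"chr{c}" for c in g_chrom],
            "start": g_start,
            "end": g_start + g_len,
            "length": g_len,
        }
    ).sort_values(["chrom", "start"], ignore_index=True)
    base_mean = rng.lognormal(np.log(config.expr_base_mean), 1.0, size=config.n_genes)
    g_mid = ((genes["start"] + genes["end"]) / 2).to_numpy()
    gene_in_region = np.zeros((len(regions), config.n_genes), dtype=bool)
    for k, reg in enumerate(regions):
        gene_in_region[k] = (
            (genes["chrom"] == reg.chrom).to_numpy()
            & (g_mid >= reg.start)
            & (g_mid < reg.end)
        )
    dosage = np.array([r.expr_dosage for r in regions], dtype=float)
    expr = np.empty((config.n_genes, n_s), dtype=int)
    for j in range(n_s):
        mult = np.ones(config.n_genes)
        for k in range(len(regions)):
            if carrier[k, j]:
                mult[gene_in_region[k]] *= dosage[k]
        expr[:, j] = _nb_counts(rng, base_mean * mult, config.nb_dispersion)
    expression = pd.DataFrame(expr, index=genes["gene_id"], columns=samples)

    truth_regions = pd.DataFrame([asdict(r) | {"name": r.name} for r in regions])
    carriers = pd.DataFrame(
        carrier, index=[r.name for r in regions], columns=samples
    )
    return SyntheticCohort(
        targets=targets,
        tumor_counts=tumor_counts,
        normal_counts=normal_counts,
        clinical=clinical,
        genes=genes,
        expression=expression,
        truth_regions=truth_regions,
        carriers=carriers,
        config=config,
    )


def default_truth_regions() -> list[TruthRegion]:
    """A small panel of planted regions exercising every downstream effect:
    a post-enriched gain, a recurrent gain with a survival hazard and dosage
    effect, and a background-frequency loss."""
    return [
        TruthRegion("chr1", 200_000, 500_000, "gain", 0.58, 0.02, 0.30,
                    expr_dosage=1.5),
        TruthRegion("chr2", 300_000, 600_000, "gain", 0.58, 0.40, 0.40,
                    hazard_ratio=3.0, expr_dosage=2.0),
        TruthRegion("chr3", 100_000, 400_000, "loss", -0.58, 0.25, 0.25,
                    expr_dosage=0.6),
    ]


# ---------------------------------------------------------------------------
# Lesion diameter trajectories
# ---------------------------------------------------------------------------


def generate_lesion_series(
    response_class: str,
    baseline_mm: float = 50.0,
    seed: int | np.random.Generator = 0,
    lesion_id: str = "lesion",
    eval_week: float = 8.0,
) -> LesionSeries:
    """Generate a diameter trajectory realizing the requested response class.

    The trajectory is built so that :func:`metacna.lesions.classify_lesion`
    recovers exactly the requested class; random margins keep draws away from
    the inclusive 20%/30% thresholds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if baseline_mm <= 0:
        raise ValueError("baseline diameter must be positive")
    b = float(baseline_mm)
    weeks = [0.0, eval_week, 2 * eval_week, 3 * eval_week, 4 * eval_week]
    if response_class == "IRES":
        d = [b, b * rng.uniform(1.25, 1.6)]
        for _ in weeks[2:]:
            d.append(d[-1] * rng.uniform(1.02, 1.2))
    elif response_class == "PR":
        d = [b, b * rng.uniform(0.75, 0.95), b * rng.uniform(0.50, 0.65)]
        nadir = d[-1]
        for _ in weeks[3:]:
            nxt = nadir * rng.uniform(0.95, 1.1)
            d.append(nxt)
            nadir = min(nadir, nxt)
    elif response_class == "SD":
        d = [b]
        nadir = b
        for _ in weeks[1:]:
            nxt = max(nadir * rng.uniform(0.92, 1.05), 0.72 * b)
            d.append(nxt)
            nadir = min(nadir, nxt)
    elif response_class == "ARES":
        if rng.random() < 0.5:  # PR phase then regrowth
            d = [b, b * rng.uniform(0.75, 0.95), b * rng.uniform(0.50, 0.65)]
        else:  # SD phase then regrowth
            d = [b, b * rng.uniform(0.75, 0.95), b * rng.uniform(0.75, 0.95)]
        nadir = min(d)
        d.append(nadir * rng.uniform(1.25, 1.5))
        for _ in weeks[len(d):]:
            d.append(d[-1] * rng.uniform(1.02, 1.2))
    else:
        raise ValueError(f"unknown response class {response_class!r}")
    return LesionSeries(lesion_id, np.array(weeks[: len(d)]), np.array(d))
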