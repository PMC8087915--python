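"""End-to-end orchestration: calls -> events -> recurrence -> comparisons ->
survival scan -> expression concordance, plus cross-cohort region overlap.

Each stage consumes the standard in-memory containers of the stage modules
and all intermediates can be written in exchange formats (SEG, BED, TSV,
JSON). Stage failures abort with a stage-identified error. Every report
records the seed and a configuration hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import calling, comparisons, expression, recurrence, survival
from .io import write_bed, write_seg
from .synthetic import SyntheticCohort

logger = logging.getLogger("metacna")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; module defaults are overridable."""

    seed: int = 0
    outdir: str | None = None
    # calling
    pseudocount: float = 1.0
    alpha_split: float = 0.01
    min_targets: int = 3
    merge_delta: float = 0.1
    n_split_permutations: int = 200
    call_thresholds: calling.CallThresholds = field(default_factory=calling.CallThresholds)
    # recurrence
    recurrence_B: int = 499
    amplitude_cap: float = 2.0
    q_threshold: float = 0.05
    # comparisons
    fisher_flag_threshold: float = 0.005
    # survival scan
    scan_B: int = 1999
    scan_alpha: float = 0.005
    scan_min_group: int = 3
    # expression
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.1
    rpkm_floor: float = 1.0
    skip_stages: tuple[str, ...] = ()

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisReport:
    segmentations: dict[str, pd.DataFrame]
    qc: pd.DataFrame
    event_matrix: recurrence.EventMatrix | None
    recurrence: dict[str, pd.DataFrame]
    focal_peaks: dict[str, pd.DataFrame]
    group_comparison: dict[str, pd.DataFrame]
    survival_scan: dict[str, pd.DataFrame]
    concordance: pd.DataFrame
    provenance: dict

    def significant_regions(self, analysis: str, direction: str) -> pd.DataFrame:
        table = getattr(self, analysis)[direction]
        flag = "flagged" if "flagged" in table.columns else "significant"
        return table[table[flag]].reset_index(drop=True)


def run_pipeline(cohort: SyntheticCohort, config: RunConfig | None = None) -> AnalysisReport:
    """Run every analysis stage on a cohort bundle.

    The cohort supplies coverage, clinical, and expression inputs (a
    synthetic cohort or any bundle with the same attributes). Stages listed
    in ``config.skip_stages`` are skipped; downstream stages that need them
    are skipped too.
    """
    config = config or RunConfig()
    clinical = cohort.clinical
    if clinical is None or len(clinical) == 0:
        raise PipelineError("validate", ValueError("empty clinical table"))
    if not set(cohort.tumor_counts.columns) <= set(clinical["sample_id"]):
        raise PipelineError(
            "validate", ValueError("coverage samples missing from clinical table")
        )
    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_samples": int(cohort.tumor_counts.shape[1]),
    }
    logger.info("run %s: %d samples", provenance["config_hash"], provenance["n_samples"])

    # --- calling ---
    segmentations: dict[str, pd.DataFrame] = {}
    qc_rows = []
    try:
        for j, sample in enumerate(cohort.tumor_counts.columns):
            tumor = cohort.targets.copy()
            tumor["count"] = cohort.tumor_counts[sample].to_numpy()
            normal = cohort.targets.copy()
            normal["count"] = cohort.normal_counts[sample].to_numpy()
            track = calling.compute_log2_ratio(
                tumor, normal, config.pseudocount, sample_id=sample
            )
            seg = calling.segment_ratios(
                track,
                alpha_split=config.alpha_split,
                min_targets=config.min_targets,
                merge_delta=config.merge_delta,
                n_permutations=config.n_split_permutations,
                seed=config.seed + j,
            )
            seg = calling.call_segments(seg, config.call_thresholds)
            segmentations[sample] = seg
            qc = calling.qc_metrics(track, seg)
            qc_rows.append(vars(qc))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("calling", exc) from exc
    qc_table = pd.DataFrame(qc_rows)
    logger.info("calling: %d samples segmented", len(segmentations))

    # --- event matrix ---
    try:
        matrix = recurrence.build_event_matrix(segmentations)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("events", exc) from exc
    logger.info("events: %d grid regions", len(matrix.regions))

    # --- recurrence ---
    recur: dict[str, pd.DataFrame] = {}
    peaks: dict[str, pd.DataFrame] = {}
    if "recurrence" not in config.skip_stages:
        try:
            for direction in ("gain", "loss"):
                scores = recurrence.recurrence_significance(
                    matrix,
                    direction,
                    B=config.recurrence_B,
                    seed=config.seed,
                    cap=config.amplitude_cap,
                    q_threshold=config.q_threshold,
                )
                recur[direction] = scores
                peaks[direction] = recurrence.extract_focal_peaks(scores)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("recurrence", exc) from exc

    # --- group comparison (pre vs post) ---
    group_cmp: dict[str, pd.DataFrame] = {}
    if "compare" not in config.skip_stages:
        try:
            labels = clinical.set_index("sample_id")["timepoint"]
            for direction in ("gain", "loss"):
                group_cmp[direction] = comparisons.fisher_scan(
                    matrix, labels, direction, config.fisher_flag_threshold
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("compare", exc) from exc

    # --- survival scan ---
    surv_scan: dict[str, pd.DataFrame] = {}
    if "survscan" not in config.skip_stages and "pfs_months" in clinical.columns:
        try:
            clin = clinical.set_index("sample_id").loc[list(matrix.samples)]
            surv = survival.SurvivalData(
                clin["pfs_months"].to_numpy(),
                clin["progression"].to_numpy(),
                sample_ids=list(matrix.samples),
            )
            scan_cfg = survival.ScanConfig(
                B=config.scan_B,
                seed=config.seed,
                alpha_perm=config.scan_alpha,
                min_group=config.scan_min_group,
            )
            for direction in ("gain", "loss"):
                surv_scan[direction] = survival.permutation_scan(
                    matrix, surv, scan_cfg, direction
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("survscan", exc) from exc

    # --- expression concordance on flagged regions ---
    concordance = pd.DataFrame()
    if "integrate" not in config.skip_stages and cohort.expression is not None:
        try:
            concordance = _concordance_stage(cohort, matrix, group_cmp, surv_scan, config)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("integrate", exc) from exc

    report = AnalysisReport(
        segmentations=segmentations,
        qc=qc_table,
        event_matrix=matrix,
        recurrence=recur,
        focal_peaks=peaks,
        group_comparison=group_cmp,
        survival_scan=surv_scan,
        concordance=concordance,
        provenance=provenance,
    )
    if config.outdir:
        _write_report(report, Path(config.outdir))
    return report


def _selected_regions(
    group_cmp: dict[str, pd.DataFrame], surv_scan: dict[str, pd.DataFrame]
) -> list[tuple[str, str, int, int]]:
    """Regions flagged by the group comparison or the survival scan."""
    selected = []
    for direction, table in group_cmp.items():
        for _, row in table[table["flagged"]].iterrows():
            selected.append((direction, row["chrom"], int(row["start"]), int(row["end"])))
    for direction, table in surv_scan.items():
        sig = table[table["significant"]] if "significant" in table.columns else table.iloc[:0]
        for _, row in sig.iterrows():
            selected.append((direction, row["chrom"], int(row["start"]), int(row["end"])))
    return sorted(set(selected))


def _concordance_stage(
    cohort: SyntheticCohort,
    matrix: recurrence.EventMatrix,
    group_cmp: dict[str, pd.DataFrame],
    surv_scan: dict[str, pd.DataFrame],
    config: RunConfig,
) -> pd.DataFrame:
    genes = cohort.genes
    g_mid = ((genes["start"] + genes["end"]) / 2).to_numpy()
    lengths = genes.set_index("gene_id")["length"]
    results = []
    region_keys = (
        (matrix.regions["chrom"].astype(str)
         + ":" + matrix.regions["start"].astype(str)
         + "-" + matrix.regions["end"].astype(str))
        .to_numpy()
    )
    for direction, chrom, start, end in _selected_regions(group_cmp, surv_scan):
        in_reg = (
            (matrix.regions["chrom"] == chrom)
            & (matrix.regions["start"] == start)
            & (matrix.regions["end"] == end)
        )
        if not in_reg.any():
            continue
        r = int(np.flatnonzero(in_reg)[0])
        carriers = [s for s, c in zip(matrix.samples, matrix.events(direction)[r]) if c]
        gene_mask = (genes["chrom"] == chrom).to_numpy() & (g_mid >= start) & (g_mid < end)
        gene_ids = genes.loc[gene_mask, "gene_id"].tolist()
        if len(gene_ids) == 0 or len(carriers) < 2:
            continue
        res = expression.region_concordance(
            cohort.expression,
            lengths,
            gene_ids,
            carriers,
            direction,
            region=region_keys[r],
            fc_threshold=config.fc_threshold,
            fdr_threshold=config.fdr_threshold,
            rpkm_floor=config.rpkm_floor,
        )
        res = res.reset_index(names="gene_id")
        results.append(res)
    if not results:
        return pd.DataFrame()
    return pd.concat(results, ignore_index=True)


def _write_report(report: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    all_segs = pd.concat(report.segmentations.values(), ignore_index=True)
    write_seg(all_segs, outdir / "segments.seg")
    report.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    for direction, table in report.recurrence.items():
        table.to_csv(outdir / f"recurrence_{direction}.tsv", sep="\t", index=False)
    for direction, table in report.focal_peaks.items():
        if len(table):
            write_bed(table, outdir / f"focal_peaks_{direction}.bed")
    for direction, table in report.group_comparison.items():
        table.to_csv(outdir / f"group_comparison_{direction}.tsv", sep="\t", index=False)
    for direction, table in report.survival_scan.items():
        table.to_csv(outdir / f"survival_scan_{direction}.tsv", sep="\t", index=False)
    if len(report.concordance):
        report.concordance.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    (outdir / "report.json").write_text(
        json.dumps(
            report.provenance
            | {
                "n_regions": len(report.event_matrix.regions)
                if report.event_matrix is not None
                else 0,
                "n_concordant": int(report.concordance["concordant"].sum())
                if len(report.concordance)
                else 0,
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# Cross-cohort region overlap
# ---------------------------------------------------------------------------


def intersect_regions(
    set_a: pd.DataFrame, set_b: pd.DataFrame, min_overlap_bp: int = 1
) -> pd.DataFrame:
    """Pairs of regions from two interval sets overlapping by at least
    ``min_overlap_bp`` base pairs (intervals 0-based half-open).

    Used for cross-cohort validation: how many regions found in one cohort
    recur in an independent one.
    """
    for name, s in (("A", set_a), ("B", set_b)):
        if (s["start"] >= s["end"]).any():
            raise ValueError(f"malformed intervals in set {name}")
    trees: dict[str, IntervalTree] = {}
    for j, row in set_b.reset_index(drop=True).iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(row["start"], row["end"], j)
    pairs = []
    for i, row in set_a.reset_index(drop=True).iterrows():
        for hit in trees.get(row["chrom"], IntervalTree()).overlap(row["start"], row["end"]):
            overlap = min(row["end"], hit.end) - max(row["start"], hit.begin)
            if overlap >= min_overlap_bp:
                pairs.append(
                    {
                        "index_a": i,
                        "index_b": hit.data,
                        "chrom": row["chrom"],
                        "overlap_bp": int(overlap),
                    }
                )
    return pd.DataFrame(pairs, columns=["index_a", "index_b", "chrom", "overlap_bp"])


def overlap_counts(
    set_a: pd.DataFrame, set_b: pd.DataFrame, min_overlap_bp: int = 1
) -> dict:
    """Summary of :func:`intersect_regions`: how many A regions have at least
    one partner in B, and the corresponding validation fraction."""
    pairs = intersect_regions(set_a, set_b, min_overlap_bp)
    n_matched = pairs["index_a"].nunique() if len(pairs) else 0
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_a_matched": int(n_matched),
        "fraction_a_matched": n_matched / len(set_a) if len(set_a) else float("nan"),
    }
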