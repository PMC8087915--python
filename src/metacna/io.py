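"""Readers and writers for the exchange formats used by the pipeline.

SEG is tab-separated (sample, chrom, start, end, n_markers, mean_log2) with
1-based inclusive coordinates on disk; BED is 0-based half-open. Internally
everything is 0-based half-open, so conversion happens exactly here.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "n_targets", "mean_log2"]


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    """Write a segment table (0-based half-open) as SEG (1-based inclusive)."""
    out = segments.copy()
    out["start"] = out["start"] + 1
    cols = [c for c in SEG_COLUMNS if c in out.columns] + [
        c for c in ("call",) if c in out.columns
    ]
    out[cols].to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG file into the internal 0-based half-open convention."""
    seg = pd.read_csv(path, sep="\t")
    seg.columns = [c.strip().lower() for c in seg.columns]
    rename = {
        "sample": "sample_id", "id": "sample_id", "chromosome": "chrom",
        "loc.start": "start", "loc.end": "end",
        "num.mark": "n_targets", "num_mark": "n_targets",
        "seg.mean": "mean_log2", "seg_mean": "mean_log2",
    }
    seg = seg.rename(columns=rename)
    missing = {"sample_id", "chrom", "start", "end", "mean_log2"} - set(seg.columns)
    if missing:
        raise ValueError(f"SEG file missing columns: {sorted(missing)}")
    seg["start"] = seg["start"].astype(int) - 1
    seg["end"] = seg["end"].astype(int)
    return seg


def write_bed(regions: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    out = regions[["chrom", "start", "end"]].copy()
    if name_col is not None and name_col in regions.columns:
        out["name"] = regions[name_col]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :4] if bed.shape[1] >= 4 else bed.iloc[:, :3]
    bed.columns = ["chrom", "start", "end", "name"][: bed.shape[1]]
    if (bed["start"] >= bed["end"]).any():
        raise ValueError("malformed BED intervals (start >= end)")
    return bed


def write_coverage(
    targets: pd.DataFrame, counts: pd.Series, path: str | Path
) -> None:
    out = targets[["target_id", "chrom", "start", "end"]].copy()
    out["count"] = counts.reindex(targets["target_id"]).to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_coverage(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t")
    missing = {"target_id", "chrom", "start", "end", "count"} - set(cov.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    return cov


def read_clinical(path: str | Path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t")
    if clin.empty:
        raise ValueError("clinical table is empty")
    if "sample_id" not in clin.columns:
        raise ValueError("clinical table needs a sample_id column")
    return clin


def write_cohort(cohort, outdir: str | Path) -> dict[str, str]:
    """Write a synthetic cohort as plain-text analysis inputs plus truth files.

    Truth labels go to their own files (truth_regions.bed/.json,
    truth_carriers.tsv) and never into the analysis inputs. Returns a
    manifest of written paths; the manifest records the config hash and seed.
    """
    outdir = Path(outdir)
    (outdir / "coverage").mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for sample in cohort.tumor_counts.columns:
        for kind, table in (("tumor", cohort.tumor_counts), ("normal", cohort.normal_counts)):
            p = outdir / "coverage" / f"{sample}.{kind}.tsv"
            write_coverage(cohort.targets, table[sample], p)
    paths["coverage_dir"] = str(outdir / "coverage")
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    paths["clinical"] = str(outdir / "clinical.tsv")
    cohort.expression.to_csv(outdir / "expression_counts.tsv", sep="\t")
    paths["expression"] = str(outdir / "expression_counts.tsv")
    cohort.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    paths["genes"] = str(outdir / "genes.tsv")
    write_bed(cohort.truth_regions, outdir / "truth_regions.bed", name_col="name")
    cohort.carriers.to_csv(outdir / "truth_carriers.tsv", sep="\t")
    truth = {
        "seed": cohort.config.seed,
        "config_hash": cohort.config.config_hash(),
        "regions": cohort.truth_regions.to_dict(orient="records"),
    }
    (outdir / "truth_regions.json").write_text(json.dumps(truth, indent=2))
    paths["truth"] = str(outdir / "truth_regions.json")
    manifest = {"seed": cohort.config.seed, "config_hash": cohort.config.config_hash()}
    (outdir / "manifest.json").write_text(json.dumps(manifest | paths, indent=2))
    return paths
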