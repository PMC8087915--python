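import numpy as np
import pandas as pd
import pytest

import metacna as m


def make_track(values, chrom="chr1", sample_id="s1", spacing=1000, width=100):
    """Ratio track on a uniform synthetic target map."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    targets = pd.DataFrame(
        {
            "target_id": [f"{chrom}_t{i}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * spacing,
            "end": np.arange(n) * spacing + width,
        }
    )
    return m.RatioTrack(sample_id, targets, values)


def coverage_tables(cohort, sample):
    """Tumor and normal coverage tables for one sample of a cohort."""
    tumor = cohort.targets.copy()
    tumor["count"] = cohort.tumor_counts[sample].to_numpy()
    normal = cohort.targets.copy()
    normal["count"] = cohort.normal_counts[sample].to_numpy()
    return tumor, normal


def event_matrix_from_arrays(gain, loss=None, amplitude=None, chrom="chr1"):
    """EventMatrix on a uniform grid from raw boolean arrays."""
    gain = np.asarray(gain, dtype=bool)
    n_r, n_s = gain.shape
    loss = np.zeros_like(gain) if loss is None else np.asarray(loss, dtype=bool)
    if amplitude is None:
        amplitude = np.where(gain | loss, 0.5, 0.0)
    regions = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_r) * 1000,
            "end": np.arange(n_r) * 1000 + 1000,
        }
    )
    return m.EventMatrix(
        regions=regions,
        samples=[f"s{i:03d}" for i in range(n_s)],
        gain=gain,
        loss=loss,
        amplitude=np.asarray(amplitude, dtype=float),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with one post-enriched gain, one hazard/dosage gain,
    and one loss; reused by read-only tests."""
    config = m.CohortConfig(
        n_pre=30,
        n_post=20,
        n_chrom=2,
        targets_per_chrom=60,
        truth_regions=[
            m.TruthRegion("chr1", 100_000, 300_000, "gain", 0.58, 0.05, 0.50,
                          expr_dosage=2.0),
            m.TruthRegion("chr2", 200_000, 400_000, "loss", -0.58, 0.30, 0.30),
        ],
        n_genes=150,
        seed=7,
    )
    return m.generate_cohort(config)
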