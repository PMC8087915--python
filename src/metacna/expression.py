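"""Transcript-dosage validation of copy-number events.

A copy-number gain or loss is called transcriptionally concordant when the
genes it covers shift expression in the same direction in event carriers.
Per gene, carriers and non-carriers are compared with a negative-binomial
likelihood-ratio test (method-of-moments dispersion pooled across groups,
library-size offsets), and the concordance rule requires an expression floor
(mean AND median > 1 RPKM in the higher-expressing group), a fold change
beyond 1.5 in the direction of the event, and FDR < 0.1.

The NB machinery is implemented directly because the dispersion/LRT recipe is
part of the defined analysis procedure; its calibration is checked by
simulation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .comparisons import bh_adjust

DISPERSION_FLOOR = 1e-8


@dataclass
class ConcordanceResult:
    gene_id: str
    region: str | None
    direction: str  # direction of the CNA: gain | loss
    fc: float  # carrier / non-carrier mean normalized expression
    p: float
    fdr: float | None
    mean_rpkm: float  # in the higher-expressing group
    median_rpkm: float
    concordant: bool | None = None


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    rpkm = 1e9 * count / (length_bp * library_size); library sizes default to
    column totals of ``counts`` (genes x samples).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return 1e9 * counts.div(lengths, axis=0).div(library_sizes, axis=1)


# ---------------------------------------------------------------------------
# Negative-binomial likelihood-ratio test
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-wise NB(size r, mean mu) log-likelihood; y, mu are genes x samples."""
    return (
        special.gammaln(y + r[:, None])
        - special.gammaln(r[:, None])
        - special.gammaln(y + 1.0)
        + r[:, None] * np.log(r[:, None] / (r[:, None] + mu))
        + y * np.log(np.where(y > 0, mu / (r[:, None] + mu), 1.0))
    ).sum(axis=1)


def _nb_fit_mu(y: np.ndarray, s: np.ndarray, r: np.ndarray) -> np.ndarray:
    """MLE of the per-gene mean mu with fixed size r and offsets s.

    Model: y_gj ~ NB(mean mu_g * s_j, size r_g). Newton iteration on
    log(mu), vectorized over genes; the Poisson solution sum(y)/sum(s) seeds
    it and is exact in the r -> inf limit.
    """
    mu = np.maximum(y.sum(axis=1) / s.sum(), 1e-12)
    for _ in range(50):
        m = mu[:, None] * s[None, :]
        w = (y + r[:, None]) * s[None, :] / (m + r[:, None])
        grad = (y / mu[:, None] - w).sum(axis=1) * mu  # d loglik / d log(mu)
        hess = -(w * r[:, None] / (m + r[:, None])).sum(axis=1) * mu
        step = np.where(hess < 0, grad / hess, 0.0)
        step = np.clip(step, -2.0, 2.0)
        new = mu * np.exp(-step)
        if np.max(np.abs(np.log(new / mu))) < 1e-10:
            mu = new
            break
        mu = new
    return mu


def _moments_dispersion(y: np.ndarray, s: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Within-group variance of y/s is pooled across the two groups and matched
    to mean + phi * mean^2; floored at DISPERSION_FLOOR.
    """
    z = y / s[None, :]
    var = np.zeros(y.shape[0])
    dof = 0
    for g in np.unique(groups):
        zg = z[:, groups == g]
        if zg.shape[1] >= 2:
            var += zg.var(axis=1, ddof=1) * (zg.shape[1] - 1)
            dof += zg.shape[1] - 1
    var /= max(dof, 1)
    mean = z.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var - mean) / (mean * mean)
    phi = np.where(np.isfinite(phi), phi, 0.0)
    return np.maximum(phi, DISPERSION_FLOOR)


def nb_test(
    counts_carriers: pd.DataFrame,
    counts_noncarriers: pd.DataFrame,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene negative-binomial test between carriers and non-carriers.

    Returns a table indexed by gene with columns ``fc`` (ratio of
    library-size-normalized group means, carriers over non-carriers) and
    ``p`` (two-sided NB likelihood-ratio test of equal means with
    method-of-moments dispersion shared between null and alternative).
    Requires at least two samples per group.
    """
    if counts_carriers.shape[1] < 2 or counts_noncarriers.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    if not counts_carriers.index.equals(counts_noncarriers.index):
        raise ValueError("gene sets differ between groups")
    y = np.concatenate(
        [counts_carriers.to_numpy(float), counts_noncarriers.to_numpy(float)], axis=1
    )
    n_a = counts_carriers.shape[1]
    groups = np.array([0] * n_a + [1] * (y.shape[1] - n_a))
    if library_sizes is None:
        lib = y.sum(axis=0)
    else:
        lib = pd.concat(
            [
                library_sizes.reindex(counts_carriers.columns),
                library_sizes.reindex(counts_noncarriers.columns),
            ]
        ).to_numpy(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    s = lib / lib.mean()
    phi = _moments_dispersion(y, s, groups)
    r = 1.0 / phi
    mu0 = _nb_fit_mu(y, s, r)
    mu_a = _nb_fit_mu(y[:, groups == 0], s[groups == 0], r)
    mu_b = _nb_fit_mu(y[:, groups == 1], s[groups == 1], r)
    ll0 = _nb_loglik(y, mu0[:, None] * s[None, :], r)
    ll1 = _nb_loglik(y[:, groups == 0], mu_a[:, None] * s[None, groups == 0], r) + _nb_loglik(
        y[:, groups == 1], mu_b[:, None] * s[None, groups == 1], r
    )
    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    mean_a = (y[:, groups == 0] / s[None, groups == 0]).mean(axis=1)
    mean_b = (y[:, groups == 1] / s[None, groups == 1]).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
    return pd.DataFrame(
        {"fc": fc, "p": p, "mean_carriers": mean_a, "mean_noncarriers": mean_b},
        index=counts_carriers.index,
    )


def concordance_call(
    direction: str,
    fc: float,
    fdr: float,
    mean_rpkm: float,
    median_rpkm: float,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.1,
    rpkm_floor: float = 1.0,
) -> bool:
    """The copy-number / expression concordance rule.

    Concordant iff the gene clears the expression floor (mean AND median RPKM
    above ``rpkm_floor``, evaluated in the higher-expressing group), the FDR
    is below threshold, and the fold change exceeds the threshold in the
    direction of the CNA (strictly: fc > 1.5 for gains, fc < 1/1.5 for
    losses).
    """
    if direction not in ("gain", "loss"):
        raise ValueError(f"unknown CNA direction {direction!r}")
    if fc <= 0:
        raise ValueError("fold change must be positive")
    floor_ok = (mean_rpkm > rpkm_floor) and (median_rpkm > rpkm_floor)
    fdr_ok = fdr < fdr_threshold
    fc_ok = fc > fc_threshold if direction == "gain" else fc < 1.0 / fc_threshold
    return bool(floor_ok and fdr_ok and fc_ok)


def region_concordance(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    genes_in_region: list[str],
    carriers: list[str],
    direction: str,
    region: str | None = None,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.1,
    rpkm_floor: float = 1.0,
) -> pd.DataFrame:
    """Test every gene in a CNA region for dosage concordance.

    ``counts`` is genes x samples; ``carriers`` names the samples bearing the
    event. FDR is computed by BH over the genes tested here (the per-analysis
    region set). Returns a table with fc, p, fdr, RPKM floor values and the
    concordant flag.
    """
    carriers = [c for c in carriers if c in counts.columns]
    noncarriers = [c for c in counts.columns if c not in carriers]
    if len(carriers) < 2 or len(noncarriers) < 2:
        raise ValueError("need at least 2 carriers and 2 non-carriers")
    genes = [g for g in genes_in_region if g in counts.index]
    if not genes:
        return pd.DataFrame(
            columns=["fc", "p", "fdr", "mean_rpkm", "median_rpkm", "concordant"]
        )
    lib = counts.sum(axis=0)
    res = nb_test(counts.loc[genes, carriers], counts.loc[genes, noncarriers], lib)
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    rpkm = compute_rpkm(counts.loc[genes], gene_lengths, lib)
    rpkm_a, rpkm_b = rpkm[carriers], rpkm[noncarriers]
    higher_is_a = res["fc"] >= 1.0
    res["mean_rpkm"] = np.where(higher_is_a, rpkm_a.mean(axis=1), rpkm_b.mean(axis=1))
    res["median_rpkm"] = np.where(
        higher_is_a, rpkm_a.median(axis=1), rpkm_b.median(axis=1)
    )
    res["region"] = region
    res["direction"] = direction
    res["concordant"] = [
        concordance_call(
            direction,
            row.fc,
            row.fdr,
            row.mean_rpkm,
            row.median_rpkm,
            fc_threshold,
            fdr_threshold,
            rpkm_floor,
        )
        for row in res.itertuples()
    ]
    return res
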