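"""Probe quality control against RNA-Seq.

Every microarray probe is scored by the Pearson correlation, across a set
of training samples, between its log2 intensities and the log2 TPM of the
gene it is annotated to.  The correlation p-value (one-sided for positive
correlation by default, from the t statistic ``r*sqrt((n-2)/(1-r^2))``) is
converted to a Storey q-value, and a probe passes when its correlation is
positive and ``q < q_threshold`` (default 0.1).  Per gene, the probes with
the maximal / minimal correlation and the maximal mean expression across
regions are designated *best* / *worst* / *highest*.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    ExpressionMatrix,
    ProbeAnnotation,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "QCConfig",
    "probe_correlation",
    "qvalues",
    "estimate_pi0",
    "assign_pass",
    "designate_probes",
    "flag_bright_probes",
    "region_mean_matrix",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class QCConfig:
    """Thresholds of the probe pass/fail rule."""

    q_threshold: float = 0.1
    side: str = "one_sided_positive"  # or "two_sided"
    min_train_samples: int = 3
    pi0_method: str = "grid"  # or "fixed" (pi0 := 1, BH-equivalent)

    def __post_init__(self) -> None:
        if not 0.0 < self.q_threshold < 1.0:
            raise ValidationError("q_threshold must be in (0, 1)")
        if self.side not in ("one_sided_positive", "two_sided"):
            raise ValidationError(f"unknown side {self.side!r}")
        if self.min_train_samples < 3:
            raise ValidationError("min_train_samples must be >= 3")


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r per row; NaN where either row has zero variance."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r = np.where(denom > 0, r, np.nan)
    return np.clip(r, -1.0, 1.0)


def correlation_pvalue(
    r: np.ndarray, n: int, side: str = "one_sided_positive"
) -> np.ndarray:
    """p-value of Pearson r from the t distribution with n-2 df.

    Undefined correlations (NaN) map to p = 1.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r ** 2, 1e-300, None))
    if side == "one_sided_positive":
        p = stats.t.sf(t, df=n - 2)
    elif side == "two_sided":
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    else:
        raise ValidationError(f"unknown side {side!r}")
    p = np.where(np.isnan(r), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def probe_correlation(
    array_log2: ExpressionMatrix,
    seq_log2: ExpressionMatrix,
    annot: ProbeAnnotation,
    train_samples: list[str],
    side: str = "one_sided_positive",
) -> pd.DataFrame:
    """Correlate each probe with its gene's RNA-Seq profile.

    Returns a DataFrame with columns ``probe_id, gene_id, r, p, n_train``.
    Probes whose gene is absent from the RNA-Seq matrix are skipped (and
    logged); zero-variance vectors yield ``r = NaN, p = 1``.
    """
    n = len(train_samples)
    if n < 3:
        raise ValidationError("need at least 3 training samples")
    arr = array_log2.subset_samples(train_samples)
    seq = seq_log2.subset_samples(train_samples)

    gene_of = annot.gene_of()
    probes = [p for p in gene_of.index if p in arr.data.index]
    genes = gene_of.loc[probes]
    in_seq = genes.isin(seq.data.index).to_numpy()
    skipped = [probes[i] for i in np.nonzero(~in_seq)[0]]
    if skipped:
        logger.info(
            "probe_correlation: %d probes skipped (gene absent from RNA-Seq)",
            len(skipped),
        )
    probes = [p for p, ok in zip(probes, in_seq) if ok]
    genes = gene_of.loc[probes]

    x = arr.data.loc[probes].to_numpy(dtype=float)
    y = seq.data.loc[genes.to_numpy()].to_numpy(dtype=float)
    r = _rowwise_pearson(x, y)
    p = correlation_pvalue(r, n, side=side)
    return pd.DataFrame(
        {
            "probe_id": probes,
            "gene_id": genes.to_numpy(),
            "r": r,
            "p": p,
            "n_train": n,
        }
    )


def estimate_pi0(
    pvals: np.ndarray, lambdas: np.ndarray | None = None
) -> float:
    """Null-proportion estimate from the p-value tail.

    Averages ``#{p > lambda} / (m * (1 - lambda))`` over a fixed lambda grid
    (0.05 to 0.90 in steps of 0.05) and clips to (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.9001, 0.05)
    m = p.size
    estimates = [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
    pi0 = float(np.mean(estimates))
    return min(max(pi0, 1.0 / m), 1.0)


def qvalues(pvals: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey-style q-values.

    ``q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j)``, capped at 1.
    With ``pi0=1`` this equals Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def assign_pass(records: pd.DataFrame, cfg: QCConfig | None = None) -> pd.DataFrame:
    """Attach q-values and the pass flag to correlation records.

    ``pass = (r > 0) and (q < q_threshold)``; undefined correlations fail.
    """
    cfg = cfg or QCConfig()
    out = records.copy()
    pi0 = None if cfg.pi0_method == "grid" else 1.0
    out["q"] = qvalues(out["p"].to_numpy(), pi0=pi0)
    r = out["r"].to_numpy()
    with np.errstate(invalid="ignore"):
        out["pass"] = (r > 0) & (out["q"].to_numpy() < cfg.q_threshold)
    out.loc[out["r"].isna(), "pass"] = False
    return out


def region_mean_matrix(
    mat: ExpressionMatrix, meta: SampleMetadata, samples: list[str] | None = None
) -> pd.DataFrame:
    """Features x regions matrix of mean values over each region's samples."""
    ids = list(samples) if samples is not None else list(mat.sample_ids)
    meta.require_samples(ids)
    regions = meta.table.loc[ids, "region"]
    return mat.data.loc[:, ids].T.groupby(regions.to_numpy()).mean().T


def designate_probes(
    records: pd.DataFrame,
    region_means: pd.DataFrame,
) -> pd.DataFrame:
    """Mark per gene the best / worst / highest probe.

    ``is_best`` = maximal between-method correlation, ``is_worst`` = minimal,
    ``is_highest`` = maximal mean expression across region means.  Ties are
    broken lexicographically by probe id; probes with undefined r are not
    eligible for best/worst unless the gene has no scored probe.
    """
    out = records.copy().sort_values("probe_id", kind="stable")
    out["is_best"] = False
    out["is_worst"] = False
    out["is_highest"] = False
    mean_expr = region_means.mean(axis=1)
    for _, idx in out.groupby("gene_id").groups.items():
        sub = out.loc[idx]
        r = sub["r"]
        if r.notna().any():
            out.loc[r.idxmax(), "is_best"] = True
            out.loc[r.idxmin(), "is_worst"] = True
        else:
            out.loc[idx[0], "is_best"] = True
            out.loc[idx[0], "is_worst"] = True
        expr = mean_expr.reindex(sub["probe_id"]).to_numpy()
        if np.isfinite(expr).any():
            out.loc[idx[int(np.nanargmax(expr))], "is_highest"] = True
        else:
            out.loc[idx[0], "is_highest"] = True
    return out.sort_index()


def flag_bright_probes(
    array_log2_means: pd.Series,
    seq_log2_means: pd.Series,
    n_sd: float = 3.0,
) -> pd.Index:
    """Flag probes far brighter than their gene's TPM predicts.

    Fits a least-squares line of mean log2 intensity on mean log2 TPM over
    all probes and flags those with a positive residual larger than
    ``n_sd`` residual standard deviations.  The residual scale is estimated
    robustly (scaled median absolute deviation) so that the outliers being
    hunted — and probes compressed onto the array background floor — do not
    inflate it.
    """
    common = array_log2_means.index
    x = seq_log2_means.reindex(common).to_numpy(dtype=float)
    y = array_log2_means.to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 10:
        raise ValidationError("flag_bright_probes needs at least 10 probes")
    slope, intercept = np.polyfit(x[ok], y[ok], 1)
    resid = y - (slope * x + intercept)
    sd = 1.4826 * float(np.median(np.abs(resid[ok] - np.median(resid[ok]))))
    if sd == 0:
        sd = 1e-12  # perfect-line bulk: any real positive deviation flags
    flagged = ok & (resid > n_sd * sd)
    return common[flagged]
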