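"""Sample-scaling and batch-adjustment normalization.

Two stages are applied to RNA-Seq (and optionally microarray) matrices
before probe scoring:

1. :func:`tbt_normalize` — TbT-style scaling in linear space.  Each sample
   is rescaled by its total signal over genes *not* differentially expressed
   between two sample groups (here: neocortex vs non-neocortex), then a
   single global multiplicative constant restores the matrix-wide sum of
   log2 values, so absolute scale is conserved.

2. :func:`combat_adjust` — parametric empirical-Bayes location/scale batch
   adjustment in log2 space (Johnson-style).  Per gene the grand mean
   ``alpha_g`` and pooled residual sd ``sigma_g`` standardize the data;
   per-batch location (``gamma``) and scale (``delta^2``) effects are
   shrunk toward normal / inverse-gamma priors whose hyperparameters are
   estimated by method of moments, and the shrunken effects are removed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionMatrix, Space, ValidationError

__all__ = ["TbTResult", "BatchAdjustModel", "tbt_normalize", "combat_adjust"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TbTResult:
    """Diagnostics of a TbT normalization run."""

    scale_factors: pd.Series          # per sample, mean 1
    de_flags: pd.Series               # per gene, True = excluded from scaling
    global_rescale_constant: float    # linear-space multiplicative constant
    de_fdr: float

    @property
    def n_de(self) -> int:
        return int(self.de_flags.sum())


@dataclasses.dataclass
class BatchAdjustModel:
    """Fitted quantities of the empirical-Bayes batch adjustment."""

    grand_mean: pd.Series             # alpha_g
    pooled_sd: pd.Series              # sigma_g
    gamma_star: pd.DataFrame          # batches x genes, shrunken locations
    delta2_star: pd.DataFrame         # batches x genes, shrunken variances
    gamma_bar: pd.Series              # per batch location-prior mean
    tau2: pd.Series                   # per batch location-prior variance
    lam: pd.Series                    # per batch inverse-gamma shape
    theta: pd.Series                  # per batch inverse-gamma scale
    n_iter: dict[str, int]
    tol: float
    constant_genes: list[str]


def _wilcoxon_de_flags(
    values: np.ndarray, groups: np.ndarray, fdr: float
) -> np.ndarray:
    """Per-gene Wilcoxon rank-sum DE flag between two groups (BH FDR)."""
    a = values[:, groups]
    b = values[:, ~groups]
    stat = stats.ranksums(a, b, axis=1)
    pvals = np.asarray(stat.pvalue)
    # constant genes give z=0, p=1 -> never flagged
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return reject


def tbt_normalize(
    mat: ExpressionMatrix,
    groups: pd.Series,
    epsilon: float,
    de_fdr: float = 0.05,
    rescale_scope: str = "matrix",
) -> tuple[ExpressionMatrix, TbTResult]:
    """TbT-style scaling of a linear-space matrix on non-DE genes.

    Parameters
    ----------
    mat
        Linear-space, strictly non-negative expression matrix.
    groups
        Boolean per sample (index = sample ids); the two-group vector the
        DE screen uses (True = neocortex in the reference analysis).
    epsilon
        Offset used for the conserved sum of ``log2(x + epsilon)``.
    de_fdr
        BH FDR level of the Wilcoxon rank-sum DE screen.
    rescale_scope
        ``"matrix"`` conserves the matrix-wide sum of log2 values with one
        global constant (default); ``"sample"`` conserves each sample's sum
        with per-sample constants.

    Returns
    -------
    (normalized matrix, TbTResult)
    """
    if mat.space is not Space.LINEAR:
        raise ValidationError("tbt_normalize expects a linear-space matrix")
    groups = groups.reindex(mat.sample_ids)
    if groups.isna().any():
        raise ValidationError("groups must cover every sample")
    g = groups.to_numpy(dtype=bool)
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValidationError("each group needs at least 2 samples")
    values = mat.data.to_numpy(dtype=float)
    if values.min() < 0:
        raise ValidationError("tbt_normalize requires non-negative values")

    de = _wilcoxon_de_flags(values, g, de_fdr)
    if de.all():
        raise ValidationError("no genes available for scaling: all flagged DE")

    totals = values[~de].sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("a sample has zero total over non-DE genes")
    factors = totals / totals.mean()
    scaled = values / factors

    target = np.log2(values + epsilon).sum()
    if rescale_scope == "matrix":

        def excess(u: float) -> float:
            return np.log2(scaled * 2.0 ** u + epsilon).sum() - target

        u = optimize.brentq(excess, -60.0, 60.0, xtol=1e-13, rtol=1e-15)
        constant = 2.0 ** u
        out = scaled * constant
    elif rescale_scope == "sample":
        col_targets = np.log2(values + epsilon).sum(axis=0)
        out = np.empty_like(scaled)
        consts = np.empty(scaled.shape[1])
        for j in range(scaled.shape[1]):
            col = scaled[:, j]
            tj = col_targets[j]

            def excess(u: float, col=col, tj=tj) -> float:
                return np.log2(col * 2.0 ** u + epsilon).sum() - tj

            uj = optimize.brentq(excess, -60.0, 60.0, xtol=1e-13, rtol=1e-15)
            consts[j] = 2.0 ** uj
            out[:, j] = col * consts[j]
        constant = float(np.exp(np.log(consts).mean()))
    else:
        raise ValidationError(f"unknown rescale_scope {rescale_scope!r}")

    result = TbTResult(
        scale_factors=pd.Series(factors, index=mat.sample_ids, name="factor"),
        de_flags=pd.Series(de, index=mat.feature_ids, name="de"),
        global_rescale_constant=float(constant),
        de_fdr=de_fdr,
    )
    logger.info(
        "tbt_normalize: %d/%d genes flagged DE; global constant %.6g",
        result.n_de,
        len(de),
        result.global_rescale_constant,
    )
    normalized = mat.copy_with(
        pd.DataFrame(out, index=mat.data.index, columns=mat.data.columns)
    )
    return normalized, result


def combat_adjust(
    mat: ExpressionMatrix,
    batches: pd.Series,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[ExpressionMatrix, BatchAdjustModel]:
    """Parametric empirical-Bayes location/scale batch adjustment (log2 space).

    Per gene g with samples j in batches i, the model is
    ``Y_ijg = alpha_g + gamma_ig + delta_ig * eps_ijg``.  Batch effects are
    estimated on standardized data ``Z = (Y - alpha_g) / sigma_g``, shrunk
    with a normal prior on locations and an inverse-gamma prior on
    variances (hyperparameters by method of moments), and removed:
    ``Y* = sigma_g / delta*_ig * (Z - gamma*_ig) + alpha_g``.

    Genes with zero pooled variance are passed through unadjusted and
    recorded in ``BatchAdjustModel.constant_genes``.
    """
    if mat.space is not Space.LOG2:
        raise ValidationError("combat_adjust expects a log2-space matrix")
    batches = batches.reindex(mat.sample_ids)
    if batches.isna().any():
        raise ValidationError("batches must cover every sample")
    batch_labels = batches.astype(str)
    levels = sorted(batch_labels.unique())
    if len(levels) < 2:
        raise ValidationError("combat_adjust needs at least 2 batches")
    masks = {lv: (batch_labels == lv).to_numpy() for lv in levels}
    for lv, mask in masks.items():
        if mask.sum() < 2:
            raise ValidationError(f"batch {lv!r} has fewer than 2 samples")

    Y = mat.data.to_numpy(dtype=float)
    n_genes, n_samples = Y.shape

    batch_means = np.stack([Y[:, m].mean(axis=1) for m in masks.values()])
    sizes = np.array([m.sum() for m in masks.values()], dtype=float)
    alpha = batch_means.T @ (sizes / n_samples)  # batch-size-weighted mean

    resid = Y.copy()
    for k, m in enumerate(masks.values()):
        resid[:, m] -= batch_means[k][:, None]
    sigma2 = (resid ** 2).sum(axis=1) / n_samples
    constant = sigma2 <= 0
    sigma = np.sqrt(np.where(constant, 1.0, sigma2))

    Z = (Y - alpha[:, None]) / sigma[:, None]

    gamma_hat = np.stack([Z[:, m].mean(axis=1) for m in masks.values()])
    delta2_hat = np.stack(
        [Z[:, m].var(axis=1, ddof=1) for m in masks.values()]
    )

    active = ~constant
    if not active.any():
        raise ValidationError("all genes have zero pooled variance")

    gamma_bar = gamma_hat[:, active].mean(axis=1)
    tau2 = gamma_hat[:, active].var(axis=1, ddof=1)
    V = delta2_hat[:, active].mean(axis=1)
    S = delta2_hat[:, active].var(axis=1, ddof=1)
    # degenerate scale prior (all delta2_hat identical): no shrinkage
    degenerate = S <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(degenerate, np.inf, V ** 2 / np.where(degenerate, 1.0, S) + 2.0)
        theta = V * (lam - 1.0)

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    n_iter: dict[str, int] = {}
    for k, (lv, m) in enumerate(masks.items()):
        n_i = float(m.sum())
        g = gamma_hat[k].copy()
        d2 = delta2_hat[k].copy()
        zi = Z[:, m]
        it = 0
        while True:
            it += 1
            g_new = (n_i * tau2[k] * gamma_hat[k] + d2 * gamma_bar[k]) / (
                n_i * tau2[k] + d2
            )
            if degenerate[k]:
                d2_new = np.full_like(d2, V[k])
            else:
                ss = ((zi - g_new[:, None]) ** 2).sum(axis=1)
                d2_new = (theta[k] + 0.5 * ss) / (n_i / 2.0 + lam[k] - 1.0)
            change = max(
                np.abs(g_new - g)[active].max(initial=0.0),
                np.abs(d2_new - d2)[active].max(initial=0.0),
            )
            g, d2 = g_new, d2_new
            if change < tol:
                break
            if it >= max_iter:
                raise ValidationError(
                    f"combat_adjust did not converge for batch {lv!r}: "
                    f"max change {change:.3g} > tol {tol:g} after {it} iterations"
                )
        gamma_star[k] = g
        delta2_star[k] = d2
        n_iter[lv] = it

    adjusted = Y.copy()
    for k, m in enumerate(masks.values()):
        zadj = (Z[:, m] - gamma_star[k][:, None]) / np.sqrt(delta2_star[k])[
            :, None
        ]
        adjusted[:, m] = zadj * sigma[:, None] + alpha[:, None]
    adjusted[constant] = Y[constant]  # constant genes pass through

    constant_genes = mat.feature_ids[constant].tolist()
    if constant_genes:
        logger.info(
            "combat_adjust: %d constant genes passed through unadjusted",
            len(constant_genes),
        )

    gene_index = mat.feature_ids
    model = BatchAdjustModel(
        grand_mean=pd.Series(alpha, index=gene_index, name="alpha"),
        pooled_sd=pd.Series(
            np.where(constant, 0.0, sigma), index=gene_index, name="sigma"
        ),
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=gene_index),
        delta2_star=pd.DataFrame(delta2_star, index=levels, columns=gene_index),
        gamma_bar=pd.Series(gamma_bar, index=levels),
        tau2=pd.Series(tau2, index=levels),
        lam=pd.Series(lam, index=levels),
        theta=pd.Series(theta, index=levels),
        n_iter=n_iter,
        tol=tol,
        constant_genes=constant_genes,
    )
    out = mat.copy_with(
        pd.DataFrame(adjusted, index=mat.data.index, columns=mat.data.columns)
    )
    return out, model
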