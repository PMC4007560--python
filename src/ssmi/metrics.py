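"""Reproducibility and concordance metrics.

The evaluation battery used to compare platforms and to validate probe
filtering/scaling:

- :func:`replicate_correlations` — Pearson correlation of absolute levels
  between replicate sample pairs (same donor, region and hemisphere).
- :func:`presence_summary` — present/absent concordance between vendor
  detection calls and RNA-Seq fragment counts at sample-fraction thresholds.
- :func:`foldchange_concordance` — Pearson correlation of log2 fold changes
  for randomly drawn (gene, region pair) triples between two matrices
  (two donors or two platforms).
- :func:`per_gene_reproducibility` / :func:`binned_reproducibility` —
  per-gene between-donor correlation of region-mean profiles, summarized in
  20 near-equal bins after sorting by expression or transcript length.
- :func:`region_anova` — one-way fixed-effects ANOVA across regions per
  gene with Bonferroni-corrected significant counts.
- :func:`subsample_stability` — probe pass rate and scaling-parameter
  stability as a function of training-set size, with region-stratified
  ("carefully selected") subsampling.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    ExpressionMatrix,
    PresenceFlags,
    ProbeAnnotation,
    SampleMetadata,
    ValidationError,
)
from .probe_qc import QCConfig, _rowwise_pearson, assign_pass, probe_correlation, region_mean_matrix
from .scaling import QuantileAnchor, fit_scaling

__all__ = [
    "replicate_correlations",
    "presence_summary",
    "foldchange_concordance",
    "per_gene_reproducibility",
    "binned_reproducibility",
    "BinnedReproducibility",
    "region_anova",
    "subsample_stability",
    "stratified_subsample",
]

logger = logging.getLogger(__name__)


def replicate_correlations(
    mat: ExpressionMatrix, meta: SampleMetadata
) -> pd.DataFrame:
    """Correlate replicate sample pairs (same donor/region/hemisphere).

    Returns one row per unordered pair with columns ``sample_a, sample_b, r``.
    """
    ids = [s for s in mat.sample_ids if s in meta.table.index]
    groups = meta.table.loc[ids].groupby(["donor", "region", "hemisphere"])
    pairs: list[tuple[str, str]] = []
    for _, sub in groups:
        reps = sub.sort_values("replicate")["sample_id"].tolist()
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                pairs.append((reps[i], reps[j]))
    if not pairs:
        raise ValidationError("no replicate pairs found")
    a = mat.data.loc[:, [p[0] for p in pairs]].to_numpy(dtype=float)
    b = mat.data.loc[:, [p[1] for p in pairs]].to_numpy(dtype=float)
    r = _rowwise_pearson(a.T, b.T)
    return pd.DataFrame(
        {"sample_a": [p[0] for p in pairs], "sample_b": [p[1] for p in pairs], "r": r}
    )


def presence_summary(
    flags_array: PresenceFlags,
    counts_seq: ExpressionMatrix,
    thresholds: tuple[float, ...] = (0.05, 0.5, 0.95),
) -> pd.DataFrame:
    """Present/absent overlap between platforms at sample-fraction thresholds.

    A gene is present in RNA-Seq in a sample when at least one fragment was
    aligned; the array flags are vendor calls supplied as inputs.  For each
    threshold ``t`` a gene counts as present on a platform when it is called
    present in at least ``t`` of the samples.  Features are matched by
    identifier (common universe).
    """
    common = flags_array.flags.index.intersection(counts_seq.feature_ids)
    arr = flags_array.flags.loc[common]
    seq_present = counts_seq.data.loc[common] >= 1
    arr_frac = arr.mean(axis=1)
    seq_frac = seq_present.mean(axis=1)
    rows = []
    for t in thresholds:
        a = arr_frac >= t
        s = seq_frac >= t
        both = int((a & s).sum())
        union = int((a | s).sum())
        rows.append(
            {
                "threshold": t,
                "n_array": int(a.sum()),
                "n_seq": int(s.sum()),
                "n_overlap": both,
                "overlap_fraction": both / union if union else np.nan,
            }
        )
    return pd.DataFrame(rows)


def foldchange_concordance(
    matA: ExpressionMatrix,
    matB: ExpressionMatrix,
    meta: SampleMetadata,
    n_draws: int = 100_000,
    regions_filter: list[str] | str | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Fold-change concordance between two matrices by random resampling.

    Draws ``n_draws`` (gene, region A, region B) triples uniformly with
    replacement (regions distinct, unordered pair sampled as an ordered
    distinct pair), computes per matrix the log2 fold change of the gene
    between the mean values of the two regions, and returns the draws plus
    the Pearson correlation of the two fold-change vectors.

    ``regions_filter`` may be a region-class name (``"neocortex"`` /
    ``"non_neocortex"``) or an explicit list of region labels.
    """
    genes = matA.feature_ids.intersection(matB.feature_ids)
    if len(genes) == 0:
        raise ValidationError("matrices share no features")
    if isinstance(regions_filter, str):
        regions = sorted(
            meta.table.loc[meta.table["region_class"] == regions_filter, "region"].unique()
        )
    elif regions_filter is not None:
        regions = sorted(regions_filter)
    else:
        regions = sorted(meta.table["region"].unique())
    if len(regions) < 2:
        raise ValidationError("need at least 2 regions after filtering")

    meansA = region_mean_matrix(matA, meta).loc[genes, regions]
    meansB = region_mean_matrix(matB, meta).loc[genes, regions]
    if meansA.isna().any().any() or meansB.isna().any().any():
        raise ValidationError("a selected region has no samples in one matrix")

    rng = np.random.default_rng(seed)
    gi = rng.integers(0, len(genes), size=n_draws)
    ra = rng.integers(0, len(regions), size=n_draws)
    rb = rng.integers(0, len(regions) - 1, size=n_draws)
    rb = np.where(rb >= ra, rb + 1, rb)  # distinct second region

    A = meansA.to_numpy(dtype=float)
    B = meansB.to_numpy(dtype=float)
    fcA = A[gi, ra] - A[gi, rb]
    fcB = B[gi, ra] - B[gi, rb]
    if np.std(fcA) == 0 or np.std(fcB) == 0:
        R = 1.0 if np.allclose(fcA, fcB) else np.nan
    else:
        R = float(np.corrcoef(fcA, fcB)[0, 1])
    draws = pd.DataFrame(
        {
            "gene_id": genes.to_numpy()[gi],
            "region_a": np.asarray(regions)[ra],
            "region_b": np.asarray(regions)[rb],
            "fc_a": fcA,
            "fc_b": fcB,
        }
    )
    return draws, R


def per_gene_reproducibility(
    matA: ExpressionMatrix,
    matB: ExpressionMatrix,
    metaA: SampleMetadata,
    metaB: SampleMetadata | None = None,
) -> pd.Series:
    """Per-gene Pearson correlation of region-mean profiles between donors.

    Genes whose region-mean vector is constant in either matrix get ``NaN``
    (excluded from downstream binning) and are logged.
    """
    metaB = metaB or metaA
    genes = matA.feature_ids.intersection(matB.feature_ids)
    meansA = region_mean_matrix(matA, metaA).loc[genes]
    meansB = region_mean_matrix(matB, metaB).loc[genes]
    regions = meansA.columns.intersection(meansB.columns)
    if len(regions) < 3:
        raise ValidationError("need at least 3 common regions")
    r = _rowwise_pearson(
        meansA.loc[:, regions].to_numpy(dtype=float),
        meansB.loc[:, regions].to_numpy(dtype=float),
    )
    n_na = int(np.isnan(r).sum())
    if n_na:
        logger.info("per_gene_reproducibility: %d constant genes -> r=NaN", n_na)
    return pd.Series(r, index=genes, name="r")


@dataclasses.dataclass
class BinnedReproducibility:
    """Summary of one bin of the sorted per-gene correlations."""

    bin_index: int
    n: int
    mean_r: float
    sem: float
    lo: float  # smallest sort value in the bin
    hi: float  # largest sort value in the bin
    sort_key: str


def binned_reproducibility(
    per_gene_r: pd.Series,
    sort_values: pd.Series,
    n_bins: int = 20,
    sort_key: str = "expression",
) -> list[BinnedReproducibility]:
    """Bin genes by a sort key and summarize per-gene correlations.

    Genes are sorted by ``sort_values`` (mean expression or transcript
    length), split into ``n_bins`` near-equal groups (any remainder spread
    over the leading bins), and each bin reports the mean correlation and
    its standard error.  Genes with undefined r are excluded first.
    """
    joined = pd.DataFrame({"r": per_gene_r, "v": sort_values.reindex(per_gene_r.index)})
    joined = joined.dropna()
    n = len(joined)
    if n < n_bins:
        raise ValidationError(f"fewer genes ({n}) than bins ({n_bins})")
    joined = joined.sort_values(["v", "r"], kind="stable")
    base = n // n_bins
    remainder = n % n_bins
    sizes = [base + (1 if i < remainder else 0) for i in range(n_bins)]
    out: list[BinnedReproducibility] = []
    start = 0
    for i, size in enumerate(sizes):
        chunk = joined.iloc[start : start + size]
        start += size
        r = chunk["r"].to_numpy()
        sem = float(np.std(r, ddof=1) / np.sqrt(size)) if size > 1 else 0.0
        out.append(
            BinnedReproducibility(
                bin_index=i + 1,
                n=size,
                mean_r=float(r.mean()),
                sem=sem,
                lo=float(chunk["v"].iloc[0]),
                hi=float(chunk["v"].iloc[-1]),
                sort_key=sort_key,
            )
        )
    return out


def region_anova(
    mat: ExpressionMatrix,
    meta: SampleMetadata,
    region_class: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA across regions of one region class.

    Returns per-gene ``F``, ``p`` and a Bonferroni flag
    (``p * n_genes < alpha``).  Degenerate genes (zero within- and
    between-group variance) get ``p = 1``.
    """
    ids = meta.table.loc[
        (meta.table["region_class"] == region_class)
        & meta.table["sample_id"].isin(mat.sample_ids),
        "sample_id",
    ].tolist()
    if not ids:
        raise ValidationError(f"no samples in region class {region_class!r}")
    regions = meta.table.loc[ids, "region"]
    by_region = [
        mat.data.loc[:, regions.index[regions == reg]].to_numpy(dtype=float)
        for reg in sorted(regions.unique())
    ]
    if len(by_region) < 2:
        raise ValidationError("need at least 2 regions")
    if any(block.shape[1] < 2 for block in by_region):
        raise ValidationError("every region needs at least 2 samples")

    # explicit sums of squares (vectorized over genes)
    n_total = sum(block.shape[1] for block in by_region)
    grand = sum(block.sum(axis=1) for block in by_region) / n_total
    ss_between = sum(
        block.shape[1] * (block.mean(axis=1) - grand) ** 2 for block in by_region
    )
    ss_within = sum(
        ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        for block in by_region
    )
    df_between = len(by_region) - 1
    df_within = n_total - len(by_region)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_between) / (ss_within / df_within)
    p = stats.f.sf(F, df_between, df_within)
    degenerate = (ss_within <= 0) & (ss_between <= 0)
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, p)
    # zero within-group variance with real between-group spread: p -> 0
    only_within_zero = (ss_within <= 0) & (ss_between > 0)
    F = np.where(only_within_zero, np.inf, F)
    p = np.where(only_within_zero, 0.0, p)
    n_genes = mat.shape[0]
    out = pd.DataFrame(
        {
            "F": F,
            "p": p,
            "bonferroni_significant": p * n_genes < alpha,
        },
        index=mat.feature_ids,
    )
    return out


def stratified_subsample(
    meta: SampleMetadata, candidates: list[str], size: int, rng: np.random.Generator
) -> list[str]:
    """Region-stratified "carefully selected" subsample.

    Picks first one sample per region class, then one per region, then
    fills uniformly at random, maximizing tissue diversity at small sizes.
    """
    if size > len(candidates):
        raise ValidationError("subsample size exceeds available samples")
    table = meta.table.loc[candidates]
    chosen: list[str] = []
    remaining = set(candidates)

    def draw_from(pool: list[str]) -> None:
        pick = pool[int(rng.integers(0, len(pool)))]
        chosen.append(pick)
        remaining.discard(pick)

    for cls in sorted(table["region_class"].unique()):
        if len(chosen) >= size:
            break
        pool = sorted(set(table.loc[table["region_class"] == cls, "sample_id"]) & remaining)
        if pool:
            draw_from(pool)
    for reg in sorted(table["region"].unique()):
        if len(chosen) >= size:
            break
        pool = sorted(set(table.loc[table["region"] == reg, "sample_id"]) & remaining)
        if pool:
            draw_from(pool)
    while len(chosen) < size:
        draw_from(sorted(remaining))
    return chosen


def subsample_stability(
    array_log2: ExpressionMatrix,
    seq_log2: ExpressionMatrix,
    annot: ProbeAnnotation,
    meta: SampleMetadata,
    train_candidates: list[str],
    sizes: list[int],
    n_rep: int = 5,
    seed: int = 0,
    qc_config: QCConfig | None = None,
    anchors: QuantileAnchor | None = None,
) -> pd.DataFrame:
    """Probe pass rate and fit stability vs number of training samples.

    For each size, repeats ``n_rep`` region-stratified subsample draws,
    reruns probe scoring + scaling, and records the pass rate and the
    median absolute deviation of (m, b) from the full-training-set fit.
    When ``size == len(train_candidates)`` the full set is used once and
    the deviations are exactly zero.
    """
    if min(sizes) < 3:
        raise ValidationError("training size must be >= 3")
    if max(sizes) > len(train_candidates):
        raise ValidationError("a requested size exceeds the training pool")
    cfg = qc_config or QCConfig()
    anchors = anchors or QuantileAnchor()

    def run(samples: list[str]) -> tuple[float, pd.DataFrame]:
        rec = probe_correlation(array_log2, seq_log2, annot, samples, side=cfg.side)
        rec = assign_pass(rec, cfg)
        params = fit_scaling(array_log2, seq_log2, annot, rec, samples, anchors)
        return float(rec["pass"].mean()), params.set_index("probe_id")

    full_rate, full_params = run(list(train_candidates))
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        rates, dm, db = [], [], []
        reps = 1 if size == len(train_candidates) else n_rep
        for _ in range(reps):
            if size == len(train_candidates):
                samples = list(train_candidates)
            else:
                samples = stratified_subsample(meta, list(train_candidates), size, rng)
            rate, params = run(samples)
            rates.append(rate)
            common = params.index.intersection(full_params.index)
            dm.append(float((params.loc[common, "m"] - full_params.loc[common, "m"]).abs().median()))
            db.append(float((params.loc[common, "b"] - full_params.loc[common, "b"]).abs().median()))
        rows.append(
            {
                "size": size,
                "pass_rate_mean": float(np.mean(rates)),
                "pass_rate_sd": float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0,
                "m_dev_median": float(np.mean(dm)),
                "b_dev_median": float(np.mean(db)),
                "n_rep": reps,
            }
        )
    return pd.DataFrame(rows)
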