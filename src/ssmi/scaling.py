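"""Quantile-anchored linear scaling of microarray probes to TPM scale.

For each probe passing quality control, the 5th and 95th percent quantiles
of its log2 intensities across the training samples are matched to the same
quantiles of its gene's log2 TPM, defining a line

    SSMI = m * log2(intensity) + b,
    m = (q95_seq - q05_seq) / (q95_array - q05_array),
    b = q05_seq - m * q05_array.

Applying the fitted parameters to any matrix from the same array platform
yields sequencing-scaled microarray intensities (SSMIs) on absolute
log2-TPM scale.  Quantiles use linear interpolation between order
statistics (the "type 7" convention).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    ProbeAnnotation,
    Space,
    Unit,
    ValidationError,
)
from .probe_qc import _rowwise_pearson

__all__ = [
    "QuantileAnchor",
    "fit_scaling",
    "apply_scaling",
    "transfer_evaluation",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class QuantileAnchor:
    """Quantile pair anchoring the linear fit."""

    lower_prob: float = 0.05
    upper_prob: float = 0.95
    interpolation: str = "linear"  # numpy quantile method ("type 7")

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower_prob < self.upper_prob <= 1.0:
            raise ValidationError("need 0 <= lower_prob < upper_prob <= 1")


def fit_scaling(
    array_log2: ExpressionMatrix,
    seq_log2: ExpressionMatrix,
    annot: ProbeAnnotation,
    qc_records: pd.DataFrame,
    train_samples: list[str],
    anchors: QuantileAnchor | None = None,
) -> pd.DataFrame:
    """Fit per-probe scaling parameters on the training samples.

    Only probes with ``pass == True`` in ``qc_records`` are fitted; probes
    whose intensity anchor quantiles coincide (constant probes) are marked
    unscalable, excluded and logged.

    Returns a DataFrame with columns ``probe_id, gene_id, m, b, q05_array,
    q95_array, q05_seq, q95_seq, n_train``.
    """
    anchors = anchors or QuantileAnchor()
    arr = array_log2.subset_samples(train_samples)
    seq = seq_log2.subset_samples(train_samples)
    passing = qc_records.loc[qc_records["pass"].astype(bool)]
    probes = [p for p in passing["probe_id"] if p in arr.data.index]
    gene_of = annot.gene_of()
    genes = gene_of.loc[probes]
    if not genes.isin(seq.data.index).all():
        missing = genes[~genes.isin(seq.data.index)].unique()[:5]
        raise ValidationError(f"genes absent from RNA-Seq matrix: {missing}")

    x = arr.data.loc[probes].to_numpy(dtype=float)
    y = seq.data.loc[genes.to_numpy()].to_numpy(dtype=float)
    probs = [anchors.lower_prob, anchors.upper_prob]
    qa = np.quantile(x, probs, axis=1, method=anchors.interpolation)
    qs = np.quantile(y, probs, axis=1, method=anchors.interpolation)
    q05_array, q95_array = qa[0], qa[1]
    q05_seq, q95_seq = qs[0], qs[1]

    span = q95_array - q05_array
    scalable = span > 0
    if (~scalable).any():
        logger.info(
            "fit_scaling: %d constant probes unscalable, excluded",
            int((~scalable).sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(scalable, (q95_seq - q05_seq) / span, np.nan)
    b = q05_seq - m * q05_array
    out = pd.DataFrame(
        {
            "probe_id": probes,
            "gene_id": genes.to_numpy(),
            "m": m,
            "b": b,
            "q05_array": q05_array,
            "q95_array": q95_array,
            "q05_seq": q05_seq,
            "q95_seq": q95_seq,
            "n_train": len(train_samples),
        }
    )
    return out.loc[scalable].reset_index(drop=True)


def apply_scaling(
    array_log2: ExpressionMatrix, params: pd.DataFrame
) -> ExpressionMatrix:
    """Apply fitted parameters: ``SSMI = m * log2(intensity) + b`` per probe.

    Probes without parameters (failed QC or unscalable) are dropped and
    counted in the log.
    """
    if array_log2.space is not Space.LOG2:
        raise ValidationError("apply_scaling expects log2 intensities")
    usable = params.dropna(subset=["m", "b"])
    probes = [p for p in usable["probe_id"] if p in array_log2.data.index]
    dropped = array_log2.data.index.difference(pd.Index(probes))
    if len(dropped):
        logger.info("apply_scaling: %d probes without parameters dropped", len(dropped))
    keyed = usable.set_index("probe_id")
    m = keyed.loc[probes, "m"].to_numpy(dtype=float)
    b = keyed.loc[probes, "b"].to_numpy(dtype=float)
    values = array_log2.data.loc[probes].to_numpy(dtype=float)
    ssmi = values * m[:, None] + b[:, None]
    out = pd.DataFrame(ssmi, index=pd.Index(probes, name="feature_id"),
                       columns=array_log2.sample_ids)
    return ExpressionMatrix(out, Space.LOG2, array_log2.platform, Unit.SSMI)


def transfer_evaluation(
    params: pd.DataFrame,
    array_log2: ExpressionMatrix,
    seq_log2: ExpressionMatrix,
    annot: ProbeAnnotation,
    probes: list[str] | None = None,
) -> pd.DataFrame:
    """Evaluate scaling transfer on held-out samples.

    For every sample present in both matrices, computes the Pearson
    correlation of absolute levels between SSMI and log2 TPM, and between
    unscaled log2 intensity and log2 TPM, over the evaluated probes
    (default: all probes with parameters).  Returns a per-sample DataFrame
    with columns ``sample_id, r_ssmi, r_unscaled, delta``.
    """
    common = [s for s in array_log2.sample_ids if s in set(seq_log2.sample_ids)]
    if not common:
        raise ValidationError("no common samples between the two matrices")
    gene_of = annot.gene_of()
    usable = params.dropna(subset=["m", "b"])
    eligible = [
        p
        for p in usable["probe_id"]
        if p in array_log2.data.index and gene_of.get(p) in seq_log2.data.index
    ]
    if probes is not None:
        eligible = [p for p in eligible if p in set(probes)]
    if len(eligible) < 2:
        raise ValidationError("fewer than 2 evaluable probes/genes")

    arr = array_log2.subset_features(eligible).subset_samples(common)
    ssmi = apply_scaling(arr, usable)
    genes = gene_of.loc[eligible].to_numpy()
    seq = seq_log2.data.loc[genes, common].to_numpy(dtype=float)

    raw = arr.data.to_numpy(dtype=float)
    scaled = ssmi.data.loc[eligible].to_numpy(dtype=float)
    r_unscaled = _rowwise_pearson(raw.T, seq.T)
    r_ssmi = _rowwise_pearson(scaled.T, seq.T)
    return pd.DataFrame(
        {
            "sample_id": common,
            "r_ssmi": r_ssmi,
            "r_unscaled": r_unscaled,
            "delta": r_ssmi - r_unscaled,
        }
    )
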