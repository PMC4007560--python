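"""Probe calibration model: fit on a training donor, transfer anywhere.

:class:`ProbeCalibration` bundles the matched inputs (microarray intensity
matrix, RNA-Seq TPM matrix, probe annotation, sample metadata) and the
preprocessing choices; ``fit()`` runs the calibration pipeline —

    TbT normalization of the RNA-Seq TPM (linear space)
    -> log2 transform of both platforms
    -> per-probe correlation + q-values + pass/fail on the training samples
    -> best / worst / highest probe designation per gene
    -> quantile-anchored linear scaling parameters per passing probe

— and returns a :class:`CalibrationResults` carrying the quality-control
records, scaling parameters, stage counts and a ``summary()`` table.
``results.transform(matrix)`` produces sequencing-scaled microarray
intensities (SSMIs) for any matrix from the same platform, and
``results.evaluate_transfer(...)`` measures how much scaling improves
between-method correlation on held-out samples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging

import pandas as pd

from . import __version__
from .datamodel import (
    DEFAULT_EPSILON,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleMetadata,
    Space,
    Unit,
    ValidationError,
    log_transform,
    write_scaling_table,
)
from .normalization import TbTResult, combat_adjust, tbt_normalize
from .probe_qc import (
    QCConfig,
    assign_pass,
    designate_probes,
    probe_correlation,
    region_mean_matrix,
)
from .scaling import QuantileAnchor, apply_scaling, fit_scaling, transfer_evaluation

__all__ = ["ProbeCalibration", "CalibrationResults"]

logger = logging.getLogger(__name__)


def config_hash(payload: dict) -> str:
    """Short stable hash of a configuration mapping (for output headers)."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


class ProbeCalibration:
    """Model object tying together matched two-platform expression data.

    Parameters
    ----------
    array
        Microarray probe intensities (linear space, probes x samples).
    seq_tpm
        RNA-Seq TPM (linear space, genes x samples).
    annotation
        Probe -> gene table.
    metadata
        Sample annotations covering every sample of both matrices.
    epsilon
        Offset for log2 transforms.
    tbt
        Apply TbT normalization to the TPM matrix (neocortex vs
        non-neocortex grouping) before log transform.
    qc_config, anchors
        Pass/fail thresholds and anchor quantiles.
    """

    def __init__(
        self,
        array: ExpressionMatrix,
        seq_tpm: ExpressionMatrix,
        annotation: ProbeAnnotation,
        metadata: SampleMetadata,
        *,
        epsilon: float = DEFAULT_EPSILON,
        tbt: bool = True,
        de_fdr: float = 0.05,
        qc_config: QCConfig | None = None,
        anchors: QuantileAnchor | None = None,
    ) -> None:
        if array.space is not Space.LINEAR or seq_tpm.space is not Space.LINEAR:
            raise ValidationError("ProbeCalibration expects linear-space inputs")
        metadata.require_samples(array.sample_ids)
        metadata.require_samples(seq_tpm.sample_ids)
        self.array = array
        self.seq_tpm = seq_tpm
        self.annotation = annotation
        self.metadata = metadata
        self.epsilon = epsilon
        self.qc_config = qc_config or QCConfig()
        self.anchors = anchors or QuantileAnchor()
        self.tbt = tbt
        self.de_fdr = de_fdr

        self.tbt_result: TbTResult | None = None
        seq = seq_tpm
        if tbt:
            groups = metadata.neocortex_mask(seq_tpm.sample_ids)
            seq, self.tbt_result = tbt_normalize(
                seq_tpm, groups, epsilon=epsilon, de_fdr=de_fdr
            )
        self.seq_log2 = log_transform(seq, epsilon)
        self.array_log2 = log_transform(array, epsilon)

    @classmethod
    def from_files(
        cls,
        array_path,
        seq_path,
        annotation_path,
        metadata_path,
        **kwargs,
    ) -> "ProbeCalibration":
        from .datamodel import (
            Platform,
            read_expression_matrix,
            read_probe_annotation,
            read_sample_metadata,
        )

        meta = read_sample_metadata(metadata_path)
        array = read_expression_matrix(
            array_path, Space.LINEAR, Platform.MICROARRAY, Unit.INTENSITY, meta
        )
        seq = read_expression_matrix(
            seq_path, Space.LINEAR, Platform.RNASEQ, Unit.TPM, meta
        )
        annot = read_probe_annotation(annotation_path)
        return cls(array, seq, annot, meta, **kwargs)

    # ------------------------------------------------------------------
    def fit(
        self,
        train_donor: str | None = None,
        train_samples: list[str] | None = None,
    ) -> "CalibrationResults":
        """Run the calibration pipeline on the designated training samples.

        Exactly one of ``train_donor`` (all of that donor's samples present
        on both platforms) or an explicit ``train_samples`` list is used;
        with neither, all common samples train.
        """
        common = [s for s in self.array.sample_ids if s in set(self.seq_tpm.sample_ids)]
        if train_samples is not None:
            train = [s for s in train_samples if s in set(common)]
            if len(train) < len(train_samples):
                raise ValidationError("some train_samples absent from a matrix")
        elif train_donor is not None:
            donor_samples = set(self.metadata.samples_of_donor(train_donor))
            train = [s for s in common if s in donor_samples]
            if not train:
                raise ValidationError(
                    f"training donor {train_donor!r} shares no samples "
                    "between the two matrices"
                )
        else:
            train = common
        if len(train) < self.qc_config.min_train_samples:
            raise ValidationError(
                f"{len(train)} training samples < min_train_samples="
                f"{self.qc_config.min_train_samples}"
            )

        records = probe_correlation(
            self.array_log2,
            self.seq_log2,
            self.annotation,
            train,
            side=self.qc_config.side,
        )
        records = assign_pass(records, self.qc_config)
        region_means = region_mean_matrix(self.array_log2, self.metadata, train)
        records = designate_probes(records, region_means)
        params = fit_scaling(
            self.array_log2,
            self.seq_log2,
            self.annotation,
            records,
            train,
            self.anchors,
        )
        counts = {
            "probes_in": int(self.array.shape[0]),
            "probes_scored": int(len(records)),
            "probes_failed": int((~records["pass"]).sum()),
            "probes_scaled": int(len(params)),
        }
        genes_pass = records.loc[records["pass"], "gene_id"].nunique()
        counts["genes_with_passing_probe"] = int(genes_pass)
        counts["genes_scored"] = int(records["gene_id"].nunique())
        logger.info("fit: %s", counts)
        return CalibrationResults(
            model=self,
            train_samples=train,
            train_donor=train_donor,
            qc_records=records,
            params=params,
            counts=counts,
        )


@dataclasses.dataclass
class CalibrationResults:
    """Fitted probe QC records and scaling parameters."""

    model: ProbeCalibration
    train_samples: list[str]
    train_donor: str | None
    qc_records: pd.DataFrame
    params: pd.DataFrame
    counts: dict

    # -- tables ---------------------------------------------------------
    @property
    def scaling_table(self) -> pd.DataFrame:
        """QC + parameters, one row per scored probe (failed: empty m/b)."""
        merged = self.qc_records.merge(
            self.params.drop(columns=["gene_id", "n_train"], errors="ignore"),
            on="probe_id",
            how="left",
        )
        return merged

    def save_table(self, path, seed: int | None = None) -> None:
        header = {
            "tool": f"ssmi {__version__}",
            "config_hash": config_hash(self.config_payload()),
            "anchors": f"{self.model.anchors.lower_prob}/{self.model.anchors.upper_prob} "
            f"(linear interpolation, type 7)",
            "n_train": len(self.train_samples),
        }
        if seed is not None:
            header["seed"] = seed
        write_scaling_table(self.scaling_table, path, header=header)

    def config_payload(self) -> dict:
        m = self.model
        return {
            "epsilon": m.epsilon,
            "tbt": m.tbt,
            "de_fdr": m.de_fdr,
            "q_threshold": m.qc_config.q_threshold,
            "side": m.qc_config.side,
            "pi0_method": m.qc_config.pi0_method,
            "lower_prob": m.anchors.lower_prob,
            "upper_prob": m.anchors.upper_prob,
            "train_donor": self.train_donor,
            "n_train": len(self.train_samples),
        }

    # -- derived quantities ----------------------------------------------
    @property
    def pass_rate(self) -> float:
        return float(self.qc_records["pass"].mean())

    @property
    def gene_pass_rate(self) -> float:
        """Fraction of scored genes with at least one passing probe."""
        return self.counts["genes_with_passing_probe"] / self.counts["genes_scored"]

    def best_probes(self, passing_only: bool = True) -> list[str]:
        rec = self.qc_records
        sel = rec["is_best"]
        if passing_only:
            sel = sel & rec["pass"]
        return rec.loc[sel, "probe_id"].tolist()

    def slope_quantiles(self, probs=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.Series:
        return self.params["m"].quantile(list(probs))

    # -- application -------------------------------------------------------
    def transform(
        self, array: ExpressionMatrix, combat_batches: pd.Series | None = None
    ) -> ExpressionMatrix:
        """Scale a microarray matrix to SSMIs.

        Accepts linear intensities (log-transformed internally with the
        model's epsilon) or an already log2 matrix.  When
        ``combat_batches`` is given, the scaled matrix is additionally
        batch-adjusted.
        """
        log2 = array if array.space is Space.LOG2 else log_transform(array, self.model.epsilon)
        ssmi = apply_scaling(log2, self.params)
        if combat_batches is not None:
            ssmi, _ = combat_adjust(ssmi, combat_batches)
        return ssmi

    def evaluate_transfer(
        self,
        array: ExpressionMatrix | None = None,
        seq_tpm: ExpressionMatrix | None = None,
        donor: str | None = None,
        best_only: bool = True,
        annotation: ProbeAnnotation | None = None,
    ) -> pd.DataFrame:
        """Per-sample correlation with RNA-Seq, before vs after scaling.

        With ``donor`` given and no explicit matrices, evaluates the model's
        held-out samples of that donor (which must be disjoint from the
        training set).  External matrices (another tissue profiled on the
        same platform) may be supplied in linear space.
        """
        model = self.model
        annotation = annotation or model.annotation
        if array is None and seq_tpm is None:
            if donor is None:
                raise ValidationError("need either matrices or a donor")
            samples = model.metadata.samples_of_donor(donor)
            overlap = set(samples) & set(self.train_samples)
            if overlap:
                raise ValidationError(
                    f"held-out donor {donor!r} overlaps the training set"
                )
            samples = [
                s
                for s in samples
                if s in set(model.array_log2.sample_ids)
                and s in set(model.seq_log2.sample_ids)
            ]
            array_log2 = model.array_log2.subset_samples(samples)
            seq_log2 = model.seq_log2.subset_samples(samples)
        else:
            if array is None or seq_tpm is None:
                raise ValidationError("supply both matrices or neither")
            array_log2 = (
                array if array.space is Space.LOG2 else log_transform(array, model.epsilon)
            )
            seq_log2 = (
                seq_tpm
                if seq_tpm.space is Space.LOG2
                else log_transform(seq_tpm, model.epsilon)
            )
        probes = self.best_probes() if best_only else None
        return transfer_evaluation(
            self.params, array_log2, seq_log2, annotation, probes=probes
        )

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        c = self.counts
        m_q = self.slope_quantiles()
        b_q = self.params["b"].quantile([0.05, 0.25, 0.5, 0.75, 0.95])
        lines = [
            "Probe calibration against RNA-Seq",
            "=" * 48,
            f"training samples          {len(self.train_samples)}"
            + (f" (donor {self.train_donor})" if self.train_donor else ""),
            f"probes scored             {c['probes_scored']}",
            f"probes passing QC         {c['probes_scored'] - c['probes_failed']}"
            f" ({self.pass_rate:.1%})",
            f"probes scaled             {c['probes_scaled']}",
            f"genes with passing probe  {c['genes_with_passing_probe']}"
            f"/{c['genes_scored']} ({self.gene_pass_rate:.1%})",
            f"median between-method r   {self.qc_records['r'].median():.3f}",
            "slope m quantiles         "
            + "  ".join(f"{p:.0%}:{v:.2f}" for p, v in m_q.items()),
            "intercept b quantiles     "
            + "  ".join(f"{p:.0%}:{v:.2f}" for p, v in b_q.items()),
            f"q threshold               {self.model.qc_config.q_threshold}"
            f" ({self.model.qc_config.side})",
            f"anchor quantiles          {self.model.anchors.lower_prob:.0%}"
            f"/{self.model.anchors.upper_prob:.0%}",
        ]
        return "\n".join(lines)
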