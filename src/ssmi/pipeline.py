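"""End-to-end runs driven by a key-value config file.

``run_fit_pipeline`` executes simulate-or-load -> TbT -> probe QC on the
training donor -> scaling fit -> scaling table CSV; ``run_evaluate_pipeline``
applies a fitted table to a held-out donor and reports the unscaled-vs-SSMI
metric battery.  Both are deterministic functions of (inputs, config, seed)
and stamp every output with the tool version, a config hash and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import __version__
from .calibration import CalibrationResults, ProbeCalibration, config_hash
from .datamodel import (
    DEFAULT_EPSILON,
    Platform,
    Space,
    Unit,
    ValidationError,
    log_transform,
    read_expression_matrix,
    read_probe_annotation,
    read_sample_metadata,
    read_scaling_table,
)
from .metrics import foldchange_concordance, replicate_correlations
from .normalization import combat_adjust
from .probe_qc import QCConfig
from .scaling import QuantileAnchor, apply_scaling, transfer_evaluation

__all__ = ["RunConfig", "run_fit_pipeline", "run_evaluate_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run."""

    array_path: str
    seq_path: str
    annotation_path: str
    metadata_path: str
    outdir: str = "."
    train_donor: str | None = None
    q_threshold: float = 0.1
    side: str = "one_sided_positive"
    lower_q: float = 0.05
    upper_q: float = 0.95
    epsilon: float = DEFAULT_EPSILON
    tbt: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a ``key: value`` config file (YAML subset, one pair a line)."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key: value'")
            key, _, raw = line.partition(":")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = raw
        for key in ("q_threshold", "lower_q", "upper_q", "epsilon"):
            if key in values:
                values[key] = float(values[key])
        if "seed" in values:
            values["seed"] = int(values["seed"])
        if "tbt" in values:
            values["tbt"] = values["tbt"].lower() in ("1", "true", "yes")
        cfg = cls(**values)
        for key in ("array_path", "seq_path", "annotation_path", "metadata_path"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise ValidationError(f"config {key} does not exist: {p}")
        return cfg

    def payload(self) -> dict:
        return dataclasses.asdict(self)

    def header(self) -> dict:
        return {
            "tool": f"ssmi {__version__}",
            "config_hash": config_hash(self.payload()),
            "seed": self.seed,
        }


def _build_model(cfg: RunConfig) -> ProbeCalibration:
    return ProbeCalibration.from_files(
        cfg.array_path,
        cfg.seq_path,
        cfg.annotation_path,
        cfg.metadata_path,
        epsilon=cfg.epsilon,
        tbt=cfg.tbt,
        qc_config=QCConfig(q_threshold=cfg.q_threshold, side=cfg.side),
        anchors=QuantileAnchor(cfg.lower_q, cfg.upper_q),
    )


def run_fit_pipeline(cfg: RunConfig) -> CalibrationResults:
    """Fit the calibration and write the scaling table + QC report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        model = _build_model(cfg)
    except ValidationError as err:
        raise ValidationError(f"stage load/normalize: {err}") from err
    try:
        results = model.fit(train_donor=cfg.train_donor)
    except ValidationError as err:
        raise ValidationError(f"stage probe_qc/fit_scaling: {err}") from err
    results.save_table(outdir / "scaling_table.csv", seed=cfg.seed)
    report = dict(cfg.header())
    report.update(results.counts)
    report["pass_rate"] = results.pass_rate
    report["gene_pass_rate"] = results.gene_pass_rate
    (outdir / "qc_report.json").write_text(json.dumps(report, indent=2) + "\n")
    logger.info("run_fit_pipeline: wrote %s", outdir / "scaling_table.csv")
    return results


def run_evaluate_pipeline(
    cfg: RunConfig,
    scaling_table_path=None,
    held_out_donor: str | None = None,
    combat: bool = False,
    n_draws: int = 100_000,
) -> dict:
    """Apply a fitted scaling table to a held-out donor and report metrics.

    The report compares unscaled log2 intensities with SSMIs per held-out
    sample (between-method correlation of absolute levels) and, with two
    donors available, fold-change concordance between donors before and
    after batch adjustment.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_path = Path(scaling_table_path or outdir / "scaling_table.csv")
    if not table_path.exists():
        raise ValidationError(f"scaling table not found: {table_path}")
    params = read_scaling_table(table_path)

    meta = read_sample_metadata(cfg.metadata_path)
    array = read_expression_matrix(
        cfg.array_path, Space.LINEAR, Platform.MICROARRAY, Unit.INTENSITY, meta
    )
    seq = read_expression_matrix(
        cfg.seq_path, Space.LINEAR, Platform.RNASEQ, Unit.TPM, meta
    )
    annot = read_probe_annotation(cfg.annotation_path)

    donors = sorted(meta.table["donor"].unique())
    if held_out_donor is None:
        held = [d for d in donors if d != cfg.train_donor]
        if not held:
            raise ValidationError("no held-out donor available")
        held_out_donor = held[0]
    samples = [
        s
        for s in meta.samples_of_donor(held_out_donor)
        if s in set(array.sample_ids) and s in set(seq.sample_ids)
    ]
    if not samples:
        raise ValidationError(f"held-out donor {held_out_donor!r} has no samples")

    array_log2 = log_transform(array.subset_samples(samples), cfg.epsilon)
    seq_log2 = log_transform(seq.subset_samples(samples), cfg.epsilon)
    best = params.loc[params["pass"] & params["is_best"], "probe_id"].tolist() if "is_best" in params.columns else None
    per_sample = transfer_evaluation(params, array_log2, seq_log2, annot, probes=best)

    report: dict = dict(cfg.header())
    report["held_out_donor"] = held_out_donor
    report["n_samples"] = len(samples)
    report["mean_r_unscaled"] = float(per_sample["r_unscaled"].mean())
    report["mean_r_ssmi"] = float(per_sample["r_ssmi"].mean())
    report["fraction_improved"] = float((per_sample["delta"] >= 0).mean())

    rep = replicate_correlations(array_log2, meta)
    report["median_replicate_r_array"] = float(rep["r"].median())

    if len(donors) >= 2 and combat:
        ssmi_all = apply_scaling(log_transform(array, cfg.epsilon), params)
        batches = meta.table.loc[list(ssmi_all.sample_ids), "batch"]
        adjusted, _ = combat_adjust(ssmi_all, batches)
        for label, mat in (("pre_combat", ssmi_all), ("post_combat", adjusted)):
            d0 = mat.subset_samples(
                [s for s in mat.sample_ids if s in set(meta.samples_of_donor(donors[0]))]
            )
            d1 = mat.subset_samples(
                [s for s in mat.sample_ids if s in set(meta.samples_of_donor(donors[1]))]
            )
            _, R = foldchange_concordance(
                d0, d1, meta, n_draws=n_draws, regions_filter="non_neocortex",
                seed=cfg.seed,
            )
            report[f"fc_concordance_{label}"] = R

    per_sample_path = outdir / "transfer_per_sample.tsv"
    with open(per_sample_path, "w") as fh:
        for key, val in cfg.header().items():
            fh.write(f"# {key}: {val}\n")
        per_sample.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    (outdir / "evaluation_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
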