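"""Matched microarray / RNA-Seq simulator with ground truth.

Emulates the study design the package targets: two donors, 22 neocortical
and 7 non-neocortical brain regions, two hemispheres and two replicates per
hemisphere (so 116 samples per donor), profiled by both platforms on the
same underlying gene abundances.

Generative model (all randomness from one seed):

- gene baseline log2 abundance ~ Normal(``baseline_log2_mean``,
  ``baseline_log2_sd``) — a wide dynamic range so a realistic share of
  genes sits in the low-count regime where sequencing is Poisson-limited;
- a ``de_fraction`` of genes carries region effects (sd larger in
  non-neocortex than neocortex) on top of a small background region sd
  shared by all genes;
- per-donor location and scale effects per gene (the batch structure the
  empirical-Bayes adjustment removes);
- RNA-Seq: fragment counts ~ Poisson(depth * relative abundance) with an
  extra log-normal sample noise; TPM = count / total * 1e6;
- microarray: each on-target probe reports the exact inverse of its linear
  transform, ``x = (log2 TPM_true - b_true) / m_true``, pushed through a
  softplus background floor and a hard saturation ceiling, plus Gaussian
  replicate noise.  Off-target probes track a different random gene;
  "bright" probes emit a high constant intensity.
- vendor-style presence flags: array = noise-free signal above the floor;
  RNA-Seq presence is derived downstream from counts >= 1.

With every noise source at zero and the floor/ceiling disabled the linear
model is closed: probe correlations are exactly 1 and the quantile fit
recovers (m_true, b_true) exactly.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    Platform,
    PresenceFlags,
    ProbeAnnotation,
    SampleMetadata,
    Space,
    Unit,
    ValidationError,
)

__all__ = ["SimulationConfig", "SyntheticTruth", "SimulationResult", "simulate", "truth_scorecard"]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the matched two-platform simulation.

    Defaults are scaled down (2000 genes, ~1.8 probes per gene, 1e5
    expected fragments per sample) so the full pipeline runs in seconds
    while preserving the regimes the method cares about: a wide abundance
    dynamic range, Poisson-limited low expressers, an intensity background
    floor, off-target and bright probes, and donor batch structure.
    """

    n_genes: int = 2000
    mean_probes_per_gene: float = 1.8   # k ~ 1 + Poisson(mean - 1)
    n_regions_neocortex: int = 22
    n_regions_other: int = 7
    n_donors: int = 2
    n_hemispheres: int = 2
    replicates_per_hemisphere: int = 2
    baseline_log2_mean: float = 1.0
    baseline_log2_sd: float = 3.5
    # upper winsorization of the baseline draw, in sd units: keeps the top
    # gene's library share realistic (a few percent) at reduced gene count,
    # where an unclipped log-normal tail would let one gene dominate the
    # compositional TPM denominator
    baseline_clip_sd: float = 2.5
    de_fraction: float = 0.3
    region_effect_sd_neocortex: float = 0.4
    region_effect_sd_other: float = 0.8
    background_region_sd: float = 0.1
    donor_location_sd: float = 0.3
    donor_scale_sd: float = 0.15
    array_noise_sd: float = 0.3
    seq_noise_sd: float = 0.15
    depth: float = 1e5                  # expected fragments per sample
    slope_median: float = 1.4           # m_true ~ LogNormal(ln median, sd)
    slope_log_sd: float = 0.4           # quartiles ~1.1-1.8: half the slopes in 1-2
    intercept_mean: float = -1.0        # b_true ~ Normal(mean, sd)
    intercept_sd: float = 3.0           # probes off by orders of magnitude exist
    off_target_fraction: float = 0.10
    bright_fraction: float = 0.02
    bright_intensity: float = 14.5     # near saturation, as cross-hybridizing
                                       # probes binding abundant material are
    background_floor: float = 1.0       # log2 intensity; -inf disables
    saturation_ceiling: float = 15.0    # log2 intensity; +inf disables
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_log2_sd",
            "region_effect_sd_neocortex",
            "region_effect_sd_other",
            "background_region_sd",
            "donor_location_sd",
            "donor_scale_sd",
            "array_noise_sd",
            "seq_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("de_fraction", "off_target_fraction", "bright_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        if self.mean_probes_per_gene < 1:
            raise ValidationError("mean_probes_per_gene must be >= 1")
        if self.n_genes < 2 or self.n_donors < 1:
            raise ValidationError("infeasible design")

    def noise_free(self) -> "SimulationConfig":
        """Copy with every noise source off and floor/ceiling disabled."""
        return dataclasses.replace(
            self,
            array_noise_sd=0.0,
            seq_noise_sd=0.0,
            off_target_fraction=0.0,
            bright_fraction=0.0,
            background_floor=-math.inf,
            saturation_ceiling=math.inf,
        )


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of one simulation run."""

    true_log2_tpm: pd.DataFrame       # genes x samples, exact log2 TPM
    baseline: pd.Series               # per-gene baseline log2 abundance
    probe_truth: pd.DataFrame         # probe_id, gene_id, tracked_gene, m_true,
                                      # b_true, on_target, bright
    de_flags: pd.Series               # genes with region effects
    transcript_length: pd.Series      # per-gene, for length-binned analyses
    depth: pd.Series                  # realized fragments per sample
    config: SimulationConfig


@dataclasses.dataclass
class SimulationResult:
    array: ExpressionMatrix           # linear intensities, probes x samples
    seq_tpm: ExpressionMatrix         # linear TPM, genes x samples
    seq_counts: ExpressionMatrix      # fragment counts, genes x samples
    presence_array: PresenceFlags
    annotation: ProbeAnnotation
    metadata: SampleMetadata
    truth: SyntheticTruth


def _softplus_floor(x: np.ndarray, floor: float) -> np.ndarray:
    """Smooth floor in log2 space: -> floor as x -> -inf, -> x for x >> floor."""
    if floor == -math.inf:
        return x
    return floor + np.log2(1.0 + np.exp2(x - floor))


def simulate(
    cfg: SimulationConfig,
    probes_from: SyntheticTruth | None = None,
    tissue_shift_sd: float | None = None,
) -> SimulationResult:
    """Generate one matched dataset plus its ground truth.

    ``probes_from`` reuses another run's probe layout and per-probe
    transforms (ids, gene assignment, m/b, off-target tracking, bright
    flags) — an "other tissue" profiled on the same array platform.  With
    ``tissue_shift_sd`` set, the new tissue also shares the source run's
    per-gene baselines up to a Normal(0, tissue_shift_sd) shift, emulating
    the substantial cross-tissue conservation of expression profiles; the
    regional structure is redrawn regardless.
    """
    rng = np.random.default_rng(cfg.seed)
    if probes_from is not None and len(probes_from.true_log2_tpm) != cfg.n_genes:
        raise ValidationError("probes_from was generated with a different n_genes")
    if tissue_shift_sd is not None and probes_from is None:
        raise ValidationError("tissue_shift_sd requires probes_from")
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    regions_neo = [f"ctx{i:02d}" for i in range(cfg.n_regions_neocortex)]
    regions_other = [f"sub{i:02d}" for i in range(cfg.n_regions_other)]
    regions = regions_neo + regions_other
    donors = [f"brain{i + 1}" for i in range(cfg.n_donors)]
    hemis = ["L", "R"][: cfg.n_hemispheres]

    # ---- sample grid & metadata ------------------------------------------
    rows = []
    for d in donors:
        for reg in regions:
            cls = "neocortex" if reg in regions_neo else "non_neocortex"
            for h in hemis:
                for rep in range(1, cfg.replicates_per_hemisphere + 1):
                    rows.append(
                        {
                            "sample_id": f"{d}_{reg}_{h}{rep}",
                            "donor": d,
                            "region": reg,
                            "region_class": cls,
                            "hemisphere": h,
                            "replicate": rep,
                            "batch": d,
                        }
                    )
    meta = SampleMetadata(pd.DataFrame(rows))
    samples = meta.table["sample_id"].tolist()
    n_samples = len(samples)
    sample_region = meta.table.loc[samples, "region"].to_numpy()
    sample_donor = meta.table.loc[samples, "donor"].to_numpy()
    region_idx = np.array([regions.index(r) for r in sample_region])
    donor_idx = np.array([donors.index(d) for d in sample_donor])

    # ---- gene truth -------------------------------------------------------
    if tissue_shift_sd is not None:
        baseline = (
            probes_from.baseline.to_numpy(dtype=float)
            + rng.normal(0.0, tissue_shift_sd, cfg.n_genes)
        )
    else:
        baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
        baseline = np.minimum(
            baseline,
            cfg.baseline_log2_mean + cfg.baseline_clip_sd * cfg.baseline_log2_sd,
        )
    de_flags = rng.random(cfg.n_genes) < cfg.de_fraction
    region_sd = np.array(
        [cfg.region_effect_sd_neocortex] * len(regions_neo)
        + [cfg.region_effect_sd_other] * len(regions_other)
    )
    region_eff = rng.normal(0.0, 1.0, (cfg.n_genes, len(regions)))
    region_eff *= np.where(de_flags[:, None], region_sd[None, :], cfg.background_region_sd)
    donor_loc = rng.normal(0.0, cfg.donor_location_sd, (cfg.n_genes, cfg.n_donors))
    donor_scale = np.exp(rng.normal(0.0, cfg.donor_scale_sd, (cfg.n_genes, cfg.n_donors)))
    if cfg.donor_location_sd == 0:
        donor_loc[:] = 0.0
    if cfg.donor_scale_sd == 0:
        donor_scale[:] = 1.0

    # per-sample true signal in log2 relative-abundance units
    scale = donor_scale[:, donor_idx]
    signal = (
        baseline[:, None]
        + donor_loc[:, donor_idx]
        + scale * region_eff[:, region_idx]
    )
    seq_noise = (
        rng.normal(0.0, cfg.seq_noise_sd, (cfg.n_genes, n_samples))
        if cfg.seq_noise_sd > 0
        else np.zeros((cfg.n_genes, n_samples))
    )
    noisy = signal + scale * seq_noise

    w = np.exp2(noisy)
    p_rel = w / w.sum(axis=0, keepdims=True)
    true_tpm = p_rel * 1e6
    true_log2_tpm = np.log2(true_tpm)

    noise_free = cfg.array_noise_sd == 0 and cfg.seq_noise_sd == 0
    expected = cfg.depth * p_rel
    if noise_free:
        counts = np.round(expected)
        tpm = true_tpm.copy()
    else:
        counts = rng.poisson(expected).astype(float)
        tot = counts.sum(axis=0)
        if (tot == 0).any():
            raise ValidationError("a sample drew zero fragments; increase depth")
        tpm = counts / tot * 1e6

    # ---- probes -----------------------------------------------------------
    if probes_from is not None:
        prev = probes_from.probe_truth
        gene_pos = {g: i for i, g in enumerate(genes)}
        probe_ids = prev["probe_id"].tolist()
        probe_gene_idx = np.array([gene_pos[g] for g in prev["gene_id"]])
        tracked = np.array([gene_pos[g] for g in prev["tracked_gene"]])
        m_true = prev["m_true"].to_numpy(dtype=float)
        b_true = prev["b_true"].to_numpy(dtype=float)
        bright = prev["bright"].to_numpy(dtype=bool)
        n_probes = len(probe_ids)
    else:
        extra = rng.poisson(cfg.mean_probes_per_gene - 1.0, cfg.n_genes)
        probe_gene_idx = np.repeat(np.arange(cfg.n_genes), 1 + extra)
        n_probes = probe_gene_idx.size
        within = np.concatenate([np.arange(k) for k in (1 + extra)])
        probe_ids = [f"p_{genes[g]}_{i}" for g, i in zip(probe_gene_idx, within)]

        m_true = np.exp(rng.normal(np.log(cfg.slope_median), cfg.slope_log_sd, n_probes))
        b_true = rng.normal(cfg.intercept_mean, cfg.intercept_sd, n_probes)
        u = rng.random(n_probes)
        bright = u < cfg.bright_fraction
        off_target = (~bright) & (u < cfg.bright_fraction + cfg.off_target_fraction)
        tracked = probe_gene_idx.copy()
        if off_target.any():
            shift = rng.integers(1, cfg.n_genes, size=int(off_target.sum()))
            tracked[off_target] = (tracked[off_target] + shift) % cfg.n_genes

    x0 = (true_log2_tpm[tracked] - b_true[:, None]) / m_true[:, None]
    if bright.any():
        x0[bright] = cfg.bright_intensity
    x_clean = np.minimum(
        _softplus_floor(x0, cfg.background_floor), cfg.saturation_ceiling
    )
    array_noise = (
        rng.normal(0.0, cfg.array_noise_sd, (n_probes, n_samples))
        if cfg.array_noise_sd > 0
        else 0.0
    )
    x_log2 = x_clean + array_noise
    intensity = np.exp2(x_log2)

    # vendor-style detection call: noise-free signal above the floor
    if cfg.background_floor == -math.inf:
        present_array = np.ones_like(x0, dtype=bool)
    else:
        present_array = x0 > cfg.background_floor

    # ---- containers -------------------------------------------------------
    sample_index = pd.Index(samples)
    gene_index = pd.Index(genes, name="feature_id")
    probe_index = pd.Index(probe_ids, name="feature_id")
    array = ExpressionMatrix(
        pd.DataFrame(intensity, index=probe_index, columns=sample_index),
        Space.LINEAR,
        Platform.MICROARRAY,
        Unit.INTENSITY,
    )
    seq_tpm = ExpressionMatrix(
        pd.DataFrame(tpm, index=gene_index, columns=sample_index),
        Space.LINEAR,
        Platform.RNASEQ,
        Unit.TPM,
    )
    seq_counts = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_index, columns=sample_index),
        Space.LINEAR,
        Platform.RNASEQ,
        Unit.COUNTS,
    )
    presence = PresenceFlags(
        pd.DataFrame(present_array, index=probe_index, columns=sample_index),
        Platform.MICROARRAY,
    )
    annot = ProbeAnnotation(
        pd.DataFrame(
            {"probe_id": probe_ids, "gene_id": [genes[g] for g in probe_gene_idx]}
        )
    )
    probe_truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": [genes[g] for g in probe_gene_idx],
            "tracked_gene": [genes[g] for g in tracked],
            "m_true": m_true,
            "b_true": b_true,
            "on_target": (tracked == probe_gene_idx) & ~bright,
            "bright": bright,
        }
    )
    transcript_length = pd.Series(
        np.exp(rng.normal(np.log(2500.0), 0.8, cfg.n_genes)),
        index=gene_index,
        name="length",
    )
    truth = SyntheticTruth(
        true_log2_tpm=pd.DataFrame(true_log2_tpm, index=gene_index, columns=sample_index),
        baseline=pd.Series(baseline, index=gene_index, name="baseline"),
        probe_truth=probe_truth,
        de_flags=pd.Series(de_flags, index=gene_index, name="de"),
        transcript_length=transcript_length,
        depth=pd.Series(counts.sum(axis=0), index=sample_index, name="depth"),
        config=cfg,
    )
    return SimulationResult(
        array=array,
        seq_tpm=seq_tpm,
        seq_counts=seq_counts,
        presence_array=presence,
        annotation=annot,
        metadata=meta,
        truth=truth,
    )


def expected_probe_correlation(
    sim: SimulationResult, samples: list[str], epsilon: float
) -> pd.Series:
    """Truth-derived per-probe population correlation over given samples.

    The correlation a probe's log2 intensity would attain with its
    *annotated* gene's observed log2(TPM + epsilon) is computed from the
    generator's ground truth: the noise-free probe signal (the inverse
    linear transform pushed through floor and ceiling), attenuated by the
    known array noise variance and by the realized sequencing measurement
    variance (observed minus true log2 TPM).  Used to stratify power
    analyses by true effect size, independently of any fitted quantity.
    """
    cfg = sim.truth.config
    pt = sim.truth.probe_truth
    gene_pos = {g: i for i, g in enumerate(sim.truth.true_log2_tpm.index)}
    tracked = np.array([gene_pos[g] for g in pt["tracked_gene"]])
    annotated = np.array([gene_pos[g] for g in pt["gene_id"]])

    true_log2 = sim.truth.true_log2_tpm.loc[:, samples].to_numpy(dtype=float)
    obs_log2 = np.log2(sim.seq_tpm.data.loc[:, samples].to_numpy(dtype=float) + epsilon)
    true_eps = np.log2(np.exp2(true_log2) + epsilon)

    x_clean = (true_log2[tracked] - pt["b_true"].to_numpy()[:, None]) / pt[
        "m_true"
    ].to_numpy()[:, None]
    bright = pt["bright"].to_numpy()
    if bright.any():
        x_clean[bright] = cfg.bright_intensity
    x_clean = np.minimum(
        _softplus_floor(x_clean, cfg.background_floor), cfg.saturation_ceiling
    )

    y_clean = true_eps[annotated]
    seq_resid_var = ((obs_log2 - true_eps) ** 2).mean(axis=1)[annotated]

    xc = x_clean - x_clean.mean(axis=1, keepdims=True)
    yc = y_clean - y_clean.mean(axis=1, keepdims=True)
    n = len(samples)
    var_x = (xc ** 2).mean(axis=1)
    var_y = (yc ** 2).mean(axis=1)
    cov = (xc * yc).mean(axis=1)
    denom = np.sqrt(
        (var_x + cfg.array_noise_sd ** 2) * (var_y + seq_resid_var)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, cov / denom, 0.0)
    return pd.Series(np.clip(rho, -1.0, 1.0), index=pt["probe_id"].to_numpy(), name="rho")


def truth_scorecard(
    truth: SyntheticTruth,
    qc_records: pd.DataFrame,
    params: pd.DataFrame | None = None,
) -> dict:
    """Recovery report of a QC + scaling run against simulation truth.

    Reports off-target detection sensitivity (fraction of off-target probes
    failing QC), the realized false discovery rate of the pass set, the
    best-probe recovery rate (genes whose designated best probe is
    on-target, among genes with at least one on-target probe scored), and
    quantiles of the (m, b) recovery error over on-target passing probes.
    """
    pt = truth.probe_truth.set_index("probe_id")
    rec = qc_records.set_index("probe_id")
    common = rec.index.intersection(pt.index)
    if len(common) == 0:
        raise ValidationError("qc records do not match the simulation truth")
    rec = rec.loc[common]
    on = pt.loc[common, "on_target"].to_numpy()
    passed = rec["pass"].to_numpy(dtype=bool)

    out: dict = {
        "n_probes": int(len(common)),
        "n_pass": int(passed.sum()),
        "pass_rate": float(passed.mean()),
        "offtarget_sensitivity": float((~passed[~on]).mean()) if (~on).any() else np.nan,
        "offtarget_pass_fraction": float(passed[~on].mean()) if (~on).any() else np.nan,
        "pass_fdr": float((~on[passed]).mean()) if passed.any() else np.nan,
        "ontarget_pass_rate": float(passed[on].mean()) if on.any() else np.nan,
    }
    if "is_best" in rec.columns:
        best = rec.loc[rec["is_best"].astype(bool)]
        genes_with_on_target = set(pt.loc[pt["on_target"], "gene_id"])
        eligible = best.loc[best["gene_id"].isin(genes_with_on_target)]
        if len(eligible):
            out["best_probe_recovery"] = float(
                pt.loc[eligible.index, "on_target"].mean()
            )
    if params is not None and len(params):
        keyed = params.set_index("probe_id")
        shared = keyed.index.intersection(pt.index)
        on_shared = shared[pt.loc[shared, "on_target"]]
        if len(on_shared):
            dm = (keyed.loc[on_shared, "m"] - pt.loc[on_shared, "m_true"]).abs()
            db = (keyed.loc[on_shared, "b"] - pt.loc[on_shared, "b_true"]).abs()
            out["m_abs_err_median"] = float(dm.median())
            out["m_abs_err_q90"] = float(dm.quantile(0.9))
            out["b_abs_err_median"] = float(db.median())
            out["b_abs_err_q90"] = float(db.quantile(0.9))
    return out
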