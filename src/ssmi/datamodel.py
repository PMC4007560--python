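"""Shared data model and TSV/CSV input-output.

Expression data from both platforms travel through the package as
:class:`ExpressionMatrix` objects: a features x samples table of real values
together with a declared *space* (``linear`` or ``log2``), the *platform*
that produced it (``microarray`` or ``rnaseq``) and the *unit* of the values
(``intensity``, ``tpm``, ``counts`` or ``ssmi``).  Sample annotations
(donor, brain region, region class, hemisphere, replicate, batch) live in a
:class:`SampleMetadata`, probe-to-gene assignment in a
:class:`ProbeAnnotation`.

All on-disk artifacts are plain text: tab-separated matrices with the
feature identifier in a first column named ``feature_id``, a two-column
probe annotation TSV, a fixed-column metadata TSV, and a CSV scaling table
combining per-probe quality-control records and linear scaling parameters.
Readers skip ``#`` comment lines so outputs may carry provenance headers.
"""

from __future__ import annotations

import dataclasses
import enum
import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Space",
    "Platform",
    "Unit",
    "ExpressionMatrix",
    "SampleMetadata",
    "ProbeAnnotation",
    "PresenceFlags",
    "ValidationError",
    "ParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_annotation",
    "read_sample_metadata",
    "write_scaling_table",
    "read_scaling_table",
    "log_transform",
    "unlog_transform",
    "DEFAULT_EPSILON",
    "SCALING_TABLE_COLUMNS",
]

#: Default offset added before taking log2 of linear values.  Small enough
#: not to distort values >= 1 (TPM or intensity) while keeping zeros finite.
DEFAULT_EPSILON = 2.0 ** -10


class ValidationError(ValueError):
    """An object violates a data-model invariant."""


class ParseError(ValueError):
    """A text artifact could not be parsed; the message names the cell."""


class Space(str, enum.Enum):
    LINEAR = "linear"
    LOG2 = "log2"


class Platform(str, enum.Enum):
    MICROARRAY = "microarray"
    RNASEQ = "rnaseq"


class Unit(str, enum.Enum):
    INTENSITY = "intensity"
    TPM = "TPM"
    COUNTS = "counts"
    SSMI = "SSMI"


@dataclasses.dataclass
class ExpressionMatrix:
    """Features x samples expression values with declared space/platform/unit.

    Parameters
    ----------
    data
        DataFrame with unique feature identifiers as index and unique
        sample identifiers as columns; all values finite.
    space
        ``linear`` (raw intensities / TPM / counts) or ``log2``.
    platform
        Producing platform, ``microarray`` or ``rnaseq``.
    unit
        Physical unit of the values.
    """

    data: pd.DataFrame
    space: Space
    platform: Platform
    unit: Unit

    def __post_init__(self) -> None:
        self.space = Space(self.space)
        self.platform = Platform(self.platform)
        self.unit = Unit(self.unit)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression matrix contains NaN/Inf values")
        if self.space is Space.LINEAR and values.size and values.min() < 0:
            raise ValidationError(
                "negative value in a linear-space matrix "
                f"(min={values.min():g})"
            )
        if self.unit is Unit.COUNTS and values.size:
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts matrix contains non-integers")

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return ExpressionMatrix(
            self.data.loc[:, ids].copy(), self.space, self.platform, self.unit
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        missing = [f for f in ids if f not in self.data.index]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing[:5]}")
        return ExpressionMatrix(
            self.data.loc[ids].copy(), self.space, self.platform, self.unit
        )

    def copy_with(self, data: pd.DataFrame, **kwargs) -> "ExpressionMatrix":
        fields = dict(space=self.space, platform=self.platform, unit=self.unit)
        fields.update(kwargs)
        return ExpressionMatrix(data, **fields)


METADATA_COLUMNS = [
    "sample_id",
    "donor",
    "region",
    "region_class",
    "hemisphere",
    "replicate",
    "batch",
]

REGION_CLASSES = ("neocortex", "non_neocortex")


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample annotations driving every grouping in the package."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id in metadata: {dup!r}")
        bad_class = set(t["region_class"]) - set(REGION_CLASSES)
        if bad_class:
            raise ValidationError(f"unknown region_class values: {bad_class}")
        bad_hemi = set(t["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValidationError(f"hemisphere must be L or R, got {bad_hemi}")
        # region_class must be a function of region
        n_class = t.groupby("region")["region_class"].nunique()
        if (n_class > 1).any():
            bad = n_class[n_class > 1].index.tolist()
            raise ValidationError(f"regions mapped to both classes: {bad}")
        self.table = t.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        """Raise unless every given sample id is annotated exactly once."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(
                f"samples absent from metadata: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        self.require_samples(sample_ids)
        return SampleMetadata(
            self.table.loc[list(sample_ids)].reset_index(drop=True)
        )

    def samples_of_donor(self, donor: str) -> list[str]:
        sel = self.table.loc[self.table["donor"] == donor, "sample_id"]
        if sel.empty:
            raise ValidationError(f"no samples for donor {donor!r}")
        return sel.tolist()

    def neocortex_mask(self, sample_ids: Iterable[str]) -> pd.Series:
        ids = list(sample_ids)
        self.require_samples(ids)
        return self.table.loc[ids, "region_class"].eq("neocortex")


@dataclasses.dataclass
class ProbeAnnotation:
    """Probe -> gene assignment; a gene may own several probes."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("probe_id", "gene_id"):
            if col not in self.table.columns:
                raise ValidationError(f"probe annotation missing {col!r}")
        if self.table["probe_id"].duplicated().any():
            dup = self.table.loc[
                self.table["probe_id"].duplicated(), "probe_id"
            ].iloc[0]
            raise ValidationError(f"duplicate probe_id: {dup!r}")
        self.table = self.table.reset_index(drop=True)

    def gene_of(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene_id"]

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])


@dataclasses.dataclass
class PresenceFlags:
    """Boolean features x samples detection calls for one platform."""

    flags: pd.DataFrame
    platform: Platform

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        if self.flags.dtypes.apply(lambda d: d != bool).any():
            self.flags = self.flags.astype(bool)

    def matches(self, mat: ExpressionMatrix) -> bool:
        return self.flags.index.equals(mat.feature_ids) and self.flags.columns.equals(
            mat.sample_ids
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype=str)


def read_expression_matrix(
    path,
    space: Space | str,
    platform: Platform | str,
    unit: Unit | str,
    metadata: SampleMetadata | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (feature_id column + one column per sample).

    Malformed numeric cells raise :class:`ParseError` naming the offending
    row and column; duplicated identifiers raise :class:`ValidationError`.
    When ``metadata`` is given, every sample id must be annotated in it.
    """
    raw = _read_table(path, sep="\t")
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected feature_id column plus samples")
    feature_col = raw.columns[0]
    features = raw[feature_col]
    values = raw.drop(columns=[feature_col])
    columns = {}
    for col in values.columns:
        converted = pd.to_numeric(values[col], errors="coerce")
        bad = converted.isna() & values[col].notna()
        if bad.any():
            row = features[bad].iloc[0]
            cell = values.loc[bad, col].iloc[0]
            raise ParseError(
                f"{path}: malformed numeric cell {cell!r} at feature "
                f"{row!r}, sample {col!r}"
            )
        if converted.isna().any():
            row = features[converted.isna()].iloc[0]
            raise ValidationError(
                f"{path}: missing value at feature {row!r}, sample {col!r}"
            )
        columns[col] = converted.astype(float)
    numeric = pd.DataFrame(columns)
    numeric.index = pd.Index(features, name="feature_id")
    mat = ExpressionMatrix(numeric, Space(space), Platform(platform), Unit(unit))
    if metadata is not None:
        metadata.require_samples(mat.sample_ids)
    return mat


def write_expression_matrix(
    mat: ExpressionMatrix, path, header: Mapping[str, object] | None = None
) -> None:
    """Write the TSV dialect read by :func:`read_expression_matrix`.

    ``header`` entries are emitted as leading ``# key: value`` comment lines
    (provenance: tool version, config hash, seed).
    """
    path = Path(path)
    buf = _io.StringIO()
    for key, val in (header or {}).items():
        buf.write(f"# {key}: {val}\n")
    out = mat.data.copy()
    out.index.name = "feature_id"
    out.to_csv(buf, sep="\t", float_format="%.12g")
    path.write_text(buf.getvalue())


def read_probe_annotation(path) -> ProbeAnnotation:
    raw = _read_table(path, sep="\t")
    if list(raw.columns[:2]) != ["probe_id", "gene_id"]:
        raise ParseError(
            f"{path}: expected columns probe_id, gene_id; got {list(raw.columns)}"
        )
    return ProbeAnnotation(raw[["probe_id", "gene_id"]])


def read_sample_metadata(path) -> SampleMetadata:
    raw = _read_table(path, sep="\t")
    if "replicate" in raw.columns:
        raw["replicate"] = raw["replicate"].astype(int)
    return SampleMetadata(raw)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.table.reset_index(drop=True).to_csv(path, sep="\t", index=False)


SCALING_TABLE_COLUMNS = [
    "probe_id",
    "gene_id",
    "m",
    "b",
    "r",
    "p",
    "q",
    "pass",
    "q05_array",
    "q95_array",
    "q05_seq",
    "q95_seq",
    "n_train",
]


def write_scaling_table(
    table: pd.DataFrame, path, header: Mapping[str, object] | None = None
) -> None:
    """Write the combined QC + scaling-parameter CSV.

    One row per probe; probes that failed QC appear with ``pass=False`` and
    empty ``m``/``b`` (and anchor quantile) cells.  Floats carry 12
    significant digits so a read-back reproduces them exactly at that
    precision.
    """
    out = table.copy()
    for col in SCALING_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[SCALING_TABLE_COLUMNS]
    path = Path(path)
    buf = _io.StringIO()
    for key, val in (header or {}).items():
        buf.write(f"# {key}: {val}\n")
    out.to_csv(buf, index=False, float_format="%.12g")
    path.write_text(buf.getvalue())


def read_scaling_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path, comment="#")
    missing = [c for c in SCALING_TABLE_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: scaling table missing columns {missing}")
    raw["pass"] = raw["pass"].astype(bool)
    return raw


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def log_transform(
    mat: ExpressionMatrix, epsilon: float = DEFAULT_EPSILON
) -> ExpressionMatrix:
    """Return ``log2(x + epsilon)`` of a linear-space matrix.

    ``epsilon`` must be positive when the matrix contains zeros.
    """
    if mat.space is not Space.LINEAR:
        raise ValidationError("log_transform expects a linear-space matrix")
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    values = mat.data.to_numpy()
    if epsilon == 0 and values.size and (values == 0).any():
        raise ValidationError("epsilon=0 with zero values: log2(0) undefined")
    out = pd.DataFrame(
        np.log2(values + epsilon), index=mat.data.index, columns=mat.data.columns
    )
    return ExpressionMatrix(out, Space.LOG2, mat.platform, mat.unit)


def unlog_transform(
    mat: ExpressionMatrix, epsilon: float = DEFAULT_EPSILON
) -> ExpressionMatrix:
    """Inverse of :func:`log_transform`: ``2**y - epsilon`` (clipped at 0)."""
    if mat.space is not Space.LOG2:
        raise ValidationError("unlog_transform expects a log2-space matrix")
    values = np.maximum(2.0 ** mat.data.to_numpy() - epsilon, 0.0)
    out = pd.DataFrame(values, index=mat.data.index, columns=mat.data.columns)
    return ExpressionMatrix(out, Space.LINEAR, mat.platform, mat.unit)
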