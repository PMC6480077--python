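"""Reading, detection filtering and ΔCq normalization of qPCR panel data.

A qPCR panel reports, for every sample × miRNA assay pair, a quantification
cycle (Cq): the PCR cycle at which amplification crosses a fixed threshold.
Lower Cq means more template. Assays whose signal never reaches the
threshold within the instrument's cycle budget (40 by default) are *absent*.

Relative abundance is expressed as ΔCq = Cq(target) − reference, where the
reference is the per-sample mean Cq of a fixed set of internal-control
miRNAs (or, alternatively, of all detected assays — "global mean"
normalization). Under this convention a more abundant miRNA has a lower
ΔCq, i.e. a higher −ΔCq.

Absent/undetermined measurements are carried as NaN throughout; the
sample × assay grids are plain :class:`pandas.DataFrame` objects.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CqMatrix",
    "DeltaCqMatrix",
    "NormalizationConfig",
    "NormalizationMethod",
    "CqParseError",
    "NormalizationError",
    "DEFAULT_CONTROL_ASSAYS",
    "DEFAULT_MAX_CYCLES",
    "read_cq_table",
    "write_cq_table",
    "apply_detection_filter",
    "undetected_assays",
    "normalize",
    "write_delta_cq",
    "read_delta_cq",
]

#: Internal-control miRNAs used as the per-sample ΔCq reference. These five
#: are widely used as stable references for serum/plasma focus panels.
DEFAULT_CONTROL_ASSAYS: tuple[str, ...] = (
    "hsa-miR-425-5p",
    "hsa-miR-423-5p",
    "hsa-miR-103a-3p",
    "hsa-miR-191-5p",
    "hsa-miR-93-5p",
)

#: Detection cutoff: a Cq at or beyond this cycle count is treated as absent.
DEFAULT_MAX_CYCLES: float = 40.0


class CqParseError(ValueError):
    """Malformed Cq table (missing header, duplicate keys, ragged rows)."""


class NormalizationError(ValueError):
    """A sample cannot be normalized (e.g. no detected control assays)."""

    def __init__(self, message: str, samples: list[str] | None = None):
        super().__init__(message)
        self.samples = samples or []


class NormalizationMethod(str, enum.Enum):
    INTERNAL_CONTROL = "internal_control"
    GLOBAL_MEAN = "global_mean"


@dataclass(frozen=True)
class NormalizationConfig:
    """How raw Cq values are turned into ΔCq values.

    Parameters
    ----------
    method:
        ``INTERNAL_CONTROL`` subtracts the per-sample mean Cq of
        ``control_assays``; ``GLOBAL_MEAN`` subtracts the per-sample mean
        Cq over all detected assays.
    control_assays:
        Reference assay identifiers (ignored for ``GLOBAL_MEAN``).
    max_cycles:
        Detection cutoff in cycles; Cq ≥ ``max_cycles`` counts as absent.
    """

    method: NormalizationMethod = NormalizationMethod.INTERNAL_CONTROL
    control_assays: tuple[str, ...] = DEFAULT_CONTROL_ASSAYS
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", NormalizationMethod(self.method))
        object.__setattr__(self, "control_assays", tuple(self.control_assays))
        if self.max_cycles <= 0:
            raise ValueError("max_cycles must be > 0")
        if (
            self.method is NormalizationMethod.INTERNAL_CONTROL
            and not self.control_assays
        ):
            raise ValueError("control_assays must be non-empty for internal-control normalization")


def _check_grid(values: pd.DataFrame, kind: str) -> None:
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {kind}: {dupes}")
    if values.columns.has_duplicates:
        dupes = values.columns[values.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate assay ids in {kind}: {dupes}")


@dataclass
class CqMatrix:
    """Raw Cq values, samples × assays; NaN marks an absent measurement."""

    cq: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cq = self.cq.astype(float)
        _check_grid(self.cq, "Cq matrix")
        finite = self.cq.to_numpy()
        if np.any(finite[np.isfinite(finite)] <= 0):
            raise ValueError("all finite Cq values must be > 0 cycles")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.cq.columns)


@dataclass
class DeltaCqMatrix:
    """Normalized ΔCq values plus the normalization that produced them."""

    delta_cq: pd.DataFrame
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)

    def __post_init__(self) -> None:
        self.delta_cq = self.delta_cq.astype(float)
        _check_grid(self.delta_cq, "ΔCq matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.delta_cq.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.delta_cq.columns)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ("sample", "assay", "cq")


def _coerce_cq(values: pd.Series) -> pd.Series:
    """Non-numeric cells ("Undetermined", blanks, ...) become NaN (absent)."""
    return pd.to_numeric(values, errors="coerce")


def read_cq_table(path, layout: str = "wide", sep: str | None = None) -> CqMatrix:
    """Read a delimited Cq table.

    ``layout="wide"``: first column is the sample id, remaining columns are
    assays. ``layout="long"``: columns ``sample``, ``assay``, ``cq``.
    The delimiter is sniffed (comma or tab) unless ``sep`` is given.
    Non-numeric Cq cells map to absent. Duplicate (sample, assay) pairs are
    an error.
    """
    layout = layout.lower()
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    try:
        raw = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise CqParseError(f"{path}: empty file or missing header") from exc
    if raw.columns.size < 2:
        raise CqParseError(f"{path}: expected a delimited header with >= 2 columns")

    if layout == "long":
        cols = [c.strip().lower() for c in raw.columns]
        missing = [c for c in _LONG_COLUMNS if c not in cols]
        if missing:
            raise CqParseError(f"{path}: long layout requires columns {_LONG_COLUMNS}, missing {missing}")
        raw.columns = cols
        dup = raw.duplicated(subset=["sample", "assay"], keep=False)
        if dup.any():
            first = raw.loc[dup, ["sample", "assay"]].iloc[0]
            raise CqParseError(
                f"{path}: duplicate (sample, assay) pair ({first['sample']}, {first['assay']})"
            )
        values = raw.assign(cq=_coerce_cq(raw["cq"])).pivot(
            index="sample", columns="assay", values="cq"
        )
        # preserve input encounter order rather than pivot's lexicographic order
        values = values.reindex(
            index=raw["sample"].drop_duplicates(),
            columns=raw["assay"].drop_duplicates(),
        )
    else:
        if raw.isna().all(axis=1).any():
            bad = int(raw.index[raw.isna().all(axis=1)][0]) + 2
            raise CqParseError(f"{path}: blank row at line {bad}")
        sample_col = raw.columns[0]
        if raw[sample_col].isna().any():
            bad = int(raw.index[raw[sample_col].isna()][0]) + 2
            raise CqParseError(f"{path}: missing sample id at line {bad}")
        if raw[sample_col].duplicated().any():
            dupes = raw.loc[raw[sample_col].duplicated(), sample_col].tolist()
            raise CqParseError(f"{path}: duplicate sample rows {dupes}")
        values = raw.set_index(sample_col).apply(_coerce_cq)

    values.index = values.index.astype(str)
    values.index.name = "sample"
    values.columns = values.columns.astype(str)
    values.columns.name = "assay"
    return CqMatrix(values)


def write_cq_table(m: CqMatrix, path, layout: str = "wide", sep: str = "\t") -> None:
    """Write a Cq matrix; absent cells are written as ``NA``."""
    if layout == "wide":
        m.cq.to_csv(path, sep=sep, na_rep="NA", index_label="sample")
    elif layout == "long":
        long = m.cq.stack(future_stack=True).rename("cq").reset_index()
        long.columns = list(_LONG_COLUMNS)
        long.to_csv(path, sep=sep, na_rep="NA", index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


# ---------------------------------------------------------------------------
# Detection filter
# ---------------------------------------------------------------------------

def apply_detection_filter(m: CqMatrix, cfg: NormalizationConfig | None = None) -> CqMatrix:
    """Mark every Cq at or beyond the cycle cutoff as absent.

    Targets that fail to cross the amplification threshold within
    ``cfg.max_cycles`` cycles carry no abundance information; a reported
    Cq ≥ the cutoff is read as "did not reach threshold" and masked.
    The operation is idempotent. Assays left with zero detected samples are
    retained (see :func:`undetected_assays` for the exclusion report).
    """
    cfg = cfg or NormalizationConfig()
    filtered = m.cq.where(m.cq < cfg.max_cycles)
    return CqMatrix(filtered, metadata=m.metadata)


def undetected_assays(m: CqMatrix) -> pd.DataFrame:
    """Report assays detected in zero samples (to exclude downstream)."""
    detected = m.cq.notna().sum(axis=0)
    report = pd.DataFrame(
        {"assay": m.assay_ids, "n_detected": detected.to_numpy(), "n_samples": len(m.sample_ids)}
    )
    return report[report["n_detected"] == 0].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(m: CqMatrix, cfg: NormalizationConfig | None = None) -> DeltaCqMatrix:
    """Convert Cq to ΔCq: per-sample reference subtraction.

    ΔCq(sample, assay) = Cq(sample, assay) − reference(sample), where the
    reference is the mean Cq over *detected* control assays
    (``INTERNAL_CONTROL``) or over all detected assays (``GLOBAL_MEAN``).
    Absent cells stay missing. Control assays receive ΔCq values like any
    other assay (marker panels simply never include them).

    Raises
    ------
    NormalizationError
        If, under internal-control normalization, any sample has zero
        detected control assays (the error lists the offending samples).
    """
    cfg = cfg or NormalizationConfig()
    cq = m.cq
    if cfg.method is NormalizationMethod.INTERNAL_CONTROL:
        controls = [a for a in cfg.control_assays if a in cq.columns]
        if not controls:
            raise NormalizationError(
                f"none of the control assays {list(cfg.control_assays)} are on the panel"
            )
        ref = cq[controls].mean(axis=1)  # mean over detected controls only
        bad = ref.index[ref.isna()].tolist()
        if bad:
            raise NormalizationError(
                f"samples with zero detected control assays: {bad}", samples=bad
            )
    else:
        ref = cq.mean(axis=1)
        bad = ref.index[ref.isna()].tolist()
        if bad:
            raise NormalizationError(f"samples with zero detected assays: {bad}", samples=bad)
    delta = cq.sub(ref, axis=0)
    return DeltaCqMatrix(delta, normalization=cfg)


def write_delta_cq(d: DeltaCqMatrix, path, sep: str = "\t") -> None:
    """Write a ΔCq matrix as samples × assays text, ``NA`` for missing."""
    d.delta_cq.to_csv(path, sep=sep, na_rep="NA", index_label="sample")


def read_delta_cq(path, sep: str | None = None,
                  cfg: NormalizationConfig | None = None,
                  negate: bool = False) -> DeltaCqMatrix:
    """Read a samples × assays ΔCq table written by :func:`write_delta_cq`.

    ``negate=True`` accepts tables printed in −ΔCq units (as reports
    typically present them, higher = more abundant) and converts to the
    internal ΔCq convention on load.
    """
    raw = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    if raw.columns.size < 2:
        raise CqParseError(f"{path}: expected a delimited header with >= 2 columns")
    values = raw.set_index(raw.columns[0]).apply(_coerce_cq)
    values.index = values.index.astype(str)
    values.index.name = "sample"
    values.columns.name = "assay"
    if negate:
        values = -values
    return DeltaCqMatrix(values, normalization=cfg or NormalizationConfig())
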