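"""Core in-memory containers shared by every pipeline stage.

Expression data live in an :class:`ExpressionMatrix` (genes x samples on a
linear or log2 scale; RT-PCR values are -dCt-like, i.e. higher = more
transcript).  Sample phenotypes live in a plain :class:`pandas.DataFrame`
validated by :func:`validate_samples`, indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("linear", "log2")
VALID_PLATFORMS = ("microarray", "rtpcr")
VALID_STATUS = ("case", "control")
VALID_SEX = ("M", "F")
VALID_CHEST_PAIN = ("asymptomatic", "atypical", "non-anginal", "typical")

#: columns every sample sheet must provide
REQUIRED_SAMPLE_COLUMNS = ("status", "sex", "age")
#: optional, recognised columns (anything else is carried through untouched)
OPTIONAL_SAMPLE_COLUMNS = (
    "diabetic",
    "neutrophil_count",
    "lymphocyte_count",
    "pair_id",
    "chest_pain",
)


class CadscoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CadscoreError):
    """Invalid configuration or parameters."""


class DataError(CadscoreError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with scale and platform tags.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    scale
        ``"linear"`` (non-negative intensities) or ``"log2"``
        (log2 intensity or -dCt).
    platform
        ``"microarray"`` or ``"rtpcr"``.
    """

    data: pd.DataFrame
    scale: str = "log2"
    platform: str = "microarray"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.platform not in VALID_PLATFORMS:
            raise ConfigurationError(f"unknown platform {self.platform!r}")
        if not isinstance(self.data, pd.DataFrame):
            raise DataError("ExpressionMatrix.data must be a DataFrame")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)

    # -- convenience views ------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        """Return a sub-matrix restricted to the given genes/samples."""
        data = self.data
        if genes is not None:
            missing = [g for g in genes if g not in data.index]
            if missing:
                raise DataError(f"genes not present: {missing}")
            data = data.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in data.columns]
            if missing:
                raise DataError(f"samples not present: {missing}")
            data = data[list(samples)]
        return ExpressionMatrix(data.copy(), scale=self.scale, platform=self.platform)

    def align_samples(self, samples: pd.DataFrame) -> "ExpressionMatrix":
        """Restrict and order columns to the sample table's index."""
        return self.subset(samples=samples.index)


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample sheet.

    The index is the sample id.  ``status``/``sex``/``chest_pain`` tokens are
    case-insensitive; unknown tokens raise :class:`DataError` naming the row.
    Records with missing age are kept but flagged via the ``age_missing``
    column so age-requiring stages can exclude them.
    """
    df = df.copy()
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample ids: {dups}")
    for col in REQUIRED_SAMPLE_COLUMNS:
        if col not in df.columns:
            raise DataError(f"sample sheet missing required column {col!r}")

    status = df["status"].astype(str).str.strip().str.lower()
    bad = df.index[~status.isin(VALID_STATUS)]
    if len(bad):
        raise DataError(f"unknown status token in rows {bad.tolist()}")
    df["status"] = status

    sex = df["sex"].astype(str).str.strip().str.upper()
    sex = sex.replace({"MALE": "M", "FEMALE": "F"})
    bad = df.index[~sex.isin(VALID_SEX)]
    if len(bad):
        raise DataError(f"unknown sex token in rows {bad.tolist()}")
    df["sex"] = sex

    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    df["age_missing"] = df["age"].isna()
    if (df["age"].dropna() <= 0).any():
        bad = df.index[df["age"] <= 0].tolist()
        raise DataError(f"non-positive age in rows {bad}")

    if "chest_pain" in df.columns:
        cp = df["chest_pain"].astype(str).str.strip().str.lower()
        cp = cp.where(df["chest_pain"].notna(), None)
        known = cp.isin(VALID_CHEST_PAIN) | cp.isna()
        if not known.all():
            raise DataError(
                f"unknown chest_pain token in rows {df.index[~known].tolist()}"
            )
        df["chest_pain"] = cp
    if "diabetic" in df.columns:
        df["diabetic"] = df["diabetic"].map(
            lambda v: bool(int(v)) if not isinstance(v, bool) else v
        )
    for col in ("neutrophil_count", "lymphocyte_count"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if (df[col].dropna() < 0).any():
                raise DataError(f"negative {col}")
    if "pair_id" in df.columns:
        _check_pairs(df)
    return df


def _check_pairs(df: pd.DataFrame) -> None:
    paired = df[df["pair_id"].notna()]
    for pid, grp in paired.groupby("pair_id"):
        counts = grp["status"].value_counts()
        if counts.get("case", 0) != 1 or counts.get("control", 0) != 1:
            raise DataError(
                f"pair {pid!r} must contain exactly one case and one control"
            )


def case_indicator(samples: pd.DataFrame) -> np.ndarray:
    """0/1 outcome vector (1 = case) in sample-sheet order."""
    return (samples["status"] == "case").to_numpy(dtype=float)


@dataclass
class QCReport:
    """Per-sample array QC metrics and pass/fail calls."""

    metrics: pd.DataFrame  # percent_present, median_correlation, median_intensity
    passed: pd.Index = field(default=None)
    excluded: pd.Index = field(default=None)
    warnings: list = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return len(self.excluded) == 0
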