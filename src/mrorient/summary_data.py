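"""Data model and file I/O for harmonized two-sample MR summary statistics.

The central container is :class:`SummaryDataset`: per-SNP association
estimates with the exposure (beta_exposure, se_exposure) and with the
outcome (beta_outcome, se_outcome) from two non-overlapping GWAS, plus
optional effect/other allele labels. Estimator results are returned as
:class:`MREstimate` records.

Files are plain tab-separated text with a header row; numeric fields are
serialized with 17 significant digits so that write → read round-trips
double precision exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "SummaryDataset",
    "MREstimate",
    "read_summary_tsv",
    "write_summary_tsv",
    "IVW_FE",
    "IVW_RE",
    "EGGER",
    "RADIAL_EGGER",
]

# Method tags used in MREstimate.method
IVW_FE = "IVW_FE"
IVW_RE = "IVW_RE"
EGGER = "EGGER"
RADIAL_EGGER = "RADIAL_EGGER"

#: Required columns of the TSV interchange format, in canonical write order.
REQUIRED_COLUMNS = ("snp", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome")
OPTIONAL_COLUMNS = ("effect_allele", "other_allele")

#: Minimum number of SNPs: MR-Egger needs m >= 3 for a positive-df fit.
MIN_SNPS = 3


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True, eq=False)
class SummaryDataset:
    """Per-SNP two-sample GWAS summary statistics.

    Parameters
    ----------
    snp_id
        Unique SNP labels.
    beta_exposure, se_exposure
        SNP-exposure association estimates and standard errors (trait units
        per effect allele). ``se_exposure`` may be 0, meaning the estimate is
        treated as exact (the no-measurement-error limit).
    beta_outcome, se_outcome
        SNP-outcome association estimates and strictly positive standard
        errors.
    effect_allele, other_allele
        Optional single-character allele labels; ``None`` if unknown.
    """

    snp_id: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            object.__setattr__(self, name, _as_float_array(getattr(self, name), name))
        for name in ("effect_allele", "other_allele"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, np.asarray(val, dtype=object))
        m = len(self.snp_id)
        if m < MIN_SNPS:
            raise ValidationError(f"need at least {MIN_SNPS} SNPs, got {m}")
        for name in (
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
            "effect_allele",
            "other_allele",
        ):
            val = getattr(self, name)
            if val is not None and len(val) != m:
                raise ValidationError(
                    f"{name} has length {len(val)}, expected {m} (length of snp_id)"
                )
        if len(set(self.snp_id)) != m:
            raise ValidationError("snp_id values must be unique")
        if np.any(self.se_outcome <= 0):
            bad = self.snp_id[np.flatnonzero(self.se_outcome <= 0)[0]]
            raise ValidationError(f"se_outcome must be strictly positive (SNP {bad!r})")
        if np.any(self.se_exposure < 0):
            bad = self.snp_id[np.flatnonzero(self.se_exposure < 0)[0]]
            raise ValidationError(f"se_exposure must be non-negative (SNP {bad!r})")

    @property
    def m(self) -> int:
        """Number of SNPs."""
        return len(self.snp_id)

    def __len__(self) -> int:
        return self.m

    def __eq__(self, other) -> bool:
        if not isinstance(other, SummaryDataset):
            return NotImplemented
        for name in ("snp_id", "beta_exposure", "se_exposure", "beta_outcome",
                     "se_outcome", "effect_allele", "other_allele"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True

    def replace(self, **kwargs) -> "SummaryDataset":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """Return the dataset as a DataFrame in canonical column order."""
        df = pd.DataFrame(
            {
                "snp": self.snp_id,
                "beta_exposure": self.beta_exposure,
                "se_exposure": self.se_exposure,
                "beta_outcome": self.beta_outcome,
                "se_outcome": self.se_outcome,
            }
        )
        if self.effect_allele is not None:
            df["effect_allele"] = self.effect_allele
        if self.other_allele is not None:
            df["other_allele"] = self.other_allele
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SummaryDataset":
        """Build a dataset from a DataFrame with the interchange columns."""
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "se_exposure"]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        if "se_exposure" not in df.columns:
            # exact-NOME default: exposure estimates treated as measured without error
            df["se_exposure"] = 0.0
        numeric = ["beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]
        for col in numeric:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[numeric].isna().any(axis=1) | df["snp"].isna()]
        if len(bad):
            warnings.warn(
                f"dropping {len(bad)} row(s) with missing required fields "
                f"(row indices: {list(bad)})",
                stacklevel=2,
            )
            df = df.drop(index=bad)
        kwargs = {}
        for col in OPTIONAL_COLUMNS:
            if col in df.columns and not df[col].isna().all():
                kwargs[col] = df[col].to_numpy(dtype=object)
        return cls(
            snp_id=df["snp"].to_numpy(dtype=object),
            beta_exposure=df["beta_exposure"].to_numpy(),
            se_exposure=df["se_exposure"].to_numpy(),
            beta_outcome=df["beta_outcome"].to_numpy(),
            se_outcome=df["se_outcome"].to_numpy(),
            **kwargs,
        )


@dataclass(frozen=True)
class MREstimate:
    """Result of a summary-data MR fit.

    ``overdispersion`` is the multiplicative residual-variance scale
    (sigma_I^2 for IVW-RE, sigma_E^2 for Egger-type fits) after flooring at
    1: standard errors are never deflated below their fixed-effect value.
    For IVW the intercept is identically zero by construction and its SE and
    p-value are reported as NaN.
    """

    method: str
    slope: float
    slope_se: float
    slope_p: float
    intercept: float = 0.0
    intercept_se: float = float("nan")
    intercept_p: float = float("nan")
    overdispersion: float = 1.0
    df: int = 0
    n_snps: int = 0

    def __post_init__(self):
        if self.method not in (IVW_FE, IVW_RE, EGGER, RADIAL_EGGER):
            raise ValidationError(f"unknown method tag {self.method!r}")


def read_summary_tsv(path) -> SummaryDataset:
    """Read a harmonized summary-statistics TSV into a :class:`SummaryDataset`.

    The file must be tab-delimited with a header row containing at least
    ``snp``, ``beta_exposure``, ``beta_outcome`` and ``se_outcome``
    (``se_exposure`` defaults to 0 when absent); column order is free.
    Rows with missing required values are dropped with a warning reporting
    their indices. Missing optional cells are encoded as ``NA``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype={"snp": str}, na_values=["NA"],
            float_precision="round_trip",
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise FormatError(f"could not parse {path}: {exc}") from exc
    return SummaryDataset.from_frame(df)


def write_summary_tsv(data: SummaryDataset, path) -> None:
    """Write a dataset to a TSV re-readable by :func:`read_summary_tsv`.

    Floats are written with 17 significant digits, enough for an exact
    round-trip of IEEE double precision. Allele columns are omitted when the
    dataset carries no labels.
    """
    df = data.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")
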