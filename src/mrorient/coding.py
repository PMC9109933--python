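"""SNP orientation (allele coding) schemes.

The coding of a SNP is the choice of which allele is counted; flipping it
negates the SNP's association estimates with every trait. A
:class:`CodingScheme` is a vector of signs over the SNPs of a dataset.
Because negating *all* signs leaves every estimator of interest unchanged,
schemes are grouped into {s, -s} equivalence classes; generated schemes are
canonicalized so the first SNP's sign is +1, giving 2^(m-1) distinct
classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import CapacityError, DimensionError, ValidationError
from .summary_data import SummaryDataset

__all__ = [
    "CodingScheme",
    "apply_coding",
    "default_coding",
    "random_codings",
    "enumerate_codings",
    "read_coding",
    "write_coding",
]

#: Guard for exhaustive enumeration (2^(m-1) classes).
MAX_ENUMERATE_M = 16


@dataclass(frozen=True, eq=False)
class CodingScheme:
    """A +/-1 orientation sign per SNP.

    ``label`` records provenance: "oracle" (the generating orientation),
    "default" (all SNPs re-oriented to be positively associated with the
    exposure), "random", or "custom".
    """

    signs: np.ndarray
    label: str = "custom"

    def __post_init__(self):
        signs = np.asarray(self.signs, dtype=np.int8)
        if signs.ndim != 1 or signs.size == 0:
            raise ValidationError("signs must be a non-empty 1-d vector")
        if not np.all(np.abs(signs) == 1):
            raise ValidationError("signs entries must be -1 or +1")
        object.__setattr__(self, "signs", signs)

    @property
    def m(self) -> int:
        return len(self.signs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CodingScheme):
            return NotImplemented
        return np.array_equal(self.signs, other.signs)

    def canonical(self) -> "CodingScheme":
        """Representative of the {s, -s} class with first sign +1."""
        if self.signs[0] < 0:
            return CodingScheme(-self.signs, self.label)
        return self


def apply_coding(data: SummaryDataset, scheme: CodingScheme) -> SummaryDataset:
    """Re-orient a dataset under a coding scheme.

    beta_exposure and beta_outcome are multiplied elementwise by the signs;
    standard errors are unchanged; allele labels are swapped (effect <->
    other) wherever the sign is -1. Applying the same scheme twice restores
    the original dataset exactly.
    """
    if scheme.m != data.m:
        raise DimensionError(f"scheme length {scheme.m} != dataset length {data.m}")
    s = scheme.signs.astype(np.float64)
    kwargs = dict(
        beta_exposure=data.beta_exposure * s,
        beta_outcome=data.beta_outcome * s,
    )
    if data.effect_allele is not None and data.other_allele is not None:
        flip = scheme.signs < 0
        ea = data.effect_allele.copy()
        oa = data.other_allele.copy()
        ea[flip], oa[flip] = data.other_allele[flip], data.effect_allele[flip]
        kwargs.update(effect_allele=ea, other_allele=oa)
    return data.replace(**kwargs)


def default_coding(data: SummaryDataset) -> CodingScheme:
    """The exposure-increasing orientation used by common MR workflows.

    Returns the scheme whose application makes every beta_exposure
    non-negative: signs = sign(beta_exposure), with exact zeros mapped
    to +1 for determinism.
    """
    signs = np.where(data.beta_exposure < 0, -1, 1).astype(np.int8)
    return CodingScheme(signs, label="default")


def enumerate_codings(m: int) -> list[CodingScheme]:
    """All 2^(m-1) canonical coding classes for m SNPs.

    Guarded at m <= 16 to avoid exponential blow-up.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if m > MAX_ENUMERATE_M:
        raise CapacityError(
            f"enumerate_codings supports m <= {MAX_ENUMERATE_M}, got {m}"
        )
    out = []
    for code in range(2 ** (m - 1)):
        signs = np.ones(m, dtype=np.int8)
        for j in range(m - 1):
            if (code >> j) & 1:
                signs[j + 1] = -1
        out.append(CodingScheme(signs, label="custom"))
    return out


def random_codings(m: int, k: int, seed) -> list[CodingScheme]:
    """k distinct random coding classes, canonicalized and reproducible.

    Distinctness is up to global flip: the capacity is 2^(m-1) classes.
    The RNG stream is dedicated to coding sampling (keyed only by ``seed``)
    so that drawing codings never perturbs data-generation streams.
    """
    if m < 1 or k < 1:
        raise ValidationError("m and k must be >= 1")
    capacity = 2 ** (m - 1)
    if k > capacity:
        raise CapacityError(
            f"requested {k} codings but only {capacity} distinct classes exist for m={m}"
        )
    rng = np.random.default_rng(seed)
    seen: set[bytes] = set()
    out: list[CodingScheme] = []
    # rejection sampling over canonical vectors; for small m where k is close
    # to capacity this is a coupon-collector loop and still terminates fast
    while len(out) < k:
        signs = np.ones(m, dtype=np.int8)
        signs[1:] = rng.integers(0, 2, size=m - 1, dtype=np.int8) * 2 - 1
        key = signs.tobytes()
        if key in seen:
            continue
        seen.add(key)
        out.append(CodingScheme(signs, label="random"))
    return out


def write_coding(scheme: CodingScheme, path) -> None:
    """Serialize a scheme as one +1/-1 per line (dataset SNP order)."""
    Path(path).write_text("".join(f"{int(s):+d}\n" for s in scheme.signs))


def read_coding(path, label: str = "custom") -> CodingScheme:
    """Read a scheme written by :func:`write_coding`."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    try:
        signs = np.array([int(ln) for ln in lines], dtype=np.int8)
    except ValueError as exc:
        raise ValidationError(f"coding file {path} contains a non-integer line") from exc
    return CodingScheme(signs, label=label)
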