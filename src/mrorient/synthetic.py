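"""Generative model: individual-level data and two-sample GWAS summaries.

The structural model is

    X = sum_j beta_Xj G_j + U + eps_X,
    Y = sum_j alpha_j G_j + theta X + U + eps_Y,

with independent biallelic genotypes G_j ~ Binomial(2, maf), a shared
standard-normal confounder U and independent normal errors. ``theta`` is
the causal effect; ``alpha_j`` is the direct (pleiotropic) effect of SNP j
on the outcome, nonzero only for invalid instruments. The signs of
``beta_x`` and ``alpha`` define the *oracle* orientation: effects are drawn
independently, so the sample covariance between them is zero on average
(the "weak" version of the InSIDE condition).

Summary statistics are per-SNP simple linear regression slopes
beta_j = cov(trait, G_j)/var(G_j) with the textbook slope standard error,
computed on two non-overlapping cohorts (one per trait).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateSNPError, ValidationError
from .summary_data import SummaryDataset

__all__ = [
    "EffectSpec",
    "TrueModel",
    "SCENARIO_SUPPORTS",
    "draw_true_model",
    "simulate_individuals",
    "gwas_summary",
    "simulate_two_sample",
    "write_individuals_tsv",
]

#: SNP-exposure effect supports per scenario (uniform over the union of intervals).
SCENARIO_SUPPORTS: dict[str, tuple[tuple[float, float], ...]] = {
    "a": ((-0.2, -0.1), (0.1, 0.2)),  # symmetric about zero: mean beta_X = 0
    "b": ((-0.1, -0.03), (0.1, 0.2)),  # mixed signs, nonzero mean
    "c": ((0.1, 0.3),),  # all positive: default coding = oracle coding
}

#: Pleiotropic effect mean by regime; SD is 0.1 in both.
PLEIOTROPY_MEAN = {"balanced": 0.0, "directional": 0.1}
PLEIOTROPY_SD = 0.1


def _rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class EffectSpec:
    """How to draw per-SNP true effects.

    ``scenario`` selects the beta_X support (see :data:`SCENARIO_SUPPORTS`);
    with ``scenario="custom"``, ``intervals`` supplies the support directly.
    ``prop_invalid`` is the fraction of instruments carrying a direct effect
    alpha_j drawn N(alpha_mean, alpha_sd^2); the remainder have alpha_j = 0.
    """

    scenario: str = "a"
    prop_invalid: float = 0.3
    pleiotropy: str = "balanced"
    intervals: tuple[tuple[float, float], ...] | None = None
    alpha_mean: float | None = None
    alpha_sd: float = PLEIOTROPY_SD

    def __post_init__(self):
        if self.scenario not in ("a", "b", "c", "custom"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "custom" and self.intervals is None:
            raise ValidationError("custom scenario requires explicit intervals")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ValidationError("prop_invalid must be in [0, 1]")
        if self.pleiotropy not in PLEIOTROPY_MEAN:
            raise ValidationError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        for lo, hi in self.support:
            if not hi > lo:
                raise ValidationError(f"interval ({lo}, {hi}) has non-positive width")

    @property
    def support(self) -> tuple[tuple[float, float], ...]:
        if self.scenario == "custom":
            return tuple(tuple(iv) for iv in self.intervals)
        return SCENARIO_SUPPORTS[self.scenario]

    @property
    def resolved_alpha_mean(self) -> float:
        if self.alpha_mean is not None:
            return self.alpha_mean
        return PLEIOTROPY_MEAN[self.pleiotropy]


@dataclass(frozen=True)
class TrueModel:
    """Generating parameters of one replication, under the oracle coding."""

    theta: float
    beta_x: np.ndarray
    alpha: np.ndarray
    maf: float | np.ndarray = 0.3
    confounder_sd: float = 1.0
    eps_x_sd: float = 1.0
    eps_y_sd: float = 1.0
    invalid: np.ndarray | None = None  # bool mask of instruments with alpha free

    def __post_init__(self):
        beta_x = np.asarray(self.beta_x, dtype=np.float64)
        alpha = np.asarray(self.alpha, dtype=np.float64)
        object.__setattr__(self, "beta_x", beta_x)
        object.__setattr__(self, "alpha", alpha)
        if beta_x.shape != alpha.shape or beta_x.ndim != 1:
            raise ValidationError("beta_x and alpha must be 1-d vectors of equal length")
        maf = np.asarray(self.maf, dtype=np.float64)
        if maf.ndim == 1 and maf.shape != beta_x.shape:
            raise ValidationError("per-SNP maf must match beta_x length")
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValidationError("maf must lie in (0, 0.5]")
        for name in ("confounder_sd", "eps_x_sd", "eps_y_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.invalid is not None:
            object.__setattr__(self, "invalid", np.asarray(self.invalid, dtype=bool))

    @property
    def m(self) -> int:
        return len(self.beta_x)


def draw_true_model(spec: EffectSpec, m: int, theta: float, seed) -> TrueModel:
    """Draw one replication's true effects.

    beta_x is i.i.d. uniform over the union of the scenario's intervals
    (interval chosen with probability proportional to its width). Exactly
    round(prop_invalid * m) SNPs — the first in draw order, which is
    exchangeable — receive alpha_j ~ N(alpha_mean, alpha_sd^2); the rest
    have alpha_j = 0.
    """
    if m < 3:
        raise ValidationError("need m >= 3 SNPs")
    rng = _rng(seed)
    intervals = np.asarray(spec.support, dtype=np.float64)
    widths = intervals[:, 1] - intervals[:, 0]
    probs = widths / widths.sum()
    idx = rng.choice(len(intervals), size=m, p=probs)
    beta_x = intervals[idx, 0] + rng.random(m) * widths[idx]
    n_invalid = int(round(spec.prop_invalid * m))
    alpha = np.zeros(m)
    invalid = np.zeros(m, dtype=bool)
    invalid[:n_invalid] = True
    if n_invalid:
        alpha[:n_invalid] = rng.normal(spec.resolved_alpha_mean, spec.alpha_sd, n_invalid)
    return TrueModel(theta=float(theta), beta_x=beta_x, alpha=alpha, invalid=invalid)


def _draw_genotypes(rng: np.random.Generator, n: int, maf, m: int) -> np.ndarray:
    """n x m genotype matrix, entries Binomial(2, maf), as int8.

    Each genotype is the sum of two Bernoulli(maf) allele draws realized by
    thresholding full-range 32-bit uniforms at round(maf * 2^32); exact to
    2^-32 per allele and much faster than generic binomial sampling.
    """
    maf = np.broadcast_to(np.asarray(maf, dtype=np.float64), (m,))
    thr = np.round(maf * 2.0**32).astype(np.uint32)
    r1 = rng.integers(0, 2**32, size=(n, m), dtype=np.uint32)
    r2 = rng.integers(0, 2**32, size=(n, m), dtype=np.uint32)
    return (r1 < thr).view(np.int8) + (r2 < thr).view(np.int8)


def simulate_individuals(model: TrueModel, n: int, seed):
    """Simulate one cohort: genotypes G (n x m, int8), exposure X, outcome Y.

    The same confounder realization U enters both X and Y; errors are
    independent normals with the model's SDs.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed)
    m = model.m
    G = _draw_genotypes(rng, n, model.maf, m)
    Gf = G.astype(np.float64)
    U = rng.normal(0.0, model.confounder_sd, n)
    eps_x = rng.normal(0.0, model.eps_x_sd, n)
    eps_y = rng.normal(0.0, model.eps_y_sd, n)
    X = Gf @ model.beta_x + U + eps_x
    Y = Gf @ model.alpha + model.theta * X + U + eps_y
    return G, X, Y


def gwas_summary(genotypes, trait):
    """Per-SNP simple-regression slope and SE of ``trait`` on each SNP.

    slope_j = cov(trait, G_j) / var(G_j); the SE is the usual simple linear
    regression slope standard error with the n-2 residual-variance
    denominator. Raises :class:`DegenerateSNPError` for monomorphic SNPs.
    """
    G = np.asarray(genotypes, dtype=np.float64)
    y = np.asarray(trait, dtype=np.float64)
    if G.ndim != 2 or y.ndim != 1 or G.shape[0] != y.shape[0]:
        raise ValidationError("genotypes must be n x m and trait length n")
    n = G.shape[0]
    if n <= 2:
        raise ValidationError("need n > 2 individuals for slope standard errors")
    sg = G.sum(axis=0)
    sg2 = np.einsum("ij,ij->j", G, G)
    sxx = sg2 - sg * sg / n
    if np.any(sxx <= 0):
        j = int(np.flatnonzero(sxx <= 0)[0])
        raise DegenerateSNPError(f"SNP at column {j} is monomorphic in this sample")
    sy = y.sum()
    syy = y @ y - sy * sy / n
    sxy = G.T @ y - sg * (sy / n)
    slope = sxy / sxx
    sse = np.maximum(syy - slope * sxy, 0.0)  # clip fp negatives on exact fits
    se = np.sqrt(sse / (n - 2) / sxx)
    return slope, se


def write_individuals_tsv(genotypes, trait, path, trait_name: str = "trait") -> None:
    """Dump one cohort as a debugging TSV: id, G_1..G_m, trait."""
    import pandas as pd

    G = np.asarray(genotypes)
    df = pd.DataFrame(G, columns=[f"G_{j + 1}" for j in range(G.shape[1])])
    df.insert(0, "id", np.arange(1, G.shape[0] + 1))
    df[trait_name] = np.asarray(trait)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def simulate_two_sample(
    model: TrueModel,
    n_exposure: int,
    n_outcome: int,
    seed,
    nome_exact: bool = False,
) -> SummaryDataset:
    """Two-sample GWAS summary statistics under the oracle coding.

    Two independent cohorts are generated from the same :class:`TrueModel`;
    exposure-side statistics come from cohort 1's (G, X) and outcome-side
    statistics from cohort 2's (G, Y). With ``nome_exact=True`` the
    estimated exposure associations are replaced by the true beta_x
    (se_exposure = 0), i.e. the no-measurement-error assumption is imposed
    exactly on the exposure side.
    """
    if min(n_exposure, n_outcome) < 3:
        raise ValidationError("cohort sizes must be >= 3")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_exp, ss_out = ss.spawn(2)
    G1, X1, _ = simulate_individuals(model, n_exposure, np.random.default_rng(ss_exp))
    G2, _, Y2 = simulate_individuals(model, n_outcome, np.random.default_rng(ss_out))
    if nome_exact:
        bx, sx = model.beta_x.copy(), np.zeros(model.m)
    else:
        bx, sx = gwas_summary(G1, X1)
    by, sy = gwas_summary(G2, Y2)
    return SummaryDataset(
        snp_id=np.array([f"snp_{j + 1}" for j in range(model.m)], dtype=object),
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
    )
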