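"""Orchestration of the simulation experiments.

:func:`run_scenario` runs replicated two-sample simulations under a
:class:`ScenarioConfig` and fits the requested estimators under the
requested orientations (oracle = as generated; default =
exposure-increasing; random = one fresh random scheme per replication),
recording per-replication estimates, diagnostics and the analytic Egger
probability limit. :func:`coding_sensitivity` re-fits MR-Egger under many
random codings of one dataset; :func:`irrelevant_iv_experiment` appends
null-strength instruments and tracks the induced InSIDE violation.

Randomness: one root seed spawns an independent SeedSequence per
replication, which in turn spawns separate streams for effect drawing,
cohort simulation and coding sampling — changing one stage never perturbs
another, and results are byte-identical across runs for a fixed config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .coding import CodingScheme, apply_coding, default_coding, random_codings
from .diagnostics import inside_covariance, nome_i_squared
from .estimators import egger, egger_plim, ivw, radial_egger
from .exceptions import CapacityError, DegenerateSNPError, ValidationError
from .summary_data import EGGER, IVW_FE, IVW_RE, RADIAL_EGGER, MREstimate, SummaryDataset
from .synthetic import EffectSpec, TrueModel, draw_true_model, simulate_two_sample

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "summarize",
    "coding_sensitivity",
    "irrelevant_iv_experiment",
]

MAX_RETRIES = 3
REJECTION_LEVEL = 0.05


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation set-up: model, sizes, replications, arms."""

    effect_spec: EffectSpec
    m: int = 100
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    theta: float = 0.2
    reps: int = 1000
    seed: int = 0
    methods: tuple[str, ...] = (IVW_RE, EGGER)
    codings: tuple[str, ...] = ("oracle", "default")
    nome_exact: bool = False

    def __post_init__(self):
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")
        if min(self.m, self.n_exposure, self.n_outcome) < 3:
            raise ValidationError("m and cohort sizes must be >= 3")
        for meth in self.methods:
            if meth not in (IVW_FE, IVW_RE, EGGER, RADIAL_EGGER):
                raise ValidationError(f"unknown method {meth!r}")
        for cod in self.codings:
            if cod not in ("oracle", "default", "random"):
                raise ValidationError(f"unknown coding arm {cod!r}")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        """Load a flat-key config (scenario, m, n_exposure, n_outcome, theta,
        prop_invalid, pleiotropy, reps, seed, and optionally methods,
        codings, nome_exact)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        spec = EffectSpec(
            scenario=raw.get("scenario", "a"),
            prop_invalid=raw.get("prop_invalid", 0.3),
            pleiotropy=raw.get("pleiotropy", "balanced"),
        )
        kwargs = {
            k: raw[k]
            for k in ("m", "n_exposure", "n_outcome", "theta", "reps", "seed", "nome_exact")
            if k in raw
        }
        for k in ("methods", "codings"):
            if k in raw:
                kwargs[k] = tuple(raw[k])
        return cls(effect_spec=spec, **kwargs)

    def to_yaml(self, path) -> None:
        raw = {
            "scenario": self.effect_spec.scenario,
            "prop_invalid": self.effect_spec.prop_invalid,
            "pleiotropy": self.effect_spec.pleiotropy,
            "m": self.m,
            "n_exposure": self.n_exposure,
            "n_outcome": self.n_outcome,
            "theta": self.theta,
            "reps": self.reps,
            "seed": self.seed,
            "methods": list(self.methods),
            "codings": list(self.codings),
            "nome_exact": self.nome_exact,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class ScenarioResult:
    """Per-replication records plus (method x coding) summary rows."""

    config: ScenarioConfig
    records: pd.DataFrame
    summary: pd.DataFrame
    retries: int = 0


_FITTERS = {
    IVW_FE: lambda d: ivw(d, "FE"),
    IVW_RE: lambda d: ivw(d, "RE"),
    EGGER: egger,
    RADIAL_EGGER: radial_egger,
}


def _estimate_row(est: MREstimate) -> dict:
    return {
        "slope": est.slope,
        "slope_se": est.slope_se,
        "slope_p": est.slope_p,
        "intercept": est.intercept,
        "intercept_se": est.intercept_se,
        "intercept_p": est.intercept_p,
        "overdispersion": est.overdispersion,
    }


def _simulate_replication(config: ScenarioConfig, rep_ss: np.random.SeedSequence):
    """Draw a TrueModel and its two-sample dataset, retrying monomorphic draws."""
    retries = 0
    for _ in range(MAX_RETRIES + 1):
        model_ss, data_ss, coding_ss = rep_ss.spawn(3)
        try:
            model = draw_true_model(
                config.effect_spec, config.m, config.theta, np.random.default_rng(model_ss)
            )
            data = simulate_two_sample(
                model, config.n_exposure, config.n_outcome, data_ss,
                nome_exact=config.nome_exact,
            )
            return model, data, coding_ss, retries
        except DegenerateSNPError:
            retries += 1
    raise DegenerateSNPError(
        f"replication failed {MAX_RETRIES + 1} times with monomorphic SNPs; "
        "increase n or maf"
    )


def _scheme_for(label: str, data: SummaryDataset, coding_rng, m: int) -> CodingScheme:
    if label == "oracle":
        return CodingScheme(np.ones(m, dtype=np.int8), label="oracle")
    if label == "default":
        return default_coding(data)
    # one fresh random scheme per replication
    signs = coding_rng.integers(0, 2, size=m, dtype=np.int8) * 2 - 1
    return CodingScheme(signs, label="random")


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run the replicated experiment described by ``config``."""
    root = np.random.SeedSequence(config.seed)
    rep_seeds = root.spawn(config.reps)
    rows: list[dict] = []
    total_retries = 0
    for r in range(config.reps):
        model, data, coding_ss, retries = _simulate_replication(config, rep_seeds[r])
        total_retries += retries
        coding_rng = np.random.default_rng(coding_ss)
        for label in config.codings:
            scheme = _scheme_for(label, data, coding_rng, config.m)
            coded = apply_coding(data, scheme)
            s = scheme.signs.astype(np.float64)
            if np.all(coded.se_exposure > 0):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    q_stat, i2 = nome_i_squared(coded.beta_exposure, coded.se_exposure)
            else:  # exact NOME: I^2 undefined
                q_stat, i2 = float("nan"), float("nan")
            inside = inside_covariance(s * model.alpha, s * model.beta_x, coded.se_outcome)
            plim = egger_plim(
                config.theta, s * model.beta_x, s * model.alpha,
                1.0 / coded.se_outcome**2,
            )
            for meth in config.methods:
                est = _FITTERS[meth](coded)
                rows.append(
                    {
                        "rep": r,
                        "method": meth,
                        "coding": label,
                        **_estimate_row(est),
                        "q_stat": q_stat,
                        "i_squared": i2,
                        "inside_cov": inside,
                        "egger_plim": plim,
                    }
                )
    records = pd.DataFrame(rows)
    return ScenarioResult(
        config=config,
        records=records,
        summary=summarize(records, config.theta),
        retries=total_retries,
    )


def summarize(records: pd.DataFrame, theta: float, by=("method", "coding")) -> pd.DataFrame:
    """Monte-Carlo summary per group.

    Columns: replication count, mean/SD of the slope, bias (mean - theta),
    RMSE, Monte-Carlo SE of the mean (SD/sqrt(reps)), empirical rejection
    rate of H0: theta = 0 at the 0.05 level, and mean I^2. The SD is NaN
    for a single replication.
    """
    if records.empty:
        raise ValidationError("empty records")
    out = []
    for key, grp in records.groupby(list(by), sort=False):
        slopes = grp["slope"].to_numpy()
        n = len(slopes)
        mean = slopes.mean()
        sd = slopes.std(ddof=1) if n > 1 else float("nan")
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(
            n_reps=n,
            mean_slope=mean,
            sd_slope=sd,
            bias=mean - theta,
            rmse=float(np.sqrt(np.mean((slopes - theta) ** 2))),
            mc_se=sd / np.sqrt(n) if n > 1 else float("nan"),
            rejection_rate=float((grp["slope_p"] < REJECTION_LEVEL).mean()),
            mean_i_squared=float(grp["i_squared"].mean()),
            mean_inside_cov=float(grp["inside_cov"].mean()),
        )
        out.append(row)
    return pd.DataFrame(out)


def coding_sensitivity(data: SummaryDataset, k: int, seed) -> pd.DataFrame:
    """MR-Egger under the default coding plus k distinct random codings.

    Schemes are canonicalized (first sign +1) and deduplicated against each
    other and against the default class, so the table holds k+1 distinct
    coding classes. Rows are sorted by slope; the default row is flagged.
    Capacity: at most 2^(m-1) - 1 random classes besides the default.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    m = data.m
    capacity = 2 ** (m - 1) - 1
    if k > capacity:
        raise CapacityError(
            f"requested {k} random codings but only {capacity} non-default classes exist"
        )
    default = default_coding(data).canonical()
    default_key = default.signs.tobytes()
    # draw one extra class so that dropping the default (if sampled) still leaves k
    cands = random_codings(m, min(k + 1, capacity + 1), seed)
    schemes = [c for c in cands if c.signs.tobytes() != default_key][:k]
    rows = []
    for scheme, is_default in [(default, True)] + [(s, False) for s in schemes]:
        fit = egger(apply_coding(data, scheme))
        rows.append(
            {
                "coding": "default" if is_default else "random",
                "is_default": is_default,
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "slope_p": fit.slope_p,
                "intercept": fit.intercept,
                "intercept_p": fit.intercept_p,
                "signs": "".join("+" if s > 0 else "-" for s in scheme.signs),
            }
        )
    return pd.DataFrame(rows).sort_values("slope", kind="mergesort").reset_index(drop=True)


def irrelevant_iv_experiment(config: ScenarioConfig, m0: int) -> ScenarioResult:
    """Effect of appending m0 irrelevant instruments (beta_X = 0).

    Three arms per replication, sharing the cohort random stream:

    * ``base`` — the m relevant instruments only;
    * ``irrelevant_pleiotropic`` — plus m0 SNPs with beta_X = 0 and alpha
      drawn from the configured pleiotropy law;
    * ``irrelevant_null`` — plus m0 SNPs with beta_X = 0 and alpha = 0.

    Records the oracle-coding Egger fit, the equal-weight InSIDE covariance
    over the full instrument set (``inside_cov``) and over the m relevant
    instruments only (``inside_cov_core``). With m0 = 0 all arms coincide.
    """
    if m0 < 0:
        raise ValidationError("m0 must be >= 0")
    root = np.random.SeedSequence(config.seed)
    rep_seeds = root.spawn(config.reps)
    rows = []
    for r in range(config.reps):
        rep_ss = rep_seeds[r]
        retries = 0
        while True:
            model_ss, ext_ss, data_ss = rep_ss.spawn(3)
            model = draw_true_model(
                config.effect_spec, config.m, config.theta, np.random.default_rng(model_ss)
            )
            ext_rng = np.random.default_rng(ext_ss)
            alpha_ext = ext_rng.normal(
                config.effect_spec.resolved_alpha_mean, config.effect_spec.alpha_sd, m0
            )
            arms = {
                "base": model,
                "irrelevant_pleiotropic": _extend(model, np.zeros(m0), alpha_ext),
                "irrelevant_null": _extend(model, np.zeros(m0), np.zeros(m0)),
            }
            try:
                for arm, arm_model in arms.items():
                    # identical (not stateful-spawned) stream per arm: common
                    # random numbers across arms, and exact no-op when m0 = 0
                    arm_ss = np.random.SeedSequence(
                        entropy=data_ss.entropy, spawn_key=data_ss.spawn_key
                    )
                    data = simulate_two_sample(
                        arm_model, config.n_exposure, config.n_outcome, arm_ss,
                        nome_exact=config.nome_exact,
                    )
                    fit = egger(data)
                    rows.append(
                        {
                            "rep": r,
                            "method": EGGER,
                            "coding": "oracle",
                            "arm": arm,
                            **_estimate_row(fit),
                            "inside_cov": inside_covariance(arm_model.alpha, arm_model.beta_x),
                            "inside_cov_core": inside_covariance(
                                model.alpha, model.beta_x
                            ),
                            "egger_plim": egger_plim(
                                config.theta, arm_model.beta_x, arm_model.alpha,
                                1.0 / data.se_outcome**2,
                            ),
                            "q_stat": float("nan"),
                            "i_squared": float("nan"),
                        }
                    )
                break
            except DegenerateSNPError:
                rows = [row for row in rows if row["rep"] != r]
                retries += 1
                if retries > MAX_RETRIES:
                    raise
    records = pd.DataFrame(rows)
    return ScenarioResult(
        config=config,
        records=records,
        summary=summarize(records, config.theta, by=("method", "arm")),
    )


def _extend(model: TrueModel, beta_ext: np.ndarray, alpha_ext: np.ndarray) -> TrueModel:
    if len(beta_ext) == 0:
        return model
    return TrueModel(
        theta=model.theta,
        beta_x=np.concatenate([model.beta_x, beta_ext]),
        alpha=np.concatenate([model.alpha, alpha_ext]),
        maf=model.maf,
        confounder_sd=model.confounder_sd,
        eps_x_sd=model.eps_x_sd,
        eps_y_sd=model.eps_y_sd,
        invalid=np.concatenate([model.invalid, alpha_ext != 0])
        if model.invalid is not None
        else None,
    )
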