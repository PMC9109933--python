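"""Scenario orchestration: reproducibility, cross-module consistency,
coding scan, irrelevant instruments."""

import numpy as np
import pandas as pd
import pytest

import mrorient.study as study_mod
from mrorient import (
    EffectSpec,
    ScenarioConfig,
    SummaryDataset,
    coding_sensitivity,
    default_coding,
    draw_true_model,
    enumerate_codings,
    irrelevant_iv_experiment,
    run_scenario,
    simulate_two_sample,
    summarize,
)
from mrorient.exceptions import CapacityError, DegenerateSNPError


def small_config(**kw) -> ScenarioConfig:
    base = dict(
        effect_spec=EffectSpec(scenario="b", prop_invalid=0.3, pleiotropy="directional"),
        m=20,
        n_exposure=4000,
        n_outcome=4000,
        theta=0.2,
        reps=5,
        seed=11,
        methods=("IVW_RE", "EGGER"),
        codings=("oracle", "default", "random"),
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestRunScenario:
    def test_reproducible_records(self):
        cfg = small_config()
        a, b = run_scenario(cfg), run_scenario(cfg)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert a.records.shape[0] == cfg.reps * len(cfg.methods) * len(cfg.codings)

    def test_ivw_rows_identical_across_codings(self):
        res = run_scenario(small_config())
        ivw_rows = res.records[res.records.method == "IVW_RE"]
        for _, grp in ivw_rows.groupby("rep"):
            assert grp["slope"].nunique() == 1
            assert grp["slope_se"].nunique() == 1

    def test_simulation_c_default_equals_oracle(self):
        # all true effects positive: the exposure-increasing orientation is
        # the generating one, so both arms agree row-by-row
        cfg = small_config(
            effect_spec=EffectSpec(scenario="c", prop_invalid=1.0, pleiotropy="directional"),
            n_exposure=20_000,
            n_outcome=20_000,
            reps=3,
            codings=("oracle", "default"),
        )
        res = run_scenario(cfg)
        piv = res.records.pivot_table(
            index=["rep", "method"], columns="coding", values="slope"
        )
        np.testing.assert_array_equal(piv["oracle"], piv["default"])

    def test_oracle_egger_variance_smaller_than_default(self):
        # re-orientation compresses the spread of beta_X, inflating the
        # Egger slope variance under the default coding
        cfg = small_config(
            effect_spec=EffectSpec(scenario="a", prop_invalid=0.3, pleiotropy="directional"),
            m=50,
            n_exposure=10_000,
            n_outcome=10_000,
            reps=40,
            methods=("EGGER",),
            codings=("oracle", "default"),
        )
        summ = run_scenario(cfg).summary.set_index("coding")
        assert summ.loc["default", "sd_slope"] > summ.loc["oracle", "sd_slope"]

    def test_radial_tracks_default_coding_egger(self):
        # both rest on an exposure-increasing-orientation InSIDE condition:
        # where that fails (scenario b, directional), their biases agree and
        # both sit far from the oracle-coding Egger fit
        cfg = small_config(
            m=50,
            n_exposure=10_000,
            n_outcome=10_000,
            reps=40,
            methods=("EGGER", "RADIAL_EGGER"),
            codings=("oracle", "default"),
        )
        summ = run_scenario(cfg).summary.set_index(["method", "coding"])
        radial = summ.loc[("RADIAL_EGGER", "default"), "mean_slope"]
        egger_def = summ.loc[("EGGER", "default"), "mean_slope"]
        egger_orc = summ.loc[("EGGER", "oracle"), "mean_slope"]
        assert abs(radial - egger_def) < 0.05
        assert abs(radial - egger_orc) > 0.2

    def test_egger_bias_matches_analytic_limit(self):
        # with exact exposure effects (no NOME violation), the mean Egger
        # slope under the default coding tracks the mean probability limit
        cfg = small_config(
            m=50,
            n_exposure=10_000,
            n_outcome=10_000,
            reps=100,
            methods=("EGGER",),
            codings=("default",),
            nome_exact=True,
        )
        rec = run_scenario(cfg).records
        diff = rec["slope"] - rec["egger_plim"]
        assert abs(diff.mean()) < 4 * diff.std(ddof=1) / np.sqrt(len(diff))
        # and the default coding is genuinely biased here (InSIDE violated)
        assert rec["egger_plim"].mean() - cfg.theta > 0.01

    def test_failed_replication_retried(self, monkeypatch):
        calls = {"n": 0}
        real = study_mod.simulate_two_sample

        def flaky(*args, **kwargs):
            calls["n"] += 1
            if calls["n"] == 1:
                raise DegenerateSNPError("synthetic failure")
            return real(*args, **kwargs)

        monkeypatch.setattr(study_mod, "simulate_two_sample", flaky)
        res = run_scenario(small_config(reps=2))
        assert res.retries == 1
        assert res.records["rep"].nunique() == 2


class TestSummarize:
    def test_bias_is_mean_minus_theta(self):
        res = run_scenario(small_config())
        for _, row in res.summary.iterrows():
            grp = res.records[
                (res.records.method == row["method"])
                & (res.records.coding == row["coding"])
            ]
            assert row["bias"] == pytest.approx(grp["slope"].mean() - 0.2)

    def test_single_replication_sd_is_nan(self):
        res = run_scenario(small_config(reps=1))
        assert res.summary["sd_slope"].isna().all()
        assert res.summary["mc_se"].isna().all()

    def test_null_rejection_calibrated(self):
        # correct model, no pleiotropy: IVW rejects H0 theta=0 at ~5%
        cfg = small_config(
            effect_spec=EffectSpec(scenario="c", prop_invalid=0.0),
            theta=0.0,
            n_exposure=3000,
            n_outcome=3000,
            reps=200,
            methods=("IVW_RE",),
            codings=("oracle",),
            seed=77,
        )
        rate = run_scenario(cfg).summary["rejection_rate"].iloc[0]
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200)


class TestConfigYaml:
    def test_round_trip(self, tmp_path):
        cfg = small_config()
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert ScenarioConfig.from_yaml(path) == cfg


class TestCodingSensitivity:
    @staticmethod
    def _dataset(rng, m):
        from conftest import random_dataset

        return random_dataset(rng, m)

    def test_exact_fit_invariant_across_codings(self):
        m = 6
        rng = np.random.default_rng(1)
        bx = rng.uniform(-0.3, 0.3, m)
        data = SummaryDataset(
            snp_id=np.array([f"s{i}" for i in range(m)], dtype=object),
            beta_exposure=bx,
            se_exposure=np.zeros(m),
            beta_outcome=0.25 * bx,
            se_outcome=rng.uniform(0.05, 0.2, m),
        )
        table = coding_sensitivity(data, k=10, seed=0)
        np.testing.assert_allclose(table["slope"], 0.25, atol=1e-10)

    def test_exhaustive_equals_enumeration(self):
        rng = np.random.default_rng(2)
        data = self._dataset(rng, 5)
        table = coding_sensitivity(data, k=15, seed=0)
        assert len(table) == 16
        assert table["is_default"].sum() == 1
        got = set(table["signs"])
        canon_default = default_coding(data).canonical()
        expected = set()
        for scheme in enumerate_codings(5):
            expected.add("".join("+" if s > 0 else "-" for s in scheme.signs))
        assert got == expected
        assert list(table["slope"]) == sorted(table["slope"])

    def test_capacity_error(self):
        data = self._dataset(np.random.default_rng(3), 5)
        with pytest.raises(CapacityError):
            coding_sensitivity(data, k=16, seed=0)

    def test_slopes_vary_on_pleiotropic_data(self):
        model = draw_true_model(
            EffectSpec(scenario="b", prop_invalid=0.3, pleiotropy="directional"),
            50, 0.2, seed=5,
        )
        data = simulate_two_sample(model, 20_000, 20_000, seed=6)
        table = coding_sensitivity(data, k=49, seed=7)
        assert table["slope"].max() - table["slope"].min() > 1e-3


class TestIrrelevantIVs:
    def test_m0_zero_is_noop(self):
        cfg = small_config(reps=3, methods=("EGGER",), codings=("oracle",))
        res = irrelevant_iv_experiment(cfg, m0=0)
        piv = res.records.pivot_table(index="rep", columns="arm", values="slope")
        np.testing.assert_array_equal(piv["base"], piv["irrelevant_pleiotropic"])
        np.testing.assert_array_equal(piv["base"], piv["irrelevant_null"])

    def test_directional_nonzero_mean_strength_breaks_inside(self):
        # scenario (c): mean beta_X > 0 and mean alpha > 0. Padding with
        # alpha=0 null-strength SNPs drags the full-set mean alpha down and
        # shifts the covariance away from zero in expectation
        # (~ m*m0*mu_a*mu_b/(m+m0)^2 = 0.0048); padding whose alpha follows
        # the same directional law leaves the means intact, so its average
        # covariance stays near zero even though each replication's is not.
        cfg = small_config(
            effect_spec=EffectSpec(scenario="c", prop_invalid=1.0, pleiotropy="directional"),
            m=30,
            n_exposure=5000,
            n_outcome=5000,
            reps=50,
        )
        res = irrelevant_iv_experiment(cfg, m0=20)
        means = res.records.groupby("arm")[["inside_cov", "inside_cov_core"]].mean()
        assert means.loc["irrelevant_null", "inside_cov"] > 0.002
        assert abs(means.loc["base", "inside_cov"]) < 1e-3
        assert abs(means.loc["irrelevant_null", "inside_cov_core"]) < 1e-3
        # Egger under the oracle coding becomes biased once padded
        summ = res.summary.set_index("arm")
        assert summ.loc["irrelevant_null", "bias"] > summ.loc["base", "bias"] + 0.01

    def test_zero_mean_strength_is_special_case(self):
        # scenario (a): sum beta_X ~ 0, so padding leaves the covariance ~ 0
        # in either padding regime
        cfg = small_config(
            effect_spec=EffectSpec(scenario="a", prop_invalid=1.0, pleiotropy="directional"),
            m=30,
            n_exposure=5000,
            n_outcome=5000,
            reps=50,
        )
        res = irrelevant_iv_experiment(cfg, m0=20)
        means = res.records.groupby("arm")["inside_cov"].mean()
        assert abs(means["irrelevant_null"]) < 2e-3
        assert abs(means["irrelevant_pleiotropic"]) < 2e-3


def test_summarize_rejects_empty():
    from mrorient.exceptions import ValidationError

    with pytest.raises(ValidationError):
        summarize(pd.DataFrame(), 0.0)
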