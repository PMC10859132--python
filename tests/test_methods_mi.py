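"""Imputation, Rubin's-rules pooling, guarded execution and the hybrid."""

import math

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from simsentry import (
    DGMSpec,
    MethodSettings,
    SimulatedDataset,
    TriggerRules,
    analyze,
    analyze_complete_records,
    analyze_mi,
    default_specs,
    generate_dataset,
    hybrid_with_backup,
    impute_confounder_once,
    pool_rubin,
    run_method_guarded,
)
from simsentry.methods import AnalysisError


def make_dataset(C, E, D, M_C, rep_id=1, label="fix"):
    return SimulatedDataset(
        rep_id=rep_id,
        dgm_label=label,
        df=pd.DataFrame(
            {"C": np.asarray(C, float), "E": np.asarray(E), "D": np.asarray(D),
             "M_C": np.asarray(M_C)}
        ),
    )


class TestPoolRubin:
    def test_zero_between_variance(self):
        pooled = pool_rubin([1.0, 1.0], [4.0, 4.0])
        assert pooled.qbar == 1.0
        assert pooled.B == 0.0
        assert pooled.T == pooled.W == 4.0

    def test_hand_arithmetic(self):
        pooled = pool_rubin([1.0, 1.2, 0.8], [0.25, 0.25, 0.25])
        assert pooled.qbar == pytest.approx(1.0)
        assert pooled.W == pytest.approx(0.25)
        assert pooled.B == pytest.approx(0.04)
        assert pooled.T == pytest.approx(0.25 + (4.0 / 3.0) * 0.04)

    def test_needs_two_imputations(self):
        with pytest.raises(AnalysisError):
            pool_rubin([1.0], [0.5])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=10),
        st.data(),
    )
    def test_total_at_least_within_variance(self, ests, data):
        vs = data.draw(
            st.lists(st.floats(0, 10), min_size=len(ests), max_size=len(ests))
        )
        pooled = pool_rubin(ests, vs)
        assert pooled.T >= pooled.W
        assert pooled.B >= 0

    def test_permutation_invariance_and_variance_scaling(self, rng):
        ests = list(rng.normal(size=5))
        vs = list(rng.uniform(0.1, 1.0, size=5))
        a = pool_rubin(ests, vs, df_complete=497)
        order = rng.permutation(5)
        b = pool_rubin([ests[i] for i in order], [vs[i] for i in order], df_complete=497)
        assert (a.qbar, a.W, a.B, a.T, a.df_BR) == pytest.approx(
            (b.qbar, b.W, b.B, b.T, b.df_BR)
        )
        c = pool_rubin(ests, [3.0 * v for v in vs], df_complete=497)
        assert c.W == pytest.approx(3.0 * a.W)
        assert c.T - (1 + 1 / 5) * c.B == pytest.approx(3.0 * (a.T - (1 + 1 / 5) * a.B))


class TestImputeOnce:
    def test_identity_when_nothing_missing(self, rng, mcar_spec):
        spec = replace(mcar_spec, gamma0=-30.0)
        data = generate_dataset(spec, rng)
        out = impute_confounder_once(data, rng)
        assert np.array_equal(out, data.df["C"].to_numpy())

    def test_successive_draws_differ(self, rng, mcar_spec):
        data = generate_dataset(mcar_spec, rng)
        a = impute_confounder_once(data, rng)
        b = impute_confounder_once(data, rng)
        miss = data.df["M_C"].to_numpy() == 1
        assert not np.array_equal(a[miss], b[miss])
        # observed values never touched
        assert np.array_equal(a[~miss], data.df["C"].to_numpy()[~miss])

    def test_conditional_means_match_observed_at_large_n(self, rng):
        # MCAR at n=100000: imputed C given (E, D) should share the
        # observed-C conditional distribution
        spec = replace(default_specs()[0], n_obs=100_000)
        data = generate_dataset(spec, rng)
        completed = impute_confounder_once(data, rng)
        df = data.df
        miss = df["M_C"].to_numpy() == 1
        for e in (0, 1):
            for d in (0, 1):
                cell = (df["E"] == e) & (df["D"] == d)
                obs_mean = df.loc[cell & ~miss, "C"].mean()
                imp = completed[(cell & miss).to_numpy()]
                assert imp.mean() == pytest.approx(obs_mean, abs=0.05)

    def test_too_few_complete_rows_is_a_recognised_failure(self):
        data = make_dataset(
            C=[0.1, 0.2, -0.3, 0.4, 0.5, 0.6],
            E=[0, 1, 0, 1, 0, 1],
            D=[0, 0, 1, 1, 0, 1],
            M_C=[1, 1, 1, 1, 0, 0],
        )
        with pytest.raises(AnalysisError, match="complete"):
            impute_confounder_once(data, np.random.default_rng(0))


class TestAnalyze:
    def test_full_equals_cca_without_missingness(self, rng, mcar_spec):
        spec = replace(mcar_spec, gamma0=-30.0)
        data = generate_dataset(spec, rng)
        full = analyze_complete_records(data, "all")
        cca = analyze_complete_records(data, "complete_cases")
        assert full.estimate == pytest.approx(cca.estimate)
        assert full.se == pytest.approx(cca.se)

    def test_mi_without_missingness_matches_full_fit(self, rng, mcar_spec):
        spec = replace(mcar_spec, gamma0=-30.0)
        data = generate_dataset(spec, rng)
        full = analyze_complete_records(data, "all")
        mi = analyze_mi(data, rng, MethodSettings(m_imputations=3))
        # every completed data set equals the original, so B = 0 and the
        # pooled estimate reproduces the full-data fit
        assert mi.estimate == pytest.approx(full.estimate)
        assert mi.se == pytest.approx(full.se)

    def test_no_events_in_complete_cases_fails_captured(self):
        rng = np.random.default_rng(9)
        n = 60
        C = rng.standard_normal(n)
        E = rng.integers(0, 2, n)
        D = np.concatenate([np.zeros(40, int), np.ones(20, int)])
        M_C = np.concatenate([np.zeros(40, int), np.ones(20, int)])  # events all masked
        data = make_dataset(C, E, D, M_C)
        out = analyze(data, "cca")
        assert out.status.startswith("failed:") or out.separation_flag

    def test_ok_outcome_invariants(self, rng, mcar_spec):
        data = generate_dataset(mcar_spec, rng)
        for label in ("full", "cca", "mi"):
            out = analyze(data, label, rng=rng)
            assert out.ok
            assert math.isfinite(out.estimate) and math.isfinite(out.se)
            assert out.ci_low <= out.estimate <= out.ci_high


class TestGuardedExecution:
    def test_always_raising_method_is_captured(self, rng, mcar_spec):
        data = generate_dataset(mcar_spec, rng)

        def bad_method(d):
            raise RuntimeError("boom")

        out = run_method_guarded(bad_method, data, method_label="bad")
        assert out.status == "failed:RuntimeError"
        assert math.isnan(out.estimate) and math.isnan(out.se)
        assert math.isnan(out.ci_low) and math.isnan(out.ci_high)

    def test_analysis_error_code_is_preserved(self, rng, mcar_spec):
        data = generate_dataset(mcar_spec, rng)

        def bad_method(d):
            raise AnalysisError("no_events")

        out = run_method_guarded(bad_method, data, method_label="bad")
        assert out.status == "failed:no_events"

    def test_sparse_dgm_produces_captured_failures(self):
        # very low exposure and event rates: a random positivity violation
        # makes some complete-case analyses fail, none of which may crash
        from simsentry.engine import RunPlan, run_study

        spec = DGMSpec(label="sparse", alpha0=-3.0, beta0=-3.0,
                       mechanism="MCAR", gamma0=0.85)
        plan = RunPlan(dgm_specs=[spec], methods=("cca",), n_sim=100, seed=3)
        res = run_study(plan)
        assert len(res.estimates) == 100
        problem = (res.estimates["status"] != "ok") | (res.estimates["separation"] == 1)
        assert problem.sum() > 0

    def test_default_dgm_produces_no_failures(self, medium_study):
        assert (medium_study.estimates["status"] == "ok").all()


class TestHybrid:
    def test_non_triggering_data_returns_primary(self, rng, mcar_spec):
        data = generate_dataset(mcar_spec, rng)
        out = analyze(data, "cca_firth_hybrid")
        assert out.ok
        assert not out.backup_used
        primary = analyze(data, "cca")
        assert out.estimate == pytest.approx(primary.estimate)

    def test_separated_complete_cases_fall_back_to_firth(self):
        rng = np.random.default_rng(9)
        n = 60
        C = rng.standard_normal(n)
        E = rng.integers(0, 2, n)
        D = np.concatenate([np.zeros(40, int), np.ones(20, int)])
        M_C = np.concatenate([np.zeros(40, int), np.ones(20, int)])
        data = make_dataset(C, E, D, M_C)
        out = analyze(data, "cca_firth_hybrid")
        assert out.ok
        assert out.backup_used
        assert math.isfinite(out.estimate) and math.isfinite(out.se)

    def test_se_trigger_catches_wild_standard_errors(self, rng, mcar_spec):
        data = generate_dataset(mcar_spec, rng)

        def absurd(d):
            from simsentry import AnalysisOutcome

            return AnalysisOutcome(
                rep_id=d.rep_id, dgm_label=d.dgm_label, method_label="h",
                estimate=-15.0, se=3000.0, ci_low=-6000, ci_high=6000,
            )

        def backup(d):
            return analyze_complete_records(d, "complete_cases", method_label="h")

        out = hybrid_with_backup(absurd, backup, data, method_label="h",
                                 triggers=TriggerRules())
        assert out.backup_used
        assert abs(out.estimate) < 10

    def test_backup_also_failing_gives_failed_status(self, rng, mcar_spec):
        data = generate_dataset(mcar_spec, rng)

        def bad(d):
            raise AnalysisError("no_events")

        out = hybrid_with_backup(bad, bad, data, method_label="h")
        assert out.status == "failed:no_events"
        assert out.backup_used
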