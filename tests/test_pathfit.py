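"""DWLS fitting, adjusted chi-square, fit indices, modification, effects."""

import numpy as np
import pandas as pd
import pytest

import crashpath as cp
from crashpath import pathfit as pf
from crashpath.dag import PathModel
from crashpath.synth import mediation_chain_spec


@pytest.fixture(scope="module")
def crash_fit(crash_table):
    table, _, spec = crash_table
    moments = cp.estimate_polychoric(table, variables=spec.model.names)
    fit = cp.fit_dwls(spec.model, moments)
    return table, spec, moments, fit


def three_variable_saturated():
    return PathModel(
        nodes=(("x", "exogenous"), ("m", "mediator"), ("y", "final-endogenous")),
        edges=(("x", "m"), ("x", "y"), ("m", "y")),
    )


class TestImpliedSigma:
    def test_chain_closed_form(self):
        model = PathModel(nodes=(("x", "exogenous"), ("m", "mediator"),
                                 ("y", "final-endogenous")),
                          edges=(("x", "m"), ("m", "y")))
        S, min_psi = pf.implied_sigma(model, np.array([0.5, 0.4]))
        assert S[0, 1] == pytest.approx(0.5)
        assert S[1, 2] == pytest.approx(0.4)
        assert S[0, 2] == pytest.approx(0.2)  # product along the chain
        np.testing.assert_allclose(np.diag(S), 1.0)
        # smallest residual variance across equations: min(1-0.5^2, 1-0.4^2)
        assert min_psi == pytest.approx(1 - 0.5**2)

    def test_feasible_theta_gives_valid_correlation_matrix(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        model = cp.hypothesized_crash_model()

        @given(st.lists(st.floats(-0.35, 0.35), min_size=7, max_size=7))
        @settings(max_examples=40, deadline=None, derandomize=True)
        def check(theta):
            S, min_psi = pf.implied_sigma(model, np.array(theta))
            assert min_psi > 0
            np.testing.assert_allclose(np.diag(S), 1.0)
            np.testing.assert_allclose(S, S.T)
            assert np.min(np.linalg.eigvalsh(S)) > -1e-10

        check()

    def test_infeasible_theta_flagged(self):
        model = three_variable_saturated()
        _, min_psi = pf.implied_sigma(model, np.array([0.9, 0.9, 0.9]))
        assert min_psi < 0


class TestFitDwls:
    def test_saturated_model_zero_discrepancy(self, crash_table):
        table, _, _ = crash_table
        model = three_variable_saturated()
        sub_vars = {"x": "passenger", "m": "misconduct", "y": "fatality"}
        df = table.data[list(sub_vars.values())].set_axis(list(sub_vars), axis=1)
        specs = tuple(
            cp.VariableSpec(new, "outcome" if new == "y" else "predictor",
                            table.spec(old).scale, table.spec(old).levels)
            for new, old in sub_vars.items())
        t = cp.load_table(df, specs)
        moments = cp.estimate_polychoric(t)
        fit = cp.fit_dwls(model, moments)
        assert fit.discrepancy == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.implied, moments.R, atol=1e-5)
        chi = cp.adjusted_chi_square(fit)
        assert chi.T == 0.0 and chi.p_value == 1.0

    def test_just_identified_matches_normal_equations(self, crash_table):
        # equationwise latent-scale regression algebra on the polychoric
        # matrix is the closed-form solution for a saturated recursive model
        table, _, _ = crash_table
        model = three_variable_saturated()
        df = table.data[["passenger", "misconduct", "fatality"]].set_axis(
            ["x", "m", "y"], axis=1)
        specs = (cp.VariableSpec("x", "predictor", "binary", table.spec("passenger").levels),
                 cp.VariableSpec("m", "predictor", "ordinal", table.spec("misconduct").levels),
                 cp.VariableSpec("y", "outcome", "binary", table.spec("fatality").levels))
        t = cp.load_table(df, specs)
        m = cp.estimate_polychoric(t)
        fit = cp.fit_dwls(model, m)
        R = m.R
        b_xm = R[0, 1]
        b_y = np.linalg.solve(R[:2, :2], R[:2, 2])
        assert fit.coefficients[("x", "m")] == pytest.approx(b_xm, abs=1e-5)
        assert fit.coefficients[("x", "y")] == pytest.approx(b_y[0], abs=1e-5)
        assert fit.coefficients[("m", "y")] == pytest.approx(b_y[1], abs=1e-5)

    def test_moment_model_mismatch_rejected(self, crash_fit):
        table, spec, moments, _ = crash_fit
        with pytest.raises(ValueError, match="different variables"):
            cp.fit_dwls(three_variable_saturated(), moments)

    def test_scale_factor_positive(self, crash_fit):
        _, _, _, fit = crash_fit
        chi = cp.adjusted_chi_square(fit)
        assert chi.scale > 0
        assert chi.T >= 0 and chi.df == 3


class TestFitIndices:
    def test_closed_form_cfi(self):
        idx = cp.fit_indices(6.09, 2, 100.0, 6, 742)
        assert idx.cfi == pytest.approx(1 - 4.09 / 94, abs=1e-6)
        assert idx.cfi == pytest.approx(0.9565, abs=1e-4)

    def test_closed_form_rmsea(self):
        idx = cp.fit_indices(6.09, 2, 100.0, 6, 742)
        assert idx.rmsea == pytest.approx(np.sqrt(4.09 / (2 * 741)), abs=1e-8)
        assert idx.rmsea == pytest.approx(0.0525, abs=1e-4)
        lo, hi = idx.rmsea_ci
        assert 0 <= lo < idx.rmsea < hi

    def test_exact_fit_limit(self):
        idx = cp.fit_indices(2.0, 2, 50.0, 6, 500)
        assert idx.rmsea == 0.0

    def test_saturated_reporting(self):
        idx = cp.fit_indices(0.0, 0, 50.0, 6, 500)
        assert idx.saturated and idx.cfi == 1.0 and idx.rmsea == 0.0

    def test_threshold_verdicts(self):
        bad = cp.fit_indices(16.09, 3, 120.0, 6, 742)
        assert bad.chi2_df == pytest.approx(16.09 / 3)
        assert not bad.verdicts["chi2_df"] or bad.chi2_df < 5  # 5.36 > 5
        good = cp.fit_indices(3.0, 2, 120.0, 6, 742)
        assert good.verdicts["rmsea"] and good.verdicts["chi2_df"]


class TestModificationIndices:
    def test_delta_df_always_one_and_ranked(self, crash_fit):
        table, spec, moments, _ = crash_fit
        mis = cp.modification_indices(spec.model, moments)
        ranked = [m for m in mis if "delta_chi2" in m]
        assert all(m["delta_df"] == 1 for m in ranked)
        deltas = [m["delta_chi2"] for m in ranked]
        assert deltas == sorted(deltas, reverse=True)

    def test_cycle_candidate_skipped(self, crash_table):
        table, _, _ = crash_table
        model = cp.hypothesized_crash_model(with_misconduct_to_collision=True)
        moments = cp.estimate_polychoric(table, variables=model.names)
        mis = cp.modification_indices(model, moments,
                                      candidates=[("collision", "misconduct")])
        assert mis[0]["skipped"] == "would create a cycle"

    def test_detects_omitted_path(self):
        spec = cp.default_crash_spec(n=2000, seed=71, misconduct_to_collision=0.3)
        t, _ = cp.simulate_structural(spec)
        hyp = cp.hypothesized_crash_model()
        m = cp.estimate_polychoric(t, variables=hyp.names)
        mis = [d for d in cp.modification_indices(hyp, m) if "delta_chi2" in d]
        assert mis[0]["path"] == ("misconduct", "collision")
        assert mis[0]["delta_chi2"] > 3.84


class TestEffects:
    def test_single_chain_product(self):
        dec = pf.effects_from_coefficients({("x", "m"): 0.5, ("m", "y"): 0.4},
                                           ["x", "m", "y"])
        assert dec.indirect[("x", "y")] == pytest.approx(0.20)
        assert dec.direct.get(("x", "y"), 0.0) == 0.0
        assert dec.total(("x", "y")) == pytest.approx(0.20)

    def test_zero_coefficient_kills_path(self):
        dec = pf.effects_from_coefficients({("x", "m"): 0.0, ("m", "y"): 0.4},
                                           ["x", "m", "y"])
        assert dec.indirect[("x", "y")] == 0.0

    def test_parallel_mediators(self):
        edges = {("x", "m1"): 0.5, ("m1", "y"): 0.4, ("x", "m2"): 0.3,
                 ("m2", "y"): 0.2}
        dec = pf.effects_from_coefficients(edges, ["x", "m1", "m2", "y"])
        assert dec.indirect[("x", "y")] == pytest.approx(0.26)

    def test_path_enumeration_oracle_on_random_dag(self):
        # independent oracle: brute-force DFS enumeration of every simple
        # directed path, multiplying coefficients along the way
        rng = np.random.default_rng(8)
        nodes = [f"v{i}" for i in range(6)]
        edges = {}
        for j in range(6):
            for i in range(j):
                if rng.random() < 0.6:
                    edges[(nodes[i], nodes[j])] = rng.uniform(-0.5, 0.5)
        children = {n: [] for n in nodes}
        for (a, b), c in edges.items():
            children[a].append(b)

        def enumerate_paths(a, b):
            # all simple directed paths a -> b as lists of nodes
            out, stack = [], [[a]]
            while stack:
                path = stack.pop()
                if path[-1] == b:
                    out.append(path)
                    continue
                for nxt in children[path[-1]]:
                    stack.append(path + [nxt])
            return out

        dec = pf.effects_from_coefficients(edges, nodes)
        for a in nodes:
            for b in nodes:
                if a == b:
                    continue
                paths = enumerate_paths(a, b)
                indirect = sum(
                    np.prod([edges[(u, v)] for u, v in zip(p[:-1], p[1:])])
                    for p in paths if len(p) >= 3)
                if any(len(p) >= 3 for p in paths):
                    assert dec.indirect[(a, b)] == pytest.approx(indirect, abs=1e-10)
                else:
                    assert (a, b) not in dec.indirect
                assert dec.total((a, b)) == pytest.approx(
                    edges.get((a, b), 0.0) + (indirect if paths else 0.0), abs=1e-10)

    def test_relabeling_invariance(self):
        edges = {("x", "m"): 0.5, ("m", "y"): 0.4, ("x", "y"): 0.1}
        a = pf.effects_from_coefficients(edges, ["x", "m", "y"])
        ren = {("u", "v"): 0.5, ("v", "w"): 0.4, ("u", "w"): 0.1}
        b = pf.effects_from_coefficients(ren, ["u", "v", "w"])
        assert a.total(("x", "y")) == b.total(("u", "w"))

    def test_effect_intervals_consistency(self, crash_fit):
        _, _, _, fit = crash_fit
        ints = pf.effect_intervals(fit)
        assert (ints["se"] >= 0).all()
        est = {(r["source"], r["target"], r["kind"]): r["estimate"]
               for _, r in ints.iterrows()}
        for a, b, kind in list(est):
            if kind == "total":
                assert est[(a, b, "total")] == pytest.approx(
                    est.get((a, b, "direct"), 0.0) + est.get((a, b, "indirect"), 0.0),
                    abs=1e-10)


class TestEquationwiseLogit:
    def test_two_by_two_cross_product_oracle(self):
        # OR for a single binary predictor equals ad/bc from the 2x2 table
        a, b, c, d = 40, 60, 25, 75  # y=1|x=1, y=0|x=1, y=1|x=0, y=0|x=0
        x = np.r_[np.ones(a + b), np.zeros(c + d)].astype(int)
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)].astype(int)
        specs = (cp.VariableSpec("x", "predictor", "binary", ("0", "1")),
                 cp.VariableSpec("y", "outcome", "binary", ("0", "1")))
        t = cp.load_table(pd.DataFrame({"x": x.astype(str), "y": y.astype(str)}), specs)
        model = PathModel(nodes=(("x", "exogenous"), ("y", "final-endogenous")),
                          edges=(("x", "y"),))
        res = cp.fit_equationwise_logit(model, t)
        assert res["y"].loc["x", "odds_ratio"] == pytest.approx((a * d) / (b * c),
                                                               rel=1e-6)

    def test_constant_outcome_error(self):
        specs = (cp.VariableSpec("x", "predictor", "binary", ("0", "1")),
                 cp.VariableSpec("y", "outcome", "binary", ("0", "1")))
        df = pd.DataFrame({"x": ["0", "1"] * 20, "y": ["0"] * 40})
        t = cp.load_table(df, specs)
        model = PathModel(nodes=(("x", "exogenous"), ("y", "final-endogenous")),
                          edges=(("x", "y"),))
        with pytest.raises(pf.SeparationError, match="constant"):
            cp.fit_equationwise_logit(model, t)

    def test_separation_names_offender(self):
        x = np.r_[np.zeros(30), np.ones(30)].astype(int)
        specs = (cp.VariableSpec("x", "predictor", "binary", ("0", "1")),
                 cp.VariableSpec("y", "outcome", "binary", ("0", "1")))
        t = cp.load_table(pd.DataFrame({"x": x.astype(str), "y": x.astype(str)}), specs)
        model = PathModel(nodes=(("x", "exogenous"), ("y", "final-endogenous")),
                          edges=(("x", "y"),))
        with pytest.raises(pf.SeparationError, match="x"):
            cp.fit_equationwise_logit(model, t)

    def test_null_coefficient_covered_by_ci(self):
        # the benchmark's noise predictors enter the outcome with true
        # log-odds slope zero; the Wald CI should cover OR = 1
        t, truth = cp.simulate_selection_benchmark(n=4000, seed=77)
        model = PathModel(
            nodes=(("passenger", "exogenous"), ("noise_00", "exogenous"),
                   ("fatality", "final-endogenous")),
            edges=(("passenger", "fatality"), ("noise_00", "fatality")))
        res = cp.fit_equationwise_logit(model, t)
        row = res["fatality"].loc["noise_00"]
        assert row["or_lo"] < 1.0 < row["or_hi"]


class TestPathAnalysisEstimator:
    def test_full_fit_surface(self, crash_table):
        table, _, spec = crash_table
        pa = cp.PathAnalysis(model=spec.model).fit(table)
        assert pa.identification_.df == 3
        assert pa.chi2_.df == 3
        assert set(pa.fit_.coefficients) == set(spec.model.edges)
        assert pa.indices_.cfi >= 0
        assert "fatality" in pa.logit_
        assert len(pa.modification_indices_) >= 1

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = cp.PathAnalysis(model=cp.hypothesized_crash_model(), estimator="dwls")
        est2 = clone(est)
        assert est2.get_params()["estimator"] == "dwls"
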