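"""Core estimator: probabilities, simulated likelihood, fitting, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crashmix as cm
from crashmix.model import (
    n_parameters,
    parameter_names,
)

from conftest import mnl_loglik_oracle


class TestChoiceProbabilities:
    def test_equal_utilities_give_equal_shares(self):
        np.testing.assert_allclose(
            cm.choice_probabilities(np.zeros(3)), [1 / 3] * 3)

    def test_log_two_utility_closed_form(self):
        p = cm.choice_probabilities(np.array([np.log(2), 0.0, 0.0]))
        np.testing.assert_allclose(p, [0.5, 0.25, 0.25])

    def test_agrees_with_direct_formula(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(100, 3))
        direct = np.exp(u) / np.exp(u).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(cm.choice_probabilities(u), direct,
                                   atol=1e-12)

    def test_sums_to_one_even_for_extreme_utilities(self):
        p = cm.choice_probabilities(np.array([800.0, -800.0, 0.0]))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            cm.choice_probabilities(np.array([np.nan, 0.0, 0.0]))


class TestSimulatedLoglik:
    def test_zero_parameters_give_equal_share_loglik(self, preset_dataset):
        spec = cm.preset_scenario(n=1, seed=1).truth.to_model_spec(n_draws=20)
        theta = np.zeros(n_parameters(spec))
        ll = cm.simulated_loglik(theta, preset_dataset.data, spec)
        assert ll == pytest.approx(-len(preset_dataset.data) * np.log(3),
                                   abs=1e-9)

    def test_sigma_zero_equals_mnl_oracle(self, mnl_dataset, mnl_truth):
        """With sigma=0 the mixed likelihood collapses to plain MNL."""
        mixed_truth = cm.TrueParameters(
            constants=dict(mnl_truth.constants),
            fixed_coefs={k: v for k, v in mnl_truth.fixed_coefs.items()
                         if k != ("rural", "SI")},
            random_means={("rural", "SI"): -0.6},
            random_sds={("rural", "SI"): 1.0},
        )
        spec = mixed_truth.to_model_spec(n_draws=50)
        theta = mixed_truth.to_theta(spec).values.copy()
        sigma_idx = list(parameter_names(spec)).index("sigma:rural[SI]")
        theta[sigma_idx] = 0.0
        data = mnl_dataset.data.head(200)
        ll_mixed = cm.simulated_loglik(theta, data, spec)
        ll_oracle = mnl_loglik_oracle(data, mnl_truth)
        assert ll_mixed == pytest.approx(ll_oracle, abs=1e-8)

    def test_location_normalization_invariance(self, preset_dataset):
        """Adding a common constant to all three utilities changes nothing."""
        spec = cm.ModelSpec(
            terms=(
                cm.Term("const", "SI"),
                cm.Term("const", "MIN"),
                cm.Term("rural", "SI", random=True),
            ),
            n_draws=30,
        )
        data = preset_dataset.data.head(300)
        theta = np.array([0.4, -0.2, -1.0, 1.5])
        ll1 = cm.simulated_loglik(theta, data, spec)
        # shift all utilities by c: add c to both constants and to the
        # (absent) reference constant -> equivalent spec with reference
        # constant made explicit
        spec_shift = cm.ModelSpec(
            terms=spec.terms + (cm.Term("const", "NI"),),
            n_draws=30,
            allow_reference_constant=True,
        )
        # layout: betas in term order (const SI, const MIN, rural, const NI),
        # then sigma of the random term
        theta_shift = np.array([0.4 + 5.0, -0.2 + 5.0, -1.0, 5.0, 1.5])
        ll2 = cm.simulated_loglik(theta_shift, data, spec_shift)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_qmc_draw_doubling_converges(self, preset_dataset):
        """|LL(2R) - LL(R)| shrinks as R doubles through 125..1000."""
        truth = preset_dataset.truth
        data = preset_dataset.data.head(400)
        lls = []
        for draws in (125, 250, 500, 1000):
            spec = truth.to_model_spec(n_draws=draws)
            lls.append(cm.simulated_loglik(truth.to_theta(spec), data, spec))
        deltas = [abs(b - a) for a, b in zip(lls, lls[1:])]
        assert deltas[-1] < deltas[0]
        assert deltas == sorted(deltas, reverse=True)

    def test_mismatched_cube_rejected(self, preset_dataset):
        spec = preset_dataset.truth.to_model_spec(n_draws=10)
        cube = cm.normal_cube(7, 10, 1)
        with pytest.raises(ValueError, match="observations"):
            cm.simulated_loglik(np.zeros(n_parameters(spec)),
                                preset_dataset.data, spec, cube=cube)


class TestNullLoglik:
    def test_equal_shares_closed_form(self):
        assert cm.null_loglik(1) == pytest.approx(-np.log(3))
        assert cm.null_loglik(100) == pytest.approx(-100 * np.log(3))

    def test_constants_only_at_empirical_shares(self):
        shares = [0.2, 0.3, 0.5]
        expected = 100 * sum(s * np.log(s) for s in shares)
        got = cm.null_loglik(100, "constants_only", shares=shares)
        assert got == pytest.approx(expected)

    def test_zero_share_contributes_nothing(self):
        got = cm.null_loglik(10, "constants_only", shares=[0.5, 0.5, 0.0])
        assert got == pytest.approx(10 * np.log(0.5))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cm.null_loglik(0)
        with pytest.raises(ValueError):
            cm.null_loglik(10, "constants_only")
        with pytest.raises(ValueError):
            cm.null_loglik(10, "equal_shares", shares=[1 / 3] * 3)


class TestShareSign:
    def test_symmetric_mean_zero(self):
        assert cm.share_sign(0.0, 3.7, "positive") == pytest.approx(50.0)

    @given(mean=st.floats(-5, 5), sd=st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_complement_identity(self, mean, sd):
        total = (cm.share_sign(mean, sd, "positive")
                 + cm.share_sign(mean, sd, "negative"))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cm.share_sign(1.0, 0.0)


class TestPseudoR2:
    def test_identical_likelihoods_give_zero(self):
        assert cm.pseudo_r2(-100.0, -100.0) == 0.0

    def test_zero_null_rejected(self):
        with pytest.raises(ValueError):
            cm.pseudo_r2(-1.0, 0.0)


class TestParameterVector:
    @given(st.lists(st.floats(-10, 10), min_size=8, max_size=8))
    @settings(max_examples=25, deadline=None)
    def test_pack_unpack_round_trip(self, values):
        spec = cm.preset_scenario(n=1, seed=1).truth.to_model_spec()
        vec = cm.ParameterVector(spec=spec, values=np.array(values))
        back = cm.ParameterVector.from_dict(spec, vec.as_dict())
        np.testing.assert_array_equal(back.values, vec.values)

    def test_wrong_length_rejected(self):
        spec = cm.preset_scenario(n=1, seed=1).truth.to_model_spec()
        with pytest.raises(ValueError, match="length"):
            cm.ParameterVector(spec=spec, values=np.zeros(3))

    def test_unknown_name_rejected(self):
        spec = cm.preset_scenario(n=1, seed=1).truth.to_model_spec()
        with pytest.raises(KeyError):
            cm.ParameterVector.from_dict(spec, {"beta:ghost[SI]": 1.0})


class TestModelSpec:
    def test_reference_constant_needs_override(self):
        with pytest.raises(ValueError, match="reference"):
            cm.ModelSpec(terms=(cm.Term("const", "NI"),))
        spec = cm.ModelSpec(terms=(cm.Term("const", "NI"),),
                            allow_reference_constant=True)
        assert spec.terms[0].variable == "const"

    def test_fixed_term_cannot_declare_shifters(self):
        with pytest.raises(ValueError, match="random"):
            cm.Term("x", "SI", random=False, mean_shifters=("z",))

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cm.ModelSpec(terms=(cm.Term("x", "SI"), cm.Term("x", "SI")))

    def test_yaml_round_trip(self, tmp_path):
        spec = cm.preset_scenario(n=1, seed=1).truth.to_model_spec(n_draws=77)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert cm.ModelSpec.from_yaml(path) == spec


class TestFit:
    def test_null_spec_matches_analytic_constants_only_optimum(
            self, mnl_dataset):
        """Constants-only fit reaches the closed-form multinomial MLE."""
        spec = cm.ModelSpec(
            terms=(cm.Term("const", "SI"), cm.Term("const", "MIN")))
        data = mnl_dataset.data
        result = cm.fit(data, spec, ll_zero_mode="constants_only")
        counts = data["severity"].value_counts(normalize=True)
        shares = [counts.get(a, 0.0) for a in ("SI", "MIN", "NI")]
        analytic = cm.null_loglik(len(data), "constants_only", shares=shares)
        assert result.ll_converged == pytest.approx(analytic, abs=1e-6)
        assert result.ll_zero == pytest.approx(analytic, abs=1e-6)

    def test_mnl_fit_matches_statsmodels_oracle(self, mnl_dataset):
        """Fixed-only fit agrees with an independent MNL implementation.

        Both models use the full parameterization (every covariate in both
        non-reference utilities, NI normalized to zero) so the parameter
        spaces coincide exactly.
        """
        sm = pytest.importorskip("statsmodels.api")
        data = mnl_dataset.data
        variables = ["rollover", "rural", "fatigue", "rear_end"]
        terms = [cm.Term("const", a) for a in ("SI", "MIN")]
        terms += [cm.Term(v, a) for v in variables for a in ("SI", "MIN")]
        spec = cm.ModelSpec(terms=tuple(terms))
        result = cm.fit(data, spec)
        # statsmodels MNLogit: outcome categories 0=NI (base), 1=SI, 2=MIN
        y = data["severity"].map({"NI": 0, "SI": 1, "MIN": 2})
        X = data[variables].astype(float).assign(const=1.0)
        ref = sm.MNLogit(y, X).fit(disp=0)
        assert result.ll_converged == pytest.approx(ref.llf, abs=1e-4)
        est = result.estimates.as_dict()
        for col, alt in ((0, "SI"), (1, "MIN")):
            for v in variables + ["const"]:
                assert est[f"beta:{v}[{alt}]"] == pytest.approx(
                    ref.params.loc[v, col], abs=2e-3), (v, alt)

    def test_mnl_coverage_of_true_parameters(self, mnl_truth):
        """95% Wald intervals cover the truth at roughly nominal rate."""
        spec = mnl_truth.to_model_spec()
        truth_vec = mnl_truth.to_theta(spec).values
        hits = total = 0
        for rep in range(30):
            design = cm.generate_design(
                2000, {"rollover": 0.14, "rural": 0.45, "fatigue": 0.02,
                       "rear_end": 0.19}, seed=500 + rep)
            ds = cm.simulate_outcomes(design, mnl_truth, seed=900 + rep)
            res = cm.fit(ds.data, spec)
            lo = res.estimates.values - 1.96 * res.std_errors
            hi = res.estimates.values + 1.96 * res.std_errors
            hits += int(((truth_vec >= lo) & (truth_vec <= hi)).sum())
            total += truth_vec.size
        assert hits / total >= 0.90

    def test_nested_model_likelihood_monotonicity(self, mnl_dataset):
        """Adding a truly relevant variable cannot lower the optimum."""
        data = mnl_dataset.data
        small = cm.ModelSpec(terms=(
            cm.Term("const", "SI"), cm.Term("const", "MIN"),
            cm.Term("fatigue", "MIN")))
        big = cm.ModelSpec(terms=small.terms + (cm.Term("rollover", "SI"),))
        ll_small = cm.fit(data, small).ll_converged
        ll_big = cm.fit(data, big).ll_converged
        assert ll_big >= ll_small - 1e-6

    def test_underidentified_data_rejected(self):
        spec = cm.preset_scenario(n=1, seed=1).truth.to_model_spec()
        tiny = cm.preset_scenario(n=5, seed=1).generate()
        with pytest.raises(ValueError, match="identify"):
            cm.fit(tiny.data, spec)

    def test_finite_difference_gradient_agrees_with_analytic(self):
        """Central differences over shared draws reproduce the analytic
        score at several points in parameter space."""
        from crashmix.model import (_build_design, _ensure_cube,
                                    _finite_diff_grad, _loglik_core)
        ds = cm.preset_scenario(n=300, seed=21).generate()
        spec = ds.truth.to_model_spec(n_draws=25)
        design = _build_design(ds.data, spec, "severity")
        cube = _ensure_cube(spec, 300, None)
        rng = np.random.default_rng(2)
        for _ in range(3):
            theta = rng.normal(scale=0.5, size=n_parameters(spec))
            _, scores = _loglik_core(theta, design, spec, cube, True)
            g_fd = _finite_diff_grad(
                lambda v: _loglik_core(v, design, spec, cube, False)[0],
                theta)
            np.testing.assert_allclose(scores.sum(axis=0), g_fd,
                                       rtol=1e-5, atol=1e-5)

    def test_sigma_reported_on_positive_scale(self):
        ds = cm.preset_scenario(n=600, seed=31).generate()
        spec = ds.truth.to_model_spec(n_draws=30)
        res = cm.fit(ds.data, spec)
        summary = res.summary_frame()
        sigma_rows = summary[summary["parameter"].str.startswith("sigma")]
        assert (sigma_rows["estimate"] > 0).all()

    def test_fit_result_serialization(self, tmp_path, mnl_dataset):
        spec = cm.ModelSpec(
            terms=(cm.Term("const", "SI"), cm.Term("const", "MIN")))
        res = cm.fit(mnl_dataset.data, spec)
        res.to_csv(tmp_path / "fit.csv")
        res.to_json(tmp_path / "fit.json")
        frame = pd.read_csv(tmp_path / "fit.csv")
        assert set(frame.columns) >= {"parameter", "estimate", "std_error",
                                      "t_stat", "significant"}
        assert res.ll_converged >= res.ll_zero
        assert 0 <= res.pseudo_r2 < 1
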