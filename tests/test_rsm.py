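"""Box-Behnken design and response-surface model tests."""

import numpy as np
import pandas as pd
import pytest

from blendsim.fixtures import (
    SyntheticDoeSpec,
    reference_factors,
    reference_runs,
    synth_doe,
)
from blendsim.rsm import (
    FactorDef,
    ResponseSurfaceModel,
    SingularDesignError,
    SpecLimits,
    build_bbd,
    code_factors,
    design_space,
    fit_rsm,
    optimize,
)

CONTENT_TERMS = ["x1", "x2", "x3", "x1x2", "x2x3"]
CU_TERMS = ["x1", "x2", "x3", "x1x3", "x2x3"]


@pytest.fixture(scope="module")
def factors():
    return reference_factors()


@pytest.fixture(scope="module")
def runs():
    return reference_runs()


@pytest.fixture(scope="module")
def content_fit(runs, factors):
    return fit_rsm(runs, "drug_content", factors, CONTENT_TERMS)


@pytest.fixture(scope="module")
def cu_fit(runs, factors):
    return fit_rsm(runs, "cu", factors, CU_TERMS)


# ----- coding ---------------------------------------------------------------

def test_coding_maps_levels(factors):
    coded = code_factors([[50, 20, 16.5], [32, 24, 24], [70, 25, 9]], factors)
    assert np.allclose(coded[0], [0, 0, 0])
    assert np.allclose(coded[1], [-0.9, 0.8, 1.0])
    assert np.allclose(coded[2], [1, 1, -1])


def test_factor_def_validates():
    with pytest.raises(ValueError):
        FactorDef("bad", 10.0, 10.0)


# ----- design construction --------------------------------------------------

def test_bbd_structure(factors):
    design = build_bbd(factors, center_runs=3, seed=5)
    assert len(design) == 15
    coded = design[[f"coded_{f.name}" for f in factors]].to_numpy()
    zeros_per_run = (coded == 0).sum(axis=1)
    assert (zeros_per_run == 1).sum() == 12       # edge midpoints
    assert (zeros_per_run == 3).sum() == 3        # centre replicates
    # multiset equals the canonical 3-factor set regardless of seed
    other = build_bbd(factors, center_runs=3, seed=99)
    key = lambda m: sorted(map(tuple, m))
    assert key(coded) == key(
        other[[f"coded_{f.name}" for f in factors]].to_numpy())


def test_bbd_no_center(factors):
    design = build_bbd(factors, center_runs=0)
    coded = design[[f"coded_{f.name}" for f in factors]].to_numpy()
    assert len(design) == 12
    assert not np.any(np.all(coded == 0, axis=1))


def test_bbd_requires_three_factors(factors):
    with pytest.raises(ValueError):
        build_bbd(factors[:2])


def test_bbd_orthogonality(factors):
    """Main effects and two-factor interactions are mutually orthogonal."""
    design = build_bbd(factors, center_runs=3)
    c = design[[f"coded_{f.name}" for f in factors]].to_numpy()
    cols = [c[:, 0], c[:, 1], c[:, 2],
            c[:, 0] * c[:, 1], c[:, 0] * c[:, 2], c[:, 1] * c[:, 2]]
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            assert abs(cols[a] @ cols[b]) < 1e-12


# ----- fitting --------------------------------------------------------------

def test_content_model_coefficients(content_fit):
    """Five-term drug-content model: published coded coefficients."""
    expect = dict(intercept=94.11, x1=-0.50, x2=-0.91, x3=0.80,
                  x1x2=-2.37, x2x3=0.42)
    for term, val in expect.items():
        assert round(content_fit.params[term], 2) == val


def test_cu_model_coefficients(cu_fit):
    expect = dict(intercept=5.20, x1=1.06, x2=-0.07, x3=-0.60,
                  x1x3=1.13, x2x3=-3.13)
    for term, val in expect.items():
        assert round(cu_fit.params[term], 2) == val


def test_intercept_equals_mean_on_orthogonal_design(content_fit, cu_fit, runs):
    assert content_fit.params["intercept"] == pytest.approx(
        runs["drug_content"].mean())
    assert cu_fit.params["intercept"] == pytest.approx(runs["cu"].mean())


def test_constant_response_gives_intercept_only(factors):
    design = build_bbd(factors, center_runs=3)
    design["y"] = 42.0
    fit = fit_rsm(design, "y", factors, CONTENT_TERMS)
    assert fit.params["intercept"] == pytest.approx(42.0)
    assert np.allclose(fit.params.drop("intercept"), 0.0, atol=1e-12)


def test_singular_design_names_aliased_terms(factors):
    coded = np.zeros((8, 3))
    coded[:, 0] = [-1, 1] * 4
    coded[:, 1] = coded[:, 0]          # aliased with x1
    model = ResponseSurfaceModel(coded, np.arange(8.0), ["x1", "x2"])
    with pytest.raises(SingularDesignError, match="aliased"):
        model.fit()


# ----- ANOVA ----------------------------------------------------------------

def test_content_anova_reproduces_published_table(content_fit):
    an = content_fit.anova().set_index("source")
    assert round(an.loc["model", "ss"], 2) == 36.88
    assert round(an.loc["residual", "ss"], 2) == 0.64
    assert round(an.loc["total", "ss"], 2) == 37.52
    assert round(an.loc["model", "F"], 2) == 103.25
    assert round(content_fit.rsquared, 4) == 0.9829
    assert round(content_fit.rsquared_adj, 4) == 0.9733
    assert round(content_fit.rsquared_pred, 4) == 0.9274


def test_cu_reduced_anova(cu_fit):
    """Backward elimination drops speed (p > 0.05); the reduced four-term
    model reproduces the published CU goodness-of-fit triple."""
    red = cu_fit.eliminate_backward(alpha=0.05)
    assert set(red.model.terms) == {"x1", "x3", "x1x3", "x2x3"}
    an = red.anova().set_index("source")
    assert round(an.loc["model", "ss"], 2) == 56.16
    assert round(an.loc["model", "F"], 2) == 59.50
    assert round(red.rsquared, 4) == 0.9597
    assert round(red.rsquared_adj, 4) == 0.9435
    assert round(red.rsquared_pred, 4) == 0.9018


def test_anova_identities(content_fit, cu_fit):
    for fit in (content_fit, cu_fit):
        assert fit.ss_model + fit.ss_resid == pytest.approx(fit.ss_total,
                                                            abs=1e-9)
        # F from the SS ratio vs the regression identity R2/(1-R2)
        f_alt = (fit.rsquared / fit.df_model) / \
            ((1 - fit.rsquared) / fit.df_resid)
        assert fit.fvalue == pytest.approx(f_alt, abs=1e-9)
        assert fit.rsquared_pred <= fit.rsquared


def test_perfect_fit_has_unit_rsquared(factors):
    spec = SyntheticDoeSpec(tuple(factors),
                            {"intercept": 10.0, "x1": 1.0, "x2x3": -2.0},
                            noise_sd=0.0, seed=3)
    table = synth_doe(spec)
    fit = fit_rsm(table, "y", factors, ["x1", "x2x3"])
    assert fit.rsquared == pytest.approx(1.0)
    assert fit.ss_resid == pytest.approx(0.0, abs=1e-18)


# ----- prediction -----------------------------------------------------------

def test_optimal_point_predictions(content_fit, cu_fit):
    """Model predictions at the optimal setting (32%, 24 rpm, 24 min)."""
    assert round(content_fit.predict([[32, 24, 24]]), 2) == 96.67
    assert round(cu_fit.predict([[32, 24, 24]]), 2) == 0.07


def test_prediction_table_all_optimal_rows(content_fit, cu_fit):
    from blendsim.fixtures import reference_optimal

    table = reference_optimal()
    settings = table[["filling_level", "rotational_speed",
                      "blending_time"]].to_numpy()
    pred_c = np.atleast_1d(content_fit.predict(settings))
    pred_u = np.atleast_1d(cu_fit.predict(settings))
    assert np.allclose(np.round(pred_c, 2), table["drug_content_pred"])
    assert np.allclose(np.round(pred_u, 2), table["cu_pred"])


def test_center_prediction_is_intercept(content_fit):
    assert content_fit.predict([[50, 20, 16.5]]) == pytest.approx(
        content_fit.params["intercept"])


def test_prediction_interval_contains_point(content_fit):
    pred, (lo, hi) = content_fit.predict([[50, 20, 16.5]], ci=True)
    assert lo < pred < hi


# ----- coefficient recovery (Monte Carlo) ------------------------------------

def test_synthetic_recovery_noiseless(factors):
    truth = {"intercept": 94.0, "x1": -0.5, "x2": -0.9, "x3": 0.8,
             "x1x2": -2.4, "x2x3": 0.4}
    table = synth_doe(SyntheticDoeSpec(tuple(factors), truth, noise_sd=0.0,
                                       seed=11))
    fit = fit_rsm(table, "y", factors, CONTENT_TERMS)
    for term, val in truth.items():
        assert fit.params[term] == pytest.approx(val, abs=1e-9)


def test_synthetic_recovery_unbiased_with_noise(factors):
    """Coefficient estimates are unbiased and match the OLS SE formula."""
    truth = {"intercept": 94.0, "x1": -0.5, "x1x2": -2.4}
    sd = 0.25
    reps = 300
    est = np.zeros((reps, 2))
    for k in range(reps):
        table = synth_doe(SyntheticDoeSpec(tuple(factors), truth, noise_sd=sd,
                                           seed=1000 + k))
        fit = fit_rsm(table, "y", factors, ["x1", "x1x2"])
        est[k] = [fit.params["x1"], fit.params["x1x2"]]
    # unbiasedness
    assert est[:, 0].mean() == pytest.approx(-0.5, abs=4 * sd / np.sqrt(8 * reps))
    assert est[:, 1].mean() == pytest.approx(-2.4, abs=4 * sd / np.sqrt(4 * reps))
    # empirical SE vs sigma/sqrt(sum x^2): x1 column has 8 non-zeros,
    # x1x2 column 4
    assert est[:, 0].std() == pytest.approx(sd / np.sqrt(8), rel=0.10)
    assert est[:, 1].std() == pytest.approx(sd / np.sqrt(4), rel=0.10)


def test_same_seed_same_table(factors):
    spec = SyntheticDoeSpec(tuple(factors), {"intercept": 1.0}, noise_sd=0.5,
                            seed=7)
    pd.testing.assert_frame_equal(synth_doe(spec), synth_doe(spec))


# ----- design space and optimisation ----------------------------------------

@pytest.fixture(scope="module")
def fits(content_fit, cu_fit):
    return {"drug_content": content_fit, "cu": cu_fit}


GRID = {"filling_level": np.linspace(30, 70, 21),
        "rotational_speed": np.linspace(15, 25, 21)}
SPECS = [SpecLimits("drug_content", lower=95.0, upper=105.0),
         SpecLimits("cu", upper=5.0)]


def test_design_space_contains_optimal_point(fits, factors):
    space = design_space(fits, SPECS, GRID, factors,
                         fixed={"blending_time": 24.0})
    ok = space[space["acceptable"]]
    assert len(ok) > 0
    at_opt = space[(space["filling_level"] == 32.0)
                   & (space["rotational_speed"] == 24.0)]
    assert bool(at_opt["acceptable"].iloc[0])


def test_design_space_impossible_and_vacuous(fits, factors):
    impossible = [SpecLimits("drug_content", lower=200.0)]
    space = design_space(fits, impossible, GRID, factors,
                         fixed={"blending_time": 24.0})
    assert not space["acceptable"].any()
    vacuous = [SpecLimits("drug_content"), SpecLimits("cu")]
    space = design_space(fits, vacuous, GRID, factors,
                         fixed={"blending_time": 24.0})
    assert space["acceptable"].all()


def test_optimize_ranks_low_fill_high_speed(fits, factors):
    top = optimize(fits, SPECS, GRID, factors,
                   {"drug_content": "maximize", "cu": "minimize"},
                   fixed={"blending_time": 24.0}, top=10)
    assert len(top) > 0
    # the optimum sits at low filling level and high speed, consistent
    # with the published optimal settings (32%, 24 rpm)
    best = top.iloc[0]
    assert best["filling_level"] <= 36.0
    assert best["rotational_speed"] >= 23.0


def test_optimize_infeasible_is_empty(fits, factors):
    out = optimize(fits, [SpecLimits("drug_content", lower=200.0)], GRID,
                   factors, {"drug_content": "maximize"},
                   fixed={"blending_time": 24.0})
    assert out.empty
    assert "diagnostic" in out.attrs
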