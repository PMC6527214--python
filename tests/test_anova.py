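"""Unit and property tests for the balanced mixed-model ANOVA engine."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cafeqg.anova import (
    AnovaTable,
    Factor,
    ModelSpec,
    UnbalancedDataError,
    derive_ems,
    estimate_components,
    fit_balanced_anova,
    synthesize_tests,
)

from conftest import REFERENCE_MS_A


def _grid(*level_counts, reps, rng, sd=1.0, names="abc"):
    levels = [range(n) for n in level_counts]
    rows = [dict(zip(names, combo)) for combo in itertools.product(*levels)
            for _ in range(reps)]
    df = pd.DataFrame(rows)
    df["y"] = rng.normal(0, sd, len(df))
    return df


# ---------------------------------------------------------------------------
# EMS structure
# ---------------------------------------------------------------------------


def test_one_random_factor_textbook_ems():
    """One-way random-effects: EMS(L) = sigma2_eps + r*sigma2_L, tested vs residual."""
    model = ModelSpec((Factor("L", 5, fixed=False),), n_replicates=4)
    ems = derive_ems(model)
    assert ems.coef.loc["L", "L"] == 4
    assert ems.coef.loc["L", "residual"] == 1
    assert ems.denominators["L"] == {"residual": 1.0}


def test_panel_design_ems_and_denominators(panel_model):
    """Four-way mixed design: highest-order interaction coefficient and the
    synthesized line-term denominator follow the inclusion-exclusion pattern."""
    ems = derive_ems(panel_model)
    assert ems.coef.loc["L", "L×E×S×X"] == 10
    assert ems.coef.loc["L", "L"] == 120
    assert ems.denominators["L"] == {
        "L×E": 1.0, "L×S": 1.0, "L×X": 1.0,
        "L×E×S": -1.0, "L×E×X": -1.0, "L×S×X": -1.0, "L×E×S×X": 1.0,
    }
    # fixed main effects are tested over their interaction with the random line
    assert ems.denominators["E"] == {"L×E": 1.0}
    assert ems.denominators["S"] == {"L×S": 1.0}
    assert ems.denominators["X"] == {"L×X": 1.0}


def test_fully_fixed_model_every_denominator_is_residual():
    model = ModelSpec((Factor("a", 2, True), Factor("b", 3, True),
                       Factor("c", 2, True)), n_replicates=3)
    ems = derive_ems(model)
    for term, weights in ems.denominators.items():
        assert weights == {"residual": 1.0}, term


def test_ems_monte_carlo_oracle():
    """Averaged mean squares over simulated datasets reproduce each EMS linear
    form in the variance components, for the 4-way mixed design."""
    rng = np.random.default_rng(42)
    nL, nE, nS, nX, r = 4, 3, 2, 2, 2
    model = ModelSpec((Factor("L", nL, False), Factor("E", nE, True),
                       Factor("S", nS, True), Factor("X", nX, True)), n_replicates=r)
    ems = derive_ems(model)
    sigma2 = {"L": 4.0, "L×E": 2.0, "L×S": 1.0, "L×X": 3.0, "L×E×S": 1.5,
              "L×E×X": 0.5, "L×S×X": 2.5, "L×E×S×X": 1.0, "residual": 2.0}
    dims = {"L": nL, "E": nE, "S": nS, "X": nX}
    random_terms = [t for t in sigma2 if t != "residual"]

    n_sim = 600
    template = _grid(nL, nE, nS, nX, reps=r, rng=rng, names=["L", "E", "S", "X"])
    ms_sum = {name: 0.0 for name in ems.coef.index}
    ms_sq = {name: 0.0 for name in ems.coef.index}
    for _ in range(n_sim):
        cell = np.zeros((nL, nE, nS, nX))
        for term in random_terms:
            facs = term.split("×")
            shape = tuple(dims[f] for f in facs)
            draw = rng.normal(0, np.sqrt(sigma2[term]), shape)
            view = np.expand_dims(draw, axis=tuple(
                i for i, f in enumerate("LESX") if f not in facs))
            cell = cell + view
        y = cell[..., None] + rng.normal(0, np.sqrt(sigma2["residual"]),
                                         (nL, nE, nS, nX, r))
        df = template.copy()
        df["y"] = y.reshape(-1)
        tab = fit_balanced_anova(df, model, "y").table
        for name in ms_sum:
            ms_sum[name] += tab.loc[name, "ms"]
            ms_sq[name] += tab.loc[name, "ms"] ** 2

    vec = np.array([sigma2[c] for c in ems.component_names])
    for term in random_terms + ["residual"]:
        expected = float(ems.coef.loc[term] @ vec)  # no fixed effects simulated
        mean_ms = ms_sum[term] / n_sim
        se = np.sqrt((ms_sq[term] / n_sim - mean_ms**2) / n_sim)
        assert abs(mean_ms - expected) < 3 * se, (term, mean_ms, expected)


# ---------------------------------------------------------------------------
# Sums of squares
# ---------------------------------------------------------------------------


def test_two_group_f_equals_squared_t(rng):
    """Single two-level fixed factor: F equals the squared pooled t statistic
    and SS equals n/2 * (mean difference)^2."""
    n = 8
    df = pd.DataFrame({"g": [0] * n + [1] * n,
                       "y": rng.normal(0, 1, 2 * n) + np.r_[np.zeros(n), np.ones(n)]})
    model = ModelSpec((Factor("g", 2, True),), n_replicates=n)
    tab = synthesize_tests(fit_balanced_anova(df, model, "y"), derive_ems(model)).table
    t_stat, p = stats.ttest_ind(df.y[df.g == 1], df.y[df.g == 0])
    diff = df.y[df.g == 1].mean() - df.y[df.g == 0].mean()
    assert tab.loc["g", "ss"] == pytest.approx(n / 2 * diff**2, rel=1e-12)
    assert tab.loc["g", "f"] == pytest.approx(t_stat**2, rel=1e-10)
    assert tab.loc["g", "p"] == pytest.approx(p, rel=1e-10)


def test_zero_residual_for_cell_mean_data(rng):
    df = _grid(3, 2, reps=4, rng=rng, names=["a", "b"])
    df["y"] = df["a"] * 1.5 - df["b"]  # constant within cells
    model = ModelSpec((Factor("a", 3, True), Factor("b", 2, True)), n_replicates=4)
    tab = fit_balanced_anova(df, model, "y").table
    assert tab.loc["residual", "ss"] == pytest.approx(0.0, abs=1e-18)


@pytest.mark.parametrize("shape,reps", [((2, 3), 2), ((3, 2, 2), 3), ((4,), 5)])
def test_ss_agree_with_projection_oracle(shape, reps, rng):
    """SS/df/MS match the classical linear-model decomposition (statsmodels OLS
    with sum-to-zero contrasts) to 1e-8 relative on small balanced data."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    names = ["a", "b", "c"][: len(shape)]
    df = _grid(*shape, reps=reps, rng=rng, names=names)
    df["y"] += sum((i + 1) * df[n] for i, n in enumerate(names))
    model = ModelSpec(tuple(Factor(n, k, True) for n, k in zip(names, shape)),
                      n_replicates=reps)
    tab = fit_balanced_anova(df, model, "y").table

    formula = "y ~ " + " * ".join(f"C({n}, Sum)" for n in names)
    ref = sm.stats.anova_lm(ols(formula, data=df).fit(), typ=1)
    for term in model.terms():
        ref_name = ":".join(f"C({n}, Sum)" for n in term)
        assert tab.loc[model.term_name(term), "ss"] == pytest.approx(
            ref.loc[ref_name, "sum_sq"], rel=1e-8)
        assert tab.loc[model.term_name(term), "df"] == ref.loc[ref_name, "df"]
    assert tab.loc["residual", "ss"] == pytest.approx(ref.loc["Residual", "sum_sq"],
                                                      rel=1e-8)


def test_df_bookkeeping(panel_model, rng):
    """Term dfs plus residual df sum to N - 1 for several designs."""
    for model in [
        panel_model,
        ModelSpec((Factor("a", 2, True), Factor("b", 5, False)), n_replicates=3),
        ModelSpec((Factor("a", 4, False),), n_replicates=7),
    ]:
        total = sum(model.term_df(t) for t in model.terms()) + model.residual_df()
        assert total == model.n_obs - 1


def test_unbalanced_data_rejected(rng):
    df = _grid(2, 2, reps=3, rng=rng, names=["a", "b"]).iloc[:-1]
    model = ModelSpec((Factor("a", 2, True), Factor("b", 2, True)), n_replicates=3)
    with pytest.raises(UnbalancedDataError):
        fit_balanced_anova(df, model, "y")


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------


def test_components_reproduce_mean_squares(panel_model):
    """Plugging raw estimates back through the EMS matrix returns the observed
    mean squares exactly (pre-truncation)."""
    ems = derive_ems(panel_model)
    anova = AnovaTable.from_mean_squares(panel_model, REFERENCE_MS_A)
    comps = estimate_components(anova, ems)
    a = ems.coef.loc[ems.component_names, ems.component_names].to_numpy()
    recon = a @ comps.table["raw"].to_numpy()
    observed = anova.table.loc[ems.component_names, "ms"].to_numpy()
    assert np.allclose(recon, observed, rtol=1e-12)


def test_negative_component_truncated(panel_model):
    """A mean square below its own error term yields a zero estimate with the
    truncation flag set and SE reported as zero; the raw value is retained."""
    ms = dict(REFERENCE_MS_A)
    ms["L×E×S×X"] = 200.0  # below the residual MS 267.3
    comps = estimate_components(AnovaTable.from_mean_squares(panel_model, ms),
                                derive_ems(panel_model))
    row = comps.table.loc["L×E×S×X"]
    assert row["truncated"]
    assert row["estimate"] == 0.0 and row["se"] == 0.0
    assert row["raw"] == pytest.approx((200.0 - 267.3) / 10, rel=1e-12)


def test_parameter_recovery_from_simulated_panels():
    """Simulating the default 46-line study at its stated variance components
    and re-estimating recovers each component within 3 propagated SEs."""
    from cafeqg.synthetic import SimulationConfig, simulate_consumption
    from cafeqg.traits import correct_evaporation

    model = ModelSpec((Factor("line_id", 46, False), Factor("exposure", 3, True),
                       Factor("solution", 2, True), Factor("sex", 2, True)),
                      n_replicates=10)
    ems = derive_ems(model)
    truth = SimulationConfig().variance_components
    name_map = {"L": "line_id", "E": "exposure", "S": "solution", "X": "sex"}

    n_ok_runs = 0
    n_runs = 4
    for seed in range(n_runs):
        cfg = SimulationConfig(seed=seed)
        records, _ = simulate_consumption(cfg)
        corrected = correct_evaporation(records)
        tab = fit_balanced_anova(corrected, model, "consumption_mm")
        comps = estimate_components(tab, ems)
        ok = True
        for term, v in truth.items():
            engine_term = "×".join(name_map.get(f, f) for f in term.split("×"))
            row = comps.table.loc[engine_term]
            if abs(row["raw"] - v) > 3 * row["raw_se"]:
                ok = False
        n_ok_runs += ok
    assert n_ok_runs >= n_runs - 1


def test_nonpositive_denominator_flagged(panel_model):
    ms = dict(REFERENCE_MS_A)
    # force the synthesized denominator of L negative
    ms["L×E×S"] = 5000.0
    ms["L×E×X"] = 5000.0
    ms["L×S×X"] = 5000.0
    tab = synthesize_tests(AnovaTable.from_mean_squares(panel_model, ms),
                           derive_ems(panel_model)).table
    assert tab.loc["L", "denom_nonpositive"]
    assert np.isnan(tab.loc["L", "f"])
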