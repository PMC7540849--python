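"""REML mixed model: closed-form oracles, gating logic, marginal means."""

import numpy as np
import pandas as pd
import pytest

from pasturepheno.experiment_design import generate_design
from pasturepheno.mixed_model import (
    MixedModelFit,
    ModelSpec,
    build_design_matrices,
    compact_letter_display,
    emm_contrast,
    emmeans,
    fit_reml,
    fit_trait,
    gate_pvalues,
    simplify_variance,
    wald_hierarchy,
)
from pasturepheno.set_smoothing import aggregate_psa_table, smooth_table, traits_table
from pasturepheno.synthetic_data import default_params, simulate


# ---------------------------------------------------------- design matrices

def test_design_matrix_shapes_at_published_scale(design10, traits10, sim10):
    from pasturepheno.synthetic_data import apply_attrition, published_attrition_rules

    filtered, _ = apply_attrition(sim10, published_attrition_rules(design10))
    harvest_ids = set(filtered.harvest["half_pot_id"])
    data = traits10[traits10["half_pot_id"].isin(harvest_ids)]
    dm = build_design_matrices(design10.table, data, "AG")
    assert dm.y.size == 236
    assert dm.Z.shape[1] == 40 + 120
    assert (dm.z_component == 0).sum() == 40
    assert (dm.z_component == 1).sum() == 120
    assert len(np.unique(dm.group_labels["full"])) == 4
    assert len(np.unique(dm.group_labels["species"])) == 2
    assert np.linalg.matrix_rank(dm.X) == dm.X.shape[1]


def test_orphan_observation_rejected(design10, traits10):
    data = traits10.head(5).copy()
    data.loc[data.index[-1], "half_pot_id"] = "GHOST"
    with pytest.raises(ValueError, match="unknown half-pots"):
        build_design_matrices(design10.table, data, "AG")


def test_single_species_subset_drops_zero_block(design10, traits10):
    grass_ids = design10.table.loc[design10.table["species"] == "grass", "half_pot_id"]
    data = traits10[traits10["half_pot_id"].isin(grass_ids)]
    dm = build_design_matrices(design10.table, data, "AG")
    assert not any(c.startswith("legume:") for c in dm.columns)
    assert np.linalg.matrix_rank(dm.X) == dm.X.shape[1]


def test_one_replicate_rank_matches_dummy_oracle():
    d = generate_design(1, seed=31)
    sim = simulate(d, default_params(), seed=32)
    agg, _ = aggregate_psa_table(sim.psa)
    tr = traits_table(smooth_table(agg))
    dm = build_design_matrices(d.table, tr, "AG")
    # oracle: span of one-hot dummies for every term in the partition
    f = dm.factors
    blocks = [np.ones((len(f), 1))]
    for col in ("greenhouse_side", "side"):
        blocks.append(pd.get_dummies(f[col]).to_numpy(float))
    cell = (
        f["species"] + ":" + f["cultivation"] + ":" + f["nitrogen"] + ":" + f["phosphorus"]
    )
    blocks.append(pd.get_dummies(cell).to_numpy(float))
    oracle = np.hstack(blocks)
    assert np.linalg.matrix_rank(dm.X) == np.linalg.matrix_rank(oracle)


# ---------------------------------------------------------------- fit_reml

def test_ols_degenerate_case_matches_closed_form():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
    y = X @ np.array([2.0, 1.0, -1.0]) + rng.normal(0, 1.7, 40)
    fit = fit_reml(y, X, None, np.zeros(40, dtype=int))
    rss = float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))
    assert fit.resid_vars["0"] == pytest.approx(rss / (40 - 3), rel=1e-6)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    assert np.allclose(fit.beta, beta, rtol=1e-8)


def test_balanced_one_way_matches_anova_estimators():
    k, m = 8, 5
    rng = np.random.default_rng(5)
    effects = rng.normal(0, 3.0, k)
    y = np.concatenate([10 + e + rng.normal(0, 1.0, m) for e in effects])
    groups = np.repeat(np.arange(k), m)
    X = np.ones((k * m, 1))
    Z = np.zeros((k * m, k))
    Z[np.arange(k * m), groups] = 1.0
    fit = fit_reml(y, X, Z, np.zeros(k * m, dtype=int))
    means = np.array([y[groups == g].mean() for g in range(k)])
    msb = m * np.sum((means - y.mean()) ** 2) / (k - 1)
    msw = sum(np.sum((y[groups == g] - means[g]) ** 2) for g in range(k)) / (k * (m - 1))
    assert fit.resid_vars["0"] == pytest.approx(msw, rel=1e-5)
    assert fit.var_components["mainunit"] == pytest.approx((msb - msw) / m, rel=1e-4)
    assert fit.loglik > -np.inf and fit.converged


def test_disjoint_residual_groups_match_groupwise_ols():
    rng = np.random.default_rng(9)
    n1, n2 = 25, 35
    y = np.concatenate([rng.normal(5, 1.0, n1), rng.normal(-2, 4.0, n2)])
    X = np.zeros((n1 + n2, 2))
    X[:n1, 0] = 1.0
    X[n1:, 1] = 1.0
    groups = np.array(["a"] * n1 + ["b"] * n2)
    fit = fit_reml(y, X, None, groups)
    assert fit.resid_vars["a"] == pytest.approx(np.var(y[:n1], ddof=1) * (n1 - 1) / (n1 - 1), rel=1e-5)
    assert fit.resid_vars["a"] == pytest.approx(float(np.sum((y[:n1] - y[:n1].mean()) ** 2) / (n1 - 1)), rel=1e-5)
    assert fit.resid_vars["b"] == pytest.approx(float(np.sum((y[n1:] - y[n1:].mean()) ** 2) / (n2 - 1)), rel=1e-5)


def test_reml_is_invariant_to_side_relabelling(design10, traits10, ag_fit):
    flipped = design10.table.copy()
    flipped["side"] = flipped["side"].map({"E": "W", "W": "E"})
    refit = fit_trait(flipped, traits10, ModelSpec(response="AG", variance_model="full"))
    assert refit.loglik == pytest.approx(ag_fit.loglik, abs=1e-4)
    for k in ag_fit.var_components:
        assert refit.var_components[k] == pytest.approx(ag_fit.var_components[k], rel=1e-3)
    for k in ag_fit.resid_vars:
        assert refit.resid_vars[k] == pytest.approx(ag_fit.resid_vars[k], rel=1e-3)


# ------------------------------------------------------- variance selection

def _fake_fit(loglik, n_params, vm):
    return MixedModelFit(
        beta=np.zeros(1), cov_beta=np.eye(1), columns=[], terms={},
        var_components={}, resid_vars={}, variance_model=vm, loglik=loglik,
        n_variance_params=n_params, converged=True, gradient_norm=0.0, n_obs=100,
    )


def test_identical_likelihoods_simplify_to_homogeneous():
    fits = {
        "full": _fake_fit(-100.0, 6, "full"),
        "species": _fake_fit(-100.0, 4, "species"),
        "nitrogen": _fake_fit(-100.0, 4, "nitrogen"),
        "homogeneous": _fake_fit(-100.0, 3, "homogeneous"),
    }
    chosen, table = simplify_variance(fits)
    assert chosen == "homogeneous"
    assert (table["lrt_stat"] == 0).all()


def test_species_difference_retained_when_nitrogen_drop_accepted():
    fits = {
        "full": _fake_fit(-100.0, 6, "full"),
        "species": _fake_fit(-100.5, 4, "species"),  # LRT 1.0, df 2 -> accept
        "nitrogen": _fake_fit(-140.0, 4, "nitrogen"),
        "homogeneous": _fake_fit(-140.0, 3, "homogeneous"),  # vs species: huge
    }
    chosen, _ = simplify_variance(fits)
    assert chosen == "species"


def test_full_model_retained_when_both_drops_rejected():
    fits = {
        "full": _fake_fit(-100.0, 6, "full"),
        "species": _fake_fit(-150.0, 4, "species"),
        "nitrogen": _fake_fit(-150.0, 4, "nitrogen"),
        "homogeneous": _fake_fit(-170.0, 3, "homogeneous"),
    }
    chosen, _ = simplify_variance(fits)
    assert chosen == "full"


# ---------------------------------------------------------------- Wald tests

def test_gating_with_no_significant_interactions_reports_all_mains():
    p = {t: 0.5 for t in ("C*N*P", "C*N", "C*P", "N*P", "C", "N", "P")}
    mask = gate_pvalues(p)
    assert all(mask.values())


def test_wald_f_matches_rss_comparison_oracle():
    # homoscedastic, fixed-effects-only: Wald F == model-comparison F
    d = generate_design(3, seed=21)
    p = default_params()
    sim = simulate(d, p, seed=22)
    agg, _ = aggregate_psa_table(sim.psa)
    tr = traits_table(smooth_table(agg))
    fit = fit_trait(d.table, tr, ModelSpec(response="AG", variance_model="homogeneous"),
                    include_random=False)
    tt = wald_hierarchy(fit, "grass").set_index("term")
    dm = fit.matrices
    X, y = dm.X, dm.y
    beta_full, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(np.sum((y - X @ beta_full) ** 2))
    n, rank = len(y), X.shape[1]
    for term in ("C*N*P", "C*N", "C", "P"):
        idx = fit.terms[f"grass:{term}"]
        Xr = np.delete(X, idx, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rss_r = float(np.sum((y - Xr @ br) ** 2))
        f_oracle = (rss_r - rss_full) / len(idx) / (rss_full / (n - rank))
        assert tt.loc[term, "F"] == pytest.approx(f_oracle, rel=1e-6)
        assert tt.loc[term, "den_df"] == n - rank


def test_wald_hierarchy_requires_species_terms(ag_fit):
    with pytest.raises(ValueError):
        wald_hierarchy(ag_fit, "clover")


# --------------------------------------------------------------- marginal means

def test_emmeans_match_cell_prediction_oracle(design10, traits10):
    import statsmodels.formula.api as smf

    # unbalanced: drop a handful of observations
    data = traits10.drop(traits10.index[[3, 10, 57, 100, 101, 180]]).copy()
    fit = fit_trait(design10.table, data, ModelSpec(response="AG", variance_model="homogeneous"),
                    include_random=False)
    em = emmeans(fit, ["species", "cultivation"])

    frame = fit.matrices.factors.copy()
    frame["AG"] = fit.matrices.y
    ols = smf.ols(
        "AG ~ C(replicate) + C(greenhouse_side) + C(side) "
        "+ C(species) * C(cultivation) * C(nitrogen) * C(phosphorus)",
        data=frame,
    ).fit()
    import itertools

    levels = {c: sorted(frame[c].unique()) for c in
              ["replicate", "greenhouse_side", "side", "species", "cultivation",
               "nitrogen", "phosphorus"]}
    grid = pd.DataFrame(
        itertools.product(*levels.values()), columns=list(levels)
    )
    grid["pred"] = ols.predict(grid)
    oracle = grid.groupby(["species", "cultivation"])["pred"].mean()
    for _, row in em.iterrows():
        assert row["emm"] == pytest.approx(
            oracle.loc[(row["species"], row["cultivation"])], rel=1e-8
        )


def test_emmeans_on_balanced_fit_recover_treatment_ordering(ag_fit):
    em = emmeans(ag_fit, ["species", "cultivation", "nitrogen", "phosphorus"])
    assert len(em) == 16
    g = em[em["species"] == "grass"].set_index(["cultivation", "nitrogen", "phosphorus"])
    # nitrogen dominates grass growth; mixtures outyield monocultures
    assert g.loc[("mono", "H", "H"), "emm"] > g.loc[("mono", "L", "H"), "emm"]
    assert g.loc[("mixture", "L", "H"), "emm"] > g.loc[("mono", "L", "H"), "emm"]
    assert (em["se"] > 0).all()
    assert em["half_lsd"].nunique() == 1


def test_emm_contrast_consistent_with_emmeans(ag_fit):
    em = emmeans(ag_fit, ["species", "cultivation"]).set_index(["species", "cultivation"])
    con = emm_contrast(
        ag_fit, ["species", "cultivation"],
        {"species": "grass", "cultivation": "mixture"},
        {"species": "grass", "cultivation": "mono"},
    )
    diff = em.loc[("grass", "mixture"), "emm"] - em.loc[("grass", "mono"), "emm"]
    assert con["estimate"] == pytest.approx(diff, rel=1e-9)
    assert 0 < con["p_value"] < 1


def test_letter_display_contract():
    means = np.array([10.0, 9.9, 1.0])
    # only the big gap is significant
    letters = compact_letter_display(means, [(0, 2), (1, 2)])
    assert letters[0] == letters[1]
    assert set(letters[0]) != set(letters[2])
    same = compact_letter_display(means, [])
    assert len(set(same)) == 1


def test_unknown_emm_factor_rejected(ag_fit):
    with pytest.raises(ValueError):
        emmeans(ag_fit, ["flavour"])
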