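"""Metabolomics arm: QC, LOD imputation, mixed models, pooling, cluster FDR."""

import numpy as np
import pandas as pd
import pytest

from metactivity.metabolite_pipeline import (
    cluster_fdr,
    convergence_pool,
    fit_models,
    impute_lod,
    qc_filter,
    run_metabolite_pipeline,
)
from metactivity.synthetic_data import (
    DEFAULT_CLUSTER_MAP,
    MetabolomicsSpec,
    simulate_metabolomics,
)


def _base_table(n_missing_met1: int = 0, n_records: int = 100) -> pd.DataFrame:
    """Single-cohort table with a controllable missing count for met1."""
    rng = np.random.default_rng(0)
    rows = []
    for i in range(n_records):
        for met in ("met1", "met2"):
            missing = met == "met1" and i < n_missing_met1
            rows.append({
                "subject": f"S{i}", "cohort": "BLSA", "region": "ITG",
                "metabolite": met,
                "concentration": np.nan if missing else float(rng.uniform(1, 5)),
                "below_lod": False, "lod": 0.5, "missing": missing,
                "group": "CN" if i % 2 else "AD", "sex": "F", "age": 85.0,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def test_over_threshold_metabolite_excluded():
    kept, log = qc_filter(_base_table(n_missing_met1=31))
    assert "met1" not in set(kept["metabolite"])
    assert "met2" in set(kept["metabolite"])
    assert log.loc[log["metabolite"] == "met1", "excluded"].all()


def test_exactly_thirty_percent_retained():
    kept, _ = qc_filter(_base_table(n_missing_met1=30))
    assert {"met1", "met2"} <= set(kept["metabolite"])


def test_no_missingness_identity():
    table = _base_table(0)
    kept, log = qc_filter(table)
    pd.testing.assert_frame_equal(kept.reset_index(drop=True), table)
    assert not log["excluded"].any()


def test_qc_and_imputation_independent_across_metabolites():
    """Relabeling metabolites permutes rows but never changes their values."""
    table = _base_table(10)
    swapped = table.copy()
    swapped["metabolite"] = swapped["metabolite"].map(
        {"met1": "met2", "met2": "met1"})
    out1 = impute_lod(qc_filter(table)[0])
    out2 = impute_lod(qc_filter(swapped)[0])
    renamed = out2.copy()
    renamed["metabolite"] = renamed["metabolite"].map(
        {"met1": "met2", "met2": "met1"})
    key = ["subject", "region", "metabolite"]
    pd.testing.assert_frame_equal(
        out1.sort_values(key).reset_index(drop=True),
        renamed.sort_values(key).reset_index(drop=True))


# ---------------------------------------------------------------------------
# LOD imputation
# ---------------------------------------------------------------------------

def test_below_lod_imputed_at_half_lod():
    table = _base_table(0)
    table.loc[0, ["below_lod", "concentration", "lod"]] = [True, np.nan, 0.8]
    out = impute_lod(table)
    assert out.loc[0, "concentration"] == pytest.approx(0.4)


def test_no_censoring_is_identity():
    table = _base_table(0)
    pd.testing.assert_frame_equal(impute_lod(table), table)


def test_per_metabolite_lods_applied_independently():
    table = _base_table(0)
    idx1 = table[table["metabolite"] == "met1"].index[0]
    idx2 = table[table["metabolite"] == "met2"].index[0]
    table.loc[idx1, ["below_lod", "concentration", "lod"]] = [True, np.nan, 0.8]
    table.loc[idx2, ["below_lod", "concentration", "lod"]] = [True, np.nan, 2.0]
    out = impute_lod(table)
    assert out.loc[idx1, "concentration"] == pytest.approx(0.4)
    assert out.loc[idx2, "concentration"] == pytest.approx(1.0)


def test_below_lod_without_lod_value_raises():
    table = _base_table(0)
    table.loc[0, ["below_lod", "concentration", "lod"]] = [True, np.nan, np.nan]
    with pytest.raises(ValueError, match="below-LOD"):
        impute_lod(table)


# ---------------------------------------------------------------------------
# Repeated-measures fits
# ---------------------------------------------------------------------------

def test_planted_beta_recovered():
    """Planted MFG effect -0.5 recovered within +-0.15 on average."""
    betas = {"metX": {"MFG": -0.5}}
    estimates = []
    for rep in range(30):
        spec = MetabolomicsSpec(n_subjects_per_group=9, betas=betas,
                                rho=0.5, sigma=0.4, cohorts=("BLSA",))
        table, _ = simulate_metabolomics(spec, seed=100 + rep)
        res = fit_models(table, "group", scope="BLSA")
        row = res[(res["metabolite"] == "metX") & (res["region"] == "MFG")]
        estimates.append(float(row["beta"].iloc[0]))
    assert abs(np.mean(estimates) + 0.5) < 0.15


def test_single_level_predictor_rejected():
    table = _base_table(0)
    table["group"] = "AD"
    with pytest.raises(ValueError, match="single level"):
        fit_models(table, "group", scope="BLSA")


def test_non_positive_concentration_rejected():
    table = _base_table(0)
    table.loc[0, "concentration"] = -1.0
    with pytest.raises(ValueError, match="positive"):
        fit_models(table, "group", scope="BLSA")


def test_pathology_predictor_uses_score_column():
    spec = MetabolomicsSpec(n_subjects_per_group=8,
                            betas={"metX": {"ITG": -0.4}}, rho=0.3, sigma=0.4)
    table, _ = simulate_metabolomics(spec, seed=5)
    res = fit_models(table, "cerad", scope="pooled")
    assert set(res["predictor"]) == {"cerad"}
    assert len(res) == 2  # one row per region


# ---------------------------------------------------------------------------
# Convergence pooling
# ---------------------------------------------------------------------------

def _results(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["metabolite", "region", "predictor",
                                       "beta", "se", "p", "scope",
                                       "n_subjects"])


def test_concordant_and_divergent_routing():
    spec = MetabolomicsSpec(n_subjects_per_group=6)
    table, _ = simulate_metabolomics(spec, seed=9)
    res_a = _results([
        ("m1", "ITG", "group", -0.2, 0.1, 0.04, "BLSA", 18),
        ("m2", "ITG", "group", +0.1, 0.1, 0.30, "BLSA", 18),
    ])
    res_b = _results([
        ("m1", "ITG", "group", -0.3, 0.1, 0.01, "ROS", 18),
        ("m2", "ITG", "group", -0.1, 0.1, 0.35, "ROS", 18),
    ])
    table = table[table["metabolite"].isin(["lanosterol"])].copy()
    table["metabolite"] = "m1"
    primary, secondary = convergence_pool(res_a, res_b, table, "group")
    assert set(primary["metabolite"]) == {"m1"}
    assert (primary["scope"] == "pooled").all()
    assert set(secondary["metabolite"]) == {"m2"}
    assert not secondary["single_cohort"].any()


def test_single_cohort_metabolite_flagged():
    spec = MetabolomicsSpec(n_subjects_per_group=6)
    table, _ = simulate_metabolomics(spec, seed=9)
    table = table[table["metabolite"] == "lanosterol"].copy()
    table["metabolite"] = "m1"
    res_a = _results([("m1", "ITG", "group", -0.2, 0.1, 0.04, "BLSA", 18),
                      ("m3", "ITG", "group", -0.2, 0.1, 0.10, "BLSA", 18)])
    res_b = _results([("m1", "ITG", "group", -0.3, 0.1, 0.01, "ROS", 18)])
    _, secondary = convergence_pool(res_a, res_b, table, "group")
    assert secondary.loc[secondary["metabolite"] == "m3",
                         "single_cohort"].all()


def test_zero_beta_counts_as_concordant():
    spec = MetabolomicsSpec(n_subjects_per_group=6)
    table, _ = simulate_metabolomics(spec, seed=9)
    table = table[table["metabolite"] == "lanosterol"].copy()
    table["metabolite"] = "m1"
    res_a = _results([("m1", "ITG", "group", 0.0, 0.1, 0.99, "BLSA", 18)])
    res_b = _results([("m1", "ITG", "group", -0.3, 0.1, 0.01, "ROS", 18)])
    primary, secondary = convergence_pool(res_a, res_b, table, "group")
    assert set(primary["metabolite"]) == {"m1"}
    assert secondary.empty


# ---------------------------------------------------------------------------
# Cluster-wise FDR
# ---------------------------------------------------------------------------

def test_cluster_bh_worked_example():
    results = _results([
        (f"m{i}", "ITG", "group", -0.1, 0.1, p, "BLSA", 18)
        for i, p in enumerate([0.01, 0.02, 0.03, 0.04])
    ])
    adjusted = cluster_fdr(results, {f"m{i}": "clusterA" for i in range(4)})
    np.testing.assert_allclose(adjusted["q"], [0.04] * 4, rtol=1e-12)


def test_singleton_cluster_keeps_raw_p():
    results = _results([("m1", "ITG", "group", -0.1, 0.1, 0.03, "BLSA", 18)])
    adjusted = cluster_fdr(results, {"m1": "clusterA"})
    assert adjusted["q"].iloc[0] == pytest.approx(0.03)


def test_clusters_adjusted_independently():
    rows = [("a1", "ITG", "group", 0.1, 0.1, 0.02, "BLSA", 18),
            ("a2", "ITG", "group", 0.1, 0.1, 0.80, "BLSA", 18),
            ("b1", "ITG", "group", 0.1, 0.1, 0.04, "BLSA", 18)]
    cmap = {"a1": "A", "a2": "A", "b1": "B"}
    q_b = cluster_fdr(_results(rows), cmap)
    rows[1] = ("a2", "ITG", "group", 0.1, 0.1, 0.001, "BLSA", 18)
    q_b2 = cluster_fdr(_results(rows), cmap)
    val1 = q_b.loc[q_b["metabolite"] == "b1", "q"].iloc[0]
    val2 = q_b2.loc[q_b2["metabolite"] == "b1", "q"].iloc[0]
    assert val1 == pytest.approx(val2)


def test_unassigned_metabolite_rejected():
    results = _results([("mX", "ITG", "group", -0.1, 0.1, 0.03, "BLSA", 18)])
    with pytest.raises(ValueError, match="without a cluster"):
        cluster_fdr(results, {"other": "A"})


# ---------------------------------------------------------------------------
# Full arm
# ---------------------------------------------------------------------------

def test_full_pipeline_scopes_and_subject_counts():
    spec = MetabolomicsSpec(n_subjects_per_group=8, lod_quantile=0.05,
                            missing_fraction=0.05)
    table, _ = simulate_metabolomics(spec, seed=2)
    results = run_metabolite_pipeline(table, DEFAULT_CLUSTER_MAP,
                                      predictors=("group",))
    assert {"metabolite", "cluster", "region", "beta", "p", "scope",
            "significant"} <= set(results.columns)
    pooled = results[results["scope"] == "pooled"]
    assert not pooled.empty
    # pooled analyses span both cohorts: more subjects than either cohort
    per_cohort = table.groupby("cohort")["subject"].nunique()
    assert pooled["p"].between(0, 1).all()
    assert per_cohort.sum() > per_cohort.max()
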