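"""Study-condition validation runs: oracle agreement, power, calibration.

These routines recompute the package's headline property checks from
scratch under fixed study conditions: MILP-vs-enumeration agreement on
random toy networks, mass-balance feasibility of returned solutions,
planted-activity power and null false-flag calibration of the full
expression -> iMAT -> Fisher pipeline, exhaustive verification of the
Fisher exact p-value, and parameter recovery / CI coverage / type-I error
of the metabolomics arm.  Both the acceptance script and the acceptance
test suite call into this module so the measured quantities are identical.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from .activity_stats import compare_groups, fisher_p
from .expression import ExpressionMatrix
from .imat_core import (
    ReactionStateSet,
    call_activity,
    enumerate_optimum,
    predict_activity,
    solve_imat,
)
from .metabolite_pipeline import fit_models, impute_lod
from .model_io import MetabolicModel, apply_media_constraints
from .synthetic_data import (
    ExpressionSpec,
    MetabolomicsSpec,
    NetworkSpec,
    make_toy_network,
    simulate_expression,
    simulate_metabolomics,
)

FORCED_MEDIA_BOUNDS = (0.01, 0.01, 0.0001)


def _random_instance(seed: int,
                     max_states: int = 6) -> tuple[MetabolicModel, ReactionStateSet]:
    """Random toy network (<= 12 reactions) with random high/low states."""
    rng = np.random.default_rng(seed)
    spec = NetworkSpec(
        n_linear_reactions=int(rng.integers(3, 7)),
        n_branches=int(rng.integers(0, 3)),
        fraction_with_and_gprs=0.3,
        include_media_reactions=bool(rng.random() < 0.5),
    )
    model, _ = make_toy_network(spec, seed=seed)
    rxn_ids = list(model.reaction_ids)
    k = min(len(rxn_ids), int(rng.integers(1, max_states + 1)))
    chosen = rng.choice(rxn_ids, size=k, replace=False)
    split = rng.random(k) < 0.5
    states = ReactionStateSet(
        f"seed{seed}",
        frozenset(np.array(chosen)[split].tolist()),
        frozenset(np.array(chosen)[~split].tolist()),
    )
    return model, states


def oracle_agreement(n_instances: int = 200, seed: int = 0) -> dict:
    """Fraction of random instances where MILP objective == oracle optimum."""
    agree = 0
    for i in range(n_instances):
        model, states = _random_instance(seed * 100_003 + i)
        milp_obj = solve_imat(model, states, epsilon=1.0).objective
        oracle_obj = enumerate_optimum(model, states, epsilon=1.0)
        agree += int(milp_obj == oracle_obj)
    return {"agree_fraction": agree / n_instances, "n": n_instances}


def feasibility_suite(n_instances: int = 50, seed: int = 0) -> dict:
    """Mass-balance residuals, bound violations, media-bound honoring.

    Applies the forced-rate media constraints (glucose-like and oxygen-like
    uptakes at 0.01, macromolecule-synthesis sink at 0.0001) where the
    generated network designates them.
    """
    max_residual = 0.0
    bound_violations = 0
    media_honored = 0
    media_checked = 0
    for i in range(n_instances):
        rng = np.random.default_rng(seed * 999_983 + i)
        model, notes = make_toy_network(
            NetworkSpec(n_linear_reactions=int(rng.integers(5, 8)),
                        n_branches=int(rng.integers(0, 3))),
            seed=seed * 999_983 + i)
        media = [(rid, bound) for rid, bound in notes["media_constraints"]]
        constrained = apply_media_constraints(model, media)
        rxn_ids = list(constrained.reaction_ids)
        k = min(len(rxn_ids), 5)
        chosen = rng.choice(rxn_ids, size=k, replace=False)
        split = rng.random(k) < 0.5
        states = ReactionStateSet(
            "s", frozenset(np.array(chosen)[split].tolist()),
            frozenset(np.array(chosen)[~split].tolist()))
        sol = solve_imat(constrained, states, epsilon=1.0)
        residual = {m.id: 0.0 for m in constrained.metabolites}
        for rxn in constrained.reactions:
            for met, coef in rxn.stoichiometry.items():
                residual[met] += coef * sol.flux[rxn.id]
        max_residual = max(max_residual,
                           max(abs(v) for v in residual.values()))
        for rxn in constrained.reactions:
            v = sol.flux[rxn.id]
            if not (rxn.lower_bound - 1e-9 <= v <= rxn.upper_bound + 1e-9):
                bound_violations += 1
        for rid, bound in media:
            media_checked += 1
            media_honored += int(sol.flux[rid] >= bound - 1e-9)
    return {
        "max_mass_balance_residual": max_residual,
        "bound_violations": bound_violations,
        "media_honored_fraction": media_honored / media_checked,
        "n": n_instances,
    }


def _power_instance(seed: int):
    """Branched toy network with the parallel-route reaction's genes planted.

    The backbone is media-forced, so knocking the planted reaction's genes
    from high (control group) to low (case group) reroutes flux through the
    parallel branch: the planted reaction's activity difference is forced by
    mass balance, not solver choice.
    """
    model, notes = make_toy_network(
        NetworkSpec(n_linear_reactions=6, n_branches=1,
                    fraction_with_and_gprs=0.3), seed=seed)
    target = notes["branches"][0]["parallel_to"]
    planted = tuple(notes["gene_map"][target])
    media = [(rid, bound) for rid, bound in notes["media_constraints"]]
    return model, planted, media


def pipeline_power(n_seeds: int = 50, n_per_group: int = 20,
                   delta: float = -4.0, seed: int = 0) -> dict:
    """Recovery rate of truly differential reactions at Fisher p < 0.05."""
    hits = 0
    total = 0
    for rep in range(n_seeds):
        inst_seed = seed * 499_979 + rep
        model, planted, media = _power_instance(inst_seed)
        spec = ExpressionSpec(n_samples_per_group=n_per_group,
                              planted_genes=planted, delta=delta)
        matrix, metadata, truth = simulate_expression(model, spec,
                                                      seed=inst_seed)
        em = ExpressionMatrix(values=matrix, metadata=metadata)
        activity = predict_activity(model, em, epsilon=1.0,
                                    media_constraints=media)
        labels = metadata["group"].to_dict()
        result = compare_groups(activity, labels, groups=("AD", "CN"))
        flagged = set(result.loc[result["p"] < 0.05, "reaction"])
        for rid in truth["differential_reactions"]:
            total += 1
            hits += int(rid in flagged)
    return {"power": hits / total if total else float("nan"),
            "n_differential": total, "n_seeds": n_seeds}


def pipeline_false_flags(n_seeds: int = 50, n_per_group: int = 20,
                         seed: int = 0) -> dict:
    """Fraction of reactions flagged at p < 0.05 when delta = 0."""
    flags = 0
    total = 0
    for rep in range(n_seeds):
        inst_seed = seed * 899_981 + rep
        model, _, media = _power_instance(inst_seed)
        spec = ExpressionSpec(n_samples_per_group=n_per_group, delta=0.0)
        matrix, metadata, _ = simulate_expression(model, spec, seed=inst_seed)
        em = ExpressionMatrix(values=matrix, metadata=metadata)
        activity = predict_activity(model, em, epsilon=1.0,
                                    media_constraints=media)
        labels = metadata["group"].to_dict()
        result = compare_groups(activity, labels, groups=("AD", "CN"))
        flags += int((result["p"] < 0.05).sum())
        total += len(result)
    return {"false_flag_fraction": flags / total, "n_reactions": total}


def fisher_enumeration_check(max_total: int = 40) -> dict:
    """Compare fisher_p with hypergeometric enumeration on all 2x2 tables.

    Covers every table with positive margins and total count <= max_total up
    to the row-swap/column-swap symmetries of the test (each equivalence
    class is evaluated once through its canonical representative with
    row-1 and column-1 margins at most half the total; the symmetries
    themselves are verified separately).  Returns the worst absolute
    p-value discrepancy and the number of canonical tables checked.
    """
    max_diff = 0.0
    n_tables = 0
    pmf_cache: dict[tuple[int, int, int], np.ndarray] = {}
    for total in range(4, max_total + 1):
        for row1 in range(1, total // 2 + 1):
            for col1 in range(row1, total // 2 + 1):
                key = (total, row1, col1)
                lo = max(0, col1 - (total - row1))
                hi = min(row1, col1)
                if key not in pmf_cache:
                    rv = stats.hypergeom(total, row1, col1)
                    pmf_cache[key] = rv.pmf(np.arange(lo, hi + 1))
                pmf = pmf_cache[key]
                for a in range(lo, hi + 1):
                    b = row1 - a
                    c = col1 - a
                    d = total - row1 - c
                    if d < 0:
                        continue
                    oracle = float(pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum())
                    got = fisher_p(a, b, c, d)
                    max_diff = max(max_diff, abs(got - min(oracle, 1.0)))
                    n_tables += 1
    return {"max_abs_p_difference": max_diff, "n_tables": n_tables}


def metabolite_recovery(n_reps: int = 200, n_subjects_per_group: int = 17,
                        planted_beta: float = -0.278, seed: int = 0) -> dict:
    """Bias and 95% CI coverage for a planted region-specific effect.

    ~3 x n_subjects_per_group subjects per cohort (about 50 with the
    default), two cohorts pooled with a cohort fixed effect; the planted
    effect mirrors a realistic log2-scale sterol decline.  A second, null
    metabolite in the same fits supplies the type-I error estimate.
    """
    betas = {"planted": {"ITG": planted_beta, "MFG": -0.1}, "null_met": {}}
    estimates = []
    covered = 0
    null_p: list[float] = []
    for rep in range(n_reps):
        spec = MetabolomicsSpec(n_subjects_per_group=n_subjects_per_group,
                                betas=betas, rho=0.5, sigma=0.4)
        table, _ = simulate_metabolomics(spec, seed=seed * 299_993 + rep)
        res = fit_models(impute_lod(table), "group", scope="pooled")
        row = res[(res["metabolite"] == "planted") & (res["region"] == "ITG")]
        beta_hat = float(row["beta"].iloc[0])
        se = float(row["se"].iloc[0])
        estimates.append(beta_hat)
        covered += int(beta_hat - 1.96 * se <= planted_beta
                       <= beta_hat + 1.96 * se)
        null_rows = res[res["metabolite"] == "null_met"]
        null_p.extend(null_rows["p"].tolist())
    return {
        "bias": float(np.mean(estimates) - planted_beta),
        "coverage": covered / n_reps,
        "type_i_error": float(np.mean(np.asarray(null_p) < 0.05)),
        "mean_beta_hat": float(np.mean(estimates)),
        "planted_beta": planted_beta,
        "n_reps": n_reps,
        "n_null_tests": len(null_p),
    }


def lod_and_missingness_edge_cases() -> dict:
    """Constructed edge cases for the QC threshold and LOD/2 imputation."""
    import pandas as pd

    from .metabolite_pipeline import qc_filter

    def table(n_missing: int) -> pd.DataFrame:
        rows = []
        for i in range(100):
            rows.append({
                "subject": f"S{i}", "cohort": "BLSA", "region": "ITG",
                "metabolite": "edge",
                "concentration": np.nan if i < n_missing else 2.0,
                "below_lod": False, "lod": 0.8, "missing": i < n_missing,
                "group": "CN" if i % 2 else "AD", "sex": "F", "age": 85.0,
            })
        return pd.DataFrame(rows)

    kept_31, _ = qc_filter(table(31))
    kept_30, _ = qc_filter(table(30))
    censored = table(0)
    censored.loc[0, ["below_lod", "concentration"]] = [True, np.nan]
    imputed = impute_lod(censored)
    return {
        "dropped_at_31_percent": "edge" not in set(kept_31["metabolite"]),
        "kept_at_30_percent": "edge" in set(kept_30["metabolite"]),
        "lod_over_imputed_value": float(
            censored.loc[0, "lod"] / imputed.loc[0, "concentration"]),
    }
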