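"""Targeted-metabolomics cohort statistics.

Implements the analysis chain for two-cohort, two-region brain metabolite
concentrations: missingness-based metabolite exclusion (>30% missing),
imputation of left-censored values at LOD/2, log2 transformation,
repeated-measures linear models per metabolite (region-specific coefficients
for an ordinal disease score or a continuous pathology score, sex and age as
covariates, unstructured within-subject covariance over the two regions,
Huber-White robust variance clustered on subject), cross-cohort convergence
pooling (associations with the same sign in both cohorts are refit on the
combined data and reported at raw p < 0.05; divergent associations stay
cohort-specific), and Benjamini-Hochberg FDR applied within each a priori
biochemical pathway cluster for the cohort-specific results.

Model fits go through statsmodels GEE, whose default covariance estimator is
exactly the clustered (sandwich) robust variance; the working within-subject
covariance over the two regions is unstructured (one correlation plus
region-specific variances).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .expression import bh_adjust

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "subject", "cohort", "region", "metabolite", "concentration",
    "below_lod", "lod", "missing", "group", "sex", "age",
)
GROUP_SCORES: Mapping[str, float] = {"CN": 0.0, "ASY": 1.0, "AD": 2.0}
PREDICTOR_COLUMNS = {"group": "group", "cerad": "cerad", "braak": "braak"}


def validate_table(table: pd.DataFrame) -> None:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"metabolite table missing columns: {missing_cols}")
    if table.empty:
        raise ValueError("metabolite table is empty")
    present = table["concentration"].notna()
    if (table.loc[present, "concentration"] <= 0).any():
        raise ValueError("concentrations must be positive where present")
    dupes = table.duplicated(subset=["subject", "region", "metabolite"])
    if dupes.any():
        raise ValueError("duplicate subject x region x metabolite records")


def load_metabolite_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("below_lod", "missing"):
        if col in table.columns and table[col].dtype == object:
            table[col] = table[col].astype(str).str.lower().isin(
                ("true", "1", "yes"))
    validate_table(table)
    return table


def load_cluster_map(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["metabolite"], frame["cluster"]))


# ---------------------------------------------------------------------------
# QC and imputation
# ---------------------------------------------------------------------------

def qc_filter(table: pd.DataFrame, max_missing_fraction: float = 0.30,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop metabolites with too many absent values; keep an exclusion log.

    A record counts as absent when its concentration is not recorded —
    below-LOD censoring included, since left-censored values are the
    dominant source of missingness in targeted panels.  The fraction is
    computed per metabolite within each cohort x region cell; a metabolite
    exceeding the threshold in any cell is excluded from all analyses.
    Metabolites at exactly the threshold are retained.
    """
    validate_table(table)
    absent = table["concentration"].isna()
    frac = (
        table.assign(absent=absent)
        .groupby(["metabolite", "cohort", "region"])["absent"]
        .mean()
        .rename("missing_fraction")
        .reset_index()
    )
    over = frac[frac["missing_fraction"] > max_missing_fraction]
    excluded = sorted(over["metabolite"].unique())
    if excluded:
        logger.info("excluding metabolites over %.0f%% missingness: %s",
                    100 * max_missing_fraction, excluded)
    kept = table[~table["metabolite"].isin(excluded)].copy()
    log = frac.assign(excluded=frac["metabolite"].isin(excluded))
    return kept, log


def impute_lod(table: pd.DataFrame) -> pd.DataFrame:
    """Fill left-censored (below-LOD) concentrations with LOD / 2."""
    out = table.copy()
    below = out["below_lod"].fillna(False).astype(bool)
    bad = below & (out["lod"].isna() | (out["lod"] <= 0))
    if bad.any():
        rows = out.loc[bad, ["subject", "region", "metabolite"]]
        raise ValueError(
            f"below-LOD records without a positive LOD value:\n{rows}")
    out.loc[below, "concentration"] = out.loc[below, "lod"] / 2.0
    return out


# ---------------------------------------------------------------------------
# Repeated-measures models
# ---------------------------------------------------------------------------

def _prepare_fit_frame(table: pd.DataFrame, predictor: str) -> pd.DataFrame:
    col = PREDICTOR_COLUMNS.get(predictor)
    if col is None:
        raise ValueError(f"predictor must be one of {list(PREDICTOR_COLUMNS)}")
    if predictor != "group" and col not in table.columns:
        raise ValueError(f"column {col!r} required for predictor {predictor!r}")
    df = table.dropna(subset=["concentration"]).copy()
    if (df["concentration"] <= 0).any():
        raise ValueError("log2 undefined: non-positive concentration present")
    df["log2c"] = np.log2(df["concentration"].astype(float))
    if predictor == "group":
        unknown = set(df["group"].unique()) - set(GROUP_SCORES)
        if unknown:
            raise ValueError(f"unknown disease groups: {sorted(unknown)}")
        df["score"] = df["group"].map(GROUP_SCORES)
    else:
        df["score"] = df[col].astype(float)
    df["sex_num"] = (df["sex"].astype(str) == "F").astype(float)
    df["age_c"] = df["age"].astype(float) - df["age"].astype(float).mean()
    return df


def _fit_one_metabolite(df: pd.DataFrame, regions: Sequence[str],
                        include_cohort: bool) -> dict[str, tuple[float, float, float]]:
    """GEE fit for one metabolite; returns region -> (beta, robust SE, p)."""
    if df["score"].nunique() < 2:
        raise ValueError("predictor has a single level in this stratum")
    df = df.sort_values(["subject", "region"]).reset_index(drop=True)
    region_idx = df["region"].map({r: i for i, r in enumerate(regions)})
    formula = "log2c ~ C(region) + C(region):score + sex_num + age_c"
    if include_cohort and df["cohort"].nunique() > 1:
        formula += " + C(cohort)"
    cov = sm.cov_struct.Unstructured()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GEE.from_formula(
                formula, groups="subject", data=df,
                time=region_idx.to_numpy(dtype=int), cov_struct=cov)
            # sandwich variance with the Mancl-DeRouen small-sample bias
            # correction: the plain sandwich is biased down at <~100 clusters
            fit = model.fit(maxiter=200, cov_type="bias_reduced")
        except Exception:
            # fall back to exchangeable working correlation
            model = sm.GEE.from_formula(
                formula, groups="subject", data=df,
                cov_struct=sm.cov_struct.Exchangeable())
            fit = model.fit(maxiter=200, cov_type="bias_reduced")
    out: dict[str, tuple[float, float, float]] = {}
    for region in regions:
        name = f"C(region)[{region}]:score"
        if name not in fit.params.index:
            continue
        beta = float(fit.params[name])
        se = float(fit.bse[name])
        p = float(fit.pvalues[name])
        out[region] = (beta, se, p)
    return out


def fit_models(
    table: pd.DataFrame,
    predictor: str = "group",
    scope: str = "pooled",
) -> pd.DataFrame:
    """Repeated-measures fits per metabolite with robust (sandwich) errors.

    ``scope`` is ``"pooled"`` (all cohorts, cohort fixed effect) or a single
    cohort name.  The outcome is log2 concentration; the predictor enters
    with region-specific coefficients (one beta per region); sex and
    mean-centered age are covariates; the working within-subject covariance
    over regions is unstructured and standard errors are clustered on
    subject.  Returns one row per metabolite x region.
    """
    validate_table(table)
    if scope == "pooled":
        data = table
        include_cohort = True
    else:
        if scope not in set(table["cohort"]):
            raise ValueError(f"unknown cohort scope {scope!r}")
        data = table[table["cohort"] == scope]
        include_cohort = False
    df = _prepare_fit_frame(data, predictor)
    regions = sorted(df["region"].unique())
    rows = []
    for met, sub in df.groupby("metabolite", sort=True):
        try:
            per_region = _fit_one_metabolite(sub, regions, include_cohort)
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - solver pathologies
            logger.warning("fit failed for %s (%s): %s", met, scope, exc)
            continue
        for region, (beta, se, p) in per_region.items():
            rows.append({
                "metabolite": met, "region": region, "predictor": predictor,
                "beta": beta, "se": se, "p": p, "scope": scope,
                "n_subjects": sub["subject"].nunique(),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Convergence pooling and cluster-wise FDR
# ---------------------------------------------------------------------------

def convergence_pool(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    combined_table: pd.DataFrame,
    predictor: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool cross-cohort convergent associations; keep divergent ones apart.

    For each metabolite x region: if the cohort-specific coefficients share
    a sign (zero counts as concordant with either sign), the association is
    refit on the combined data with a cohort fixed effect and reported as a
    primary (pooled, raw-p) result; otherwise the cohort-specific rows are
    routed to the secondary set for cluster-wise FDR.  Metabolites present
    in only one cohort go to the secondary set with a flag.
    """
    key = ["metabolite", "region"]
    a = results_a.set_index(key)
    b = results_b.set_index(key)
    shared = a.index.intersection(b.index)
    concordant = [
        idx for idx in shared
        if a.loc[idx, "beta"] * b.loc[idx, "beta"] >= 0.0
    ]
    pooled_all = fit_models(combined_table, predictor=predictor,
                            scope="pooled")
    pooled_all = pooled_all.set_index(key)
    primary = pooled_all.loc[
        [idx for idx in concordant if idx in pooled_all.index]
    ].reset_index()
    primary["convergent"] = True

    secondary_rows = []
    divergent = [idx for idx in shared if idx not in set(concordant)]
    for source in (a, b):
        for idx in divergent:
            row = source.loc[idx].to_dict()
            row.update({"metabolite": idx[0], "region": idx[1],
                        "single_cohort": False})
            secondary_rows.append(row)
        only = [idx for idx in source.index if idx not in shared]
        for idx in only:
            row = source.loc[idx].to_dict()
            row.update({"metabolite": idx[0], "region": idx[1],
                        "single_cohort": True})
            secondary_rows.append(row)
    secondary = pd.DataFrame(secondary_rows)
    return primary, secondary


def cluster_fdr(results: pd.DataFrame,
                cluster_map: Mapping[str, str],
                alpha: float = 0.05) -> pd.DataFrame:
    """BH adjustment within each a priori pathway cluster.

    Adjustment families are cluster x region x predictor x scope, so the
    correction spans exactly the metabolite comparisons within one cluster
    for one contrast.  Every metabolite must be assigned to a cluster.
    """
    if results.empty:
        out = results.copy()
        out["cluster"] = pd.Series(dtype=str)
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    unassigned = sorted(set(results["metabolite"]) - set(cluster_map))
    if unassigned:
        raise ValueError(f"metabolites without a cluster: {unassigned}")
    out = results.copy()
    out["cluster"] = out["metabolite"].map(cluster_map)
    out["q"] = np.nan
    family_cols = [c for c in ("cluster", "region", "predictor", "scope")
                   if c in out.columns]
    for _, idx in out.groupby(family_cols).groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


# ---------------------------------------------------------------------------
# Full metabolite arm
# ---------------------------------------------------------------------------

def run_metabolite_pipeline(
    table: pd.DataFrame,
    cluster_map: Mapping[str, str],
    predictors: Sequence[str] = ("group",),
    cohorts: Sequence[str] | None = None,
    max_missing_fraction: float = 0.30,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """QC -> LOD/2 imputation -> per-cohort fits -> pooling -> cluster FDR.

    Returns one table with primary (pooled, raw p at ``alpha``) and
    secondary (cohort-specific, cluster-FDR-adjusted) rows distinguished by
    the ``scope`` column.
    """
    kept, _ = qc_filter(table, max_missing_fraction)
    imputed = impute_lod(kept)
    if cohorts is None:
        cohorts = sorted(imputed["cohort"].unique())
    if len(cohorts) != 2:
        raise ValueError("convergence pooling needs exactly two cohorts")
    blocks = []
    for predictor in predictors:
        res_a = fit_models(imputed, predictor, scope=cohorts[0])
        res_b = fit_models(imputed, predictor, scope=cohorts[1])
        primary, secondary = convergence_pool(res_a, res_b, imputed, predictor)
        primary["cluster"] = primary["metabolite"].map(dict(cluster_map))
        primary["q"] = np.nan
        primary["significant"] = primary["p"] < alpha
        if not secondary.empty:
            secondary = cluster_fdr(secondary, cluster_map, alpha)
        blocks.append(primary)
        if not secondary.empty:
            blocks.append(secondary)
    columns = ["metabolite", "cluster", "region", "predictor", "beta", "se",
               "p", "q", "scope", "significant"]
    result = pd.concat(blocks, ignore_index=True, sort=False)
    for col in columns:
        if col not in result.columns:
            result[col] = np.nan
    return result[columns].sort_values(
        ["predictor", "metabolite", "region", "scope"]).reset_index(drop=True)


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    out = results.copy()
    for col in ("beta", "se"):
        out[col] = out[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
    for col in ("p", "q"):
        out[col] = out[col].map(lambda v: f"{v:.4g}" if pd.notna(v) else "")
    out.to_csv(path, sep="\t", index=False)
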