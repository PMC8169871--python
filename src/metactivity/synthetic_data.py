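"""Synthetic inputs for every pipeline stage.

Three generators cover the pipeline's inputs so all stages are testable
without any external download:

* :func:`make_toy_network` — small mass-balanced stoichiometric networks with
  GPR rules, a forced uptake, optional parallel branches (alternative routes)
  and designated uptake/sink reactions so media-style lower-bound constraints
  (0.01 / 0.01 / 0.0001) are applicable;
* :func:`simulate_expression` — log-scale expression matrices with planted
  high/low genes that drive reaction-activity differences between two groups;
* :func:`simulate_metabolomics` — two-cohort, two-region repeated-measures
  metabolite concentration tables with group effects linear in an ordinal
  disease score, within-subject correlation, left-censoring at a limit of
  detection (LOD) and additional missingness at random.

Each generator is deterministic under a fixed seed and serializes its planted
truth alongside the data, so downstream recovery checks never need to peek at
generator internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import (
    GprExpression,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
)

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Layout of a random toy network.

    ``n_linear_reactions`` counts the backbone including its uptake and
    secretion exchanges (minimum 3: uptake, one conversion, secretion).
    Each branch adds a two-reaction parallel route around one backbone
    conversion, giving the network alternative mass-balanced paths.
    """

    n_linear_reactions: int = 6
    n_branches: int = 1
    fraction_with_and_gprs: float = 0.3
    bounds: tuple[float, float] = (0.0, 10.0)
    include_media_reactions: bool | None = None  # None: auto (n >= 5)


@dataclass(frozen=True)
class ExpressionSpec:
    """Planted-difference expression simulation.

    Per-gene baselines are N(baseline_mean, baseline_sd), shared across
    samples; planted genes start at ``planted_baseline`` (default: 2 SD above
    the baseline mean, i.e. clearly highly expressed) and are shifted by
    ``delta`` in the second group; i.i.d. N(0, noise_sd) noise is added to
    every value.
    """

    n_samples_per_group: int = 20
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    planted_genes: tuple[str, ...] = ()
    delta: float = 0.0
    noise_sd: float = 0.3
    planted_baseline: float | None = None
    groups: tuple[str, str] = ("CN", "AD")


@dataclass(frozen=True)
class MetabolomicsSpec:
    """Two-cohort, two-region repeated-measures metabolomics simulation.

    ``betas`` maps metabolite -> region -> effect per unit of the ordinal
    disease score (CN=0, ASY=1, AD=2) on the log2 concentration scale.
    ``rho`` is the within-subject correlation of the two regional
    measurements; ``sigma`` the residual SD on the log2 scale.  Values below
    the per-metabolite LOD (the ``lod_quantile`` of generated concentrations)
    are left-censored; an extra ``missing_fraction`` is removed at random.
    """

    n_subjects_per_group: int = 15
    betas: dict = field(default_factory=dict)
    baseline_log2: float = 3.0
    rho: float = 0.5
    sigma: float = 0.4
    lod_quantile: float = 0.0
    missing_fraction: float = 0.0
    cohorts: tuple[str, ...] = ("BLSA", "ROS")
    regions: tuple[str, str] = ("ITG", "MFG")
    groups: tuple[str, ...] = ("CN", "ASY", "AD")


# Effect sizes of the default simulation profile are in the |beta| ~ 0.1-0.3
# range typical of log2-scale brain oxysterol differences, so the default
# power characteristics are realistic rather than optimistic.
DEFAULT_BETAS: dict[str, dict[str, float]] = {
    "lanosterol": {"ITG": -0.09, "MFG": -0.278},
    "24S-hydroxycholesterol": {"ITG": -0.113, "MFG": -0.05},
    "7-ketocholesterol": {"ITG": 0.304, "MFG": 0.1},
    "7beta-hydroxycholesterol": {"ITG": 0.237, "MFG": 0.08},
    "cholesterol": {},
    "desmosterol": {},
    "27-hydroxycholesterol": {},
    "7alpha-hydroxycholesterol": {"ITG": 0.154},
    "5a6a-epoxycholesterol": {"ITG": 0.199},
}

# Three a priori biochemical pathway clusters used by the cluster-wise FDR.
DEFAULT_CLUSTER_MAP: dict[str, str] = {
    "cholesterol": "biosynthesis",
    "lanosterol": "biosynthesis",
    "desmosterol": "biosynthesis",
    "24S-hydroxycholesterol": "catabolism-enzymatic",
    "27-hydroxycholesterol": "catabolism-enzymatic",
    "7alpha-hydroxycholesterol": "catabolism-enzymatic",
    "7-ketocholesterol": "catabolism-non-enzymatic",
    "7beta-hydroxycholesterol": "catabolism-non-enzymatic",
    "5a6a-epoxycholesterol": "catabolism-non-enzymatic",
}

GROUP_SCORES: dict[str, float] = {"CN": 0.0, "ASY": 1.0, "AD": 2.0}


# ---------------------------------------------------------------------------
# Toy networks
# ---------------------------------------------------------------------------

def make_toy_network(
    spec: NetworkSpec, seed: int = 0
) -> tuple[MetabolicModel, dict]:
    """Generate a connected, mass-balanced toy network with GPRs.

    Returns the model and a ground-truth annotation dict: backbone reaction
    ids, branch route pairs (each parallel to one backbone conversion), the
    designated uptake/auxiliary-uptake/sink ids, and the genes attached to
    each reaction.  Zero flux is always feasible before media constraints.
    """
    n = spec.n_linear_reactions
    if n < 3:
        raise ValueError("n_linear_reactions must be >= 3")
    if spec.n_branches < 0:
        raise ValueError("n_branches must be >= 0")
    n_internal = n - 2  # backbone conversions between uptake and secretion
    if spec.n_branches > 0 and n_internal < 1:
        raise ValueError("branches require at least one backbone conversion")
    lb, ub = spec.bounds
    if lb > 0:
        raise ValueError("bounds must admit zero flux")
    rng = np.random.default_rng(seed)
    include_media = spec.include_media_reactions
    if include_media is None:
        include_media = n >= 5

    mets = [Metabolite(f"M{i}", compartment="c") for i in range(1, n_internal + 2)]
    reactions: list[Reaction] = []
    genes: list[str] = []
    gene_map: dict[str, list[str]] = {}

    def make_gpr(rxn_id: str) -> GprExpression | None:
        u = rng.random()
        g1 = f"g_{rxn_id}_1"
        if u < spec.fraction_with_and_gprs:
            g2 = f"g_{rxn_id}_2"
            genes.extend([g1, g2])
            gene_map[rxn_id] = [g1, g2]
            return parse_gpr(f"{g1} and {g2}")
        if u < spec.fraction_with_and_gprs + 0.25:
            g2 = f"g_{rxn_id}_2"
            genes.extend([g1, g2])
            gene_map[rxn_id] = [g1, g2]
            return parse_gpr(f"{g1} or {g2}")
        genes.append(g1)
        gene_map[rxn_id] = [g1]
        return parse_gpr(g1)

    reactions.append(Reaction("EX_in", {"M1": 1.0}, max(lb, 0.0), ub,
                              subsystem="exchange"))
    backbone = ["EX_in"]
    for i in range(1, n_internal + 1):
        rid = f"R{i}"
        reactions.append(Reaction(
            rid, {f"M{i}": -1.0, f"M{i+1}": 1.0}, max(lb, 0.0), ub,
            gpr=make_gpr(rid), subsystem="backbone"))
        backbone.append(rid)
    reactions.append(Reaction(
        "EX_out", {f"M{n_internal+1}": -1.0}, max(lb, 0.0), ub,
        subsystem="exchange"))
    backbone.append("EX_out")

    branches: list[dict] = []
    for b in range(spec.n_branches):
        seg = int(rng.integers(1, n_internal + 1))
        xid = f"X{b+1}"
        mets.append(Metabolite(xid, compartment="c"))
        r1, r2 = f"B{b+1}a", f"B{b+1}b"
        reactions.append(Reaction(
            r1, {f"M{seg}": -1.0, xid: 1.0}, max(lb, 0.0), ub,
            gpr=make_gpr(r1), subsystem="branch"))
        reactions.append(Reaction(
            r2, {xid: -1.0, f"M{seg+1}": 1.0}, max(lb, 0.0), ub,
            gpr=make_gpr(r2), subsystem="branch"))
        branches.append({"parallel_to": f"R{seg}", "route": [r1, r2]})

    annotations: dict = {
        "backbone": backbone,
        "branches": branches,
        "gene_map": gene_map,
        "uptake": "EX_in",
        "aux_uptake": None,
        "sink": "EX_out",
    }
    if include_media:
        # auxiliary (oxygen-like) uptake feeding a macromolecule-synthesis
        # sink that also drains the last internal metabolite; no single
        # backbone conversion is pinned by the auxiliary supply, so parallel
        # routes stay substitutable under forced media bounds
        mets.append(Metabolite("AUX", compartment="c"))
        reactions.append(Reaction("EX_aux", {"AUX": 1.0}, max(lb, 0.0), ub,
                                  subsystem="exchange"))
        reactions.append(Reaction(
            "DM_macro", {f"M{n_internal+1}": -1.0, "AUX": -1.0},
            max(lb, 0.0), ub, subsystem="sink"))
        annotations["aux_uptake"] = "EX_aux"
        annotations["macro_sink"] = "DM_macro"
        annotations["media_constraints"] = [
            ["EX_in", 0.01], ["EX_aux", 0.01], ["DM_macro", 0.0001]]

    model = MetabolicModel(
        metabolites=tuple(mets), reactions=tuple(reactions),
        genes=tuple(dict.fromkeys(genes)),
        name=f"toy_network_seed{seed}", version="1")
    model.validate()
    return model, annotations


def mini_cholesterol_fixture() -> MetabolicModel:
    """Fixed 12-reaction / 11-metabolite toy cholesterol pathway model.

    Traces acetyl-CoA through HMG-CoA and mevalonate to lanosterol, then
    through the two parallel post-squalene routes (Bloch via desmosterol,
    Kandutsch-Russell via 7-dehydrocholesterol) to cholesterol, and on to
    24S-hydroxycholesterol with a lumped bile-acid export sink.  An
    NADPH/NADP+ pair with a regeneration reaction closes the redox balance.
    The SOAT1 esterification step is a deliberate dead end (cholesteryl ester
    has no consumer), so it can never carry steady-state flux — a
    blocked-reaction edge case for the activity pipeline.  Stoichiometry is
    pedagogical (unit coefficients except where noted), not biochemical.
    """
    mets = [
        Metabolite("accoa", "acetyl-CoA", "c"),
        Metabolite("hmgcoa", "HMG-CoA", "c"),
        Metabolite("mva", "(R)-mevalonate", "c"),
        Metabolite("lanosterol", "lanosterol", "r"),
        Metabolite("desmosterol", "desmosterol", "r"),
        Metabolite("dhc7", "7-dehydrocholesterol", "r"),
        Metabolite("chol", "cholesterol", "c"),
        Metabolite("ohc24", "24S-hydroxycholesterol", "c"),
        Metabolite("ce", "cholesteryl ester", "c"),
        Metabolite("nadph", "NADPH", "c"),
        Metabolite("nadp", "NADP+", "c"),
    ]
    lb, ub = 0.0, 1000.0
    pre = "De novo cholesterol biosynthesis (pre-squalene)"
    post = "De novo cholesterol biosynthesis (post-squalene)"
    cat = "Cholesterol catabolism (enzymatic)"
    rxns = [
        Reaction("EX_accoa", {"accoa": 1.0}, lb, ub, subsystem="exchange",
                 name="acetyl-CoA uptake"),
        Reaction("R_HMGSYN", {"accoa": -3.0, "hmgcoa": 1.0}, lb, ub,
                 gpr=parse_gpr("ACAT2 and HMGCS1"), subsystem=pre,
                 name="lumped acetoacetyl-CoA/HMG-CoA synthesis"),
        Reaction("R_HMGCR", {"hmgcoa": -1.0, "nadph": -2.0,
                             "mva": 1.0, "nadp": 2.0}, lb, ub,
                 gpr=parse_gpr("HMGCR"), subsystem=pre,
                 name="HMG-CoA reductase"),
        Reaction("R_PRESQ", {"mva": -1.0, "lanosterol": 1.0}, lb, ub,
                 subsystem=pre, name="lumped mevalonate-to-lanosterol"),
        Reaction("R_BLOCH", {"lanosterol": -1.0, "nadph": -1.0,
                             "desmosterol": 1.0, "nadp": 1.0}, lb, ub,
                 subsystem=post, name="lumped Bloch-route demethylation"),
        Reaction("R_DHCR24", {"desmosterol": -1.0, "nadph": -1.0,
                              "chol": 1.0, "nadp": 1.0}, lb, ub,
                 gpr=parse_gpr("DHCR24"), subsystem=post,
                 name="desmosterol reductase"),
        Reaction("R_KR", {"lanosterol": -1.0, "nadph": -1.0,
                          "dhc7": 1.0, "nadp": 1.0}, lb, ub,
                 gpr=parse_gpr("DHCR24"), subsystem=post,
                 name="lumped Kandutsch-Russell route"),
        Reaction("R_DHCR7", {"dhc7": -1.0, "nadph": -1.0,
                             "chol": 1.0, "nadp": 1.0}, lb, ub,
                 gpr=parse_gpr("DHCR7"), subsystem=post,
                 name="7-dehydrocholesterol reductase"),
        Reaction("R_NADPH", {"nadp": -1.0, "nadph": 1.0}, lb, ub,
                 subsystem="Cofactor regeneration", name="NADPH regeneration"),
        Reaction("R_CYP46A1", {"chol": -1.0, "ohc24": 1.0}, lb, ub,
                 gpr=parse_gpr("CYP46A1"), subsystem=cat,
                 name="cholesterol 24S-hydroxylase"),
        Reaction("R_BILE_SINK", {"ohc24": -1.0}, lb, ub,
                 gpr=parse_gpr("HSD3B7"), subsystem=cat,
                 name="lumped bile-acid export sink"),
        Reaction("R_SOAT1", {"chol": -1.0, "ce": 1.0}, lb, ub,
                 gpr=parse_gpr("SOAT1"), subsystem="Cholesterol esterification",
                 name="cholesterol esterification (dead-end store)"),
    ]
    model = MetabolicModel(
        metabolites=tuple(mets), reactions=tuple(rxns),
        genes=("ACAT2", "HMGCS1", "HMGCR", "DHCR24", "DHCR7",
               "CYP46A1", "HSD3B7", "SOAT1"),
        name="mini_cholesterol", version="1",
        annotations={
            "media_constraints": [
                ["EX_accoa", 0.01], ["R_NADPH", 0.01], ["R_BILE_SINK", 0.0001]],
            "bloch_route": ["R_BLOCH", "R_DHCR24"],
            "kr_route": ["R_KR", "R_DHCR7"],
        })
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    model: MetabolicModel, spec: ExpressionSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a genes-x-samples log-scale expression matrix with metadata.

    Group-2 samples are shifted by ``spec.delta`` on the planted genes.  The
    returned truth dict records the planted genes and, from the noiseless
    group-level values, the expression state (high/low/moderate) each
    GPR-bearing reaction takes in each group plus the reactions whose state
    flips between high and low — the ones whose activity difference is forced
    rather than solver-dependent.
    """
    if spec.delta is None:
        raise ValueError("delta must be set (use 0.0 for a null simulation)")
    missing = set(spec.planted_genes) - set(model.genes)
    if missing:
        raise ValueError(f"planted genes absent from model: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    genes = list(model.genes)
    n_per = spec.n_samples_per_group
    g1, g2 = spec.groups
    samples = [f"{g1}_{i+1}" for i in range(n_per)] + \
              [f"{g2}_{i+1}" for i in range(n_per)]
    groups = [g1] * n_per + [g2] * n_per

    planted_base = (spec.planted_baseline if spec.planted_baseline is not None
                    else spec.baseline_mean + 2.0 * spec.baseline_sd)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    planted_idx = [genes.index(g) for g in spec.planted_genes]
    baseline[planted_idx] = planted_base

    values = np.tile(baseline[:, None], (1, len(samples)))
    for idx in planted_idx:
        values[idx, n_per:] += spec.delta
    values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    matrix.index.name = "gene"

    metadata = pd.DataFrame({
        "sample": samples,
        "group": groups,
        "sex": rng.choice(["F", "M"], size=len(samples)).tolist(),
        "age": np.round(rng.normal(85.0, 8.0, size=len(samples)), 1),
        "batch": [f"b{(i % 2) + 1}" for i in range(len(samples))],
        "region": "CTX",
    }).set_index("sample")

    truth = _expression_truth(model, spec, genes, baseline, planted_idx)
    return matrix, metadata, truth


def _expression_truth(model, spec, genes, baseline, planted_idx) -> dict:
    """Noiseless per-group reaction states implied by the planted shifts."""
    vals1 = dict(zip(genes, baseline))
    shifted = baseline.copy()
    shifted[planted_idx] += spec.delta
    vals2 = dict(zip(genes, shifted))
    pooled = np.concatenate([baseline, shifted])
    q25, q75 = np.quantile(pooled, [0.25, 0.75])

    def state(value: float) -> str:
        if value > q75:
            return "high"
        if value < q25:
            return "low"
        return "moderate"

    states: dict[str, dict[str, str]] = {}
    forced: list[str] = []
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        s1 = state(rxn.gpr.evaluate(vals1))
        s2 = state(rxn.gpr.evaluate(vals2))
        states[rxn.id] = {spec.groups[0]: s1, spec.groups[1]: s2}
        if {s1, s2} == {"high", "low"}:
            forced.append(rxn.id)
    return {
        "planted_genes": list(spec.planted_genes),
        "delta": spec.delta,
        "noiseless_thresholds": [float(q25), float(q75)],
        "reaction_states": states,
        "differential_reactions": forced,
    }


# ---------------------------------------------------------------------------
# Metabolomics simulation
# ---------------------------------------------------------------------------

def simulate_metabolomics(
    spec: MetabolomicsSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-format two-cohort, two-region metabolite table.

    log2 concentration = baseline + region-specific beta * disease score
    + subject effect (within-subject correlation ``rho`` across regions)
    + N(0, sigma) noise.  CERAD (0-3) and Braak (0-6) are ordinal scores with
    group-dependent means ordered AD > ASY > CN.  Censoring below the
    per-metabolite LOD and extra missingness at random are applied last.
    """
    if not (0.0 <= spec.rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    if spec.n_subjects_per_group < 3:
        raise ValueError("need >= 3 subjects per cohort per group")
    rng = np.random.default_rng(seed)
    betas = spec.betas or DEFAULT_BETAS
    metabolites = list(betas)
    tau = spec.sigma * np.sqrt(spec.rho / (1.0 - spec.rho))

    cerad_means = {"CN": 0.3, "ASY": 2.2, "AD": 2.6}
    braak_means = {"CN": 2.8, "ASY": 3.6, "AD": 4.8}

    records = []
    for cohort in spec.cohorts:
        for group in spec.groups:
            for i in range(spec.n_subjects_per_group):
                subj = f"{cohort}_{group}_{i+1}"
                score = GROUP_SCORES[group]
                sex = str(rng.choice(["F", "M"]))
                age = float(np.round(rng.normal(88.0, 7.0), 1))
                cerad = int(np.clip(np.round(
                    rng.normal(cerad_means[group], 0.5)), 0, 3))
                braak = int(np.clip(np.round(
                    rng.normal(braak_means[group], 1.0)), 0, 6))
                u = rng.normal(0.0, tau, size=len(metabolites))
                for m_idx, met in enumerate(metabolites):
                    for region in spec.regions:
                        beta = betas[met].get(region, 0.0)
                        log2c = (spec.baseline_log2 + beta * score +
                                 u[m_idx] + rng.normal(0.0, spec.sigma))
                        records.append({
                            "subject": subj, "cohort": cohort,
                            "region": region, "metabolite": met,
                            "concentration": float(2.0 ** log2c),
                            "group": group, "sex": sex, "age": age,
                            "cerad": cerad, "braak": braak,
                        })
    table = pd.DataFrame.from_records(records)
    table["below_lod"] = False
    table["missing"] = False
    table["lod"] = np.nan

    lods: dict[str, float] = {}
    for met, sub in table.groupby("metabolite"):
        if spec.lod_quantile > 0:
            lod = float(np.quantile(sub["concentration"], spec.lod_quantile))
        else:
            lod = float(sub["concentration"].min()) / 10.0
        lods[met] = lod
        table.loc[table["metabolite"] == met, "lod"] = lod
        if spec.lod_quantile > 0:
            censored = (table["metabolite"] == met) & \
                       (table["concentration"] < lod)
            table.loc[censored, "below_lod"] = True
            table.loc[censored, "concentration"] = np.nan
    if spec.missing_fraction > 0:
        eligible = np.flatnonzero(~table["below_lod"])
        n_miss = int(round(spec.missing_fraction * len(eligible)))
        drop = rng.choice(eligible, size=n_miss, replace=False)
        table.loc[table.index[drop], "missing"] = True
        table.loc[table.index[drop], "concentration"] = np.nan

    truth = {
        "betas": {m: dict(b) for m, b in betas.items()},
        "baseline_log2": spec.baseline_log2,
        "rho": spec.rho,
        "sigma": spec.sigma,
        "group_scores": dict(GROUP_SCORES),
        "lod": lods,
        "spec": asdict(spec) | {"betas": {m: dict(b) for m, b in betas.items()}},
    }
    return table, truth


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_expression_tsv(matrix: pd.DataFrame, metadata: pd.DataFrame,
                         matrix_path: str | Path,
                         metadata_path: str | Path) -> None:
    matrix.to_csv(matrix_path, sep="\t", float_format="%.6f")
    metadata.to_csv(metadata_path, sep="\t")


def write_metabolite_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_cluster_map_tsv(cluster_map: dict[str, str],
                          path: str | Path) -> None:
    pd.DataFrame(
        {"metabolite": list(cluster_map), "cluster": list(cluster_map.values())}
    ).to_csv(path, sep="\t", index=False)
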