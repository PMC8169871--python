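"""iMAT: expression discretization, MILP activity prediction, activity calls.

The integrative metabolic analysis tool (iMAT) reconciles a steady-state flux
distribution with discretized gene expression.  Expression values pooled
across all genes and samples of a dataset define 25th/75th percentile
thresholds; GPR rules map gene values onto reactions (OR -> max over
isoenzymes, AND -> min over complex members); reactions above the 75th
percentile are "highly expressed" (set R_H), below the 25th "lowly
expressed" (R_L), the rest moderate.  A mixed-integer linear program then
maximizes the number of highly-expressed reactions carrying flux at least
epsilon in magnitude plus lowly-expressed reactions carrying zero flux,
subject to mass balance S.v = 0 and the flux bounds:

    maximize   sum_{r in R_H} (y+_r + y-_r) + sum_{r in R_L} y_r
    s.t.       S v = 0,   lb <= v <= ub
               v_r + y+_r (lb_r - eps) >= lb_r          (r in R_H)
               v_r + y-_r (ub_r + eps) <= ub_r          (r in R_H)
               y+_r + y-_r <= 1                         (r in R_H)
               lb_r (1 - y_r) <= v_r <= ub_r (1 - y_r)  (r in R_L)

with per-reaction big-M constants taken from the bounds.  The MILP is solved
by HiGHS (scipy.optimize.milp) to proven optimality; an exhaustive
enumeration oracle over the indicator assignments is provided for
cross-checking on small instances.  Each sample's optimum is converted into
a binary activity call per reaction (|v| above a tolerance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .expression import ExpressionMatrix
from .model_io import MetabolicModel

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1.0
DEFAULT_ACTIVITY_TOL = 1e-6
MASS_BALANCE_TOL = 1e-6
ENUMERATION_CAP = 16


class ImatError(RuntimeError):
    pass


class ImatInfeasibleError(ImatError):
    """The network admits no flux distribution under the applied constraints."""


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    """Pooled 25th/75th percentile expression thresholds."""

    q25: float
    q75: float

    def __post_init__(self) -> None:
        if self.q25 > self.q75:
            raise ValueError("q25 must be <= q75")


def pooled_thresholds(matrix: ExpressionMatrix) -> Thresholds:
    """Empirical 25th/75th percentiles of all gene-x-sample values pooled.

    Linear-interpolation quantiles (numpy default) over the full dataset,
    mirroring a single global discretization per dataset.
    """
    values = matrix.values.to_numpy(dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty expression matrix")
    q25, q75 = np.quantile(values, [0.25, 0.75])
    return Thresholds(float(q25), float(q75))


def per_gene_thresholds(matrix: ExpressionMatrix) -> dict[str, Thresholds]:
    """Per-gene 25th/75th percentiles across samples (alternative mode)."""
    out: dict[str, Thresholds] = {}
    for gene, row in matrix.values.iterrows():
        q25, q75 = np.quantile(row.to_numpy(dtype=float), [0.25, 0.75])
        out[gene] = Thresholds(float(q25), float(q75))
    return out


def reaction_expression(model: MetabolicModel,
                        gene_values: Mapping[str, float]) -> dict[str, float]:
    """Map gene expression onto reactions through GPR rules.

    OR nodes (isoenzymes) take the maximum over children, AND nodes (enzyme
    complexes) the minimum.  Reactions without a GPR, or whose GPR references
    a gene absent from ``gene_values``, are skipped (logged) — they carry no
    gene evidence.
    """
    out: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        try:
            out[rxn.id] = float(rxn.gpr.evaluate(gene_values))
        except KeyError as exc:
            logger.info("reaction %s skipped: gene %s has no expression value",
                        rxn.id, exc)
    return out


@dataclass(frozen=True)
class ReactionStateSet:
    """Per-sample partition of reactions into high / low (rest moderate)."""

    sample_id: str
    high: frozenset[str]
    low: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.high & self.low
        if overlap:
            raise ValueError(f"reactions both high and low: {sorted(overlap)}")


def assign_states(reaction_values: Mapping[str, float],
                  thresholds: Thresholds,
                  sample_id: str = "") -> ReactionStateSet:
    """Strictly-above-q75 -> high, strictly-below-q25 -> low, else moderate.

    Values equal to a threshold, and reactions absent from
    ``reaction_values`` (no GPR / no evidence), are moderate.
    """
    high = frozenset(r for r, v in reaction_values.items() if v > thresholds.q75)
    low = frozenset(r for r, v in reaction_values.items() if v < thresholds.q25)
    return ReactionStateSet(sample_id=sample_id, high=high, low=low)


# ---------------------------------------------------------------------------
# MILP
# ---------------------------------------------------------------------------

@dataclass
class ImatSolution:
    """One optimal iMAT solution for one sample."""

    flux: dict[str, float]
    high_indicators: dict[str, tuple[int, int]]  # reaction -> (y+, y-)
    low_indicators: dict[str, int]
    objective: int
    status: str
    epsilon: float
    sample_id: str = ""


def _stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            S[met_index[met], j] = coef
    return S


def solve_imat(model: MetabolicModel, states: ReactionStateSet,
               epsilon: float = DEFAULT_EPSILON) -> ImatSolution:
    """Solve the iMAT MILP for one sample to proven optimality.

    Raises :class:`ImatInfeasibleError` when the constrained network admits
    no steady-state flux distribution at all (e.g. inconsistent media
    constraints), and :class:`ImatError` on solver failure.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rxn_ids = list(model.reaction_ids)
    unknown = (states.high | states.low) - set(rxn_ids)
    if unknown:
        raise ValueError(f"state set references unknown reactions: {sorted(unknown)}")
    n = len(rxn_ids)
    lbs = np.array([r.lower_bound for r in model.reactions])
    ubs = np.array([r.upper_bound for r in model.reactions])
    if not (np.isfinite(lbs).all() and np.isfinite(ubs).all()):
        raise ValueError("solve_imat requires finite flux bounds")

    high = sorted(states.high)
    low = sorted(states.low)
    idx = {r: j for j, r in enumerate(rxn_ids)}
    n_high, n_low = len(high), len(low)
    n_vars = n + 2 * n_high + n_low

    S = _stoichiometric_matrix(model)
    rows, row_lb, row_ub = [], [], []
    Sfull = np.zeros((S.shape[0], n_vars))
    Sfull[:, :n] = S
    rows.append(Sfull)
    row_lb.extend([0.0] * S.shape[0])
    row_ub.extend([0.0] * S.shape[0])

    extra = np.zeros((3 * n_high + 2 * n_low, n_vars))
    k = 0
    for h, rid in enumerate(high):
        j = idx[rid]
        yp = n + 2 * h
        ym = n + 2 * h + 1
        # v_r + y+ (lb - eps) >= lb
        extra[k, j] = 1.0
        extra[k, yp] = lbs[j] - epsilon
        row_lb.append(lbs[j]); row_ub.append(np.inf); k += 1
        # v_r + y- (ub + eps) <= ub
        extra[k, j] = 1.0
        extra[k, ym] = ubs[j] + epsilon
        row_lb.append(-np.inf); row_ub.append(ubs[j]); k += 1
        # y+ + y- <= 1
        extra[k, yp] = 1.0
        extra[k, ym] = 1.0
        row_lb.append(-np.inf); row_ub.append(1.0); k += 1
    for l, rid in enumerate(low):
        j = idx[rid]
        y = n + 2 * n_high + l
        # v_r + lb y >= lb  (y=1 -> v >= 0)
        extra[k, j] = 1.0
        extra[k, y] = lbs[j]
        row_lb.append(lbs[j]); row_ub.append(np.inf); k += 1
        # v_r + ub y <= ub  (y=1 -> v <= 0)
        extra[k, j] = 1.0
        extra[k, y] = ubs[j]
        row_lb.append(-np.inf); row_ub.append(ubs[j]); k += 1
    rows.append(extra)

    A = np.vstack(rows)
    constraints = LinearConstraint(A, np.array(row_lb), np.array(row_ub))
    c = np.zeros(n_vars)
    c[n:] = -1.0  # maximize indicator sum
    integrality = np.zeros(n_vars)
    integrality[n:] = 1
    var_lb = np.concatenate([lbs, np.zeros(2 * n_high + n_low)])
    var_ub = np.concatenate([ubs, np.ones(2 * n_high + n_low)])

    res = milp(c=c, constraints=constraints, integrality=integrality,
               bounds=Bounds(var_lb, var_ub),
               options={"mip_rel_gap": 0.0, "presolve": True})
    if res.status == 2:
        raise ImatInfeasibleError(
            "iMAT MILP infeasible: review media constraints and flux bounds")
    if res.status != 0 or res.x is None:
        raise ImatError(f"MILP solver failure: {res.message}")

    x = res.x
    flux = {rid: float(x[idx[rid]]) for rid in rxn_ids}
    high_ind = {rid: (int(round(x[n + 2 * h])), int(round(x[n + 2 * h + 1])))
                for h, rid in enumerate(high)}
    low_ind = {rid: int(round(x[n + 2 * n_high + l]))
               for l, rid in enumerate(low)}
    objective = sum(a + b for a, b in high_ind.values()) + sum(low_ind.values())
    return ImatSolution(flux=flux, high_indicators=high_ind,
                        low_indicators=low_ind, objective=objective,
                        status="optimal", epsilon=epsilon,
                        sample_id=states.sample_id)


def enumerate_optimum(model: MetabolicModel, states: ReactionStateSet,
                      epsilon: float = DEFAULT_EPSILON) -> int:
    """Exhaustive oracle: best indicator sum over all binary assignments.

    Tries every assignment of the indicator variables and checks LP
    feasibility of the implied flux constraints (mass balance + tightened
    bounds).  Independent of the MILP path; limited to
    |R_H| + |R_L| <= 16 reactions.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    high = sorted(states.high)
    low = sorted(states.low)
    if len(high) + len(low) > ENUMERATION_CAP:
        raise ValueError(
            f"enumeration capped at |R_H|+|R_L| <= {ENUMERATION_CAP}")
    rxn_ids = list(model.reaction_ids)
    idx = {r: j for j, r in enumerate(rxn_ids)}
    lbs = np.array([r.lower_bound for r in model.reactions])
    ubs = np.array([r.upper_bound for r in model.reactions])
    S = _stoichiometric_matrix(model)
    b = np.zeros(S.shape[0])

    # options per high reaction: unsatisfied / forward (v>=eps) / backward
    high_opts: list[list[tuple[int, float, float]]] = []
    for rid in high:
        j = idx[rid]
        opts = [(0, lbs[j], ubs[j])]
        if ubs[j] >= epsilon:
            opts.append((1, max(lbs[j], epsilon), ubs[j]))
        if lbs[j] <= -epsilon:
            opts.append((1, lbs[j], min(ubs[j], -epsilon)))
        high_opts.append(opts)
    low_opts: list[list[tuple[int, float, float]]] = []
    for rid in low:
        j = idx[rid]
        opts = [(0, lbs[j], ubs[j])]
        if lbs[j] <= 0.0 <= ubs[j]:
            opts.append((1, 0.0, 0.0))
        low_opts.append(opts)

    def feasible(assignment: Sequence[tuple[int, float, float]]) -> bool:
        lo, hi = lbs.copy(), ubs.copy()
        for rid, (_, a, bnd) in zip(high + low, assignment):
            j = idx[rid]
            lo[j], hi[j] = a, bnd
        res = linprog(c=np.zeros(len(rxn_ids)), A_eq=S, b_eq=b,
                      bounds=list(zip(lo, hi)), method="highs")
        return res.status == 0

    import itertools

    best = -1
    combos = sorted(
        itertools.product(*(high_opts + low_opts)),
        key=lambda combo: -sum(opt[0] for opt in combo))
    for combo in combos:
        score = sum(opt[0] for opt in combo)
        if score <= best:
            break  # sorted descending: nothing better remains
        if feasible(combo):
            best = score
    if best < 0:
        raise ImatInfeasibleError("no feasible flux distribution at all")
    return best


# ---------------------------------------------------------------------------
# Activity calling
# ---------------------------------------------------------------------------

def call_activity(solution: ImatSolution,
                  tol: float = DEFAULT_ACTIVITY_TOL) -> dict[str, int]:
    """Binary per-reaction activity: active iff |v_r| > tol at the optimum."""
    if tol < 0:
        raise ValueError("tolerance must be nonnegative")
    if solution.status != "optimal":
        raise ImatError(f"cannot call activity on status {solution.status!r}")
    return {r: int(abs(v) > tol) for r, v in solution.flux.items()}


def robust_activity(model: MetabolicModel, states: ReactionStateSet,
                    epsilon: float = DEFAULT_EPSILON) -> dict[str, int]:
    """Alternate-optima-aware activity calls.

    Fixes the indicator objective at its optimum, then asks per reaction
    whether any optimal solution carries |v_r| >= epsilon; a reaction that
    can is called active.  Slower than the single-optimum mode; intended for
    small networks or borderline reactions.
    """
    base = solve_imat(model, states, epsilon)
    rxn_ids = list(model.reaction_ids)
    activity: dict[str, int] = {}
    for rid in rxn_ids:
        can_fwd = _optimum_allows(model, states, epsilon, base.objective,
                                  rid, direction=+1)
        can_bwd = (model.reaction(rid).lower_bound <= -epsilon and
                   _optimum_allows(model, states, epsilon, base.objective,
                                   rid, direction=-1))
        activity[rid] = int(can_fwd or can_bwd)
    return activity


def _optimum_allows(model: MetabolicModel, states: ReactionStateSet,
                    epsilon: float, objective: int, rxn_id: str,
                    direction: int) -> bool:
    """Feasibility of: objective attained AND v_rxn >= eps (or <= -eps)."""
    from dataclasses import replace as _replace

    rxn = model.reaction(rxn_id)
    if direction > 0:
        if rxn.upper_bound < epsilon:
            return False
        forced = _replace(rxn, lower_bound=max(rxn.lower_bound, epsilon))
    else:
        if rxn.lower_bound > -epsilon:
            return False
        forced = _replace(rxn, upper_bound=min(rxn.upper_bound, -epsilon))
    forced_model = _replace(
        model, reactions=tuple(forced if r.id == rxn_id else r
                               for r in model.reactions))
    try:
        sol = solve_imat(forced_model, states, epsilon)
    except ImatInfeasibleError:
        return False
    return sol.objective >= objective


# ---------------------------------------------------------------------------
# Activity matrix container and pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class ActivityMatrix:
    """Binary reactions x samples activity calls with provenance."""

    reactions: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray  # int {0,1}, reactions x samples
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.reactions), len(self.samples)):
            raise ValueError("activity matrix shape mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("activity entries must be 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.reactions),
                            columns=list(self.samples))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, val in sorted(self.provenance.items()):
                fh.write(f"# {key}={val}\n")
            frame = self.to_frame()
            frame.index.name = "reaction"
            frame.to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ActivityMatrix":
        provenance: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                provenance[key.strip()] = val
                body_start = i + 1
            else:
                break
        from io import StringIO
        frame = pd.read_csv(StringIO("".join(lines[body_start:])),
                            sep="\t", index_col=0)
        return cls(reactions=tuple(frame.index), samples=tuple(frame.columns),
                   values=frame.to_numpy(), provenance=provenance)


def predict_activity(
    model: MetabolicModel,
    expression: ExpressionMatrix,
    epsilon: float = DEFAULT_EPSILON,
    activity_tol: float = DEFAULT_ACTIVITY_TOL,
    media_constraints: Iterable[tuple[str, float]] = (),
    quantile_mode: str = "global",
    residualize_covariates: Sequence[str] | None = None,
    robust: bool = False,
) -> ActivityMatrix:
    """Run the per-sample iMAT arm end to end and return binary activity.

    Steps: optional covariate residualization of the expression matrix;
    pooled (or per-gene) thresholds; GPR mapping; state assignment; media
    constraints; one MILP per sample; activity calling.
    """
    from .expression import residualize as _residualize
    from .model_io import apply_media_constraints

    if residualize_covariates:
        expression = _residualize(expression, residualize_covariates)
    constrained = apply_media_constraints(model, media_constraints) \
        if media_constraints else model

    if quantile_mode == "global":
        thresholds = pooled_thresholds(expression)
        gene_thresholds = None
    elif quantile_mode == "per_gene":
        thresholds = None
        gene_thresholds = per_gene_thresholds(expression)
    else:
        raise ValueError("quantile_mode must be 'global' or 'per_gene'")

    rxn_ids = list(model.reaction_ids)
    columns = []
    for sample in expression.samples:
        gene_vals = expression.gene_values(sample)
        if gene_thresholds is not None:
            # discretize genes per-gene first, then map the 0/1/2 codes
            coded = {}
            for g, v in gene_vals.items():
                th = gene_thresholds[g]
                coded[g] = 2.0 if v > th.q75 else (0.0 if v < th.q25 else 1.0)
            rxn_vals = reaction_expression(constrained, coded)
            states = assign_states(rxn_vals, Thresholds(0.5, 1.5),
                                   sample_id=sample)
        else:
            rxn_vals = reaction_expression(constrained, gene_vals)
            states = assign_states(rxn_vals, thresholds, sample_id=sample)
        if robust:
            activity = robust_activity(constrained, states, epsilon)
        else:
            solution = solve_imat(constrained, states, epsilon)
            activity = call_activity(solution, activity_tol)
        columns.append([activity[r] for r in rxn_ids])

    values = np.array(columns).T if columns else np.zeros((len(rxn_ids), 0))
    return ActivityMatrix(
        reactions=tuple(rxn_ids), samples=tuple(expression.samples),
        values=values,
        provenance={
            "epsilon": epsilon, "activity_tol": activity_tol,
            "quantile_mode": quantile_mode, "solver": "scipy-highs",
            "robust": robust,
        })
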