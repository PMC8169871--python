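"""Case-control comparison of binary reaction activity.

Each reaction's per-sample activity calls are tabulated into a 2x2 table
(active/inactive by group) and compared with Fisher's exact test (two-sided,
probability-mass rule by default).  The effect size is the sample
cross-product odds ratio (a*d)/(b*c) with the zero-cell conventions used in
the source tables: a zero numerator with positive denominator renders as
``0.000``, a zero denominator with positive numerator as ``Inf``, and both
zero as ``NA``.  Significance at the network level uses the raw p-value at
0.05; a BH-adjusted column is emitted alongside for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .imat_core import ActivityMatrix
from .model_io import MetabolicModel


@dataclass(frozen=True)
class ReactionComparison:
    """2x2 activity counts and Fisher test for one reaction.

    ``a``: group-1 active, ``b``: group-1 inactive, ``c``: group-2 active,
    ``d``: group-2 inactive.  ``odds_ratio`` is the cross-product ratio; the
    special values 0.0 / inf / nan encode the zero-cell conventions.
    """

    reaction_id: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float


def activity_contingency(activity: ActivityMatrix,
                         labels: Mapping[str, str],
                         reaction_id: str,
                         groups: tuple[str, str] | None = None,
                         ) -> tuple[int, int, int, int]:
    """Counts (a, b, c, d) of active/inactive samples by group.

    Every sample must carry one of exactly two group labels.  ``groups``
    fixes which label is group 1 (the case group); by default labels are
    taken in sorted order.
    """
    unlabeled = [s for s in activity.samples if s not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled samples: {unlabeled}")
    observed = sorted({labels[s] for s in activity.samples})
    if len(observed) != 2:
        raise ValueError(f"need exactly 2 groups, got {observed}")
    g1, g2 = groups if groups is not None else (observed[0], observed[1])
    if {g1, g2} != set(observed):
        raise ValueError(f"groups {g1, g2} do not match labels {observed}")
    try:
        row = list(activity.reactions).index(reaction_id)
    except ValueError:
        raise KeyError(f"reaction {reaction_id!r} not in activity matrix")
    a = b = c = d = 0
    for j, sample in enumerate(activity.samples):
        active = activity.values[row, j] == 1
        if labels[sample] == g1:
            a += active
            b += not active
        else:
            c += active
            d += not active
    return int(a), int(b), int(c), int(d)


def fisher_p(a: int, b: int, c: int, d: int,
             two_sided_rule: str = "prob") -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    ``prob`` (default): sum of hypergeometric probabilities of all tables
    with fixed margins whose probability does not exceed the observed
    table's.  ``double``: twice the smaller one-sided tail, capped at 1.
    Tables with an empty margin have p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    if two_sided_rule == "prob":
        return float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1])
    if two_sided_rule == "double":
        n, k, m = a + b + c + d, a + b, a + c
        rv = stats.hypergeom(n, k, m)
        p_low = rv.cdf(a)
        p_high = rv.sf(a - 1)
        return float(min(1.0, 2.0 * min(p_low, p_high)))
    raise ValueError("two_sided_rule must be 'prob' or 'double'")


def odds_ratio_convention(a: int, b: int, c: int, d: int) -> float:
    """Sample cross-product odds ratio with zero-cell conventions.

    (a*d)/(b*c); numerator zero with positive denominator -> 0.0 (rendered
    "0.000"), denominator zero with positive numerator -> inf ("Inf"), both
    zero -> nan ("NA").
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    num = a * d
    den = b * c
    if num == 0 and den == 0:
        return math.nan
    if den == 0:
        return math.inf
    if num == 0:
        return 0.0
    return num / den


def render_odds_ratio(value: float) -> str:
    """Table-style rendering: 0.000 / Inf / NA / fixed 3 decimals."""
    if math.isnan(value):
        return "NA"
    if math.isinf(value):
        return "Inf"
    return f"{value:.3f}"


def compare_groups(
    activity: ActivityMatrix,
    labels: Mapping[str, str],
    groups: tuple[str, str] | None = None,
    reactions: Iterable[str] | None = None,
    alpha: float = 0.05,
    two_sided_rule: str = "prob",
    model: MetabolicModel | None = None,
) -> pd.DataFrame:
    """Per-reaction Fisher comparison of activity between two groups.

    Returns a DataFrame in deterministic (sorted reaction id) order with the
    2x2 counts, cross-product odds ratio, raw two-sided p, a significance
    flag at raw ``alpha`` (the network-level threshold), and a BH-adjusted
    ``q`` column for transparency.  ``reactions`` restricts the comparison
    to a subset (e.g. the reactions controlled by a pathway gene list).
    """
    if reactions is None:
        selected = sorted(activity.reactions)
    else:
        selected = sorted(set(reactions))
        unknown = set(selected) - set(activity.reactions)
        if unknown:
            raise KeyError(f"reactions not in activity matrix: {sorted(unknown)}")
    subsystems = {}
    if model is not None:
        subsystems = {r.id: r.subsystem for r in model.reactions}

    rows = []
    for rid in selected:
        a, b, c, d = activity_contingency(activity, labels, rid, groups)
        p = fisher_p(a, b, c, d, two_sided_rule)
        rows.append({
            "reaction": rid,
            "subsystem": subsystems.get(rid, ""),
            "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": odds_ratio_convention(a, b, c, d),
            "p": p,
        })
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    result["significant"] = result["p"] < alpha
    return result


def write_comparison_tsv(result: pd.DataFrame, path: str | Path) -> None:
    """Write a comparison report with literal Inf/NA/0.000 OR renderings."""
    out = result.copy()
    out["odds_ratio"] = out["odds_ratio"].map(render_odds_ratio)
    out["p"] = out["p"].map(lambda v: f"{v:.4g}")
    out["q"] = out["q"].map(lambda v: f"{v:.4g}")
    out.to_csv(path, sep="\t", index=False)
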