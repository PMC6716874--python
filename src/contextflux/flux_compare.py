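"""Condition submodels, FBA/FVA, and the six-status differential flux classifier.

A context-specific model is turned into naive- and primed-specific submodels
by transcriptionally silencing genes strongly down-regulated in each
condition (three logFC thresholds, BH-adjusted p < 0.05) and zeroing the
bounds of every reaction whose GPR can no longer be satisfied.  Flux
variability analysis under a biomass objective floor then yields, per
reaction, a feasible flux interval in each condition, and the interval pair
is classified into one of six statuses:

    A  naive interval entirely above primed          (up in naive)
    B  primed interval entirely above naive          (up in primed)
    C  naive interval shifted upward, overlapping    (up in naive)
    D  primed interval shifted upward, overlapping   (up in primed)
    E  unchanged / mutually covering intervals
    F  inactive in both conditions

Calls robust across all three thresholds define the final up-in-naive /
up-in-primed reaction sets, whose GPR genes feed pathway enrichment.

FBA/FVA are solved through COBRApy (GLPK); an independent linprog-based
formulation lives in the test suite as the numerical oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_io import MetabolicModel, Reaction, to_cobra

__all__ = [
    "InfeasibleModelError",
    "add_biomass",
    "apply_medium",
    "fba",
    "fva",
    "derive_condition_model",
    "classify_status",
    "consensus_status",
    "genes_from_reactions",
    "LOGFC_THRESHOLDS",
]

LOGFC_THRESHOLDS = (1.00, 0.85, 0.70)
UP_NAIVE = frozenset("AC")
UP_PRIMED = frozenset("BD")


class InfeasibleModelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model preparation
# ---------------------------------------------------------------------------

def add_biomass(model: MetabolicModel, biomass: dict[str, float],
                reaction_id: str = "biomass") -> MetabolicModel:
    """Append an irreversible biomass reaction and make it the objective.

    ``biomass`` maps metabolite id -> coefficient (negative = consumed);
    at least one species must be consumed.  Unknown metabolites are an error.
    """
    if not any(c < 0 for c in biomass.values()):
        raise ValueError("biomass must consume at least one species")
    unknown = sorted(set(biomass) - set(model.metabolite_ids()))
    if unknown:
        raise ValueError(f"biomass references unknown metabolites: {unknown}")
    out = model.copy()
    if reaction_id in set(out.reaction_ids()):
        raise ValueError(f"model already has a reaction {reaction_id!r}")
    out.reactions.append(Reaction(
        id=reaction_id, name="biomass", subsystem="biomass",
        lower_bound=0.0, upper_bound=1000.0, stoichiometry=dict(biomass)))
    out.objective_id = reaction_id
    out.validate()
    return out


def apply_medium(model: MetabolicModel, medium: dict[str, float],
                 default_policy: str = "closed") -> MetabolicModel:
    """Constrain exchange lower bounds to a growth-medium composition.

    Listed exchange reactions get the given uptake lower bound (must be
    <= 0).  Under the default 'closed' policy every unlisted exchange gets
    lower bound 0 (no uptake); 'open' leaves them untouched.  Secretion
    (upper) bounds are never modified.
    """
    if default_policy not in ("closed", "open"):
        raise ValueError("default_policy must be 'closed' or 'open'")
    exchange_ids = {r.id for r in model.exchanges()}
    bad = sorted(set(medium) - exchange_ids)
    if bad:
        raise ValueError(f"not exchange reactions: {bad}")
    positive = sorted(r for r, b in medium.items() if b > 0)
    if positive:
        raise ValueError(f"medium uptake bounds must be <= 0: {positive}")
    out = model.copy()
    for r in out.reactions:
        if r.id in medium:
            r.lower_bound = float(medium[r.id])
        elif r.id in exchange_ids and default_policy == "closed":
            r.lower_bound = max(r.lower_bound, 0.0)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------

def fba(model: MetabolicModel):
    """Maximize the model objective; returns (objective value, flux Series)."""
    if model.objective_id is None:
        raise ValueError("model has no objective reaction")
    cm = to_cobra(model)
    sol = cm.optimize()
    if sol.status != "optimal":
        raise InfeasibleModelError(f"FBA on {model.id!r}: solver status {sol.status}")
    return float(sol.objective_value), sol.fluxes.copy()


def fva(model: MetabolicModel, objective_fraction: float = 0.9) -> pd.DataFrame:
    """Flux variability analysis at the given objective floor.

    For each reaction, minimum and maximum flux subject to steady state,
    bounds, and objective >= objective_fraction * FBA optimum (2N LPs).
    Returns a DataFrame indexed by reaction id with columns vmin/vmax.
    """
    if not 0 <= objective_fraction <= 1:
        raise ValueError("objective_fraction must lie in [0, 1]")
    from cobra.flux_analysis import flux_variability_analysis

    cm = to_cobra(model)
    if model.objective_id is None:
        cm.objective = {}
    sol = cm.slim_optimize(error_value=None) if model.objective_id else 0.0
    if sol is None:
        raise InfeasibleModelError(f"FVA on {model.id!r}: infeasible model")
    res = flux_variability_analysis(cm, fraction_of_optimum=objective_fraction)
    res = res.rename(columns={"minimum": "vmin", "maximum": "vmax"})
    return res.loc[model.reaction_ids()]


# ---------------------------------------------------------------------------
# condition submodels
# ---------------------------------------------------------------------------

def derive_condition_model(model: MetabolicModel, de: pd.DataFrame,
                           downregulated_in: str,
                           logfc_threshold: float,
                           padj_threshold: float = 0.05,
                           mode: str = "gpr") -> MetabolicModel:
    """Silence genes strongly down-regulated in one condition.

    logFC is naive - primed, so genes down in naive have logFC <=
    -logfc_threshold and genes down in primed have logFC >= +logfc_threshold
    (with adj_p < padj_threshold in both cases).  Under ``mode='gpr'`` a
    reaction is zero-bounded only when its GPR evaluates to false with the
    silenced genes off and every other gene on (isozyme-redundant reactions
    survive); ``mode='any'`` zeroes every reaction touching a silenced gene.
    Reactions without a GPR are never touched.
    """
    if downregulated_in not in ("naive", "primed"):
        raise ValueError("downregulated_in must be 'naive' or 'primed'")
    if mode not in ("gpr", "any"):
        raise ValueError("mode must be 'gpr' or 'any'")
    sig = de["adj_p"] < padj_threshold
    if downregulated_in == "naive":
        down = de.index[sig & (de["logFC"] <= -logfc_threshold)]
    else:
        down = de.index[sig & (de["logFC"] >= logfc_threshold)]
    off = set(down) & set(model.genes)
    out = model.copy()
    out.id = f"{model.id}__{downregulated_in}"
    for r in out.reactions:
        if r.gpr is None:
            continue
        if mode == "any":
            disabled = bool(r.gene_ids() & off)
        else:
            disabled = not r.gpr.evaluate({g: g not in off for g in r.gene_ids()})
        if disabled:
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# six-status classification
# ---------------------------------------------------------------------------

def _interval(table: pd.DataFrame, rid: str) -> tuple[float, float]:
    if rid in table.index:
        return float(table.loc[rid, "vmin"]), float(table.loc[rid, "vmax"])
    return (0.0, 0.0)      # absent from a model == zero-bounded there


def classify_one(naive: tuple[float, float], primed: tuple[float, float],
                 tol: float = 1e-6) -> str:
    """Status of a single reaction from its two flux intervals."""
    a_n, b_n = naive
    a_p, b_p = primed
    if max(abs(a_n), abs(b_n), abs(a_p), abs(b_p)) < tol:
        return "F"
    if a_n > b_p + tol:
        return "A"
    if a_p > b_n + tol:
        return "B"
    ge_n = a_n >= a_p - tol and b_n >= b_p - tol
    gt_n = a_n > a_p + tol or b_n > b_p + tol
    if ge_n and gt_n:
        return "C"
    ge_p = a_p >= a_n - tol and b_p >= b_n - tol
    gt_p = a_p > a_n + tol or b_p > b_n + tol
    if ge_p and gt_p:
        return "D"
    return "E"


def classify_status(naive: pd.DataFrame, primed: pd.DataFrame,
                    tol: float = 1e-6) -> pd.DataFrame:
    """Classify every reaction present in either interval table.

    Returns a DataFrame (status, direction_flip) over the id union; a
    reaction absent from one table counts as interval (0, 0) there.  The
    ``direction_flip`` flag marks reactions constrained to strictly opposite
    signs in the two conditions (one direction per model), which the single
    status letter cannot express.
    """
    ids = sorted(set(naive.index) | set(primed.index))
    rows = []
    for rid in ids:
        n = _interval(naive, rid)
        p = _interval(primed, rid)
        status = classify_one(n, p, tol)
        flip = (n[1] < -tol and p[0] > tol) or (p[1] < -tol and n[0] > tol)
        rows.append({"status": status, "direction_flip": flip})
    return pd.DataFrame(rows, index=pd.Index(ids, name="reaction"))


def consensus_status(calls: dict[float, pd.DataFrame]):
    """Robust up-naive / up-primed sets across the logFC thresholds.

    ``calls`` maps threshold -> classify_status output on a shared reaction
    universe.  A reaction is robustly up in naive iff its status is in
    {A, C} at every threshold; symmetrically {B, D} for primed.
    """
    tables = list(calls.values())
    universe = set(tables[0].index)
    for t in tables[1:]:
        if set(t.index) != universe:
            raise ValueError("status calls cover different reaction universes")
    up_naive = {r for r in universe
                if all(t.loc[r, "status"] in UP_NAIVE for t in tables)}
    up_primed = {r for r in universe
                 if all(t.loc[r, "status"] in UP_PRIMED for t in tables)}
    return sorted(up_naive), sorted(up_primed)


def genes_from_reactions(model: MetabolicModel, reactions) -> set[str]:
    """Union of the genes appearing in the GPRs of the listed reactions."""
    known = set(model.reaction_ids())
    unknown = sorted(set(reactions) - known)
    if unknown:
        raise KeyError(f"unknown reaction ids: {unknown}")
    genes: set[str] = set()
    for r in model.reactions:
        if r.id in set(reactions):
            genes |= r.gene_ids()
    return genes
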