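"""Context-specific model extraction by cost-penalized dependency assessment.

Given confidence tiers (high / medium / negative) over the reactions of a
generic model, the extractor asks, for every high-confidence reaction, which
lower-confidence reactions it *needs* in order to carry flux: an LP minimizes
the tier-weighted total flux through candidate reactions subject to steady
state, bounds, and a minimum flux through the target.  Candidates active at
the optimum form the target's support.  Medium-confidence reactions that ever
appear in a support are promoted into the core; negative-confidence reactions
are promoted only when they support at least ``nc_promotion_min`` targets.
A second pass lets promoted medium reactions pull in any remaining negative
reactions they strictly require.  The final submodel (high + promoted) is
pruned to flux consistency, with the guarantee that high-tier reactions are
never pruned (a blocked high reaction is an extraction failure).

The assessment uses deterministic costs (medium cheap, negative expensive)
rather than noise-perturbed repeated solves; the promotion tally plays the
role of the occurrence count in the original algorithm, which keeps the
extraction exactly reproducible.

All LPs are solved with scipy's HiGHS backend on the split (all-forward)
network, so penalties act on flux magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel, Reaction, stoichiometric_matrix

__all__ = [
    "ExtractionParams",
    "ExtractionResult",
    "ExtractionError",
    "split_reversible",
    "dependency_assess",
    "corda_extract",
    "model_stats",
]


class ExtractionError(RuntimeError):
    """A high-confidence reaction cannot carry flux in the extracted model."""


@dataclass(frozen=True)
class ExtractionParams:
    """Knobs of the dependency assessment.

    flux_threshold : minimum flux (mmol/gDW/h) a tested reaction must carry,
        clipped per-target to its maximum feasible flux.
    mc_cost / nc_cost : LP penalty per unit flux through medium / negative
        candidates (nc_cost >> mc_cost makes negative reactions a last resort).
    nc_promotion_min : number of high-confidence targets a negative reaction
        must support before it is promoted into the core.
    tol : flux magnitude below which a reaction counts as inactive.
    """

    flux_threshold: float = 1.0
    mc_cost: float = 1.0
    nc_cost: float = 100.0
    nc_promotion_min: int = 2
    tol: float = 1e-6

    def __post_init__(self):
        if min(self.flux_threshold, self.mc_cost, self.nc_cost, self.tol) <= 0:
            raise ValueError("all extraction parameters must be positive")
        if self.nc_cost <= self.mc_cost:
            raise ValueError("nc_cost must exceed mc_cost")
        if self.nc_promotion_min < 1:
            raise ValueError("nc_promotion_min must be >= 1")


@dataclass
class ExtractionResult:
    submodel: MetabolicModel
    included: dict[str, list[str]]            # origin tier -> reaction ids kept
    dependency_tally: dict[str, int] = field(default_factory=dict)

    def included_ids(self) -> set[str]:
        return set().union(*map(set, self.included.values())) if self.included else set()


# ---------------------------------------------------------------------------
# reversible splitting
# ---------------------------------------------------------------------------

def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Make every reaction irreversible by splitting reversible ones.

    A reversible reaction r with bounds (lb < 0, ub) becomes ``r__fwd`` with
    bounds (0, ub) and ``r__rev`` (negated stoichiometry) with bounds
    (0, -lb).  Merging fluxes as v = v_fwd - v_rev recovers the original flux
    space.  Irreversible reactions pass through unchanged.
    """
    model.validate()
    out = []
    for r in model.reactions:
        if r.lower_bound >= 0:
            out.append(r.copy())
            continue
        fwd = r.copy()
        fwd.id = f"{r.id}__fwd"
        fwd.lower_bound = 0.0
        fwd.upper_bound = max(r.upper_bound, 0.0)
        rev = r.copy()
        rev.id = f"{r.id}__rev"
        rev.stoichiometry = {m: -c for m, c in r.stoichiometry.items()}
        rev.lower_bound = 0.0
        rev.upper_bound = -r.lower_bound
        out += [fwd, rev]
    split = MetabolicModel(
        metabolites=list(model.metabolites),
        reactions=out,
        genes=list(model.genes),
        objective_id=None,
        id=f"{model.id}__split",
    )
    split.validate()
    return split


def split_parent(split_id: str) -> str:
    """Original reaction id behind a split id."""
    for suffix in ("__fwd", "__rev"):
        if split_id.endswith(suffix):
            return split_id[: -len(suffix)]
    return split_id


# ---------------------------------------------------------------------------
# dependency assessment LP
# ---------------------------------------------------------------------------

class _SplitLP:
    """Cached LP matrices for a split (all-forward) model."""

    def __init__(self, split_model: MetabolicModel):
        self.model = split_model
        self.rxn_ids = split_model.reaction_ids()
        self.index = {r: i for i, r in enumerate(self.rxn_ids)}
        self.S = stoichiometric_matrix(split_model).to_numpy()
        self.bounds = [(r.lower_bound, r.upper_bound) for r in split_model.reactions]

    def solve(self, c, extra_lb: dict[str, float] | None = None):
        bounds = list(self.bounds)
        if extra_lb:
            for rid, lb in extra_lb.items():
                i = self.index[rid]
                bounds[i] = (max(bounds[i][0], lb), bounds[i][1])
        res = linprog(c, A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
                      bounds=bounds, method="highs")
        return res

    def max_flux(self, target: str) -> float:
        c = np.zeros(len(self.rxn_ids))
        c[self.index[target]] = -1.0
        res = self.solve(c)
        if not res.success:
            return 0.0
        return float(-res.fun)


def dependency_assess(split_model: MetabolicModel | _SplitLP, target: str,
                      candidate_costs: dict[str, float],
                      flux_threshold: float = 1.0,
                      tol: float = 1e-6) -> set[str] | None:
    """Support set of candidate reactions required by ``target``.

    Minimizes sum(cost_i * v_i) over the candidates subject to S v = 0,
    bounds, and v_target >= min(flux_threshold, max feasible target flux).
    Returns the candidates with v_i > tol at the optimum, or ``None`` when
    the target cannot carry any flux at all (unsupportable; not an error).
    """
    lp = split_model if isinstance(split_model, _SplitLP) else _SplitLP(split_model)
    if target not in lp.index:
        raise KeyError(f"no reaction {target!r} in split model")
    if any(cost < 0 for cost in candidate_costs.values()):
        raise ValueError("candidate costs must be nonnegative")
    vmax = lp.max_flux(target)
    if vmax < tol:
        return None
    threshold = min(flux_threshold, vmax)
    c = np.zeros(len(lp.rxn_ids))
    for rid, cost in candidate_costs.items():
        if rid in lp.index:
            c[lp.index[rid]] = cost
    res = lp.solve(c, extra_lb={target: threshold})
    if not res.success:      # numerically infeasible despite clipping
        return None
    v = res.x
    return {rid for rid in candidate_costs
            if rid in lp.index and v[lp.index[rid]] > tol}


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _split_costs(split_ids, tier_of, which: dict[str, float]) -> dict[str, float]:
    costs = {}
    for sid in split_ids:
        tier = tier_of[split_parent(sid)]
        if tier in which:
            costs[sid] = which[tier]
    return costs


def _find_blocked(model: MetabolicModel, tol: float) -> set[str]:
    """Reactions unable to carry |flux| >= tol at steady state (no objective)."""
    import cobra.flux_analysis
    from .model_io import to_cobra

    cm = to_cobra(model)
    cm.objective = {}
    blocked = cobra.flux_analysis.find_blocked_reactions(cm, zero_cutoff=tol)
    return set(blocked)


def corda_extract(model: MetabolicModel, tiers: dict[str, str],
                  params: ExtractionParams = ExtractionParams()) -> ExtractionResult:
    """Extract the context-specific submodel implied by confidence tiers.

    Three passes (see module docstring), then iterative flux-consistency
    pruning of non-high reactions.  Raises :class:`ExtractionError` if a
    high-tier reaction ends up blocked.
    """
    model.validate()
    missing = set(model.reaction_ids()) - set(tiers)
    if missing:
        raise ValueError(f"tiers missing for reactions: {sorted(missing)}")
    high = [r for r in model.reaction_ids() if tiers[r] == "high"]
    if not high:
        raise ValueError("high tier is empty")

    split = split_reversible(model)
    lp = _SplitLP(split)
    split_ids = split.reaction_ids()

    # pass 1: assess every high reaction against medium+negative candidates
    tally: dict[str, int] = {}
    pass1_costs = _split_costs(split_ids, tiers,
                               {"medium": params.mc_cost, "negative": params.nc_cost})
    promoted_medium: set[str] = set()
    nc_support_counts: dict[str, set[str]] = {}
    pass1_support: dict[str, set[str]] = {}
    for rid in high:
        targets = [s for s in split_ids if split_parent(s) == rid]
        supported = False
        support_parents: set[str] = set()
        for t in targets:
            sup = dependency_assess(lp, t, pass1_costs,
                                    params.flux_threshold, params.tol)
            if sup is None:
                continue
            supported = True
            support_parents |= {split_parent(s) for s in sup}
        if not supported:
            # target blocked even in the generic network; the consistency
            # pruning below will surface this as an extraction failure
            continue
        pass1_support[rid] = support_parents
        for p in support_parents:
            tally[p] = tally.get(p, 0) + 1
            if tiers[p] == "medium":
                promoted_medium.add(p)
            else:
                nc_support_counts.setdefault(p, set()).add(rid)

    # pass 2: promote negatives supporting enough high targets
    promoted_negative = {
        p for p, supported in nc_support_counts.items()
        if len(supported) >= params.nc_promotion_min
    }

    # pass 3: promoted medium reactions may require further negative reactions
    remaining_negative = {r for r in model.reaction_ids()
                          if tiers[r] == "negative" and r not in promoted_negative}
    core = set(high) | promoted_medium | promoted_negative
    if remaining_negative and promoted_medium:
        keep3 = core | remaining_negative
        sub3 = model.subset(keep3, model_id=f"{model.id}__pass3")
        split3 = split_reversible(sub3)
        lp3 = _SplitLP(split3)
        costs3 = _split_costs(split3.reaction_ids(), tiers, {"negative": params.nc_cost})
        costs3 = {k: v for k, v in costs3.items()
                  if split_parent(k) in remaining_negative}
        for rid in sorted(promoted_medium):
            targets = [s for s in split3.reaction_ids() if split_parent(s) == rid]
            for t in targets:
                sup = dependency_assess(lp3, t, costs3, params.flux_threshold, params.tol)
                if sup:
                    promoted = {split_parent(s) for s in sup}
                    promoted_negative |= promoted
                    remaining_negative -= promoted

    included = set(high) | promoted_medium | promoted_negative

    # rescue pass: a high reaction may still be blocked when its only
    # negative-tier supports fell below the promotion tally; such supports
    # are required regardless of the tally, so pull its assessed support in
    while True:
        sub = model.subset(included, model_id=f"{model.id}__rescue")
        blocked_high = _find_blocked(sub, params.tol) & set(high)
        rescued = False
        for rid in sorted(blocked_high):
            extra = pass1_support.get(rid, set()) - included
            if extra:
                included |= extra
                rescued = True
        if not rescued:
            break

    # prune to flux consistency; high reactions must survive
    while True:
        sub = model.subset(included, model_id=f"{model.id}__context")
        blocked = _find_blocked(sub, params.tol)
        blocked_high = sorted(blocked & set(high))
        if blocked_high:
            raise ExtractionError(
                f"high-confidence reactions blocked in the extracted model: {blocked_high}")
        if not blocked:
            break
        included -= blocked

    submodel = model.subset(included, model_id=f"{model.id}__context")
    by_tier = {
        "high": sorted(r for r in included if tiers[r] == "high"),
        "medium": sorted(r for r in included if tiers[r] == "medium"),
        "negative": sorted(r for r in included if tiers[r] == "negative"),
    }
    return ExtractionResult(submodel=submodel, included=by_tier,
                            dependency_tally=dict(sorted(tally.items())))


def model_stats(model: MetabolicModel) -> tuple[int, int, int]:
    """(n_metabolites, n_reactions, n_genes) after dropping orphans.

    Orphan metabolites/genes are those referenced by no remaining reaction.
    """
    used_mets = set()
    used_genes = set()
    for r in model.reactions:
        used_mets |= set(r.stoichiometry)
        used_genes |= r.gene_ids()
    n_mets = sum(1 for m in model.metabolites if m.id in used_mets)
    n_genes = sum(1 for g in model.genes if g in used_genes)
    return (n_mets, len(model.reactions), n_genes)
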