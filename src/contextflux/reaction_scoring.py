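"""Map gene expression onto reactions through GPR rules and assign the
high / medium / negative confidence tiers that drive context extraction.

GPR aggregation follows the standard semantics of expression-to-reaction
mapping: AND (enzyme complex) takes the minimum of its operands, OR
(isozymes) the maximum.  Genes present in the model but absent from the
expression matrix score 0 ("not expressed"); genes in the matrix but absent
from the model are ignored.  By default the top and bottom 10% of *scored*
reactions become the high and negative tiers, everything else (including
GPR-less reactions, whose inclusion is left to network topology) is medium.
"""

from __future__ import annotations

import math

import pandas as pd

from .expression import ExpressionMatrix
from .model_io import MetabolicModel

__all__ = [
    "summarize_gene_expression",
    "score_reactions",
    "assign_tiers",
    "tier_table",
]

TIERS = ("high", "medium", "negative")


def summarize_gene_expression(x: ExpressionMatrix, condition: str | None = None,
                              model_genes=None) -> pd.Series:
    """Per-gene mean log2 expression over the selected samples.

    ``condition`` restricts to one condition's samples (None = all).  Genes
    listed in ``model_genes`` but missing from the matrix are appended with
    expression 0 (treated as not expressed).
    """
    if condition is None:
        cols = list(x.samples)
    else:
        cols = list(x.samples[(x.condition == condition).to_numpy()])
    if not cols:
        raise ValueError(f"no samples selected for condition {condition!r}")
    means = x.values[cols].mean(axis=1)
    if model_genes is not None:
        absent = [g for g in model_genes if g not in means.index]
        if absent:
            means = pd.concat([means, pd.Series(0.0, index=absent)])
    means.name = "mean_log2_expression"
    return means


def score_reactions(model: MetabolicModel, gene_expr) -> dict[str, float]:
    """Evaluate each reaction's GPR over gene scores (AND=min, OR=max).

    Reactions with an empty GPR are absent from the result (undefined);
    genes missing from ``gene_expr`` contribute 0.
    """
    model.validate()
    expr = dict(gene_expr.items() if hasattr(gene_expr, "items") else gene_expr)
    scores: dict[str, float] = {}
    for r in model.reactions:
        if r.gpr is None:
            continue
        values = {g: float(expr.get(g, 0.0)) for g in r.gpr.genes()}
        scores[r.id] = float(r.gpr.aggregate(values))
    return scores


def assign_tiers(model: MetabolicModel, scores: dict[str, float],
                 high_frac: float = 0.10, neg_frac: float = 0.10) -> dict[str, str]:
    """Assign every model reaction one of {high, medium, negative}.

    Among the N scored reactions, the top ceil(high_frac * N) by score are
    high and the bottom ceil(neg_frac * N) negative; the remainder and all
    unscored reactions are medium.  Ties at a cutoff are broken by
    lexicographic reaction id, so the assignment is deterministic and the
    tier counts are exact.
    """
    if not (0 < high_frac and 0 < neg_frac and high_frac + neg_frac < 1):
        raise ValueError("need 0 < high_frac, neg_frac and high_frac + neg_frac < 1")
    rxn_ids = model.reaction_ids()
    unknown = set(scores) - set(rxn_ids)
    if unknown:
        raise KeyError(f"scores for unknown reactions: {sorted(unknown)}")
    scored = sorted(scores)                      # lexicographic base order
    n = len(scored)
    if n < 3:
        raise ValueError(f"need at least 3 scored reactions, got {n}")
    n_high = math.ceil(high_frac * n)
    n_neg = math.ceil(neg_frac * n)
    by_score_desc = sorted(scored, key=lambda r: (-scores[r], r))
    by_score_asc = sorted(scored, key=lambda r: (scores[r], r))
    high = set(by_score_desc[:n_high])
    negative = set([r for r in by_score_asc if r not in high][:n_neg])
    tiers = {}
    for rid in rxn_ids:
        if rid in high:
            tiers[rid] = "high"
        elif rid in negative:
            tiers[rid] = "negative"
        else:
            tiers[rid] = "medium"
    return tiers


def tier_table(model: MetabolicModel, scores: dict[str, float],
               tiers: dict[str, str]) -> pd.DataFrame:
    """Reaction/score/tier table (TSV-ready)."""
    return pd.DataFrame(
        {
            "score": [scores.get(r, float("nan")) for r in model.reaction_ids()],
            "tier": [tiers[r] for r in model.reaction_ids()],
        },
        index=pd.Index(model.reaction_ids(), name="reaction"),
    )
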