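"""Reporter metabolites: metabolites around which transcriptional change
concentrates.

Each metabolite's neighborhood is the union of genes in the GPRs of the
reactions that produce or consume it (1-step, compartment-specific, with no
currency-metabolite exclusion by default — highly connected cofactors such
as NAD must remain scorable).  Per gene, the differential-expression p-value
is converted to z = Phi^-1(1 - p); the metabolite's raw score is the
normalized neighborhood sum Z_raw = sum(z) / sqrt(k).  Because gene-set size
and the global p-value distribution inflate raw scores, the score is
corrected against a sampled background: for each neighborhood size k,
``n_background`` random size-k gene sets are drawn from the scored universe,
and Z_corrected = (Z_raw - mu_k) / sigma_k.  One-tailed p-values follow from
the normal tail, with BH adjustment across metabolites.

Direction is reported separately as the mean sign of the neighborhood
logFCs (the z-aggregate measures significance, not direction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .expression import benjamini_hochberg
from .model_io import MetabolicModel

__all__ = [
    "metabolite_gene_neighborhood",
    "reporter_scores",
    "significant_reporters",
]

P_CLAMP = 1e-15


def metabolite_gene_neighborhood(model: MetabolicModel,
                                 exclude=None) -> dict[str, set[str]]:
    """Metabolite id -> set of genes in adjacent reactions' GPRs.

    Metabolites touched only by GPR-less reactions get no entry (unscored).
    ``exclude`` optionally drops listed metabolite ids (e.g. a currency-
    metabolite exclusion list).
    """
    model.validate()
    excluded = set(exclude or ())
    nb: dict[str, set[str]] = {}
    for r in model.reactions:
        genes = r.gene_ids()
        if not genes:
            continue
        for met in r.stoichiometry:
            if met in excluded:
                continue
            nb.setdefault(met, set()).update(genes)
    return nb


def _gene_z(de: pd.DataFrame) -> pd.Series:
    p = de["p_value"].clip(P_CLAMP, 1 - P_CLAMP)
    return pd.Series(norm.ppf(1.0 - p), index=de.index)


def reporter_scores(neighborhood: dict[str, set[str]], de: pd.DataFrame,
                    n_background: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Background-corrected reporter scores for every scorable metabolite.

    Neighborhood genes without a DE p-value are dropped; metabolites whose
    neighborhood becomes empty are excluded.  The sampling universe for the
    background is the full set of DE-tested genes.  Metabolites whose size-k
    background has zero spread are flagged ``degenerate`` and carry no
    corrected score.

    Returns a DataFrame indexed by metabolite with columns
    k, Z_raw, Z_corrected, p, adj_p, direction, degenerate.
    """
    z = _gene_z(de)
    universe = list(z.index)
    zvals = z.to_numpy()
    rng = np.random.default_rng(seed)

    kept: dict[str, list[str]] = {}
    for met, genes in neighborhood.items():
        genes_in = [g for g in genes if g in z.index]
        if genes_in:
            kept[met] = genes_in
    if not kept:
        raise ValueError("no metabolite has DE-scored neighborhood genes")

    sizes = sorted({len(g) for g in kept.values()})
    kmax = max(sizes)
    if kmax > len(universe):
        raise ValueError(
            f"neighborhood size {kmax} exceeds the scored universe ({len(universe)})")

    # one permutation pass per background draw; cumulative sums give the
    # background for every k at once
    perm_sums = np.empty((n_background, kmax))
    for b in range(n_background):
        idx = rng.permutation(len(universe))[:kmax]
        perm_sums[b] = np.cumsum(zvals[idx])
    mu = {k: perm_sums[:, k - 1].mean() / np.sqrt(k) for k in sizes}
    sigma = {k: perm_sums[:, k - 1].std(ddof=1) / np.sqrt(k) for k in sizes}

    rows = []
    for met in sorted(kept):
        genes = kept[met]
        k = len(genes)
        z_raw = float(z[genes].sum() / np.sqrt(k))
        degenerate = False
        if sigma[k] < 1e-12:
            if k < len(universe) and abs(z_raw - mu[k]) < 1e-9:
                # no spread because every gene carries the same evidence:
                # the neighborhood is exactly at background level
                z_corr, p = 0.0, 0.5
            else:
                # k spans the whole universe (or numerics broke): the
                # background carries no information
                degenerate = True
                z_corr, p = np.nan, np.nan
        else:
            z_corr = (z_raw - mu[k]) / sigma[k]
            p = float(norm.sf(z_corr))
            p = min(max(p, P_CLAMP), 1 - P_CLAMP)
        direction = float(np.sign(de.loc[genes, "logFC"]).mean()) \
            if "logFC" in de.columns else np.nan
        rows.append({"metabolite": met, "k": k, "Z_raw": z_raw,
                     "Z_corrected": z_corr, "p": p,
                     "direction": direction, "degenerate": degenerate})
    table = pd.DataFrame(rows).set_index("metabolite")
    ok = ~table["degenerate"]
    adj = pd.Series(np.nan, index=table.index)
    if ok.any():
        adj[ok] = benjamini_hochberg(table.loc[ok, "p"])
    table["adj_p"] = adj
    return table[["k", "Z_raw", "Z_corrected", "p", "adj_p",
                  "direction", "degenerate"]]


def significant_reporters(scores: pd.DataFrame, alpha: float = 0.05,
                          use_adjusted: bool = True) -> pd.DataFrame:
    """Reporters below the significance cut, ranked by corrected score.

    Adds a ``one_minus_p`` column (1 - p), the quantity conventionally
    annotated on pathway maps.  ``use_adjusted=False`` cuts on the raw p
    instead of the BH-adjusted one.
    """
    col = "adj_p" if use_adjusted else "p"
    ok = scores[~scores["degenerate"]]
    sig = ok[ok[col] < alpha].copy()
    sig["one_minus_p"] = 1.0 - sig["p"]
    return sig.sort_values("Z_corrected", ascending=False)
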