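"""Synthetic inputs: a toy genome-scale network and batch-structured expression.

The toy network is a deliberately small (~35 reaction) caricature of central
carbon and cofactor metabolism in pluripotent cells:

* a glucose uptake / glycolysis-like chain ending in pyruvate,
* a TCA-like cycle that regenerates its carrier (oxaloacetate-like),
* an oxygen exchange plus an OXPHOS-like ATP-producing reaction,
* a tryptophan -> kynurenine -> ... -> NAD branch gated by a dedicated gene
  per step, with a rate-limiting "IDO1-like" gene on the first committed step,
* a biomass reaction consuming an ATP-like species, a precursor (G6P-like)
  and de-novo NAD, set as the growth objective.

Because biomass is the only NAD consumer and the kynurenine-like branch its
only producer, deleting (or transcriptionally silencing) the branch abolishes
growth — the planted causal structure every downstream stage must recover.

Expression matrices are simulated on the log2 scale (microarray-like) with
per-batch additive shifts, per-batch multiplicative noise scaling, i.i.d.
Gaussian noise, and planted condition effects (naive - primed log2
fold-changes), mirroring the batch structure of merged public stem-cell
transcriptome series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model_io import MetabolicModel, Metabolite, Reaction, parse_gpr
from .expression import ExpressionMatrix

__all__ = [
    "ToyNetworkSpec",
    "ExpressionSimSpec",
    "make_toy_network",
    "simulate_expression",
    "plant_pathway_downregulation",
    "TRP_BRANCH_GENES",
    "TRP_BRANCH_REACTIONS",
    "toy_gene_sets",
]

# Gene complement of the tryptophan/kynurenine-like branch, in pathway order.
# g_ido1 is the rate-limiting first committed step.
TRP_BRANCH_GENES = (
    "g_trpt", "g_ido1", "g_afmid", "g_kmo", "g_kynu",
    "g_haao", "g_qprt", "g_nmnat1",
)
TRP_BRANCH_REACTIONS = (
    "TRPt", "IDO", "KYNF", "KMO", "KYNU", "HAAO", "QPRT", "NMNAT",
)


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Parameters of the toy network generator (deterministic given seed)."""

    include_trp_branch: bool = True
    n_extra_reactions: int = 10
    seed: int = 0


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Log2-scale expression simulation parameters.

    ``de_genes`` maps gene id -> planted log2 fold-change (naive - primed;
    negative = down in naive).  Batch effects follow an additive shift
    gamma_{g,b} ~ Normal(m_b, batch_shift_sd) with per-batch mean shift
    m_b ~ Normal(0, batch_shift_sd), and a multiplicative noise scale
    phi_{g,b} ~ Uniform(batch_scale_range) applied to the residual noise.
    """

    n_genes: int = 2000
    n_batches: int = 3
    samples_per_condition_per_batch: int = 20
    batch_shift_sd: float = 1.0
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    de_genes: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_batches < 1 or self.samples_per_condition_per_batch < 1:
            raise ValueError("all counts must be >= 1")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        lo, hi = self.batch_scale_range
        if not (0 < lo <= hi):
            raise ValueError("batch_scale_range must be 0 < lo <= hi")


# ---------------------------------------------------------------------------
# toy network
# ---------------------------------------------------------------------------

def _rxn(rid, stoich, gpr, lb=0.0, ub=1000.0, subsystem=""):
    return Reaction(id=rid, name=rid, subsystem=subsystem, lower_bound=lb,
                    upper_bound=ub, stoichiometry=stoich, gpr=parse_gpr(gpr))


def make_toy_network(spec: ToyNetworkSpec = ToyNetworkSpec()) -> MetabolicModel:
    """Build the toy metabolic model; biomass FBA optimum > 0 on the default medium.

    With ``include_trp_branch=False`` the NAD species becomes unreachable from
    any exchange, so the NAD-requiring biomass reaction is blocked (optimum 0).
    """
    reactions: list[Reaction] = []

    # exchanges (single-metabolite boundary reactions; lb < 0 = uptake)
    reactions += [
        _rxn("EX_glc", {"glc_e": -1}, "g_ex_glc", lb=-10.0, subsystem="exchange"),
        _rxn("EX_o2", {"o2_e": -1}, "g_ex_o2", lb=-20.0, subsystem="exchange"),
        _rxn("EX_co2", {"co2_e": -1}, "g_ex_co2", lb=0.0, subsystem="exchange"),
    ]
    # glycolysis-like chain
    reactions += [
        _rxn("GLCt", {"glc_e": -1, "glc_c": 1}, "g_glut1", subsystem="glycolysis"),
        _rxn("HEX", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
             "g_hk1 or g_hk2", subsystem="glycolysis"),
        _rxn("PGI", {"g6p_c": -1, "fbp_c": 1}, "g_pgi", lb=-1000.0,
             subsystem="glycolysis"),
        _rxn("FBA", {"fbp_c": -1, "g3p_c": 2}, "g_fba", subsystem="glycolysis"),
        _rxn("PYK", {"g3p_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1},
             "g_pyk and g_eno", subsystem="glycolysis"),
    ]
    # TCA-like cycle regenerating the oaa-like carrier; pyruvate carboxylase
    # fills the pool, carbon leaves as CO2
    reactions += [
        _rxn("PDH", {"pyr_c": -1, "accoa_c": 1, "co2_c": 1}, "g_pdha", subsystem="tca"),
        _rxn("PC", {"pyr_c": -1, "atp_c": -1, "oaa_c": 1, "adp_c": 1},
             "g_pc", subsystem="tca"),
        _rxn("CS", {"accoa_c": -1, "oaa_c": -1, "cit_c": 1}, "g_cs", subsystem="tca"),
        _rxn("IDH", {"cit_c": -1, "akg_c": 1, "co2_c": 1}, "g_idh", subsystem="tca"),
        _rxn("AKGDH", {"akg_c": -1, "suc_c": 1, "co2_c": 1}, "g_sucla", subsystem="tca"),
        _rxn("MDH", {"suc_c": -1, "oaa_c": 1}, "g_mdh2", lb=-1000.0, subsystem="tca"),
    ]
    # oxygen transport + OXPHOS-like ATP production
    reactions += [
        _rxn("O2t", {"o2_e": -1, "o2_c": 1}, "g_o2t", subsystem="oxphos"),
        _rxn("CO2t", {"co2_c": -1, "co2_e": 1}, "g_co2t", subsystem="oxphos"),
        _rxn("OXPHOS", {"pyr_c": -1, "o2_c": -1, "adp_c": -3, "atp_c": 3, "co2_c": 1},
             "(g_nd1 and g_nd2) or g_altox", subsystem="oxphos"),
    ]
    # tryptophan -> kynurenine -> NAD branch (one dedicated gene per step)
    if spec.include_trp_branch:
        reactions += [
            _rxn("EX_trp", {"trp_e": -1}, "g_ex_trp", lb=-5.0, subsystem="exchange"),
            _rxn("TRPt", {"trp_e": -1, "trp_c": 1}, "g_trpt", subsystem="trp_kynurenine"),
            _rxn("IDO", {"trp_c": -1, "nfk_c": 1}, "g_ido1", subsystem="trp_kynurenine"),
            _rxn("KYNF", {"nfk_c": -1, "kyn_c": 1}, "g_afmid", subsystem="trp_kynurenine"),
            _rxn("KMO", {"kyn_c": -1, "hkyn_c": 1}, "g_kmo", subsystem="trp_kynurenine"),
            _rxn("KYNU", {"hkyn_c": -1, "haa_c": 1}, "g_kynu", subsystem="trp_kynurenine"),
            _rxn("HAAO", {"haa_c": -1, "quin_c": 1}, "g_haao", subsystem="trp_kynurenine"),
            _rxn("QPRT", {"quin_c": -1, "namn_c": 1}, "g_qprt", subsystem="trp_kynurenine"),
            _rxn("NMNAT", {"namn_c": -1, "atp_c": -1, "nad_c": 1, "adp_c": 1},
                 "g_nmnat1", subsystem="trp_kynurenine"),
        ]
    # biomass: ATP-like + sugar and TCA-derived precursors + de-novo NAD;
    # the oaa drain keeps the anaplerotic step (PC) flux-consistent
    reactions.append(
        _rxn("biomass",
             {"atp_c": -2, "g6p_c": -1, "oaa_c": -0.5, "nad_c": -0.1, "adp_c": 2},
             "g_growth", subsystem="biomass"))

    # flux-consistent extra reactions: parallel g6p -> x_i -> co2 detours
    n_pairs, leftover = divmod(max(spec.n_extra_reactions, 0), 2)
    for i in range(n_pairs):
        mid = f"x{i}_c"
        reactions.append(_rxn(f"EXTRA{i}_in", {"g6p_c": -1, mid: 1},
                              f"g_extra{i}a", subsystem="extra"))
        reactions.append(_rxn(f"EXTRA{i}_out", {mid: -1, "co2_c": 1},
                              f"g_extra{i}b", subsystem="extra"))
    if leftover:
        # odd count: one redundant isozyme copy of the last detour's exit step
        mid = "x0_c" if n_pairs else "g6p_c"
        reactions.append(_rxn("EXTRA_iso", {mid: -1, "co2_c": 1},
                              "g_extra_iso", subsystem="extra"))

    met_ids: list[str] = []
    for r in reactions:
        for m in r.stoichiometry:
            if m not in met_ids:
                met_ids.append(m)
    metabolites = [
        Metabolite(m, name=m, compartment="e" if m.endswith("_e") else "c")
        for m in met_ids
    ]
    genes = sorted(set().union(*(r.gene_ids() for r in reactions)))
    model = MetabolicModel(metabolites=metabolites, reactions=reactions,
                           genes=genes, objective_id="biomass", id="toy_network")
    model.validate()
    return model


def toy_gene_sets(model: MetabolicModel | None = None) -> dict[str, set[str]]:
    """Pathway-style gene sets over the toy network (GMT-ready).

    Sets follow the toy subsystems plus an "adhesion-like" dummy set of
    non-metabolic filler genes, so enrichment runs end-to-end without any
    external pathway database.
    """
    if model is None:
        model = make_toy_network()
    sets: dict[str, set[str]] = {}
    for r in model.reactions:
        if not r.subsystem or r.subsystem in ("exchange", "biomass"):
            continue
        sets.setdefault(r.subsystem, set()).update(r.gene_ids())
    sets["adhesion_like"] = {f"gene_{i:04d}" for i in range(1, 21)}
    return sets


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def _gene_universe(model_genes, n_genes: int) -> list[str]:
    model_genes = list(model_genes)
    if len(model_genes) > n_genes:
        raise ValueError("n_genes smaller than the model gene complement")
    filler = [f"gene_{i:04d}" for i in range(1, n_genes - len(model_genes) + 1)]
    return model_genes + filler


def simulate_expression(model_genes, spec: ExpressionSimSpec) -> ExpressionMatrix:
    """Simulate a log2 gene x sample matrix with batch and condition structure.

    x[g,s] = mu_g + Delta_g * I(naive) + gamma_{g,b(s)} + phi_{g,b(s)} * eps,
    with mu_g ~ Normal(7, 1.5) baselines.  Deterministic for a fixed seed.
    """
    spec.validate()
    genes = _gene_universe(model_genes, spec.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    missing = set(spec.de_genes) - set(genes)
    if missing:
        raise ValueError(f"de_genes not in the simulated universe: {sorted(missing)}")

    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    B = spec.n_batches
    spc = spec.samples_per_condition_per_batch

    mu = rng.normal(7.0, 1.5, size=G)
    delta = np.zeros(G)
    for g, lfc in spec.de_genes.items():
        delta[gene_index[g]] = lfc

    batch_mean_shift = (rng.normal(0.0, spec.batch_shift_sd, size=B)
                        if spec.batch_shift_sd > 0 else np.zeros(B))
    gamma = (rng.normal(batch_mean_shift[None, :], spec.batch_shift_sd, size=(G, B))
             if spec.batch_shift_sd > 0 else np.zeros((G, B)))
    lo, hi = spec.batch_scale_range
    phi = rng.uniform(lo, hi, size=(G, B))

    samples, batches, conditions = [], [], []
    columns = []
    for b in range(B):
        for cond in ("naive", "primed"):
            for i in range(spc):
                samples.append(f"b{b + 1}_{cond}_{i + 1}")
                batches.append(f"batch{b + 1}")
                conditions.append(cond)
                eps = rng.normal(0.0, spec.noise_sd, size=G)
                col = mu + (delta if cond == "naive" else 0.0) + gamma[:, b] + phi[:, b] * eps
                columns.append(col)
    values = pd.DataFrame(np.column_stack(columns), index=genes, columns=samples)
    meta = pd.DataFrame({"batch": batches, "condition": conditions}, index=samples)
    return ExpressionMatrix(values=values, metadata=meta)


def plant_pathway_downregulation(spec: ExpressionSimSpec, pathway_genes,
                                 logfc: float) -> ExpressionSimSpec:
    """Return a spec with every pathway gene planted at the given log2FC.

    Negative ``logfc`` means down in naive.  Re-planting a gene at a different
    fold-change raises a conflict error; re-planting at the same value is a
    no-op for that gene.
    """
    # pathway genes are typically model genes, which are prepended to the
    # universe by simulate_expression; membership is re-checked there.
    de = dict(spec.de_genes)
    for g in pathway_genes:
        if g in de and de[g] != logfc:
            raise ValueError(
                f"gene {g!r} already planted at logFC {de[g]}, conflicting with {logfc}")
        de[g] = logfc
    return replace(spec, de_genes=de)
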