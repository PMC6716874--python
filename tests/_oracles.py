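"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's solver path: flux LPs are formulated
from scratch on the raw stoichiometry with scipy's HiGHS backend, boolean /
statistical primitives are written as direct brute-force definitions.
"""

import itertools
import math

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# LP oracle: FBA/FVA straight from the stoichiometry dictionaries
# ---------------------------------------------------------------------------

def _lp_parts(model):
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_ids = [r.id for r in model.reactions]
    S = np.zeros((len(met_index), len(rxn_ids)))
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            S[met_index[met], j] = coef
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, rxn_ids, bounds


def fba_oracle(model):
    """Maximize the objective reaction; returns the optimum."""
    S, rxn_ids, bounds = _lp_parts(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.objective_id)] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    assert res.success, res.message
    return -res.fun


def fva_oracle(model, objective_fraction=0.9):
    """Brute-force FVA: 2N independent LPs with an explicit objective floor."""
    S, rxn_ids, bounds = _lp_parts(model)
    n = len(rxn_ids)
    A_ub, b_ub = None, None
    if model.objective_id is not None:
        opt = fba_oracle(model)
        row = np.zeros(n)
        row[rxn_ids.index(model.objective_id)] = -1.0
        A_ub = row[None, :]
        b_ub = np.array([-objective_fraction * opt])
    out = {}
    for j, rid in enumerate(rxn_ids):
        lohi = []
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
            assert res.success, f"{rid}: {res.message}"
            lohi.append(sign * res.fun)
        out[rid] = (lohi[0], lohi[1])
    return out


# ---------------------------------------------------------------------------
# GPR brute force
# ---------------------------------------------------------------------------

def gpr_truth_table(tree, genes):
    """All boolean evaluations of a GPR tree over the listed genes."""
    genes = sorted(genes)
    table = {}
    for bits in itertools.product([False, True], repeat=len(genes)):
        assignment = dict(zip(genes, bits))
        table[bits] = _eval_recursive(tree, assignment)
    return table


def _eval_recursive(tree, assignment):
    if tree.op == "gene":
        return assignment[tree.gene]
    vals = [_eval_recursive(c, assignment) for c in tree.children]
    return all(vals) if tree.op == "and" else any(vals)


def gpr_score_recursive(tree, expr):
    if tree.op == "gene":
        return expr[tree.gene]
    vals = [gpr_score_recursive(c, expr) for c in tree.children]
    return min(vals) if tree.op == "and" else max(vals)


def random_gpr_text(rng, genes, depth=0):
    """Random well-formed GPR rule text."""
    if depth >= 3 or rng.random() < 0.35:
        return rng.choice(genes)
    op = rng.choice([" and ", " or "])
    k = rng.integers(2, 4)
    parts = [random_gpr_text(rng, genes, depth + 1) for _ in range(k)]
    return "(" + op.join(parts) + ")"


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def bh_oracle(pvals):
    """BH step-up by direct sort-and-cummin."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def hypergeom_tail_oracle(overlap, universe, set_size, query_size):
    """P(X >= overlap) by direct combinatorial enumeration."""
    total = math.comb(universe, query_size)
    acc = 0
    for x in range(overlap, min(set_size, query_size) + 1):
        if universe - set_size < query_size - x:
            continue
        acc += math.comb(set_size, x) * math.comb(universe - set_size, query_size - x)
    return acc / total


def status_oracle(naive, primed, tol=1e-6):
    """Decision-table transcription of the six-status figure semantics."""
    a_n, b_n = naive
    a_p, b_p = primed
    if all(abs(v) < tol for v in (a_n, b_n, a_p, b_p)):
        return "F"          # inactive in both
    if a_n > b_p + tol:
        return "A"          # disjoint, naive above
    if a_p > b_n + tol:
        return "B"          # disjoint, primed above
    naive_shifted_up = (a_n >= a_p - tol and b_n >= b_p - tol
                        and (a_n > a_p + tol or b_n > b_p + tol))
    primed_shifted_up = (a_p >= a_n - tol and b_p >= b_n - tol
                         and (a_p > a_n + tol or b_p > b_n + tol))
    if naive_shifted_up:
        return "C"
    if primed_shifted_up:
        return "D"
    return "E"
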