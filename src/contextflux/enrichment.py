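"""Over-representation analysis of gene sets (hypergeometric + BH).

Pathway collections are read from GMT files (name, description, genes per
tab-separated line).  For a query gene list drawn from a universe, each set's
p-value is the hypergeometric upper tail: the probability of observing at
least the seen overlap when |query| genes are sampled without replacement
from a universe containing |set ∩ universe| members of the set.  BH
adjustment is applied across sets and results are ranked by p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .expression import benjamini_hochberg

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "enrich"]


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        empty = sorted(n for n, s in self.sets.items() if not s)
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; duplicate set names or short lines are errors."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def enrich(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` against each set.

    Query genes outside the universe are dropped with a warning.  Returns a
    DataFrame (set_size, overlap, p_value, adj_p) sorted by p-value; set
    sizes are taken after intersection with the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe dropped")
        query &= universe
    M = len(universe)
    N = len(query)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = genes & universe
        n = len(in_universe)
        ov = len(in_universe & query)
        p = float(hypergeom.sf(ov - 1, M, n, N)) if n else 1.0
        rows.append({"set": name, "set_size": n, "overlap": ov,
                     "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows).set_index("set")
    table["adj_p"] = benjamini_hochberg(table["p_value"])
    return table.sort_values("p_value", kind="stable")
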