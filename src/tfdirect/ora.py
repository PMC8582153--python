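"""Hypergeometric over-representation analysis against GMT gene-set collections.

For a query gene set of size n drawn from a universe of N genes, a
collection set of size K overlapping the query in k genes is scored by the
upper-tail hypergeometric probability P(X >= k); p-values are BH-adjusted
across the collection.  The universe is typically the expressed universe
(genes passing the CPM filter), not the whole annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from tfdirect.de import benjamini_hochberg


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with a declared universe.

    Sets that are empty after intersection with the universe are dropped
    with a warning.
    """

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty universe")
        trimmed: dict[str, set[str]] = {}
        dropped = []
        for name, genes in self.sets.items():
            inter = set(genes) & self.universe
            if inter:
                trimmed[name] = inter
            else:
                dropped.append(name)
        if dropped:
            warnings.warn(f"dropping {len(dropped)} set(s) empty after universe intersection")
        self.sets = trimmed


def read_gmt(path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Read GMT (name, description, genes...) into a GeneSetCollection."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return GeneSetCollection(sets=sets, universe=set(universe))


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(genes)) + "\n")


def hypergeometric_ora(query: set[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA of a query set against a collection.

    Query genes outside the universe are reported and dropped.  Returns a
    DataFrame indexed by set name with columns k (overlap), K (set size),
    n (query size), expected, p, adj_p, sorted by p.
    """
    if not query:
        raise ValueError("empty query set")
    outside = set(query) - collection.universe
    if outside:
        warnings.warn(f"dropping {len(outside)} query gene(s) outside the universe")
    q = set(query) & collection.universe
    if not q:
        raise ValueError("no query genes inside the universe")
    N = len(collection.universe)
    n = len(q)
    rows = []
    for name, genes in collection.sets.items():
        K = len(genes)
        k = len(q & genes)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, K * n / N, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "expected", "p"]
    ).set_index("set")
    out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
    return out.sort_values("p")
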