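"""Fisher's-exact gene-set overrepresentation against GMT libraries.

Given a query gene list (typically a DEG class), a gene-set library and a
background universe (by convention the expressed-gene set that the DEGs
were drawn from, not the whole genome), each term is scored with the
one-sided hypergeometric tail probability

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the term size within the universe, n the
query size within the universe and k the observed overlap. Benjamini-
Hochberg adjustment is applied across the tested terms of one library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetLibrary", "fisher_overrep", "enrich"]


@dataclass
class GeneSetLibrary:
    """Named collection of gene sets (a parsed GMT library)."""

    name: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def fisher_overrep(
    query: set[str], term: set[str], universe: set[str]
) -> tuple[int, int, int, int, float]:
    """One-sided overrepresentation test of ``query`` against ``term``.

    Both sets are intersected with the universe before counting. Returns
    (k, K, n, N, p) with p the upper hypergeometric tail P(X >= k),
    numerically stable for universes up to ~1e5 genes via the survival
    function. An empty query after intersection gives k=0, p=1 with a
    warning.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    q = query & universe
    t = term & universe
    if not q:
        warnings.warn("query is empty after universe intersection", stacklevel=2)
        return 0, len(t), 0, len(universe), 1.0
    k = len(q & t)
    K = len(t)
    n = len(q)
    N = len(universe)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, min(p, 1.0)


def enrich(
    query: set[str],
    library: GeneSetLibrary,
    universe: set[str],
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Overrepresentation of ``query`` against every term of a library.

    Terms with fewer than ``min_term_size`` genes inside the universe are
    not tested. ``overlap_pct`` is 100*k/K (fraction of the term covered,
    the convention of enrichment-browser displays); ``query_pct`` = 100*k/n
    is also provided. Rows are sorted by ascending p, ties by descending
    overlap_pct then term name; ``q`` is the BH-adjusted p across the
    tested terms.
    """
    if not library.sets:
        raise ValueError(f"library {library.name!r} is empty")
    if len(query) > len(universe):
        raise ValueError(
            f"query ({len(query)}) larger than universe ({len(universe)})"
        )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-query warning once, below
        q_in = query & universe
        for term_name, genes in library.sets.items():
            t = set(genes) & universe
            if len(t) < min_term_size:
                continue
            k, K, n, N, p = fisher_overrep(query, set(genes), universe)
            rows.append(
                {
                    "term": term_name,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "overlap_pct": 100.0 * k / K,
                    "query_pct": (100.0 * k / n) if n else 0.0,
                    "p": p,
                }
            )
    if not q_in:
        warnings.warn("query is empty after universe intersection", stacklevel=2)
    table = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "overlap_pct", "query_pct", "p"]
    )
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(
            ["p", "overlap_pct", "term"], ascending=[True, False, True]
        ).reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
    return table
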