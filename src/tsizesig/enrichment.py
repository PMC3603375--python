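"""Gene-set overrepresentation with the conservative EASE statistic.

The EASE score is the upper-tail hypergeometric probability recomputed
after removing one gene from the observed overlap: for an overlap of k
query genes with an m-gene set drawn against an N-gene universe, the
reported p is P(X >= k - 1) for a hypergeometric X with k - 1 successes
required — a deliberate penalization that keeps single-gene overlaps from
reaching significance (k <= 1 always gives p = 1).  Benjamini–Hochberg
adjustment is applied across all tested terms.

Gene sets are supplied by the user as GMT; the background universe
defaults to the genes present on the analyzed array, not the genome.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["ease_p", "hypergeom_p", "enrich"]

logger = logging.getLogger(__name__)


def hypergeom_p(k: int, m: int, n: int, N: int) -> float:
    """Plain upper-tail hypergeometric P(X >= k)."""
    _check_counts(k, m, n, N)
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def ease_p(k: int, m: int, n: int, N: int) -> float:
    """EASE score: hypergeometric tail with one overlap gene removed.

    Parameters: ``k`` observed overlap, ``m`` gene-set size, ``n`` query
    size, ``N`` universe size.  Returns P(X >= k - 1); ``k <= 1`` gives 1.
    """
    _check_counts(k, m, n, N)
    if k <= 1:
        return 1.0
    return float(hypergeom.sf(k - 2, N, m, n))


def _check_counts(k: int, m: int, n: int, N: int) -> None:
    if min(k, m, n, N) < 0 or k > min(m, n) or m > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, m={m}, n={n}, N={N}")


def enrich(query, collection: dict[str, set[str]], universe) -> pd.DataFrame:
    """Overrepresentation of ``query`` in each named gene set.

    Query genes outside the universe are dropped with a warning; gene-set
    members outside the universe do not count toward the set size.  One row
    per term with overlap >= 1, sorted by p ascending, with columns
    ``term``, ``overlap_genes``, ``count``, ``percent`` (of the query),
    ``p_value`` (EASE) and ``benjamini``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("enrich: %d query genes outside the universe dropped", len(outside))
        query &= universe
    N, n = len(universe), len(query)

    rows = []
    for term, members in collection.items():
        members_bg = members & universe
        overlap = sorted(members_bg & query)
        k, m = len(overlap), len(members_bg)
        if k < 1 or m == 0:
            continue
        rows.append({
            "term": term,
            "overlap_genes": overlap,
            "count": k,
            "percent": 100.0 * k / n if n else 0.0,
            "p_value": ease_p(k, m, n, N),
        })
    if not rows:
        return pd.DataFrame(columns=["term", "overlap_genes", "count", "percent",
                                     "p_value", "benjamini"])
    out = pd.DataFrame(rows)
    out["benjamini"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def write_enrichment_tsv(result: pd.DataFrame, path) -> None:
    """Write results mirroring the Term/Genes/Count/%/P/Benjamini layout."""
    flat = result.copy()
    flat["overlap_genes"] = flat["overlap_genes"].map(", ".join)
    flat.to_csv(path, sep="\t", index=False,
                columns=["term", "overlap_genes", "count", "percent", "p_value", "benjamini"])
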