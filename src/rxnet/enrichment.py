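"""Fisher's-exact gene-set over-representation.

For each term with K members in a universe of N genes, the overlap k
with a query of n genes is tested against the hypergeometric upper
tail P(X >= k) — the one-tailed Fisher exact test for
over-representation.  Corrected q-values default to
Benjamini-Hochberg across the tested terms (Bonferroni available).
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import InvalidInputError


def fisher_enrichment(
    query,
    terms: dict[str, set],
    universe,
    correction: str = "BH",
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One-tailed over-representation test per term.

    Term gene sets are intersected with the universe and the query
    must be a subset of it.  Returns rows (term, name, k, K, n, N, p,
    q) sorted by q then p ascending.
    """
    universe = set(universe)
    query = set(query)
    if not query or not universe:
        raise InvalidInputError("empty query or universe")
    if not query <= universe:
        raise InvalidInputError("query must be a subset of the universe")
    if correction not in {"BH", "bonferroni"}:
        raise InvalidInputError(f"unknown correction {correction!r}")
    N, n = len(universe), len(query)
    rows = []
    for term_id in sorted(terms):
        members = set(terms[term_id]) & universe
        K = len(members)
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term_id,
                "name": (term_names or {}).get(term_id, term_id),
                "k": k, "K": K, "n": n, "N": N,
                "p": min(1.0, p),
            }
        )
    df = pd.DataFrame(rows)
    method = "fdr_bh" if correction == "BH" else "bonferroni"
    df["q"] = multipletests(df["p"].to_numpy(), method=method)[1]
    return df.sort_values(["q", "p", "term"]).reset_index(drop=True)


def read_annotation(path: str) -> tuple[dict[str, set], dict[str, str]]:
    """Annotation TSV (term_id, term_name, gene) -> (term sets, names)."""
    df = pd.read_csv(path, sep="\t")
    terms: dict[str, set] = {}
    names: dict[str, str] = {}
    for row in df.itertuples():
        terms.setdefault(row.term_id, set()).add(row.gene)
        names[row.term_id] = getattr(row, "term_name", row.term_id)
    return terms, names


def write_enrichment(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
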