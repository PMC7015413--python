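"""Gene-set over-representation analysis.

One-sided hypergeometric tests of a query gene list against an annotated
background, from user-supplied gene -> term maps (GO terms or pathway
identifiers), with Benjamini-Hochberg q-values.  Term maps are flat:
no ontology hierarchy is traversed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def read_term_map(path) -> pd.DataFrame:
    """Two-column gene<TAB>term file."""
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "term"],
                       dtype=str, comment="#")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    Raises for p-values outside (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query_genes, term_map: pd.DataFrame, background_genes
           ) -> pd.DataFrame:
    """Hypergeometric over-representation of every term in the query.

    The background is restricted to annotated genes (those with at least
    one term); unannotated query genes are dropped with a logged count.
    For each term with K background genes, k query hits, query size n and
    background size N, the p-value is the upper tail P(X >= k) of the
    hypergeometric distribution.  Rows are sorted by ascending p (term id
    breaks ties) and carry BH q-values.
    """
    gene2terms: dict[str, set[str]] = {}
    for g, t in zip(term_map["gene"], term_map["term"]):
        gene2terms.setdefault(g, set()).add(t)

    background = set(background_genes) & set(gene2terms)
    query = set(query_genes)
    dropped = len(query - background)
    if dropped:
        log.info("%d query genes lack annotation or background membership; "
                 "dropped", dropped)
    query &= background
    if not query:
        raise ValueError("no annotated query genes: nothing to test")

    n_bg = len(background)
    n_q = len(query)
    term_bg: dict[str, int] = {}
    term_q: dict[str, int] = {}
    for g in background:
        for t in gene2terms[g]:
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in query:
                term_q[t] = term_q.get(t, 0) + 1

    rows = []
    for term in sorted(term_bg):
        big_k = term_bg[term]
        k = term_q.get(term, 0)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_q))
        p = min(p, 1.0)
        rows.append((term, k, big_k, n_q, n_bg, p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value"])
    df = df.sort_values(["p_value", "term"]).reset_index(drop=True)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df


def top_terms(rows: pd.DataFrame, limit: int = 20) -> pd.DataFrame:
    """First *limit* rows by ascending p-value, ties broken by term id."""
    return (rows.sort_values(["p_value", "term"])
            .head(limit)
            .reset_index(drop=True))


def significant_terms(rows: pd.DataFrame, alpha: float = 0.05,
                      on: str = "p_value") -> pd.DataFrame:
    """Rows with p (or q) below *alpha*."""
    if on not in ("p_value", "q_value"):
        raise ValueError("on must be 'p_value' or 'q_value'")
    return rows[rows[on] < alpha].reset_index(drop=True)


def write_enrichment_tsv(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
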