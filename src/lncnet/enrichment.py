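"""Hypergeometric over-representation and guilt-by-association function prediction.

The tail probability P(X >= k) is computed by exact integer summation of
the hypergeometric pmf, so small-universe results agree with enumeration
to machine precision.  The enrichment ratio is the observed overlap
fraction relative to its expectation, (k/n)/(K/N).

Function prediction assigns each differentially expressed lncRNA the
terms enriched (p < 0.05) in its co-expressed coding genes, pools all
(lncRNA, term, p) pairs, keeps the ``top_pairs`` most reliable by p, and
reports the ``top_terms`` most frequent terms among the kept pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .data_model import GeneSetCollection
from .differential import bh_adjust

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["set_id", "k", "n", "K", "N", "p_value", "q_value",
                      "ratio", "enriched"]


def hypergeom_tail_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), exactly.

    N genes in the universe, K of them in the set, n selected; k observed
    in the overlap.  Computed as an exact integer ratio of binomial sums.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    numerator = sum(comb(K, j) * comb(N - K, n - j)
                    for j in range(k, min(n, K) + 1) if n - j <= N - K)
    return numerator / comb(N, n)


def enrichment_ratio(k: int, n: int, K: int, N: int) -> float:
    """Fold enrichment (k/n)/(K/N): observed overlap over expectation."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must be positive")
    return (k / n) / (K / N)


def enrich_set(genes: Iterable[str], collection: GeneSetCollection,
               p_threshold: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``genes`` in every set of the collection.

    Symbols outside the collection's universe are dropped with a logged
    count.  Returns one record per set with counts (k, n, K, N), the
    exact tail p, the enrichment ratio, a BH q over the collection
    (reported for reference; the ``enriched`` flag uses raw p < threshold),
    sorted by ascending p with ties broken by set id.
    """
    genes = set(genes)
    inside = genes & collection.universe
    if len(inside) < len(genes):
        log.warning("enrich_set: dropped %d gene(s) outside the universe",
                    len(genes) - len(inside))
    if not inside:
        log.warning("enrich_set: empty gene set after universe restriction")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    N = len(collection.universe)
    n = len(inside)
    rows = []
    for set_id in collection.set_ids:
        members = collection.members(set_id)
        K = len(members)
        k = len(inside & members)
        rows.append((set_id, k, n, K, N,
                     hypergeom_tail_p(k, K, n, N),
                     enrichment_ratio(k, n, K, N)))
    records = pd.DataFrame(rows, columns=["set_id", "k", "n", "K", "N",
                                          "p_value", "ratio"])
    records["q_value"] = bh_adjust(records["p_value"].to_numpy())
    records["enriched"] = records["p_value"] < p_threshold
    return records.sort_values(["p_value", "set_id"], kind="mergesort",
                               ignore_index=True)[ENRICHMENT_COLUMNS]


@dataclass
class FunctionPrediction:
    """Guilt-by-association output: reliable pairs and frequent terms."""

    pairs: pd.DataFrame           # lncrna_id, set_id, p_value; ascending p
    term_frequency: dict[str, int]
    top_terms: list[str]


def predict_lncrna_functions(edges: pd.DataFrame, annot: pd.DataFrame,
                             collection: GeneSetCollection,
                             config: AnalysisConfig | None = None,
                             ) -> FunctionPrediction:
    """Predict lncRNA functions from their co-expressed coding genes.

    For each lncRNA in ``edges``, its passing co-expressed mRNA probes are
    mapped to gene symbols and tested against every term; pairs with
    p < enrich_p_threshold are pooled, sorted by ascending p (ties:
    lncRNA id, then term id) and truncated to ``top_pairs``.  Term
    frequencies are counted over the kept pairs and the ``top_terms``
    most frequent terms reported (ties: smaller minimum p, then term id).
    """
    config = config or AnalysisConfig()
    passing = edges[edges["passes"]] if len(edges) else edges
    if passing.empty:
        log.warning("predict_lncrna_functions: no passing co-expression edges")
        return FunctionPrediction(
            pd.DataFrame(columns=["lncrna_id", "set_id", "p_value"]), {}, [])
    all_pairs = []
    for lnc_id, fam in passing.groupby("lncrna_id", sort=True):
        genes = set(annot.loc[[m for m in fam["mrna_id"] if m in annot.index],
                              "gene_symbol"])
        records = enrich_set(genes, collection, config.enrich_p_threshold)
        hits = records[records["enriched"]]
        for _, row in hits.iterrows():
            all_pairs.append((lnc_id, row["set_id"], row["p_value"]))
    pairs = pd.DataFrame(all_pairs, columns=["lncrna_id", "set_id", "p_value"])
    pairs = pairs.sort_values(["p_value", "lncrna_id", "set_id"],
                              kind="mergesort", ignore_index=True)
    pairs = pairs.head(config.top_pairs)
    freq = pairs["set_id"].value_counts().to_dict()
    min_p = pairs.groupby("set_id")["p_value"].min()
    ranked = sorted(freq, key=lambda s: (-freq[s], min_p[s], s))
    return FunctionPrediction(pairs, freq, ranked[: config.top_terms])
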