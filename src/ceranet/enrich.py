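"""Hypergeometric over-representation of gene sets against term maps.

The kernel is the exact upper-tail hypergeometric probability computed in
log space, the same statistic the ceRNA screen applies to shared-miRNA
sets.  Significance is tiered at raw p < 0.05 ("significant") and
p < 0.01 ("highly significant"); no multiple-testing correction is applied
by default, though a Bonferroni option is provided.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ParameterError


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exactly, in log space.

    ``N`` is the universe size, ``K`` the number of marked items, ``n`` the
    draw size and ``k`` the observed number of marked draws.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N or min(K, n, k) < 0:
        raise ParameterError(
            f"inconsistent hypergeometric parameters N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    j = np.arange(k, min(K, n) + 1)
    log_terms = (
        _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _log_comb(n: int | np.ndarray, k: np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def assign_tier(p: float, p_significant: float = 0.05, p_strong: float = 0.01) -> str:
    if p < p_strong:
        return "highly_significant"
    if p < p_significant:
        return "significant"
    return "ns"


def enrich(
    study_genes: Iterable[str],
    background_genes: Iterable[str] | None,
    term_map: pd.DataFrame,
    p_significant: float = 0.05,
    p_strong: float = 0.01,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``study_genes`` in each term.

    ``term_map`` has columns ``term_id`` and ``gene_id``.  The background
    defaults to every gene appearing in the map; term genes outside the
    background are dropped (their count is recorded in
    ``result.attrs["n_dropped"]``).  Only terms with at least one study hit
    are reported, sorted by ascending p (ties broken by term id).  With
    ``bonferroni`` the tiers are assigned on p multiplied by the number of
    tested terms.
    """
    if not {"term_id", "gene_id"}.issubset(term_map.columns):
        raise ParameterError("term_map needs columns term_id and gene_id")
    if background_genes is None:
        background = set(term_map["gene_id"])
    else:
        background = set(background_genes)
    study = set(study_genes) & background
    N = len(background)
    rows = []
    n_dropped = 0
    terms = term_map.groupby("term_id", sort=True)["gene_id"]
    n_terms_tested = 0
    for term_id, genes in terms:
        gene_set = set(genes)
        n_dropped += len(gene_set - background)
        gene_set &= background
        if not gene_set:
            continue
        n_terms_tested += 1
        k = len(gene_set & study)
        if k == 0:
            continue
        p = hypergeom_upper_tail(N, len(gene_set), len(study), k)
        rows.append(
            {
                "term_id": term_id,
                "term_size": len(gene_set),
                "study_hits": k,
                "study_size": len(study),
                "background_size": N,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_size", "study_hits", "study_size",
            "background_size", "p_value",
        ],
    )
    if len(out):
        tier_p = out["p_value"] * (n_terms_tested if bonferroni else 1)
        out["tier"] = [assign_tier(p, p_significant, p_strong) for p in tier_p]
        out = out.sort_values(
            ["p_value", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        out["tier"] = pd.Series(dtype=str)
    out.attrs["n_dropped"] = n_dropped
    return out
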