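"""Gene-set enrichment of the candidate genes with the EASE score.

The EASE score is a conservative variant of the one-tailed Fisher /
hypergeometric enrichment test: one gene is removed from the list-term
overlap before computing the upper tail, penalizing terms supported by very
few genes.  With overlap k, list size n, term size K and background size N:

    ease_p = P(X >= k - 1),   X ~ Hypergeometric(N, K, n)

and the degenerate overlaps k = 0 and k = 1 score 1 by definition.  Terms
pass when EASE < ease_max and a Benjamini-Hochberg adjusted q-value <
fdr_max (strict inequalities).

The background universe defaults to the measured genes that carry at least
one annotation; the exact background used by annotation web services is an
external moving target, so numeric agreement with any given service release
is out of reach by design — the selection logic, not the service's frozen
database, is what is reproduced here.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSet

logger = logging.getLogger(__name__)


def ease_p(k: int, n: int, K: int, N: int) -> float:
    """EASE score: jackknifed one-tailed hypergeometric upper tail.

    Parameters are the overlap ``k``, gene-list size ``n``, term size in
    the background ``K`` and background size ``N``.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if k <= 1:
        return 1.0
    # P(X >= k-1) = sf(k-2)
    return float(hypergeom.sf(k - 2, N, K, n))


def fisher_enrich_p(k: int, n: int, K: int, N: int) -> float:
    """Plain (unjackknifed) one-tailed enrichment p, for comparison."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(candidates: Iterable[str], gene_sets: Sequence[GeneSet],
           background: Iterable[str] | None = None) -> pd.DataFrame:
    """EASE-score enrichment of ``candidates`` against every gene set.

    ``background`` defaults to the union of all gene-set members
    (annotated universe); candidates outside the background are ignored
    with a log message.  Returns one row per term with the contingency
    counts, ease_p and fdr_q.
    """
    candidates = set(candidates)
    if background is None:
        background = set().union(*(gs.members for gs in gene_sets))
    else:
        background = set(background)
    in_bg = candidates & background
    outside = len(candidates) - len(in_bg)
    if outside:
        logger.info("%d candidate gene(s) outside the background ignored",
                    outside)
    n = len(in_bg)
    N = len(background)
    rows = []
    for gs in gene_sets:
        term_bg = gs.members & background
        K = len(term_bg)
        k = len(term_bg & in_bg)
        if K == 0:
            continue
        rows.append({
            "term_id": gs.term_id,
            "term_name": gs.term_name,
            "k": k, "n": n, "K": K, "N": N,
            "ease_p": ease_p(k, n, K, N),
        })
    if not rows:
        raise ValueError("no term overlaps the background universe")
    df = pd.DataFrame(rows)
    df["fdr_q"] = bh_fdr(df["ease_p"])
    return df.sort_values("ease_p", kind="stable").reset_index(drop=True)


def significant_terms(results: pd.DataFrame, ease_max: float = 0.05,
                      fdr_max: float = 0.05) -> pd.DataFrame:
    """Terms with ease_p < ease_max AND fdr_q < fdr_max, best first."""
    keep = (results["ease_p"] < ease_max) & (results["fdr_q"] < fdr_max)
    out = (results[keep]
           .sort_values("ease_p", kind="stable")
           .reset_index(drop=True))
    if out.empty:
        logger.warning("no term passed ease_p < %g and fdr_q < %g",
                       ease_max, fdr_max)
    return out


def write_enrichment(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
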