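"""Mapping annotated gene pairs onto the galaxy classification.

For each enriched term, all unordered pairs of its annotated genes are
formed and looked up in the pair classification.  Only the group-specific
pairs enter the 2x2 table:

    a = mapped normal-specific strong pairs
    b = mapped normal-specific weak  pairs (= disease-specific strong)
    c = mapped disease-specific strong pairs
    d = mapped disease-specific weak  pairs (= normal-specific strong)

so b = c and a = d by construction — a normal-specific strong pair IS a
disease-specific weak pair.  Pairs strong or weak in both groups contribute
to no cell.  A one-sided Fisher exact test (alternative: a larger than
expected under fixed margins) asks whether the term has more
normal-specific strong pairs than disease-specific strong pairs; p-values
are Bonferroni-corrected by the number of tested terms.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from itertools import combinations

import pandas as pd
from scipy.stats import hypergeom

from .classify import (COMMON_STRONG, COMMON_WEAK, DISEASE_SPECIFIC_STRONG,
                       NORMAL_SPECIFIC_STRONG)
from .io import GeneSet

logger = logging.getLogger(__name__)


def annotated_pairs(gs: GeneSet,
                    analyzed_genes: Iterable[str]) -> list[tuple[str, str]]:
    """All unordered pairs of the term's genes that were analyzed.

    Pairs are returned in canonical (lexicographically sorted) order.
    """
    genes = sorted(gs.members & set(analyzed_genes))
    if len(genes) < 2:
        logger.warning("term %s: only %d analyzed gene(s); no pairs",
                       gs.term_id, len(genes))
        return []
    return list(combinations(genes, 2))


def contingency(pairs: Sequence[tuple[str, str]],
                classified: pd.DataFrame) -> tuple[int, int, int, int]:
    """Build the (a, b, c, d) table for a collection of annotated pairs.

    Every pair must be present in the classification; common (both-strong
    or both-weak) pairs are counted toward no cell.
    """
    cat_of = dict(zip(zip(classified["gene_i"], classified["gene_j"]),
                      classified["category"]))
    counts = {NORMAL_SPECIFIC_STRONG: 0, DISEASE_SPECIFIC_STRONG: 0,
              COMMON_STRONG: 0, COMMON_WEAK: 0}
    for pair in pairs:
        try:
            counts[cat_of[pair]] += 1
        except KeyError:
            raise ValueError(
                f"pair {pair} absent from the classification") from None
    a = counts[NORMAL_SPECIFIC_STRONG]
    c = counts[DISEASE_SPECIFIC_STRONG]
    # normal-specific weak == disease-specific strong and vice versa
    return a, c, c, a


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The alternative is that ``a`` is larger than expected under fixed
    margins; the p-value is the hypergeometric tail P(X >= a) with
    population a+b+c+d, a+b successes and a+c draws.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    return float(hypergeom.sf(a - 1, n, a + b, a + c))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, m * p)


def mapping_significance(p_bonferroni: float, alpha: float = 0.05) -> bool:
    """A term is significantly mapped when corrected p is strictly < alpha."""
    return p_bonferroni < alpha


def mapping_tests(terms: Sequence[GeneSet], classified: pd.DataFrame,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Run the full mapping analysis over a collection of enriched terms.

    The Bonferroni multiplier is the number of terms entering this stage.
    Terms with fewer than two analyzed genes yield no pairs and are
    reported with NaN p-values.
    """
    analyzed = set(classified["gene_i"]) | set(classified["gene_j"])
    m = len(terms)
    if m == 0:
        raise ValueError("no terms to test")
    rows = []
    for gs in terms:
        pairs = annotated_pairs(gs, analyzed)
        row = {"term_id": gs.term_id, "term_name": gs.term_name,
               "n_annotated_pairs": len(pairs)}
        if pairs:
            a, b, c, d = contingency(pairs, classified)
            if a + b + c + d > 0:
                p = fisher_one_sided(a, b, c, d)
                p_corr = bonferroni(p, m)
                row.update(a=a, b=b, c=c, d=d, p_one_sided=p,
                           p_bonferroni=p_corr,
                           significant=mapping_significance(p_corr, alpha))
            else:
                row.update(a=0, b=0, c=0, d=0, p_one_sided=float("nan"),
                           p_bonferroni=float("nan"), significant=False)
        else:
            row.update(a=0, b=0, c=0, d=0, p_one_sided=float("nan"),
                       p_bonferroni=float("nan"), significant=False)
        rows.append(row)
    return pd.DataFrame(rows)


def write_mapping(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
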