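"""Per-group absolute Pearson co-expression for all unordered gene pairs.

For genes i, j the co-expression level within a group is C(i,j) = |r| where
r is the Pearson correlation of the two expression profiles over that
group's samples only. The absolute value is taken because a strong
relationship in either the positive or the negative direction counts as
co-expression. Correlations are never pooled across groups: pooling would
confound between-group mean shifts with co-expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import DISEASE, NORMAL, ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_SAMPLES = 3  # a correlation over fewer points is meaningless


def abs_pearson(x, y) -> float:
    """Absolute Pearson correlation of two equal-length profiles.

    Raises on vectors shorter than three points or with zero variance
    (the correlation is undefined there; callers are expected to have
    filtered degenerate genes first).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D vectors")
    if x.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return abs(float(xc @ yc) / np.sqrt(vx * vy))


def drop_degenerate_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose profile is constant within either group."""
    keep = []
    for gene in m.gene_ids:
        row = m.values.loc[gene]
        degenerate = False
        for group in (NORMAL, DISEASE):
            vals = row[m.samples_in(group)].to_numpy(dtype=float)
            if np.ptp(vals) == 0.0:
                logger.info("dropping %s: constant in %s group", gene, group)
                degenerate = True
                break
        if not degenerate:
            keep.append(gene)
    if len(keep) < 2:
        raise ValueError("fewer than 2 genes with non-degenerate profiles")
    return m.subset_genes(keep)


def _group_abs_corr(values: pd.DataFrame) -> np.ndarray:
    """Upper-triangle |r| values for the rows of ``values`` (genes x samples)."""
    r = np.corrcoef(values.to_numpy(dtype=float))
    iu = np.triu_indices(r.shape[0], k=1)
    return np.abs(r[iu])


def pairwise_coexpression(m: ExpressionMatrix) -> pd.DataFrame:
    """Co-expression table over all g(g-1)/2 unordered gene pairs.

    Returns a DataFrame with columns ``gene_i``, ``gene_j`` (canonical
    lexicographic order, gene_i < gene_j), ``c_normal`` and ``c_disease``.
    """
    for group in (NORMAL, DISEASE):
        n = len(m.samples_in(group))
        if n < MIN_SAMPLES:
            raise ValueError(
                f"{group} group has {n} samples; need >= {MIN_SAMPLES}")
    # canonical order makes pair identity deterministic across runs
    genes = sorted(m.gene_ids)
    values = m.values.loc[genes]
    iu = np.triu_indices(len(genes), k=1)
    gene_arr = np.asarray(genes, dtype=object)
    table = pd.DataFrame({
        "gene_i": gene_arr[iu[0]],
        "gene_j": gene_arr[iu[1]],
        "c_normal": _group_abs_corr(values[m.samples_in(NORMAL)]),
        "c_disease": _group_abs_corr(values[m.samples_in(DISEASE)]),
    })
    if np.isnan(table[["c_normal", "c_disease"]].to_numpy()).any():
        raise ValueError("undefined correlation encountered; run "
                         "drop_degenerate_genes first")
    logger.info("computed co-expression for %d pairs of %d genes",
                len(table), len(genes))
    return table


def write_coexpression(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_coexpression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"gene_i": str, "gene_j": str})
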