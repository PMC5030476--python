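"""Consensus selection of miRNA target genes by database vote.

Candidate targets of a miRNA cluster are chosen in two steps: per mature
miRNA, keep genes predicted by at least ``min_databases`` of the prediction
databases covering that miRNA (default 4, matching the at-least-4-of-5
vote); then take the union over all cluster members. Prediction tables are
consumed as frozen local files — database contents drift over time, so live
querying is deliberately unsupported.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

MIR_17_92 = (
    "miR-17-5p", "miR-17-3p", "miR-18a", "miR-19a",
    "miR-20a", "miR-19b", "miR-92-1",
)


def read_predictions(path) -> pd.DataFrame:
    """Read a TSV of columns mirna_id, database_name, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "database_name", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.drop_duplicates()


def consensus_per_mirna(predictions: pd.DataFrame, mirna: str,
                        min_databases: int = 4) -> set[str]:
    """Genes predicted for ``mirna`` by at least ``min_databases`` databases.

    A gene counts once per database regardless of how many transcript
    entries mention it. Only databases that cover the miRNA at all take
    part in the vote.
    """
    sub = predictions[predictions["mirna_id"] == mirna]
    databases = set(sub["database_name"])
    if len(databases) < min_databases:
        raise ValueError(
            f"{mirna}: only {len(databases)} database(s) available, "
            f"need at least {min_databases}")
    votes = (sub.drop_duplicates(["database_name", "gene_id"])
             .groupby("gene_id")["database_name"].nunique())
    return set(votes.index[votes >= min_databases])


def cluster_candidates(
        consensus_sets: dict[str, set[str]]) -> dict[str, set[str]]:
    """Union of per-miRNA consensus sets, with supporting-miRNA provenance.

    Returns a mapping gene -> set of miRNAs that voted for it; the candidate
    gene set is the mapping's keys.
    """
    if not any(consensus_sets.values()):
        raise ValueError("all consensus sets are empty")
    support: dict[str, set[str]] = {}
    for mirna, genes in consensus_sets.items():
        for gene in genes:
            support.setdefault(gene, set()).add(mirna)
    logger.info("cluster candidates: %d genes from %d miRNAs",
                len(support), len(consensus_sets))
    return support


def restrict_to_measured(candidates: set[str],
                         m: ExpressionMatrix) -> set[str]:
    """Candidates actually measured on the array."""
    measured = set(candidates) & set(m.gene_ids)
    if not measured:
        raise ValueError("no candidate gene is present in the expression "
                         "matrix; cannot proceed")
    logger.info("restricted %d candidates to %d measured genes",
                len(candidates), len(measured))
    return measured
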