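"""End-to-end orchestration of the co-expression galaxy analysis.

Stages: read expression (collapse probes if a probe map is given) ->
optional miRNA-target consensus -> per-group co-expression -> cutoff
detection -> pair classification -> optional enrichment -> optional pair
mapping.  When no prediction tables are supplied the gene universe is all
measured genes, so the statistical core is usable beyond the original
miRNA-cluster use case; when no gene sets are supplied the run stops after
the galaxy summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import classify, coexpression, cutoff, enrichment, io, mapping, targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    expression_path: str
    groups_path: str
    out_dir: str
    probe_map_path: str | None = None
    predictions_path: str | None = None
    gene_sets_path: str | None = None
    gene_sets_format: str = "gmt"
    mirnas: tuple[str, ...] = targets.MIR_17_92
    min_databases: int = 4
    ks_alpha: float = 0.05
    ease_max: float = 0.05
    fdr_max: float = 0.05
    mapping_alpha: float = 0.05
    background: str = "annotated"  # or "all-measured"
    make_plots: bool = True

    def __post_init__(self) -> None:
        for label, p in [("expression", self.expression_path),
                         ("groups", self.groups_path)]:
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        for p in (self.probe_map_path, self.predictions_path,
                  self.gene_sets_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        for label, v in [("ks_alpha", self.ks_alpha),
                         ("ease_max", self.ease_max),
                         ("fdr_max", self.fdr_max),
                         ("mapping_alpha", self.mapping_alpha)]:
            if not 0.0 < v < 1.0:
                raise ValueError(f"{label} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "mirnas" in payload:
            payload["mirnas"] = tuple(payload["mirnas"])
        return cls(**payload)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of result objects.

    Artifacts written under ``cfg.out_dir``: the pair table, cutoff JSON,
    classification TSV, galaxy summary JSON, enrichment and mapping TSVs
    (when gene sets are given), plots, and a run log of thresholds.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    groups = io.read_groups(cfg.groups_path)
    m = io.read_expression(cfg.expression_path, groups)
    if cfg.probe_map_path:
        m = io.collapse_probes(m, io.read_probe_map(cfg.probe_map_path))
    m = io.drop_missing_genes(m)

    if cfg.predictions_path:
        preds = targets.read_predictions(cfg.predictions_path)
        consensus = {mir: targets.consensus_per_mirna(preds, mir,
                                                      cfg.min_databases)
                     for mir in cfg.mirnas}
        support = targets.cluster_candidates(consensus)
        measured = targets.restrict_to_measured(set(support), m)
        m = m.subset_genes(measured)
        report["candidate_support"] = {g: sorted(support[g])
                                       for g in sorted(measured)}

    m = coexpression.drop_degenerate_genes(m)
    table = coexpression.pairwise_coexpression(m)
    coexpression.write_coexpression(table, out / "pairs.tsv")

    cut = cutoff.detect_cutoff(table, cfg.ks_alpha)
    cut.to_json(out / "cutoff.json")
    report["cutoff"] = cut

    classified = classify.classify_pairs(table, cut.C)
    classified.to_csv(out / "pair_classification.tsv", sep="\t", index=False)
    summary = classify.galaxy_summary(classified)
    classify.write_summary(summary, out / "galaxy_summary.json")
    report["galaxy"] = summary

    if cfg.make_plots:
        cutoff.plot_exceedance(table, cut, out / "exceedance.png")
        classify.galaxy_plot(classified, cut.C, out / "galaxy.png")

    if cfg.gene_sets_path:
        gene_sets = io.read_gene_sets(cfg.gene_sets_path,
                                      cfg.gene_sets_format)
        background = (set(m.gene_ids) if cfg.background == "all-measured"
                      else None)
        enr = enrichment.enrich(m.gene_ids, gene_sets, background)
        enrichment.write_enrichment(enr, out / "enrichment.tsv")
        report["enrichment"] = enr
        sig = enrichment.significant_terms(enr, cfg.ease_max, cfg.fdr_max)
        sig_ids = set(sig["term_id"])
        sig_sets = [gs for gs in gene_sets if gs.term_id in sig_ids]
        if sig_sets:
            mapped = mapping.mapping_tests(sig_sets, classified,
                                           cfg.mapping_alpha)
            mapping.write_mapping(mapped, out / "mapping.tsv")
            report["mapping"] = mapped
        else:
            logger.warning("no significant terms; mapping stage skipped")
    else:
        logger.info("no gene sets supplied; stopping after classification")

    with open(out / "run_log.json", "w") as fh:
        json.dump({
            "version": __version__,
            "n_genes": m.n_genes,
            "n_pairs": len(table),
            "ks_alpha": cfg.ks_alpha,
            "ease_max": cfg.ease_max,
            "fdr_max": cfg.fdr_max,
            "mapping_alpha": cfg.mapping_alpha,
            "min_databases": cfg.min_databases,
            "cutoff": {"D": cut.D, "C": cut.C,
                       "D_critical": cut.D_critical,
                       "significant": cut.significant},
        }, fh, indent=2)
    return report
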