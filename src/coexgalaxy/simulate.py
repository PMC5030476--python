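"""Synthetic two-group expression data with planted block correlation.

Each gene belongs to a correlation block or is unstructured noise.  Within
group g, a gene of block b is drawn from a single-factor model

    x = sqrt(rho_bg) * z + sqrt(1 - rho_bg) * e

with z a per-sample block factor shared by the block's genes and e
independent standard Gaussian noise, so two same-block genes have
population correlation exactly rho_bg in that group while cross-block and
noise genes are uncorrelated.  Setting rho_disease = 0 for a block models
co-expression lost in disease.  Sample-size defaults (8 normal, 9 disease)
mirror a typical small two-group microarray study; at that scale sample
|r| values are extremely noisy and per-pair category calls should not be
over-trusted — use more samples for recovery experiments.

All randomness flows from the explicit seed through one generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import math

import numpy as np
import pandas as pd

from .classify import category_from_flags
from .io import DISEASE, NORMAL, ExpressionMatrix, GeneSet


@dataclass(frozen=True)
class Block:
    """A planted correlation block."""

    block_id: str
    n_genes: int
    rho_normal: float
    rho_disease: float

    def __post_init__(self) -> None:
        for rho in (self.rho_normal, self.rho_disease):
            if not 0.0 <= rho < 1.0:
                raise ValueError(
                    f"block {self.block_id}: rho must lie in [0, 1), "
                    f"got {rho}")
        if self.n_genes < 1:
            raise ValueError(f"block {self.block_id}: n_genes must be >= 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Design of a synthetic two-group dataset."""

    blocks: tuple[Block, ...]
    n_noise_genes: int = 0
    n_normal_samples: int = 8
    n_disease_samples: int = 9
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory; no implicit entropy")
        total = sum(b.n_genes for b in self.blocks) + self.n_noise_genes
        if total < 2:
            raise ValueError("need at least 2 genes in total")
        ids = [b.block_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ValueError("block ids must be unique")

    @property
    def n_genes(self) -> int:
        return sum(b.n_genes for b in self.blocks) + self.n_noise_genes


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    gene_block: pd.Series  # gene_id -> block_id, or "" for noise genes
    block_rho: pd.DataFrame  # block_id -> rho_normal, rho_disease

    def within_block_pairs(self) -> pd.DataFrame:
        """All same-block gene pairs with their planted correlations."""
        rows = []
        for block_id, genes in self.gene_block.groupby(self.gene_block):
            if not block_id:
                continue
            rho_n = self.block_rho.loc[block_id, "rho_normal"]
            rho_d = self.block_rho.loc[block_id, "rho_disease"]
            for gi, gj in combinations(sorted(genes.index), 2):
                rows.append({"gene_i": gi, "gene_j": gj,
                             "block_id": block_id,
                             "rho_normal": rho_n, "rho_disease": rho_d})
        return pd.DataFrame(
            rows, columns=["gene_i", "gene_j", "block_id",
                           "rho_normal", "rho_disease"])


def _sample_group(rng: np.random.Generator, cfg: SyntheticConfig,
                  group: str, n_samples: int) -> np.ndarray:
    rows = []
    for block in cfg.blocks:
        rho = block.rho_normal if group == NORMAL else block.rho_disease
        z = rng.standard_normal(n_samples)
        e = rng.standard_normal((block.n_genes, n_samples))
        rows.append(math.sqrt(rho) * z + math.sqrt(1.0 - rho) * e)
    if cfg.n_noise_genes:
        rows.append(rng.standard_normal((cfg.n_noise_genes, n_samples)))
    return np.vstack(rows)


def generate_dataset(
        cfg: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a synthetic dataset; deterministic for a given config."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids, block_of = [], []
    for block in cfg.blocks:
        for i in range(block.n_genes):
            gene_ids.append(f"{block.block_id}_g{i:03d}")
            block_of.append(block.block_id)
    for i in range(cfg.n_noise_genes):
        gene_ids.append(f"noise_g{i:03d}")
        block_of.append("")

    normal = _sample_group(rng, cfg, NORMAL, cfg.n_normal_samples)
    disease = _sample_group(rng, cfg, DISEASE, cfg.n_disease_samples)
    samples = ([f"normal_{i:02d}" for i in range(cfg.n_normal_samples)]
               + [f"disease_{i:02d}" for i in range(cfg.n_disease_samples)])
    groups = {s: (NORMAL if s.startswith("normal") else DISEASE)
              for s in samples}
    values = pd.DataFrame(np.hstack([normal, disease]),
                          index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples)
    truth = SyntheticTruth(
        gene_block=pd.Series(block_of, index=gene_ids, name="block_id"),
        block_rho=pd.DataFrame(
            {"rho_normal": [b.rho_normal for b in cfg.blocks],
             "rho_disease": [b.rho_disease for b in cfg.blocks]},
            index=pd.Index([b.block_id for b in cfg.blocks],
                           name="block_id")))
    return ExpressionMatrix(values, groups), truth


def planted_pair_categories(truth: SyntheticTruth,
                            threshold: float) -> pd.DataFrame:
    """Expected galaxy category of every within-block pair at a threshold.

    Mirrors the classification truth table on the planted correlations:
    a pair is expected strong in a group when its block's rho in that
    group is >= threshold.
    """
    pairs = truth.within_block_pairs()
    pairs["expected_category"] = [
        category_from_flags(rn >= threshold, rd >= threshold)
        for rn, rd in zip(pairs["rho_normal"], pairs["rho_disease"])]
    return pairs


def synthetic_gene_sets(truth: SyntheticTruth, n_terms: int, seed: int,
                        min_size: int = 4,
                        max_size: int | None = None) -> list[GeneSet]:
    """Draw annotation terms over the synthetic genes.

    Terms are biased toward block genes (each term samples within one
    randomly chosen block plus a sprinkling of other genes) so that
    downstream mapping tests see non-trivial contingency tables.
    """
    rng = np.random.default_rng(seed)
    all_genes = np.asarray(truth.gene_block.index)
    blocks = [b for b in truth.block_rho.index]
    if max_size is None:
        max_size = max(min_size, len(all_genes) // 2)
    sets = []
    for t in range(n_terms):
        size = int(rng.integers(min_size, max_size + 1))
        if blocks:
            block_id = blocks[int(rng.integers(len(blocks)))]
            block_genes = np.asarray(
                truth.gene_block.index[truth.gene_block == block_id])
            n_block = min(len(block_genes), max(2, size // 2))
            chosen = set(rng.choice(block_genes, n_block, replace=False))
        else:
            chosen = set()
        rest = np.asarray([g for g in all_genes if g not in chosen])
        n_rest = min(len(rest), size - len(chosen))
        if n_rest > 0:
            chosen |= set(rng.choice(rest, n_rest, replace=False))
        sets.append(GeneSet(f"TERM{t:03d}", f"synthetic term {t}",
                            frozenset(chosen)))
    return sets


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the gene -> block assignment and block correlations as TSV."""
    df = truth.gene_block.to_frame()
    df = df.join(truth.block_rho, on="block_id")
    df.to_csv(path, sep="\t", index_label="gene_id")
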