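"""Reading and writing expression matrices, probe maps and gene sets.

Expression data arrive as a TSV with one row per gene (or probe), one column
per sample, plus a two-level group assignment (``normal`` / ``disease``).
Probe-level matrices are collapsed to gene level by averaging all probes that
interrogate the same mRNA, on the already-normalized intensity scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

NORMAL = "normal"
DISEASE = "disease"
GROUP_LABELS = (NORMAL, DISEASE)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of genes (one annotation term)."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} has no members")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized intensities with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or probe) id, columns are sample ids.
    groups
        Mapping from sample id to ``"normal"`` or ``"disease"``. Every
        column of ``values`` must be covered, and both groups must be
        non-empty.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dups}")
        cols = self.values.columns
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups}")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing from group assignment: {missing}")
        bad = {s: g for s, g in self.groups.items()
               if s in cols and g not in GROUP_LABELS}
        if bad:
            raise ValueError(
                f"group labels must be one of {GROUP_LABELS}, got {bad}")
        # restrict to samples actually present, preserving column order
        self.groups = {s: self.groups[s] for s in cols}
        for label in GROUP_LABELS:
            if label not in self.groups.values():
                raise ValueError(f"group {label!r} has no samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def group_values(self, group: str) -> pd.DataFrame:
        """Submatrix of the columns belonging to one group."""
        return self.values[self.samples_in(group)]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Matrix restricted to ``genes`` (order: current row order)."""
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], dict(self.groups))


def read_expression(path, group_spec: dict[str, str]) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = gene/probe id).

    Every sample column must appear in ``group_spec``. Non-numeric cells
    and duplicated sample columns are rejected with their coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.columns.duplicated().any():
        dup = sorted(set(raw.columns[raw.columns.duplicated()]))
        raise ValueError(f"{path}: duplicated sample column(s) {dup}")
    try:
        values = raw.astype(float)
    except ValueError:
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & raw.notna()
        r, c = next(zip(*bad.values.nonzero()))
        raise ValueError(
            f"{path}: non-numeric cell at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}: {raw.iat[r, c]!r}") from None
    m = ExpressionMatrix(values, dict(group_spec))
    logger.info("read %d rows x %d samples from %s",
                m.n_genes, len(m.sample_ids), path)
    return m


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_groups(path) -> dict[str, str]:
    """Read a two-column sample_id <TAB> group file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                     dtype=str)
    return dict(zip(df["sample"], df["group"]))


def write_groups(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_probe_map(path) -> dict[str, str]:
    """Two-column TSV probe_id <TAB> gene_id; each probe maps to one gene."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"],
                     dtype=str)
    if df["probe"].duplicated().any():
        dups = sorted(set(df.loc[df["probe"].duplicated(), "probe"]))
        raise ValueError(f"{path}: probes mapped more than once: {dups}")
    return dict(zip(df["probe"], df["gene"]))


def collapse_probes(m: ExpressionMatrix,
                    probe_map: dict[str, str]) -> ExpressionMatrix:
    """Average all probe rows interrogating the same gene, per sample.

    Every probe row must be present in ``probe_map``; unmapped probes are
    an error rather than being silently dropped.
    """
    unmapped = [p for p in m.gene_ids if p not in probe_map]
    if unmapped:
        raise ValueError(f"probes absent from probe map: {sorted(unmapped)}")
    gene_of = pd.Series({p: probe_map[p] for p in m.gene_ids})
    collapsed = m.values.groupby(gene_of).mean()
    logger.info("collapsed %d probes to %d genes", m.n_genes,
                collapsed.shape[0])
    return ExpressionMatrix(collapsed, dict(m.groups))


def drop_missing_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with any missing value; correlations need complete rows."""
    keep = m.values.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d genes with missing values", dropped)
    out = m.values.loc[keep]
    if out.shape[0] < 2:
        raise ValueError("fewer than 2 genes with complete data")
    return ExpressionMatrix(out, dict(m.groups))


def read_gene_sets(path, format: str = "gmt") -> list[GeneSet]:
    """Read gene sets from GMT or two-column (term <TAB> gene) TSV.

    GMT lines are ``term <TAB> description <TAB> gene1 <TAB> gene2 ...``.
    Duplicate members are removed; terms left with no members are dropped
    with a warning.
    """
    if format not in ("gmt", "two-column"):
        raise ValueError(f"unknown gene-set format {format!r}")
    sets: list[GeneSet] = []
    if format == "gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: malformed GMT line "
                        f"(need term, description, members)")
                term, desc, members = parts[0], parts[1], parts[2:]
                members = frozenset(g for g in members if g)
                if not members:
                    logger.warning("%s:%d: term %r has no members; dropped",
                                   path, lineno, term)
                    continue
                sets.append(GeneSet(term, desc or term, members))
    else:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["term", "gene"], dtype=str)
        if df.isna().any(axis=None):
            bad = int(df.isna().any(axis=1).idxmax()) + 1
            raise ValueError(f"{path}:{bad}: malformed two-column line")
        for term, sub in df.groupby("term", sort=False):
            members = frozenset(sub["gene"])
            sets.append(GeneSet(str(term), str(term), members))
    logger.info("read %d gene sets from %s", len(sets), path)
    return sets


def write_gene_sets(sets: list[GeneSet], path) -> None:
    """Write gene sets in GMT format."""
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.term_id}\t{gs.term_name}\t{members}\n")
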