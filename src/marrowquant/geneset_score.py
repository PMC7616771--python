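"""Per-cell gene-set expression-fraction scores on UMI count matrices.

A cell's score for a gene set (ECM, chemokine, niche-support-factor lists) is
the fraction of its UMIs falling on the *expressed* members of the set:

    score(cell) = sum(counts over expressed set genes) / sum(counts over all genes)

where a set gene counts as expressed when its total UMI count summed over all
cells of the compartment (hematopoietic or stromal, filtered independently)
reaches ``min_total_umis`` (default 50).  The denominator is deliberately the
*unfiltered* total of the cell, so scores are bounded in [0, 1] and invariant
to global rescaling of a cell's counts.  Cells with zero total counts get a
missing score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import group_stats

logger = logging.getLogger(__name__)


@dataclass
class UmiCounts:
    """Sparse genes x cells UMI count matrix with cell annotations.

    ``cell_groups`` carries one label per cell (e.g. control vs disease);
    ``compartment`` tags which expressed-gene filtering universe the matrix
    belongs to (``"hematopoietic"`` or ``"stromal"``).
    """

    matrix: sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_groups: np.ndarray | None = None
    compartment: str = "stromal"

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match gene/cell id lengths")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("UMI counts must be non-negative")
        if self.cell_groups is not None:
            self.cell_groups = np.asarray(self.cell_groups)
            if self.cell_groups.shape != (len(self.cell_ids),):
                raise ValueError("cell_groups must have one label per cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @classmethod
    def from_mtx_dir(cls, path: str | Path, groups_csv: str | Path | None = None,
                     compartment: str = "stromal") -> "UmiCounts":
        """Read matrix.mtx + features.tsv + barcodes.tsv (CellRanger layout).

        ``groups_csv`` optionally maps cell_id -> group (and compartment)."""
        path = Path(path)
        matrix = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
        genes = pd.read_csv(path / "features.tsv", sep="\t", header=None
                            )[0].astype(str).tolist()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None
                            )[0].astype(str).tolist()
        groups = None
        if groups_csv is not None:
            gdf = pd.read_csv(groups_csv).set_index("cell_id")
            groups = gdf.loc[cells, "group"].to_numpy()
            if "compartment" in gdf.columns:
                compartment = str(gdf["compartment"].iloc[0])
        return cls(matrix, genes, cells, cell_groups=groups,
                   compartment=compartment)

    def to_mtx_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(self.matrix))
        pd.Series(self.gene_ids).to_csv(path / "features.tsv", sep="\t",
                                        header=False, index=False)
        pd.Series(self.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                        header=False, index=False)


@dataclass
class GeneSet:
    """A named gene list, optionally with a category per gene
    (e.g. collagen / glycoprotein / proteoglycan for ECM sets)."""

    name: str
    gene_ids: list[str]
    categories: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene set must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene set ids must be unique")

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        """Two-column CSV: gene_id[, category]."""
        df = pd.read_csv(path)
        if "gene_id" not in df.columns:
            raise ValueError("gene-set CSV needs a 'gene_id' column")
        cats = (dict(zip(df["gene_id"], df["category"]))
                if "category" in df.columns else None)
        return cls(name or Path(path).stem, df["gene_id"].astype(str).tolist(),
                   categories=cats)


@dataclass
class ScoreConfig:
    """Expressed-gene filter settings: a set gene must reach ``min_total_umis``
    summed over all cells of the compartment to enter the numerator."""

    min_total_umis: int = 50

    def __post_init__(self) -> None:
        if self.min_total_umis < 0:
            raise ValueError("min_total_umis must be non-negative")


@dataclass
class ScoreVector:
    """Per-cell scores in [0, 1] (NaN for zero-count cells) with provenance."""

    scores: np.ndarray
    cell_ids: list[str]
    geneset_name: str
    expressed_genes: list[str]
    config: ScoreConfig = field(default_factory=ScoreConfig)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids,
                             f"{self.geneset_name}_score": self.scores})


def filter_expressed_genes(counts: UmiCounts, geneset: GeneSet,
                           config: ScoreConfig | None = None) -> list[str]:
    """Set genes whose compartment-wide UMI total reaches the threshold.

    Genes in the set but absent from the matrix are dropped with a warning.
    Order of the returned list follows the gene set.
    """
    config = config or ScoreConfig()
    index = {g: i for i, g in enumerate(counts.gene_ids)}
    missing = [g for g in geneset.gene_ids if g not in index]
    if missing:
        logger.warning("%d/%d gene-set genes absent from the matrix (e.g. %s)",
                       len(missing), len(geneset.gene_ids), missing[:3])
    present = [g for g in geneset.gene_ids if g in index]
    if not present:
        return []
    totals = np.asarray(
        counts.matrix[[index[g] for g in present], :].sum(axis=1)).ravel()
    return [g for g, t in zip(present, totals) if t >= config.min_total_umis]


def score_cells(counts: UmiCounts, expressed_genes: list[str],
                geneset_name: str = "geneset",
                config: ScoreConfig | None = None) -> ScoreVector:
    """Per-cell set fraction: expressed-set UMIs / all UMIs of the cell.

    The denominator is the unfiltered per-cell total; zero-total cells score
    NaN (they are upstream QC failures, not zeros).
    """
    config = config or ScoreConfig()
    index = {g: i for i, g in enumerate(counts.gene_ids)}
    unknown = [g for g in expressed_genes if g not in index]
    if unknown:
        raise ValueError(f"expressed genes not in matrix: {unknown[:5]}")
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel().astype(float)
    if expressed_genes:
        rows = [index[g] for g in expressed_genes]
        set_sum = np.asarray(counts.matrix[rows, :].sum(axis=0)).ravel().astype(float)
    else:
        set_sum = np.zeros(counts.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(totals > 0, set_sum / np.maximum(totals, 1), np.nan)
    return ScoreVector(scores, counts.cell_ids, geneset_name,
                       list(expressed_genes), config)


def score_geneset(counts: UmiCounts, geneset: GeneSet,
                  config: ScoreConfig | None = None) -> ScoreVector:
    """Convenience: expressed-gene filter then per-cell scoring."""
    expressed = filter_expressed_genes(counts, geneset, config)
    return score_cells(counts, expressed, geneset_name=geneset.name,
                       config=config)


def count_expressed_set_genes(counts: UmiCounts, geneset: GeneSet,
                              config: ScoreConfig | None = None,
                              ) -> dict[str, int]:
    """How many set genes pass the expressed filter, overall and per category.

    Mirrors compartment-level summaries such as "N ECM genes expressed by the
    stroma, of which k collagens".  Requires categories when the set has them;
    returns ``{"total": n, "<category>": n_c, ...}``.
    """
    expressed = filter_expressed_genes(counts, geneset, config)
    out = {"total": len(expressed)}
    if geneset.categories is not None:
        known = set(geneset.categories.values())
        for g in expressed:
            if g not in geneset.categories:
                raise ValueError(f"gene {g!r} has no category label")
        for cat in sorted(known):
            out[cat] = sum(1 for g in expressed if geneset.categories[g] == cat)
    return out


def compare_score_groups(scores: ScoreVector, cell_groups: np.ndarray,
                         adjust: str = "bh") -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum between cell-group score
    distributions, with multiplicity adjustment across pairs.

    Missing (NaN) scores are dropped per group; a group with no usable scores
    raises.  Returns one row per group pair with medians, direction, U, p and
    adjusted p.
    """
    cell_groups = np.asarray(cell_groups)
    if cell_groups.shape != scores.scores.shape:
        raise ValueError("cell_groups must align with scores")
    by_group: dict[str, np.ndarray] = {}
    for g in pd.unique(cell_groups):
        vals = scores.scores[cell_groups == g]
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 non-missing scores")
        by_group[str(g)] = vals

    rows = []
    for ga, gb in itertools.combinations(by_group, 2):
        res = group_stats.wilcoxon_rank_sum(by_group[ga], by_group[gb])
        rows.append({
            "group_a": ga, "group_b": gb,
            "n_a": by_group[ga].size, "n_b": by_group[gb].size,
            "median_a": float(np.median(by_group[ga])),
            "median_b": float(np.median(by_group[gb])),
            "mean_a": float(np.mean(by_group[ga])),
            "mean_b": float(np.mean(by_group[gb])),
            "direction": "a>b" if np.median(by_group[ga]) > np.median(by_group[gb])
                         else ("a<b" if np.median(by_group[ga]) < np.median(by_group[gb])
                               else "a=b"),
            "statistic": res.statistic, "p": res.p, "method": res.method,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = group_stats.adjust_pvalues(df["p"].to_numpy(),
                                                      method=adjust)
    return df
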