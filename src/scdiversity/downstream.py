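"""Group differential expression and gene-set signature scoring.

Compares tumor cells from diversity-high vs diversity-low tumors gene by
gene with a two-sided Wilcoxon rank-sum test (BH-adjusted), and scores gene
programs (e.g. stem-cell differentiation) as the per-cell mean of z-scored
expression over the set — a transparent stand-in for heavier gene-set
variation machinery.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import NormalizedMatrix

__all__ = ["STEMNESS_GENES", "read_gmt", "group_de", "signature_score"]

# Stemness-associated genes repeatedly elevated in diversity-high tumor cells
# (progenitor markers plus YAP-linked stem regulators).
STEMNESS_GENES: tuple[str, ...] = (
    "ICAM1", "SOX4", "ALDH1A1", "BMI1", "SOX9", "SMAD2", "MYC",
    "EPCAM", "KRT19", "PROM1", "CD24",
)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def group_de(
    norm: NormalizedMatrix,
    groups: np.ndarray,
    group_a: str = "high",
    group_b: str = "low",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-gene rank-sum test of ``group_a`` vs ``group_b`` cells.

    Log fold change is the natural log of the ratio of group means of
    normalized (pre-log) expression, with a pseudocount of 1 on the
    counts-per-scale_total scale. Two-sided p-values, BH-adjusted.
    """
    groups = np.asarray(groups)
    a = np.flatnonzero(groups == group_a)
    b = np.flatnonzero(groups == group_b)
    if len(a) < min_cells or len(b) < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells per group, got {len(a)} {group_a!r} / "
            f"{len(b)} {group_b!r}"
        )
    linear = norm.linear()
    mean_a = linear[:, a].mean(axis=1)
    mean_b = linear[:, b].mean(axis=1)
    lfc = np.log((mean_a + 1.0) / (mean_b + 1.0))

    values = np.asarray(norm.values, dtype=float)
    stat, p = stats.mannwhitneyu(
        values[:, a], values[:, b], axis=1, alternative="two-sided", method="asymptotic"
    )
    p_adj = multipletests(p, method="fdr_bh")[1]
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    return pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "lfc": lfc,
            "statistic": stat,
            "p_value": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    )


def signature_score(norm: NormalizedMatrix, gene_set) -> pd.Series:
    """Per-cell mean of z-scored (across cells) expression of the set genes.

    Genes absent from the matrix are dropped with a warning; an empty
    intersection is an error (the score of nothing is undefined, not zero).
    Constant genes contribute a flat zero.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in set(norm.gene_ids)]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} set genes absent from matrix: {missing[:10]}")
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    X = np.asarray(norm.values[norm.gene_index(present)], dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(Z.mean(axis=0), index=pd.Index(norm.barcodes, name="barcode"))
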