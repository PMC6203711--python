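"""Differential expression on log2 expression matrices.

Implements the expression arm of the analysis: per-gene mean-centering for
heat-map display, two-group differential-expression calling (Welch t-test
with a fold-change gate on the log2 scale), paired tumor/normal testing
with Benjamini-Hochberg FDR, and unsupervised hierarchical clustering of
samples on correlation distance.

Fold changes are differences of log2 values, so a ">= 2-fold" rule means
``|delta log2| >= 1``.  Abundance inputs (e.g. FPKM) should be
``log2(x + 1)``-transformed first (:func:`log_transform`).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.cluster import hierarchy as _h
from scipy.spatial.distance import squareform

from . import stats
from .io import IntegrityError

__all__ = ["normalize_to_gene_mean", "log_transform", "de_genes", "paired_de",
           "hierarchical_cluster"]


def log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount) transform for abundance-scale inputs."""
    if (matrix.values < 0).any():
        raise ValueError("abundance matrix must be non-negative")
    return np.log2(matrix + pseudocount)


def normalize_to_gene_mean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each gene on its cross-sample mean (values already log scale).

    Output row means are zero; applying the operation twice is a no-op.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to center")
    return matrix.sub(matrix.mean(axis=1), axis=0)


def _welch_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t-test; returns (t, df, two-sided p).

    Degenerate rows (zero variance in both groups) get t=0, p=1 when the
    means agree and +-inf t, p=0 otherwise, mirroring the scalar
    conventions in :mod:`nashsom.stats`.
    """
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(m1 == m2, 0.0, np.inf * np.sign(m1 - m2)), t)
    df = np.where(degenerate, n1 + n2 - 2, df)
    p = 2.0 * _sps.t.sf(np.abs(t), df)
    p = np.where(degenerate & (m1 == m2), 1.0, p)
    return t, df, np.minimum(p, 1.0)


def de_genes(matrix: pd.DataFrame, groups: Mapping[str, str],
             fold_min: float = 2.0, alpha: float = 0.05
             ) -> tuple[list[str], list[str], pd.DataFrame]:
    """Two-group differential expression on a log2 matrix.

    A gene is *up* when its group-1-minus-group-2 mean difference is at
    least ``log2(fold_min)`` (inclusive) with Welch p < ``alpha``; *down*
    symmetrically.  Group 1 is the alphabetically first label.  Returns
    (up list, down list, full per-gene table).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    g1 = [s for s in matrix.columns if groups.get(s) == labels[0]]
    g2 = [s for s in matrix.columns if groups.get(s) == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 samples per group")
    t, df, p = _welch_rows(matrix[g1].to_numpy(), matrix[g2].to_numpy())
    diff = matrix[g1].mean(axis=1) - matrix[g2].mean(axis=1)
    cut = np.log2(fold_min)
    table = pd.DataFrame({
        "log2fc": diff, "t": t, "df": df, "p": p,
        "up": (diff >= cut) & (p < alpha),
        "down": (diff <= -cut) & (p < alpha),
    }, index=matrix.index)
    table.attrs["test"] = "Welch t-test"
    up = list(table.index[table["up"]])
    down = list(table.index[table["down"]])
    return up, down, table


def paired_de(matrix: pd.DataFrame, pairing: Mapping[str, str],
              alpha: float = 0.05, fdr_max: float = 0.15
              ) -> tuple[list[str], pd.DataFrame]:
    """Paired tumor-vs-normal differential expression with BH adjustment.

    ``pairing`` maps each tumor column to its matched normal column and
    must form a perfect matching over the matrix columns.  Genes are
    reported when raw paired-t p < ``alpha`` and BH-adjusted p <=
    ``fdr_max``; with ``fdr_max=1`` the criterion reduces to the raw-p
    rule.
    """
    tumors = list(pairing)
    normals = [pairing[t] for t in tumors]
    cols = tumors + normals
    if len(set(cols)) != len(cols):
        raise IntegrityError("pairing reuses a sample")
    missing = set(cols) - set(matrix.columns)
    if missing or set(matrix.columns) - set(cols):
        raise IntegrityError("pairing is not a perfect matching of matrix columns")
    if len(tumors) < 2:
        raise ValueError("need at least 2 pairs")
    d = matrix[tumors].to_numpy() - matrix[normals].to_numpy()
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
    p = 2.0 * _sps.t.sf(np.abs(t), n - 1)
    p = np.minimum(np.where(degenerate & (mean == 0), 1.0, p), 1.0)
    fdr = stats.bh_adjust(p)
    table = pd.DataFrame({"mean_diff": mean, "t": t, "p": p, "fdr": fdr,
                          "selected": (p < alpha) & (fdr <= fdr_max)},
                         index=matrix.index)
    return list(table.index[table["selected"]]), table


def hierarchical_cluster(matrix: pd.DataFrame
                         ) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of samples, 1 - Pearson correlation, average
    linkage.

    Samples are pre-sorted by id before linkage so the result is invariant
    to input column order; ties in merge height then resolve
    deterministically.  Returns (scipy linkage matrix, leaf-order sample
    ids).  A zero-variance sample has no defined correlation and raises.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    cols = sorted(matrix.columns)
    X = matrix[cols].to_numpy()
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = cols[int(np.argmax(sds == 0))]
        raise ValueError(f"sample {bad!r} has zero variance; correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)   # symmetrize rounding noise
    linkage = _h.linkage(squareform(dist, checks=False), method="average")
    order = _h.leaves_list(linkage)
    return linkage, [cols[i] for i in order]
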