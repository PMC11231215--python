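"""Mutual-information co-expression network inference with top-k pruning.

One expression matrix (genes x samples, log-scale abundances) yields one
undirected weighted network per phenotype: MI is estimated for every gene
pair with an equal-frequency-binning plug-in estimator (Miller-Madow bias
corrected, natural log), pairs are ranked by MI, and the top k edges are
retained.  No data-processing-inequality filtering is applied: the goal is
a co-expression network, not a regulatory-network approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples table of log-scale abundances for one phenotype.

    Parameters
    ----------
    genes : list of str
        Unique gene identifiers (row names).
    samples : list of str
        Sample identifiers (column names).
    values : ndarray, shape (n_genes, n_samples)
        Log-scale expression values; no missing entries allowed.
    phenotype : str
        Label of the phenotype the samples belong to.
    """

    genes: list
    samples: list
    values: np.ndarray
    phenotype: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        if len(self.samples) < 3:
            raise ValueError("need at least 3 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("missing or non-finite values are not accepted")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, phenotype: str = "") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            raise ValueError(f"{path}: missing values are not accepted")
        return cls(
            genes=[str(g) for g in df.index],
            samples=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            phenotype=phenotype,
        )


@dataclass(frozen=True)
class ScoredPair:
    """An unordered gene pair with its mutual information in nats."""

    gene_a: str
    gene_b: str
    mi: float

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("self-pairs are not allowed")
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)


@dataclass
class WeightedNetwork:
    """Undirected simple graph of genes with MI edge weights after pruning."""

    edges: pd.DataFrame  # columns gene_a, gene_b, mi; canonical gene_a < gene_b
    phenotype: str = ""
    k_retained: int = 0

    def __post_init__(self):
        e = self.edges
        if (e["gene_a"] == e["gene_b"]).any():
            raise ValueError("self-loops are not allowed")
        swap = e["gene_a"] > e["gene_b"]
        if swap.any():
            a = e["gene_a"].where(~swap, e["gene_b"])
            b = e["gene_b"].where(~swap, e["gene_a"])
            self.edges = e.assign(gene_a=a, gene_b=b)
        if self.edges.duplicated(["gene_a", "gene_b"]).any():
            raise ValueError("duplicate edges are not allowed")

    @property
    def nodes(self) -> list:
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return set(zip(self.edges["gene_a"], self.edges["gene_b"]))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_weighted_edges_from(
            self.edges[["gene_a", "gene_b", "mi"]].itertuples(index=False, name=None),
            weight="weight",
        )
        return g

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, phenotype: str = "") -> "WeightedNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        return cls(edges=df, phenotype=phenotype, k_retained=len(df))

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


# ---------------------------------------------------------------------------
# pair counting
# ---------------------------------------------------------------------------


def n_possible_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs, n*(n-1)/2.

    For a 15,267-gene transcriptome this is 116,533,011 potential edges.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    return n_genes * (n_genes - 1) // 2


def retained_fraction_percent(k: int, n_pairs: int) -> float:
    """Percentage of pairs kept by a top-k cutoff, truncated to two decimals."""
    pct = 100.0 * k / n_pairs
    return np.floor(pct * 100) / 100


# ---------------------------------------------------------------------------
# discretization and MI estimation
# ---------------------------------------------------------------------------


def default_bins(n_samples: int) -> int:
    """Default equal-frequency bin count, max(2, floor(sqrt(n)/2))."""
    return max(2, int(np.floor(np.sqrt(n_samples) / 2)))


def quantile_bin(values, n_bins: int):
    """Equal-frequency (quantile) discretization by rank.

    Ties are broken by stable original order, so bin occupancies differ by
    at most one.  A constant vector is degenerate: every sample lands in
    bin 0 and the flag is set; its MI with anything is 0 downstream.

    Returns
    -------
    labels : ndarray of int
    degenerate : bool
    """
    values = np.asarray(values)
    n = len(values)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if n < n_bins:
        raise ValueError("need at least n_bins samples")
    if np.all(values == values[0]):
        return np.zeros(n, dtype=np.int64), True
    order = np.argsort(values, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    return rank * n_bins // n, False


def _entropy_and_support(counts: np.ndarray, n: int):
    p = counts[counts > 0] / n
    return -np.sum(p * np.log(p)), int((counts > 0).sum())


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Miller-Madow-corrected plug-in MI between two vectors, in nats.

    Both vectors are quantile-binned, the joint contingency table gives the
    plug-in estimate H(X)+H(Y)-H(X,Y), each entropy is bias-corrected by
    (support-1)/(2n), and the result is clamped at 0.  Symmetric in its
    arguments; a constant input gives exactly 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n_bins is None:
        n_bins = default_bins(n)
    if n < n_bins**2:
        warnings.warn(
            f"only {n} samples for {n_bins}x{n_bins} bins; MI estimate is noisy",
            stacklevel=2,
        )
    bx, dx = quantile_bin(x, n_bins)
    by, dy = quantile_bin(y, n_bins)
    if dx or dy:
        return 0.0
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins)
    hx, mx = _entropy_and_support(np.bincount(bx, minlength=n_bins), n)
    hy, my = _entropy_and_support(np.bincount(by, minlength=n_bins), n)
    hxy, mxy = _entropy_and_support(joint, n)
    mi = hx + hy - hxy + (mx + my - mxy - 1) / (2 * n)
    return max(mi, 0.0)


def _bin_matrix(matrix: ExpressionMatrix, n_bins: int):
    """Quantile-bin every gene; returns labels (g x n), marginal entropies,
    supports, and the degenerate-gene mask."""
    g, n = matrix.n_genes, matrix.n_samples
    labels = np.empty((g, n), dtype=np.int64)
    h = np.empty(g)
    m = np.empty(g, dtype=np.int64)
    degen = np.zeros(g, dtype=bool)
    for i in range(g):
        labels[i], degen[i] = quantile_bin(matrix.values[i], n_bins)
        h[i], m[i] = _entropy_and_support(np.bincount(labels[i], minlength=n_bins), n)
    return labels, h, m, degen


def all_pairs_mi(
    matrix: ExpressionMatrix,
    n_bins: int | None = None,
    block_size: int = 256,
) -> pd.DataFrame:
    """MI for every unordered gene pair of one expression matrix.

    Pairs are processed in row blocks: per block pair the joint contingency
    tables of all gene pairs are accumulated with one matrix product per
    joint bin cell, which bounds memory at O(block_size^2 * n_bins^2) while
    remaining fully vectorized.  Output rows are in canonical order
    (i < j by row index) and deterministic.

    Returns
    -------
    DataFrame with columns gene_a, gene_b, mi — exactly n*(n-1)/2 rows.
    """
    n = matrix.n_samples
    if n_bins is None:
        n_bins = default_bins(n)
    g = matrix.n_genes
    labels, h_marg, m_marg, degen = _bin_matrix(matrix, n_bins)

    # one-hot indicators per bin: ind[u] is (g x n)
    ind = [(labels == u).astype(np.float64) for u in range(n_bins)]

    starts = list(range(0, g, block_size))
    out_i = []
    out_j = []
    out_mi = []
    for bi, si in enumerate(starts):
        ei = min(si + block_size, g)
        for sj in starts[bi:]:
            ej = min(sj + block_size, g)
            na, nb = ei - si, ej - sj
            neg_hxy = np.zeros((na, nb))
            mxy = np.zeros((na, nb), dtype=np.int64)
            for u in range(n_bins):
                iu = ind[u][si:ei]
                for v in range(n_bins):
                    c = iu @ ind[v][sj:ej].T  # joint counts for cell (u, v)
                    nz = c > 0
                    p = np.where(nz, c, 1.0) / n
                    neg_hxy += np.where(nz, p * np.log(p), 0.0)
                    mxy += nz
            mi = (
                h_marg[si:ei, None]
                + h_marg[None, sj:ej]
                + neg_hxy
                + (m_marg[si:ei, None] + m_marg[None, sj:ej] - mxy - 1) / (2 * n)
            )
            np.maximum(mi, 0.0, out=mi)
            if degen[si:ei].any() or degen[sj:ej].any():
                mi[degen[si:ei], :] = 0.0
                mi[:, degen[sj:ej]] = 0.0
            ii, jj = np.meshgrid(
                np.arange(si, ei), np.arange(sj, ej), indexing="ij"
            )
            keep = ii < jj
            out_i.append(ii[keep])
            out_j.append(jj[keep])
            out_mi.append(mi[keep])
    idx_a = np.concatenate(out_i)
    idx_b = np.concatenate(out_j)
    mi_all = np.concatenate(out_mi)
    order = np.lexsort((idx_b, idx_a))  # canonical row order, block-independent
    idx_a, idx_b, mi_all = idx_a[order], idx_b[order], mi_all[order]
    gene_arr = np.asarray(matrix.genes, dtype=object)
    return pd.DataFrame(
        {"gene_a": gene_arr[idx_a], "gene_b": gene_arr[idx_b], "mi": mi_all}
    )


def top_k_threshold(pairs: pd.DataFrame, k: int, phenotype: str = "") -> WeightedNetwork:
    """Keep the k highest-MI pairs (ties at the k-th value are all kept).

    Nodes of the resulting network are the genes incident to at least one
    retained edge, so the node count is typically below the input gene
    count when k is a small fraction of all pairs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the {len(pairs)} available pairs")
    mi = pairs["mi"].to_numpy()
    kth = np.partition(mi, len(mi) - k)[len(mi) - k]
    kept = pairs[mi >= kth].sort_values(
        ["mi", "gene_a", "gene_b"], ascending=[False, True, True]
    )
    # canonicalize orientation (gene_a < gene_b lexicographically)
    swap = kept["gene_a"] > kept["gene_b"]
    kept = kept.assign(
        gene_a=kept["gene_a"].where(~swap, kept["gene_b"]),
        gene_b=kept["gene_b"].where(~swap, kept["gene_a"]),
    ).reset_index(drop=True)
    return WeightedNetwork(edges=kept, phenotype=phenotype, k_retained=k)
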