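"""Overrepresentation analysis (ORA) of communities against gene sets.

Each retained community is tested for overlap with every annotation term
by the exact hypergeometric upper tail; p-values are corrected per
community with Benjamini-Hochberg, and a community counts as *enriched*
when any term reaches q < alpha.  An optional permutation mode resamples
random gene sets of the same size as a cross-check of the exact tail.

The testing universe is the intersection of the network's genes with the
annotation universe: community membership is conditional on surviving the
top-k pruning, so the background must be too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = [
    "community",
    "term",
    "description",
    "k",
    "K",
    "n",
    "N",
    "p_value",
    "q_value",
]


@dataclass
class AnnotationDB:
    """Gene-set database: term id -> (description, gene set), plus the
    annotation universe (GMT-compatible)."""

    terms: dict  # term id -> (description, frozenset of genes)
    universe: frozenset

    def __post_init__(self):
        self.universe = frozenset(self.universe)
        clean = {}
        for tid, (desc, genes) in self.terms.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"term {tid} has no genes")
            if not genes <= self.universe:
                raise ValueError(f"term {tid} has genes outside the universe")
            clean[tid] = (desc, genes)
        self.terms = clean

    def __len__(self):
        return len(self.terms)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for tid, (desc, genes) in self.terms.items():
                fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")

    @classmethod
    def from_gmt(cls, path, universe=None) -> "AnnotationDB":
        terms = {}
        seen = set()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:60]!r}")
                tid, desc, genes = parts[0], parts[1], parts[2:]
                terms[tid] = (desc, frozenset(genes))
                seen.update(genes)
        return cls(terms, frozenset(universe) if universe is not None else frozenset(seen))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the term size, n the community size, and k
    the observed overlap.  Computed from log-gamma factorials for
    numerical stability.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError("term or community larger than the universe")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _permutation_tail(community, term_genes, universe, k_obs, n_perm, rng):
    universe = sorted(universe)
    n = len(community)
    hits = 0
    term_genes = set(term_genes)
    for _ in range(n_perm):
        draw = rng.choice(len(universe), size=n, replace=False)
        k = sum(1 for i in draw if universe[i] in term_genes)
        hits += k >= k_obs
    return (hits + 1) / (n_perm + 1)


def ora_community(
    community_genes,
    db: AnnotationDB,
    universe=None,
    community_label: str = "",
    min_term_size: int = 3,
    min_overlap: int = 1,
    method: str = "exact",
    n_perm: int = 1000,
    rng=None,
) -> pd.DataFrame:
    """Test one community against every term of the database.

    Results carry the (k, K, n, N) counts restricted to the universe, the
    hypergeometric upper-tail p-value (or a resampling estimate when
    ``method='permutation'``), and BH q-values over this community's term
    family.  Terms with overlap below ``min_overlap`` or fewer than
    ``min_term_size`` universe genes are not tested.
    """
    universe = frozenset(universe) if universe is not None else db.universe
    if not universe:
        raise ValueError("empty universe")
    community = frozenset(community_genes) & universe
    if not community:
        raise ValueError("community has no genes in the universe")
    N = len(universe)
    n = len(community)
    rows = []
    for tid in sorted(db.terms):
        desc, genes = db.terms[tid]
        term_u = genes & universe
        K = len(term_u)
        if K < min_term_size:
            continue
        k = len(community & term_u)
        if k < min_overlap:
            continue
        if method == "exact":
            p = hypergeom_upper_tail(k, K, n, N)
        elif method == "permutation":
            rng = rng if rng is not None else np.random.default_rng(0)
            p = _permutation_tail(community, term_u, universe, k, n_perm, rng)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((community_label, tid, desc, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    df["q_value"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    return df


def ora_all_communities(
    community_set, db: AnnotationDB, universe=None, **kwargs
) -> pd.DataFrame:
    """ORA for every community of a CommunitySet; one concatenated table."""
    frames = []
    for comm in community_set:
        genes = frozenset(comm.genes) & (
            frozenset(universe) if universe is not None else db.universe
        )
        if not genes:
            continue
        frames.append(
            ora_community(
                comm.genes, db, universe, community_label=comm.label, **kwargs
            )
        )
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def significant_terms(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Map community label -> set of terms with q < alpha."""
    sig = results[results["q_value"] < alpha]
    return {
        label: set(group["term"]) for label, group in sig.groupby("community")
    }


def select_communities_by_terms(
    results: pd.DataFrame, keywords, alpha: float = 0.05
) -> set:
    """Communities with at least one significant term whose description
    matches any keyword (case-insensitive substring).

    An auditable replacement for manual curation of, e.g., inflammation-
    and immune-response-related communities.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    kws = [k.lower() for k in keywords]
    sig = results[results["q_value"] < alpha]
    match = sig["description"].str.lower().apply(
        lambda d: any(k in d for k in kws)
    )
    return set(sig.loc[match, "community"])


def exclusive_terms(significant_by_network: dict) -> dict:
    """Terms significant in exactly one network, keyed by that network.

    Input maps network label -> set of significant term ids (union over
    its communities); requires at least two networks.
    """
    if len(significant_by_network) < 2:
        raise ValueError("need at least 2 networks")
    out = {}
    for name, terms in significant_by_network.items():
        others = set().union(
            *(t for n, t in significant_by_network.items() if n != name)
        )
        out[name] = set(terms) - others
    return out


def significance_matrix(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Binary community x term matrix of significant enrichments
    (heatmap-ready)."""
    sig = results[results["q_value"] < alpha]
    if not len(sig):
        return pd.DataFrame()
    mat = pd.crosstab(sig["community"], sig["term"])
    return (mat > 0).astype(int)
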