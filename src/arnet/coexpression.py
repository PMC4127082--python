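"""Weighted gene coexpression network construction and module detection.

The network is unsigned: adjacency a_ij = |cor(g_i, g_j)|^beta with the
soft-threshold power beta chosen for approximate scale-free topology. Gene
similarity is the topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,  k_i = sum_{j != i} a_ij,

and modules are branches of the average-linkage dendrogram of 1 - TOM cut
at an adaptive height and validated by cohesion (within-branch overlap
must clearly exceed overlap with the rest of the network). Unassigned
genes are "grey".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._types import ExpressionMatrix

#: deterministic size-ranked module palette; "grey" is reserved for unassigned
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]

GREY = "grey"


@dataclass
class CoexpressionNetwork:
    """Adjacency, TOM, and connectivity for one soft-threshold power."""

    beta: float
    adjacency: pd.DataFrame  # diagonal defined as 1
    tom: pd.DataFrame  # diagonal defined as 1
    connectivity: pd.Series  # k_i = off-diagonal row sums of adjacency
    scale_free_fit: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.adjacency.index


@dataclass
class ModuleAssignment:
    """Gene -> module partition with the dendrogram it came from."""

    labels: pd.Series  # gene id -> color name; "grey" = unassigned
    module_sizes: pd.Series  # color -> count, descending
    linkage_matrix: np.ndarray
    gene_order: pd.Index

    def genes_in(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    @property
    def modules(self) -> list[str]:
        return [m for m in self.module_sizes.index if m != GREY]


def _values(expr) -> tuple[pd.DataFrame, pd.Index]:
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    return df, df.index


def preprocess_expression(raw, log2: bool = True):
    """Log2 transform then quantile-normalize an expression matrix.

    After normalization every sample (column) carries an identical multiset
    of values — the mean of the per-sample sorted vectors — while within-
    sample ranks are preserved. ``log2=False`` skips the log step for data
    already on a log-like scale (e.g. the simulator's output).
    """
    df, _ = _values(raw)
    x = df.to_numpy(dtype=float)
    if log2:
        if (x <= 0).any():
            bad = np.argwhere(x <= 0)[:5]
            where = ", ".join(f"({df.index[i]}, {df.columns[j]})" for i, j in bad)
            raise ValueError(f"log2 requires strictly positive values; offending entries: {where}")
        x = np.log2(x)

    ref = np.sort(x, axis=0).mean(axis=1)
    ranks = pd.DataFrame(x).rank(method="average", axis=0).to_numpy() - 1.0
    normed = np.interp(ranks, np.arange(len(ref)), ref)
    out = pd.DataFrame(normed, index=df.index, columns=df.columns)
    if isinstance(raw, ExpressionMatrix):
        return ExpressionMatrix(out, raw.genes)
    return out


def _abs_correlation(df: pd.DataFrame, method: str = "pearson") -> np.ndarray:
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = df.index[sd == 0][:5].tolist()
        raise ValueError(f"constant gene(s) have undefined correlation: {bad}")
    if method == "spearman":
        x = pd.DataFrame(x).rank(axis=1).to_numpy()
    r = np.corrcoef(x)
    return np.clip(np.abs(r), 0.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """(R^2, slope) of the log-log frequency vs connectivity fit.

    Connectivities are binned into equal-width bins; the fit regresses
    log10(bin frequency) on log10(bin mean connectivity). Approximate
    scale-free topology shows a high R^2 with a negative slope.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or k.min() == k.max():
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    means = np.array([k[which == b].mean() if freq[b] else np.nan for b in range(n_bins)])
    keep = (freq > 0) & (means > 0)
    if keep.sum() < 3:
        return 0.0, 0.0
    lx, ly = np.log10(means[keep]), np.log10(freq[keep])
    slope, _ = np.polyfit(lx, ly, 1)
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r * r), float(slope)


def pick_soft_threshold(
    expr,
    candidate_powers=tuple(range(1, 13)),
    r2_threshold: float = 0.8,
    fallback_power: float = 6.0,
    method: str = "pearson",
) -> tuple[float, pd.DataFrame]:
    """Choose the soft-threshold power for approximate scale-free topology.

    For each candidate power the connectivity distribution of the implied
    adjacency is summarized by its scale-free fit R^2; the smallest power
    whose fit has R^2 >= ``r2_threshold`` with a negative slope is chosen,
    falling back to ``fallback_power`` when none qualifies.
    """
    candidate_powers = list(candidate_powers)
    if len(candidate_powers) < 3:
        raise ValueError("need at least 3 candidate powers")
    df, genes = _values(expr)
    if len(genes) < 20:
        raise ValueError("need at least 20 genes to assess scale-free topology")
    absr = _abs_correlation(df, method=method)
    np.fill_diagonal(absr, 0.0)

    rows = []
    for power in candidate_powers:
        a = absr**power
        k = a.sum(axis=0)
        r2, slope = scale_free_fit(k)
        rows.append({"power": power, "r_squared": r2, "slope": slope,
                     "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[(table["r_squared"] >= r2_threshold) & (table["slope"] < 0)]
    beta = float(ok["power"].iloc[0]) if len(ok) else float(fallback_power)
    return beta, table


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap of a symmetric adjacency with entries in [0, 1].

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj; the diagonal is defined as 1.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=0)
    l_mat = a @ a  # zero diagonal makes (A @ A)_ij exactly l_ij
    tom = (l_mat + a) / (np.minimum.outer(k, k) + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def compute_tom(expr, beta: float, method: str = "pearson") -> CoexpressionNetwork:
    """Build the weighted network and its topological overlap matrix."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    df, genes = _values(expr)
    a = _abs_correlation(df, method=method) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    tom = tom_from_adjacency(a)

    adjacency = a.copy()
    np.fill_diagonal(adjacency, 1.0)
    return CoexpressionNetwork(
        beta=float(beta),
        adjacency=pd.DataFrame(adjacency, index=genes, columns=genes),
        tom=pd.DataFrame(tom, index=genes, columns=genes),
        connectivity=pd.Series(k, index=genes, name="connectivity"),
    )


def detect_modules(
    network: CoexpressionNetwork,
    min_module_size: int = 30,
    cut_span: float = 0.99,
    cohesion_ratio: float = 3.0,
) -> ModuleAssignment:
    """Cut the TOM dendrogram into modules, validating branches by cohesion.

    Average-linkage clustering is applied to the dissimilarity 1 - TOM and
    the tree is cut at an adaptive height ``cut_span`` of the way from the
    5th-percentile merge height to the maximum, which tracks the network's
    own scale (higher soft-threshold powers compress all heights toward 1).
    A resulting cluster becomes a module when it holds at least
    ``min_module_size`` genes and is cohesive: its mean within-cluster
    topological overlap must exceed ``cohesion_ratio`` times its mean
    overlap with the rest of the genes. Arbitrary slices of uncorrelated
    genes have a ratio near 1 and are rejected, so pure-noise input yields
    no modules. Leftover genes join the module they cohere with under the
    same ratio rule; the rest are grey. Labels are color names ranked by
    descending module size.
    """
    if min_module_size < 2:
        raise ValueError(f"min_module_size must be >= 2, got {min_module_size}")
    if not 0.0 < cut_span <= 1.0:
        raise ValueError(f"cut_span must lie in (0, 1], got {cut_span}")
    tom = network.tom.to_numpy()
    if not np.isfinite(tom).all():
        raise ValueError("TOM contains non-finite entries")
    genes = network.tom.index
    n = len(genes)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)

    labels = np.full(n, -1, dtype=int)
    if n == 1:
        z = np.empty((0, 4))
        found: list[np.ndarray] = []
    else:
        z = linkage(squareform(dissim, checks=False), method="average")
        heights = z[:, 2]
        low, high = float(np.quantile(heights, 0.05)), float(heights.max())
        # the 1e-9 floor keeps a numerically flat tree (all genes identical
        # up to rounding) in one cluster instead of splitting it arbitrarily
        cut = max(low + cut_span * (high - low), 1e-9)
        raw = fcluster(z, t=cut, criterion="distance")
        found = []
        all_idx = np.arange(n)
        for c in np.unique(raw):
            members = np.where(raw == c)[0]
            if len(members) < min_module_size:
                continue
            inside = tom[np.ix_(members, members)]
            within = (inside.sum() - len(members)) / (len(members) * (len(members) - 1))
            outside = np.setdiff1d(all_idx, members, assume_unique=True)
            if len(outside) == 0:
                found.append(members)
                continue
            between = tom[np.ix_(members, outside)].mean()
            if within >= cohesion_ratio * between:
                found.append(members)

    for mi, members in enumerate(found):
        labels[members] = mi

    # leftover genes join the module they cohere with, by the same ratio rule
    if found:
        all_idx = np.arange(n)
        for gi in np.where(labels == -1)[0]:
            sims = np.array([tom[gi, m].mean() for m in found])
            best = int(np.argmax(sims))
            rest = np.setdiff1d(all_idx, np.append(found[best], gi), assume_unique=False)
            if len(rest) == 0 or sims[best] >= cohesion_ratio * tom[gi, rest].mean():
                labels[gi] = best
    modules = [np.where(labels == mi)[0] for mi in range(len(found))]

    order = sorted(
        range(len(modules)),
        key=lambda mi: (-(labels == mi).sum(), str(genes[min(modules[mi])])),
    )
    color_of = {}
    for rank, mi in enumerate(order):
        color_of[mi] = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
    named = pd.Series(
        [color_of.get(l, GREY) for l in labels], index=genes, name="module"
    )
    sizes = named.value_counts()
    ordered_sizes = sizes.reindex(
        [c for c in [color_of[mi] for mi in order] if c in sizes.index]
        + ([GREY] if GREY in sizes.index else [])
    )
    return ModuleAssignment(
        labels=named,
        module_sizes=ordered_sizes.astype(int),
        linkage_matrix=z,
        gene_order=genes,
    )


def randomize(expr, mode: str, seed: int):
    """Randomized-expression negative controls.

    ``labels`` permutes gene identifiers only (values untouched), breaking
    the gene-annotation link; ``values`` independently permutes each gene's
    values across samples, destroying inter-gene correlation.
    """
    df, genes = _values(expr)
    rng = np.random.default_rng(seed)
    if mode == "labels":
        perm = rng.permutation(len(genes))
        out = pd.DataFrame(df.to_numpy(), index=genes[perm], columns=df.columns)
    elif mode == "values":
        x = df.to_numpy().copy()
        for i in range(x.shape[0]):
            x[i] = x[i, rng.permutation(x.shape[1])]
        out = pd.DataFrame(x, index=genes, columns=df.columns)
    else:
        raise ValueError(f"unknown randomization mode {mode!r}; use 'labels' or 'values'")
    if isinstance(expr, ExpressionMatrix):
        return ExpressionMatrix(out, expr.genes)
    return out
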