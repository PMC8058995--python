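"""Weighted coexpression network over miRNAs: soft threshold selection,
adjacency and topological overlap, module detection with eigengenes,
subnetwork export, miRNA-target correlation, and hypergeometric set
enrichment.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with the
soft-thresholding power beta (default 12).  The topological overlap
matrix is

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with k the connectivity (adjacency row sums, diagonal excluded) and
TOM_ii = 1.  Modules come from average-linkage clustering of 1 - TOM with
a static tree cut and a minimum module size; modules whose eigengenes
(first principal component of the standardized module expression, signed
to track the mean profile) correlate above 1 - merge_height are merged.
Module names follow the conventional colour palette by descending size;
unassigned nodes are grey.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

MODULE_COLOURS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
]


@dataclass(frozen=True)
class NetworkParams:
    beta: int = 12
    scale_free_r2_target: float = 0.8
    min_module_size: int = 10
    merge_height: float = 0.25
    static_cut_height: float = 0.98

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be a positive integer")


@dataclass
class CoexpressionNetwork:
    nodes: list[str]
    adjacency: np.ndarray
    tom: np.ndarray
    params: NetworkParams
    modules: pd.Series | None = None  # node -> colour
    eigengenes: pd.DataFrame | None = None  # sample x module colour


def correlate_pairs(
    mirna_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    negative_threshold: float = 0.0,
) -> pd.DataFrame:
    """Pearson correlation over matched sample columns for miRNA-target pairs."""
    common = [c for c in mirna_expr.columns if c in target_expr.columns]
    if len(common) < 3:
        raise ValueError("need at least 3 matched samples to correlate")
    rows = []
    for mir, tgt in pairs:
        r = float(np.corrcoef(
            mirna_expr.loc[mir, common].to_numpy(float),
            target_expr.loc[tgt, common].to_numpy(float),
        )[0, 1])
        rows.append((mir, tgt, r, r < negative_threshold))
    return pd.DataFrame(rows, columns=["mirna", "target", "r", "negative"])


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) ~ log10 k regression (scale-free fit)."""
    k = k[k > 0]
    if len(k) < 4:
        return 0.0
    if np.isclose(k.min(), k.max(), rtol=1e-6):
        # degenerate point-mass connectivity (e.g. exact block-diagonal
        # modules): every power fits equally well; report the maximum
        return 1.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = np.array([
        k[(k >= lo) & (k < hi)].mean() if c else np.nan
        for lo, hi, c in zip(edges[:-1], edges[1:], counts)
    ])
    ok = (counts > 0) & np.isfinite(centers) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(counts[ok] / counts.sum())
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(-np.sign(slope) * r**2)


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta over rows (nodes) of ``expr``."""
    C = np.corrcoef(expr.to_numpy(float))
    C = np.nan_to_num(C, nan=0.0)
    A = np.abs(C) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.8,
    default_beta: int = 12,
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power reaching the scale-free fit target.

    Falls back to ``default_beta`` with a warning when no candidate
    reaches the target.  Returns (beta, fit table with signed R^2 and mean
    connectivity per candidate).
    """
    rows = []
    chosen = None
    for beta in candidate_betas:
        A = adjacency_matrix(expr, beta)
        k = A.sum(axis=1) - 1.0
        r2 = _scale_free_fit(k)
        rows.append((beta, r2, float(k.mean())))
        if chosen is None and r2 >= r2_target:
            chosen = beta
    table = pd.DataFrame(rows, columns=["beta", "signed_r2", "mean_connectivity"])
    if chosen is None:
        warnings.warn(
            f"no candidate power reached scale-free R^2 {r2_target}; "
            f"falling back to beta={default_beta}"
        )
        chosen = default_beta
    return chosen, table


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap from an adjacency matrix (unit diagonal)."""
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    return T


def build_network(expr: pd.DataFrame, params: NetworkParams = NetworkParams()) -> CoexpressionNetwork:
    """Adjacency + TOM over the rows of a node x sample expression matrix."""
    A = adjacency_matrix(expr, params.beta)
    if not np.allclose(A, A.T):
        raise AssertionError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1 + 1e-12:
        raise AssertionError("adjacency entries must lie in [0, 1]")
    T = tom_matrix(A)
    if T.min() < -1e-12 or T.max() > 1 + 1e-9:
        raise AssertionError("TOM entries must lie in [0, 1]")
    return CoexpressionNetwork(list(expr.index), A, np.clip(T, 0.0, 1.0), params)


def module_eigengene(expr: pd.DataFrame) -> np.ndarray:
    """First principal component of the standardized module expression.

    Signed to correlate positively with the module's mean profile; a
    single-node module returns its standardized profile.
    """
    X = expr.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    if Z.shape[0] == 1:
        return Z[0]
    _u, _s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return eig


def detect_modules(
    network: CoexpressionNetwork, expr: pd.DataFrame
) -> CoexpressionNetwork:
    """Label modules by clustering 1 - TOM, then merge similar eigengenes.

    Clusters below ``min_module_size`` become grey (unassigned); the rest
    are named by the colour palette in descending size order.  Modules
    whose eigengenes correlate above 1 - merge_height are merged, and
    eigengenes recomputed.
    """
    p = network.params
    n = len(network.nodes)
    if n < 2:
        network.modules = pd.Series(["grey"] * n, index=network.nodes)
        return network
    D = 1.0 - network.tom
    np.fill_diagonal(D, 0.0)
    link = average(squareform((D + D.T) / 2, checks=False))
    labels = fcluster(link, t=p.static_cut_height, criterion="distance")

    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    module_sets = [g for g in groups.values() if len(g) >= p.min_module_size]

    # merge modules with near-identical eigengenes
    merged = True
    while merged and len(module_sets) > 1:
        merged = False
        eigs = [module_eigengene(expr.iloc[g]) for g in module_sets]
        for i in range(len(module_sets)):
            for j in range(i + 1, len(module_sets)):
                r = np.corrcoef(eigs[i], eigs[j])[0, 1]
                if 1.0 - r < p.merge_height:
                    module_sets[i] = module_sets[i] + module_sets[j]
                    del module_sets[j]
                    merged = True
                    break
            if merged:
                break

    module_sets.sort(key=len, reverse=True)
    colours = pd.Series(["grey"] * n, index=network.nodes)
    eig_cols = {}
    for rank, g in enumerate(module_sets):
        colour = MODULE_COLOURS[rank % len(MODULE_COLOURS)]
        for i in g:
            colours.iloc[i] = colour
        eig_cols[colour] = module_eigengene(expr.iloc[g])
    network.modules = colours
    network.eigengenes = pd.DataFrame(eig_cols, index=expr.columns)
    return network


def extract_subnetwork(
    network: CoexpressionNetwork,
    seed_nodes,
    weight_floor: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Edges incident to seed nodes with TOM >= floor, plus node degrees."""
    seeds = {s for s in seed_nodes}
    idx = {n: i for i, n in enumerate(network.nodes)}
    missing = seeds - set(idx)
    if missing:
        raise ValueError(f"seed nodes not in network: {sorted(missing)}")
    edges = []
    for a in sorted(seeds):
        i = idx[a]
        for b, j in idx.items():
            if j == i:
                continue
            w = network.tom[i, j]
            if w >= weight_floor and (b not in seeds or a < b):
                edges.append((a, b, float(w)))
    df = pd.DataFrame(edges, columns=["node1", "node2", "weight"])
    degree = (
        pd.concat([df["node1"], df["node2"]]).value_counts().rename("degree")
        if len(df)
        else pd.Series(dtype=int, name="degree")
    )
    return df, degree


def enrich(
    gene_set,
    annotation: pd.DataFrame,
    background=None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment per term with BH adjustment.

    ``annotation`` has columns (gene-like id, term); ``background``
    defaults to all annotated genes.  Terms entirely absent from the
    background are skipped with a warning.
    """
    gcol, tcol = annotation.columns[:2]
    bg = set(background) if background is not None else set(annotation[gcol])
    genes = set(gene_set) & bg
    if not genes:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N", "p", "q"])
    N = len(bg)
    n = len(genes)
    rows = []
    for term, sub in annotation.groupby(tcol):
        members = set(sub[gcol]) & bg
        K = len(members)
        if K == 0:
            warnings.warn(f"term {term} absent from background; skipped")
            continue
        k = len(genes & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, p))
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    out["q"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out.sort_values("p", ignore_index=True)
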