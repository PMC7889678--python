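"""Signed weighted co-expression network, TOM, and module detection.

The network stage follows the classic weighted co-expression recipe:
Pearson correlation of log2 expression across samples, signed soft
adjacency ``((1 + r)/2) ** beta``, topological overlap similarity,
average-linkage clustering on ``1 - TOM`` with a static height cut,
and a first-principal-component eigengene per module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "ModuleAssignment",
    "ModuleEigengenes",
    "correlation_matrix",
    "signed_adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "scale_free_fit",
]

UNASSIGNED = 0


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the signed co-expression network stage."""

    beta: int = 8
    min_module_size: int = 10
    cut_height: float = 0.5
    network_type: str = "signed"
    linkage_method: str = "average"

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not (0.0 < self.cut_height <= 1.0):
            raise ValueError("cut_height must be in (0, 1]")
        if self.network_type != "signed":
            raise ValueError("only signed networks are supported")
        if self.linkage_method != "average":
            raise ValueError("only average linkage is supported")


@dataclass
class ModuleAssignment:
    """Gene -> module labels; 0 marks genes assigned to no module.

    Module labels are 1..k ranked by decreasing size (ties broken by
    the smallest member gene position).
    """

    module_of_gene: pd.Series
    labels: list[int]
    unassigned_label: int = UNASSIGNED
    linkage_matrix: np.ndarray | None = field(default=None, repr=False)

    def members(self, label: int) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == label])

    def sizes(self) -> dict[int, int]:
        return {m: int((self.module_of_gene == m).sum()) for m in self.labels}


@dataclass
class ModuleEigengenes:
    """First-principal-component summary profile per module.

    Each eigengene has unit Euclidean norm across samples and is
    sign-aligned so it correlates non-negatively with the module's mean
    standardized expression.
    """

    values: pd.DataFrame  # module x sample
    variance_explained: dict[int, float]


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between all gene pairs across samples.

    ``expr`` is gene x sample with >= 3 samples.  Genes with zero
    variance get correlation 0 with everything (diagonal stays 1) and a
    logged warning — the floor rule can produce all-constant genes.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlations")
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "%d zero-variance gene(s); correlations set to 0: %s",
            int(flat.sum()),
            list(expr.index[flat]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(arr)
    cor[flat, :] = 0.0
    cor[:, flat] = 0.0
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def signed_adjacency(cor: pd.DataFrame, beta: int = 8) -> pd.DataFrame:
    """Signed soft adjacency ``((1 + r)/2) ** beta`` with unit diagonal.

    Maps r = -1 to 0 (anti-correlated genes unconnected) and r = +1
    to 1.
    """
    a = np.power((1.0 + cor.to_numpy(dtype=float)) / 2.0, beta)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity of a weighted network.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj over u != i, j and k_i the connectivity of
    node i (diagonal excluded); TOM_ii = 1.  Zero denominators (fully
    disconnected pairs) give TOM_ij = 0.
    """
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l_mat = a @ a  # for i != j this already excludes u = i, j terms with a_ii = 0
    k = a.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l_mat + a) / denom
    tom[denom == 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame, config: NetworkConfig | None = None
) -> ModuleAssignment:
    """Cut the 1 - TOM average-linkage dendrogram at a fixed height.

    Subtrees merged at or below ``cut_height`` become candidate groups;
    groups with at least ``min_module_size`` genes become modules,
    labelled 1..k by decreasing size; all other genes get label 0.
    """
    config = config or NetworkConfig()
    genes = list(tom.index)
    n = len(genes)
    if n < 2 or n < config.min_module_size:
        return ModuleAssignment(
            module_of_gene=pd.Series(UNASSIGNED, index=genes),
            labels=[],
            linkage_matrix=None,
        )
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    z = linkage(squareform(dissim, checks=False), method=config.linkage_method)
    groups = fcluster(z, t=config.cut_height, criterion="distance")

    module_of = pd.Series(UNASSIGNED, index=genes, dtype=int)
    sizes = pd.Series(groups).value_counts()
    big = [g for g, size in sizes.items() if size >= config.min_module_size]
    # rank by decreasing size; ties by first member position for determinism
    first_pos = {g: int(np.argmax(groups == g)) for g in big}
    big.sort(key=lambda g: (-sizes[g], first_pos[g]))
    labels = []
    for rank, g in enumerate(big, start=1):
        module_of.iloc[np.flatnonzero(groups == g)] = rank
        labels.append(rank)
    return ModuleAssignment(
        module_of_gene=module_of, labels=labels, linkage_matrix=z
    )


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(x, dtype=float)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def module_eigengenes(
    expr: pd.DataFrame, assignment: ModuleAssignment
) -> ModuleEigengenes:
    """First principal component of each module's standardized expression.

    Member genes are z-scored across samples (n-1 denominator), and the
    first left singular vector of the samples x genes submatrix is the
    eigengene (unit norm).  ``variance_explained`` is the first singular
    value's share of total variance.
    """
    rows = {}
    var_exp = {}
    for label in assignment.labels:
        members = assignment.members(label)
        sub = _zscore_rows(expr.loc[members].to_numpy(dtype=float))
        x = sub.T  # samples x genes
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        me = u[:, 0]
        total = float((s**2).sum())
        var_exp[label] = float(s[0] ** 2 / total) if total > 0 else 0.0
        mean_profile = sub.mean(axis=0)
        if float(me @ mean_profile) < 0:
            me = -me
        rows[label] = me
    values = pd.DataFrame(rows, index=expr.columns).T
    values.index.name = "module"
    return ModuleEigengenes(values=values, variance_explained=var_exp)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10):
    """Goodness of scale-free topology fit.

    Bins node connectivities, regresses log10 frequency on log10 mean
    connectivity per bin, and returns ``(r_squared, signed_r_squared)``
    where the signed version carries the slope's sign.  Degenerate
    (constant-connectivity) networks return (0, 0) with a warning.
    """
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    if np.allclose(k, k[0]):
        logger.warning("constant connectivity; scale-free fit undefined")
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = float(k[mask].mean())
        if mean_k <= 0:
            continue
        log_freq.append(np.log10(mask.sum() / len(k)))
        log_k.append(np.log10(mean_k))
    if len(log_k) < 3:
        logger.warning("too few occupied bins for a scale-free fit")
        return 0.0, 0.0
    fit = linregress(log_k, log_freq)
    r2 = float(fit.rvalue**2)
    return r2, float(np.sign(fit.slope) * r2)
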