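"""Module detection and eigengene summaries.

Average-linkage hierarchical clustering of the TOM dissimilarity, a
static-height tree cut with a minimum module size (the simplified "tree"
flavour of dynamic tree cut), and first-principal-component module
eigengenes with a stable orientation rule.

Module labels: 0 is the unassigned "grey" class; positive ids are ordered
by decreasing module size and mapped onto a fixed colour palette so that
runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix
from .errors import DegenerateModuleError, InvalidMatrixError
from .network import TOMatrix
from .stats import cor_matrix

log = logging.getLogger(__name__)

__all__ = [
    "PALETTE",
    "GREY",
    "Dendrogram",
    "ModuleAssignment",
    "EigengeneSet",
    "cluster_tom",
    "dynamic_tree_cut",
    "module_eigengene",
    "eigengene_adjacency",
]

GREY = "grey"

# Fixed ordered palette (grey is reserved for unassigned analytes).
PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
    "yellowgreen", "skyblue2", "plum", "orangered", "mediumpurple",
)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over analytes.

    ``merges`` is a scipy linkage matrix: each row (left, right, height,
    count) with non-decreasing heights.
    """

    merges: np.ndarray
    analyte_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.analyte_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.analyte_ids[i] for i in leaves_list(self.merges)]


@dataclass
class ModuleAssignment:
    """analyte -> module id map; id 0 is the grey/unassigned class."""

    labels: pd.Series  # index analyte id, values int
    colors: dict[int, str] = field(default_factory=dict)
    min_size: int = 30

    def __post_init__(self) -> None:
        self.colors.setdefault(0, GREY)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels.values) - {0})

    def color_of(self, analyte: str) -> str:
        return self.colors[int(self.labels.loc[analyte])]

    def members(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}

    def as_colors(self) -> pd.Series:
        return self.labels.map(self.colors)


@dataclass
class EigengeneSet:
    """module x sample matrix of first-PC summaries (unit variance).

    Rows are indexed by module colour; each eigengene is oriented so its
    correlation with the module's mean standardised expression is
    positive, making module-trait signs stable across runs.
    """

    me: pd.DataFrame
    module_ids: dict[str, int] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return list(self.me.index)

    @property
    def samples(self) -> list[str]:
        return list(self.me.columns)


def cluster_tom(tom: TOMatrix) -> Dendrogram:
    """Average-linkage clustering of the dissimilarity 1 - omega."""
    omega = np.asarray(tom.omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise InvalidMatrixError("TOM must be square")
    if not np.allclose(omega, omega.T, atol=1e-10):
        raise InvalidMatrixError("TOM must be symmetric")
    d = 1.0 - omega
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    merges = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(merges=merges, analyte_ids=list(tom.analyte_ids))


def dynamic_tree_cut(
    dend: Dendrogram,
    min_size: int = 30,
    cut_height: float = 0.75,
    cut_quantile: float | None = None,
) -> ModuleAssignment:
    """Static-height tree cut with a minimum module size.

    Branches are the maximal subtrees whose internal merge heights all lie
    at or below the cut (equivalently: the forest obtained by deleting
    merges above the cut).  Branches with >= ``min_size`` leaves become
    modules, ordered by decreasing size (ties broken by first leaf index);
    all other leaves are grey (label 0).

    ``cut_height`` is an absolute height on the 1 - TOM scale; passing
    ``cut_quantile`` instead places the cut at that quantile of the merge
    heights.
    """
    n = dend.n_leaves
    if min_size > n:
        log.warning("min_size %d exceeds leaf count %d: everything is grey", min_size, n)
        labels = pd.Series(0, index=dend.analyte_ids, dtype=int)
        return ModuleAssignment(labels=labels, min_size=min_size)
    if cut_quantile is not None:
        # inclusive of merges exactly at the quantile value
        cut_height = float(np.quantile(dend.heights, cut_quantile)) * (1 + 1e-12) + 1e-12
    raw = fcluster(dend.merges, t=cut_height, criterion="distance")
    counts = pd.Series(raw).value_counts()
    keep = [c for c in counts.index if counts[c] >= min_size]
    # order candidate modules by decreasing size, ties by first member position
    first_pos = {c: int(np.argmax(raw == c)) for c in keep}
    keep.sort(key=lambda c: (-counts[c], first_pos[c]))
    relabel = {c: i + 1 for i, c in enumerate(keep)}
    labels = pd.Series([relabel.get(c, 0) for c in raw], index=dend.analyte_ids, dtype=int)
    colors = {0: GREY}
    for c, i in relabel.items():
        colors[i] = PALETTE[(i - 1) % len(PALETTE)]
    return ModuleAssignment(labels=labels, colors=colors, min_size=min_size)


def _standardise_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def module_eigengene(expr: ExpressionMatrix, assign: ModuleAssignment) -> EigengeneSet:
    """First principal component of each module's standardised submatrix.

    Each analyte is standardised across samples; the eigengene is the
    leading right singular vector (sample-space component) scaled to unit
    variance, sign-flipped when negatively correlated with the module's
    mean standardised expression.
    """
    missing = [a for a in assign.labels.index if a not in expr.data.index]
    if missing:
        raise DegenerateModuleError(f"analytes missing from expression matrix: {missing[:5]}")
    rows, ids = [], {}
    for m in assign.module_ids:
        members = assign.members(m)
        if len(members) < 2:
            raise DegenerateModuleError(f"module {m} has fewer than 2 analytes")
        z = _standardise_rows(expr.data.loc[members].to_numpy())
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        sd = eig.std(ddof=1)
        if sd > 0:
            eig = eig / sd
        if np.corrcoef(eig, z.mean(axis=0))[0, 1] < 0:
            eig = -eig
        color = assign.colors[m]
        ids[color] = m
        rows.append(pd.Series(eig, index=expr.samples, name=color))
    me = pd.DataFrame(rows) if rows else pd.DataFrame(columns=expr.samples)
    return EigengeneSet(me=me, module_ids=ids)


def eigengene_adjacency(mes: EigengeneSet, method: str = "spearman") -> pd.DataFrame:
    """Pairwise correlation between module eigengenes (unit diagonal)."""
    if len(mes.modules) < 2:
        raise DegenerateModuleError("need at least 2 modules")
    rho, _ = cor_matrix(mes.me.to_numpy(), method=method)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=mes.modules, columns=mes.modules)
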