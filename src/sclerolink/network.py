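"""Weighted coexpression network construction.

Soft-thresholded adjacency (unsigned by default), scale-free topology fit,
soft-threshold power selection, and the topological overlap matrix (TOM)
whose complement is the clustering dissimilarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix
from .errors import DegenerateInputError, UndefinedFitError
from .stats import cor_matrix

log = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "AdjacencyMatrix",
    "TOMatrix",
    "adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "topological_overlap",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Network construction settings for one compartment.

    ``power_beta`` is the soft-threshold exponent; when set (default 7.0,
    the transcript-compartment convention) it bypasses data-driven
    selection.  Set it to ``None`` to pick the smallest candidate power
    whose scale-free fit reaches ``scale_free_r2_cut``.

    ``protein_sd_param`` is a provenance-only placeholder for the
    proteomic "standard deviation parameter for soft-thresholding"
    (0.2 blister, 0.3 plasma); it has no defined formula in standard
    WGCNA and never enters any computation here.
    """

    power_beta: float | None = 7.0
    correlation_method: str = "pearson"
    signed: bool = False
    candidate_powers: tuple[float, ...] = tuple(range(1, 21))
    scale_free_r2_cut: float = 0.8
    protein_sd_param: float | None = None

    def __post_init__(self) -> None:
        if self.power_beta is not None and self.power_beta < 1:
            raise ValueError("power_beta must be >= 1")
        if list(self.candidate_powers) != sorted(set(self.candidate_powers)):
            raise ValueError("candidate_powers must be strictly increasing")


@dataclass
class AdjacencyMatrix:
    """Symmetric analyte x analyte adjacency with entries in [0, 1]."""

    a: np.ndarray
    analyte_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=self.analyte_ids, columns=self.analyte_ids)


@dataclass
class TOMatrix:
    """Symmetric topological overlap matrix; 1 - omega is a dissimilarity."""

    omega: np.ndarray
    analyte_ids: list[str]

    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.omega
        np.fill_diagonal(d, 0.0)
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omega, index=self.analyte_ids, columns=self.analyte_ids)


def _drop_constant_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    values = expr.values
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        dropped = [a for a, c in zip(expr.analytes, constant) if c]
        log.warning(
            "dropping %d constant analyte row(s) from %s: %s%s",
            len(dropped), expr.compartment, dropped[:5], "..." if len(dropped) > 5 else "",
        )
        expr = expr.subset_analytes([a for a, c in zip(expr.analytes, constant) if not c])
    return expr


def adjacency(expr: ExpressionMatrix, cfg: NetworkConfig, power: float | None = None) -> AdjacencyMatrix:
    """Soft-thresholded adjacency a_ij = |cor|^beta (unsigned) or
    ((1 + cor)/2)^beta (signed).  The diagonal is forced to 1."""
    if len(expr.samples) < 3:
        raise DegenerateInputError("adjacency requires at least 3 samples")
    expr = _drop_constant_rows(expr)
    beta = power if power is not None else cfg.power_beta
    if beta is None:
        raise ValueError("no power supplied: set cfg.power_beta or pass power=")
    cor, _ = cor_matrix(expr.values, method=cfg.correlation_method)
    if cfg.signed:
        a = ((1.0 + cor) / 2.0) ** beta
    else:
        a = np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(a=a, analyte_ids=expr.analytes)


def scale_free_fit(adj: AdjacencyMatrix, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-distribution regression.

    Connectivity ``k_i`` is the off-diagonal row sum of the adjacency.
    ``k`` is binned into ``n_bins`` equal-width bins; log10(mean observed
    frequency) is regressed on log10(mean k) over non-empty bins.  The
    returned fit index is R^2 times ``-sign(slope)``, so it is positive
    only when p(k) decreases with k (the scale-free direction).
    """
    a = adj.a
    if a.shape[0] < 10:
        raise DegenerateInputError("scale-free fit requires at least 10 analytes")
    k = a.sum(axis=1) - np.diag(a)
    if np.ptp(k) <= 1e-10 * max(1.0, float(np.abs(k).max())):
        raise UndefinedFitError("all connectivities identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        mean_k.append(members.mean())
        freq.append(members.size / k.size)
    mean_k = np.asarray(mean_k)
    freq = np.asarray(freq)
    keep = mean_k > 0
    mean_k, freq = mean_k[keep], freq[keep]
    if mean_k.size < 2:
        raise UndefinedFitError("fewer than 2 non-empty connectivity bins")
    res = sps.linregress(np.log10(mean_k), np.log10(freq))
    r2 = res.rvalue**2
    return float(-np.sign(res.slope) * r2) if res.slope != 0 else 0.0


def pick_soft_threshold(
    expr: ExpressionMatrix, cfg: NetworkConfig, n_bins: int = 10
) -> tuple[pd.DataFrame, float]:
    """Soft-threshold power selection by scale-free topology fit.

    Returns a table of (power, fit_r2, mean_k) over the candidate powers
    and the chosen power: the smallest candidate reaching
    ``cfg.scale_free_r2_cut``, falling back (with a warning) to the
    candidate maximising the fit.  A fixed ``cfg.power_beta`` bypasses
    selection entirely.
    """
    if cfg.power_beta is not None:
        table = pd.DataFrame(columns=["power", "fit_r2", "mean_k"])
        return table, float(cfg.power_beta)
    if not cfg.candidate_powers:
        raise ValueError("candidate_powers is empty")
    rows = []
    for power in cfg.candidate_powers:
        adj = adjacency(expr, cfg, power=power)
        k = adj.a.sum(axis=1) - np.diag(adj.a)
        try:
            r2 = scale_free_fit(adj, n_bins=n_bins)
        except UndefinedFitError:
            r2 = np.nan
        rows.append({"power": float(power), "fit_r2": r2, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    reaching = table[table["fit_r2"] >= cfg.scale_free_r2_cut]
    if len(reaching):
        chosen = float(reaching["power"].iloc[0])
    else:
        chosen = float(table.loc[table["fit_r2"].idxmax(), "power"])
        log.warning(
            "no candidate power reached scale-free R^2 >= %.2f; using %g (best fit %.3f)",
            cfg.scale_free_r2_cut, chosen, table["fit_r2"].max(),
        )
    return table, chosen


def topological_overlap(adj: AdjacencyMatrix) -> TOMatrix:
    """Unsigned topological overlap.

    omega_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j,
    with L_ij the shared-neighbour sum and k the off-diagonal
    connectivity; omega_ii = 1.
    """
    a = adj.a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    loops = a @ a  # L_ij includes only u != i, j because diag(a) = 0
    num = loops + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = num / den
    omega[~np.isfinite(omega)] = 0.0
    np.fill_diagonal(omega, 1.0)
    return TOMatrix(omega=omega, analyte_ids=list(adj.analyte_ids))
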