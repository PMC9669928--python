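"""Module-trait and analyte-trait association.

Gene significance (GS) is the correlation of an individual analyte with
the early-dcSSc indicator; module membership (kME) is the correlation of
an analyte with its own module's eigengene.  Hub analytes satisfy
GS > 0.6, kME > 0.7 and p < 0.01 on both (strict inequalities) inside a
disease-anchored, non-grey module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, TraitTable
from .errors import DegenerateInputError
from .modules import GREY, EigengeneSet, ModuleAssignment
from .stats import bh_fdr, cor_matrix

__all__ = [
    "HubThresholds",
    "ModuleTraitResult",
    "module_trait_correlation",
    "gene_significance",
    "module_membership",
    "build_hub_table",
    "select_hubs",
]

ANCHOR_TRAIT = "early_dcSSc"


@dataclass(frozen=True)
class HubThresholds:
    """Hub selection cuts (strict inequalities)."""

    gs_cut: float = 0.6
    kme_cut: float = 0.7
    p_cut: float = 0.01


@dataclass
class ModuleTraitResult:
    """Long-format (module, trait) correlations with BH adjustment."""

    table: pd.DataFrame  # columns: module, trait, rho, p, p_adj
    alpha: float = 0.05

    def significant(self, trait: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["p_adj"] < self.alpha]
        if trait is not None:
            t = t[t["trait"] == trait]
        return t

    def significant_modules(self, trait: str) -> list[str]:
        return list(self.significant(trait)["module"])


def module_trait_correlation(
    mes: EigengeneSet,
    traits: TraitTable,
    method: str = "spearman",
    alpha: float = 0.05,
) -> ModuleTraitResult:
    """Correlate every eigengene with every numeric/indicator trait.

    BH adjustment is applied across the whole module x trait matrix of
    the compartment.  Constant traits yield NaN (reported as missing).
    """
    trait_mat = traits.numeric_traits(samples=mes.samples)
    rho, p = cor_matrix(mes.me.to_numpy(), trait_mat.to_numpy(), method=method)
    records = []
    for i, module in enumerate(mes.modules):
        for j, trait in enumerate(trait_mat.index):
            records.append({"module": module, "trait": trait, "rho": rho[i, j], "p": p[i, j]})
    table = pd.DataFrame(records)
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    return ModuleTraitResult(table=table, alpha=alpha)


def gene_significance(
    expr: ExpressionMatrix,
    trait,
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-analyte correlation with a (binary or numeric) trait.

    Returns a DataFrame indexed by analyte with columns ``gs`` and
    ``gs_p``; constant analytes get NaN and are excluded from hub
    candidacy downstream.
    """
    trait = pd.Series(trait)
    if list(trait.index) != list(expr.samples):
        try:
            trait = trait.loc[expr.samples]
        except KeyError as exc:
            raise DegenerateInputError("trait not aligned with expression samples") from exc
    rho, p = cor_matrix(expr.values, trait.to_numpy()[None, :], method=method)
    return pd.DataFrame({"gs": rho[:, 0], "gs_p": p[:, 0]}, index=expr.analytes)


def module_membership(
    expr: ExpressionMatrix,
    mes: EigengeneSet,
    assign: ModuleAssignment,
    method: str = "spearman",
) -> pd.DataFrame:
    """kME: correlation of each analyte with its OWN module eigengene.

    Grey analytes receive missing kME.  Returns a DataFrame indexed by
    analyte with columns ``module`` (colour), ``kme``, ``kme_p``.
    """
    rho, p = cor_matrix(expr.values, mes.me.to_numpy(), method=method)
    col_of = {color: j for j, color in enumerate(mes.modules)}
    out = pd.DataFrame(
        {"module": [assign.color_of(a) for a in expr.analytes]},
        index=expr.analytes,
    )
    kme = np.full(len(expr.analytes), np.nan)
    kme_p = np.full(len(expr.analytes), np.nan)
    for i, a in enumerate(expr.analytes):
        color = out.at[a, "module"]
        if color != GREY and color in col_of:
            kme[i] = rho[i, col_of[color]]
            kme_p[i] = p[i, col_of[color]]
    out["kme"] = kme
    out["kme_p"] = kme_p
    return out


def build_hub_table(
    expr: ExpressionMatrix,
    mes: EigengeneSet,
    assign: ModuleAssignment,
    traits: TraitTable,
    method: str = "spearman",
    thresholds: HubThresholds = HubThresholds(),
    anchor_trait: str = ANCHOR_TRAIT,
) -> pd.DataFrame:
    """Per-analyte GS/kME table with the hub flag.

    ``hub_flag = (GS > gs_cut) & (kME > kme_cut) & (gs_p < p_cut)
    & (kme_p < p_cut) & (module != grey)``; unadjusted p-values are used
    at this step (study-wide BH applies to the later cascade families).
    """
    gs = gene_significance(expr, traits.indicator(anchor_trait, expr.samples), method=method)
    mm = module_membership(expr, mes, assign, method=method)
    table = mm.join(gs)
    with np.errstate(invalid="ignore"):
        table["hub_flag"] = (
            (table["gs"] > thresholds.gs_cut)
            & (table["kme"] > thresholds.kme_cut)
            & (table["gs_p"] < thresholds.p_cut)
            & (table["kme_p"] < thresholds.p_cut)
            & (table["module"] != GREY)
        ).fillna(False)
    return table


def select_hubs(
    hub_table: pd.DataFrame,
    modules: list[str] | None = None,
    thresholds: HubThresholds = HubThresholds(),
) -> list[str]:
    """Analytes meeting all four hub conditions (strict inequalities),
    optionally restricted to a set of disease-anchored module colours."""
    t = hub_table
    with np.errstate(invalid="ignore"):
        mask = (
            (t["gs"] > thresholds.gs_cut)
            & (t["kme"] > thresholds.kme_cut)
            & (t["gs_p"] < thresholds.p_cut)
            & (t["kme_p"] < thresholds.p_cut)
            & (t["module"] != GREY)
        )
    mask = mask.fillna(False)
    if modules is not None:
        mask &= t["module"].isin(modules)
    return list(t.index[mask])
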