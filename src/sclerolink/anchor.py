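"""Cross-compartment anchoring and the cascading candidate filter.

Modules are anchored across compartments by requiring (i) a significant
module-trait association with early dcSSc and (ii) at least one
significant cross-compartment partner module that itself passes the trait
criterion.  Hub analytes from anchored modules are intersected across
modalities via the gene<->protein identifier map, then run through the
sequential correlation cascade:

  stage 0: hub in an anchored skin module AND an anchored blister module
  stage 1: skin transcript  <->  blister protein correlation
  stage 2: blister protein  <->  plasma protein correlation
  stage 3: plasma protein   <->  mRSS correlation
  stage 4: 12-month skin transcript <-> 12-month mRSS correlation

Each stage's p-values are BH-adjusted within that stage's family;
survivors are carried forward, so stage sets are nested by construction
(and asserted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .containers import ExpressionMatrix, TraitTable
from .errors import AmbiguousMappingError, DegenerateOverlapError
from .modules import EigengeneSet
from .stats import bh_fdr, cor_matrix, correlate
from .traits import ANCHOR_TRAIT, ModuleTraitResult

log = logging.getLogger(__name__)

__all__ = [
    "IdentifierMap",
    "CascadeReport",
    "crossmodal_module_correlation",
    "select_anchored_modules",
    "intersect_hubs",
    "cascade_filter",
]


@dataclass
class IdentifierMap:
    """One-to-one map between gene symbols and protein assay names."""

    gene_to_protein: dict[str, str]

    def __post_init__(self) -> None:
        proteins = list(self.gene_to_protein.values())
        dupes = sorted({p for p in proteins if proteins.count(p) > 1})
        if dupes:
            raise AmbiguousMappingError(f"proteins mapped by multiple genes: {dupes}")
        self.protein_to_gene = {p: g for g, p in self.gene_to_protein.items()}

    def protein(self, gene: str) -> str | None:
        return self.gene_to_protein.get(gene)

    def gene(self, protein: str) -> str | None:
        return self.protein_to_gene.get(protein)

    def unmapped(self, genes) -> list[str]:
        return [g for g in genes if g not in self.gene_to_protein]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_symbol": list(self.gene_to_protein),
             "protein_assay": list(self.gene_to_protein.values())}
        )


@dataclass
class CascadeReport:
    """Audit trail of the cascading filter: per-stage survivor sets
    (gene symbols) and per-stage correlation tables."""

    stages: dict[str, list[str]] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    alpha: float = 0.05

    STAGE_ORDER = (
        "stage0_shared_hubs",
        "stage1_skin_blister",
        "stage2_blister_plasma",
        "stage3_mrss",
        "stage4_followup",
    )

    def sizes(self) -> dict[str, int]:
        return {s: len(self.stages[s]) for s in self.STAGE_ORDER if s in self.stages}

    def assert_nested(self) -> None:
        present = [s for s in self.STAGE_ORDER if s in self.stages]
        for a, b in zip(present, present[1:]):
            if not set(self.stages[b]) <= set(self.stages[a]):
                raise AssertionError(f"cascade stages not nested: {b} is not a subset of {a}")

    def summary(self) -> dict:
        return {"alpha": self.alpha, "sizes": self.sizes(),
                "stages": {k: list(v) for k, v in self.stages.items()}}


def crossmodal_module_correlation(
    mes_a: EigengeneSet,
    mes_b: EigengeneSet,
    method: str = "spearman",
) -> pd.DataFrame:
    """All pairwise correlations between two compartments' eigengenes
    over their shared samples, with BH adjustment across the matrix."""
    shared = [s for s in mes_a.samples if s in set(mes_b.samples)]
    if len(shared) < 3:
        raise DegenerateOverlapError(f"only {len(shared)} shared samples")
    a = mes_a.me.loc[:, shared].to_numpy()
    b = mes_b.me.loc[:, shared].to_numpy()
    rho, p = cor_matrix(a, b, method=method)
    records = []
    for i, ma in enumerate(mes_a.modules):
        for j, mb in enumerate(mes_b.modules):
            records.append({"module_a": ma, "module_b": mb, "rho": rho[i, j], "p": p[i, j]})
    table = pd.DataFrame(records)
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    return table


def select_anchored_modules(
    mt_a: ModuleTraitResult,
    mt_b: ModuleTraitResult,
    cross: pd.DataFrame,
    trait: str = ANCHOR_TRAIT,
    alpha: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Modules kept per compartment: trait-significant AND having at
    least one significant cross-compartment partner that is itself
    trait-significant."""
    sig_a = set(mt_a.significant_modules(trait))
    sig_b = set(mt_b.significant_modules(trait))
    sig_cross = cross[cross["p_adj"] < alpha]
    keep_a, keep_b = set(), set()
    for _, row in sig_cross.iterrows():
        if row["module_a"] in sig_a and row["module_b"] in sig_b:
            keep_a.add(row["module_a"])
            keep_b.add(row["module_b"])
    if not keep_a:
        log.info("no anchored module pairs found (trait=%s, alpha=%g)", trait, alpha)
    return sorted(keep_a), sorted(keep_b)


def intersect_hubs(
    hubs_skin: list[str],
    hubs_blister: list[str],
    idmap: IdentifierMap,
) -> list[str]:
    """Analytes (gene symbols) that are hubs in both compartments.

    Skin hubs are gene symbols, blister hubs protein assay names; the
    identifier map links them.  Unmapped hubs are logged and excluded.
    """
    unmapped = idmap.unmapped(hubs_skin)
    if unmapped:
        log.info("excluding %d unmapped skin hub(s): %s%s",
                 len(unmapped), unmapped[:5], "..." if len(unmapped) > 5 else "")
    blister_set = set(hubs_blister)
    return [g for g in hubs_skin if idmap.protein(g) in blister_set]


def _stage_table(pairs, alpha: float, method: str) -> pd.DataFrame:
    """Correlate each (analyte, x, y) pair, BH-adjust within the stage."""
    records = []
    for analyte, x, y in pairs:
        try:
            res = correlate(x, y, method=method)
            records.append({"analyte": analyte, "rho": res.rho, "p": res.p, "n": res.n})
        except Exception as exc:  # degenerate pair: report, never survives
            log.warning("cascade: analyte %s excluded (%s)", analyte, exc)
            records.append({"analyte": analyte, "rho": float("nan"), "p": float("nan"), "n": 0})
    table = pd.DataFrame(records).set_index("analyte")
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    table["pass"] = table["p_adj"] < alpha
    return table


def cascade_filter(
    shared_hubs: list[str],
    expr_skin: ExpressionMatrix,
    prot_blister: ExpressionMatrix,
    prot_plasma: ExpressionMatrix,
    traits: TraitTable,
    idmap: IdentifierMap,
    expr_skin_month12: ExpressionMatrix | None = None,
    traits_month12: TraitTable | None = None,
    alpha: float = 0.05,
    method: str = "spearman",
) -> CascadeReport:
    """Run the sequential cross-compartment correlation cascade.

    ``shared_hubs`` are gene symbols hub in both anchored skin and
    blister modules (stage 0).  Correlations at each stage use the
    maximal set of samples carrying both measurements; analytes absent
    from a required compartment are excluded with a logged reason.
    """
    report = CascadeReport(alpha=alpha)

    def usable(genes, matrix: ExpressionMatrix, proteins: bool):
        kept, dropped = [], []
        for g in genes:
            ident = idmap.protein(g) if proteins else g
            if ident is not None and ident in matrix.data.index:
                kept.append(g)
            else:
                dropped.append(g)
        if dropped:
            log.warning("cascade: %d analyte(s) absent from %s: %s%s",
                        len(dropped), matrix.compartment, dropped[:5],
                        "..." if len(dropped) > 5 else "")
        return kept

    stage0 = list(shared_hubs)
    report.stages["stage0_shared_hubs"] = stage0

    # stage 1: skin transcript vs blister protein
    genes = usable(usable(stage0, expr_skin, False), prot_blister, True)
    shared = [s for s in expr_skin.samples if s in set(prot_blister.samples)]
    pairs = [
        (g,
         expr_skin.data.loc[g, shared].to_numpy(),
         prot_blister.data.loc[idmap.protein(g), shared].to_numpy())
        for g in genes
    ]
    t1 = _stage_table(pairs, alpha, method)
    report.tables["stage1_skin_blister"] = t1
    stage1 = [g for g in genes if bool(t1.at[g, "pass"])]
    report.stages["stage1_skin_blister"] = stage1

    # stage 2: blister protein vs plasma protein
    genes = usable(stage1, prot_plasma, True)
    shared = [s for s in prot_blister.samples if s in set(prot_plasma.samples)]
    pairs = [
        (g,
         prot_blister.data.loc[idmap.protein(g), shared].to_numpy(),
         prot_plasma.data.loc[idmap.protein(g), shared].to_numpy())
        for g in genes
    ]
    t2 = _stage_table(pairs, alpha, method)
    report.tables["stage2_blister_plasma"] = t2
    stage2 = [g for g in genes if bool(t2.at[g, "pass"])]
    report.stages["stage2_blister_plasma"] = stage2

    # stage 3: plasma protein vs mRSS (significance required in plasma)
    mrss = traits.mrss(prot_plasma.samples)
    pairs = [
        (g, prot_plasma.data.loc[idmap.protein(g)].to_numpy(), mrss.to_numpy())
        for g in stage2
    ]
    t3 = _stage_table(pairs, alpha, method)
    report.tables["stage3_mrss"] = t3
    stage3 = [g for g in stage2 if bool(t3.at[g, "pass"])]
    report.stages["stage3_mrss"] = stage3

    # stage 4: 12-month skin transcript vs 12-month mRSS (follow-up cohort)
    if expr_skin_month12 is not None and traits_month12 is not None:
        genes = usable(stage3, expr_skin_month12, False)
        mrss12 = traits_month12.mrss(expr_skin_month12.samples)
        pairs = [
            (g, expr_skin_month12.data.loc[g].to_numpy(), mrss12.to_numpy())
            for g in genes
        ]
        t4 = _stage_table(pairs, alpha, method)
        report.tables["stage4_followup"] = t4
        stage4 = [g for g in genes if bool(t4.at[g, "pass"])]
        report.stages["stage4_followup"] = stage4

    report.assert_nested()
    return report
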