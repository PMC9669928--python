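"""End-to-end orchestration: network -> modules -> traits -> anchor ->
cascade -> composite, with a machine-readable run manifest.

The pipeline consumes either an in-memory :class:`~sclerolink.simulate.SyntheticStudy`
or a :class:`PipelineInput` of file paths, executes the stages in order,
optionally writes every intermediate artefact, and records a manifest
(stage list, seed, config hash, package versions).  An empty
anchored-module set is not an exception: the run halts with an
informative status and partial outputs are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import anchor as anchor_mod
from . import io as io_mod
from .composite import CompositeModel, ModelEvaluation, evaluate_model, lasso_fit
from .containers import ExpressionMatrix, TraitTable
from .errors import ConfigError, PipelineHaltedError
from .modules import EigengeneSet, ModuleAssignment, cluster_tom, dynamic_tree_cut, module_eigengene
from .network import NetworkConfig, adjacency, pick_soft_threshold, topological_overlap
from .traits import HubThresholds, ModuleTraitResult, build_hub_table, module_trait_correlation, select_hubs

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineInput", "PipelineResult", "CompartmentResult", "run_pipeline"]

STAGES = ("network", "modules", "traits", "anchor", "cascade", "composite")


@dataclass
class PipelineConfig:
    """All tunables of one run; round-trips through YAML unchanged."""

    skin_network: NetworkConfig = field(default_factory=NetworkConfig)
    blister_network: NetworkConfig = field(default_factory=NetworkConfig)
    min_module_size: int = 30
    cut_height: float = 0.75
    cut_quantile: float | None = None
    trait_method: str = "spearman"
    hub_thresholds: HubThresholds = field(default_factory=HubThresholds)
    cascade_alpha: float = 0.05
    lasso_cv_folds: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_module_size < 2:
            raise ConfigError("min_module_size must be >= 2")
        if not (0 < self.cascade_alpha < 1):
            raise ConfigError("cascade_alpha must lie in (0, 1)")
        if self.cut_quantile is not None and not (0 < self.cut_quantile <= 1):
            raise ConfigError("cut_quantile must lie in (0, 1]")
        for t in (self.hub_thresholds.gs_cut, self.hub_thresholds.kme_cut):
            if not (0 <= t <= 1):
                raise ConfigError("hub correlation thresholds must lie in [0, 1]")
        if not (0 < self.hub_thresholds.p_cut < 1):
            raise ConfigError("hub p threshold must lie in (0, 1)")

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        d["skin_network"] = NetworkConfig(**{
            **d.get("skin_network", {}),
            "candidate_powers": tuple(d.get("skin_network", {}).get("candidate_powers", tuple(range(1, 21)))),
        })
        d["blister_network"] = NetworkConfig(**{
            **d.get("blister_network", {}),
            "candidate_powers": tuple(d.get("blister_network", {}).get("candidate_powers", tuple(range(1, 21)))),
        })
        d["hub_thresholds"] = HubThresholds(**d.get("hub_thresholds", {}))
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class PipelineInput:
    """File-based pipeline input; any missing path halts at the stage
    that needs it."""

    expr_skin: str
    prot_blister: str
    prot_plasma: str
    metadata: str
    identifier_map: str
    expr_skin_month12: str | None = None


@dataclass
class CompartmentResult:
    """Per-compartment network/module artefacts."""

    assignment: ModuleAssignment
    eigengenes: EigengeneSet
    module_trait: ModuleTraitResult
    hub_table: pd.DataFrame
    chosen_power: float
    power_table: pd.DataFrame


@dataclass
class PipelineResult:
    status: str
    skin: CompartmentResult | None = None
    blister: CompartmentResult | None = None
    cross_modules: pd.DataFrame | None = None
    anchored_skin: list[str] = field(default_factory=list)
    anchored_blister: list[str] = field(default_factory=list)
    shared_hubs: list[str] = field(default_factory=list)
    cascade: anchor_mod.CascadeReport | None = None
    model: CompositeModel | None = None
    evaluation: ModelEvaluation | None = None
    manifest: dict = field(default_factory=dict)


def _analyse_compartment(
    expr: ExpressionMatrix,
    traits: TraitTable,
    net_cfg: NetworkConfig,
    cfg: PipelineConfig,
) -> CompartmentResult:
    power_table, power = pick_soft_threshold(expr, net_cfg)
    adj = adjacency(expr, net_cfg, power=power)
    tom = topological_overlap(adj)
    dend = cluster_tom(tom)
    assign = dynamic_tree_cut(
        dend, min_size=cfg.min_module_size, cut_height=cfg.cut_height, cut_quantile=cfg.cut_quantile
    )
    expr_used = expr.subset_analytes(list(assign.labels.index))
    mes = module_eigengene(expr_used, assign)
    mt = module_trait_correlation(mes, traits, method=cfg.trait_method, alpha=cfg.cascade_alpha)
    hub_table = build_hub_table(
        expr_used, mes, assign, traits, method=cfg.trait_method, thresholds=cfg.hub_thresholds
    )
    return CompartmentResult(
        assignment=assign, eigengenes=mes, module_trait=mt,
        hub_table=hub_table, chosen_power=power, power_table=power_table,
    )


def _load_input(inp: PipelineInput):
    from .simulate import SyntheticStudy  # local import to avoid cycle

    def need(path, stage):
        if path is None or not Path(path).exists():
            raise PipelineHaltedError(stage, f"missing input file: {path}")
        return path

    traits = io_mod.read_metadata(need(inp.metadata, "network"))
    expr_skin = io_mod.read_expression_matrix(need(inp.expr_skin, "network"), "skin")
    prot_blister = io_mod.read_expression_matrix(need(inp.prot_blister, "network"), "blister")
    prot_plasma = io_mod.read_expression_matrix(need(inp.prot_plasma, "cascade"), "plasma")
    idmap = io_mod.read_identifier_map(need(inp.identifier_map, "anchor"))
    skin12 = None
    if inp.expr_skin_month12 is not None:
        skin12 = io_mod.read_expression_matrix(
            need(inp.expr_skin_month12, "cascade"), "skin", visit="month12"
        )
    return SyntheticStudy(
        traits=traits, expr_skin=expr_skin, prot_blister=prot_blister,
        prot_plasma=prot_plasma, expr_skin_month12=skin12, idmap=idmap,
        truth=None, config=None,
    )


def run_pipeline(study, cfg: PipelineConfig | None = None, out_dir=None) -> PipelineResult:
    """Execute the full integration pipeline.

    ``study`` is a :class:`SyntheticStudy`-like bundle (or a
    :class:`PipelineInput` of paths).  Returns a :class:`PipelineResult`
    whose ``status`` is ``"ok"`` or ``"halted:<stage>:<reason>"``; the
    manifest lists completed stages, the seed and a config hash.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(study, PipelineInput):
        study = _load_input(study)
    t0 = time.time()
    completed: list[str] = []
    manifest = {"seed": cfg.seed, "config_sha256": cfg.digest(), "stages": completed}

    traits_base = study.traits.for_visit("baseline")
    result = PipelineResult(status="ok", manifest=manifest)

    # network + modules + traits, per compartment
    result.skin = _analyse_compartment(study.expr_skin, traits_base, cfg.skin_network, cfg)
    result.blister = _analyse_compartment(study.prot_blister, traits_base, cfg.blister_network, cfg)
    completed.extend(["network", "modules", "traits"])

    # crossmodal anchoring
    if not result.skin.eigengenes.modules or not result.blister.eigengenes.modules:
        result.status = "halted:anchor:no modules detected"
        _finish(manifest, t0, out_dir, result, study)
        return result
    result.cross_modules = anchor_mod.crossmodal_module_correlation(
        result.skin.eigengenes, result.blister.eigengenes, method=cfg.trait_method
    )
    result.anchored_skin, result.anchored_blister = anchor_mod.select_anchored_modules(
        result.skin.module_trait, result.blister.module_trait,
        result.cross_modules, alpha=cfg.cascade_alpha,
    )
    completed.append("anchor")
    if not result.anchored_skin:
        result.status = "halted:anchor:no anchored module pairs"
        _finish(manifest, t0, out_dir, result, study)
        return result

    # hub intersection + cascade
    hubs_skin = select_hubs(result.skin.hub_table, modules=result.anchored_skin, thresholds=cfg.hub_thresholds)
    hubs_blister = select_hubs(result.blister.hub_table, modules=result.anchored_blister, thresholds=cfg.hub_thresholds)
    result.shared_hubs = anchor_mod.intersect_hubs(hubs_skin, hubs_blister, study.idmap)
    if not result.shared_hubs:
        result.status = "halted:cascade:no shared hub analytes"
        _finish(manifest, t0, out_dir, result, study)
        return result
    traits12 = study.traits.for_visit("month12")
    result.cascade = anchor_mod.cascade_filter(
        result.shared_hubs, study.expr_skin, study.prot_blister, study.prot_plasma,
        traits_base, study.idmap,
        expr_skin_month12=study.expr_skin_month12,
        traits_month12=traits12 if len(traits12.df) else None,
        alpha=cfg.cascade_alpha, method=cfg.trait_method,
    )
    completed.append("cascade")

    # composite model on the plasma values of all shared hubs
    plasma_ids = [study.idmap.protein(g) for g in result.shared_hubs]
    X = study.prot_plasma.data.loc[plasma_ids].T
    X.columns = result.shared_hubs
    y = traits_base.mrss(X.index)
    if len(result.shared_hubs) < 2:
        result.status = "halted:composite:fewer than 2 shared hubs"
        _finish(manifest, t0, out_dir, result, study)
        return result
    result.model = lasso_fit(X, y, cv_folds=min(cfg.lasso_cv_folds, len(y) - 1), seed=cfg.seed)
    if result.model.status == "empty":
        result.status = "ok:empty_model"
    else:
        result.evaluation = evaluate_model(
            result.model, X, y, groups=traits_base.subgroups(X.index)
        )
    completed.append("composite")
    _finish(manifest, t0, out_dir, result, study)
    return result


def _finish(manifest, t0, out_dir, result, study) -> None:
    import sklearn
    import numpy
    import scipy

    manifest.update(
        {
            "status": result.status,
            "runtime_s": round(time.time() - t0, 3),
            "versions": {
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "sklearn": sklearn.__version__,
                "pandas": pd.__version__,
            },
        }
    )
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, comp in (("skin", result.skin), ("blister", result.blister)):
        if comp is None:
            continue
        io_mod.write_module_assignment(comp.assignment, out / f"{name}_modules.tsv")
        io_mod.write_eigengenes(comp.eigengenes, out / f"{name}_eigengenes.tsv")
        comp.module_trait.table.to_csv(out / f"{name}_module_trait.tsv", sep="\t", index=False)
        comp.hub_table.to_csv(out / f"{name}_hub_table.tsv", sep="\t", index_label="analyte")
    if result.cross_modules is not None:
        result.cross_modules.to_csv(out / "crossmodal_modules.tsv", sep="\t", index=False)
    if result.cascade is not None:
        io_mod.write_cascade_report(result.cascade, out / "cascade")
    if result.model is not None:
        (out / "composite_model.json").write_text(result.model.to_json())
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
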