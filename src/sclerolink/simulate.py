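"""Synthetic multi-compartment cohort generator with ground truth.

Emulates the statistical structure the integration pipeline assumes: four
clinical subgroups with a latent skin-severity trait (mRSS-like, subgroup
means from the proteomics-cohort demographics), implanted coexpression
modules in skin transcripts and blister proteins, a subset of modules
sharing one latent factor across the two compartments and coupled to
severity, attenuated leakage of blister signal into plasma, private
severity components carried by a small set of "composite" analytes, and
pure-noise background analytes.

Generative model (all values on continuous log2-like scales):

  severity   s_j = round(drive_j + kappa * sum_k u_kj) clipped to [0, 51],
             where drive_j = mu_g(j) + shared jitter is the disease drive
             and the u_k are private severity components carried only by
             the composite analytes (clinically: facets of skin score not
             explained by the global disease process)
  factors    f_m = alpha_m * z(drive) + sqrt(1 - alpha_m^2) * eta_m, with
             shared modules using one factor across skin and blister
  analytes   x_ij = mu_i + tau_i * (lambda_i * f_m(j) + sigma * eps_ij)
  plasma     leakage for shared-module proteins:
             attenuation * signal_blister + c * u_k (composite only) + noise

The generator's defaults define the study conditions every recovery test
runs under; they are deliberately in the regime where hub analytes exist
(near-ceiling factor coupling), because the anchor trait - the early-dcSSc
indicator - is only imperfectly aligned with severity (late dcSSc also has
high mRSS, capping that correlation near 0.75).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anchor import IdentifierMap
from .containers import SUBGROUPS, ExpressionMatrix, TraitTable
from .errors import ConfigError

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticStudy", "generate_cohort", "generate_multiomics", "simulate_study"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the canonical study conditions."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"early_dcSSc": 14, "late_dcSSc": 11, "lcSSc": 16, "HC": 16}
    )
    severity_means: dict[str, float] = field(
        default_factory=lambda: {"early_dcSSc": 17.0, "late_dcSSc": 11.0, "lcSSc": 4.0, "HC": 0.0}
    )
    severity_jitter_sd: float = 3.0
    n_transcripts: int = 2000
    n_blister_proteins: int = 500
    n_plasma_proteins: int = 500
    n_skin_modules: int = 5
    n_blister_modules: int = 5
    n_plasma_modules: int = 3
    n_shared_modules: int = 2
    module_size_range: tuple[int, int] = (40, 60)
    loading_range: tuple[float, float] = (0.90, 0.98)
    trait_coupling: float = 0.97
    secondary_coupling: float = 0.75
    noise_sd: float = 0.30
    n_shared_hubs: int = 22
    n_composite: int = 4
    composite_severity_weight: float = 1.45
    composite_plasma_coupling: float = 0.8
    plasma_attenuation: float = 0.6
    plasma_noise_sd: float = 0.4
    month12_drift_sd: float = 5.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    scale_range: tuple[float, float] = (0.8, 1.5)
    seed: int = 1

    def validate(self) -> None:
        if set(self.group_sizes) != set(SUBGROUPS):
            raise ConfigError(f"group_sizes must cover {SUBGROUPS}")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ConfigError("every subgroup needs at least 2 samples")
        for g, m in self.severity_means.items():
            if not (0 <= m <= 51):
                raise ConfigError(f"severity mean for {g} outside [0, 51]")
        if self.module_size_range[0] < 30:
            raise ConfigError("module sizes must be >= 30")
        if self.module_size_range[0] > self.module_size_range[1]:
            raise ConfigError("module_size_range must be (low, high) with low <= high")
        if self.n_shared_modules > min(self.n_skin_modules, self.n_blister_modules):
            raise ConfigError("n_shared_modules exceeds per-compartment module count")
        if self.n_shared_hubs > self.module_size_range[0]:
            raise ConfigError("n_shared_hubs cannot exceed the smallest module size")
        if self.n_composite > self.n_shared_hubs:
            raise ConfigError("n_composite cannot exceed n_shared_hubs")
        if not (0 < self.plasma_attenuation <= 1):
            raise ConfigError("plasma_attenuation must lie in (0, 1]")
        if self.n_skin_modules * self.module_size_range[1] > self.n_transcripts:
            raise ConfigError("skin module sizes exceed the transcript budget")
        if self.n_blister_modules * self.module_size_range[1] > self.n_blister_proteins:
            raise ConfigError("blister module sizes exceed the protein budget")
        if self.n_plasma_proteins != self.n_blister_proteins:
            raise ConfigError("plasma and blister share one assay panel: protein counts must match")
        private = self.n_composite * self.composite_severity_weight**2
        if private > self.severity_jitter_sd**2 + 1e-12:
            raise ConfigError(
                "composite private-factor variance exceeds the severity jitter variance; "
                "lower composite_severity_weight or raise severity_jitter_sd"
            )

    def coupling_of(self, shared_index: int) -> float:
        """Trait coupling of the i-th shared module (0-based)."""
        return self.trait_coupling if shared_index == 0 else self.secondary_coupling


@dataclass
class SyntheticTruth:
    """Ground truth implanted by the generator.

    ``module_labels`` maps compartment name to an analyte -> integer
    label series (0 = background); shared modules carry the same positive
    id in skin and blister.  ``composite_genes`` is a subset of
    ``hub_genes``; ``composite_weights`` records, per composite gene, the
    weight of its private factor in the severity jitter and its loading
    in plasma.
    """

    module_labels: dict[str, pd.Series]
    shared_pairs: list[tuple[int, int]]
    hub_genes: list[str]
    composite_genes: list[str]
    composite_weights: dict[str, dict[str, float]]
    severity: pd.Series
    severity_month12: pd.Series

    def __post_init__(self) -> None:
        if not set(self.composite_genes) <= set(self.hub_genes):
            raise ConfigError("composite genes must be a subset of the shared hub genes")

    def to_json(self) -> str:
        return json.dumps(
            {
                "module_labels": {c: s.to_dict() for c, s in self.module_labels.items()},
                "shared_pairs": [list(p) for p in self.shared_pairs],
                "hub_genes": self.hub_genes,
                "composite_genes": self.composite_genes,
                "composite_weights": self.composite_weights,
                "severity": self.severity.to_dict(),
                "severity_month12": self.severity_month12.to_dict(),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            module_labels={c: pd.Series(v, dtype=int) for c, v in d["module_labels"].items()},
            shared_pairs=[tuple(p) for p in d["shared_pairs"]],
            hub_genes=d["hub_genes"],
            composite_genes=d["composite_genes"],
            composite_weights=d["composite_weights"],
            severity=pd.Series(d["severity"], dtype=float),
            severity_month12=pd.Series(d["severity_month12"], dtype=float),
        )


@dataclass
class SyntheticStudy:
    """Bundle of everything one simulated study produces."""

    traits: TraitTable
    expr_skin: ExpressionMatrix
    prot_blister: ExpressionMatrix
    prot_plasma: ExpressionMatrix
    expr_skin_month12: ExpressionMatrix
    idmap: IdentifierMap
    truth: SyntheticTruth
    config: SimConfig

    @property
    def traits_baseline(self) -> TraitTable:
        return self.traits.for_visit("baseline")

    @property
    def traits_month12(self) -> TraitTable:
        return self.traits.for_visit("month12")


def _standardise(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ConfigError("severity has zero variance; cannot build trait-coupled factors")
    return (v - v.mean()) / sd


def generate_cohort(cfg: SimConfig) -> tuple[TraitTable, dict]:
    """Subgroup labels, integer severity and the latent private factors.

    Baseline visit for every sample; a month-12 visit (with severity
    drifted per subject) exists only for the early-dcSSc subgroup,
    mirroring a 12-month prospective follow-up of early diffuse disease.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sample_ids, subgroups = [], []
    for g in SUBGROUPS:
        for _ in range(cfg.group_sizes[g]):
            sample_ids.append(f"S{len(sample_ids) + 1:03d}")
            subgroups.append(g)
    n = len(sample_ids)
    mu = np.array([cfg.severity_means[g] for g in subgroups])

    u = rng.standard_normal((cfg.n_composite, n))
    kappa = cfg.composite_severity_weight
    resid_var = cfg.severity_jitter_sd**2 - cfg.n_composite * kappa**2
    resid_sd = np.sqrt(max(resid_var, 0.0))
    drive = mu + resid_sd * rng.standard_normal(n)  # global disease process
    severity = np.clip(np.round(drive + kappa * u.sum(axis=0)), 0, 51).astype(int)

    rows = [
        {"sample_id": s, "subgroup": g, "mrss": int(v), "visit": "baseline"}
        for s, g, v in zip(sample_ids, subgroups, severity)
    ]
    early = [s for s, g in zip(sample_ids, subgroups) if g == "early_dcSSc"]
    drift = cfg.month12_drift_sd * rng.standard_normal(len(early))
    sev12, drive12 = {}, {}
    private = kappa * u.sum(axis=0)
    for s, d in zip(early, drift):
        i = sample_ids.index(s)
        drive12[s] = float(drive[i] + d)
        sev12[s] = int(np.clip(np.round(drive12[s] + private[i]), 0, 51))
        rows.append({"sample_id": s, "subgroup": "early_dcSSc", "mrss": sev12[s], "visit": "month12"})

    traits = TraitTable(pd.DataFrame(rows))
    latent = {
        "u": pd.DataFrame(u, index=[f"u{k + 1}" for k in range(cfg.n_composite)], columns=sample_ids),
        "severity": pd.Series(severity, index=sample_ids, dtype=int),
        "severity_month12": pd.Series(sev12, dtype=int),
        "drive": pd.Series(drive, index=sample_ids, dtype=float),
        "drive_month12": pd.Series(drive12, dtype=float),
        "subgroup": pd.Series(subgroups, index=sample_ids),
        "rng": rng,
    }
    return traits, latent


def _module_sizes(rng, n_modules: int, cfg: SimConfig) -> list[int]:
    lo, hi = cfg.module_size_range
    return [int(rng.integers(lo, hi + 1)) for _ in range(n_modules)]


def _compartment_signal(rng, n_analytes, n_samples, module_members, factors, loadings, cfg):
    """Signal-scale matrix (analyte x sample): module analytes load on
    their factor, background analytes are pure noise."""
    out = rng.standard_normal((n_analytes, n_samples))  # background rows: unit noise
    for m, idx in module_members.items():
        f = factors[m]
        lam = loadings[m]
        eps = rng.standard_normal((len(idx), n_samples))
        out[idx] = lam[:, None] * f[None, :] + cfg.noise_sd * eps
    return out


def generate_multiomics(traits: TraitTable, latent: dict, cfg: SimConfig) -> SyntheticStudy:
    """Generate skin, blister, plasma and 12-month skin matrices.

    Shared modules reuse one latent factor across skin and blister;
    blister shared-module proteins leak into plasma with attenuation;
    composite analytes additionally carry their private severity factor
    into plasma.  All matrices get per-analyte baselines and scales so
    values look like log-scale expression / NPX rather than z-scores.
    """
    cfg.validate()
    rng = latent["rng"]
    samples = list(latent["severity"].index)
    n = len(samples)
    # trait-coupled factors track the latent disease drive; the measured
    # mRSS adds the composite analytes' private components on top
    z = _standardise(latent["drive"].to_numpy())
    u = latent["u"].to_numpy()

    lo_l, hi_l = cfg.loading_range

    def draw_loadings(k):
        return rng.uniform(lo_l, hi_l, size=k)

    def factor(alpha):
        eta = rng.standard_normal(n)
        return alpha * z + np.sqrt(max(1.0 - alpha**2, 0.0)) * eta

    # ---- module layout -------------------------------------------------
    gene_ids = [f"GENE{i:04d}" for i in range(1, cfg.n_transcripts + 1)]
    protein_ids = [f"PROT{i:04d}" for i in range(1, cfg.n_blister_proteins + 1)]

    skin_sizes = _module_sizes(rng, cfg.n_skin_modules, cfg)
    blister_sizes = _module_sizes(rng, cfg.n_blister_modules, cfg)

    shared_factors = [factor(cfg.coupling_of(i)) for i in range(cfg.n_shared_modules)]

    skin_members: dict[int, np.ndarray] = {}
    pos = 0
    for m, size in enumerate(skin_sizes, start=1):
        skin_members[m] = np.arange(pos, pos + size)
        pos += size
    blister_members: dict[int, np.ndarray] = {}
    pos = 0
    for m, size in enumerate(blister_sizes, start=1):
        blister_members[m] = np.arange(pos, pos + size)
        pos += size

    skin_factors = {
        m: (shared_factors[m - 1] if m <= cfg.n_shared_modules else factor(0.0))
        for m in skin_members
    }
    blister_factors = {
        m: (shared_factors[m - 1] if m <= cfg.n_shared_modules else factor(0.0))
        for m in blister_members
    }
    skin_loadings = {m: draw_loadings(len(idx)) for m, idx in skin_members.items()}
    blister_loadings = {m: draw_loadings(len(idx)) for m, idx in blister_members.items()}

    # identifier map: hub genes of the primary shared module map onto the
    # first proteins of the primary blister module; a slice of the second
    # shared module and some background analytes are mapped too.
    gene_to_protein: dict[str, str] = {}
    hub_gene_idx = skin_members[1][: cfg.n_shared_hubs]
    hub_prot_idx = blister_members[1][: cfg.n_shared_hubs]
    for gi, pi in zip(hub_gene_idx, hub_prot_idx):
        gene_to_protein[gene_ids[gi]] = protein_ids[pi]
    if cfg.n_shared_modules >= 2:
        k = min(10, len(skin_members[2]), len(blister_members[2]))
        for gi, pi in zip(skin_members[2][:k], blister_members[2][:k]):
            gene_to_protein[gene_ids[gi]] = protein_ids[pi]
    bg_genes = np.arange(sum(skin_sizes), min(sum(skin_sizes) + 50, cfg.n_transcripts))
    bg_prots = np.arange(sum(blister_sizes), min(sum(blister_sizes) + 50, cfg.n_blister_proteins))
    for gi, pi in zip(bg_genes, bg_prots):
        gene_to_protein[gene_ids[gi]] = protein_ids[pi]
    idmap = IdentifierMap(gene_to_protein)

    # ---- signal-scale matrices ----------------------------------------
    skin_sig = _compartment_signal(rng, cfg.n_transcripts, n, skin_members, skin_factors, skin_loadings, cfg)
    blister_sig = _compartment_signal(
        rng, cfg.n_blister_proteins, n, blister_members, blister_factors, blister_loadings, cfg
    )

    # plasma: shared-module proteins leak from blister; composite genes
    # add their private severity factor; dedicated decoy modules and
    # background fill the rest of the panel.
    plasma_sig = rng.standard_normal((cfg.n_plasma_proteins, n))
    shared_prot_idx = np.concatenate(
        [blister_members[m] for m in range(1, cfg.n_shared_modules + 1)]
    )
    nu = rng.standard_normal((len(shared_prot_idx), n))
    plasma_sig[shared_prot_idx] = (
        cfg.plasma_attenuation * blister_sig[shared_prot_idx] + cfg.plasma_noise_sd * nu
    )
    composite_gene_ids = [gene_ids[i] for i in hub_gene_idx[: cfg.n_composite]]
    for k, gi in enumerate(hub_gene_idx[: cfg.n_composite]):
        pi = int(hub_prot_idx[k])
        plasma_sig[pi] += cfg.composite_plasma_coupling * u[k]

    # plasma-only decoy modules on the unused tail of the panel
    free = [i for i in range(cfg.n_plasma_proteins) if i not in set(shared_prot_idx)]
    plasma_members: dict[int, np.ndarray] = {}
    pos = 0
    for m in range(1, cfg.n_plasma_modules + 1):
        size = int(rng.integers(*cfg.module_size_range) + 0)
        if pos + size > len(free):
            break
        plasma_members[m] = np.asarray(free[pos : pos + size])
        pos += size
    for m, idx in plasma_members.items():
        f = factor(0.0)
        lam = draw_loadings(len(idx))
        eps = rng.standard_normal((len(idx), n))
        plasma_sig[idx] = lam[:, None] * f[None, :] + cfg.noise_sd * eps

    # ---- baselines and scales -----------------------------------------
    def dress(sig, ids, reuse=None):
        if reuse is None:
            mu_a = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=sig.shape[0])
            tau = rng.uniform(*cfg.scale_range, size=sig.shape[0])
        else:
            mu_a, tau = reuse
        return pd.DataFrame(mu_a[:, None] + tau[:, None] * sig, index=ids, columns=samples), (mu_a, tau)

    skin_df, skin_dress = dress(skin_sig, gene_ids)
    blister_df, blister_dress = dress(blister_sig, protein_ids)
    # plasma reuses the blister per-assay baseline/scale (same assay panel)
    plasma_df, _ = dress(plasma_sig, protein_ids, reuse=blister_dress)

    # ---- month-12 skin matrix (early-dcSSc follow-up cohort) ----------
    early = list(latent["severity_month12"].index)
    z12 = _standardise(latent["drive_month12"].to_numpy())
    n12 = len(early)
    skin12_sig = rng.standard_normal((cfg.n_transcripts, n12))
    for m, idx in skin_members.items():
        alpha = cfg.coupling_of(m - 1) if m <= cfg.n_shared_modules else 0.0
        eta = rng.standard_normal(n12)
        f12 = alpha * z12 + np.sqrt(max(1.0 - alpha**2, 0.0)) * eta
        eps = rng.standard_normal((len(idx), n12))
        skin12_sig[idx] = skin_loadings[m][:, None] * f12[None, :] + cfg.noise_sd * eps
    mu_a, tau = skin_dress
    skin12_df = pd.DataFrame(mu_a[:, None] + tau[:, None] * skin12_sig, index=gene_ids, columns=early)

    # ---- ground truth --------------------------------------------------
    def labels(ids, members):
        lab = pd.Series(0, index=ids, dtype=int)
        for m, idx in members.items():
            lab.iloc[idx] = m
        return lab

    hub_gene_list = [gene_ids[i] for i in hub_gene_idx]
    truth = SyntheticTruth(
        module_labels={
            "skin": labels(gene_ids, skin_members),
            "blister": labels(protein_ids, blister_members),
            "plasma": labels(protein_ids, plasma_members),
        },
        shared_pairs=[(m, m) for m in range(1, cfg.n_shared_modules + 1)],
        hub_genes=hub_gene_list,
        composite_genes=composite_gene_ids,
        composite_weights={
            g: {
                "severity_weight": cfg.composite_severity_weight,
                "plasma_loading": float(
                    cfg.composite_plasma_coupling * blister_dress[1][int(hub_prot_idx[k])]
                ),
            }
            for k, g in enumerate(composite_gene_ids)
        },
        severity=latent["severity"].astype(float),
        severity_month12=latent["severity_month12"].astype(float),
    )

    return SyntheticStudy(
        traits=traits,
        expr_skin=ExpressionMatrix(skin_df, compartment="skin", visit="baseline"),
        prot_blister=ExpressionMatrix(blister_df, compartment="blister", visit="baseline"),
        prot_plasma=ExpressionMatrix(plasma_df, compartment="plasma", visit="baseline"),
        expr_skin_month12=ExpressionMatrix(skin12_df, compartment="skin", visit="month12"),
        idmap=idmap,
        truth=truth,
        config=cfg,
    )


def simulate_study(cfg: SimConfig | None = None) -> SyntheticStudy:
    """Convenience wrapper: cohort + multi-omics in one call."""
    cfg = cfg or SimConfig()
    traits, latent = generate_cohort(cfg)
    return generate_multiomics(traits, latent, cfg)
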