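# Methods

## Scope and data model

`sclerolink` implements a cross-compartment coexpression analysis for
multi-compartment cohorts in systemic sclerosis: skin biopsy
transcriptomics, blister-fluid proteomics and plasma proteomics from the
same participants, with subgroup labels (early dcSSc, late dcSSc, lcSSc,
healthy controls), an mRSS severity score per disease participant, and a
baseline plus an optional 12-month visit restricted to the early-dcSSc
cohort. Inputs are assumed pre-normalised (rlog-style expression for
transcripts, NPX log2 for proteins); read processing and assay
normalisation are out of scope, as are pathway enrichment (needs
external gene-set databases) and graphics.

## Network construction

Adjacency is unsigned soft-thresholded correlation, `a_ij =
|cor(x_i, x_j)|^β`, with Pearson correlation on the normalised matrix
(the coexpression convention) even though trait associations elsewhere
default to Spearman; both are configurable, as is the signed variant
`((1 + cor)/2)^β`. Constant analyte rows are dropped with a warning.

The default power is β = 7.0 for every compartment. A data-driven
selection path exists (`power_beta=None`): connectivities are binned
(10 equal-width bins), log10 frequency is regressed on log10 mean
connectivity, and the fit index is R² signed by the negative regression
slope; the smallest candidate power reaching 0.8 wins, falling back to
the best fit with a warning. We deliberately do **not** make selection
the default for protein compartments: the proteomic "standard deviation
parameter for soft-thresholding" sometimes quoted for such data (0.2
blister, 0.3 plasma) has no counterpart in standard coexpression
methodology, so it is stored in `NetworkConfig.protein_sd_param` for
provenance only and never enters a formula, and a single fixed default
power keeps the downstream dendrogram geometry comparable across
compartments.

Topological overlap uses the standard unsigned form with the
shared-neighbour sum computed by matrix multiplication; a brute-force
O(n³) loop serves as the oracle in tests (agreement to 1e-12). Matrices
are dense; the intended scale (≤ ~20 000 analytes) fits comfortably in
memory without block-wise decomposition.

## Module detection

Average-linkage hierarchical clustering of `d = 1 − ω`, then the
simplified "tree" flavour of dynamic tree cut: delete all merges above a
cut height, keep every resulting branch with at least `min_size = 30`
leaves as a module, label everything else grey. Module ids are ordered
by decreasing size and mapped to a fixed colour palette, so runs are
reproducible (deterministic naming replaces random colour titles).
Eigengene-similarity module merging is not implemented: the cut is the
only module-forming step, which keeps detected modules in one-to-one
correspondence with dendrogram branches.

**Cut-height default.** The cut is an absolute height 0.75 on the
`1 − TOM` scale, not a quantile of merge heights. A quantile default is
degenerate on module-plus-background data: with a few hundred module
analytes among thousands of background analytes, ~85% of all merges are
background merges concentrated just below the maximum height, so any
high quantile (e.g. 0.99) lands above nearly every merge and returns one
giant background module. On soft-power-7 networks, implanted modules
complete their internal merges well below 0.65 while background and
cross-module merges sit above 0.85, so 0.75 separates the two regimes
with margin. A `cut_quantile` mode is still available (inclusive of
merges exactly at the quantile).

Eigengenes are the leading right singular vector of the row-standardised
module submatrix, scaled to unit variance (ddof = 1) and sign-oriented
toward positive correlation with the module's mean standardised
expression, which keeps module–trait signs stable across runs and
machines.

## Trait association and hubs

Gene significance is the correlation of an analyte with the early-dcSSc
indicator encoded 1/0 (point-biserial through the configured method);
module membership is the correlation with the own-module eigengene;
grey analytes get missing kME. Module–trait correlations are BH-adjusted
across the whole module × trait family per compartment at 0.05.
Correlation defaults to Spearman study-wide (Pearson by argument).

Hub analytes must satisfy, with strict inequalities, GS > 0.6,
kME > 0.7 and p < 0.01 on **both** p-values — the threshold is applied
to the GS and the kME test alike, using unadjusted p at this step (the
BH families are the module–trait matrices and the cascade stages).
Hubs are then restricted to anchored modules: a module is anchored iff
its early-dcSSc association survives BH at 0.05 *and* it has at least
one cross-compartment partner module that is itself trait-significant
with a BH-significant eigengene–eigengene correlation.

## Cascade and composite model

Shared hubs — analytes hub in an anchored skin module and, through a
one-to-one gene↔protein-assay identifier map, in an anchored blister
module — pass through four sequential filters: skin↔blister
correlation, blister↔plasma, plasma↔mRSS (significance is required in
plasma; skin and blister mRSS correlations are reported but do not
filter), and 12-month skin transcript↔12-month mRSS. Each stage is a
separate BH family at α = 0.05 (the stages are reported sequentially,
so per-stage families; raw p-values are retained in the per-stage
tables). Survivor sets are nested by construction and asserted on every
run. Correlations use the maximal pairwise-complete sample set, which
accommodates unequal blister availability.

The composite model is a LASSO of mRSS on the plasma NPX values of
*all* shared hubs (not only post-cascade survivors — the cascade is
reported alongside for interpretation). Predictors are standardised;
the penalty is chosen by 10-fold cross-validated MSE (minimum rule,
shuffled folds seeded from the run seed) over a log-spaced grid;
coefficients are back-transformed to the NPX scale, and the reported
model is the penalised fit at the chosen penalty, not an OLS refit
(the later OLS only relates predicted to actual). An all-zero fit is a
legitimate outcome reported as `status="empty"`, not an exception.
Evaluation: OLS of actual on predicted (r from fitted-vs-observed, p
from the F test), Bland–Altman bias ± 1.96·SD (ddof = 1), and one-way
ANOVA with Tukey–Kramer post-hoc contrasts of the predicted score
across subgroups (healthy controls enter only this comparison).

## Synthetic cohort generator

The generator (`sclerolink.simulate`) emulates the statistical structure
the analysis assumes, with group sizes 14/11/16/16 and subgroup mRSS
means 17/11/4/0 matching the proteomics-cohort demographics it mirrors.
Severity decomposes as `mRSS = drive + κ·Σ u_k` (rounded, clipped to
0–51): `drive` is the global disease process (subgroup mean plus
residual jitter), and the `u_k` are four private standard-normal
components, each carried into plasma only by one designated composite
analyte. Trait-coupled module factors track the standardised *drive*
(`f = α·z(drive) + √(1−α²)·η`); shared modules reuse one factor across
skin and blister; analytes are `x = μ_i + τ_i(λ_i f + σ ε)` with
per-analyte baselines and scales so values resemble log2/NPX data;
background analytes are pure noise. Plasma values of shared-module
proteins are `attenuation·blister_signal + noise`, with the composite
analytes adding `c·u_k`; the plasma panel shares the blister assay ids.
A 12-month skin matrix is regenerated for the early-dcSSc cohort with
per-subject severity drift; 12-month plasma is intentionally not
generated (follow-up plasma proteomes are typically unavailable).

Default parameters (one place: `SimConfig`): jitter sd 3.0 mRSS units
with κ = 1.45 per private component, primary/secondary shared-module
coupling α = 0.97 / 0.75, loadings 0.90–0.98, analyte noise sd 0.30,
plasma attenuation 0.6 with noise sd 0.4 and composite plasma loading
c = 0.8, 12-month drift sd 5.0 (mRSS in early diffuse disease commonly
moves by several points over a year). Two structural facts shaped these
choices. First, the anchor trait is the *early-dcSSc indicator* while
severity is also high in late dcSSc, so the trait–severity correlation
is capped near 0.75–0.82 regardless of noise; hub analytes
(GS > 0.6 by design) therefore require near-ceiling factor coupling —
this is the regime in which hub-based discovery is possible at all, and
it is the regime the generator deliberately occupies. Second, routing
the private components through the severity jitter (rather than letting
module factors see the full mRSS) is what makes each composite analyte
carry signal no decoy can substitute, so that sparse selection is
well-posed.

What the generator does *not* emulate: count noise and normalisation
artefacts of sequencing, Olink assay chemistry (hook effects, LOD
censoring), batch effects, missing blister draws, correlated clinical
covariates, and heavy-tailed expression. Passing recovery tests
therefore demonstrates that the pipeline's logic is correct and
well-calibrated under its own assumptions — not that real cohorts of
this size would yield equally clean recovery.

## Numerical choices and degenerate inputs

- Spearman p-values use the t-approximation (n − 2 df), which scales to
  thousands of analytes; exact permutation p-values are a non-goal.
- Pairwise-complete handling for correlations, listwise for OLS/LASSO;
  correlations need ≥ 3 complete pairs and non-zero variance, otherwise
  typed errors (`DegenerateInputError`, `UndefinedCorrelationError`).
- BH adjustment propagates NaN inputs as NaN and excludes them from the
  ranking; adjusted values are clipped at 1 and order-preserving.
- ANOVA with zero between-group variance returns F = 0, p = 1; zero
  within-group variance with separated means returns F = ∞, p = 0;
  groups with < 2 observations raise. Tukey uses the unequal-n
  (Tukey–Kramer) studentized-range form.
- Tree-cut ties: candidate modules of equal size are ordered by first
  leaf position, making colour assignment deterministic.
- The unpenalised LASSO limit (`lambda_grid=[0]`) is solved by the same
  coordinate descent (tight tolerance), matching OLS to 1e-6 on
  well-conditioned designs.
- All randomness flows from explicit integer seeds (generator seed for
  data, run seed for CV fold shuffling).

## Problem sizes

Unit tests run a scaled-down cohort (400 transcripts, 160 proteins,
3 modules); the acceptance suite and the analysis scripts run the full
default conditions (2000 transcripts, 500 + 500 proteins, 5 + 5 + 3
modules, 57 + 14 samples) across 5–10 seeds, which completes in a few
minutes on a single CPU. These sizes are the package's canonical study
conditions, scaled to keep dense TOM computation (the O(n³) step)
routine.

## Known limitations

- The tree cut is the simplified static-height variant; the published
  adaptive "hybrid" dynamic cut with its PAM stage is a non-goal, so
  very close or nested modules that the adaptive method would split may
  be merged here (and vice versa for shallow branches).
- Module counts on real data (tens of modules in transcriptome-scale
  inputs) depend on data unavailable at this scale; they are not
  reproduction targets of the synthetic conditions.
- The identifier map must be one-to-one; many-to-one gene↔assay
  relations (isoforms, protein complexes) raise rather than guess.
- LASSO support under heavy collinearity is intrinsically unstable;
  support-recovery guarantees hold for the generator's regime, where
  each true analyte carries unique signal.
- No longitudinal change-score modelling: 12-month data enter only as a
  confirmation filter, mirroring the absence of follow-up plasma.
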