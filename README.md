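# sclerolink

Cross-compartment coexpression anchoring of skin transcriptomics,
blister-fluid proteomics and plasma proteomics in systemic sclerosis,
with a LASSO-derived plasma composite surrogate for the modified Rodnan
skin score (mRSS).

## The problem

Skin severity in systemic sclerosis is scored clinically by the mRSS
(17 sites, 0–3 each, total 0–51), which suffers from inter-observer
variability. Skin biopsy transcriptomics and dermal suction-blister
fluid proteomics sample the local disease environment directly, but
neither is practical for routine monitoring. The idea implemented here
is to use the skin and blister compartments as *anchors*: find
coexpression modules that are shared between the two compartments and
associated with early diffuse cutaneous disease (early dcSSc), select
their hub analytes, keep the ones whose signal survives all the way into
plasma and tracks mRSS, and compress those into a small plasma protein
panel that predicts the skin score from a blood draw.

The pipeline is intended for analysts working with per-compartment
analyte × sample matrices (log-scale expression for transcripts, Olink
NPX log2 units for proteins) plus a sample metadata table (subgroup,
mRSS, visit). Because no public dataset accompanies the design, a
first-class synthetic cohort generator with ground truth
(`sclerolink.simulate`) defines the study conditions every test runs
under.

## Method

Per compartment, a weighted coexpression network in the WGCNA style:

- adjacency `a_ij = |cor(x_i, x_j)|^β` (unsigned, β = 7 by default;
  signed and data-driven scale-free selection available),
- topological overlap
  `ω_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
- average-linkage clustering of `1 − ω` with a static-height tree cut
  (minimum module size 30; unassigned analytes are grey),
- module eigengenes `ME` = first principal component of the
  standardised module submatrix, oriented positively.

Association and anchoring (Spearman throughout, Benjamini–Hochberg
FDR < 0.05 per family):

- gene significance `GS_i = cor(x_i, early-dcSSc indicator)`,
- module membership `kME_i = cor(x_i, ME_own module)`,
- hub analytes: `GS > 0.6`, `kME > 0.7`, both `p < 0.01`, inside a
  module that is trait-significant *and* has a significant
  cross-compartment partner module,
- a cascade over the shared skin∩blister hubs: skin↔blister
  correlation, blister↔plasma, plasma↔mRSS, and 12-month skin
  transcript↔12-month mRSS in the early-dcSSc follow-up cohort
  (stage sets are nested by construction).

Finally a LASSO regression of mRSS on the plasma NPX values of all
shared hubs (standardised predictors, 10-fold cross-validated penalty,
coefficients back-transformed to the NPX scale), evaluated by
predicted-vs-actual OLS, Bland–Altman limits of agreement, and subgroup
ANOVA with Tukey post-hoc contrasts. The published four-analyte panel is
shipped as `sclerolink.PUBLISHED_COMPOSITE`:

```
mRSS = −25.898 + 0.0014·TNC + 2.818·COMP + 1.343·COL4A1 + 2.562·SPON1
```

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic cohort (57 baseline participants: 14 early dcSSc /
11 late dcSSc / 16 lcSSc / 16 healthy controls; 2000 transcripts,
500 blister/plasma proteins, 5 implanted modules per compartment of
which 2 are shared and trait-coupled, 22 implanted shared hub genes of
which 4 carry private severity signal into plasma):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_build_networks.py
python analysis/03_detect_modules.py
python analysis/04_anchor_modules.py
python analysis/05_hub_analytes.py
python analysis/06_cascade.py
python analysis/07_composite_model.py --seed 1
```

which prints, at seed 1:

```
skin: 5 modules, sizes [56, 52, 49, 48, 47], 1748 grey analytes, ARI vs implanted truth = 1.000
blister: 5 modules, sizes [60, 60, 57, 49, 45], 229 grey analytes, ARI vs implanted truth = 1.000
anchored module pairs -> skin: ['green', 'yellow'], blister: ['green', 'turquoise']
26 analytes are hubs in both compartments (sensitivity vs implanted truth: 1.00)
cascade survivor counts: 26 -> 26 -> 26 -> 26 -> 22
LASSO kept 15/26 analytes (lambda = 0.15)
implanted composite analytes in support: 4/4 ['GENE0001', 'GENE0002', 'GENE0003', 'GENE0004']
predicted vs actual mRSS: r = 0.961 (p = 1.85e-32)
Bland-Altman: bias 0.00, limits of agreement [-3.70, 3.70]
subgroup ANOVA of predicted mRSS: p = 4.51e-22
```

Module detection recovers the five implanted modules exactly (ARI 1.0),
anchoring keeps precisely the two shared trait-coupled modules per
compartment, all 22 implanted hub genes are recovered (plus a few from
the weakly coupled second shared module), and the LASSO support contains
all four implanted composite analytes. Everything is also available in
one call: `sclerolink.run_pipeline(simulate_study(SimConfig(seed=1)))`.

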