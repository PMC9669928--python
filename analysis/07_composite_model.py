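#!/usr/bin/env python
"""Fit and evaluate the plasma composite mRSS surrogate.

LASSO on the plasma NPX values of all shared hub analytes (10-fold CV,
minimum-MSE penalty), coefficients back-transformed to the NPX scale;
evaluation by predicted-vs-actual OLS, Bland-Altman limits of agreement,
and subgroup ANOVA of the predicted score.
"""

import argparse
import json
from pathlib import Path

from sclerolink import evaluate_model, io, lasso_fit, predict_mrss
from sclerolink.simulate import SyntheticTruth

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "composite"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    data = ROOT / "data"
    shared = json.loads((ROOT / "hubs" / "shared_hubs.json").read_text())
    idmap = io.read_identifier_map(data / "identifier_map.tsv")
    plasma = io.read_expression_matrix(data / "plasma_npx.tsv", "plasma")
    traits = io.read_metadata(data / "metadata.csv").for_visit("baseline")
    truth = SyntheticTruth.from_json((data / "truth.json").read_text())

    X = plasma.data.loc[[idmap.protein(g) for g in shared]].T
    X.columns = shared
    y = traits.mrss(X.index)

    model = lasso_fit(X, y, cv_folds=10, seed=seed)
    (OUT / "composite_model.json").write_text(model.to_json())
    print(f"LASSO kept {len(model.coefficients)}/{len(shared)} analytes "
          f"(lambda = {model.lambda_:.4g})")
    recovered = set(truth.composite_genes) & set(model.coefficients)
    print(f"implanted composite analytes in support: "
          f"{len(recovered)}/{len(truth.composite_genes)} {sorted(recovered)}")

    ev = evaluate_model(model, X, y, groups=traits.subgroups(X.index))
    pred = predict_mrss(model, X)
    pred.rename("predicted_mrss").to_frame().assign(actual_mrss=y).to_csv(
        OUT / "predicted_vs_actual.tsv", sep="\t", index_label="sample_id"
    )
    summary = {
        "r_pred_actual": ev.r_pred_actual,
        "p": ev.p,
        "bland_altman": {
            "bias": ev.bland_altman.bias,
            "loa_low": ev.bland_altman.loa_low,
            "loa_high": ev.bland_altman.loa_high,
        },
        "subgroup_anova_p": None if ev.subgroup_anova is None else ev.subgroup_anova.p,
        "tukey": None if ev.subgroup_anova is None else ev.subgroup_anova.pairwise,
    }
    (OUT / "evaluation.json").write_text(json.dumps(summary, indent=2))
    print(f"predicted vs actual mRSS: r = {ev.r_pred_actual:.3f} (p = {ev.p:.2e})")
    ba = ev.bland_altman
    print(f"Bland-Altman: bias {ba.bias:.2f}, limits of agreement "
          f"[{ba.loa_low:.2f}, {ba.loa_high:.2f}]")
    if ev.subgroup_anova:
        print(f"subgroup ANOVA of predicted mRSS: p = {ev.subgroup_anova.p:.2e}")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    main(p.parse_args().seed)
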