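#!/usr/bin/env python
"""Select hub analytes and intersect them across compartments.

Gene significance (correlation with the early-dcSSc indicator) and
module membership (correlation with the own-module eigengene) per
analyte; hubs satisfy GS > 0.6, kME > 0.7 and p < 0.01 on both, inside
an anchored module.  Skin hub genes are intersected with blister hub
proteins through the identifier map.
"""

import json
from pathlib import Path

from sclerolink import io
from sclerolink.anchor import intersect_hubs
from sclerolink.simulate import SyntheticTruth
from sclerolink.traits import build_hub_table, select_hubs

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "hubs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    traits = io.read_metadata(ROOT / "data" / "metadata.csv").for_visit("baseline")
    anchored = json.loads((ROOT / "anchoring" / "anchored_modules.json").read_text())
    idmap = io.read_identifier_map(ROOT / "data" / "identifier_map.tsv")
    truth = SyntheticTruth.from_json((ROOT / "data" / "truth.json").read_text())

    hubs = {}
    for name, matrix in (("skin", "skin_expression.tsv"), ("blister", "blister_npx.tsv")):
        expr = io.read_expression_matrix(ROOT / "data" / matrix, name)
        assign = io.read_module_assignment(ROOT / "modules" / f"{name}_modules.tsv")
        mes = io.read_eigengenes(ROOT / "modules" / f"{name}_eigengenes.tsv")
        mes.module_ids = {c: i for i, c in assign.colors.items() if c in mes.me.index}
        table = build_hub_table(expr, mes, assign, traits)
        table.to_csv(OUT / f"{name}_hub_table.tsv", sep="\t", index_label="analyte")
        hubs[name] = select_hubs(table, modules=anchored[name])
        print(f"{name}: {len(hubs[name])} hub analytes in anchored modules "
              f"{anchored[name]}")

    shared = intersect_hubs(hubs["skin"], hubs["blister"], idmap)
    (OUT / "shared_hubs.json").write_text(json.dumps(shared, indent=2))
    sens = len(set(shared) & set(truth.hub_genes)) / len(truth.hub_genes)
    print(f"{len(shared)} analytes are hubs in both compartments "
          f"(sensitivity vs implanted truth: {sens:.2f})")


if __name__ == "__main__":
    main()
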