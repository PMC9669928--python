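#!/usr/bin/env python
"""Anchor modules to the early-dcSSc trait and across compartments.

Correlates every module eigengene with the clinical traits (Spearman, BH
within each compartment's module x trait family), correlates skin and
blister eigengenes with each other, and keeps the module pairs that are
trait-significant on both sides with a significant cross-compartment
partner.
"""

import json
from pathlib import Path

from sclerolink import io
from sclerolink.anchor import crossmodal_module_correlation, select_anchored_modules
from sclerolink.traits import module_trait_correlation

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "anchoring"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    traits = io.read_metadata(ROOT / "data" / "metadata.csv").for_visit("baseline")
    mes = {
        name: io.read_eigengenes(ROOT / "modules" / f"{name}_eigengenes.tsv")
        for name in ("skin", "blister")
    }
    mt = {
        name: module_trait_correlation(m, traits)
        for name, m in mes.items()
    }
    for name, res in mt.items():
        res.table.to_csv(OUT / f"{name}_module_trait.tsv", sep="\t", index=False)
        sig = res.significant_modules("early_dcSSc")
        print(f"{name}: modules correlated with early dcSSc (BH p<0.05): {sig}")

    cross = crossmodal_module_correlation(mes["skin"], mes["blister"])
    cross.to_csv(OUT / "crossmodal_modules.tsv", sep="\t", index=False)
    anchored_skin, anchored_blister = select_anchored_modules(mt["skin"], mt["blister"], cross)
    (OUT / "anchored_modules.json").write_text(
        json.dumps({"skin": anchored_skin, "blister": anchored_blister}, indent=2)
    )
    print(f"anchored module pairs -> skin: {anchored_skin}, blister: {anchored_blister}")


if __name__ == "__main__":
    main()
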