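#!/usr/bin/env python
"""Run the cross-compartment correlation cascade on the shared hubs.

Stage 1: skin transcript vs blister protein; stage 2: blister vs plasma;
stage 3: plasma vs mRSS; stage 4: 12-month skin transcript vs 12-month
mRSS in the early-dcSSc follow-up cohort.  Each stage is BH-adjusted
within its own family; survivors carry forward (nested by construction).
"""

from pathlib import Path

from sclerolink import io
from sclerolink.anchor import cascade_filter

import json

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "cascade"


def main() -> None:
    data = ROOT / "data"
    shared = json.loads((ROOT / "hubs" / "shared_hubs.json").read_text())
    traits = io.read_metadata(data / "metadata.csv")
    report = cascade_filter(
        shared,
        io.read_expression_matrix(data / "skin_expression.tsv", "skin"),
        io.read_expression_matrix(data / "blister_npx.tsv", "blister"),
        io.read_expression_matrix(data / "plasma_npx.tsv", "plasma"),
        traits.for_visit("baseline"),
        io.read_identifier_map(data / "identifier_map.tsv"),
        expr_skin_month12=io.read_expression_matrix(
            data / "skin_expression_month12.tsv", "skin", visit="month12"
        ),
        traits_month12=traits.for_visit("month12"),
    )
    io.write_cascade_report(report, OUT)
    sizes = report.sizes()
    arrow = " -> ".join(str(sizes[s]) for s in report.STAGE_ORDER if s in sizes)
    print(f"cascade survivor counts: {arrow}")
    print(f"final candidates: {report.stages[report.STAGE_ORDER[-1]]}")


if __name__ == "__main__":
    main()
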