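"""In-memory containers for compartment matrices and sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

SUBGROUPS = ("early_dcSSc", "late_dcSSc", "lcSSc", "HC")
VISITS = ("baseline", "month12")
MRSS_MAX = 51


@dataclass
class ExpressionMatrix:
    """Analyte x sample numeric matrix tagged with compartment and visit.

    ``data`` rows are analytes (index = analyte ids), columns are sample
    ids.  Values are on a continuous log-like scale (rlog-style expression
    for transcripts, NPX log2 for proteins).
    """

    data: pd.DataFrame
    compartment: str = "unspecified"
    visit: str = "baseline"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate analyte ids: {dupes}")
        self.data = self.data.astype(float)

    @property
    def analytes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.compartment, self.visit)

    def subset_analytes(self, analyte_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(analyte_ids)], self.compartment, self.visit)


@dataclass
class TraitTable:
    """Per-sample clinical metadata: subgroup, mRSS, visit, indicators.

    The disease-subgroup indicators (``early_dcSSc`` etc.) are derived
    binary traits; ``mrss`` is the modified Rodnan skin score (0-51).
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "subgroup", "mrss", "visit")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise SchemaError(f"metadata missing required column(s): {missing}")
        df = self.df.copy()
        bad = set(df["subgroup"]) - set(SUBGROUPS)
        if bad:
            raise SchemaError(f"unknown subgroup value(s): {sorted(bad)}")
        bad_visit = set(df["visit"]) - set(VISITS)
        if bad_visit:
            raise SchemaError(f"unknown visit value(s): {sorted(bad_visit)}")
        mrss = pd.to_numeric(df["mrss"], errors="coerce")
        present = mrss.notna()
        if ((mrss[present] < 0) | (mrss[present] > MRSS_MAX)).any():
            raise SchemaError(f"mrss values must lie in [0, {MRSS_MAX}]")
        disease = df["subgroup"] != "HC"
        if (disease & ~present).any():
            raise SchemaError("mrss must be present for all disease samples")
        df["mrss"] = mrss
        if df.duplicated(["sample_id", "visit"]).any():
            raise SchemaError("duplicate (sample_id, visit) rows in metadata")
        self.df = df.reset_index(drop=True)

    def for_visit(self, visit: str) -> "TraitTable":
        return TraitTable(self.df[self.df["visit"] == visit].copy())

    def indexed(self) -> pd.DataFrame:
        """One row per sample_id (requires a single visit)."""
        if self.df["sample_id"].duplicated().any():
            raise SchemaError("sample ids not unique; select a visit first")
        return self.df.set_index("sample_id")

    def numeric_traits(self, samples=None) -> pd.DataFrame:
        """Trait x sample numeric matrix: mRSS plus subgroup indicators."""
        meta = self.indexed()
        if samples is not None:
            meta = meta.loc[list(samples)]
        traits = pd.DataFrame(index=meta.index)
        traits["mrss"] = meta["mrss"]
        for g in SUBGROUPS:
            traits[g] = (meta["subgroup"] == g).astype(float)
        return traits.T

    def indicator(self, subgroup: str, samples=None) -> pd.Series:
        if subgroup not in SUBGROUPS:
            raise SchemaError(f"unknown subgroup {subgroup!r}")
        meta = self.indexed()
        if samples is not None:
            meta = meta.loc[list(samples)]
        return (meta["subgroup"] == subgroup).astype(float)

    def mrss(self, samples=None) -> pd.Series:
        meta = self.indexed()
        if samples is not None:
            meta = meta.loc[list(samples)]
        return meta["mrss"]

    def subgroups(self, samples=None) -> pd.Series:
        meta = self.indexed()
        if samples is not None:
            meta = meta.loc[list(samples)]
        return meta["subgroup"]
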