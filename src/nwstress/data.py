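"""Core containers: expression matrix and factorial sample metadata.

The experimental design is a three-factor factorial: organ (leaf, root,
stem) x nitrogen supply (optimal, limiting) x water condition, where the
five water conditions are ordered -- optimal supply (1), mild stress (2),
severe stress (3), rewatered 2 h (4), rewatered 5 h (5) -- so that a
per-entity expression trajectory over them can be treated as longitudinal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ORGANS = ("leaf", "root", "stem")
NITROGEN_LEVELS = ("optimal", "limiting")
#: Ordered water conditions, indexed 1..5.
WATER_LEVELS = (1, 2, 3, 4, 5)
WATER_NAMES = {
    1: "optimal",
    2: "mild stress",
    3: "severe stress",
    4: "rewatered 2h",
    5: "rewatered 5h",
}

#: Allowed scale states of an expression matrix.
SCALES = ("raw", "log2", "log2-baselined")


@dataclass
class ExpressionMatrix:
    """Entities x samples intensity table with an explicit scale flag.

    ``values`` is a DataFrame indexed by entity id with one column per
    sample id. ``scale`` is one of ``raw`` (linear intensities, >= 0),
    ``log2`` (log2 intensities) or ``log2-baselined`` (log2 intensities
    centred per entity to the median across all samples).
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.scale == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw-scale matrix contains negative intensities")

    @property
    def entity_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, entity_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(entity_ids)], self.scale)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="entity_id")

    @classmethod
    def read_tsv(cls, path: str | Path, scale: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, scale)


@dataclass
class SampleMetadata:
    """Sample-level design descriptors for the factorial experiment.

    ``table`` has columns sample_id, organ, nitrogen, water (int 1..5),
    replicate; sample_id is unique.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "organ", "nitrogen", "water", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        bad_org = set(t["organ"]) - set(ORGANS)
        if bad_org:
            raise ValueError(f"unknown organ labels: {sorted(bad_org)}")
        bad_n = set(t["nitrogen"]) - set(NITROGEN_LEVELS)
        if bad_n:
            raise ValueError(f"unknown nitrogen labels: {sorted(bad_n)}")
        bad_w = set(t["water"]) - set(WATER_LEVELS)
        if bad_w:
            raise ValueError(f"unknown water levels: {sorted(bad_w)}")
        n_cond = t.groupby(["organ", "nitrogen", "water"], observed=True).size()
        if len(n_cond) > 30:
            raise ValueError("more than 30 unique (organ, nitrogen, water) conditions")
        under = n_cond[n_cond < 2]
        if len(under):
            raise ValueError(
                f"conditions with fewer than 2 replicates: {list(under.index)}"
            )

    def samples_for(self, organ=None, nitrogen=None, water=None) -> list[str]:
        """Sample ids matching the given factor levels (None = any)."""
        t = self.table
        mask = np.ones(len(t), dtype=bool)
        if organ is not None:
            mask &= (t["organ"] == organ).to_numpy()
        if nitrogen is not None:
            mask &= (t["nitrogen"] == nitrogen).to_numpy()
        if water is not None:
            mask &= (t["water"] == water).to_numpy()
        return t.loc[mask, "sample_id"].tolist()

    def conditions(self):
        """Iterate (organ, nitrogen, water) -> list of sample ids."""
        for key, grp in self.table.groupby(
            ["organ", "nitrogen", "water"], observed=True, sort=True
        ):
            yield key, grp["sample_id"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t"))


def check_matrix_metadata(matrix: ExpressionMatrix, metadata: SampleMetadata) -> None:
    """Ensure every matrix sample column is described in the metadata."""
    known = set(metadata.table["sample_id"])
    orphan = [s for s in matrix.sample_ids if s not in known]
    if orphan:
        raise ValueError(f"matrix columns without metadata rows: {orphan[:5]}...")
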