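"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_SAMPLE_COLUMNS = ("exposure", "dose", "replicate")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with per-sample metadata.

    ``values`` is a DataFrame indexed by gene ID with one column per
    sample; ``samples`` is indexed by sample ID and carries at least
    ``exposure``, ``dose`` (ug/mouse, 0 = vehicle control) and
    ``replicate`` columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        missing_cols = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample metadata missing columns: {missing_cols}")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {missing.tolist()[:5]}")
        if (self.samples.loc[self.values.columns, "dose"] < 0).any():
            raise ValueError("negative dose in sample metadata")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def subset_exposure(self, exposure: str, pooled_controls: bool = False) -> "ExpressionMatrix":
        """Columns for one exposure (its vehicle controls carry the same
        exposure label). ``pooled_controls`` additionally pulls in the
        dose-0 samples of every other exposure, mirroring designs that
        pool vehicle groups for analysis."""
        meta = self.samples.loc[self.values.columns]
        keep = meta["exposure"] == exposure
        if pooled_controls:
            keep |= meta["dose"] == 0
        cols = meta.index[keep]
        return ExpressionMatrix(self.values[cols], self.samples.loc[cols])

    def doses(self) -> np.ndarray:
        """Dose per column, aligned with ``values.columns``."""
        return self.samples.loc[self.values.columns, "dose"].to_numpy(float)


@dataclass
class GeneSetCollection:
    """Named gene sets (modules / pathways), optionally with expected
    per-gene regulation directions (+1 induced, -1 repressed) used by
    the activation z-score."""

    sets: dict[str, list[str]]
    directions: dict[str, dict[str, int]] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {name}")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes within set: {name}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()
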