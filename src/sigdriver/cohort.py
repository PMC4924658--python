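"""Expression cohort container: a log2 gene x sample matrix with sample metadata.

The cohort is the common currency of the integration and differential-expression
stages. Values are log2-scale expression, genes as rows. Each sample carries a
study (batch) label and a two-class group label, ``control`` or ``case``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

GROUPS = ("control", "case")


@dataclass
class ExpressionCohort:
    """Log2 expression matrix (genes x samples) plus per-sample annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as rows (index = gene ids), samples as columns.
    samples : pandas.DataFrame
        Indexed by sample id, with columns ``study`` (batch label) and
        ``group`` (``control`` or ``case``). Column order must match
        ``values.columns``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    name: str = field(default="cohort")

    def __post_init__(self):
        if not self.values.index.is_unique:
            raise ConfigurationError("gene ids must be unique")
        if not self.values.columns.equals(self.samples.index):
            # allow same set, different order
            if set(self.values.columns) != set(self.samples.index):
                raise ConfigurationError("matrix columns and annotation rows disagree")
            self.samples = self.samples.loc[self.values.columns]
        missing = {"study", "group"} - set(self.samples.columns)
        if missing:
            raise ConfigurationError(f"annotation lacks columns: {sorted(missing)}")
        bad = set(self.samples["group"]) - set(GROUPS)
        if bad:
            raise ConfigurationError(f"unknown group labels: {sorted(bad)}")
        if self.values.isna().any().any():
            raise ConfigurationError("expression matrix contains missing values")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def batch(self) -> pd.Series:
        return self.samples["study"]

    @property
    def group(self) -> pd.Series:
        return self.samples["group"]

    @property
    def case_mask(self) -> np.ndarray:
        return (self.samples["group"] == "case").to_numpy()

    def subset(self, genes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionCohort":
        """Return a new cohort restricted to the given genes and/or samples."""
        values = self.values
        if genes is not None:
            values = values.loc[list(genes)]
        if samples is not None:
            values = values[list(samples)]
        return ExpressionCohort(values.copy(), self.samples.loc[values.columns].copy(),
                                name=self.name)

    def split_by_study(self) -> list["ExpressionCohort"]:
        """One cohort per study label, in sorted label order."""
        out = []
        for study in sorted(self.samples["study"].unique()):
            ids = self.samples.index[self.samples["study"] == study]
            out.append(ExpressionCohort(self.values[ids].copy(),
                                        self.samples.loc[ids].copy(), name=str(study)))
        return out

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, matrix_path, annotation_path) -> None:
        m = self.values.copy()
        m.index.name = "gene"
        m.to_csv(matrix_path, sep="\t")
        ann = self.samples.copy()
        ann.index.name = "sample_id"
        ann = ann.rename(columns={"study": "study_id"})
        ann.to_csv(annotation_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path, annotation_path, name: str | None = None
                 ) -> "ExpressionCohort":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
        ann = ann.rename(columns={"study_id": "study", "batch": "study"})
        ann = ann.loc[values.columns]
        return cls(values, ann, name=name or Path(str(matrix_path)).stem)
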