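"""Core in-memory containers shared by every pipeline stage."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns understood by the pipeline, in canonical order
METADATA_FIELDS = ("tissue", "tree", "dye", "species", "timepoint")


@dataclass
class ExpressionMatrix:
    """A genes x samples table of log2 intensities plus per-sample design metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes (unique ids), columns are samples (unique ids).
        NaN marks a missing measurement; all non-missing entries must be finite.
    metadata : pandas.DataFrame
        Indexed by sample id; any subset of :data:`METADATA_FIELDS` may be
        populated (``tissue``/``tree``/``dye`` for the multi-tissue design,
        ``species``/``timepoint``/``tree`` for the seasonal design).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.values.columns)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        missing_meta = self.values.columns.difference(self.metadata.index)
        if len(missing_meta):
            raise ValueError(f"samples without metadata record: {missing_meta.tolist()}")
        vals = self.values.to_numpy(dtype=float)
        bad = np.isinf(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        # keep metadata aligned to the sample order of the matrix
        self.metadata = self.metadata.loc[self.values.columns]

    # -- convenience accessors -------------------------------------------------
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

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``genes`` (order preserved)."""
        missing = pd.Index(genes).difference(self.values.index)
        if len(missing):
            raise KeyError(f"genes not in matrix: {missing.tolist()}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.metadata.copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.metadata.copy())
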