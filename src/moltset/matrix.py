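"""Core expression-matrix container shared by every pipeline stage.

The matrix is a dense features x samples grid of intensities, either on
linear scale (strictly positive, as measured) or on log2 scale (as all the
downstream statistics expect), together with a sample -> developmental-state
map. A thin frozen wrapper around a pandas DataFrame keeps id bookkeeping
honest without hiding the DataFrame from callers who want it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Features x samples expression values with sample state labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids.
    state_of
        Mapping from sample id to developmental-state label. Every sample
        column must be covered.
    scale
        Either ``"linear"`` (all values > 0) or ``"log2"``.
    """

    values: pd.DataFrame
    state_of: Mapping[str, str]
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        missing = [s for s in cols if s not in self.state_of]
        if missing:
            raise ValueError(f"samples without a state label: {missing[:5]}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.values.isna().any().any():
            raise ValueError("expression values contain missing entries")
        if self.scale == "linear" and (self.values.to_numpy() <= 0).any():
            bad = self.values.stack()
            bad = bad[bad <= 0]
            feat, samp = bad.index[0]
            raise ValueError(
                f"linear-scale matrix has non-positive value at feature "
                f"{feat!r}, sample {samp!r}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_state(self, state: str) -> list[str]:
        return [s for s in self.values.columns if self.state_of[s] == state]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """Return a copy carrying new values but the same sample labels."""
        return ExpressionMatrix(values, dict(self.state_of), scale or self.scale)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return ExpressionMatrix(
            self.values[sample_ids], {s: self.state_of[s] for s in sample_ids}, self.scale
        )
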