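"""In-memory containers for count and expression data.

Both containers hold a genes x samples value table together with the
gene annotations of the panel and the sample annotations of the design
table, kept index-aligned at construction time.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Container contents violate an invariant."""


def _check_alignment(values: pd.DataFrame, genes: pd.DataFrame,
                     samples: pd.DataFrame) -> None:
    if not values.index.equals(genes.index):
        raise ValidationError("gene annotation index does not match value rows")
    if not values.columns.equals(samples.index):
        raise ValidationError("sample annotation index does not match value columns")


@dataclasses.dataclass
class CountMatrix:
    """Raw or rescaled probe counts (genes x samples).

    ``require_int`` is enforced for raw digital counts (simulation and
    file input); lane/reference rescaling produces non-integer counts and
    constructs with ``require_int=False``.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame
    require_int: bool = True

    def __post_init__(self) -> None:
        _check_alignment(self.values, self.genes, self.samples)
        vals = self.values.to_numpy()
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.values.index[g]!r} in sample "
                f"{self.values.columns[s]!r}")
        if self.require_int and not np.allclose(vals, np.rint(vals)):
            g, s = np.argwhere(~np.isclose(vals, np.rint(vals)))[0]
            raise ValidationError(
                f"non-integer count for gene {self.values.index[g]!r} in "
                f"sample {self.values.columns[s]!r}")

    def class_rows(self, cls: str) -> pd.DataFrame:
        return self.values.loc[self.genes["cls"] == cls]

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), self.genes.copy(),
                           self.samples.copy(), self.require_int)

    def equals(self, other: "CountMatrix") -> bool:
        return (self.values.equals(other.values)
                and self.genes.equals(other.genes)
                and self.samples[["condition_id", "donor", "day"]].equals(
                    other.samples[["condition_id", "donor", "day"]]))


@dataclasses.dataclass
class ExpressionMatrix:
    """Normalized log2-scale expression (counted genes x samples).

    ``meta`` records the normalization provenance: lane factors applied,
    reference genes used, glog transform parameters and any pseudo-count
    events.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_alignment(self.values, self.genes, self.samples)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("expression matrix contains non-finite entries")

    def subset_samples(self, mask: pd.Series) -> "ExpressionMatrix":
        cols = self.samples.index[mask]
        return ExpressionMatrix(self.values[cols], self.genes,
                                self.samples.loc[cols], dict(self.meta))

    def day_samples(self, day: int) -> "ExpressionMatrix":
        return self.subset_samples(self.samples["day"] == day)
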