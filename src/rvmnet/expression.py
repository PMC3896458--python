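"""Expression-matrix container for a two-group (case vs control) design.

Intensities are linear-scale positive values (one row per gene, one column
per sample); statistics downstream are computed on log2-transformed values
while fold changes stay on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """Genes x samples positive intensity table plus a two-group design.

    Parameters
    ----------
    intensities
        DataFrame indexed by gene id with sample ids as columns; linear scale,
        strictly positive.
    design
        Mapping (or Series) sample id -> group, where group is ``"case"`` or
        ``"control"``. Every sample column must be assigned exactly one group
        and each group must contain at least two samples.
    """

    intensities: pd.DataFrame
    design: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.design, pd.Series):
            self.design = pd.Series(dict(self.design))
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()].unique()
            raise InvalidInputError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.intensities.columns.has_duplicates:
            raise InvalidInputError("duplicate sample ids in matrix header")
        missing = [s for s in self.intensities.columns if s not in self.design.index]
        if missing:
            raise InvalidInputError(f"samples missing from design: {missing}")
        bad_groups = set(self.design.unique()) - set(GROUPS)
        if bad_groups:
            raise InvalidInputError(f"unknown group labels in design: {sorted(bad_groups)}")
        values = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("non-numeric or non-finite intensity in matrix")
        if np.any(values <= 0):
            gi, si = np.argwhere(values <= 0)[0]
            raise InvalidInputError(
                f"non-positive intensity at gene {self.intensities.index[gi]!r}, "
                f"sample {self.intensities.columns[si]!r}"
            )
        for grp in GROUPS:
            if len(self.samples(grp)) < 2:
                raise InvalidInputError(f"group {grp!r} has fewer than 2 samples")

    # -- accessors -------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def samples(self, group: str) -> list[str]:
        """Sample ids belonging to *group*, in matrix column order."""
        return [s for s in self.intensities.columns if self.design.get(s) == group]

    def log2(self) -> pd.DataFrame:
        """Log2-transformed intensities (the scale on which tests are run)."""
        return np.log2(self.intensities)

    @property
    def n_case(self) -> int:
        return len(self.samples("case"))

    @property
    def n_control(self) -> int:
        return len(self.samples("control"))
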