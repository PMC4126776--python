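"""Shared data containers for calibration training sets and sediment cores.

The field's data model is simple and tabular: a site x taxon abundance
matrix paired with a site x variable water-quality table, and, for
paleolimnological application, an ordered depth/date x taxon stratigraphy.
All three are thin wrappers around :class:`pandas.DataFrame` that enforce
the invariants the downstream statistics rely on (non-negativity, row
normalization of relative data, monotone chronologies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four abundance representations a training set may use.
ABUNDANCE_BASES = ("density", "biovolume", "rel_density", "rel_biovolume")

#: Bases whose rows are proportions summing to one.
RELATIVE_BASES = ("rel_density", "rel_biovolume")


@dataclass
class AbundanceMatrix:
    """Site x taxon abundance matrix with sample metadata.

    Parameters
    ----------
    data
        Abundances, one row per sampling event, one column per taxon.
        Units depend on ``basis``: cells/ml (``density``), um^3/ml
        (``biovolume``) or proportions (relative bases).
    basis
        One of :data:`ABUNDANCE_BASES`.
    season, lake
        Optional per-sample categorical labels (indexed like ``data``).
    """

    data: pd.DataFrame
    basis: str = "rel_density"
    season: pd.Series | None = None
    lake: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.basis not in ABUNDANCE_BASES:
            raise ValueError(
                f"basis must be one of {ABUNDANCE_BASES}, got {self.basis!r}"
            )
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative abundance at sample "
                f"{self.data.index[r]!r}, taxon {self.data.columns[c]!r}"
            )
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        for name in ("season", "lake"):
            labels = getattr(self, name)
            if labels is not None and not labels.index.equals(self.data.index):
                raise ValueError(f"{name} labels must be indexed like data")

    # -- convenience ---------------------------------------------------

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def taxa(self) -> pd.Index:
        return self.data.columns

    @property
    def is_relative(self) -> bool:
        return self.basis in RELATIVE_BASES

    def row_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def occurrences(self) -> pd.Series:
        """Number of samples in which each taxon is present (abundance > 0)."""
        return (self.data > 0).sum(axis=0)

    def to_relative(self) -> "AbundanceMatrix":
        """Convert counts/biovolumes to within-sample proportions.

        Rows with zero total are left as all-zero rows (they carry no
        compositional information) and a warning is emitted.
        """
        if self.is_relative:
            return self
        sums = self.data.sum(axis=1)
        empty = sums == 0
        if empty.any():
            warnings.warn(
                f"{int(empty.sum())} sample(s) with zero total abundance "
                "left as zero rows during normalization",
                stacklevel=2,
            )
        rel = self.data.div(sums.where(~empty, 1.0), axis=0)
        new_basis = "rel_density" if self.basis == "density" else "rel_biovolume"
        return AbundanceMatrix(rel, new_basis, season=self.season, lake=self.lake)


@dataclass
class CoreStratigraphy:
    """Ordered downcore record of relative taxon abundances.

    ``abundances`` rows are proportions (sum to one within tolerance);
    ``dates`` is the externally supplied chronology (calendar years), one
    per interval, monotone with depth. Reconstruction outputs (DI-TP and
    error bands) are attached by :func:`wacalib.reconstruction.reconstruct_core`
    as the ``reconstruction`` frame.
    """

    abundances: pd.DataFrame
    dates: pd.Series
    depths: pd.Series | None = None
    true_gradient: pd.Series | None = None
    reconstruction: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.abundances) == 0:
            raise ValueError("a core must contain at least one interval")
        if not self.dates.index.equals(self.abundances.index):
            raise ValueError("dates must be indexed like abundances")
        d = self.dates.to_numpy(dtype=float)
        if len(d) > 1 and not (np.all(np.diff(d) > 0) or np.all(np.diff(d) < 0)):
            raise ValueError("core dates must be strictly monotone")
        vals = self.abundances.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("negative relative abundance in core")
        sums = vals.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = self.abundances.index[np.argmax(np.abs(sums - 1.0))]
            raise ValueError(
                f"core interval {bad!r} relative abundances do not sum to 1"
            )

    @property
    def intervals(self) -> pd.Index:
        return self.abundances.index

    @property
    def n_intervals(self) -> int:
        return len(self.abundances)
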