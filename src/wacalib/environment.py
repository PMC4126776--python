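"""Water-quality table handling: transformations, derived ratios, PCA, screening.

Limnological variables are strongly right-skewed, so each variable carries a
registered transformation (``none``, ``log`` = base-10 logarithm, or
``sqrt``) that is applied before any statistics are computed. The registry
travels with the table so that models calibrated on transformed gradients
can never silently disagree with the data they are applied to.

Several variables (chlorophyll, fluorescence, nitrate) can legitimately be
zero; a log transform then needs an offset. The offset defaults to half the
smallest positive observed value, is recorded in the registry, and is used
symmetrically by the inverse transform.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TRANSFORMS = ("none", "log", "sqrt")

#: Molar masses (g/mol) used for nutrient ratio variables.
MOLAR_MASS = {"N": 14.0067, "P": 30.973762, "Si": 28.0855}


def transform_variable(values, kind: str, offset: float = 0.0) -> np.ndarray:
    """Apply a registered skew-removing transform elementwise.

    ``log`` is base 10. ``offset`` is added before a log transform (to
    accommodate zeros) and must make every value strictly positive.
    """
    x = np.asarray(values, dtype=float)
    if kind == "none":
        return x.copy()
    if kind == "sqrt":
        if np.nanmin(x) < 0:
            raise ValueError("sqrt transform requires non-negative values")
        return np.sqrt(x)
    if kind == "log":
        shifted = x + offset
        if np.nanmin(shifted) <= 0:
            bad = int(np.nanargmin(shifted))
            raise ValueError(
                f"log transform requires positive values; element {bad} is "
                f"{x[bad]} (offset {offset})"
            )
        return np.log10(shifted)
    raise ValueError(f"unknown transform {kind!r}")


def inverse_transform_variable(values, kind: str, offset: float = 0.0) -> np.ndarray:
    """Exact inverse of :func:`transform_variable` on the transform's range."""
    y = np.asarray(values, dtype=float)
    if kind == "none":
        return y.copy()
    if kind == "sqrt":
        return y**2
    if kind == "log":
        return 10.0**y - offset
    raise ValueError(f"unknown transform {kind!r}")


@dataclass
class EnvironmentTable:
    """Site x variable water-quality table with transform registry.

    Parameters
    ----------
    data
        Measurements in original units, one row per sampling event.
    transforms
        Per-variable transform kind; variables absent from the mapping
        default to ``none``.
    coords
        Per-site positions, columns ``x``/``y`` (planar, km) or
        ``lon``/``lat`` (geographic).
    season, lake
        Optional per-sample categorical labels.
    log_offsets
        Per-variable additive offsets used under ``log``; filled in lazily
        (half the smallest positive value) for variables containing zeros.
    """

    data: pd.DataFrame
    transforms: dict = field(default_factory=dict)
    coords: pd.DataFrame | None = None
    season: pd.Series | None = None
    lake: pd.Series | None = None
    log_offsets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate site id {dup!r}")
        for v, kind in self.transforms.items():
            if kind not in TRANSFORMS:
                raise ValueError(f"unknown transform {kind!r} for {v!r}")
        if self.coords is not None and not self.coords.index.equals(self.data.index):
            raise ValueError("coords must be indexed like data")

    @property
    def sites(self) -> pd.Index:
        return self.data.index

    @property
    def variables(self) -> pd.Index:
        return self.data.columns

    @property
    def coord_mode(self) -> str:
        if self.coords is None:
            return "none"
        return "lonlat" if "lon" in self.coords.columns else "planar"

    def transform_of(self, variable: str) -> str:
        return self.transforms.get(variable, "none")

    def _offset_for(self, variable: str) -> float:
        """Offset used under log; auto-derived for variables with zeros."""
        if variable in self.log_offsets:
            return self.log_offsets[variable]
        x = self.data[variable].to_numpy(dtype=float)
        offset = 0.0
        if np.nanmin(x) <= 0:
            positive = x[x > 0]
            if positive.size == 0:
                raise ValueError(
                    f"variable {variable!r} has no positive values to anchor "
                    "a log offset"
                )
            offset = 0.5 * float(positive.min())
            warnings.warn(
                f"variable {variable!r} contains non-positive values; "
                f"log offset {offset:.6g} applied",
                stacklevel=3,
            )
        self.log_offsets[variable] = offset
        return offset

    def transformed_variable(self, variable: str) -> pd.Series:
        kind = self.transform_of(variable)
        offset = self._offset_for(variable) if kind == "log" else 0.0
        col = self.data[variable]
        bad = col.index[(col + offset <= 0) & col.notna()] if kind == "log" else []
        if len(bad):
            raise ValueError(
                f"log transform of {variable!r} undefined at site {bad[0]!r}"
            )
        return pd.Series(
            transform_variable(col.to_numpy(dtype=float), kind, offset),
            index=col.index,
            name=variable,
        )

    def transformed(self, variables=None) -> pd.DataFrame:
        """Table of transformed values for the requested variables."""
        variables = list(self.data.columns) if variables is None else list(variables)
        return pd.DataFrame({v: self.transformed_variable(v) for v in variables})

    def inverse_transform(self, variable: str, values) -> np.ndarray:
        kind = self.transform_of(variable)
        offset = self._offset_for(variable) if kind == "log" else 0.0
        return inverse_transform_variable(values, kind, offset)

    def with_variables(self, new: pd.DataFrame, transforms: dict | None = None):
        """Return a copy with extra variables appended (original units)."""
        data = pd.concat([self.data, new], axis=1)
        tr = dict(self.transforms)
        tr.update(transforms or {})
        return EnvironmentTable(
            data, tr, coords=self.coords, season=self.season, lake=self.lake,
            log_offsets=dict(self.log_offsets),
        )


def derive_ratios(
    table: EnvironmentTable,
    n_var: str = "NOx",
    p_var: str = "TP",
    si_var: str = "Silica",
    units: dict | None = None,
) -> EnvironmentTable:
    """Append molar nutrient ratio variables N:P, N:Si and P:Si.

    Mass concentrations are converted to molar concentrations using the
    elemental molar masses before the ratio is taken. ``units`` maps each
    input variable to ``"mg/L"`` or ``"ug/L"`` (defaults: nitrogen and
    silica in mg/L, phosphorus in ug/L, the usual reporting units).
    A zero denominator yields a missing value with a warning, never an
    error; missing inputs propagate as missing.
    """
    units = {**{n_var: "mg/L", p_var: "ug/L", si_var: "mg/L"}, **(units or {})}
    scale = {"mg/L": 1.0, "ug/L": 1e-3}

    def molar(var: str, element: str) -> pd.Series:
        col = table.data[var].astype(float) * scale[units[var]]
        return col / MOLAR_MASS[element]

    n = molar(n_var, "N")
    p = molar(p_var, "P")
    si = molar(si_var, "Si")

    def ratio(num: pd.Series, den: pd.Series, name: str) -> pd.Series:
        zero = (den == 0) & den.notna()
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero denominator(s) in {name}; "
                "set to missing",
                stacklevel=2,
            )
        out = num / den.where(~zero)
        out.name = name
        return out

    new = pd.DataFrame(
        {
            "NtoP": ratio(n, p, "NtoP"),
            "NtoSi": ratio(n, si, "NtoSi"),
            "PtoSi": ratio(p, si, "PtoSi"),
        }
    )
    return table.with_variables(
        new, transforms={"NtoP": "sqrt", "NtoSi": "log", "PtoSi": "log"}
    )


@dataclass
class PCASummary:
    """PCA of the standardized (zero-mean, unit-variance) environment."""

    loadings: pd.DataFrame  # variable x axis
    scores: pd.DataFrame  # site x axis
    eigenvalue_fractions: np.ndarray  # per-axis share of total variance
    means: pd.Series
    sds: pd.Series


def pca_environment(
    table: EnvironmentTable, variables=None, n_axes: int = 2
) -> tuple[PCASummary, EnvironmentTable]:
    """PCA of transformed, standardized variables; appends PC1..PCn.

    Works on the correlation matrix (each transformed variable scaled to
    zero mean and unit variance). Sites with any missing value among the
    requested variables are dropped listwise, with a warning reporting the
    count. Returns the PCA summary and a copy of the table with the leading
    axis scores appended as new variables (transform ``none``).
    """
    X = table.transformed(variables)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("PCA needs at least 2 variables and 3 sites")
    complete = X.dropna()
    dropped = len(X) - len(complete)
    if dropped:
        warnings.warn(f"{dropped} site(s) dropped listwise for PCA", stacklevel=2)
    sds = complete.std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"constant variable {bad!r} cannot be standardized")
    means = complete.mean()
    Z = (complete - means) / sds
    u, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    fractions = s**2 / np.sum(s**2)
    axes = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=Z.columns, columns=axes)
    scores = pd.DataFrame(u * s, index=Z.index, columns=axes)
    summary = PCASummary(loadings, scores, fractions, means, sds)
    new = scores.iloc[:, :n_axes].reindex(table.sites)
    return summary, table.with_variables(new)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with Bonferroni-adjusted significance."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # after Bonferroni over unordered pairs
    n_pairs_tested: int
    alpha: float


def correlation_screen(
    table: EnvironmentTable, variables=None, alpha: float = 0.05
) -> CorrelationReport:
    """Pearson correlation matrix of transformed variables.

    Significance is Bonferroni-corrected over all unordered variable pairs.
    Each pair is evaluated on its complete cases (pairwise deletion); a
    pair with fewer than 3 complete cases is rejected.
    """
    X = table.transformed(variables)
    cols = list(X.columns)
    m = len(cols)
    n_pairs = m * (m - 1) // 2
    r = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        pair = X[[a, b]].dropna()
        if len(pair) < 3:
            raise ValueError(f"fewer than 3 complete pairs for ({a!r}, {b!r})")
        res = stats.pearsonr(pair[a], pair[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    sig = pd.DataFrame(
        p.to_numpy() <= alpha / max(n_pairs, 1), index=cols, columns=cols
    )
    for c in cols:
        sig.loc[c, c] = True
    return CorrelationReport(r, p, sig.astype(bool), n_pairs, alpha)
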