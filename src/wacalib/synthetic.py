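"""Synthetic training sets, environmental fields and sediment cores.

Everything downstream of this module (taxon coefficients, the weighted-
averaging transfer function, the spatial stress tests, ordination, downcore
reconstruction) is validated against data with known truth generated here.
The generator reproduces the statistical structure the calibration assumes:

* environmental variables as spatially autocorrelated Gaussian random
  fields with chosen variograms and cross-variable correlations;
* taxa with unimodal (Gaussian) responses along one transformed gradient,
  counted with multinomial (or Poisson / negative-binomial) noise;
* downcore stratigraphies drawn from the same response model along a
  prescribed trophic trajectory, e.g. a temporary enrichment excursion.

It deliberately contains no mechanistic plankton dynamics (no seasonality
or succession): only the structure the statistics rest on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, CoreStratigraphy
from .environment import EnvironmentTable

VARIOGRAM_FAMILIES = ("exponential", "spherical", "gaussian")


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass
class SpeciesPool:
    """Taxon response parameters along the calibration gradient.

    ``true_optimum`` and ``true_tolerance`` are on the *transformed*
    gradient scale (e.g. log10 ug/L for total phosphorus);
    ``max_abundance`` is the expected count at the optimum.
    """

    table: pd.DataFrame  # columns: true_optimum, true_tolerance, max_abundance, group

    def __post_init__(self) -> None:
        required = {"true_optimum", "true_tolerance", "max_abundance"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"species pool missing columns {sorted(missing)}")
        if "group" not in self.table.columns:
            self.table = self.table.assign(group="diatom")
        if len(self.table) < 2:
            raise ValueError("a species pool needs at least 2 taxa")
        if not np.all(np.isfinite(self.table["true_optimum"])):
            raise ValueError("optima must be finite")
        if np.any(self.table["true_tolerance"] <= 0):
            raise ValueError("tolerances must be strictly positive")
        if np.any(self.table["max_abundance"] < 0):
            raise ValueError("max_abundance must be non-negative")

    @property
    def taxa(self) -> pd.Index:
        return self.table.index

    def expected_abundance(self, x) -> np.ndarray:
        """Expected abundance of every taxon at gradient positions ``x``.

        Gaussian response: ``c_k * exp(-(x - u_k)^2 / (2 t_k^2))``.
        Returns an ``len(x) x n_taxa`` array.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        u = self.table["true_optimum"].to_numpy()
        t = self.table["true_tolerance"].to_numpy()
        c = self.table["max_abundance"].to_numpy()
        return c * np.exp(-((x[:, None] - u[None, :]) ** 2) / (2 * t[None, :] ** 2))


@dataclass
class FieldSpec:
    """Marginal variogram of one simulated environmental variable."""

    mean: float
    nugget: float = 0.0
    sill: float = 1.0
    range_: float = 100.0  # distance units (km)
    family: str = "exponential"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.sill < 0:
            raise ValueError("nugget and sill must be non-negative")
        if self.range_ <= 0:
            raise ValueError("range must be strictly positive")
        if self.family not in VARIOGRAM_FAMILIES:
            raise ValueError(f"family must be one of {VARIOGRAM_FAMILIES}")

    @property
    def total_variance(self) -> float:
        return self.nugget + self.sill


@dataclass
class CoreScenario:
    """Downcore ground truth: dated intervals and a TP trajectory.

    ``tp_trajectory`` is on the transformed gradient scale, one value per
    interval; ``dates`` must be strictly monotone.
    """

    dates: np.ndarray
    tp_trajectory: np.ndarray
    count_total: int = 400
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=float)
        self.tp_trajectory = np.asarray(self.tp_trajectory, dtype=float)
        if self.dates.size == 0:
            raise ValueError("core scenario needs at least one interval")
        if self.dates.size != self.tp_trajectory.size:
            raise ValueError("dates and tp_trajectory lengths differ")
        diffs = np.diff(self.dates)
        if diffs.size and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("dates must be strictly monotone")
        if not np.all(np.isfinite(self.tp_trajectory)):
            raise ValueError("tp_trajectory must be finite")
        if self.count_total < 1:
            raise ValueError("count_total must be at least 1")

    @property
    def n_intervals(self) -> int:
        return int(self.dates.size)


# ---------------------------------------------------------------------------
# Gaussian random fields
# ---------------------------------------------------------------------------


def correlogram(h, family: str, range_: float) -> np.ndarray:
    """Spatial correlation at lag ``h`` for a unit-sill, zero-nugget model."""
    h = np.asarray(h, dtype=float)
    if family == "exponential":
        return np.exp(-h / range_)
    if family == "gaussian":
        return np.exp(-((h / range_) ** 2))
    if family == "spherical":
        s = np.clip(h / range_, 0.0, 1.0)
        return 1.0 - 1.5 * s + 0.5 * s**3
    raise ValueError(f"unknown family {family!r}")


def pairwise_distances(coords: pd.DataFrame) -> np.ndarray:
    """All-pairs distances in km; planar Euclidean or great-circle."""
    if {"lon", "lat"}.issubset(coords.columns):
        return _haversine_matrix(
            coords["lon"].to_numpy(float), coords["lat"].to_numpy(float)
        )
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    earth_radius_km = 6371.0
    lon_r, lat_r = np.radians(lon), np.radians(lat)
    dlat = lat_r[:, None] - lat_r[None, :]
    dlon = lon_r[:, None] - lon_r[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat_r[:, None]) * np.cos(lat_r[None, :]) * np.sin(dlon / 2) ** 2
    )
    return 2 * earth_radius_km * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def simulate_grf(
    distances: np.ndarray, spec: FieldSpec, rng: np.random.Generator
) -> np.ndarray:
    """One standardized Gaussian random field realization (variance 1).

    The field's covariance among sites is
    ``(sill * rho(h) + nugget * 1{h=0}) / (sill + nugget)``, simulated
    exactly by Cholesky factorization of the full covariance matrix —
    appropriate for desk-scale site counts. A degenerate spec
    (``sill + nugget == 0``) yields the zero field.
    """
    n = distances.shape[0]
    total = spec.total_variance
    if total == 0:
        return np.zeros(n)
    cov = spec.sill * correlogram(distances, spec.family, spec.range_)
    cov[np.diag_indices(n)] = total
    cov /= total
    # tiny jitter guards against numerically semi-definite matrices
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    return chol @ rng.standard_normal(n)


def simulate_environment(
    coords: pd.DataFrame,
    specs: dict,
    correlation: np.ndarray | pd.DataFrame | None = None,
    seed: int | np.random.Generator | None = None,
    transforms: dict | None = None,
) -> EnvironmentTable:
    """Simulate correlated environmental variables over fixed sites.

    Each variable is a Gaussian random field with its own marginal
    variogram (``specs`` maps variable name -> :class:`FieldSpec`).
    Cross-variable correlation is induced by linear mixing of the
    independent standardized fields with a matrix square root of
    ``correlation``; marginal variograms are preserved approximately
    (exactly when all specs share one variogram). Values are generated on
    the transformed scale ``mean + sqrt(nugget+sill) * field`` and stored
    in original units according to ``transforms`` (e.g. a log-scale field
    is exponentiated before storage so the table holds ug/L).
    """
    variables = list(specs)
    if coords.index.duplicated().any():
        raise ValueError("duplicate site ids in coords")
    d = pairwise_distances(coords)
    if np.any(d[~np.eye(len(coords), dtype=bool)] == 0):
        raise ValueError("coordinates must be distinct")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    p = len(variables)
    if correlation is None:
        corr = np.eye(p)
    else:
        corr = (
            correlation.loc[variables, variables].to_numpy()
            if isinstance(correlation, pd.DataFrame)
            else np.asarray(correlation, dtype=float)
        )
    if corr.shape != (p, p) or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-8:
        raise ValueError(
            "correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eigval.min():.3g})"
        )
    mix = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None))) @ eigvec.T

    fields = np.column_stack(
        [simulate_grf(d, specs[v], rng) for v in variables]
    )
    mixed = fields @ mix.T

    transforms = transforms or {}
    data = {}
    for j, v in enumerate(variables):
        spec = specs[v]
        transformed_values = spec.mean + np.sqrt(spec.total_variance) * mixed[:, j]
        kind = transforms.get(v, "none")
        if kind == "log":
            data[v] = 10.0**transformed_values
        elif kind == "sqrt":
            data[v] = transformed_values**2
        else:
            data[v] = transformed_values
    table = pd.DataFrame(data, index=coords.index)
    return EnvironmentTable(table, dict(transforms), coords=coords.copy())


# ---------------------------------------------------------------------------
# assemblages and cores
# ---------------------------------------------------------------------------


def expected_proportions(pool: SpeciesPool, x) -> np.ndarray:
    """Expected relative abundance of each taxon at gradient positions x."""
    mu = pool.expected_abundance(x)
    totals = mu.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("zero expected total abundance at some site")
    return mu / totals


def simulate_assemblages(
    pool: SpeciesPool,
    env: EnvironmentTable,
    gradient_variable: str,
    count_total: int = 400,
    noise: str = "multinomial",
    nb_dispersion: float = 5.0,
    seed: int | np.random.Generator | None = None,
) -> AbundanceMatrix:
    """Draw count assemblages along one transformed environmental gradient.

    Under ``multinomial`` noise (the default — it emulates counting a fixed
    number of valves per sample) each sample's counts sum exactly to
    ``count_total`` and the expected relative abundance of taxon *k* at
    site *i* is proportional to ``c_k exp(-(x_i-u_k)^2 / (2 t_k^2))``.
    ``poisson`` and ``negative_binomial`` draw absolute counts with mean
    ``count_total * p_ik`` for absolute-abundance studies.

    Taxa that end up absent from every sample are dropped with a warning.
    """
    if gradient_variable not in env.variables:
        raise ValueError(f"gradient variable {gradient_variable!r} not in table")
    if count_total < 1:
        raise ValueError("count_total must be at least 1")
    x = env.transformed_variable(gradient_variable).to_numpy()
    props = expected_proportions(pool, x)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = len(x)
    if noise == "multinomial":
        counts = np.vstack(
            [rng.multinomial(count_total, props[i]) for i in range(n)]
        )
    elif noise == "poisson":
        counts = rng.poisson(count_total * props)
    elif noise == "negative_binomial":
        mu = count_total * props
        k = nb_dispersion
        counts = np.where(
            mu > 0, rng.negative_binomial(k, np.clip(k / (k + mu), 1e-12, 1.0)), 0
        )
    else:
        raise ValueError(f"unknown noise model {noise!r}")

    data = pd.DataFrame(counts, index=env.sites, columns=pool.taxa, dtype=float)
    absent = data.columns[(data.sum(axis=0) == 0)]
    if len(absent):
        warnings.warn(
            f"{len(absent)} taxa absent from every sample were dropped",
            stacklevel=2,
        )
        data = data.drop(columns=absent)
    return AbundanceMatrix(data, basis="density", season=env.season, lake=env.lake)


def simulate_core(
    pool: SpeciesPool,
    scenario: CoreScenario,
    seed: int | np.random.Generator | None = None,
) -> CoreStratigraphy:
    """Draw a dated stratigraphy from the shared response model.

    Each interval's assemblage is a multinomial draw of
    ``scenario.count_total`` valves on the expected proportions at that
    interval's trajectory value, then converted to relative abundances
    (rows sum to 1). The pool should be the one used for the training
    simulation so that fossil assemblages have modern analogs.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    props = expected_proportions(pool, scenario.tp_trajectory)
    counts = np.vstack(
        [rng.multinomial(scenario.count_total, props[i]) for i in range(scenario.n_intervals)]
    )
    rel = counts / counts.sum(axis=1, keepdims=True)
    index = pd.Index(range(1, scenario.n_intervals + 1), name="interval")
    abundances = pd.DataFrame(rel, index=index, columns=pool.taxa)
    depths = (
        pd.Series(scenario.depths, index=index, name="depth")
        if scenario.depths is not None
        else pd.Series(
            np.linspace(0.0, 30.0, scenario.n_intervals)[::-1]
            if scenario.n_intervals > 1
            else [0.0],
            index=index,
            name="depth",
        )
    )
    return CoreStratigraphy(
        abundances,
        dates=pd.Series(scenario.dates, index=index, name="year"),
        depths=depths,
        true_gradient=pd.Series(scenario.tp_trajectory, index=index, name="true_tp"),
    )


# ---------------------------------------------------------------------------
# standard study conditions
# ---------------------------------------------------------------------------

#: Log10-TP field emulating a large-lake survey: mean ~3.5 ug/L, marginal
#: sd ~0.33 log units, spatial range 300 km over a ~1000 km domain.
DEFAULT_TP_FIELD = FieldSpec(
    mean=0.55, nugget=0.01, sill=0.10, range_=300.0, family="exponential"
)

#: Conventional diatom count size per sample.
DEFAULT_COUNT_TOTAL = 400


def random_coords(
    n_sites: int, extent_km: float = 1000.0, seed=None
) -> pd.DataFrame:
    """Uniform planar site positions on an ``extent_km`` square."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    xy = rng.uniform(0.0, extent_km, size=(n_sites, 2))
    return pd.DataFrame(
        xy, columns=["x", "y"], index=pd.Index(range(n_sites), name="site")
    )


def default_species_pool(
    n_taxa: int = 100,
    gradient_mean: float = DEFAULT_TP_FIELD.mean,
    gradient_sd: float | None = None,
    seed=None,
) -> SpeciesPool:
    """Pool of unimodal taxa spanning the simulated gradient.

    Optima are uniform over +-2 marginal standard deviations around the
    gradient mean, keeping every taxon's response sampled on both flanks
    (an optimum beyond the sampled gradient makes the WA estimate
    intrinsically truncated, a property of the estimator rather than of
    any implementation); tolerances uniform on [0.10, 0.30] gradient units
    — one third to one gradient standard deviation, so every taxon turns
    over appreciably along the gradient (a taxon with a niche broader than
    the gradient has a nearly flat response and a centroid-shrunk WA
    optimum whatever the estimator); peak expected counts log-normal
    around 10.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sd = gradient_sd if gradient_sd is not None else np.sqrt(
        DEFAULT_TP_FIELD.total_variance
    )
    optima = rng.uniform(gradient_mean - 2.0 * sd, gradient_mean + 2.0 * sd, n_taxa)
    tolerances = rng.uniform(0.10, 0.30, n_taxa)
    maxima = rng.lognormal(mean=np.log(10.0), sigma=0.7, size=n_taxa)
    table = pd.DataFrame(
        {
            "true_optimum": optima,
            "true_tolerance": tolerances,
            "max_abundance": maxima,
            "group": "diatom",
        },
        index=pd.Index([f"taxon_{i:03d}" for i in range(n_taxa)], name="taxon"),
    )
    return SpeciesPool(table)


def benchmark_training_set(
    n_sites: int = 500,
    n_taxa: int = 100,
    count_total: int = DEFAULT_COUNT_TOTAL,
    tp_field: FieldSpec = DEFAULT_TP_FIELD,
    seed: int | None = 0,
):
    """The standard synthetic benchmark used throughout the tests.

    Returns ``(pool, env, abundance)`` where the environment holds a
    spatially autocorrelated TP field (stored in ug/L, transform log) and
    counts are multinomial with ``count_total`` valves per sample.
    """
    rng = np.random.default_rng(seed)
    coords = random_coords(n_sites, seed=rng)
    env = simulate_environment(
        coords, {"TP": tp_field}, seed=rng, transforms={"TP": "log"}
    )
    pool = default_species_pool(
        n_taxa, gradient_mean=tp_field.mean,
        gradient_sd=np.sqrt(tp_field.total_variance), seed=rng,
    )
    abundance = simulate_assemblages(
        pool, env, "TP", count_total=count_total, seed=rng
    )
    return pool, env, abundance


def enrichment_core_scenario(
    n_intervals: int = 26,
    start_year: float = 1700.0,
    end_year: float = 2010.0,
    baseline: float = 0.45,
    peak_increase: float = 0.40,
    onset_year: float = 1900.0,
    peak_year: float = 1950.0,
    recovery_year: float = 1990.0,
    count_total: int = DEFAULT_COUNT_TOTAL,
) -> CoreScenario:
    """A temporary-enrichment core: low baseline TP, a 20th-century
    ramp-up to ``baseline + peak_increase`` (log10 ug/L) and recovery.

    Emulates an oligotrophic-lake record whose mid-century nutrient pulse
    is followed by a return toward the pre-disturbance state.
    """
    dates = np.linspace(start_year, end_year, n_intervals)
    traj = np.full(n_intervals, baseline)
    rise = (dates > onset_year) & (dates <= peak_year)
    traj[rise] += peak_increase * (dates[rise] - onset_year) / (peak_year - onset_year)
    fall = (dates > peak_year) & (dates <= recovery_year)
    traj[fall] += peak_increase * (recovery_year - dates[fall]) / (
        recovery_year - peak_year
    )
    return CoreScenario(dates=dates, tp_trajectory=traj, count_total=count_total)
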