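"""Spatial stress tests for transfer functions.

Training sets collected over large, spatially coherent waterbodies violate
the independence assumption behind cross-validated performance statistics:
neighboring samples share both assemblages and environment, so leave-one-out
r2 can flatter a model badly. Two complementary diagnostics are provided:

* the **neighborhood-deletion (rne) test** — cross-validated r2 is tracked
  while training sites are deleted (a) at random, (b) within a growing
  geographic radius of each test site, (c) matching the same count but
  nearest in environmental value. A geographic curve falling below the
  random curve is the signature of spatial autocorrelation propping up the
  model.
* the **spatially structured randomization test** — the environmental
  variable is replaced by Gaussian random fields sharing its fitted
  variogram, the model is refit each time, and the real model's r2 is
  located within the simulated distribution. A model whose skill merely
  reflects spatial structure will sit inside the null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import AbundanceMatrix
from .synthetic import FieldSpec, correlogram, pairwise_distances, simulate_grf
from . import transfer


# ---------------------------------------------------------------------------
# variograms
# ---------------------------------------------------------------------------


@dataclass
class EmpiricalVariogram:
    lag: np.ndarray  # bin-centre distances
    gamma: np.ndarray  # semivariance per bin
    count: np.ndarray  # pair count per bin


@dataclass
class VariogramModel:
    family: str
    nugget: float
    sill: float
    range_: float
    empirical: EmpiricalVariogram
    grid_fallback: bool = False

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.nugget + self.sill * (1.0 - correlogram(h, self.family, self.range_))


def empirical_variogram(
    coords: pd.DataFrame, values, n_bins: int = 15, max_lag: float | None = None
) -> EmpiricalVariogram:
    """Binned semivariance: gamma(h) = mean squared difference / 2.

    Pairs are binned by separation distance up to ``max_lag`` (default:
    half the maximum inter-site distance, the usual reliability cutoff);
    empty bins are omitted.
    """
    z = np.asarray(values, dtype=float)
    d = pairwise_distances(coords)
    n = d.shape[0]
    if n < 2:
        raise ValueError("variogram needs at least 2 sites")
    iu = np.triu_indices(n, k=1)
    h = d[iu]
    if np.all(h == 0):
        raise ValueError("all sites are coincident")
    if max_lag is None:
        max_lag = 0.5 * h.max()
    sq = 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
    inside = h <= max_lag
    h, sq = h[inside], sq[inside]
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    lags, gammas, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        lags.append(h[sel].mean())
        gammas.append(sq[sel].mean())
        counts.append(int(sel.sum()))
    return EmpiricalVariogram(np.array(lags), np.array(gammas), np.array(counts))


def fit_variogram(
    empirical: EmpiricalVariogram, family: str = "exponential"
) -> VariogramModel:
    """Weighted least-squares fit of a theoretical variogram model.

    Cressie-style weights (pair count / model^2) emphasize short,
    well-populated lags. Parameters are bounded non-negative; if the
    optimizer fails, a coarse grid search supplies the fit and the result
    is flagged.
    """
    if len(empirical.lag) < 3:
        raise ValueError("variogram fit needs at least 3 non-empty bins")
    h, g, c = empirical.lag, empirical.gamma, empirical.count

    def residuals(theta):
        nugget, sill, rng_ = theta
        model = nugget + sill * (1.0 - correlogram(h, family, rng_))
        w = np.sqrt(c) / np.maximum(model, 1e-12)
        return w * (g - model)

    g_max = max(g.max(), 1e-12)
    h_max = h.max()
    x0 = np.array([0.1 * g_max, 0.9 * g_max, h_max / 3])
    lower = np.array([0.0, 0.0, h_max / 100])
    upper = np.array([2 * g_max, 5 * g_max, 10 * h_max])
    try:
        res = optimize.least_squares(residuals, x0, bounds=(lower, upper))
        if not res.success:
            raise RuntimeError(res.message)
        nugget, sill, rng_ = res.x
        return VariogramModel(family, float(nugget), float(sill), float(rng_), empirical)
    except Exception:
        warnings.warn("variogram optimizer failed; grid-search fallback", stacklevel=2)
        best, best_sse = None, np.inf
        for nug in np.linspace(0, g_max, 8):
            for sill in np.linspace(0, 2 * g_max, 12):
                for rng_ in np.geomspace(h_max / 100, 2 * h_max, 12):
                    model = nug + sill * (1.0 - correlogram(h, family, rng_))
                    sse = float((c * (g - model) ** 2).sum())
                    if sse < best_sse:
                        best_sse, best = sse, (nug, sill, rng_)
        return VariogramModel(family, *map(float, best), empirical, grid_fallback=True)


# ---------------------------------------------------------------------------
# randomization test
# ---------------------------------------------------------------------------


@dataclass
class RandomizationResult:
    actual_r2: float
    simulated_r2: np.ndarray
    percentile: float  # percent of simulations below the actual model
    p: float
    variogram: VariogramModel


def random_tf_test(
    abundance: AbundanceMatrix,
    gradient: pd.Series,
    coords: pd.DataFrame,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
    family: str = "exponential",
    tolerance_dw: bool = True,
    cross_validated: bool = False,
) -> RandomizationResult:
    """Significance of a WA model against spatially structured noise.

    The gradient's empirical variogram is fitted, then ``n_sim`` Gaussian
    random fields with that variogram (and the gradient's mean) replace the
    gradient; each time the WA model is refit and its r2 recorded. By
    default the apparent r2 is used; set ``cross_validated`` for the
    (slower) jackknifed version. ``p`` uses the +1 correction;
    ``percentile`` locates the real model in the null distribution.
    A variogram fit failure aborts the test (never silently proceeds).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = gradient.reindex(abundance.samples)

    emp = empirical_variogram(coords, x.to_numpy())
    vg = fit_variogram(emp, family)
    if vg.nugget + vg.sill <= 0:
        raise RuntimeError("degenerate variogram fit; randomization test aborted")

    def performance(series: pd.Series) -> float:
        if cross_validated:
            return transfer.jackknife(abundance, series, tolerance_dw=tolerance_dw).r2_jack
        return transfer.apparent_r2(abundance, series, tolerance_dw=tolerance_dw)

    actual = performance(x)
    d = pairwise_distances(coords)
    spec = FieldSpec(
        mean=float(x.mean()), nugget=vg.nugget, sill=vg.sill,
        range_=vg.range_, family=family,
    )
    scale = np.sqrt(spec.total_variance)
    sims = np.empty(n_sim)
    for s in range(n_sim):
        z = spec.mean + scale * simulate_grf(d, spec, rng)
        sims[s] = performance(pd.Series(z, index=abundance.samples))
    p = (1 + int(np.sum(sims >= actual))) / (n_sim + 1)
    percentile = 100.0 * float(np.mean(sims < actual))
    return RandomizationResult(actual, sims, percentile, float(p), vg)


# ---------------------------------------------------------------------------
# neighborhood-deletion (rne) test
# ---------------------------------------------------------------------------


@dataclass
class RneResult:
    """Cross-validated r2 per deletion radius under three deletion schemes."""

    table: pd.DataFrame  # columns: radius, r2_random, r2_geographic, r2_environmental
    deleted_counts: pd.DataFrame  # per radius x test sample: geographic deletion count
    skipped: pd.DataFrame  # per radius: samples with no usable training set left


def rne_test(
    abundance: AbundanceMatrix,
    gradient: pd.Series,
    coords: pd.DataFrame,
    radii,
    seed: int | np.random.Generator | None = None,
    tolerance_dw: bool = True,
) -> RneResult:
    """Random / geographic / environmental neighborhood deletion curves.

    Leave-one-out over the training set: for each test sample and radius
    ``r``, the geographic scheme deletes every other training site within
    ``r`` km; the environmental scheme deletes the *same count* of sites
    nearest in gradient value; the random scheme deletes the same count at
    random. The WA model is refit on what remains and the held-out sample
    predicted; pooled predictions give one r2 per scheme per radius. At
    radius 0 nothing is deleted and all three schemes equal the ordinary
    jackknife r2. Samples left unpredictable by a deletion are skipped and
    counted.
    """
    Y_df = abundance.data if abundance.is_relative else abundance.to_relative().data
    x = gradient.reindex(Y_df.index).to_numpy(dtype=float)
    Y = Y_df.to_numpy(dtype=float)
    n = len(Y_df)
    d = pairwise_distances(coords.reindex(Y_df.index))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def loo_prediction(i: int, deleted: np.ndarray) -> float:
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mask[deleted] = False
        if mask.sum() < 3:
            return np.nan
        x_tr = x[mask]
        if np.std(x_tr) == 0:
            return np.nan
        floor = float(np.std(x_tr, ddof=1) / 10.0)
        u, t, keep, xhat0 = transfer._wa_core(Y[mask], x_tr, tolerance_dw, floor)
        try:
            b0, b1 = transfer._deshrink_inverse(x_tr, xhat0)
        except ValueError:
            return np.nan
        raw = transfer._wa_average(
            Y[i : i + 1, keep], u[keep], t[keep], tolerance_dw, floor
        )[0]
        return b0 + b1 * raw if np.isfinite(raw) else np.nan

    env_order = np.argsort(np.abs(x[:, None] - x[None, :]), axis=1, kind="stable")

    rows, count_rows, skip_rows = [], [], []
    for r in radii:
        preds = {"random": np.full(n, np.nan),
                 "geographic": np.full(n, np.nan),
                 "environmental": np.full(n, np.nan)}
        counts = np.zeros(n, dtype=int)
        for i in range(n):
            others = np.arange(n) != i
            geo_del = np.where(others & (d[i] <= r))[0] if r > 0 else np.array([], int)
            m = len(geo_del)
            counts[i] = m
            # same count, nearest in gradient value (test sample excluded)
            env_candidates = env_order[i][env_order[i] != i]
            env_del = env_candidates[:m]
            rand_del = rng.choice(np.where(others)[0], size=m, replace=False) if m else np.array([], int)
            preds["geographic"][i] = loo_prediction(i, geo_del)
            preds["environmental"][i] = loo_prediction(i, env_del)
            preds["random"][i] = loo_prediction(i, rand_del)
        row = {"radius": r}
        skips = {"radius": r}
        for scheme, p in preds.items():
            ok = np.isfinite(p)
            skips[scheme] = int(np.sum(~ok))
            if ok.sum() >= 3:
                r2 = np.corrcoef(x[ok], p[ok])[0, 1] ** 2
            else:
                r2 = np.nan
            row[f"r2_{scheme}"] = float(r2)
        rows.append(row)
        count_rows.append(counts)
        skip_rows.append(skips)
    table = pd.DataFrame(rows)
    deleted = pd.DataFrame(
        count_rows, index=pd.Index(list(radii), name="radius"), columns=Y_df.index
    )
    return RneResult(table, deleted, pd.DataFrame(skip_rows))
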