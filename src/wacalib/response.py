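"""Per-taxon response modelling along environmental gradients.

For every sufficiently common taxon and every (transformed) water-quality
variable, three descriptions of the taxon-gradient relationship are
produced:

* a linear fit — its slope sign, reported only when the Pearson
  correlation is significant (P < 0.05);
* a unimodal ("Gaussian") fit — a quadratic regression on a log link, the
  standard Gaussian response model of gradient analysis, whose argmax is
  the taxon's optimum; a paired t-test on absolute residuals flags taxa
  for which the unimodal fit beats the linear one;
* the weighted-averaging (WA) optimum — the abundance-weighted mean of the
  gradient values where the taxon occurs.

Optima are rescaled to integer indicator values 0-10 over the observed
gradient range; seasonal and per-lake specificities are the taxon's share
of summed abundance per category, also on a 0-10 scale. A permutation test
on a penalized-spline smoother assesses whether a taxon responds to the
phosphorus gradient at all, and whether that response survives removal of
the alkalinity signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline

from .containers import AbundanceMatrix
from .environment import EnvironmentTable


# ---------------------------------------------------------------------------
# eligibility and elementary fits
# ---------------------------------------------------------------------------


def eligible_taxa(abundance: AbundanceMatrix, min_occurrences: int = 5) -> list:
    """Taxa observed in strictly more than ``min_occurrences`` samples.

    Column order is preserved. The conventional thresholds are 5 for
    coefficient tables and 10 for the smoother-based gradient tests.
    """
    occ = abundance.occurrences()
    return [t for t in abundance.taxa if occ[t] > min_occurrences]


@dataclass
class LinearFit:
    sign: int  # -1, 0, +1 ; 0 when not significant
    r: float
    p: float


def fit_linear(abundance_k, x, alpha: float = 0.05) -> LinearFit:
    """Sign of the linear taxon-gradient relationship (Pearson test).

    The OLS slope sign is reported only when the Pearson correlation is
    significant at ``alpha``; otherwise the sign is 0. Zero-variance
    abundance yields sign 0 with p = 1.
    """
    y = np.asarray(abundance_k, dtype=float)
    xv = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(xv)
    y, xv = y[ok], xv[ok]
    if len(y) < 3:
        raise ValueError("linear fit needs at least 3 sites with data")
    if np.var(y) == 0 or np.var(xv) == 0:
        return LinearFit(0, 0.0, 1.0)
    res = stats.pearsonr(xv, y)
    sign = int(np.sign(res.statistic)) if res.pvalue < alpha else 0
    return LinearFit(sign, float(res.statistic), float(res.pvalue))


@dataclass
class GaussianFit:
    optimum: float
    better_than_linear: bool
    converged: bool
    p_vs_linear: float


def fit_gaussian(abundance_k, x, alpha: float = 0.05) -> GaussianFit:
    """Unimodal response fit; optimum = argmax over the observed range.

    Fits ``log E[y] = b0 + b1 x + b2 x^2`` by iteratively reweighted least
    squares (a Poisson-family GLM, the canonical Gaussian response model
    for abundance data). When the quadratic coefficient is negative the
    optimum is the analytic vertex ``-b1 / (2 b2)``, clipped to the
    observed gradient range; a non-concave fit puts the optimum on the
    boundary where the fitted curve is higher. The ``better_than_linear``
    flag comes from a paired t-test on the absolute residuals of the
    unimodal versus ordinary linear fits (P < ``alpha``). On
    non-convergence the linear optimum convention (range boundary) is used
    and the flag is False.
    """
    y = np.asarray(abundance_k, dtype=float)
    xv = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(xv)
    y, xv = y[ok], xv[ok]
    if len(y) < 5:
        raise ValueError("gaussian fit needs at least 5 sites with data")
    lo, hi = float(xv.min()), float(xv.max())

    lin = np.polyfit(xv, y, 1)
    lin_fitted = np.polyval(lin, xv)
    lin_optimum = hi if lin[0] >= 0 else lo

    X = np.column_stack([np.ones_like(xv), xv, xv**2])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
        if not np.all(np.isfinite(glm.params)):
            raise ValueError("non-finite coefficients")
        b0, b1, b2 = glm.params
        gau_fitted = np.exp(np.clip(X @ glm.params, -700, 700))
    except Exception:
        warnings.warn("gaussian fit did not converge; linear fallback", stacklevel=2)
        return GaussianFit(lin_optimum, False, False, 1.0)

    if b2 < 0:
        optimum = float(np.clip(-b1 / (2 * b2), lo, hi))
    else:
        # convex / monotone on the range: argmax is at a boundary
        at_lo = b0 + b1 * lo + b2 * lo**2
        at_hi = b0 + b1 * hi + b2 * hi**2
        optimum = lo if at_lo >= at_hi else hi

    res_g = np.abs(y - gau_fitted)
    res_l = np.abs(y - lin_fitted)
    if np.allclose(res_g, res_l):
        return GaussianFit(optimum, False, True, 1.0)
    tres = stats.ttest_rel(res_l, res_g)
    better = bool(tres.pvalue < alpha and res_g.mean() < res_l.mean())
    return GaussianFit(optimum, better, True, float(tres.pvalue))


def wa_optimum(abundance_k, x) -> float:
    """Abundance-weighted mean of gradient values: u = sum(y x) / sum(y).

    Invariant under rescaling all abundances. All-zero abundance is
    undefined and returned as NaN.
    """
    y = np.asarray(abundance_k, dtype=float)
    xv = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(xv)
    y, xv = y[ok], xv[ok]
    total = y.sum()
    if total == 0:
        return float("nan")
    return float((y * xv).sum() / total)


def rescale_indicator(optimum: float, gradient_min: float, gradient_max: float) -> int:
    """Map an optimum to an integer 0-10 over the observed gradient range.

    Rounds half up (so 0.5 -> 1), matching the integer presentation of
    published indicator checklists. Optima outside the range are clipped
    with a warning.
    """
    if not gradient_min < gradient_max:
        raise ValueError("gradient_min must be below gradient_max")
    if math.isnan(optimum):
        raise ValueError("optimum is undefined")
    if optimum < gradient_min or optimum > gradient_max:
        warnings.warn("optimum outside gradient range; clipped", stacklevel=2)
        optimum = min(max(optimum, gradient_min), gradient_max)
    scaled = 10.0 * (optimum - gradient_min) / (gradient_max - gradient_min)
    return int(math.floor(scaled + 0.5))


def categorical_specificity(abundance_k, labels, categories=None) -> pd.Series:
    """Share of a taxon's total abundance per category, on a 0-10 scale.

    The raw shares sum to one; each is multiplied by ten and rounded half
    up, so a strictly summer taxon scores (spring 0, summer 10).
    """
    y = pd.Series(np.asarray(abundance_k, dtype=float))
    lab = pd.Series(np.asarray(labels), index=y.index)
    if lab.isna().any():
        raise ValueError("every sample must be labeled")
    sums = y.groupby(lab).sum()
    if categories is not None:
        sums = sums.reindex(categories, fill_value=0.0)
    total = sums.sum()
    shares = sums / total if total > 0 else sums * 0.0
    return shares.map(lambda s: int(math.floor(10.0 * s + 0.5)))


# ---------------------------------------------------------------------------
# penalized-spline smoother and permutation tests
# ---------------------------------------------------------------------------


def _bspline_basis(x: np.ndarray, n_basis: int = 6, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with quantile-placed interior knots."""
    n_interior = max(n_basis - degree - 1, 0)
    if n_interior:
        qs = np.linspace(0, 100, n_interior + 2)[1:-1]
        interior = np.percentile(x, qs)
    else:
        interior = np.array([])
    lo, hi = x.min(), x.max()
    pad = 1e-8 * max(hi - lo, 1.0)
    t = np.concatenate(
        [[lo - pad] * (degree + 1), interior, [hi + pad] * (degree + 1)]
    )
    return BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()


def _second_diff_penalty(k: int) -> np.ndarray:
    D = np.diff(np.eye(k), n=2, axis=0)
    return D.T @ D


def _penalized_rss(B: np.ndarray, y: np.ndarray, lam: float, P: np.ndarray):
    BtB = B.T @ B
    coef = np.linalg.solve(BtB + lam * P, B.T @ y)
    fitted = B @ coef
    rss = float(((y - fitted) ** 2).sum())
    return rss, fitted, coef


_LAMBDA_GRID = np.logspace(-4, 4, 17)


class _PenalizedSmoother:
    """Penalized B-spline regression with GCV smoothness selection.

    The smoothing parameter is re-selected for every response vector, so a
    permutation test that applies :meth:`deviance_explained` to both the
    observed and the permuted data stays exchangeable under the null
    (fixing the observed data's lambda for the permutations would inflate
    the observed statistic by its own selection step). Row permutations of
    the design leave ``B'B`` unchanged, so the per-lambda normal-equation
    factorizations are computed once.
    """

    def __init__(self, B: np.ndarray, P: np.ndarray, grid=_LAMBDA_GRID):
        self.B = B
        self.n = B.shape[0]
        BtB = B.T @ B
        self.grid = np.asarray(grid, dtype=float)
        self.inverses = [np.linalg.inv(BtB + lam * P) for lam in self.grid]
        self.edf = [float(np.trace(inv @ BtB)) for inv in self.inverses]

    def rss_at_gcv(self, y: np.ndarray) -> tuple[float, float]:
        """(RSS, lambda) at the GCV-optimal smoothing for this response."""
        Bty = self.B.T @ y
        yty = float(y @ y)
        best = (np.inf, np.inf, self.grid[0])
        for lam, inv, edf in zip(self.grid, self.inverses, self.edf):
            coef = inv @ Bty
            # RSS via the normal equations; B'B inv appears inside `inv`
            rss = yty - 2 * float(coef @ Bty) + float(
                coef @ (self.B.T @ (self.B @ coef))
            )
            gcv = self.n * rss / max(self.n - edf, 1e-8) ** 2
            if gcv < best[0]:
                best = (gcv, rss, lam)
        return best[1], best[2]

    def deviance_explained(self, y: np.ndarray) -> float:
        tss = float(((y - y.mean()) ** 2).sum())
        rss, _ = self.rss_at_gcv(y)
        return 1.0 - rss / tss


def _gcv_lambda(B: np.ndarray, y: np.ndarray, P: np.ndarray, grid=None) -> float:
    """Smoothing parameter by generalized cross-validation on a log grid."""
    grid = _LAMBDA_GRID if grid is None else grid
    smoother = _PenalizedSmoother(B, P, grid)
    return smoother.rss_at_gcv(np.asarray(y, dtype=float))[1]


@dataclass
class SmoothTestResult:
    deviance_explained: float
    p: float
    testable: bool


def gam_tp_significance(
    abundance_k,
    tp,
    n_perm: int = 199,
    seed: int | np.random.Generator | None = None,
    n_basis: int = 6,
) -> SmoothTestResult:
    """Permutation test of a taxon's smooth response to the TP gradient.

    A penalized cubic spline of relative abundance on transformed TP is
    fitted (smoothness by GCV); the statistic is the deviance explained
    (1 - RSS/TSS). Significance comes from ``n_perm`` Monte Carlo
    permutations of TP across samples:
    ``p = (1 + #{permuted >= observed}) / (n_perm + 1)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(abundance_k, dtype=float)
    x = np.asarray(tp, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return SmoothTestResult(0.0, 1.0, False)
    try:
        B = _bspline_basis(x, n_basis)
        P = _second_diff_penalty(B.shape[1])
        smoother = _PenalizedSmoother(B, P)
        dev_obs = smoother.deviance_explained(y)
    except np.linalg.LinAlgError:
        warnings.warn("smoother failed; taxon reported untestable", stacklevel=2)
        return SmoothTestResult(float("nan"), 1.0, False)
    # permuting TP across samples is equivalent to permuting the response
    # against a fixed design; the GCV selection is repeated per permutation
    exceed = 0
    for _ in range(n_perm):
        if smoother.deviance_explained(y[rng.permutation(len(y))]) >= dev_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return SmoothTestResult(dev_obs, float(p), True)


def gam_tp_given_alk(
    abundance_k,
    tp,
    alk,
    n_perm: int = 199,
    seed: int | np.random.Generator | None = None,
    n_basis: int = 6,
) -> SmoothTestResult:
    """Test the unique smooth TP signal after removing the alkalinity signal.

    The statistic is the added deviance explained by a TP spline on top of
    an alkalinity-only spline (both penalized, smoothness chosen by GCV on
    the observed fits). Permutations reshuffle TP across samples while the
    alkalinity design stays fixed, so the null preserves the
    alkalinity-abundance relationship.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(abundance_k, dtype=float)
    x_tp = np.asarray(tp, dtype=float)
    x_alk = np.asarray(alk, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return SmoothTestResult(0.0, 1.0, False)
    try:
        A = _bspline_basis(x_alk, n_basis)
        B = _bspline_basis(x_tp, n_basis)
        Pa = _second_diff_penalty(A.shape[1])
        Pb = _second_diff_penalty(B.shape[1])
        lam_a = _gcv_lambda(A, y, Pa)
        rss_null, fitted_a, _ = _penalized_rss(A, y, lam_a, Pa)
        resid_smoother = _PenalizedSmoother(B, Pb)
        resid = y - fitted_a

        def added_dev(Bmat: np.ndarray, resid_for_lam: np.ndarray) -> float:
            # lambda for the TP block re-selected by GCV against the
            # alkalinity residuals, identically for observed and permuted
            _, lam_b = resid_smoother.rss_at_gcv(resid_for_lam)
            full = np.hstack([A, Bmat])
            k_a, k_b = A.shape[1], Bmat.shape[1]
            P_full = np.zeros((k_a + k_b, k_a + k_b))
            P_full[:k_a, :k_a] = lam_a * Pa
            P_full[k_a:, k_a:] = lam_b * Pb
            BtB = full.T @ full
            # ridge on the block diagonal keeps collinear designs solvable
            coef = np.linalg.solve(
                BtB + P_full + 1e-8 * np.eye(k_a + k_b), full.T @ y
            )
            rss_full = float(((y - full @ coef) ** 2).sum())
            return (rss_null - rss_full) / tss

        dev_obs = added_dev(B, resid)
    except np.linalg.LinAlgError:
        warnings.warn("smoother failed; taxon reported untestable", stacklevel=2)
        return SmoothTestResult(float("nan"), 1.0, False)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(y))
        # GCV of resid on B[perm] equals GCV of resid[perm^-1] on B
        if added_dev(B[perm], resid[np.argsort(perm)]) >= dev_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return SmoothTestResult(dev_obs, float(p), True)


# ---------------------------------------------------------------------------
# coefficient table
# ---------------------------------------------------------------------------

SEASONS = ("spring", "summer")


def build_coefficient_table(
    abundance: AbundanceMatrix,
    env: EnvironmentTable,
    variables=None,
    min_occurrences: int = 5,
    lakes=None,
) -> pd.DataFrame:
    """Assemble the per-taxon indicator checklist.

    For each eligible taxon (present in more than ``min_occurrences``
    samples) and each variable: the significant linear sign (+1/0/-1), the
    Gaussian-fit indicator value 0-10 with its better-than-linear flag, and
    the WA indicator value 0-10. Season and lake specificity columns are
    included when the abundance matrix carries those labels. The row order
    follows the abundance matrix's taxon order; the ``abundance_basis``
    column records which of the four representations produced the table.
    """
    variables = list(env.variables) if variables is None else list(variables)
    X = env.transformed(variables).reindex(abundance.samples)
    taxa = eligible_taxa(abundance, min_occurrences)
    rows = []
    for taxon in taxa:
        y = abundance.data[taxon]
        row: dict = {"taxon": taxon, "n_occurrences": int((y > 0).sum())}
        if abundance.season is not None:
            spec = categorical_specificity(
                y.to_numpy(), abundance.season.to_numpy(), categories=SEASONS
            )
            for s in SEASONS:
                row[f"season_{s}"] = spec[s]
        if abundance.lake is not None:
            cats = lakes if lakes is not None else sorted(
                pd.unique(abundance.lake.dropna())
            )
            spec = categorical_specificity(
                y.to_numpy(), abundance.lake.to_numpy(), categories=cats
            )
            for c in cats:
                row[f"lake_{c}"] = spec[c]
        for v in variables:
            xv = X[v]
            ok = xv.notna()
            lin = fit_linear(y[ok], xv[ok])
            gau = fit_gaussian(y[ok], xv[ok])
            u = wa_optimum(y[ok], xv[ok])
            lo, hi = float(xv[ok].min()), float(xv[ok].max())
            row[f"{v}_lin"] = lin.sign
            row[f"{v}_gau"] = rescale_indicator(gau.optimum, lo, hi)
            row[f"{v}_gau_better"] = gau.better_than_linear
            row[f"{v}_wa"] = (
                rescale_indicator(u, lo, hi) if np.isfinite(u) else pd.NA
            )
            row[f"{v}_wa_optimum"] = u
        rows.append(row)
    if not rows:
        cols = ["taxon", "n_occurrences"]
        table = pd.DataFrame(columns=cols)
    else:
        table = pd.DataFrame(rows)
    table["abundance_basis"] = abundance.basis
    return table.set_index("taxon") if len(table) else table
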