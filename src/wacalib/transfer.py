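"""Weighted-averaging (WA) transfer function for an environmental gradient.

The calibration model of quantitative paleoecology: a taxon's optimum is
the abundance-weighted mean of the gradient values where it occurs, and an
assemblage's initial inference is the abundance-weighted mean of its taxa's
optima. Averaging twice shrinks the range of inferences, so a post-hoc
"inverse deshrinking" regression of the observed gradient on the initial
inferences rescales them. Optional tolerance downweighting gives
narrow-niche taxa more say. Predictive skill is estimated by leave-one-out
jackknifing, which refits the full pipeline without each sample.

All gradient quantities live on the transformed scale (for total
phosphorus, log10 ug/L); back-transformation is the caller's business via
the environment table's registry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix


@dataclass
class WAModel:
    """Fitted weighted-averaging calibration model.

    ``optima``/``tolerances`` are per-taxon on the transformed gradient;
    ``deshrink_intercept``/``deshrink_slope`` (b0, b1) map initial WA
    estimates to final predictions ``b0 + b1 * xhat0``.
    """

    optima: pd.Series
    tolerances: pd.Series
    deshrink_intercept: float
    deshrink_slope: float
    tolerance_dw: bool
    deshrink: str  # {"inverse", "none"}
    gradient_transform: str = "log"
    tolerance_floor: float = 0.0
    n_training_samples: int = 0

    @property
    def taxa(self) -> pd.Index:
        return self.optima.index

    @property
    def fingerprint(self) -> str:
        return f"{self.n_training_samples} samples; {len(self.taxa)} taxa"

    def effective_tolerances(self) -> pd.Series:
        return self.tolerances.clip(lower=self.tolerance_floor)


@dataclass
class Prediction:
    """Per-sample inferences plus analog bookkeeping."""

    values: pd.Series  # deshrunk, transformed gradient units
    raw: pd.Series  # pre-deshrinking weighted averages
    coverage: pd.Series  # fraction of assemblage mass in modeled taxa
    no_overlap: pd.Index  # samples sharing no taxa with the model


@dataclass
class CrossValReport:
    """Apparent and jackknifed (leave-one-out) performance."""

    r2_apparent: float
    r2_jack: float
    rmse_apparent: float
    rmsep_jack: float
    predictions_apparent: pd.Series
    predictions_jack: pd.Series
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _as_relative(abundance: AbundanceMatrix) -> pd.DataFrame:
    if not abundance.is_relative:
        raise ValueError(
            "WA calibration requires a relative abundance basis; convert "
            "with AbundanceMatrix.to_relative()"
        )
    return abundance.data


def _wa_core(
    Y: np.ndarray, x: np.ndarray, tolerance_dw: bool, tolerance_floor: float
):
    """Optima, tolerances and initial estimates from arrays.

    Returns (u, t, keep, xhat0) where ``keep`` marks taxa with nonzero
    total abundance (others carry NaN coefficients and are excluded).
    """
    colsum = Y.sum(axis=0)
    keep = colsum > 0
    u = np.full(Y.shape[1], np.nan)
    t = np.full(Y.shape[1], np.nan)
    u[keep] = (Y[:, keep] * x[:, None]).sum(axis=0) / colsum[keep]
    sq = (Y[:, keep] * (x[:, None] - u[keep][None, :]) ** 2).sum(axis=0)
    t[keep] = np.sqrt(np.maximum(sq / colsum[keep], 0.0))
    xhat0 = _wa_average(Y[:, keep], u[keep], t[keep], tolerance_dw, tolerance_floor)
    return u, t, keep, xhat0


def _wa_average(
    Y: np.ndarray,
    u: np.ndarray,
    t: np.ndarray,
    tolerance_dw: bool,
    tolerance_floor: float,
) -> np.ndarray:
    """Weighted average of taxon optima per sample (NaN when no mass)."""
    if tolerance_dw:
        t_eff = np.maximum(t, tolerance_floor)
        W = Y / t_eff[None, :] ** 2
    else:
        W = Y
    wsum = W.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = (W @ u) / wsum
    out[wsum == 0] = np.nan
    return out


def _deshrink_inverse(x: np.ndarray, xhat0: np.ndarray) -> tuple[float, float]:
    """OLS of observed gradient on initial estimates -> (b0, b1)."""
    ok = np.isfinite(xhat0)
    if ok.sum() < 2 or np.var(xhat0[ok]) == 0:
        raise ValueError("degenerate initial estimates; cannot deshrink")
    b1, b0 = np.polyfit(xhat0[ok], x[ok], 1)
    return float(b0), float(b1)


def fit_wa(
    abundance: AbundanceMatrix,
    gradient: pd.Series,
    tolerance_dw: bool = True,
    deshrink: str = "inverse",
    gradient_transform: str = "log",
) -> WAModel:
    """Fit a WA model on a relative-abundance training set.

    Parameters
    ----------
    abundance
        Training assemblages, relative basis.
    gradient
        Transformed environmental values, indexed like the samples.
    tolerance_dw
        Downweight each taxon by ``1 / tolerance^2`` when averaging
        optima into sample estimates. Tolerances below a floor (one tenth
        of the gradient's standard deviation) are raised to the floor so a
        single-occurrence taxon cannot dominate.
    deshrink
        ``"inverse"`` (regress observed on initial estimates) or ``"none"``.

    Taxa with zero total abundance are dropped with a warning.
    """
    Y_df = _as_relative(abundance)
    x = gradient.reindex(Y_df.index).to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("gradient contains missing values")
    if deshrink not in ("inverse", "none"):
        raise ValueError("deshrink must be 'inverse' or 'none'")
    Y = Y_df.to_numpy(dtype=float)
    floor = float(np.std(x, ddof=1) / 10.0) if len(x) > 1 else 0.0
    u, t, keep, xhat0 = _wa_core(Y, x, tolerance_dw, floor)
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} taxa with zero total abundance dropped",
            stacklevel=2,
        )
    if deshrink == "inverse":
        b0, b1 = _deshrink_inverse(x, xhat0)
    else:
        b0, b1 = 0.0, 1.0
    taxa = Y_df.columns[keep]
    return WAModel(
        optima=pd.Series(u[keep], index=taxa, name="optimum"),
        tolerances=pd.Series(t[keep], index=taxa, name="tolerance"),
        deshrink_intercept=b0,
        deshrink_slope=b1,
        tolerance_dw=tolerance_dw,
        deshrink=deshrink,
        gradient_transform=gradient_transform,
        tolerance_floor=floor,
        n_training_samples=len(Y_df),
    )


def predict(model: WAModel, assemblages: pd.DataFrame) -> Prediction:
    """Infer the gradient for assemblages (rows = samples, relative basis).

    Each row is renormalized over the taxa the model was trained on;
    ``coverage`` reports the fraction of the original assemblage those
    taxa account for. A sample sharing no taxa with the model gets a
    missing prediction and is listed in ``no_overlap``.
    """
    common = assemblages.columns.intersection(model.taxa)
    total = assemblages.sum(axis=1)
    in_model = assemblages[common].sum(axis=1) if len(common) else pd.Series(
        0.0, index=assemblages.index
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        coverage = (in_model / total.where(total > 0)).fillna(0.0)
    if len(common) == 0:
        nan = pd.Series(np.nan, index=assemblages.index)
        return Prediction(nan, nan.copy(), coverage, assemblages.index)
    Y = assemblages[common].to_numpy(dtype=float)
    u = model.optima[common].to_numpy()
    t = model.tolerances[common].to_numpy()
    raw = _wa_average(Y, u, t, model.tolerance_dw, model.tolerance_floor)
    values = model.deshrink_intercept + model.deshrink_slope * raw
    raw_s = pd.Series(raw, index=assemblages.index, name="raw")
    values_s = pd.Series(values, index=assemblages.index, name="inferred")
    no_overlap = assemblages.index[~np.isfinite(raw)]
    return Prediction(values_s, raw_s, coverage, no_overlap)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _performance(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    ok = np.isfinite(predicted)
    r = stats.pearsonr(observed[ok], predicted[ok]).statistic
    rmse = float(np.sqrt(np.mean((observed[ok] - predicted[ok]) ** 2)))
    return float(r**2), rmse


def apparent_r2(
    abundance: AbundanceMatrix, gradient: pd.Series, **options
) -> float:
    """Apparent (non-cross-validated) r2 of a freshly fitted WA model."""
    model = fit_wa(abundance, gradient, **options)
    pred = predict(model, _as_relative(abundance))
    x = gradient.reindex(abundance.samples).to_numpy(dtype=float)
    return _performance(x, pred.values.to_numpy())[0]


def jackknife(
    abundance: AbundanceMatrix,
    gradient: pd.Series,
    tolerance_dw: bool = True,
    deshrink: str = "inverse",
) -> CrossValReport:
    """Leave-one-out cross-validation of the full WA pipeline.

    For every sample the optima, tolerances and deshrinking regression are
    refit without it, and the held-out sample is predicted. A held-out
    sample whose taxa all vanish from the reduced training set cannot be
    predicted and is excluded from the report (count logged).
    """
    Y_df = _as_relative(abundance)
    n = len(Y_df)
    if n < 10:
        raise ValueError("jackknifing needs at least 10 samples")
    x_full = gradient.reindex(Y_df.index).to_numpy(dtype=float)
    Y_full = Y_df.to_numpy(dtype=float)

    model = fit_wa(abundance, gradient, tolerance_dw=tolerance_dw, deshrink=deshrink)
    pred_app = predict(model, Y_df).values
    r2_app, rmse_app = _performance(x_full, pred_app.to_numpy())

    preds = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Y_train, x_train = Y_full[mask], x_full[mask]
        floor = float(np.std(x_train, ddof=1) / 10.0)
        u, t, keep, xhat0 = _wa_core(Y_train, x_train, tolerance_dw, floor)
        if deshrink == "inverse":
            try:
                b0, b1 = _deshrink_inverse(x_train, xhat0)
            except ValueError:
                mask[i] = True
                continue
        else:
            b0, b1 = 0.0, 1.0
        raw_i = _wa_average(
            Y_full[i : i + 1, keep], u[keep], t[keep], tolerance_dw, floor
        )[0]
        if np.isfinite(raw_i):
            preds[i] = b0 + b1 * raw_i
        mask[i] = True

    excluded = int(np.sum(~np.isfinite(preds)))
    if excluded:
        warnings.warn(
            f"{excluded} sample(s) unpredictable when held out; excluded",
            stacklevel=2,
        )
    r2_jack, rmsep = _performance(x_full, preds)
    return CrossValReport(
        r2_apparent=r2_app,
        r2_jack=r2_jack,
        rmse_apparent=rmse_app,
        rmsep_jack=rmsep,
        predictions_apparent=pred_app,
        predictions_jack=pd.Series(preds, index=Y_df.index, name="jackknife"),
        n_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# modern analog technique
# ---------------------------------------------------------------------------


def squared_chord(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Squared chord dissimilarity between rows of p and rows of q."""
    sp, sq = np.sqrt(p), np.sqrt(q)
    return ((sp[:, None, :] - sq[None, :, :]) ** 2).sum(axis=-1)


@dataclass
class MATResult:
    values: pd.Series  # inferred gradient per test sample
    analog_distances: pd.DataFrame  # test sample x analog rank (variable width)
    analog_ids: pd.DataFrame


def mat_predict(
    training: AbundanceMatrix,
    gradient: pd.Series,
    test: pd.DataFrame,
    k: int = 5,
    metric: str = "squared_chord",
) -> MATResult:
    """Modern analog technique: mean gradient of the k closest assemblages.

    Dissimilarity defaults to squared chord distance on relative
    abundances (the discipline's standard for percentage data). Training
    samples tied with the k-th smallest distance are all included, and the
    effective analog count is visible in the result's ragged columns.
    """
    if metric != "squared_chord":
        raise ValueError("only the squared_chord metric is implemented")
    Y = _as_relative(training)
    if k > len(Y):
        raise ValueError("k cannot exceed the number of training samples")
    cols = Y.columns.union(test.columns)
    Yt = Y.reindex(columns=cols, fill_value=0.0).to_numpy(dtype=float)
    Tt = test.reindex(columns=cols, fill_value=0.0).to_numpy(dtype=float)
    x = gradient.reindex(Y.index).to_numpy(dtype=float)
    D = squared_chord(Tt, Yt)
    values, dist_rows, id_rows = [], [], []
    for i in range(D.shape[0]):
        order = np.argsort(D[i], kind="stable")
        kth = D[i, order[k - 1]]
        chosen = order[D[i, order] <= kth + 1e-12]
        values.append(float(np.mean(x[chosen])))
        dist_rows.append(D[i, chosen])
        id_rows.append(Y.index[chosen].to_list())
    width = max(len(r) for r in dist_rows)
    dist = pd.DataFrame(
        [list(r) + [np.nan] * (width - len(r)) for r in dist_rows],
        index=test.index,
        columns=[f"analog_{j + 1}" for j in range(width)],
    )
    ids = pd.DataFrame(
        [list(r) + [None] * (width - len(r)) for r in id_rows],
        index=test.index,
        columns=dist.columns,
    )
    return MATResult(
        pd.Series(values, index=test.index, name="mat_inferred"), dist, ids
    )
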