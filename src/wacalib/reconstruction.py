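"""Downcore application of a calibrated transfer function, with diagnostics.

Applying a modern calibration to fossil assemblages only makes sense when
the reconstructed variable actually organizes the fossil data. Two
diagnostics quantify that:

* ``lambda_ratio`` — the variance of the fossil assemblages captured by
  the first axis of an RDA constrained to the reconstruction (lambda_R),
  as a fraction of the first unconstrained PCA axis (lambda_P). Values
  near 1 mean the reconstruction tracks the core's main compositional
  gradient; the constrained axis can never beat the unconstrained one, so
  the ratio lies in (0, 1].
* ``ditp_pca_correlation`` — the Pearson correlation between the inferred
  series and the first PCA axis scores of the fossil data. The raw signed
  value is returned (PCA axis orientation is arbitrary) together with its
  magnitude.

Error bands are drawn as the inference +- the jackknife RMSEP on the
transformed (log) scale and back-transformed, so they are asymmetric in
concentration units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CoreStratigraphy
from .environment import inverse_transform_variable
from .ordination import pca_species, rda
from .transfer import CrossValReport, WAModel, predict


def reconstruct_core(
    model: WAModel,
    core: CoreStratigraphy,
    crossval: CrossValReport | None = None,
    coverage_floor: float = 0.5,
) -> CoreStratigraphy:
    """Infer the gradient for every core interval; attach error bands.

    Each interval is renormalized over the model's taxa; the fraction of
    assemblage mass those taxa carry is reported as ``coverage`` and
    intervals below ``coverage_floor`` are flagged (never dropped). An
    interval sharing no taxa with the model gets a missing inference.
    Bands are ``inference +- RMSEP_jack`` on the transformed scale, also
    back-transformed to concentration units when the model's gradient
    transform is log.
    """
    pred = predict(model, core.abundances)
    out = pd.DataFrame(index=core.intervals)
    out["year"] = core.dates
    if core.depths is not None:
        out["depth"] = core.depths
    out["ditp_transformed"] = pred.values
    out["coverage"] = pred.coverage
    out["low_coverage"] = pred.coverage < coverage_floor
    if out["low_coverage"].any():
        warnings.warn(
            f"{int(out['low_coverage'].sum())} interval(s) below coverage "
            f"floor {coverage_floor}",
            stacklevel=2,
        )
    rmsep = crossval.rmsep_jack if crossval is not None else np.nan
    out["band_lo_transformed"] = out["ditp_transformed"] - rmsep
    out["band_hi_transformed"] = out["ditp_transformed"] + rmsep
    kind = model.gradient_transform
    for col_t, col in [
        ("ditp_transformed", "ditp"),
        ("band_lo_transformed", "band_lo"),
        ("band_hi_transformed", "band_hi"),
    ]:
        out[col] = inverse_transform_variable(out[col_t].to_numpy(), kind)
    return CoreStratigraphy(
        abundances=core.abundances,
        dates=core.dates,
        depths=core.depths,
        true_gradient=core.true_gradient,
        reconstruction=out,
    )


@dataclass
class LambdaRatio:
    lambda_r: float
    lambda_p: float

    @property
    def ratio(self) -> float:
        return self.lambda_r / self.lambda_p


def lambda_ratio(core_species: pd.DataFrame, ditp) -> LambdaRatio:
    """lambda_R / lambda_P reconstruction-relevance diagnostic.

    lambda_R: axis-1 constrained variance fraction of an RDA of the core
    species on the inferred series alone; lambda_P: axis-1 fraction of an
    unconstrained PCA. Needs at least 3 intervals and a non-constant
    inferred series.
    """
    series = pd.Series(np.asarray(ditp, dtype=float), index=core_species.index)
    if len(core_species) < 3:
        raise ValueError("lambda ratio needs at least 3 intervals")
    if series.std(ddof=0) == 0:
        raise ValueError("inferred series is constant; lambda ratio undefined")
    constrained = rda(core_species, series.to_frame("ditp"))
    unconstrained = pca_species(core_species)
    lam_r = float(constrained.constrained_fractions[0])
    lam_p = float(unconstrained.unconstrained_fractions[0])
    return LambdaRatio(lam_r, lam_p)


@dataclass
class DitpPcaCorrelation:
    r: float  # signed, with the PCA axis as returned (orientation arbitrary)
    abs_r: float
    n: int


def ditp_pca_correlation(core_species: pd.DataFrame, ditp) -> DitpPcaCorrelation:
    """Pearson r between the inferred series and PCA axis-1 interval scores.

    The sign depends on the arbitrary orientation of the PCA axis and is
    reported as-is; ``abs_r`` is the orientation-free magnitude.
    """
    series = np.asarray(ditp, dtype=float)
    if len(core_species) < 3:
        raise ValueError("correlation needs at least 3 intervals")
    if np.std(series) == 0:
        raise ValueError("inferred series is constant; correlation undefined")
    scores = pca_species(core_species).site_scores.iloc[:, 0].to_numpy()
    if np.std(scores) == 0:
        raise ValueError("degenerate core: PCA axis 1 has no variance")
    r = float(stats.pearsonr(series, scores).statistic)
    return DitpPcaCorrelation(r, abs(r), len(series))
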