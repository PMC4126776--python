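"""CSV interchange formats, model serialization and run configuration.

All tabular artifacts are UTF-8 CSV with a header row: abundance matrices
(samples as rows, taxa as columns, optional ``season``/``lake`` metadata
columns), environment tables (sites x variables, coordinate columns ``x``/
``y`` or ``lon``/``lat``), cores (``year`` and optional ``depth`` columns
followed by taxon columns). The environment transform registry is
serialized as a YAML sidecar so models and tables cannot silently disagree.
Fitted WA models are written as a plain-text coefficient file: ``#``-header
lines carrying the transform, options and training fingerprint, then a
``taxon,optimum,tolerance`` CSV body.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import AbundanceMatrix, CoreStratigraphy
from .environment import EnvironmentTable
from .transfer import WAModel

_META_COLS = ("season", "lake")
_COORD_COLS = ("x", "y", "lon", "lat")


def read_abundance(
    path, basis: str, renormalize: bool = False
) -> AbundanceMatrix:
    """Read a site x taxon abundance CSV (first column = sample id).

    Relative bases are verified to row-sum to 1 within 1e-6; with
    ``renormalize`` rows are rescaled instead (warning), otherwise a
    violation is an error.
    """
    df = pd.read_csv(path, index_col=0)
    season = df.pop("season") if "season" in df.columns else None
    lake = df.pop("lake") if "lake" in df.columns else None
    values = df.to_numpy(dtype=float)
    if values.size and np.nanmin(values) < 0:
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative abundance at sample {df.index[r]!r}, taxon "
            f"{df.columns[c]!r} in {path}"
        )
    matrix = AbundanceMatrix(df.astype(float), basis, season=season, lake=lake)
    if matrix.is_relative:
        sums = matrix.row_sums()
        off = (sums - 1.0).abs() > 1e-6
        if off.any():
            if not renormalize:
                raise ValueError(
                    f"{int(off.sum())} row(s) of {path} do not sum to 1 "
                    f"(first: {sums.index[off.argmax()]!r}); pass "
                    "renormalize=True to rescale"
                )
            warnings.warn(
                f"renormalized {int(off.sum())} row(s) of {path}", stacklevel=2
            )
            matrix = AbundanceMatrix(
                df.div(sums, axis=0), basis, season=season, lake=lake
            )
    return matrix


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    df = matrix.data.copy()
    if matrix.season is not None:
        df.insert(0, "season", matrix.season)
    if matrix.lake is not None:
        df.insert(0, "lake", matrix.lake)
    df.to_csv(path)


def read_environment(path, transforms_path=None) -> EnvironmentTable:
    """Read a site x variable CSV plus an optional YAML transform registry."""
    df = pd.read_csv(path, index_col=0)
    coords = None
    coord_cols = [c for c in _COORD_COLS if c in df.columns]
    if coord_cols:
        coords = df[coord_cols]
        df = df.drop(columns=coord_cols)
    season = df.pop("season") if "season" in df.columns else None
    lake = df.pop("lake") if "lake" in df.columns else None
    transforms, offsets = {}, {}
    if transforms_path is not None and Path(transforms_path).exists():
        registry = yaml.safe_load(Path(transforms_path).read_text()) or {}
        transforms = registry.get("transforms", {})
        offsets = registry.get("log_offsets", {})
    return EnvironmentTable(
        df.astype(float), transforms, coords=coords, season=season, lake=lake,
        log_offsets=offsets,
    )


def write_environment(table: EnvironmentTable, path, transforms_path=None) -> None:
    df = table.data.copy()
    if table.coords is not None:
        for c in reversed(table.coords.columns):
            df.insert(0, c, table.coords[c])
    df.to_csv(path)
    if transforms_path is not None:
        Path(transforms_path).write_text(
            yaml.safe_dump(
                {
                    "transforms": dict(table.transforms),
                    "log_offsets": {k: float(v) for k, v in table.log_offsets.items()},
                }
            )
        )


def read_core(path) -> CoreStratigraphy:
    df = pd.read_csv(path, index_col=0)
    if "year" not in df.columns:
        raise ValueError(f"core file {path} lacks a 'year' column")
    dates = df.pop("year")
    depths = df.pop("depth") if "depth" in df.columns else None
    truth = df.pop("true_tp") if "true_tp" in df.columns else None
    return CoreStratigraphy(
        df.astype(float), dates=dates, depths=depths, true_gradient=truth
    )


def write_core(core: CoreStratigraphy, path) -> None:
    df = core.abundances.copy()
    if core.true_gradient is not None:
        df.insert(0, "true_tp", core.true_gradient)
    if core.depths is not None:
        df.insert(0, "depth", core.depths)
    df.insert(0, "year", core.dates)
    df.to_csv(path)


def write_model(model: WAModel, path) -> None:
    lines = [
        f"# gradient_transform: {model.gradient_transform}",
        f"# tolerance_dw: {model.tolerance_dw}",
        f"# deshrink: {model.deshrink}",
        f"# deshrink_intercept: {float(model.deshrink_intercept)!r}",
        f"# deshrink_slope: {float(model.deshrink_slope)!r}",
        f"# tolerance_floor: {float(model.tolerance_floor)!r}",
        f"# training: {model.fingerprint}",
        "taxon,optimum,tolerance",
    ]
    for taxon in model.taxa:
        lines.append(
            f"{taxon},{float(model.optima[taxon])!r},{float(model.tolerances[taxon])!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path) -> WAModel:
    header: dict = {}
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            header[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    df = pd.DataFrame(
        [row.split(",") for row in body[1:]], columns=body[0].split(",")
    ).set_index("taxon")
    n_samples = int(header.get("training", "0 samples").split()[0])
    return WAModel(
        optima=df["optimum"].astype(float).rename("optimum"),
        tolerances=df["tolerance"].astype(float).rename("tolerance"),
        deshrink_intercept=float(header["deshrink_intercept"]),
        deshrink_slope=float(header["deshrink_slope"]),
        tolerance_dw=header["tolerance_dw"] == "True",
        deshrink=header["deshrink"],
        gradient_transform=header["gradient_transform"],
        tolerance_floor=float(header.get("tolerance_floor", 0.0)),
        n_training_samples=n_samples,
    )


#: Recognized run-configuration keys and their defaults.
CONFIG_DEFAULTS = {
    "basis": "rel_density",
    "tolerance_dw": True,
    "deshrink": "inverse",
    "n_perm": 199,
    "n_sim": 1000,
    "radii": [0.0, 100.0, 300.0, 600.0],
    "seed": 0,
    "coords": "planar",
    "n_sites": 500,
    "n_taxa": 100,
    "count_total": 400,
}


def read_config(path=None, overrides: dict | None = None) -> dict:
    """Plain-text key-value (YAML) run configuration; unknown keys rejected."""
    config = dict(CONFIG_DEFAULTS)
    loaded = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
    for source in (loaded, overrides or {}):
        for key, value in source.items():
            if key not in CONFIG_DEFAULTS:
                raise ValueError(f"unknown configuration key {key!r}")
            if value is not None:
                config[key] = value
    return config
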