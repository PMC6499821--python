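"""Orchestration of the analysis designs over a gridded dataset.

A plan is a list of named regression models over a CellTable: each model
names a response (log language diversity by default, or speaker-population
summaries), its predictors (land coverage and an intercept are always
included), and the predictors to test by drop-one likelihood-ratio tests.
The pipeline builds the phylogenetic similarity and centroid-distance
matrices once per (subsampled) cell set, fits each model by ML-GLS, runs
the drop-one tests with the reduced fits warm-started at the full optimum,
and formats rows as ``t (p) LR`` — the layout of the climate, landscape
and biodiversity result tables.

Also here: the latitudinal-gradient test (log diversity on absolute
latitude, plus the does-latitude-add-to-climate augmentation test),
residual hotspot mapping at |standardized residual| >= 1.96 with the
family-count regression on residuals, and the variance partition
(predicted R^2 of the full model, the climate share of it, and the
GLS-minus-OLS difference that prices spatial and phylogenetic
non-independence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from . import grid as gridmod
from .gls import (
    FitResult,
    GLSConfig,
    LRResult,
    fit_gls,
    fit_ols,
    lr_test,
    standardized_residuals,
)
from .similarity import pairwise_distances, phylosor_matrix
from .tree import LanguageTree

__all__ = [
    "ModelSpec",
    "ModelRun",
    "AnalysisPlan",
    "build_design",
    "run_plan",
    "latitude_gradient",
    "residual_hotspots",
    "variance_partition",
    "format_row",
]


@dataclass(frozen=True)
class ModelSpec:
    """One regression design over the CellTable.

    ``response`` is a CellTable column; with ``log_response`` the natural
    log is taken (the convention for language diversity).  Intercept and
    land coverage are always included.  ``categoricals`` maps a column to
    its reference level for dummy coding.
    """

    response: str = "diversity"
    predictors: tuple[str, ...] = ()
    log_response: bool = True
    include_land: bool = True
    categoricals: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ModelRun:
    name: str
    spec: ModelSpec
    drop_one: tuple[str, ...] = ()


@dataclass(frozen=True)
class AnalysisPlan:
    models: tuple[ModelRun, ...]
    step: int = 1
    row_offset: int = 0
    col_offset: int = 0


class DesignError(ValueError):
    pass


def build_design(
    cells: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response vector and full-rank design matrix for a model spec.

    Returns ``(y, X, names)``; dummy-coded categorical columns are named
    ``col[level]``.  A rank-deficient design raises :class:`DesignError`
    naming the collinear columns.
    """
    missing = [
        p
        for p in list(spec.predictors) + [spec.response]
        if p not in cells.columns
    ]
    if missing:
        raise DesignError(f"columns missing from CellTable: {missing}")
    y = cells[spec.response].to_numpy(dtype=float)
    if spec.log_response:
        if np.any(y <= 0):
            raise DesignError(
                f"log response requires positive {spec.response!r} values"
            )
        y = np.log(y)
    cols: list[np.ndarray] = [np.ones(len(cells))]
    names: list[str] = ["intercept"]
    if spec.include_land:
        cols.append(cells["land_fraction"].to_numpy(dtype=float))
        names.append("land_fraction")
    for p in spec.predictors:
        if p in spec.categoricals:
            ref = spec.categoricals[p]
            levels = sorted(set(cells[p].astype(str)))
            if ref not in levels:
                raise DesignError(f"reference level {ref!r} absent from {p!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((cells[p].astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{p}[{lev}]")
        else:
            cols.append(cells[p].to_numpy(dtype=float))
            names.append(p)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        culprits = _collinear_columns(X, names)
        raise DesignError(f"collinear design; implicated columns: {culprits}")
    return y, X, names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    culprits = []
    for j in range(X.shape[1]):
        Xr = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(Xr) == np.linalg.matrix_rank(X):
            culprits.append(names[j])
    return culprits


def _columns_for(name: str, names: list[str]) -> list[int]:
    """Design-matrix column indices belonging to a (possibly dummy-coded)
    predictor."""
    idx = [
        j
        for j, n in enumerate(names)
        if n == name or n.startswith(f"{name}[")
    ]
    if not idx:
        raise DesignError(f"predictor {name!r} not in design")
    return idx


def format_row(t: float, p: float, lr: float | None = None) -> str:
    """Table-style cell: ``t (p)`` with the LR statistic appended."""
    s = f"{t:.2f} ({p:.3f})"
    if lr is not None:
        s += f" {lr:.2f}"
    return s


def _fit_with_drops(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    P: np.ndarray,
    d: np.ndarray,
    drop_one: Sequence[str],
    config: GLSConfig,
) -> tuple[FitResult, dict[str, LRResult]]:
    full = fit_gls(y, X, P, d, config=config, names=names)
    reduced_fits: dict[str, FitResult] = {}
    for name in drop_one:
        idx = _columns_for(name, names)
        Xr = np.delete(X, idx, axis=1)
        nr = [n for j, n in enumerate(names) if j not in idx]
        reduced_fits[name] = fit_gls(
            y, Xr, P, d, config=config, names=nr, extra_starts=[full.params]
        )
    # a reduced model can only out-fit the full one through a local optimum;
    # warm-start a full refit from the reduced optima to restore nesting
    if reduced_fits and max(r.loglik for r in reduced_fits.values()) > full.loglik:
        refit = fit_gls(
            y, X, P, d, config=config, names=names,
            extra_starts=[r.params for r in reduced_fits.values()] + [full.params],
        )
        if refit.loglik > full.loglik:
            full = refit
    drops = {
        name: lr_test(full, red, df=len(_columns_for(name, names)))
        for name, red in reduced_fits.items()
    }
    return full, drops


def run_plan(
    cells: pd.DataFrame,
    tree: LanguageTree,
    plan: AnalysisPlan,
    config: GLSConfig | None = None,
) -> dict:
    """Run every model in the plan; emit a JSON-serializable report.

    The report is invariant to cell and predictor ordering up to labels,
    and bit-identical across reruns with the same config.
    """
    config = config or GLSConfig()
    cells = gridmod.subsample(cells, plan.step, plan.row_offset, plan.col_offset)
    P = phylosor_matrix(tree, cells)
    d = pairwise_distances(cells)
    report: dict = {"n_cells": int(len(cells)), "models": {}}
    for run in plan.models:
        y, X, names = build_design(cells, run.spec)
        full, drops = _fit_with_drops(y, X, names, P, d, run.drop_one, config)
        rows = {}
        for name in run.drop_one:
            j = _columns_for(name, names)
            lr = drops[name]
            if len(j) == 1:
                rows[name] = format_row(full.t[j[0]], full.p[j[0]], lr.lr)
            else:  # categorical: no single t; report the LR test
                rows[name] = f"LR {lr.lr:.2f} (df {lr.df}, p {lr.p:.3f})"
        report["models"][run.name] = {
            "fit": full.to_dict(),
            "drop_one": {k: v.to_dict() for k, v in drops.items()},
            "rows": rows,
        }
    return report


def latitude_gradient(
    cells: pd.DataFrame,
    tree: LanguageTree,
    config: GLSConfig | None = None,
    climate_predictors: Sequence[str] | None = None,
) -> dict:
    """The latitudinal-gradient tests.

    Fits log diversity on absolute latitude (plus land coverage) by GLS
    and, when climate predictors are supplied, the augmentation test of
    whether latitude still improves a model already holding the climate
    variables (it should not if climate explains the gradient).
    """
    if "lat" not in cells.columns:
        raise DesignError("latitude gradient requires geographic centroids")
    config = config or GLSConfig()
    cells = cells.copy()
    cells["abs_latitude"] = np.abs(cells["lat"].to_numpy(dtype=float))
    if np.ptp(cells["abs_latitude"].to_numpy()) == 0:
        raise DesignError("absolute latitude is constant over cells (degenerate)")
    P = phylosor_matrix(tree, cells)
    d = pairwise_distances(cells)
    spec = ModelSpec(predictors=("abs_latitude",))
    y, X, names = build_design(cells, spec)
    fit = fit_gls(y, X, P, d, config=config, names=names)
    out = {"gradient_fit": fit.to_dict()}
    if climate_predictors:
        aug_spec = ModelSpec(
            predictors=tuple(climate_predictors) + ("abs_latitude",)
        )
        y2, X2, names2 = build_design(cells, aug_spec)
        full, drops = _fit_with_drops(
            y2, X2, names2, P, d, ["abs_latitude"], config
        )
        out["augmentation"] = drops["abs_latitude"].to_dict()
    return out


def residual_hotspots(
    fit: FitResult,
    cells: pd.DataFrame,
    y: np.ndarray,
    X: np.ndarray,
    P: np.ndarray,
    d: np.ndarray,
    config: GLSConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Map-shaped residual table plus the family-count regression.

    Flags cells whose standardized residual from the fitted model exceeds
    |1.96| (unexplained diversity hotspots and coldspots), and fits a GLS
    of the residuals on the per-cell number of language families — the
    qualitative check of whether deeper lineage accumulation tracks the
    unexplained diversity.
    """
    config = config or GLSConfig()
    report = standardized_residuals(fit, y, X, P, d)
    table = cells.copy()
    table["residual"] = report.standardized
    table["hotspot"] = report.standardized >= 1.96
    table["coldspot"] = report.standardized <= -1.96
    keep = ["cell_id", "row", "col", "residual", "hotspot", "coldspot"]
    for c in ("lon", "lat", "x", "y", "n_families"):
        if c in table.columns:
            keep.append(c)
    fam = None
    if "n_families" in cells.columns:
        Xf = np.column_stack(
            [np.ones(len(cells)), cells["n_families"].to_numpy(dtype=float)]
        )
        fam_fit = fit_gls(
            report.standardized,
            Xf,
            P,
            d,
            config=config,
            names=["intercept", "n_families"],
        )
        fam = fam_fit.to_dict()
    return table[[c for c in keep if c in table.columns]], {
        "shapiro_p": report.shapiro_p,
        "n_flagged": int(np.sum(report.flags)),
        "families_regression": fam,
    }


def variance_partition(
    cells: pd.DataFrame,
    tree: LanguageTree,
    full_spec: ModelSpec,
    climate_spec: ModelSpec,
    config: GLSConfig | None = None,
) -> dict:
    """Predicted-R^2 partition of the full model.

    Reports the full-model GLS predicted R^2, the share of it carried by
    the climate-only model, and the GLS-minus-OLS difference, which
    quantifies how much apparent explanatory power rides on spatial
    autocorrelation and phylogenetic non-independence.
    """
    config = config or GLSConfig()
    P = phylosor_matrix(tree, cells)
    d = pairwise_distances(cells)
    y, X, names = build_design(cells, full_spec)
    yc, Xc, names_c = build_design(cells, climate_spec)
    gls_full = fit_gls(y, X, P, d, config=config, names=names)
    gls_climate = fit_gls(yc, Xc, P, d, config=config, names=names_c)
    ols_full = fit_ols(y, X, names=names)
    r2_full = gls_full.predicted_r2
    r2_climate = gls_climate.predicted_r2
    return {
        "predicted_r2_full_gls": r2_full,
        "predicted_r2_climate_gls": r2_climate,
        "climate_share": (r2_climate / r2_full) if r2_full else np.nan,
        "predicted_r2_full_ols": ols_full.predicted_r2,
        "gls_minus_ols": r2_full - ols_full.predicted_r2,
        "full_fit": gls_full.to_dict(),
    }


def write_report(report: dict, path) -> None:
    """Serialize a report deterministically (sorted keys)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
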