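"""Spatially explicit occupancy prediction.

Projects a fitted (or model-averaged) occupancy model onto a covariate
grid — typically 100 m cells — producing map-ready psi estimates with
delta-method standard errors, plus one-covariate response curves with
Wald confidence bands.  All intervals are built on the logit scale and
back-transformed, so they respect the [0, 1] bounds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .occupancy import AveragedModel, OccupancyFit, build_design
from .prep import Standardization


def _coef_block(model, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and covariance block for the named design columns."""
    pos = [list(model.coef.index).index(n) for n in names]
    coef = model.coef.to_numpy()[pos]
    vcov = np.asarray(model.vcov)[np.ix_(pos, pos)]
    return coef, vcov


def predict_psi_grid(
    model: OccupancyFit | AveragedModel,
    grid_covariates: pd.DataFrame,
    standardization: Standardization | None = None,
) -> pd.DataFrame:
    """Predict occupancy over a covariate grid.

    Grid covariates are standardized with the means/SDs stored at fit
    time, so grid cells and camera sites share one scale.  Cells with
    any missing model covariate get missing predictions.  Returns the
    grid with ``psi_hat``, ``se_psi`` and the logit-scale ``eta``/
    ``se_eta`` columns appended.
    """
    std = standardization or model.standardization
    terms = tuple(model.psi_terms)
    needed = [t for t in terms if t != "habitat"]
    missing_cols = [t for t in needed
                    if t not in grid_covariates.columns
                    and f"{t}_m" not in grid_covariates.columns]
    if "habitat" in terms and "habitat" not in grid_covariates.columns:
        missing_cols.append("habitat")
    if missing_cols:
        raise KeyError(f"grid is missing model covariates: {missing_cols}")

    grid = std.apply(grid_covariates) if std is not None else grid_covariates.copy()
    used = [(t if t in grid.columns else f"{t}_m") for t in needed]
    if "habitat" in terms:
        used.append("habitat")
    ok = grid[used].notna().all(axis=1) if used else pd.Series(True, index=grid.index)

    out = grid_covariates.copy()
    out["psi_hat"] = np.nan
    out["se_psi"] = np.nan
    out["eta"] = np.nan
    out["se_eta"] = np.nan
    if ok.any():
        names, x = build_design(grid.loc[ok], terms, "psi", check=False)
        coef, vcov = _coef_block(model, names)
        eta = x @ coef
        var_eta = np.einsum("ij,jk,ik->i", x, vcov, x)
        se_eta = np.sqrt(np.clip(var_eta, 0.0, None))
        psi = expit(eta)
        out.loc[ok, "eta"] = eta
        out.loc[ok, "se_eta"] = se_eta
        out.loc[ok, "psi_hat"] = psi
        out.loc[ok, "se_psi"] = psi * (1.0 - psi) * se_eta
    return out


def response_curve(
    model: OccupancyFit | AveragedModel,
    covariate: str,
    values: np.ndarray,
    others_at: dict[str, float] | None = None,
    side: str = "psi",
    observed_span: tuple[float, float] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted psi or p along one covariate with a Wald CI.

    ``values`` are on the original covariate scale (standardized with
    the stored transform when available); other covariates sit at the
    given reference values (default: their means, i.e. z-score 0).
    Requesting values outside ``observed_span`` flags extrapolation
    with a warning.
    """
    import warnings

    from scipy.stats import norm

    if side not in ("psi", "p"):
        raise ValueError("side must be 'psi' or 'p'")
    terms = model.psi_terms if side == "psi" else model.p_terms
    if covariate not in terms:
        raise ValueError(f"{covariate!r} is not a {side} covariate of this model")
    if observed_span is not None:
        lo, hi = observed_span
        if np.min(values) < lo or np.max(values) > hi:
            warnings.warn(f"response curve extrapolates beyond the observed "
                          f"span of {covariate!r}")

    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame({covariate: values})
    for t in terms:
        if t == covariate:
            continue
        frame[t] = (others_at or {}).get(t, 0.0)
    std = model.standardization
    if std is not None:
        key = covariate if covariate in std.means else f"{covariate}_m"
        if key in std.means:
            frame[covariate] = (values - std.means[key]) / std.sds[key]

    names, x = build_design(frame, tuple(terms), side, check=False)
    coef, vcov = _coef_block(model, names)
    eta = x @ coef
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", x, vcov, x), 0.0, None))
    zq = norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame({
        covariate: values,
        "estimate": expit(eta),
        "lower": expit(eta - zq * se),
        "upper": expit(eta + zq * se),
    })


def write_ascii_grid(grid: pd.DataFrame, path, value: str = "psi_hat",
                     cellsize: float = 100.0, nodata: float = -9999.0) -> None:
    """Write one grid column as an ESRI ASCII raster (.asc)."""
    xs = np.sort(grid["cell_x"].unique())
    ys = np.sort(grid["cell_y"].unique())
    pivot = grid.pivot_table(index="cell_y", columns="cell_x", values=value)
    pivot = pivot.reindex(index=ys[::-1], columns=xs)  # top row = max y
    arr = pivot.to_numpy()
    with open(path, "w") as fh:
        fh.write(f"ncols {len(xs)}\n")
        fh.write(f"nrows {len(ys)}\n")
        fh.write(f"xllcorner {xs.min() - cellsize / 2:.3f}\n")
        fh.write(f"yllcorner {ys.min() - cellsize / 2:.3f}\n")
        fh.write(f"cellsize {cellsize:g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in arr:
            vals = [f"{nodata:g}" if np.isnan(v) else f"{v:.6f}" for v in row]
            fh.write(" ".join(vals) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII raster back as (array, header)."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.array(rows)
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr[arr == nodata] = np.nan
    return arr, header


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
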