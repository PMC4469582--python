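"""Cell-level climate values, diagnostics and decorrelated PCA predictors.

Bioclimatic indices on a common raster grid are strongly multicollinear, so
before they enter a regression they are decorrelated by principal component
analysis on the standardized per-cell values; *all* components are retained
so that no climatic information is discarded — the PCA is a rotation, not a
reduction.  This module also provides per-cell extraction, resampling of a
finer raster (altitude) onto the climate grid, a pairwise-correlation
report, and spatial-gradient correlations (longitude, latitude, altitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator
from sklearn.decomposition import PCA

from .grid import ClimateStack, GridGeometry

__all__ = ["extract_cell_values", "resample_to_grid", "collinearity_report",
           "gradient_correlations", "pca_scores", "PCAResult"]


def extract_cell_values(stack: ClimateStack, cell_ids) -> pd.DataFrame:
    """Long table of (cell_id, layer, value) for the requested cells.

    NaN cells are returned with ``missing=True`` so callers can drop them
    listwise.
    """
    cell_ids = np.asarray(cell_ids, int)
    frames = []
    for name in stack.layer_names:
        vals = stack.values_at_cells(name, cell_ids)
        frames.append(pd.DataFrame({"cell_id": cell_ids, "layer": name,
                                    "value": vals, "missing": np.isnan(vals)}))
    return pd.concat(frames, ignore_index=True)


def cell_value_matrix(stack: ClimateStack, cell_ids, dropna: bool = True):
    """Cells-by-layers value matrix; optionally drops cells with any NaN.

    Returns (kept_cell_ids, matrix, layer_names).
    """
    cell_ids = np.asarray(cell_ids, int)
    mat = np.column_stack([stack.values_at_cells(name, cell_ids)
                           for name in stack.layer_names])
    if dropna:
        keep = ~np.isnan(mat).any(axis=1)
        return cell_ids[keep], mat[keep], stack.layer_names
    return cell_ids, mat, stack.layer_names


def resample_to_grid(fine: np.ndarray, fine_geometry: GridGeometry,
                     target: GridGeometry, method: str = "mean") -> np.ndarray:
    """Resample a finer raster onto the target grid.

    ``mean`` averages all fine cells whose centres fall inside each coarse
    cell (NaN-aware); ``bilinear`` interpolates fine cell-centre values at
    the coarse cell centres.
    """
    fine = np.asarray(fine, float)
    if fine.shape != (fine_geometry.n_y, fine_geometry.n_x):
        raise ValueError("fine array shape does not match its geometry")
    if (fine_geometry.east <= target.origin_lon or
            target.east <= fine_geometry.origin_lon or
            fine_geometry.north <= target.origin_lat or
            target.north <= fine_geometry.origin_lat):
        raise ValueError("fine raster extent is disjoint from target extent")

    flon, flat = fine_geometry.center_arrays()
    if method == "mean":
        inside = target.contains(flon, flat)
        if not inside.any():
            raise ValueError("no fine cell centres fall inside the target extent")
        cid = np.full(flon.shape, -1, dtype=int)
        cid[inside] = target.cell_id(flon[inside], flat[inside])
        out = np.full((target.n_y, target.n_x), np.nan)
        flat_vals = fine.ravel()
        flat_cid = cid.ravel()
        ok = (flat_cid >= 0) & ~np.isnan(flat_vals)
        sums = np.bincount(flat_cid[ok], weights=flat_vals[ok],
                           minlength=target.n_cells)
        counts = np.bincount(flat_cid[ok], minlength=target.n_cells)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return means.reshape(target.n_y, target.n_x)
    if method == "bilinear":
        lat_axis = fine_geometry.origin_lat + (np.arange(fine_geometry.n_y) + 0.5) \
            * fine_geometry.cell_size_deg
        lon_axis = fine_geometry.origin_lon + (np.arange(fine_geometry.n_x) + 0.5) \
            * fine_geometry.cell_size_deg
        interp = RegularGridInterpolator((lat_axis, lon_axis), fine,
                                         bounds_error=False, fill_value=np.nan)
        tlon, tlat = target.center_arrays()
        pts = np.column_stack([tlat.ravel(), tlon.ravel()])
        return interp(pts).reshape(target.n_y, target.n_x)
    raise ValueError(f"unknown resampling method {method!r}")


def _check_variance(mat: np.ndarray, names) -> None:
    sd = np.nanstd(mat, axis=0)
    bad = [n for n, s in zip(names, sd) if s == 0.0 or np.isnan(s)]
    if bad:
        raise ValueError(f"zero-variance layers: {bad}")


def collinearity_report(stack: ClimateStack, cell_ids) -> pd.DataFrame:
    """All pairwise Pearson correlations between layers over the cells.

    Returns a long symmetric table (layer_a, layer_b, r, p_value) including
    the unit diagonal.
    """
    kept, mat, names = cell_value_matrix(stack, cell_ids)
    if len(kept) < 3:
        raise ValueError("need at least 3 cells with complete data")
    _check_variance(mat, names)
    rows = []
    for a, name_a in enumerate(names):
        for b, name_b in enumerate(names):
            if a == b:
                r, p = 1.0, 0.0
            elif a < b:
                r, p = stats.pearsonr(mat[:, a], mat[:, b])
            else:
                prev = rows[b * len(names) + a]
                r, p = prev["r"], prev["p_value"]
            rows.append({"layer_a": name_a, "layer_b": name_b,
                         "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)


def gradient_correlations(stack: ClimateStack, cell_ids,
                          altitude=None) -> pd.DataFrame:
    """Pearson r of each layer against cell-centre lon, lat and altitude.

    ``altitude`` may be given per cell; otherwise the stack's altitude band
    is used if present.  A zero-variance coordinate (single row or column of
    cells) yields r = 0 for that axis.
    """
    kept, mat, names = cell_value_matrix(stack, cell_ids)
    if len(kept) < 3:
        raise ValueError("need at least 3 cells with complete data")
    _check_variance(mat, names)
    lon, lat = stack.geometry.cell_center(kept)
    if altitude is None and stack.altitude is not None:
        altitude = stack.values_at_cells("altitude", kept)
    elif altitude is not None:
        altitude = np.asarray(altitude, float)
        if altitude.shape != (len(np.asarray(cell_ids)),):
            raise ValueError("altitude must align with cell_ids")
        keep_mask = np.isin(np.asarray(cell_ids, int), kept)
        altitude = altitude[keep_mask]

    def _r(x, y):
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            return 0.0
        return float(stats.pearsonr(x, y)[0])

    rows = []
    for idx, name in enumerate(names):
        v = mat[:, idx]
        rows.append({
            "layer": name,
            "r_lon": _r(lon, v),
            "r_lat": _r(lat, v),
            "r_alt": _r(altitude, v) if altitude is not None else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class PCAResult:
    """Full-rank PCA of standardized layer values across cells."""

    cell_ids: np.ndarray          # cells retained (complete data)
    scores: np.ndarray            # cells x components
    loadings: np.ndarray          # layers x components
    explained_variance_fractions: np.ndarray
    layer_names: list[str]
    mean: np.ndarray              # per-layer mean used for standardization
    scale: np.ndarray             # per-layer sd (ddof=1)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"pc{k + 1:02d}": self.scores[:, k]
                for k in range(self.n_components)}
        return pd.DataFrame({"cell_id": self.cell_ids, **cols})


def pca_scores(stack: ClimateStack, cell_ids) -> PCAResult:
    """Correlation-matrix PCA of the stack over the given cells.

    Layers are standardized to zero mean and unit variance (ddof=1), so the
    PCA acts on the correlation matrix and is unit-free.  All components are
    retained; loading signs are fixed by making each component's
    largest-magnitude loading positive.  Cells with missing data in any
    layer are dropped listwise.
    """
    kept, mat, names = cell_value_matrix(stack, cell_ids)
    if len(kept) < 2:
        raise ValueError("need at least 2 cells with complete data")
    _check_variance(mat, names)
    mean = mat.mean(axis=0)
    scale = mat.std(axis=0, ddof=1)
    zmat = (mat - mean) / scale
    pca = PCA(n_components=min(zmat.shape), svd_solver="full")
    scores = pca.fit_transform(zmat)
    loadings = pca.components_.T  # layers x components
    # deterministic sign: dominant loading of each component positive
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    frac = pca.explained_variance_ratio_
    return PCAResult(cell_ids=kept, scores=scores, loadings=loadings,
                     explained_variance_fractions=frac, layer_names=list(names),
                     mean=mean, scale=scale)
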