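"""Downstream analyses of trained encoders.

Four families of analysis are provided:

* **Image properties** — brightness (mean intensity), RMS contrast
  (population standard deviation), and complexity as mean spatial
  information, the pixelwise magnitude of the two 3x3 Sobel responses.
* **Spatial grids** — per-neuron prediction vectors interpolated onto a
  regular (25, 25, 10) grid over normalized cortical coordinates
  (piecewise-linear simplex interpolation; cells outside the convex hull of
  the recorded neurons are missing), plus distance-vs-similarity curves and
  reference-cell correlation heatmaps within or across brains.
* **Retinotopic maps** — per-neuron receptive-field centers read off the
  position networks of an ensemble and averaged over members.
* **Artificial receptive fields (aRFs)** — prediction-weighted averages of
  white-noise stimuli (the spike-triggered-average analogue for a model
  neuron), with rotated 2-D Gaussian fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator
from scipy.optimize import least_squares

from .encoder import ModelParams
from .objects import fallback_box


# ---------------------------------------------------------------------------
# Image properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageProperties:
    brightness: float   # mean pixel intensity
    contrast: float     # population standard deviation of intensities
    complexity: float   # mean spatial information (edge-magnitude units)


def image_properties(image: np.ndarray) -> ImageProperties:
    """Brightness, contrast and mean spatial information of one grayscale
    image. Sobel filtering uses the standard 3x3 kernels with reflect
    padding; SI = sqrt(s_v^2 + s_h^2) pixelwise."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    s_v = ndimage.sobel(image, axis=1, mode="reflect")  # vertical edges: d/dx
    s_h = ndimage.sobel(image, axis=0, mode="reflect")  # horizontal edges: d/dy
    si = np.sqrt(s_v**2 + s_h**2)
    return ImageProperties(
        brightness=float(image.mean()),
        contrast=float(image.std()),
        complexity=float(si.mean()),
    )


# ---------------------------------------------------------------------------
# Spatial grids
# ---------------------------------------------------------------------------

@dataclass
class SpatialGrid:
    """Per-cell interpolated value vectors on a regular cortical grid.

    ``values`` is (nx, ny, nz, K); cells outside the data hull hold NaN.
    ``x`` and ``y`` are evenly spaced in [-1, 1]; ``z`` spans the given or
    observed coordinate range.
    """

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def missing_mask(self) -> np.ndarray:
        """(nx, ny, nz) boolean: True where a cell has any missing value."""
        return np.isnan(self.values).any(axis=-1)

    def cell_coordinates(self) -> np.ndarray:
        """(n_cells, 3) coordinates in C order (x fastest-varying last)."""
        gx, gy, gz = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def grid_neurons(
    coords_norm: np.ndarray,
    values: np.ndarray,
    shape: tuple[int, int, int] = (25, 25, 10),
    z_range: tuple[float, float] | None = None,
) -> SpatialGrid:
    """Interpolate per-neuron value vectors onto a regular grid.

    ``coords_norm`` is (n, 3) normalized coordinates, ``values`` (n, K) —
    typically one column per probe image. X and Y grid lines are ``shape[0]``
    / ``shape[1]`` points evenly spaced in [-1, 1]; Z spans ``z_range`` (pass
    the joint range over subjects when gridding several brains) or the data's
    own z extent. Linear simplex interpolation; cells outside the convex hull
    are NaN.
    """
    coords_norm = np.asarray(coords_norm, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    if coords_norm.ndim != 2 or coords_norm.shape[1] != 3:
        raise ValueError("coords_norm must be (n, 3)")
    if len(values) != len(coords_norm):
        raise ValueError("one value row per neuron required")
    if len(coords_norm) < 4:
        raise ValueError("3-D interpolation needs at least 4 points")
    nx, ny, nz = shape
    x = np.linspace(-1.0, 1.0, nx)
    y = np.linspace(-1.0, 1.0, ny)
    zlo, zhi = z_range if z_range is not None else (coords_norm[:, 2].min(), coords_norm[:, 2].max())
    z = np.linspace(zlo, zhi, nz)
    try:
        interp = LinearNDInterpolator(coords_norm, values)
    except Exception as exc:  # QhullError on degenerate geometry
        raise ValueError(f"degenerate neuron geometry: {exc}") from exc
    gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    vals = interp(pts).reshape(nx, ny, nz, values.shape[1])
    return SpatialGrid(values=vals, x=x, y=y, z=z)


def _cell_correlation_matrix(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Row-wise Pearson correlations between (n, K) arrays; rows with zero
    variance give NaN."""
    def _std(v):
        c = v - v.mean(axis=1, keepdims=True)
        s = np.sqrt((c**2).sum(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = c / s
        out[np.squeeze(s == 0, axis=1)] = np.nan
        return out

    an = _std(a)
    bn = an if b is None else _std(b)
    return an @ bn.T


def distance_similarity_curve(
    grid: SpatialGrid,
    grid2: SpatialGrid | None = None,
) -> list[tuple[int, float]]:
    """Mean cell-to-cell correlation as a function of rank distance.

    Non-missing cells (shared between the two grids in the across-brain
    case) are sorted by Euclidean distance to the bottom-left-most remaining
    cell; the k-th off-diagonal of their correlation matrix (within one
    grid, or between matched cells of two grids) is averaged with
    missing-aware means. Returns ``[(k, mean corr), ...]``.
    """
    keep = ~grid.missing_mask().ravel()
    if grid2 is not None:
        if grid2.shape != grid.shape:
            raise ValueError("grids must share a shape")
        keep &= ~grid2.missing_mask().ravel()
    if keep.sum() < 2:
        raise ValueError("need at least two non-missing cells")
    coords = grid.cell_coordinates()[keep]
    a = grid.values.reshape(-1, grid.values.shape[-1])[keep]
    b = None if grid2 is None else grid2.values.reshape(-1, grid2.values.shape[-1])[keep]
    # squared distance keeps exact ties exact; stable sort fixes tie order
    order = np.argsort(((coords - coords[0]) ** 2).sum(axis=1), kind="stable")
    a = a[order]
    b = b if b is None else b[order]
    C = _cell_correlation_matrix(a, b)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k in range(len(a)):
            diag = np.diagonal(C, offset=k)
            val = float(np.nanmean(diag)) if np.any(~np.isnan(diag)) else float("nan")
            out.append((k, val))
    return out


def binned_distance_similarity(
    grid: SpatialGrid,
    grid2: SpatialGrid | None = None,
    n_bins: int = 20,
) -> list[tuple[float, float]]:
    """Sensitivity variant of :func:`distance_similarity_curve`: all cell
    pairs grouped into ``n_bins`` equal-width bins of true Euclidean pair
    distance, returning ``[(bin center, mean correlation), ...]``. Unlike
    the rank-distance curve this does not depend on the sort order."""
    keep = ~grid.missing_mask().ravel()
    if grid2 is not None:
        if grid2.shape != grid.shape:
            raise ValueError("grids must share a shape")
        keep &= ~grid2.missing_mask().ravel()
    if keep.sum() < 2:
        raise ValueError("need at least two non-missing cells")
    coords = grid.cell_coordinates()[keep]
    a = grid.values.reshape(-1, grid.values.shape[-1])[keep]
    b = None if grid2 is None else grid2.values.reshape(-1, grid2.values.shape[-1])[keep]
    C = _cell_correlation_matrix(a, b)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(coords), k=1)
    d, c = dist[iu], C[iu]
    good = ~np.isnan(c)
    d, c = d[good], c[good]
    edges = np.linspace(0.0, d.max() + 1e-12, n_bins + 1)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (d >= lo) & (d < hi)
        if mask.any():
            out.append((float((lo + hi) / 2), float(c[mask].mean())))
    return out


def curve_distance_correlation(curve: list[tuple[int, float]]) -> float:
    """Pearson correlation between rank distance k and mean similarity."""
    k = np.array([c[0] for c in curve], dtype=float)
    v = np.array([c[1] for c in curve], dtype=float)
    good = ~np.isnan(v)
    k, v = k[good], v[good]
    return float(np.corrcoef(k, v)[0, 1])


_PLANES = {"XY": 2, "XZ": 1, "YZ": 0}


def reference_correlation_map(
    grid: SpatialGrid,
    reference_cell: tuple[int, int, int],
    plane: str = "XY",
    grid2: SpatialGrid | None = None,
) -> np.ndarray:
    """Correlations of every cell to a reference cell, projected onto a
    plane by a missing-aware mean along the orthogonal axis.

    Within one brain the reference vector comes from ``grid`` itself; for an
    across-brain pair pass the second brain as ``grid2`` and the reference
    cell indexes into it. Cells missing in either grid stay missing.
    """
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}")
    source = grid2 if grid2 is not None else grid
    ref = source.values[reference_cell]
    if np.isnan(ref).any():
        raise ValueError(f"reference cell {reference_cell} is missing")
    vals = grid.values.reshape(-1, grid.values.shape[-1])
    C = _cell_correlation_matrix(vals, ref[None, :]).reshape(grid.shape)
    if grid2 is not None:
        C[grid2.missing_mask()] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(C, axis=_PLANES[plane])


# ---------------------------------------------------------------------------
# Retinotopy
# ---------------------------------------------------------------------------

def retinotopic_map(models: list[ModelParams], subject_id: str):
    """Per-neuron anatomical coordinates against ensemble-averaged
    receptive-field centers -> DataFrame (neuron_id, coord_x, coord_y,
    mu_x, mu_y)."""
    import pandas as pd

    if not models:
        raise ValueError("need at least one model")
    for m in models:
        if subject_id not in m.readouts:
            raise KeyError(f"no readout for subject {subject_id!r}")
    mus = np.mean([m.readouts[subject_id].positions_mu() for m in models], axis=0)
    coords = models[0].readouts[subject_id].coords
    return pd.DataFrame(
        {
            "neuron_id": np.arange(len(coords)),
            "coord_x": coords[:, 0],
            "coord_y": coords[:, 1],
            "mu_x": mus[:, 0],
            "mu_y": mus[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# Artificial receptive fields
# ---------------------------------------------------------------------------

def estimate_arf(
    predict_fn,
    image_shape: tuple[int, int],
    n_images: int = 100_000,
    rng: np.random.Generator | None = None,
    batch_size: int = 500,
) -> np.ndarray:
    """Prediction-weighted average of white-noise stimuli -> (m, H, W).

    ``predict_fn`` maps a batch of noise images (B, H, W) in normalized
    intensity units to nonnegative per-neuron predictions (B, m); the aRF is
    ``sum_t p_t * x_t / sum_t p_t`` per neuron, the model analogue of a
    spike-triggered average.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = rng or np.random.default_rng(0)
    h, w = image_shape
    num = None
    den = None
    done = 0
    while done < n_images:
        b = min(batch_size, n_images - done)
        x = rng.standard_normal((b, h, w)).astype(np.float32)
        p = np.asarray(predict_fn(x), dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != b:
            raise ValueError("predict_fn must return (batch, m) predictions")
        if num is None:
            num = np.zeros((p.shape[1], h, w))
            den = np.zeros(p.shape[1])
        num += np.einsum("bm,bhw->mhw", p, x.astype(np.float64), optimize=True)
        den += p.sum(axis=0)
        done += b
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den[:, None, None]


def model_noise_predict_fn(models: list[ModelParams], subject_id: str, batch_size: int = 128):
    """predict_fn for :func:`estimate_arf` driving an ensemble with pure
    noise stimuli: the noise is already in normalized units and carries no
    objects, so the object channels take the whole-image fallback box."""
    from .stimulus import build_inputs
    from .training import ensemble_predict

    box = fallback_box()

    def fn(noise: np.ndarray) -> np.ndarray:
        inputs = build_inputs(noise, 0.0, 1.0, [box] * len(noise))
        return ensemble_predict(models, inputs, subject_id, batch_size=batch_size).values

    return fn


# ---------------------------------------------------------------------------
# 2-D Gaussian fits
# ---------------------------------------------------------------------------

@dataclass
class GaussianFit:
    amplitude: float
    center_x: float
    center_y: float
    sigma_x: float
    sigma_y: float
    theta: float     # orientation, radians
    offset: float
    residual: float  # RMS of the fit residual
    success: bool


def _gauss2d(params, xs, ys):
    amp, cx, cy, sx, sy, th, off = params
    xr = (xs - cx) * np.cos(th) + (ys - cy) * np.sin(th)
    yr = -(xs - cx) * np.sin(th) + (ys - cy) * np.cos(th)
    return amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2)) + off


def fit_gaussian_2d(arf_map: np.ndarray) -> GaussianFit:
    """Least-squares rotated 2-D Gaussian fit of a receptive-field map.

    Initialization comes from the intensity moments of the mean-subtracted
    map (dominant-polarity side); the center is constrained to the image.
    Non-convergence is reported via ``success=False``, never an exception.
    """
    arf_map = np.asarray(arf_map, dtype=np.float64)
    if arf_map.ndim != 2:
        raise ValueError("map must be 2-D")
    if not np.all(np.isfinite(arf_map)):
        raise ValueError("map must be finite")
    if arf_map.max() == arf_map.min():
        raise ValueError("map is constant; nothing to fit")
    h, w = arf_map.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    off0 = float(np.median(arf_map))
    dev = arf_map - off0
    # fit the dominant polarity (aRFs can be OFF-dominated, i.e. negative)
    sign = 1.0 if dev.max() >= -dev.min() else -1.0
    mass = np.clip(sign * dev, 0.0, None)
    total = mass.sum()
    cx0 = float((xs * mass).sum() / total)
    cy0 = float((ys * mass).sum() / total)
    sx0 = float(np.sqrt(((xs - cx0) ** 2 * mass).sum() / total)) or 1.0
    sy0 = float(np.sqrt(((ys - cy0) ** 2 * mass).sum() / total)) or 1.0
    amp0 = sign * float(np.abs(dev).max())
    p0 = [amp0, cx0, cy0, max(sx0, 0.5), max(sy0, 0.5), 0.0, off0]
    span = float(arf_map.max() - arf_map.min())
    lo = [-10 * span, 0.0, 0.0, 0.1, 0.1, -np.pi, arf_map.min() - span]
    hi = [10 * span, w - 1e-9, h - 1e-9, w, h, np.pi, arf_map.max() + span]
    p0 = np.clip(p0, lo, hi)
    try:
        res = least_squares(
            lambda p: (_gauss2d(p, xs, ys) - arf_map).ravel(),
            p0,
            bounds=(lo, hi),
            max_nfev=2000,
        )
        ok = bool(res.success)
        p = res.x
        rms = float(np.sqrt(np.mean(res.fun**2)))
    except Exception:
        ok, p, rms = False, np.asarray(p0), float("nan")
    return GaussianFit(
        amplitude=float(p[0]),
        center_x=float(p[1]),
        center_y=float(p[2]),
        sigma_x=float(p[3]),
        sigma_y=float(p[4]),
        theta=float(p[5]),
        offset=float(p[6]),
        residual=rms,
        success=ok,
    )
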