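"""Rotation-based SPECT forward / adjoint projection model.

This module implements the system model shared by the acquisition simulator
and the OS-EM reconstruction: a rotation-based projector with voxel-wise
attenuation along the detector normal and a distance-dependent Gaussian
collimator-detector response (CDR).

Conventions
-----------
* Volumes are ``(nx, ny, nz)`` arrays: ``x`` patient left-right, ``y``
  posterior→anterior, ``z`` axial.  Voxels are isotropic, 0-based indices.
* View angle 0 is anterior (detector on the +y side); angles increase
  counterclockwise when viewed from +z.
* The detector grid equals the in-plane volume grid: ``(n_u, n_v) = (nx, nz)``
  with bin size equal to the voxel size.
* Attenuation is accumulated voxel-by-voxel from the emission voxel to the
  detector with the half-voxel-offset convention (the emitting voxel
  contributes half its own mu·dx).

The in-plane rotation is a bilinear-interpolation gather, materialised as a
sparse matrix per view angle so that the adjoint (`back_project`) is the
exact matrix transpose of the forward operation — the property OS-EM needs.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

__all__ = [
    "LN2",
    "TC99M_HALF_LIFE_H",
    "decay_factor",
    "CollimatorResponse",
    "NO_BLUR",
    "AcquisitionGeometry",
    "ProjectionSet",
    "SystemModel",
    "forward_project",
    "back_project",
]

LN2 = float(np.log(2.0))

#: Physical half-life of Tc-99m used throughout (hours).
TC99M_HALF_LIFE_H = 6.0


def decay_factor(t_h, half_life_h: float = TC99M_HALF_LIFE_H):
    """Physical decay factor exp(-ln2 * t / T_phys).

    Parameters
    ----------
    t_h : float or array-like
        Time post injection in hours; must be non-negative.
    half_life_h : float
        Physical half-life in hours (default 6.0 h for Tc-99m).
    """
    if half_life_h <= 0:
        raise ValueError(f"half_life_h must be positive, got {half_life_h}")
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time post injection must be non-negative")
    out = np.exp(-LN2 * t / half_life_h)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CollimatorResponse:
    """Distance-dependent Gaussian collimator-detector response.

    sigma(d) = sqrt(sigma0^2 + (slope * d)^2), d = distance to detector (cm).
    Defaults are representative of a low-energy ultra-high-resolution
    parallel-hole collimator.
    """

    sigma0_cm: float = 0.2
    slope: float = 0.02

    def __post_init__(self):
        if self.sigma0_cm < 0 or self.slope < 0:
            raise ValueError("sigma0_cm and slope must be non-negative")

    def sigma_cm(self, distance_cm):
        d = np.maximum(np.asarray(distance_cm, dtype=float), 0.0)
        return np.sqrt(self.sigma0_cm**2 + (self.slope * d) ** 2)


#: A response with no blur at all (ideal pinpoint collimator).
NO_BLUR = CollimatorResponse(0.0, 0.0)


@dataclass
class AcquisitionGeometry:
    """SPECT orbit description.

    ``orbit_radius_cm`` may be a scalar (circular orbit) or a per-view array
    (body-contouring orbit).  Energy windows are stored in keV and must not
    overlap; they label the two count arrays carried by a
    :class:`ProjectionSet` ("photopeak": 140 keV +/- 7.5%, "scatter":
    108-129 keV).
    """

    n_views: int = 120
    arc_deg: float = 360.0
    orbit_radius_cm: float | np.ndarray = 15.0
    seconds_per_view: float = 8.0
    photopeak_window_kev: tuple[float, float] = (129.5, 150.5)
    scatter_window_kev: tuple[float, float] = (108.0, 129.0)

    def __post_init__(self):
        if self.n_views <= 0:
            raise ValueError("n_views must be positive")
        if self.seconds_per_view <= 0:
            raise ValueError("seconds_per_view must be positive")
        lo1, hi1 = self.photopeak_window_kev
        lo2, hi2 = self.scatter_window_kev
        if not (hi2 <= lo1 or hi1 <= lo2):
            raise ValueError("photopeak and scatter energy windows overlap")
        radii = np.broadcast_to(
            np.asarray(self.orbit_radius_cm, dtype=float), (self.n_views,)
        )
        if np.any(radii <= 0):
            raise ValueError("orbit radii must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * (self.arc_deg / self.n_views)

    @property
    def orbit_radii_cm(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.orbit_radius_cm, dtype=float), (self.n_views,)
        ).copy()


@dataclass
class ProjectionSet:
    """Per-view, per-energy-window count images.

    ``counts[window]`` has shape ``(n_views, n_u, n_v)``.  For simulated data
    ``scatter_expectation`` carries the noise-free expectation of the scatter
    component inside the photopeak window (the "matched" scatter estimate a
    reconstruction may use for compensation).
    """

    counts: dict[str, np.ndarray]
    geometry: AcquisitionGeometry
    voxel_size_cm: float
    time_post_injection_h: float = 0.0
    scatter_expectation: np.ndarray | None = None

    def __post_init__(self):
        for name, arr in self.counts.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3 or arr.shape[0] != self.geometry.n_views:
                raise ValueError(
                    f"window {name!r}: expected (n_views, n_u, n_v) with "
                    f"n_views={self.geometry.n_views}, got {arr.shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"window {name!r}: counts must be non-negative")
            self.counts[name] = arr


@functools.lru_cache(maxsize=720)
def _rotation_operator(nx: int, ny: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse bilinear gather rotating in-plane content into the detector
    frame of a view at ``angle_deg`` (detector on the +y side)."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xo, yo = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx, dy = xo - cx, yo - cy
    # source coordinates: rotate the output grid back into the world frame
    xs = cx + c * dx - s * dy
    ys = cy + s * dx + c * dy

    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    fx, fy = xs - x0, ys - y0

    rows_out = (xo * ny + yo).ravel()
    data, rows, cols = [], [], []
    for ddx, ddy, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xi, yi = x0 + ddx, y0 + ddy
        valid = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
        wv = np.where(valid, w, 0.0).ravel()
        keep = wv > 0
        rows.append(rows_out[keep])
        cols.append((np.clip(xi, 0, nx - 1) * ny + np.clip(yi, 0, ny - 1)).ravel()[keep])
        data.append(wv[keep])
    mat = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny),
    )
    return mat.tocsr()


class SystemModel:
    """Linear SPECT system operator for a fixed attenuation map and geometry.

    Caches the per-view rotated attenuation factors so repeated forward /
    adjoint applications (OS-EM) stay cheap.  ``mu_grid=None`` disables
    attenuation; ``response=NO_BLUR`` (or ``None``) disables the CDR.
    """

    def __init__(
        self,
        mu_grid: np.ndarray | None,
        geometry: AcquisitionGeometry,
        response: CollimatorResponse | None,
        voxel_size_cm: float,
        grid_shape: tuple[int, int, int] | None = None,
    ):
        if mu_grid is None and grid_shape is None:
            raise ValueError("grid_shape is required when mu_grid is None")
        self.mu_grid = None if mu_grid is None else np.asarray(mu_grid, dtype=float)
        self.shape = tuple(grid_shape) if mu_grid is None else self.mu_grid.shape
        if len(self.shape) != 3:
            raise ValueError("volume must be 3-D (nx, ny, nz)")
        self.geometry = geometry
        self.response = response or NO_BLUR
        self.voxel = float(voxel_size_cm)
        self._att_cache: dict[int, np.ndarray] = {}
        nx, ny, nz = self.shape
        # y coordinate of each in-plane row relative to the volume centre (cm)
        self._y_cm = (np.arange(ny) - (ny - 1) / 2.0) * self.voxel

    def _rot(self, view: int) -> sparse.csr_matrix:
        nx, ny, _ = self.shape
        return _rotation_operator(nx, ny, float(self.geometry.angles_deg[view]))

    def _rotate(self, vol: np.ndarray, view: int, adjoint: bool = False) -> np.ndarray:
        nx, ny, nz = self.shape
        R = self._rot(view)
        flat = vol.reshape(nx * ny, nz)
        out = (R.T @ flat) if adjoint else (R @ flat)
        return out.reshape(nx, ny, nz)

    def _attenuation(self, view: int) -> np.ndarray | None:
        """exp(-integral mu dl) from each voxel centre to the detector, in the
        rotated frame of ``view`` (detector at +y)."""
        if self.mu_grid is None:
            return None
        att = self._att_cache.get(view)
        if att is None:
            rot_mu = self._rotate(self.mu_grid, view)
            # tail[:, j, :] = sum over j' >= j of mu  (path toward +y)
            tail = np.cumsum(rot_mu[:, ::-1, :], axis=1)[:, ::-1, :]
            att = np.exp(-self.voxel * (tail - 0.5 * rot_mu))
            self._att_cache[view] = att
        return att

    def _sigma_vox(self, view: int) -> np.ndarray:
        dist = self.geometry.orbit_radii_cm[view] - self._y_cm
        return self.response.sigma_cm(dist) / self.voxel

    def forward(self, activity: np.ndarray, views=None) -> np.ndarray:
        """Project ``activity`` (MBq per voxel) into MBq-weighted ray sums.

        Returns an array ``(len(views), nx, nz)``.
        """
        activity = np.asarray(activity, dtype=float)
        if activity.shape != self.shape:
            raise ValueError(
                f"activity shape {activity.shape} != system grid {self.shape}"
            )
        views = range(self.geometry.n_views) if views is None else views
        views = list(views)
        nx, ny, nz = self.shape
        out = np.zeros((len(views), nx, nz))
        for k, v in enumerate(views):
            w = self._rotate(activity, v)
            att = self._attenuation(v)
            if att is not None:
                w = w * att
            sig = self._sigma_vox(v)
            proj = np.zeros((nx, nz))
            for j in range(ny):
                plane = w[:, j, :]
                if sig[j] > 1e-8:
                    plane = gaussian_filter(
                        plane, sigma=sig[j], mode="constant", truncate=4.0
                    )
                proj += plane
            out[k] = proj
        return out

    def adjoint(self, projections: np.ndarray, views=None) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        views = range(self.geometry.n_views) if views is None else views
        views = list(views)
        projections = np.asarray(projections, dtype=float)
        nx, ny, nz = self.shape
        if projections.shape != (len(views), nx, nz):
            raise ValueError(
                f"projections shape {projections.shape} != ({len(views)}, {nx}, {nz})"
            )
        vol = np.zeros(self.shape)
        for k, v in enumerate(views):
            p = projections[k]
            sig = self._sigma_vox(v)
            g = np.empty(self.shape)
            for j in range(ny):
                if sig[j] > 1e-8:
                    g[:, j, :] = gaussian_filter(
                        p, sigma=sig[j], mode="constant", truncate=4.0
                    )
                else:
                    g[:, j, :] = p
            att = self._attenuation(v)
            if att is not None:
                g *= att
            vol += self._rotate(g, v, adjoint=True)
        return vol


def forward_project(
    activity_grid: np.ndarray,
    mu_grid: np.ndarray | None,
    geometry: AcquisitionGeometry,
    response: CollimatorResponse | None = None,
    voxel_size_cm: float = 1.0,
    views=None,
) -> np.ndarray:
    """One-shot forward projection (see :class:`SystemModel`)."""
    if mu_grid is not None and np.shape(mu_grid) != np.shape(activity_grid):
        raise ValueError("activity_grid and mu_grid shapes differ")
    sm = SystemModel(
        mu_grid, geometry, response, voxel_size_cm, grid_shape=np.shape(activity_grid)
    )
    return sm.forward(activity_grid, views=views)


def back_project(
    projections: np.ndarray,
    mu_grid: np.ndarray | None,
    geometry: AcquisitionGeometry,
    response: CollimatorResponse | None = None,
    voxel_size_cm: float = 1.0,
    grid_shape: tuple[int, int, int] | None = None,
    views=None,
) -> np.ndarray:
    """One-shot adjoint projection (see :class:`SystemModel`)."""
    if grid_shape is None:
        if mu_grid is None:
            raise ValueError("grid_shape required when mu_grid is None")
        grid_shape = np.shape(mu_grid)
    sm = SystemModel(mu_grid, geometry, response, voxel_size_cm, grid_shape=grid_shape)
    return sm.adjoint(projections, views=views)
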