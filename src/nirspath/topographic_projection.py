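"""Scalp-field mapping into a normalized 2-D polar head space.

Scalar fields indexed by scalp position (layer thicknesses, DPF, PPF,
sensitivity) are compared across subjects in a standardized disk:

1. heads are registered to a template by similarity alignment of the
   nasion and preauricular fiducials (optionally refined by iterative
   closest point on scalp surface samples);
2. values are read along the inward surface normal at each scalp position
   (:func:`surface_layer_maps` for the anatomical thicknesses);
3. positions are mapped through a far-side vertical-perspective azimuthal
   projection about the vertex axis (the classical twilight construction:
   viewpoint on the vertex axis ``P`` head radii beyond the antipode,
   injective out to a 108 deg polar angle) using ellipsoid-normalized
   coordinates, so two heads differing only by scale project identically;
4. scattered values are linearly interpolated onto an equidistant polar
   grid and medians are taken cellwise across subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError, GeometryError
from .synthetic_head import (AIR, BRAIN, CSF, SCALP, SKULL, HeadModel,
                             OptodeSet, scalp_radius_from_circumference,
                             _ASPECT)

__all__ = [
    "PolarMap",
    "SimilarityTransform",
    "register_to_template",
    "surface_layer_maps",
    "azimuthal_project",
    "azimuthal_unproject",
    "interpolate_polar",
    "group_median",
    "template_fiducials",
    "PROJECTION_VIEW_DISTANCE",
    "PROJECTION_MAX_POLAR_DEG",
]

PROJECTION_VIEW_DISTANCE = 1.4  # head radii beyond the antipode
PROJECTION_MAX_POLAR_DEG = 108.0


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * R @ x + t"""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    residual_mm: float

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(pts) @ self.rotation.T) + self.translation


def _umeyama(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping src points onto dst."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    cov = xd.T @ xs / len(src)
    U, S, Vt = np.linalg.svd(cov)
    sgn = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        sgn[2, 2] = -1.0
    R = U @ sgn @ Vt
    var_s = (xs**2).sum() / len(src)
    if var_s == 0:
        raise GeometryError("degenerate fiducials: zero spread")
    scale = float((S * np.diag(sgn)).sum() / var_s)
    t = mu_d - scale * R @ mu_s
    res = float(np.sqrt(((scale * src @ R.T + t - dst) ** 2).sum(axis=1).mean()))
    return SimilarityTransform(rotation=R, scale=scale, translation=t,
                               residual_mm=res)


def template_fiducials(circumference_cm: float = 38.8) -> dict[str, np.ndarray]:
    """Fiducials of the package's template head (default-size ellipsoid)."""
    axes = scalp_radius_from_circumference(circumference_cm) * _ASPECT
    return {
        "nasion": np.array([0.0, axes[1], 0.0]),
        "inion": np.array([0.0, -axes[1], 0.0]),
        "left_preauricular": np.array([-axes[0], 0.0, 0.0]),
        "right_preauricular": np.array([axes[0], 0.0, 0.0]),
    }


def register_to_template(
    head: HeadModel,
    template: dict[str, np.ndarray] | None = None,
    icp_refine: bool = False,
    icp_iterations: int = 10,
    icp_samples: int = 1500,
) -> SimilarityTransform:
    """Similarity registration of a head to the template fiducial frame.

    Aligns nasion and both preauricular points by least squares; with
    ``icp_refine`` the transform is polished by iterative closest point
    between scalp-surface voxel samples and the template ellipsoid surface.
    """
    if template is None:
        template = template_fiducials()
    keys = ("nasion", "left_preauricular", "right_preauricular")
    for k in keys:
        if k not in head.fiducials:
            raise GeometryError(f"missing fiducial {k!r}")
    src = np.array([head.fiducials[k] for k in keys])
    dst = np.array([template[k] for k in keys])
    if np.linalg.matrix_rank(src - src.mean(0), tol=1e-6) < 2:
        raise GeometryError("degenerate fiducials: coincident or collinear")
    tf = _umeyama(src, dst)
    if not icp_refine:
        return tf

    # scalp surface samples: scalp voxels with an air neighbour
    lab = head.labels
    surf = (lab == SCALP) & (
        (np.roll(lab, 1, 0) == AIR) | (np.roll(lab, -1, 0) == AIR)
        | (np.roll(lab, 1, 1) == AIR) | (np.roll(lab, -1, 1) == AIR)
        | (np.roll(lab, 1, 2) == AIR) | (np.roll(lab, -1, 2) == AIR))
    idx = np.argwhere(surf)
    if len(idx) > icp_samples:
        sel = np.linspace(0, len(idx) - 1, icp_samples).astype(int)
        idx = idx[sel]
    pts = head.index_to_world(idx)
    t_axes = scalp_radius_from_circumference(38.8) * _ASPECT
    t_center = 0.5 * (template["left_preauricular"] + template["right_preauricular"])
    for _ in range(icp_iterations):
        moved = tf.apply(pts)
        q = (moved - t_center) / t_axes
        nq = np.linalg.norm(q, axis=1, keepdims=True)
        nq[nq == 0] = 1.0
        closest = q / nq * t_axes + t_center  # radial projection onto template
        tf = _umeyama(pts, closest)
    return tf


# ---------------------------------------------------------------------------
# Surface-normal layer maps
# ---------------------------------------------------------------------------

def surface_layer_maps(
    head: HeadModel,
    optodes: OptodeSet,
    max_depth_mm: float = 50.0,
    step_fraction: float = 0.25,
) -> dict[str, np.ndarray]:
    """Layer thicknesses along the inward normal at every scalp position.

    Returns arrays aligned with ``optodes.labels``: ``skull_thickness``,
    ``csf_thickness``, ``cortical_depth`` (scalp surface to brain) and
    ``scalp_thickness``, in mm.  Positions whose ray leaves the volume
    before reaching brain are flagged NaN.
    """
    vs = head.voxel_size_mm
    step = step_fraction * vs
    n_steps = int(max_depth_mm / step)
    labels = head.labels
    shape = np.array(labels.shape)
    out = {k: np.full(len(optodes), np.nan) for k in
           ("scalp_thickness", "skull_thickness", "csf_thickness", "cortical_depth")}

    for i in range(len(optodes)):
        p0 = optodes.positions_mm[i]
        d = -optodes.normals[i]
        # start from just outside the surface to catch the first scalp voxel
        start = p0 - d * vs
        first = {SCALP: np.nan, SKULL: np.nan, CSF: np.nan, BRAIN: np.nan}
        ok = True
        for s in range(n_steps):
            p = start + d * (s * step)
            idx = np.floor((p - head.origin_mm) / vs + 0.5).astype(int)
            if np.any(idx < 0) or np.any(idx >= shape):
                ok = s * step < 2 * vs  # allow the initial outside nudge
                if not ok:
                    break
                continue
            lbl = labels[tuple(idx)]
            if lbl != AIR and np.isnan(first.get(lbl, 0.0)):
                first[lbl] = s * step
            if lbl == BRAIN:
                break
        if np.isnan(first[SCALP]) or np.isnan(first[BRAIN]):
            continue
        entry = first[SCALP]
        t_skull = (first[CSF] - first[SKULL]) if not (
            np.isnan(first[SKULL]) or np.isnan(first[CSF])) else np.nan
        t_csf = (first[BRAIN] - first[CSF]) if not np.isnan(first[CSF]) else np.nan
        out["scalp_thickness"][i] = (first[SKULL] - entry
                                     if not np.isnan(first[SKULL]) else np.nan)
        out["skull_thickness"][i] = t_skull
        out["csf_thickness"][i] = t_csf
        out["cortical_depth"][i] = first[BRAIN] - entry
    return out


# ---------------------------------------------------------------------------
# Azimuthal projection (far-side vertical perspective)
# ---------------------------------------------------------------------------

def _r_of_theta(theta: np.ndarray, k: float) -> np.ndarray:
    return np.sin(theta) * (1.0 + k) / (np.cos(theta) + k)


_K = PROJECTION_VIEW_DISTANCE
_THETA_MAX = math.radians(PROJECTION_MAX_POLAR_DEG)
_R_MAX = float(_r_of_theta(np.array([_THETA_MAX]), _K)[0])


def azimuthal_project(
    point_mm: np.ndarray,
    head_center: np.ndarray,
    head_radius: float | np.ndarray,
    view_distance: float = PROJECTION_VIEW_DISTANCE,
) -> tuple[np.ndarray, np.ndarray]:
    """Project scalp points about the vertex axis into the unit disk.

    ``head_radius`` may be a scalar or the ellipsoid semi-axes; coordinates
    are normalized by it, making the projection invariant to head size.
    Returns (uv array, in_domain mask); points beyond the 108 deg horizon
    get NaN coordinates and a False flag.
    """
    p = np.atleast_2d(np.asarray(point_mm, dtype=float))
    q = (p - np.asarray(head_center)) / np.asarray(head_radius)
    nq = np.linalg.norm(q, axis=1, keepdims=True)
    if np.any(nq == 0):
        raise DomainError("cannot project the head center")
    q = q / nq
    theta = np.arccos(np.clip(q[:, 2], -1.0, 1.0))
    k = view_distance
    theta_max = math.acos(-1.0 / k) if k > 1 else math.pi  # injectivity bound
    theta_lim = min(theta_max - 1e-9, _THETA_MAX if k == _K else theta_max - 1e-9)
    r_norm = float(_r_of_theta(np.array([theta_lim]), k)[0])
    ok = theta <= theta_lim
    with np.errstate(invalid="ignore", divide="ignore"):
        r = _r_of_theta(theta, k) / r_norm
    az_norm = np.linalg.norm(q[:, :2], axis=1)
    az_norm[az_norm == 0] = 1.0
    u = r * q[:, 0] / az_norm
    v = r * q[:, 1] / az_norm
    u[~ok] = np.nan
    v[~ok] = np.nan
    uv = np.column_stack([u, v])
    if np.asarray(point_mm).ndim == 1:
        return uv[0], ok[0]
    return uv, ok


def azimuthal_unproject(
    uv: np.ndarray,
    head_center: np.ndarray,
    head_radius: float | np.ndarray,
    view_distance: float = PROJECTION_VIEW_DISTANCE,
) -> np.ndarray:
    """Analytic inverse of :func:`azimuthal_project` (points on the surface)."""
    uv2 = np.atleast_2d(np.asarray(uv, dtype=float))
    k = view_distance
    theta_max = math.acos(-1.0 / k) if k > 1 else math.pi
    theta_lim = min(theta_max - 1e-9, _THETA_MAX if k == _K else theta_max - 1e-9)
    r_norm = float(_r_of_theta(np.array([theta_lim]), k)[0])
    R = np.linalg.norm(uv2, axis=1) * r_norm
    # R = sin(t)(1+k)/(cos(t)+k)  ->  quadratic in c = cos(t)
    A = R**2 + (1 + k) ** 2
    B = 2 * R**2 * k
    C = R**2 * k**2 - (1 + k) ** 2
    disc = np.sqrt(np.maximum(B**2 - 4 * A * C, 0.0))
    c = (-B + disc) / (2 * A)  # branch with theta <= theta_c
    c = np.clip(c, -1.0, 1.0)
    s = np.sqrt(1.0 - c**2)
    az = np.arctan2(uv2[:, 1], uv2[:, 0])
    q = np.column_stack([s * np.cos(az), s * np.sin(az), c])
    pts = q * np.asarray(head_radius) + np.asarray(head_center)
    if np.asarray(uv).ndim == 1:
        return pts[0]
    return pts


# ---------------------------------------------------------------------------
# Polar grid interpolation and group statistics
# ---------------------------------------------------------------------------

@dataclass
class PolarMap:
    """Scalar field on an equidistant polar grid over the unit disk.

    ``values[i, j]`` is the cell at radius ``radii[i]``, azimuth
    ``azimuths[j]``; invalid cells are masked (and NaN in ``values``).
    """

    values: np.ndarray  # (n_radii, n_azimuths)
    radii: np.ndarray
    azimuths: np.ndarray
    mask: np.ndarray  # True where valid

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.radii, columns=self.azimuths)


def interpolate_polar(
    uv: np.ndarray,
    values: np.ndarray,
    grid_shape: tuple[int, int] = (64, 128),
) -> PolarMap:
    """Linear scattered-to-grid interpolation onto the polar grid.

    Cells outside the convex hull of the scattered points (or fed only NaN
    values) are masked.
    """
    from scipy.interpolate import griddata

    uv = np.asarray(uv, dtype=float)
    values = np.asarray(values, dtype=float)
    good = np.isfinite(values) & np.all(np.isfinite(uv), axis=1)
    if good.sum() < 3:
        raise DomainError("need at least 3 valid scattered points")
    n_r, n_az = grid_shape
    radii = (np.arange(n_r) + 0.5) / n_r
    azimuths = 2 * np.pi * (np.arange(n_az) + 0.5) / n_az
    RR, AA = np.meshgrid(radii, azimuths, indexing="ij")
    gx = RR * np.cos(AA)
    gy = RR * np.sin(AA)
    grid = griddata(uv[good], values[good], (gx, gy), method="linear")
    mask = np.isfinite(grid)
    return PolarMap(values=grid, radii=radii, azimuths=azimuths, mask=mask)


def render_polar_map(pmap: PolarMap, path, title: str = "",
                     cmap: str = "viridis") -> None:
    """Save a figure-style topographic rendering of a polar map (PNG etc.)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(4.5, 4))
    # matplotlib's polar axes take (theta, r)
    AA, RR = np.meshgrid(np.concatenate([pmap.azimuths,
                                         pmap.azimuths[:1] + 2 * np.pi]),
                         pmap.radii)
    vals = np.concatenate([pmap.values, pmap.values[:, :1]], axis=1)
    pc = ax.pcolormesh(AA, RR, vals, cmap=cmap, shading="nearest")
    ax.set_theta_zero_location("N")  # nasion up
    ax.set_yticklabels([])
    ax.set_xticklabels([])
    if title:
        ax.set_title(title)
    fig.colorbar(pc, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def group_median(maps: list[PolarMap], min_valid_fraction: float = 0.5) -> PolarMap:
    """Cellwise median across subjects; cells valid in < 50% of subjects masked."""
    if not maps:
        raise DomainError("empty map list")
    shape = maps[0].grid_shape
    for m in maps:
        if m.grid_shape != shape:
            raise ConfigurationError("all maps must share the grid shape")
    stack = np.stack([m.values for m in maps])
    valid = np.stack([m.mask for m in maps])
    frac = valid.mean(axis=0)
    with np.errstate(all="ignore"):
        med = np.nanmedian(np.where(valid, stack, np.nan), axis=0)
    mask = frac >= min_valid_fraction
    med[~mask] = np.nan
    return PolarMap(values=med, radii=maps[0].radii.copy(),
                    azimuths=maps[0].azimuths.copy(), mask=mask)
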