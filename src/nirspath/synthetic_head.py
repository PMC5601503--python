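"""Parametric four-layer synthetic head models and 10-5 optode layouts.

The generator stands in for an MRI-derived pediatric cohort: each subject is
a tri-axial ellipsoid head with nested scalp / skull / CSF / brain shells
whose base thicknesses are sampled from cohort distributions calibrated to
published school-age anatomy (skull median ~2.5-2.7 mm, CSF ~5.1 mm,
scalp-to-cortex depth ~10.2 mm), plus smooth regional modulations:

* the skull is a configurable factor thicker over a crown/posterior cap,
* the CSF layer gains a few millimetres near the vertex,
* in female subjects the brain surface is recessed (thicker CSF) over a
  frontal patch, emulating the frontal-sinus-related sex difference.

Head size is derived from the sampled head circumference using the
10%-elevation ring convention (circumference measured at the horizontal
cross-section reached 10 % of the way up the preauricular coronal arc).
See ``docs/methods.md`` for what this emulates and what it does not.

Voxel label convention: 0 air, 1 scalp, 2 skull, 3 CSF, 4 brain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, GeometryError, ResolutionError

__all__ = [
    "AIR", "SCALP", "SKULL", "CSF", "BRAIN",
    "FieldDist", "SubjectParams", "CohortSpec", "HeadModel", "OptodeSet",
    "sample_cohort", "build_head", "place_optodes_10_5", "measure_arcs",
    "homogeneous_slab", "scalp_arc_distance", "scalp_radius_from_circumference",
    "ten_five_names",
    "save_head_nifti", "load_head_nifti", "save_optodes_text",
]

AIR, SCALP, SKULL, CSF, BRAIN = 0, 1, 2, 3, 4

# Fixed ellipsoid aspect: semi-axes = scalp_radius_mm * (RL, AP, SI).
# Slightly longer front-to-back than ear-to-ear, near-spherical vertically.
_ASPECT = np.array([0.96, 1.04, 1.00])


# ---------------------------------------------------------------------------
# Cohort specification and sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldDist:
    """Truncated sampling distribution for one subject parameter.

    ``log=False``: truncated normal with the given mean and SD.
    ``log=True``: truncated lognormal; ``mean`` is the median and ``spread``
    the SD of log-values (right-skewed anatomical thicknesses).
    """

    mean: float
    spread: float
    min: float
    max: float
    log: bool = False

    def validate(self, name: str) -> None:
        if not self.min < self.max:
            raise ConfigurationError(
                f"distribution for {name!r}: min ({self.min}) must be < max ({self.max})"
            )
        if self.spread < 0:
            raise ConfigurationError(
                f"distribution for {name!r}: spread must be >= 0, got {self.spread}"
            )
        if not self.min <= self.mean <= self.max:
            raise ConfigurationError(
                f"distribution for {name!r}: mean {self.mean} outside [{self.min}, {self.max}]"
            )

    def draw(self, rng: np.random.Generator) -> float:
        if self.spread == 0.0:
            return float(self.mean)
        for _ in range(10_000):
            if self.log:
                v = self.mean * math.exp(rng.normal(0.0, self.spread))
            else:
                v = rng.normal(self.mean, self.spread)
            if self.min <= v <= self.max:
                return float(v)
        # Pathological spec (almost-zero acceptance region): clamp.
        return float(min(max(self.mean, self.min), self.max))


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one synthetic subject."""

    subject_id: str
    sex: str  # "male" | "female"
    age_months: float
    head_circumference_cm: float
    scalp_radius_mm: float
    skull_thickness_base_mm: float
    csf_thickness_base_mm: float
    cortical_depth_base_mm: float
    crown_skull_multiplier: float = 2.5
    vertex_csf_bonus_mm: float = 3.0
    frontal_depth_offset_mm: float = 0.0
    # RL/AP/SI semi-axis ratios; None = the cohort default; (1,1,1) = sphere
    aspect_ratios: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("skull_thickness_base_mm", "csf_thickness_base_mm",
                     "cortical_depth_base_mm", "scalp_radius_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.cortical_depth_base_mm < (
            self.skull_thickness_base_mm + self.csf_thickness_base_mm
        ):
            raise ConfigurationError(
                "cortical_depth_base_mm must be >= skull + CSF base thickness"
            )
        if self.frontal_depth_offset_mm < 0:
            raise ConfigurationError("frontal_depth_offset_mm must be >= 0")

    @property
    def scalp_thickness_mm(self) -> float:
        """Scalp (skin) layer thickness implied by depth = scalp + skull + CSF."""
        return (
            self.cortical_depth_base_mm
            - self.skull_thickness_base_mm
            - self.csf_thickness_base_mm
        )

    @property
    def semi_axes_mm(self) -> np.ndarray:
        aspect = _ASPECT if self.aspect_ratios is None else np.asarray(
            self.aspect_ratios, dtype=float)
        return self.scalp_radius_mm * aspect


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level distributions.

    Defaults are calibrated to the published school-age cohort: 46/90 male,
    age 58-131 months, head circumference ~38.8 cm (10%-ring convention),
    skull median ~2.6 mm, CSF ~5.1 mm, cortical depth ~10.2 mm, with a weak
    age-circumference coupling giving an expected linear R^2 of ~0.176 and a
    mild circumference-depth coupling.
    """

    n_subjects: int = 90
    sex_ratio: float = 46.0 / 90.0  # male fraction
    age_months: FieldDist = field(
        default_factory=lambda: FieldDist(94.2, 16.8, 58.0, 131.4))
    head_circumference_cm: FieldDist = field(
        default_factory=lambda: FieldDist(38.8, 2.2, 33.7, 44.5))
    # Base (unmodulated) per-subject layer parameters.  The printed cohort
    # spreads and ranges describe whole-map statistics; the regional
    # modulations (crown skull factor, vertex CSF bonus) supply most of that
    # spatial spread, so the per-subject base spreads here are narrower.
    skull_thickness_base_mm: FieldDist = field(
        default_factory=lambda: FieldDist(2.585, 0.30, 1.1, 9.6, log=True))
    csf_thickness_base_mm: FieldDist = field(
        default_factory=lambda: FieldDist(5.1, 0.70, 3.0, 9.0))
    cortical_depth_base_mm: FieldDist = field(
        default_factory=lambda: FieldDist(10.17, 1.2, 6.2, 14.7))
    crown_skull_multiplier: FieldDist = field(
        default_factory=lambda: FieldDist(2.5, 0.0, 1.0, 4.0))
    vertex_csf_bonus_mm: FieldDist = field(
        default_factory=lambda: FieldDist(3.0, 0.0, 0.0, 6.0))
    frontal_depth_offset_mm: FieldDist = field(
        default_factory=lambda: FieldDist(2.5, 0.0, 0.0, 5.0))
    # Couplings: circumference on age (cm/month; R^2 = (beta*sd_age/sd_circ)^2)
    # and cortical depth on circumference (mm/cm).
    age_circ_beta: float = 0.062
    depth_circ_beta: float = 0.30
    min_scalp_thickness_mm: float = 1.0

    _FIELDS = (
        "age_months", "head_circumference_cm", "skull_thickness_base_mm",
        "csf_thickness_base_mm", "cortical_depth_base_mm",
        "crown_skull_multiplier", "vertex_csf_bonus_mm",
        "frontal_depth_offset_mm",
    )

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must be a fraction in [0, 1]")
        for name in self._FIELDS:
            getattr(self, name).validate(name)


def _ring_perimeter_unit(fraction_up: float = 0.10) -> float:
    """Perimeter of the `fraction_up` coronal-elevation ring at scalp_radius=1 mm."""
    a, b, c = _ASPECT
    # coronal arc LPA -> vertex -> RPA in the x-z plane
    psi = np.linspace(0.0, np.pi, 4001)
    pts = np.stack([-a * np.cos(psi), np.zeros_like(psi), c * np.sin(psi)], axis=1)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    z10 = float(np.interp(fraction_up * s[-1], s, pts[:, 2]))
    k = math.sqrt(max(0.0, 1.0 - (z10 / c) ** 2))
    th = np.linspace(0.0, 2 * np.pi, 4001)
    ring = np.stack([a * k * np.cos(th), b * k * np.sin(th)], axis=1)
    return float(np.linalg.norm(np.diff(ring, axis=0), axis=1).sum())


_RING_PERIM_UNIT = _ring_perimeter_unit()


def scalp_radius_from_circumference(circumference_cm: float) -> float:
    """Scalp radius (mm) whose 10%-elevation ring perimeter equals the circumference."""
    return 10.0 * circumference_cm / _RING_PERIM_UNIT


def sample_cohort(spec: CohortSpec, seed: int) -> list[SubjectParams]:
    """Draw a reproducible cohort of subject parameter sets.

    Truncated sampling keeps every field inside its stated range; the
    invariant cortical_depth >= skull + CSF (+ a minimum scalp thickness) is
    enforced by joint rejection.  The same seed always yields the identical
    cohort.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    n_male = int(round(spec.sex_ratio * n))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)

    subjects: list[SubjectParams] = []
    for i in range(n):
        sex = str(sexes[i])
        age = spec.age_months.draw(rng)
        # circumference = mean + beta*(age - age_mean) + residual, truncated
        circ_dist = spec.head_circumference_cm
        if circ_dist.spread == 0.0:
            circ = circ_dist.mean
        else:
            explained_sd = abs(spec.age_circ_beta) * spec.age_months.spread
            resid_sd = math.sqrt(max(0.0, circ_dist.spread**2 - explained_sd**2))
            shift = spec.age_circ_beta * (age - spec.age_months.mean)
            circ = FieldDist(
                circ_dist.mean + shift, resid_sd,
                circ_dist.min, circ_dist.max,
            ).draw(rng) if resid_sd > 0 else min(
                max(circ_dist.mean + shift, circ_dist.min), circ_dist.max)

        # Depth is sampled compositionally (depth = scalp + skull + CSF) so the
        # >= invariant holds without rejection and all three medians stay
        # calibrated.  The scalp layer absorbs the residual depth variance and
        # the circumference coupling.
        skull = spec.skull_thickness_base_mm.draw(rng)
        csf = spec.csf_thickness_base_mm.draw(rng)
        d_dist = spec.cortical_depth_base_mm
        sk_dist = spec.skull_thickness_base_mm
        # expected skull thickness (lognormal mean = median * exp(sigma^2/2))
        skull_mean = (sk_dist.mean * math.exp(sk_dist.spread**2 / 2.0)
                      if sk_dist.log else sk_dist.mean)
        scalp_mean = d_dist.mean - skull_mean - spec.csf_thickness_base_mm.mean
        skull_sd = sk_dist.mean * sk_dist.spread if sk_dist.log else sk_dist.spread
        scalp_var = d_dist.spread**2 - skull_sd**2 - spec.csf_thickness_base_mm.spread**2
        scalp_sd = math.sqrt(max(scalp_var, 0.0))
        scalp = scalp_mean if scalp_sd == 0.0 else rng.normal(scalp_mean, scalp_sd)
        scalp += spec.depth_circ_beta * (circ - circ_dist.mean)
        scalp = max(scalp, spec.min_scalp_thickness_mm)
        depth = skull + csf + scalp

        offset = spec.frontal_depth_offset_mm.draw(rng)
        subjects.append(SubjectParams(
            subject_id=f"sub-{i + 1:03d}",
            sex=sex,
            age_months=age,
            head_circumference_cm=circ,
            scalp_radius_mm=scalp_radius_from_circumference(circ),
            skull_thickness_base_mm=skull,
            csf_thickness_base_mm=csf,
            cortical_depth_base_mm=depth,
            crown_skull_multiplier=spec.crown_skull_multiplier.draw(rng),
            vertex_csf_bonus_mm=spec.vertex_csf_bonus_mm.draw(rng),
            frontal_depth_offset_mm=offset if sex == "female" else 0.0,
        ))
    return subjects


# ---------------------------------------------------------------------------
# Head voxelization
# ---------------------------------------------------------------------------

# Raised-cosine regional patches: (unit direction of center, angular half-width rad)
_CROWN_PATCH = (np.array([0.0, -0.30, 0.954]) / np.linalg.norm([0.0, -0.30, 0.954]),
                math.radians(65.0))
_VERTEX_PATCH = (np.array([0.0, 0.30, 0.954]) / np.linalg.norm([0.0, 0.30, 0.954]),
                 math.radians(45.0))
_FRONTAL_PATCH = (np.array([0.0, 0.906, 0.423]),  # ~25 deg above the nasion equator
                  math.radians(40.0))


def _patch_weight(u: np.ndarray, center: np.ndarray, half_width: float) -> np.ndarray:
    """Raised-cosine bump: 1 at the patch center, 0 beyond half_width."""
    cosd = np.clip(u @ center, -1.0, 1.0)
    d = np.arccos(cosd)
    w = 0.5 * (1.0 + np.cos(np.pi * np.minimum(d / half_width, 1.0)))
    w[d >= half_width] = 0.0
    return w


@dataclass
class HeadModel:
    """Labeled voxel head volume with fiducials and generation parameters."""

    labels: np.ndarray  # (nx, ny, nz) int8
    voxel_size_mm: float
    origin_mm: np.ndarray  # world coordinate of voxel (0,0,0) center
    fiducials: dict[str, np.ndarray]
    params: SubjectParams

    @property
    def center_mm(self) -> np.ndarray:
        """Ellipsoid center (midpoint of the preauricular points)."""
        return 0.5 * (self.fiducials["left_preauricular"]
                      + self.fiducials["right_preauricular"])

    @property
    def semi_axes_mm(self) -> np.ndarray:
        return self.params.semi_axes_mm

    def world_to_index(self, p: np.ndarray) -> np.ndarray:
        return np.rint((np.asarray(p) - self.origin_mm) / self.voxel_size_mm).astype(np.int64)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=float) * self.voxel_size_mm

    def surface_normal(self, p: np.ndarray) -> np.ndarray:
        """Outward smooth-ellipsoid normal at (or near) a scalp point."""
        axes = self.semi_axes_mm
        grad = 2.0 * (np.asarray(p) - self.center_mm) / axes**2
        nrm = np.linalg.norm(grad)
        if nrm == 0:
            raise GeometryError("normal undefined at the ellipsoid center")
        return grad / nrm


def _layer_thicknesses(params: SubjectParams, u: np.ndarray) -> tuple[np.ndarray, ...]:
    """Directional scalp/skull/CSF thickness fields for unit directions ``u``."""
    w_crown = _patch_weight(u, *_CROWN_PATCH)
    w_vertex = _patch_weight(u, *_VERTEX_PATCH)
    t_scalp = np.full(u.shape[0], params.scalp_thickness_mm)
    t_skull = params.skull_thickness_base_mm * (
        1.0 + (params.crown_skull_multiplier - 1.0) * w_crown
    )
    t_csf = (
        params.csf_thickness_base_mm
        + params.vertex_csf_bonus_mm * w_vertex
    )
    if params.frontal_depth_offset_mm > 0.0:
        t_csf = t_csf + params.frontal_depth_offset_mm * _patch_weight(u, *_FRONTAL_PATCH)
    return t_scalp, t_skull, t_csf


def build_head(params: SubjectParams, voxel_size_mm: float = 1.0,
               margin_mm: float = 3.0) -> HeadModel:
    """Voxelize one subject into a nested-shell four-layer ellipsoid head.

    Layer boundaries are measured radially from the scalp surface inward
    (radial ~ normal for this near-spherical geometry).  Raises
    :class:`ResolutionError` if any layer is thinner than one voxel.
    """
    if not 0.5 <= voxel_size_mm <= 2.0:
        raise ConfigurationError(
            f"voxel_size_mm must be in [0.5, 2.0], got {voxel_size_mm}")
    vs = float(voxel_size_mm)
    axes = params.semi_axes_mm
    thinnest = min(params.scalp_thickness_mm, params.skull_thickness_base_mm,
                   params.csf_thickness_base_mm)
    if thinnest < vs - 1e-9:
        raise ResolutionError(
            f"thinnest layer ({thinnest:.2f} mm) is below one voxel ({vs} mm); "
            "reduce voxel_size_mm"
        )

    half = axes.max() + margin_mm
    n_half = int(math.ceil(half / vs))
    dims = 2 * n_half + 1
    # center sits exactly on the central voxel center
    origin = -vs * np.array([n_half, n_half, n_half], dtype=float)
    c = origin[0] + vs * np.arange(dims)
    x = c[:, None, None]
    y = c[None, :, None]
    z = c[None, None, :]
    rho2 = x * x + y * y + z * z
    rho = np.sqrt(rho2)
    rho_safe = np.where(rho == 0, 1.0, rho)
    # distance from center to the scalp surface along the voxel direction
    m = np.sqrt((x / axes[0]) ** 2 + (y / axes[1]) ** 2 + (z / axes[2]) ** 2)
    R = rho_safe / np.where(m == 0, 1.0, m)
    shape = (dims, dims, dims)

    def patch_grid(center: np.ndarray, half_width: float) -> np.ndarray:
        cosd = (x * center[0] + y * center[1] + z * center[2]) / rho_safe
        w = np.zeros(shape)
        sel = cosd > math.cos(half_width)
        d = np.arccos(np.clip(cosd[sel], -1.0, 1.0))
        w[sel] = 0.5 * (1.0 + np.cos(np.pi * d / half_width))
        return w

    t_skull = params.skull_thickness_base_mm * (
        1.0 + (params.crown_skull_multiplier - 1.0) * patch_grid(*_CROWN_PATCH))
    t_csf = params.csf_thickness_base_mm \
        + params.vertex_csf_bonus_mm * patch_grid(*_VERTEX_PATCH)
    if params.frontal_depth_offset_mm > 0.0:
        t_csf = t_csf + params.frontal_depth_offset_mm * patch_grid(*_FRONTAL_PATCH)
    r1 = R - params.scalp_thickness_mm
    r2 = r1 - t_skull
    r3 = r2 - t_csf

    labels = np.zeros(shape, dtype=np.int8)
    labels[rho <= R] = SCALP
    labels[rho <= r1] = SKULL
    labels[rho <= r2] = CSF
    labels[rho <= r3] = BRAIN
    labels[rho == 0] = BRAIN
    if not np.any(labels == BRAIN):
        raise GeometryError("brain region is empty; head too small for its layers")

    fid = {
        "nasion": np.array([0.0, axes[1], 0.0]),
        "inion": np.array([0.0, -axes[1], 0.0]),
        "left_preauricular": np.array([-axes[0], 0.0, 0.0]),
        "right_preauricular": np.array([axes[0], 0.0, 0.0]),
    }
    return HeadModel(labels=labels, voxel_size_mm=vs, origin_mm=origin,
                     fiducials=fid, params=params)


def homogeneous_slab(tissue_label: int = BRAIN, size_mm: float = 120.0,
                     depth_mm: float = 60.0, voxel_size_mm: float = 1.0) -> HeadModel:
    """Flat homogeneous medium under air, for benchmarking against diffusion
    theory (semi-infinite approximations).  Not a nested-shell head: the
    shell-ordering invariant intentionally does not apply.

    The surface is the plane z = 0; tissue occupies z < 0.
    """
    vs = float(voxel_size_mm)
    nxy = int(round(size_mm / vs))
    nz_tissue = int(round(depth_mm / vs))
    nz_air = 3
    labels = np.zeros((nxy, nxy, nz_tissue + nz_air), dtype=np.int8)
    labels[:, :, :nz_tissue] = tissue_label
    # voxel centers: topmost tissue voxel center at z = -vs/2
    origin = np.array([-size_mm / 2 + vs / 2, -size_mm / 2 + vs / 2,
                       -(nz_tissue - 0.5) * vs])
    params = SubjectParams(
        subject_id="slab", sex="male", age_months=96.0,
        head_circumference_cm=38.8,
        scalp_radius_mm=size_mm,
        skull_thickness_base_mm=1.0, csf_thickness_base_mm=1.0,
        cortical_depth_base_mm=3.0,
        crown_skull_multiplier=1.0, vertex_csf_bonus_mm=0.0,
        frontal_depth_offset_mm=0.0,
    )
    fid = {
        "nasion": np.array([0.0, size_mm / 2, 0.0]),
        "inion": np.array([0.0, -size_mm / 2, 0.0]),
        "left_preauricular": np.array([-size_mm / 2, 0.0, 0.0]),
        "right_preauricular": np.array([size_mm / 2, 0.0, 0.0]),
    }
    return HeadModel(labels=labels, voxel_size_mm=vs, origin_mm=origin,
                     fiducials=fid, params=params)


# ---------------------------------------------------------------------------
# Ellipsoid arc geometry
# ---------------------------------------------------------------------------

def _polyline_point_at_fraction(pts: np.ndarray, frac: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = frac * s[-1]
    return np.array([np.interp(target, s, pts[:, k]) for k in range(3)])


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _midline_arc(axes: np.ndarray, n: int = 2001) -> np.ndarray:
    """Nasion -> vertex -> inion polyline on the ellipsoid (x = 0 plane)."""
    psi = np.linspace(0.0, np.pi, n)
    return np.stack(
        [np.zeros_like(psi), axes[1] * np.cos(psi), axes[2] * np.sin(psi)], axis=1)


def _coronal_arc(axes: np.ndarray, n: int = 2001) -> np.ndarray:
    """LPA -> vertex -> RPA polyline on the ellipsoid (y = 0 plane)."""
    psi = np.linspace(0.0, np.pi, n)
    return np.stack(
        [-axes[0] * np.cos(psi), np.zeros_like(psi), axes[2] * np.sin(psi)], axis=1)


def _equator_arc(axes: np.ndarray, side: int, n: int = 2001) -> np.ndarray:
    """Nasion -> preauricular -> inion along the equator; side -1 left, +1 right."""
    phi = np.linspace(0.0, np.pi, n)
    return np.stack(
        [side * axes[0] * np.sin(phi), axes[1] * np.cos(phi), np.zeros_like(phi)],
        axis=1)


def _plane_section(axes: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray, n: int = 721) -> np.ndarray:
    """Closed plane-ellipsoid intersection curve through three surface points.

    Computed on the unit-sphere preimage (where the section is a circle) and
    mapped back; returned as a polyline over the full circle.
    """
    q1, q2, q3 = (np.asarray(p) / axes for p in (p1, p2, p3))
    nrm = np.cross(q2 - q1, q3 - q1)
    nn = np.linalg.norm(nrm)
    if nn < 1e-12:
        raise GeometryError("collinear points: plane section undefined")
    nrm = nrm / nn
    d = float(nrm @ q1)
    if abs(d) >= 1.0:
        raise GeometryError("plane does not intersect the surface")
    center = d * nrm
    r = math.sqrt(1.0 - d * d)
    e1 = q1 - center
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(nrm, e1)
    alpha = np.linspace(0.0, 2 * np.pi, n)
    circ = center + r * (np.outer(np.cos(alpha), e1) + np.outer(np.sin(alpha), e2))
    return circ * axes


def _section_arc_between(axes: np.ndarray, curve_from: np.ndarray,
                         q_from: np.ndarray, q_to: np.ndarray) -> np.ndarray:
    """Shorter sub-arc of a closed section polyline between two of its points."""
    # locate nearest polyline vertices
    i = int(np.argmin(np.linalg.norm(curve_from - q_from, axis=1)))
    j = int(np.argmin(np.linalg.norm(curve_from - q_to, axis=1)))
    npts = curve_from.shape[0] - 1  # closed: last == first
    if i == j:
        return curve_from[[i, j]]
    fwd = (np.arange(i, i + (j - i) % npts + 1)) % npts
    bwd = (np.arange(j, j + (i - j) % npts + 1)) % npts
    arc_f = curve_from[fwd]
    arc_b = curve_from[bwd][::-1]
    return arc_f if _polyline_length(arc_f) <= _polyline_length(arc_b) else arc_b


def scalp_arc_distance(head: HeadModel, p1: np.ndarray, p2: np.ndarray) -> float:
    """Geodesic-style scalp distance: length of the central plane section arc.

    Exact great-circle geodesic on a sphere; a close approximation on the
    near-spherical ellipsoids used here.
    """
    axes = head.semi_axes_mm
    c = head.center_mm
    q1 = np.asarray(p1, dtype=float) - c
    q2 = np.asarray(p2, dtype=float) - c
    # project both points exactly onto the ellipsoid surface along the radius
    u1 = q1 / np.sqrt(((q1 / axes) ** 2).sum())
    u2 = q2 / np.sqrt(((q2 / axes) ** 2).sum())
    w1, w2 = u1 / axes, u2 / axes
    cosang = float(np.clip(w1 @ w2 / (np.linalg.norm(w1) * np.linalg.norm(w2)), -1, 1))
    ang = math.acos(cosang)
    if ang < 1e-9:
        return 0.0
    a1 = w1 / np.linalg.norm(w1)
    a2 = w2 / np.linalg.norm(w2)
    e2 = a2 - (a2 @ a1) * a1
    e2 = e2 / np.linalg.norm(e2)
    t = np.linspace(0.0, ang, 129)
    pts = (np.outer(np.cos(t), a1) + np.outer(np.sin(t), e2)) * axes
    return _polyline_length(pts)


# ---------------------------------------------------------------------------
# 10-5 optode layout
# ---------------------------------------------------------------------------

# Sagittal rows of the extended 10-5 grid: (row prefix, midline fraction,
# maximal lateral slot, temporal prefix for slots 7-10 or None).
# Lateral slot k (0..10) sits at fraction k/10 of the hemicontour from the
# midline (k=0) to the equator (k=10); slot names follow the convention
# z, 1h, 1, 3h, 3, 5h, 5, 7h, 7, 9h, 9 (odd left, even right, h = half-step
# toward the midline).
_ROWS: list[tuple[str, float, int, str | None]] = [
    ("N", 0.00, 0, None),
    ("Fp", 0.10, 2, None),
    ("AFp", 0.15, 10, None),
    ("AF", 0.20, 10, None),
    ("AFF", 0.25, 10, None),
    ("F", 0.30, 10, None),
    ("FFC", 0.35, 10, "FFT"),
    ("FC", 0.40, 10, "FT"),
    ("FCC", 0.45, 10, "FTT"),
    ("C", 0.50, 10, "T"),
    ("CCP", 0.55, 10, "TTP"),
    ("CP", 0.60, 10, "TP"),
    ("CPP", 0.65, 10, "TPP"),
    ("P", 0.70, 10, None),
    ("PPO", 0.75, 10, None),
    ("PO", 0.80, 10, None),
    ("POO", 0.85, 10, None),
    ("O", 0.90, 2, None),
    ("OI", 0.95, 2, None),
    ("I", 1.00, 0, None),  # laterals I1/I2/I1h/I2h sit on the equator ring
]


def _slot_name(prefix: str, temporal: str | None, k: int, side: int) -> str:
    """Name of lateral slot k (1..10) on side -1 (left/odd) or +1 (right/even)."""
    use_prefix = temporal if (temporal is not None and k >= 7) else prefix
    if k % 2 == 1:  # half-step position
        base = k if side < 0 else k + 1
        return f"{use_prefix}{base}h"
    base = k - 1 if side < 0 else k
    return f"{use_prefix}{base}"


def ten_five_names() -> list[str]:
    """The 346 named scalp positions of the layout (fixed order)."""
    names: list[str] = []
    for prefix, frac, max_k, temporal in _ROWS:
        if max_k == 0:
            names.append(prefix + "z")
            continue
        names.append(prefix + "z")
        for k in range(1, max_k + 1):
            names.append(_slot_name(prefix, temporal, k, -1))
            names.append(_slot_name(prefix, temporal, k, +1))
    # inion-level lateral positions on the equator ring
    names += ["I1", "I2", "I1h", "I2h"]
    # legacy aliases and periauricular points
    names += ["T3", "T4", "T5", "T6", "A1", "A2", "M1", "M2"]
    # fiducial scalp points
    names += ["LPA", "RPA"]
    return names


@dataclass
class OptodeSet:
    """Named scalp positions with snapped voxel coordinates and outward normals."""

    labels: list[str]
    positions_mm: np.ndarray  # (n, 3), scalp-surface voxel centers
    normals: np.ndarray  # (n, 3), outward unit normals (smooth ellipsoid)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown 10-5 position {label!r}") from None

    def position(self, label: str) -> np.ndarray:
        return self.positions_mm[self.index(label)]

    def normal(self, label: str) -> np.ndarray:
        return self.normals[self.index(label)]


def _analytic_grid_points(axes: np.ndarray) -> dict[str, np.ndarray]:
    """Smooth-surface coordinates (relative to center) of all 346 positions."""
    midline = _midline_arc(axes)
    eq_l = _equator_arc(axes, -1)
    eq_r = _equator_arc(axes, +1)
    pts: dict[str, np.ndarray] = {}
    pts["Nz"] = _polyline_point_at_fraction(midline, 0.0)
    pts["Iz"] = _polyline_point_at_fraction(midline, 1.0)
    pts["LPA"] = _polyline_point_at_fraction(eq_l, 0.5)
    pts["RPA"] = _polyline_point_at_fraction(eq_r, 0.5)

    for prefix, frac, max_k, temporal in _ROWS:
        if prefix in ("N", "I"):
            continue
        m = _polyline_point_at_fraction(midline, frac)
        pts[prefix + "z"] = m
        if max_k == 0:
            continue
        el = _polyline_point_at_fraction(eq_l, frac)
        er = _polyline_point_at_fraction(eq_r, frac)
        section = _plane_section(axes, m, el, er)
        for side, e in ((-1, el), (+1, er)):
            half = _section_arc_between(axes, section, m, e)
            for k in range(1, max_k + 1):
                pts[_slot_name(prefix, temporal, k, side)] = (
                    _polyline_point_at_fraction(half, k / 10.0))

    # inion-level laterals on the equator (below the O/OI rows)
    pts["I1"] = _polyline_point_at_fraction(eq_l, 0.90)
    pts["I2"] = _polyline_point_at_fraction(eq_r, 0.90)
    pts["I1h"] = _polyline_point_at_fraction(eq_l, 0.95)
    pts["I2h"] = _polyline_point_at_fraction(eq_r, 0.95)
    # legacy aliases share the modern positions
    pts["T3"] = pts["T7"]
    pts["T4"] = pts["T8"]
    pts["T5"] = pts["P7"]
    pts["T6"] = pts["P8"]
    # periauricular points on the equator just behind the ears
    pts["A1"] = _polyline_point_at_fraction(eq_l, 0.525)
    pts["A2"] = _polyline_point_at_fraction(eq_r, 0.525)
    pts["M1"] = _polyline_point_at_fraction(eq_l, 0.575)
    pts["M2"] = _polyline_point_at_fraction(eq_r, 0.575)
    return pts


def _snap_to_scalp_voxel(head: HeadModel, p_world: np.ndarray,
                         search_radius_vox: int = 3) -> np.ndarray:
    """Nearest scalp-surface voxel center (label 1 with an air 6-neighbour).

    Tie-break: lowest flat index among voxels at the minimal distance.
    """
    labels = head.labels
    vs = head.voxel_size_mm
    idx0 = head.world_to_index(p_world)
    best: tuple[float, int] | None = None
    best_idx = None
    r = search_radius_vox
    nx, ny, nz = labels.shape
    for _ in range(4):  # widen the search if needed
        lo = np.maximum(idx0 - r, 0)
        hi = np.minimum(idx0 + r + 1, [nx, ny, nz])
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        cand = np.argwhere(sub == SCALP) + lo
        for ci in cand:
            i, j, k = int(ci[0]), int(ci[1]), int(ci[2])
            has_air = False
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                ii, jj, kk = i + di, j + dj, k + dk
                if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                    has_air = True  # grid edge counts as outside
                    break
                if labels[ii, jj, kk] == AIR:
                    has_air = True
                    break
            if not has_air:
                continue
            center = head.index_to_world(ci)
            dist = float(np.linalg.norm(center - p_world))
            flat = (i * ny + j) * nz + k
            key = (round(dist / (1e-9 * vs)), flat)  # distance ties -> lowest index
            if best is None or key < best:
                best = key
                best_idx = center
        if best_idx is not None:
            return best_idx
        r *= 2
    raise GeometryError("no scalp-surface voxel found near requested position")


def place_optodes_10_5(head: HeadModel) -> OptodeSet:
    """Construct the 346-position extended 10-5 layout on a head.

    Positions are generated by proportional subdivision of scalp arcs
    (nasion-inion midline, preauricular coronal arc, then transverse
    contours at each 5 % sagittal level) on the smooth ellipsoid, then
    snapped to the nearest scalp-surface voxel center.
    """
    fid = head.fiducials
    pairs = [(a, b) for i, a in enumerate(fid.values())
             for b in list(fid.values())[i + 1:]]
    if any(np.linalg.norm(a - b) < 4 * head.voxel_size_mm for a, b in pairs):
        raise GeometryError("degenerate fiducials: coincident or nearly so")

    center = head.center_mm
    analytic = _analytic_grid_points(head.semi_axes_mm)
    names = ten_five_names()
    positions = np.empty((len(names), 3))
    normals = np.empty((len(names), 3))
    for i, name in enumerate(names):
        p_world = analytic[name] + center
        positions[i] = _snap_to_scalp_voxel(head, p_world)
        normals[i] = head.surface_normal(p_world)
    return OptodeSet(labels=names, positions_mm=positions, normals=normals)


def measure_arcs(head: HeadModel) -> dict[str, float]:
    """Scalp arc measurements, in cm.

    ``circumference_cm`` follows the 10%-elevation convention: the perimeter
    of the horizontal cross-section at the height reached 10 % of the way up
    the preauricular coronal arc.  ``arc_AP_cm`` is nasion -> inion over the
    vertex; ``arc_RL_cm`` is preauricular -> preauricular over the vertex.
    """
    axes = head.semi_axes_mm
    ap = _polyline_length(_midline_arc(axes))
    rl_pts = _coronal_arc(axes)
    rl = _polyline_length(rl_pts)
    p10 = _polyline_point_at_fraction(rl_pts, 0.10)
    k = math.sqrt(max(0.0, 1.0 - (p10[2] / axes[2]) ** 2))
    th = np.linspace(0.0, 2 * np.pi, 2001)
    ring = np.stack([axes[0] * k * np.cos(th), axes[1] * k * np.sin(th),
                     np.full_like(th, p10[2])], axis=1)
    circ = _polyline_length(ring)
    return {
        "circumference_cm": circ / 10.0,
        "arc_AP_cm": ap / 10.0,
        "arc_RL_cm": rl / 10.0,
    }


# ---------------------------------------------------------------------------
# I/O: NIfTI label volume + JSON sidecar; optode text table
# ---------------------------------------------------------------------------

def save_head_nifti(head: HeadModel, path: str | Path) -> None:
    """Write the label volume as NIfTI-1 plus a JSON sidecar of fiducials/params."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([head.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = head.origin_mm
    nib.save(nib.Nifti1Image(head.labels.astype(np.uint8), affine), str(path))
    sidecar = {
        "voxel_size_mm": head.voxel_size_mm,
        "origin_mm": head.origin_mm.tolist(),
        "fiducials": {k: v.tolist() for k, v in head.fiducials.items()},
        "params": {k: (list(v) if isinstance(v, (tuple, list, np.ndarray))
                       else v if (v is None or isinstance(v, (str, float, int)))
                       else float(v))
                   for k, v in vars(head.params).items()},
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2))


def load_head_nifti(path: str | Path) -> HeadModel:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    params = SubjectParams(**sidecar["params"])
    return HeadModel(
        labels=np.asarray(img.dataobj).astype(np.int8),
        voxel_size_mm=float(sidecar["voxel_size_mm"]),
        origin_mm=np.array(sidecar["origin_mm"], dtype=float),
        fiducials={k: np.array(v, dtype=float)
                   for k, v in sidecar["fiducials"].items()},
        params=params,
    )


def save_optodes_text(optodes: OptodeSet, path: str | Path) -> None:
    """Whitespace-delimited `label x y z` table (optode-position file style)."""
    lines = [f"{lab} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}"
             for lab, p in zip(optodes.labels, optodes.positions_mm)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_optodes_text(path: str | Path) -> tuple[list[str], np.ndarray]:
    labels, pos = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) != 4:
            continue
        labels.append(parts[0])
        pos.append([float(x) for x in parts[1:]])
    return labels, np.array(pos)
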