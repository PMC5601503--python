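"""Voxel-based Monte Carlo photon transport through a labeled head volume.

The scheme is the standard continuous-absorption photon-migration walk:

* photons launch with unit weight at a scalp position along the inward
  normal (specular reflection at launch is skipped — the photon starts just
  inside the scalp);
* free paths are sampled from the local scattering coefficient
  ``mu_s = mu_s'/(1-g)``, with the remaining scattering optical depth
  carried across voxel and tissue boundaries (essential in near-transparent
  CSF, where free paths exceed the layer thickness);
* directions update by Henyey-Greenstein sampling with the local ``g``;
* absorption is applied continuously: the photon weight is
  ``exp(-sum_t mu_a,t * L_t)`` with per-tissue path accumulators ``L_t``,
  which makes partial-pathlength tallies exact and low-variance;
* unpolarized Fresnel reflection/refraction is applied at voxel faces where
  the refractive index changes (including total internal reflection); a
  photon transmitted into air is recorded with its exit position, weight
  and per-tissue pathlengths — there is no numerical-aperture cut;
* low-weight photons undergo Russian roulette, and photons exceeding a
  maximum total pathlength are terminated.

Reproducibility: every photon runs on its own counter-derived RNG substream
(splitmix64-seeded xorshift128+), so a given (seed, config) always produces
identical tallies, independent of execution order.

Energy bookkeeping per run: ``launched + roulette_gain = detected +
absorbed + terminated + escaped`` holds to float rounding; the residual is
reported with every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigurationError, DomainError, GeometryError
from .optical_properties import TissueOptics
from .synthetic_head import (AIR, BRAIN, HeadModel, OptodeSet,
                             scalp_arc_distance)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "run_simulation",
    "detect_channels",
    "sensitivity_db",
    "hg_sample_cos",
    "CHANNEL_COLUMNS",
]

_TISSUE_ORDER = ("scalp", "skull", "csf", "brain")
_TISSUE_ALIASES = {"skin": "scalp"}


@dataclass(frozen=True)
class SimulationConfig:
    """Transport run configuration.

    ``n_photons`` defaults to 1e6 — a desk-scale count; the per-channel
    Monte Carlo error contracts as 1/sqrt(n).  ``detector_aperture_mm`` is
    the capture radius around each detector position in ``aperture`` mode.
    """

    n_photons: int = 1_000_000
    seed: int = 0
    wavelength_nm: float = 690.0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_total_path_mm: float = 1500.0
    detector_aperture_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ConfigurationError("n_photons must be >= 1")
        if not 0.0 < self.roulette_threshold < 1.0:
            raise ConfigurationError("roulette_threshold must be in (0, 1)")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ConfigurationError("roulette_survival must be in (0, 1)")
        if self.detector_aperture_mm <= 0:
            raise ConfigurationError("detector_aperture_mm must be > 0")
        if self.max_total_path_mm <= 0:
            raise ConfigurationError("max_total_path_mm must be > 0")


@dataclass
class SimulationResult:
    """Per-photon detection records plus run-level weight totals.

    Arrays are aligned: row i describes the i-th detected photon.
    """

    exit_positions_mm: np.ndarray  # (n_detected, 3)
    exit_weights: np.ndarray  # (n_detected,)
    paths_by_tissue_mm: np.ndarray  # (n_detected, 4): scalp, skull, CSF, brain
    region_paths_mm: np.ndarray  # (n_detected,) pathlength inside region mask
    totals: dict[str, float]
    config: SimulationConfig
    source_position_mm: np.ndarray
    source_direction: np.ndarray

    @property
    def total_paths_mm(self) -> np.ndarray:
        return self.paths_by_tissue_mm.sum(axis=1)

    @property
    def n_detected(self) -> int:
        return int(self.exit_weights.shape[0])

    @property
    def conservation_residual(self) -> float:
        t = self.totals
        lhs = t["launched"] + t["roulette_gain"]
        rhs = t["detected"] + t["absorbed"] + t["terminated"] + t["escaped"]
        return abs(lhs - rhs) / lhs

    def to_frame(self) -> pd.DataFrame:
        """Detection records as a table (one row per detected photon)."""
        return pd.DataFrame({
            "exit_x_mm": self.exit_positions_mm[:, 0],
            "exit_y_mm": self.exit_positions_mm[:, 1],
            "exit_z_mm": self.exit_positions_mm[:, 2],
            "exit_weight": self.exit_weights,
            "path_scalp_mm": self.paths_by_tissue_mm[:, 0],
            "path_skull_mm": self.paths_by_tissue_mm[:, 1],
            "path_csf_mm": self.paths_by_tissue_mm[:, 2],
            "path_brain_mm": self.paths_by_tissue_mm[:, 3],
            "path_region_mm": self.region_paths_mm,
            "total_path_mm": self.total_paths_mm,
        })


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _xs128p_next(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return (state[0] + state[1]) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _rand_u01(state):
    # 53-bit uniform in [0, 1); never exactly 1
    return (_xs128p_next(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _transport_kernel(labels, region, has_region, vs, ox, oy, oz,
                      mu_a, mu_s, g_arr, n_arr,
                      sx, sy, sz, dx, dy, dz,
                      n_photons, seed,
                      w_thresh, w_survive, max_path,
                      out_pos, out_w, out_paths, out_rpath, totals):
    nx, ny, nz = labels.shape
    n_det = 0
    absorbed = 0.0
    terminated = 0.0
    escaped = 0.0
    detected = 0.0
    roulette_gain = 0.0
    state = np.empty(2, dtype=np.uint64)

    for ph in range(n_photons):
        # counter-derived per-photon substream
        base = _splitmix64(np.uint64(seed) ^ (np.uint64(ph) * np.uint64(0x9E3779B97F4A7C15)))
        state[0] = _splitmix64(base)
        state[1] = _splitmix64(base ^ np.uint64(0xDEADBEEFCAFEF00D))
        if state[0] == np.uint64(0) and state[1] == np.uint64(0):
            state[0] = np.uint64(1)

        px, py, pz = sx, sy, sz
        ux, uy, uz = dx, dy, dz
        i = int(np.floor((px - ox) / vs + 0.5))
        j = int(np.floor((py - oy) / vs + 0.5))
        k = int(np.floor((pz - oz) / vs + 0.5))
        # nudge through any leading air voxels (source sits on the surface)
        guard = 0
        while (0 <= i < nx and 0 <= j < ny and 0 <= k < nz
               and labels[i, j, k] == 0 and guard < 8):
            px += ux * vs * 0.5
            py += uy * vs * 0.5
            pz += uz * vs * 0.5
            i = int(np.floor((px - ox) / vs + 0.5))
            j = int(np.floor((py - oy) / vs + 0.5))
            k = int(np.floor((pz - oz) / vs + 0.5))
            guard += 1

        p_scalp = 0.0
        p_skull = 0.0
        p_csf = 0.0
        p_brain = 0.0
        rpath = 0.0
        a_depth = 0.0  # absorption optical depth; weight = exp(-a_depth)
        gain = 0.0
        total = 0.0
        tau = -np.log(1.0 - _rand_u01(state))
        alive = True
        detected_flag = False

        while alive:
            if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
                # left the computational grid (slab sides / margins)
                w = np.exp(-a_depth)
                escaped += w
                alive = False
                break
            lbl = labels[i, j, k]
            ms = mu_s[lbl]
            ma = mu_a[lbl]

            # distances to the three forward voxel faces
            if ux > 0.0:
                tx = ((ox + (i + 0.5) * vs) - px) / ux
            elif ux < 0.0:
                tx = ((ox + (i - 0.5) * vs) - px) / ux
            else:
                tx = 1e30
            if uy > 0.0:
                ty = ((oy + (j + 0.5) * vs) - py) / uy
            elif uy < 0.0:
                ty = ((oy + (j - 0.5) * vs) - py) / uy
            else:
                ty = 1e30
            if uz > 0.0:
                tz = ((oz + (k + 0.5) * vs) - pz) / uz
            elif uz < 0.0:
                tz = ((oz + (k - 0.5) * vs) - pz) / uz
            else:
                tz = 1e30

            t_bound = tx
            axis = 0
            if ty < t_bound:
                t_bound = ty
                axis = 1
            if tz < t_bound:
                t_bound = tz
                axis = 2
            if t_bound < 0.0:
                t_bound = 0.0

            t_scat = tau / ms if ms > 0.0 else 1e30
            t_left = max_path - total
            step = t_bound
            event = 0  # 0 boundary, 1 scatter, 2 path-limit
            if t_scat < step:
                step = t_scat
                event = 1
            if t_left < step:
                step = t_left
                event = 2

            px += ux * step
            py += uy * step
            pz += uz * step
            total += step
            tau -= ms * step
            if lbl == 1:
                p_scalp += step
            elif lbl == 2:
                p_skull += step
            elif lbl == 3:
                p_csf += step
            elif lbl == 4:
                p_brain += step
                if has_region and region[i, j, k] != 0:
                    rpath += step
            a_depth += ma * step

            if event == 2:
                terminated += np.exp(-a_depth)
                alive = False
            elif event == 1:
                # scatter: Henyey-Greenstein deflection about current direction
                gg = g_arr[lbl]
                if gg != 0.0:
                    tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * _rand_u01(state))
                    ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                else:
                    ct = 2.0 * _rand_u01(state) - 1.0
                st = np.sqrt(1.0 - ct * ct)
                phi = 2.0 * np.pi * _rand_u01(state)
                cp = np.cos(phi)
                sp = np.sin(phi)
                if abs(uz) > 0.99999:
                    nux = st * cp
                    nuy = st * sp
                    nuz = ct * (1.0 if uz > 0.0 else -1.0)
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    nuz = -st * cp * den + uz * ct
                ux, uy, uz = nux, nuy, nuz
                tau = -np.log(1.0 - _rand_u01(state))
                # Russian roulette on low weight
                w = np.exp(-a_depth)
                if w < w_thresh:
                    if _rand_u01(state) < w_survive:
                        gain += w * (1.0 / w_survive - 1.0)
                        a_depth += np.log(w_survive)  # weight /= survival
                    else:
                        terminated += w
                        alive = False
            else:
                # voxel face crossing; check refractive-index step
                ni2 = i
                nj2 = j
                nk2 = k
                if axis == 0:
                    ni2 += 1 if ux > 0.0 else -1
                elif axis == 1:
                    nj2 += 1 if uy > 0.0 else -1
                else:
                    nk2 += 1 if uz > 0.0 else -1
                if not (0 <= ni2 < nx and 0 <= nj2 < ny and 0 <= nk2 < nz):
                    w = np.exp(-a_depth)
                    escaped += w
                    alive = False
                else:
                    lbl2 = labels[ni2, nj2, nk2]
                    n1 = n_arr[lbl]
                    n2 = n_arr[lbl2]
                    crossed = True
                    if n1 != n2:
                        if axis == 0:
                            ci = abs(ux)
                        elif axis == 1:
                            ci = abs(uy)
                        else:
                            ci = abs(uz)
                        eta = n1 / n2
                        sin_t2 = eta * eta * (1.0 - ci * ci)
                        if sin_t2 >= 1.0:
                            crossed = False  # total internal reflection
                        else:
                            ct2 = np.sqrt(1.0 - sin_t2)
                            rs = (n1 * ci - n2 * ct2) / (n1 * ci + n2 * ct2)
                            rp = (n1 * ct2 - n2 * ci) / (n1 * ct2 + n2 * ci)
                            refl = 0.5 * (rs * rs + rp * rp)
                            if _rand_u01(state) < refl:
                                crossed = False
                            else:
                                # refract: scale tangentials, set normal comp.
                                if axis == 0:
                                    uy *= eta
                                    uz *= eta
                                    ux = ct2 if ux > 0.0 else -ct2
                                elif axis == 1:
                                    ux *= eta
                                    uz *= eta
                                    uy = ct2 if uy > 0.0 else -ct2
                                else:
                                    ux *= eta
                                    uy *= eta
                                    uz = ct2 if uz > 0.0 else -ct2
                    if not crossed:
                        # mirror reflection at the face
                        if axis == 0:
                            ux = -ux
                        elif axis == 1:
                            uy = -uy
                        else:
                            uz = -uz
                    else:
                        if lbl2 == 0 and lbl != 0:
                            # exits into air: detection
                            w = np.exp(-a_depth)
                            out_pos[n_det, 0] = px
                            out_pos[n_det, 1] = py
                            out_pos[n_det, 2] = pz
                            out_w[n_det] = w
                            out_paths[n_det, 0] = p_scalp
                            out_paths[n_det, 1] = p_skull
                            out_paths[n_det, 2] = p_csf
                            out_paths[n_det, 3] = p_brain
                            out_rpath[n_det] = rpath
                            n_det += 1
                            detected += w
                            detected_flag = True
                            alive = False
                        else:
                            i = ni2
                            j = nj2
                            k = nk2

        w_final = np.exp(-a_depth)
        if not detected_flag:
            # weight at death already credited to terminated/escaped
            pass
        absorbed += (1.0 + gain) - w_final
        roulette_gain += gain

    totals[0] = float(n_photons)
    totals[1] = detected
    totals[2] = absorbed
    totals[3] = terminated
    totals[4] = escaped
    totals[5] = roulette_gain
    return n_det


@njit(cache=True)
def _hg_kernel(g, n, seed, out):
    state = np.empty(2, dtype=np.uint64)
    base = _splitmix64(np.uint64(seed))
    state[0] = _splitmix64(base)
    state[1] = _splitmix64(base ^ np.uint64(0xDEADBEEFCAFEF00D))
    for i in range(n):
        if g != 0.0:
            tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * _rand_u01(state))
            ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
        else:
            ct = 2.0 * _rand_u01(state) - 1.0
        out[i] = ct


def hg_sample_cos(g: float, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` Henyey-Greenstein deflection cosines (mean -> g)."""
    out = np.empty(n, dtype=np.float64)
    _hg_kernel(float(g), int(n), int(seed) & 0x7FFFFFFF, out)
    return out


# ---------------------------------------------------------------------------
# Python driver
# ---------------------------------------------------------------------------

def _optics_arrays(optics: Mapping[str, TissueOptics]) -> tuple[np.ndarray, ...]:
    mu_a = np.zeros(5)
    mu_s = np.zeros(5)
    g = np.zeros(5)
    n = np.ones(5)
    seen = set()
    for name, t in optics.items():
        key = _TISSUE_ALIASES.get(name.lower(), name.lower())
        if key not in _TISSUE_ORDER:
            raise ConfigurationError(f"unknown tissue {name!r}")
        idx = _TISSUE_ORDER.index(key) + 1
        mu_a[idx] = t.mu_a
        mu_s[idx] = t.mu_s
        g[idx] = t.g
        n[idx] = t.n
        seen.add(key)
    missing = set(_TISSUE_ORDER) - seen
    if missing:
        raise ConfigurationError(f"optics missing for tissues: {sorted(missing)}")
    return mu_a, mu_s, g, n


def run_simulation(
    head: HeadModel,
    optics: Mapping[str, TissueOptics],
    source_position_mm: np.ndarray,
    source_direction: np.ndarray,
    config: SimulationConfig,
    region_mask: np.ndarray | None = None,
) -> SimulationResult:
    """Simulate photon migration from one source on the scalp.

    ``optics`` maps tissue names (scalp/skin, skull, csf, brain) to their
    properties.  ``source_direction`` must point into the head.  The
    optional ``region_mask`` (same shape as ``head.labels``) enables the
    per-photon region pathlength tally used by :func:`sensitivity_db`.
    """
    mu_a, mu_s, g, n = _optics_arrays(optics)
    src = np.asarray(source_position_mm, dtype=float)
    d = np.asarray(source_direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise GeometryError("source direction must be nonzero")
    d = d / nd

    # the source must sit on (within a voxel of) the scalp surface
    probe = src + 0.5 * head.voxel_size_mm * d
    idx = head.world_to_index(probe)
    shape = np.array(head.labels.shape)
    inside = np.all((idx >= 0) & (idx < shape))
    found = False
    for t in np.linspace(0.0, 3.0 * head.voxel_size_mm, 7):
        idx = head.world_to_index(src + t * d)
        if np.all((idx >= 0) & (idx < shape)) and head.labels[tuple(idx)] != AIR:
            found = True
            break
    if not (inside and found):
        raise GeometryError("source is not on the scalp surface")

    if region_mask is not None:
        if region_mask.shape != head.labels.shape:
            raise DomainError("region mask shape must match the head volume")
        region = np.ascontiguousarray(region_mask.astype(np.uint8))
        if not region.any():
            raise DomainError("region mask is empty")
        has_region = True
    else:
        region = np.zeros((1, 1, 1), dtype=np.uint8)
        has_region = False

    npho = config.n_photons
    out_pos = np.empty((npho, 3), dtype=np.float64)
    out_w = np.empty(npho, dtype=np.float64)
    out_paths = np.empty((npho, 4), dtype=np.float64)
    out_rpath = np.empty(npho, dtype=np.float64)
    totals_arr = np.zeros(6, dtype=np.float64)

    labels = np.ascontiguousarray(head.labels)
    n_det = _transport_kernel(
        labels, region, has_region,
        float(head.voxel_size_mm),
        float(head.origin_mm[0]), float(head.origin_mm[1]), float(head.origin_mm[2]),
        mu_a, mu_s, g, n,
        float(src[0]), float(src[1]), float(src[2]),
        float(d[0]), float(d[1]), float(d[2]),
        int(npho), int(config.seed) & 0x7FFFFFFFFFFFFFFF,
        float(config.roulette_threshold), float(config.roulette_survival),
        float(config.max_total_path_mm),
        out_pos, out_w, out_paths, out_rpath, totals_arr,
    )
    totals = {
        "launched": totals_arr[0],
        "detected": totals_arr[1],
        "absorbed": totals_arr[2],
        "terminated": totals_arr[3],
        "escaped": totals_arr[4],
        "roulette_gain": totals_arr[5],
    }
    return SimulationResult(
        exit_positions_mm=out_pos[:n_det].copy(),
        exit_weights=out_w[:n_det].copy(),
        paths_by_tissue_mm=out_paths[:n_det].copy(),
        region_paths_mm=out_rpath[:n_det].copy(),
        totals=totals,
        config=config,
        source_position_mm=src,
        source_direction=d,
    )


CHANNEL_COLUMNS = [
    "source", "detector", "rho_mm", "intensity",
    "mean_total_path_mm", "mean_brain_path_mm",
    "region_intensity", "n_detected",
]


def detect_channels(
    result: SimulationResult,
    optodes: OptodeSet,
    source_label: str,
    head: HeadModel,
    mode: str = "aperture",
) -> pd.DataFrame:
    """Pool detected photons into per-detector channel measurements.

    ``aperture`` mode assigns each exit photon to every detector within
    ``detector_aperture_mm`` (Euclidean); ``nearest`` mode partitions all
    exits by nearest detector.  Mean pathlengths are exit-weight-weighted;
    ``rho_mm`` is the scalp arc distance from the source.  Channels with no
    detected photons carry intensity 0 and NaN means.
    """
    from scipy.spatial import cKDTree

    if mode not in ("aperture", "nearest"):
        raise ConfigurationError(f"unknown detection mode {mode!r}")
    n_launched = result.totals["launched"]
    src_i = optodes.index(source_label)
    src_pos = optodes.positions_mm[src_i]
    exits = result.exit_positions_mm
    w = result.exit_weights
    tot = result.total_paths_mm
    brain = result.paths_by_tissue_mm[:, 3]
    rpath = result.region_paths_mm

    rows = []
    det_idx: list[np.ndarray]
    if exits.shape[0] == 0:
        det_idx = [np.empty(0, dtype=int)] * len(optodes)
    elif mode == "aperture":
        tree = cKDTree(exits)
        det_idx = [np.asarray(tree.query_ball_point(
            optodes.positions_mm[i], result.config.detector_aperture_mm), dtype=int)
            for i in range(len(optodes))]
    else:
        tree = cKDTree(optodes.positions_mm)
        _, nearest = tree.query(exits)
        det_idx = [np.flatnonzero(nearest == i) for i in range(len(optodes))]

    for i, lab in enumerate(optodes.labels):
        if i == src_i:
            continue
        sel = det_idx[i]
        rho = scalp_arc_distance(head, src_pos, optodes.positions_mm[i])
        if sel.size == 0:
            rows.append((source_label, lab, rho, 0.0, np.nan, np.nan, 0.0, 0))
            continue
        ws = w[sel]
        wsum = ws.sum()
        rows.append((
            source_label, lab, rho,
            wsum / n_launched,
            float(np.average(tot[sel], weights=ws)),
            float(np.average(brain[sel], weights=ws)),
            float(ws[rpath[sel] > 0].sum() / n_launched),
            int(sel.size),
        ))
    return pd.DataFrame(rows, columns=CHANNEL_COLUMNS)


def sensitivity_db(
    channels: pd.DataFrame,
    rho_range_mm: tuple[float, float] = (25.0, 35.0),
    accessibility_threshold_db: float = -40.0,
) -> tuple[float, bool]:
    """Region sensitivity in dB at ~30 mm source-detector spacing.

    ``10*log10`` of the region-reaching detected weight fraction, maximized
    over channels whose separation falls in ``rho_range_mm``.  Returns the
    value and whether the region clears the accessibility threshold.
    Requires channels computed from a simulation run with a region mask.
    """
    sel = channels[(channels.rho_mm >= rho_range_mm[0])
                   & (channels.rho_mm <= rho_range_mm[1])]
    if len(sel) == 0:
        raise DomainError("no channels in the requested separation range")
    best = float(sel.region_intensity.max())
    if best <= 0.0:
        return float("-inf"), False
    value = 10.0 * np.log10(best)
    return value, bool(value >= accessibility_threshold_db)
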