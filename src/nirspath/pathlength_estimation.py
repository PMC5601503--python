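"""Differential and partial pathlength factor estimation.

DPF and PPF relate the mean photon pathlength (total, and brain-only) to
the source-detector scalp separation rho.  Per source position they are
estimated from the channels at rho in [10, 40] mm by iteratively reweighted
least squares with the Tukey bisquare weight function (c = 4.685), seeded
by intensity weights so that sparsely sampled long channels do not dominate.

Estimator modes
---------------
``slope`` (default, through-origin): DPF is the robust slope of mean total
path on rho constrained through the origin — the direct rendering of the
defining proportionality ``path = DPF * L``.  On layered heads with a
transparent CSF shell the path-separation relation is noticeably concave,
so an unconstrained intercept absorbs most of the signal and its slope no
longer measures path per unit separation; the intercept variant remains
available (``intercept=True``).  ``ratio`` mode returns the weighted mean
of per-channel path/rho ratios instead of a regression slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, FitError, InsufficientDataError

__all__ = [
    "PathlengthFactors",
    "channel_dpf",
    "channel_ppf",
    "fit_dpf_ppf",
    "pvf",
    "robust_line_fit",
]

BISQUARE_C = 4.685  # standard 95%-efficiency tuning constant


@dataclass(frozen=True)
class PathlengthFactors:
    """Fitted pathlength factors at one source position and wavelength."""

    position_label: str
    wavelength_nm: float
    dpf: float
    ppf: float
    pvf: float
    n_channels_used: int
    dpf_stderr: float
    ppf_stderr: float
    intercept_total_mm: float
    intercept_brain_mm: float
    robust_weight_sum: float

    def __post_init__(self) -> None:
        if self.dpf <= 0:
            raise DomainError(f"dpf must be > 0, got {self.dpf}")
        if not 0.0 <= self.ppf <= self.dpf * (1.0 + 1e-12):
            raise DomainError("ppf must lie in [0, dpf]")


def channel_dpf(measurement) -> float:
    """Per-channel pathlength factor: mean total path / separation."""
    return _channel_factor(measurement, "mean_total_path_mm")


def channel_ppf(measurement) -> float:
    """Per-channel brain pathlength factor: mean brain path / separation."""
    return _channel_factor(measurement, "mean_brain_path_mm")


def _channel_factor(measurement, column: str) -> float:
    rho = float(measurement["rho_mm"])
    n = int(measurement["n_detected"])
    if rho <= 0:
        raise DomainError(f"rho must be > 0, got {rho}")
    if n == 0:
        raise DomainError("channel has no detected photons; factor undefined")
    value = float(measurement[column])
    if not np.isfinite(value):
        raise DomainError(f"{column} is undefined for this channel")
    return value / rho


def robust_line_fit(
    x: np.ndarray,
    y: np.ndarray,
    base_weights: np.ndarray | None = None,
    through_origin: bool = True,
    c: float = BISQUARE_C,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[float, float, float, np.ndarray]:
    """IRLS bisquare line fit; returns (slope, intercept, slope stderr, weights).

    ``base_weights`` multiply the bisquare weights throughout (intensity
    weighting).  Raises :class:`FitError` on non-convergence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be 1-D arrays of equal length")
    n = x.size
    w0 = np.ones(n) if base_weights is None else np.asarray(base_weights, float)
    if np.any(w0 < 0) or not np.any(w0 > 0):
        raise ConfigurationError("base weights must be nonnegative, not all zero")
    w0 = w0 / w0.max()

    X = x[:, None] if through_origin else np.column_stack([x, np.ones(n)])
    p = X.shape[1]

    def wls(w):
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        return beta

    beta = wls(w0)
    w = w0.copy()
    last_delta = np.inf
    converged = False
    for it in range(max_iter):
        r = y - X @ beta
        # robust residual scale (normalized MAD), base-weighted residuals
        scale = 1.4826 * _weighted_median(np.abs(r), w0)
        if scale <= max(1e-12, 1e-12 * float(np.abs(y).max() or 1.0)):
            w = w0.copy()
            beta = wls(w)
            converged = True
            break
        u = r / (c * scale)
        wb = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        w = w0 * wb
        if not np.any(w > 0):
            raise FitError("all observations rejected by the bisquare weights")
        beta_new = wls(w)
        last_delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta)))
        if it >= max_iter // 2:
            # damp late iterations: IRLS with a re-estimated scale can enter
            # a small limit cycle; averaging breaks it without changing the
            # fixed point
            beta = 0.5 * (beta + beta_new)
        else:
            beta = beta_new
        if last_delta < tol:
            converged = True
            break
    if not converged and last_delta > 1e-4:
        raise FitError(
            f"robust fit did not converge in {max_iter} iterations "
            f"(last slope {beta[0]:.4g}, last step {last_delta:.2g})"
        )

    r = y - X @ beta
    dof = max(n - p, 1)
    s2 = float((w * r**2).sum() / (w.sum() * dof / n)) if w.sum() > 0 else 0.0
    xtx = np.linalg.inv((X * w[:, None]).T @ X)
    slope_se = float(np.sqrt(max(s2 * xtx[0, 0] * w.sum() / n, 0.0)))
    intercept = float(beta[1]) if not through_origin else 0.0
    return float(beta[0]), intercept, slope_se, w


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    if cw[-1] <= 0:
        return float(np.median(values))
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def fit_dpf_ppf(
    channels: pd.DataFrame,
    position_label: str = "",
    wavelength_nm: float = 690.0,
    rho_range_mm: tuple[float, float] = (10.0, 40.0),
    mode: str = "slope",
    intercept: bool = False,
    weighting: str = "intensity",
    min_detected: int = 10,
) -> PathlengthFactors:
    """Estimate DPF and PPF from one source's channel table.

    Channels outside ``rho_range_mm`` or with fewer than ``min_detected``
    photons are excluded.  ``weighting='intensity'`` seeds the robust fit
    with weights proportional to detected weight; ``'uniform'`` disables
    this.  See the module docstring for ``mode``/``intercept``.
    """
    if mode not in ("slope", "ratio"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if weighting not in ("intensity", "uniform"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    usable = channels[
        (channels.rho_mm >= rho_range_mm[0])
        & (channels.rho_mm <= rho_range_mm[1])
        & (channels.n_detected >= max(min_detected, 1))
        & np.isfinite(channels.mean_total_path_mm)
    ]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"only {len(usable)} usable channels in rho range {rho_range_mm}; "
            "need at least 3"
        )
    rho = usable.rho_mm.to_numpy()
    total = usable.mean_total_path_mm.to_numpy()
    brain = np.nan_to_num(usable.mean_brain_path_mm.to_numpy(), nan=0.0)
    w0 = usable.intensity.to_numpy() if weighting == "intensity" else None

    if mode == "ratio":
        w = np.ones_like(rho) if w0 is None else w0
        dpf = float(np.average(total / rho, weights=w))
        ppf = float(np.average(brain / rho, weights=w))
        nw = w / w.sum()
        dpf_se = float(np.sqrt(np.sum(nw**2 * (total / rho - dpf) ** 2)))
        ppf_se = float(np.sqrt(np.sum(nw**2 * (brain / rho - ppf) ** 2)))
        icpt_t = icpt_b = 0.0
        wsum = float(w.sum())
    else:
        dpf, icpt_t, dpf_se, w_t = robust_line_fit(
            rho, total, base_weights=w0, through_origin=not intercept)
        ppf, icpt_b, ppf_se, w_b = robust_line_fit(
            rho, brain, base_weights=w0, through_origin=not intercept)
        wsum = float(w_t.sum())

    ppf = min(max(ppf, 0.0), dpf)
    return PathlengthFactors(
        position_label=position_label,
        wavelength_nm=wavelength_nm,
        dpf=dpf,
        ppf=ppf,
        pvf=pvf(dpf, ppf),
        n_channels_used=int(len(usable)),
        dpf_stderr=dpf_se,
        ppf_stderr=ppf_se,
        intercept_total_mm=icpt_t,
        intercept_brain_mm=icpt_b,
        robust_weight_sum=wsum,
    )


def pvf(dpf: float, ppf: float) -> float:
    """Partial volume factor PVF = PPF / DPF."""
    if dpf <= 0:
        raise DomainError(f"dpf must be > 0, got {dpf}")
    return ppf / dpf
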