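"""Tissue optical properties for near-infrared photon transport.

Scattering follows the reduced-scattering power law

    mu_s'(lambda) = a * (lambda / 500 nm)^(-b)        [/mm]

and absorption is a linear mixture of the principal tissue chromophores

    mu_a = B*S*mu_a,HbO2 + B*(1-S)*mu_a,Hb + W*mu_a,water + F*mu_a,fat

with B the whole-blood volume fraction, S hemoglobin oxygen saturation,
W water fraction and F fat fraction.  The blood spectra are for whole blood
at the conventional 150 g hemoglobin / L reference concentration.

Simulations default to the printed constants in :data:`TISSUE_TABLE` (skin, skull,
CSF, brain at 690/780/808/830/850 nm) so that transport runs are anchored to
a fixed, citable property set; the power-law and mixture models are provided
for other wavelengths and compositions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ScatteringParams",
    "AbsorptionComposition",
    "ChromophoreSpectra",
    "TissueOptics",
    "SCATTERING_PARAMS",
    "TISSUE_TABLE",
    "TISSUES",
    "WAVELENGTHS_NM",
    "default_spectra",
    "reduced_scattering",
    "absorption",
    "blood_volume_fraction",
    "tabulated_properties",
    "mus_from_musp",
    "optics_to_frame",
    "optics_from_frame",
]

TISSUES = ("skin", "skull", "csf", "brain")
WAVELENGTHS_NM = (690.0, 780.0, 808.0, 830.0, 850.0)


@dataclass(frozen=True)
class ScatteringParams:
    """Power-law reduced scattering: amplitude ``a`` (/mm at 500 nm), power ``b``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"scattering amplitude a must be > 0, got {self.a}")


@dataclass(frozen=True)
class AbsorptionComposition:
    """Chromophore composition: blood volume B, saturation S, water W, fat F (fractions)."""

    B: float
    S: float
    W: float
    F: float = 0.0

    def __post_init__(self) -> None:
        for name in ("B", "S", "W", "F"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"composition fraction {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class TissueOptics:
    """Bulk optical properties of one tissue at one wavelength."""

    mu_a: float  # absorption coefficient, /mm
    mu_s_prime: float  # reduced scattering coefficient, /mm
    g: float  # scattering anisotropy (mean cosine)
    n: float  # refractive index

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s_prime < 0:
            raise ValueError("mu_a and mu_s_prime must be >= 0")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"anisotropy g={self.g} outside [0, 1)")
        if self.n < 1.0:
            raise ValueError(f"refractive index n={self.n} < 1")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s' / (1 - g), /mm."""
        return mus_from_musp(self.mu_s_prime, self.g)


# Power-law scattering parameters (a in /mm, b unitless) for the three
# scattering tissues; CSF is modeled as a near-transparent constant.
SCATTERING_PARAMS = {
    "skin": ScatteringParams(a=4.6, b=1.421),
    "skull": ScatteringParams(a=2.29, b=0.716),
    "brain": ScatteringParams(a=2.42, b=1.611),
}

# Printed property table used by the transport engine: tissue -> wavelength
# -> (mu_a /mm, mu_s' /mm, g, n).  All tissues share g = 0.89; CSF has
# n = 1.33 and a constant residual scattering of 0.01 /mm, the others n = 1.45.
TISSUE_TABLE: dict[str, dict[float, TissueOptics]] = {
    "skin": {
        690.0: TissueOptics(0.021, 2.91, 0.89, 1.45),
        780.0: TissueOptics(0.014, 2.45, 0.89, 1.45),
        808.0: TissueOptics(0.012, 2.33, 0.89, 1.45),
        830.0: TissueOptics(0.012, 2.24, 0.89, 1.45),
        850.0: TissueOptics(0.012, 2.16, 0.89, 1.45),
    },
    "skull": {
        690.0: TissueOptics(0.026, 1.82, 0.89, 1.45),
        780.0: TissueOptics(0.025, 1.67, 0.89, 1.45),
        808.0: TissueOptics(0.025, 1.62, 0.89, 1.45),
        830.0: TissueOptics(0.025, 1.59, 0.89, 1.45),
        850.0: TissueOptics(0.027, 1.57, 0.89, 1.45),
    },
    "csf": {
        690.0: TissueOptics(0.001, 0.01, 0.89, 1.33),
        780.0: TissueOptics(0.002, 0.01, 0.89, 1.33),
        808.0: TissueOptics(0.002, 0.01, 0.89, 1.33),
        830.0: TissueOptics(0.003, 0.01, 0.89, 1.33),
        850.0: TissueOptics(0.004, 0.01, 0.89, 1.33),
    },
    "brain": {
        690.0: TissueOptics(0.010, 1.44, 0.89, 1.45),
        780.0: TissueOptics(0.011, 1.18, 0.89, 1.45),
        808.0: TissueOptics(0.011, 1.12, 0.89, 1.45),
        830.0: TissueOptics(0.012, 1.07, 0.89, 1.45),
        850.0: TissueOptics(0.014, 1.03, 0.89, 1.45),
    },
}

# ---------------------------------------------------------------------------
# Embedded chromophore spectra, 650-950 nm.
#
# Molar extinction coefficients of oxy-/deoxy-hemoglobin (log10 convention,
# 1/(cm*M)) from the standard literature compilation used throughout tissue
# optics, and absorption coefficients (1/cm) of pure water and of soft-tissue
# fat.  Whole-blood absorption below is derived at 150 g Hb / L:
#   mu_a_blood = ln(10) * eps * (150 / 64500 mol/L).
# ---------------------------------------------------------------------------
_LAMBDA_NM = np.array(
    [650, 660, 670, 680, 690, 700, 710, 720, 730, 740, 750, 760, 770, 780,
     790, 800, 810, 820, 830, 840, 850, 860, 870, 880, 890, 900, 910, 920,
     930, 940, 950], dtype=float
)
_EPS_HBO2 = np.array(  # 1/(cm*M), log10 base
    [368.0, 319.6, 294.0, 277.6, 276.0, 290.0, 314.9, 348.0, 390.0, 446.0,
     518.0, 586.0, 650.0, 710.0, 774.0, 816.0, 864.0, 916.0, 974.0, 1022.0,
     1058.0, 1086.0, 1122.0, 1154.0, 1178.0, 1198.0, 1210.0, 1220.0, 1221.0,
     1214.0, 1204.0], dtype=float
)
_EPS_HB = np.array(  # 1/(cm*M), log10 base
    [3750.1, 3226.6, 2795.1, 2407.9, 2052.0, 1794.3, 1540.5, 1325.9, 1102.2,
     1115.9, 1405.2, 1548.5, 1311.9, 1075.4, 965.6, 761.7, 717.1, 693.0,
     693.0, 692.4, 691.3, 691.3, 698.6, 707.0, 724.0, 742.0, 762.0, 785.0,
     803.0, 816.0, 819.0], dtype=float
)
_MU_A_WATER_PER_CM = np.array(
    [0.0032, 0.0036, 0.0042, 0.0047, 0.0050, 0.0060, 0.0079, 0.0104, 0.0168,
     0.0266, 0.0260, 0.0256, 0.0244, 0.0236, 0.0231, 0.0220, 0.0222, 0.0262,
     0.0290, 0.0356, 0.0433, 0.0520, 0.0564, 0.0559, 0.0618, 0.0679, 0.0775,
     0.1090, 0.1820, 0.2670, 0.3880], dtype=float
)
_MU_A_FAT_PER_CM = np.array(
    [0.0120, 0.0105, 0.0093, 0.0084, 0.0078, 0.0074, 0.0072, 0.0072, 0.0076,
     0.0082, 0.0086, 0.0090, 0.0092, 0.0094, 0.0096, 0.0098, 0.0102, 0.0110,
     0.0124, 0.0146, 0.0174, 0.0210, 0.0250, 0.0290, 0.0330, 0.0400, 0.0560,
     0.0980, 0.1060, 0.0560, 0.0380], dtype=float
)

_HB_MOLAR_MASS_G_PER_MOL = 64500.0
_BLOOD_HB_G_PER_L = 150.0


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Wavelength-indexed absorption (/mm) of the four tissue chromophores.

    ``mu_hbo2`` / ``mu_hb`` are for fully oxygenated / deoxygenated *whole
    blood* at the 150 g Hb / L reference.  Values between tabulated points
    are linearly interpolated.
    """

    wavelengths_nm: np.ndarray
    mu_hbo2: np.ndarray
    mu_hb: np.ndarray
    mu_water: np.ndarray
    mu_fat: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.mu_hbo2, self.mu_hb, self.mu_water, self.mu_fat):
            if arr.shape != self.wavelengths_nm.shape:
                raise ValueError("spectra arrays must share the wavelength grid")
            if np.any(arr <= 0):
                raise ValueError("chromophore absorption must be strictly positive")

    def _interp(self, values: np.ndarray, wavelength_nm: float) -> float:
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if not lo <= wavelength_nm <= hi:
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside spectral coverage "
                f"[{lo:g}, {hi:g}] nm"
            )
        return float(np.interp(wavelength_nm, self.wavelengths_nm, values))

    def hbo2(self, wavelength_nm: float) -> float:
        return self._interp(self.mu_hbo2, wavelength_nm)

    def hb(self, wavelength_nm: float) -> float:
        return self._interp(self.mu_hb, wavelength_nm)

    def water(self, wavelength_nm: float) -> float:
        return self._interp(self.mu_water, wavelength_nm)

    def fat(self, wavelength_nm: float) -> float:
        return self._interp(self.mu_fat, wavelength_nm)


def default_spectra() -> ChromophoreSpectra:
    """The embedded 650-950 nm chromophore spectra (all in /mm)."""
    c_molar = _BLOOD_HB_G_PER_L / _HB_MOLAR_MASS_G_PER_MOL  # mol/L
    ln10 = np.log(10.0)
    to_per_mm = 0.1  # 1/cm -> 1/mm
    return ChromophoreSpectra(
        wavelengths_nm=_LAMBDA_NM.copy(),
        mu_hbo2=ln10 * _EPS_HBO2 * c_molar * to_per_mm,
        mu_hb=ln10 * _EPS_HB * c_molar * to_per_mm,
        mu_water=_MU_A_WATER_PER_CM * to_per_mm,
        mu_fat=_MU_A_FAT_PER_CM * to_per_mm,
    )


def reduced_scattering(params: ScatteringParams, wavelength_nm: float) -> float:
    """mu_s'(lambda) = a * (lambda/500)^(-b), in /mm."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength_nm}")
    return params.a * (wavelength_nm / 500.0) ** (-params.b)


def absorption(
    comp: AbsorptionComposition,
    spectra: ChromophoreSpectra,
    wavelength_nm: float,
) -> float:
    """Linear chromophore mixture absorption coefficient, /mm."""
    return (
        comp.B * comp.S * spectra.hbo2(wavelength_nm)
        + comp.B * (1.0 - comp.S) * spectra.hb(wavelength_nm)
        + comp.W * spectra.water(wavelength_nm)
        + comp.F * spectra.fat(wavelength_nm)
    )


def blood_volume_fraction(
    c_hb_molar: float,
    mw_hb: float = 66458.0,
    blood_hb_density: float = _BLOOD_HB_G_PER_L,
) -> float:
    """Blood volume fraction B = c_Hb[mol/L] * MW[g/mol] / (g Hb per L blood)."""
    if c_hb_molar < 0:
        raise ValueError("hemoglobin concentration must be >= 0")
    if mw_hb <= 0 or blood_hb_density <= 0:
        raise ValueError("molar mass and blood Hb density must be > 0")
    return c_hb_molar * mw_hb / blood_hb_density


def tabulated_properties(tissue: str, wavelength_nm: float) -> TissueOptics:
    """Printed default properties for (tissue, wavelength).

    Only the five canonical wavelengths are tabulated; other wavelengths
    raise a lookup error pointing at :func:`reduced_scattering` /
    :func:`absorption`.
    """
    tissue = tissue.lower()
    if tissue not in TISSUE_TABLE:
        raise KeyError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    try:
        return TISSUE_TABLE[tissue][float(wavelength_nm)]
    except KeyError:
        raise KeyError(
            f"wavelength {wavelength_nm} nm is not tabulated "
            f"(supported: {WAVELENGTHS_NM}); use reduced_scattering() and "
            "absorption() for arbitrary wavelengths"
        ) from None


def mus_from_musp(mu_s_prime: float, g: float) -> float:
    """Scattering coefficient mu_s = mu_s' / (1 - g) (similarity relation)."""
    if not 0.0 <= g < 1.0:
        raise ValueError(f"anisotropy g={g} must lie in [0, 1)")
    return mu_s_prime / (1.0 - g)


def optics_to_frame(
    tissues: Iterable[str] = TISSUES,
    wavelengths_nm: Iterable[float] = WAVELENGTHS_NM,
) -> pd.DataFrame:
    """Tabulate properties as rows (tissue, wavelength, mu_a, mu_s_prime, g, n)."""
    rows = []
    for t in tissues:
        for w in wavelengths_nm:
            o = tabulated_properties(t, w)
            rows.append(
                {"tissue": t, "wavelength_nm": w, "mu_a": o.mu_a,
                 "mu_s_prime": o.mu_s_prime, "g": o.g, "n": o.n}
            )
    return pd.DataFrame(rows)


def optics_from_frame(frame: pd.DataFrame) -> dict[str, dict[float, TissueOptics]]:
    """Inverse of :func:`optics_to_frame` (CSV round-trip support)."""
    out: dict[str, dict[float, TissueOptics]] = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row["tissue"]), {})[float(row["wavelength_nm"])] = TissueOptics(
            float(row["mu_a"]), float(row["mu_s_prime"]), float(row["g"]), float(row["n"])
        )
    return out
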