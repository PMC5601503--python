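"""Shared fixtures.

The expensive Monte Carlo fixtures are session-scoped so the median-geometry
transport run is computed once and shared between the tests that need it.
"""

from __future__ import annotations

import numpy as np
import pytest

import nirspath as nn


def tabulated_optics(wavelength_nm: float):
    return {t: nn.tabulated_properties("skin" if t == "scalp" else t, wavelength_nm)
            for t in ("scalp", "skull", "csf", "brain")}


def median_geometry_params(**overrides) -> nn.SubjectParams:
    """Cohort median geometry: skull 2.5 mm, CSF 5.1 mm, depth 10.2 mm."""
    kw = dict(
        subject_id="median", sex="male", age_months=96.0,
        head_circumference_cm=38.8,
        scalp_radius_mm=nn.scalp_radius_from_circumference(38.8),
        skull_thickness_base_mm=2.5, csf_thickness_base_mm=5.1,
        cortical_depth_base_mm=10.2, crown_skull_multiplier=1.0,
        vertex_csf_bonus_mm=0.0, frontal_depth_offset_mm=0.0,
    )
    kw.update(overrides)
    return nn.SubjectParams(**kw)


def sphere_params(radius_mm: float = 70.0, skull: float = 2.6,
                  csf: float = 5.1, depth: float = 10.2) -> nn.SubjectParams:
    """A perfectly spherical uniform head (no regional modulation)."""
    return nn.SubjectParams(
        subject_id="sphere", sex="male", age_months=96.0,
        head_circumference_cm=38.8,
        scalp_radius_mm=radius_mm,
        skull_thickness_base_mm=skull, csf_thickness_base_mm=csf,
        cortical_depth_base_mm=depth, crown_skull_multiplier=1.0,
        vertex_csf_bonus_mm=0.0, frontal_depth_offset_mm=0.0,
        aspect_ratios=(1.0, 1.0, 1.0),
    )


@pytest.fixture(scope="session")
def median_head():
    head = nn.build_head(median_geometry_params(), 1.0)
    optodes = nn.place_optodes_10_5(head)
    return head, optodes


@pytest.fixture(scope="session")
def median_sim_690(median_head):
    """1e6-photon transport run at 690 nm from the lateral C3 position."""
    head, optodes = median_head
    cfg = nn.SimulationConfig(n_photons=1_000_000, seed=7, wavelength_nm=690.0)
    res = nn.run_simulation(head, tabulated_optics(690.0), optodes.position("C3"),
                            -optodes.normal("C3"), cfg)
    channels = nn.detect_channels(res, optodes, "C3", head)
    return res, channels


@pytest.fixture(scope="session")
def default_cohort():
    return nn.sample_cohort(nn.CohortSpec(), seed=1)


@pytest.fixture(scope="session")
def matched_slab_sim():
    """Homogeneous index-matched slab run used by the diffusion-theory checks."""
    slab = nn.homogeneous_slab(size_mm=160.0, depth_mm=80.0)
    optics = {t: nn.TissueOptics(mu_a=0.01, mu_s_prime=1.0, g=0.89, n=1.0)
              for t in ("scalp", "skull", "csf", "brain")}
    cfg = nn.SimulationConfig(n_photons=250_000, seed=3,
                              max_total_path_mm=2500.0)
    res = nn.run_simulation(slab, optics, np.array([0.0, 0.0, 0.0]),
                            np.array([0.0, 0.0, -1.0]), cfg)
    return slab, res
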